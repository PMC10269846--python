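# Methods

This note records the models implemented by `coretier`, the defaults that
matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the underlying methods leave room.

## Preprocessing

Raw count tables are filtered once (no iteration): taxa whose total count
over all samples is ≤ 2 (singletons and doubletons) are removed first,
then samples with fewer than 1000 remaining reads. Doing the taxon pass
first means a sample's depth is judged on the taxa that survive, which is
the stricter and more reproducible reading of a one-shot filter.

Abundance is the Hellinger transform, `sqrt(count / row_sum)`; every
transformed sample row has unit L2 norm, so Bray–Curtis distances between
rows are bounded and dominated less by the most abundant taxa. For the
neutral-model fit the transformed table is multiplied by 1000 and rounded
to integers; columns that round to all-zero are retained and logged so the
taxon universe is stable across stages.

NMDS is non-metric SMACOF (scikit-learn) with 20 random restarts seeded
`seed, seed+1, …`; the reported stress is Kruskal stress-1 computed
against an isotonic regression of the input dissimilarities, and the
lowest-stress configuration is kept, so stress is non-increasing in the
number of restarts and runs are reproducible. Distance decay regresses
each sample pair's Bray–Curtis dissimilarity on the haversine distance
(Earth radius 6371.0088 km) between their site coordinates by OLS;
same-site pairs enter at 0 km. A sample-pair (not site-centroid) design is
the default because it uses all the data; a degenerate design (all pairs
at 0 km) is an error.

## Core tiers

Both levels of the core definition use strict `>` comparisons, and the
same threshold is applied within subcommunities (occurrence fraction) and
across them (core′ recurrence). Real subcommunities are the site
populations from the sample metadata; "simulated" subcommunities are 100
draws of 30 samples from the pooled meta-community, without replacement
(with-replacement draws are available behind a flag). The 100 draws act as
the N_comm subcommunities of the across-level definition, giving one
simulated core set per threshold.

Jaccard agreement of two empty sets is defined as 1: at very high
thresholds both real and simulated cores are empty, and treating that as
agreement keeps the agreement curve at 1 at the right edge — but empty
sets are barred from forming tiers. Non-adjacent J = 1 runs that reproduce
a set already seen at higher thresholds are merged into that tier's record
(extra intervals are kept) rather than numbered again. Core-set abundance
is the summed Hellinger mass of member taxa over all samples divided by
the table total; tier selection takes the tier closest to a target
abundance (default 50%), breaking exact ties toward the higher-threshold
tier.

Note that the lowest-threshold tier is structurally trivial: at thresholds
near 0 every observed taxon is core in both the real and subsampled data,
so the bottom tier contains the whole observed community. Meaningful tiers
sit above the occupancy of the rare tail.

## Synthetic meta-communities

The generator plants three taxon classes across `n_sites` site
subcommunities: core taxa (prevalence 0.9 everywhere by default), epidemic
taxa (prevalence 0.95 in 1 random site, 0.02 elsewhere), and a rare tail
whose per-taxon occupancy is drawn from an L-shaped scaled Beta on
[0, 0.25] with mean 0.1. The occupancy cap is deliberate: ground-truth
labels must be a *recoverable* partition, so the rare tail is kept
separated from the thresholds at which the planted core is diagnosed. With
an unbounded occupancy distribution a handful of "rare" taxa would
legitimately cross into mid-threshold core sets and the labels would no
longer mean what they claim.

Presence realizes the planted prevalence with minimal variance: in a site
of n samples a taxon with prevalence p colonizes `floor(p·n)` samples plus
a stochastically rounded remainder, chosen uniformly. A taxon planted at
0.9 therefore occurs in exactly 27 of 30 samples. i.i.d. Bernoulli
presence would make the observed site prevalence of a 0.9-prevalence taxon
fluctuate with s.d. ≈ 0.055, and the probability that five core taxa all
stay above an 0.8 occurrence threshold in all five sites is only ~0.15 per
realization — the planted structure would not be recoverable at the
thresholds it is planted for. Conditional abundances are log-normal around
class weights (core ≫ epidemic > rare, tuned so the planted core carries
roughly half the Hellinger mass), and counts are multinomial at a
negative-binomial library size (mean 5000, shape 2), emulating uneven
amplicon depth. The generator does not emulate sequencing error, chimeras,
taxonomic misassignment, or phylogenetic correlation between taxa; tests
passing on these data show algorithmic correctness, not robustness to
those artifacts.

## Neutral community model

The fit follows the standard frequency-space procedure: p_i is the mean
observed relative abundance, f_i the occurrence frequency, N the mean
library size, d = 1/N, and m minimizes the untransformed least-squares
distance between f and `1 − BetaCDF(d; Nmp, Nm(1−p))`. R² = 1 − SSE/SST
and may be negative for terrible fits; taxa never observed are excluded
from the fit but retained in reports. The 95% CIs for m and the prediction
band come from a percentile bootstrap over taxa (default 1000 replicates);
Wilson score intervals at the sample count are available as an
alternative band. The two bands answer different questions: the bootstrap
band carries parameter uncertainty only and is very tight when many taxa
are fitted, so almost any sampling noise in f lands outside it; the Wilson
band carries the binomial sampling width of a frequency estimated from
n samples and reproduces the familiar picture in which most taxa of a
neutrally assembled community are classified neutral. Both are computed by
`fit_ncm`; the bootstrap band is the default and the band method is
recorded in the fit.

The matching generator draws per-sample proportions from
`Beta(Nmp_i, Nm(1−p_i))`, detects a taxon when its proportion exceeds
1/n_reads, renormalizes the detected composition (compositional closure,
which keeps library sizes at n_reads and the data-derived N consistent
with the generator's N) and expresses rounded integer counts. Parameter
recovery at N = 1000, 500 taxa, 200 samples is within a few percent at
m ≤ 0.1 and within ~10% at m = 0.3. A residual systematic bias is
intrinsic to the plug-in procedure at these sizes: the mean *observed*
relative abundance of a near-detection taxon underestimates its source
abundance, which bends the fitted curve and shifts m̂ upward by ~6% at
m = 0.3 even on noise-free expected data, while at small m the ~20%
per-taxon noise in p̂ acts as an errors-in-variables attenuation. Because
the taxa-resampling bootstrap CI is centred on the biased estimate and
only ~±2–3% wide, its coverage of the true m falls well short of nominal
in those regimes; the acceptance suite asserts nominal coverage and the
assertion fails honestly, with the measured coverage in the message.
Source-pool abundances for recovery experiments are log-normal (σ = 1.0)
over 500 taxa, a moderate species-abundance spread.

## Dissimilarity–overlap curves

For a sample pair, overlap is the average total relative abundance on the
shared support and dissimilarity is the root Jensen–Shannon divergence
(log base 2, range [0, 1]) of the two compositions renormalized to that
support; pairs with empty shared support are skipped and counted.
Partition-restricted DOC renormalizes rows within the partition's taxa
first — compositions must sum to 1 for the divergence to be meaningful.
The curve is a LOWESS smooth (default frac 2/3) on a 50-point overlap
grid; bands come from bootstrapping samples (not pairs, default 100
replicates; self-pairs of a resampled duplicate are excluded); the null
permutes every taxon's abundance vector across samples independently. The
change point is operationalized as the start of the maximal suffix over
which the smoothed slope stays negative through the maximum observed
overlap; a curve whose final segment rises has no change point and is
rendered at the right edge. The universal-regime generator places each
sample at a position λ along an approach to one shared composition,
coupling the fraction of shared taxa carried (overlap) to the
multiplicative noise amplitude (dissimilarity); this guarantees the
negative dissimilarity–overlap trend at high overlap without integrating a
population-dynamics ODE, which is deliberate — the detection target is the
trend, not the dynamics that produce it.

## Co-occurrence networks and the D-measure

Within each subcommunity, Spearman's rho (average ranks for ties) is
computed for every taxon pair after dropping taxa constant in that
subcommunity (count logged); p-values are exact permutation p for n ≤ 9
samples and the t approximation otherwise. Edges require |rho| > 0.8 AND
p < 0.001, both strict, with raw p-values — deliberately no
multiple-testing correction, so the frequency filter across subcommunities
is the error control: combined networks keep edges present in strictly
more than 20 of the 100 bootstrap subcommunity networks. At fixture scale
(50 independent taxa × 30 samples) the per-network false-positive yield is
effectively zero.

Node metrics are degree, component-scaled (Wasserman–Faust) closeness with
isolated vertices at 0, and normalized betweenness with fractional credit
for tied shortest paths.

The structural D-measure between two graphs combines (w1 = 0.45) the
Jensen–Shannon distance between mean node-distance distributions, (w2 =
0.45) the difference of square-rooted network node dispersions (NND:
generalized JS divergence of the per-node distance distributions
normalized by log(diameter+1)), and (w3 = 0.10) the average JS distance
between sorted α-centrality distributions of the graphs and of their
complements. Numerical conventions: per-node distance distributions have a
dedicated final bin for unreachable pairs, kept aligned when supports of
different length are compared; an edgeless graph has NND 0; α-centrality
solves `c = αAᵀc + deg/(N−1)` with α = 1/(1 + spectral radius), strictly
below the reciprocal spectral radius so the series converges, and an
all-zero centrality vector (empty graph) is treated as uniform. The
measure is symmetric, exactly 0 for identical graphs, and bounded by 1
with the default weights. The test suite checks it against a second,
independently written adjacency-matrix transcription (Floyd–Warshall
distances, scipy entropies) to 1e-9 on all ≤ 8-node fixture pairs.

## Pipeline

One root seed spawns per-stage seeds (recorded in the report); all tabular
output uses fixed float formatting and sorted JSON keys, so re-running an
identical config is byte-identical. Default problem sizes for the
end-to-end synthetic run are 5 sites × 30 samples and ~250 taxa, with 100
bootstrap subcommunities — chosen so a complete run, including the
neutral-model bootstrap and DOC nulls, takes a couple of minutes on one
CPU. Stage failures abort the run with the stage name and leave a partial
report.

## Known limitations

* The tier definition inherits the trivial bottom tier (all observed
  taxa) and, at very high thresholds, empty-set agreement; consumers
  should read tiers in the mid-threshold range.
* NCM classification depends strongly on the band choice (see above).
* The DOC change point is a heuristic operationalization of a visual
  feature; curves that plateau without descending report no change point.
* Spearman networks on compositional data can pick up closure-induced
  negative correlations; the combined-network frequency filter suppresses
  but does not eliminate this.
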
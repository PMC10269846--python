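# coretier

Tiered, statistically supported core-microbiota diagnosis and
partition-aware community-assembly analysis for taxon-abundance tables.

## The problem

Microbiome studies routinely split a community into a stable, prevalent
**core** and a variable **noncore** tail, but the prevalence cutoff that
defines the core is usually picked by hand, and abundance-weighted
definitions are easily fooled by *epidemic* taxa — organisms that are
extremely prevalent at one site but absent elsewhere. `coretier`
implements a two-level prevalence definition that is robust to both
problems, validates it by bootstrap subsampling, and then asks whether the
resulting core and noncore partitions assemble differently — via the Sloan
neutral community model, dissimilarity-overlap curves, and shared
co-occurrence networks.

## The model

For subcommunity *j* with *N*<sub>samp</sub> samples, a taxon is **core′**
at threshold *t* when its occurrence fraction strictly exceeds *t*:

```
core'_j(t) = { tax_i : occurrence_i / N_samp > t }
```

and it is **core** in the meta-community of *N*<sub>comm</sub>
subcommunities when the fraction of subcommunities in which it is core′
also strictly exceeds the same *t*:

```
core(t) = { tax_i : n(tax_i in core'_j) / N_comm > t }
```

An epidemic taxon that is core′ in only 1 of 5 subcommunities is denied
membership for every *t* ≥ 0.2, no matter how abundant it is.

Sweeping *t* over every integer percent 0–99 for the real site
subcommunities **and** for 100 bootstrap subcommunities (30 samples drawn
from the pooled meta-community) yields two core sets per threshold and
their Jaccard agreement *J*. Maximal threshold runs with *J* = 1 and a
constant, nonempty set are **tiers** (numbered from high thresholds down);
the tier whose cumulative Hellinger abundance is closest to 50% defines
the core/noncore partition used downstream:

* **NCM** — the Sloan model predicts a taxon's occurrence frequency from
  its mean relative abundance *p* as `1 − BetaCDF(d; Nmp, Nm(1−p))` with
  *N* the mean community size, *m* the migration rate and *d* = 1/*N* the
  detection limit; *m* is fitted by least squares with bootstrap CIs, and
  taxa are labelled above/neutral/below the 95% band.
* **DOC** — for every sample pair, overlap (shared-taxon mass) vs root
  Jensen–Shannon dissimilarity of the shared composition; a smoothed curve
  that turns downward at high overlap (change point left of the curve end,
  slope below a taxon-permutation null) indicates universal dynamics.
* **Networks** — per-subcommunity Spearman networks (|rho| > 0.8,
  p < 0.001, strict), combined by keeping edges present in more than 20 of
  the 100 bootstrap subcommunities; node centralities and the three-term
  weighted graph D-measure (w = 0.45/0.45/0.10) compare network structure.

A fully seeded synthetic meta-community generator plants core, epidemic
and rare taxa with known labels, so every stage can be tested against
ground truth.

## Worked example

```python
import coretier as ct

spec = ct.MetaCommunitySpec(seed=42)            # 5 sites x 30 samples
table, meta, truth = ct.simulate_metacommunity(spec)

abundance = ct.hellinger(table)
real = ct.subcommunities_by_site(table, meta)
sim = ct.simulate_subcommunities(table, n_samples=30, reps=100, seed=1)
sweep = ct.threshold_sweep(real, sim, abundance)
tiers = ct.identify_tiers(sweep)
for t in tiers.tiers:
    print(f"tier {t.index}: thresholds {t.interval[0]}-{t.interval[1]}%, "
          f"{len(t.taxa)} taxa, {100*t.abundance:.1f}% of abundance")
part = ct.select_tier(tiers, target_abundance=0.5)
print(f"selected tier {part.tier_index}: core = {sorted(part.core)}")

scaled = ct.scale_round(abundance, 1000)
fit = ct.fit_ncm(scaled, seed=2, n_boot=200)
print(f"NCM: m = {fit.m:.4f}, Nm = {fit.Nm:.1f}, R^2 = {fit.r_squared:.3f}")
```

prints

```
tier 1: thresholds 30-83%, 5 taxa, 51.4% of abundance
tier 2: thresholds 0-3%, 203 taxa, 100.0% of abundance
selected tier 1: core = ['core_000', 'core_001', 'core_002', 'core_003', 'core_004']
NCM: m = 0.0023, Nm = 7.7, R^2 = 0.942
```

The sweep isolates exactly the five planted core taxa over a wide,
bootstrap-stable threshold interval (the trivial bottom tier contains
every observed taxon); they carry ~51% of the Hellinger abundance, so the
closest-to-50% rule selects them. The small fitted *Nm* reflects the
strong site structure of the planted community — dispersal limitation
produces differentiated subcommunities.

The same stages are scriptable from the shell via the `coretier` console
command (`simulate`, `core`, `ncm`, `doc`, `net`, and `run` for the whole
pipeline from a YAML config).

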
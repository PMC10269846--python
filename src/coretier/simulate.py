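"""Synthetic meta-communities with ground-truth structure.

The main generator plants three classes of taxa across a set of site
subcommunities:

* **core** taxa — highly prevalent in every site, carrying a large share of
  the abundance;
* **epidemic** taxa — highly prevalent in only one (or a few) site(s), the
  classic confounder for prevalence-based core definitions;
* **rare** taxa — a long tail with L-shaped occupancy drawn from a scaled
  Beta distribution on [0, ``rare_occupancy_max``], shared across sites
  (no site structure). The cap keeps the planted classes separable so the
  ground-truth labels remain a recoverable partition.

Presence realizes the planted per-site prevalence exactly: in a site of
``n`` samples a taxon with prevalence ``p`` colonizes ``floor(p*n)`` plus
a stochastically rounded remainder of samples, chosen uniformly without
replacement. Conditional abundances are log-normal, and integer counts
are multinomial at a negative-binomially drawn library size — mimicking
uneven amplicon sequencing depth. Additional generators produce data under the Sloan
neutral model, under "universal" vs "independent" dissimilarity-overlap
dynamics, and with planted monotone taxon-taxon associations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables import AbundanceTable, CountTable, SampleMetadata


@dataclass
class MetaCommunitySpec:
    """Parameters of one host meta-community split into site subcommunities."""

    n_sites: int = 5
    samples_per_site: int = 30
    n_core: int = 5
    core_prevalence: float = 0.9
    n_epidemic: int = 3
    epidemic_sites: int = 1
    epidemic_prevalence: float = 0.95
    epidemic_background: float = 0.02
    n_rare: int = 200
    rare_occupancy_mean: float = 0.1
    rare_occupancy_max: float = 0.25
    rare_occupancy_conc: float = 2.0
    core_weight: float = 30.0
    epidemic_weight: float = 5.0
    rare_weight: float = 1.0
    depth_mean: int = 5000
    depth_dispersion: float = 2.0
    host: str = "host_A"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_sites < 1 or self.samples_per_site < 1:
            raise ValueError("need at least one site and one sample per site")
        if self.n_core + self.n_epidemic + self.n_rare <= 0:
            raise ValueError("spec implies zero taxa")
        for name in ("core_prevalence", "epidemic_prevalence"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if not (0 < self.rare_occupancy_mean <= 1):
            raise ValueError("rare_occupancy_mean must lie in (0, 1]")
        if self.n_rare and not (self.rare_occupancy_mean < self.rare_occupancy_max <= 1):
            raise ValueError("need rare_occupancy_mean < rare_occupancy_max <= 1")
        if self.epidemic_sites > self.n_sites:
            raise ValueError("epidemic_sites cannot exceed n_sites")
        if self.depth_mean < 1 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")


@dataclass
class GroundTruth:
    """Planted labels and per-site prevalences for a simulated meta-community."""

    labels: dict[str, str]  # taxon -> {core, epidemic, rare}
    prevalence: pd.DataFrame = field(repr=False)  # sites x taxa planted prevalence

    def taxa_with(self, label: str) -> set[str]:
        return {t for t, l in self.labels.items() if l == label}


def _lognormal_weights(rng, base, sigma):
    return base * rng.lognormal(mean=0.0, sigma=sigma)


def simulate_metacommunity(
    spec: MetaCommunitySpec,
) -> tuple[CountTable, SampleMetadata, GroundTruth]:
    """Draw one host meta-community according to ``spec``.

    Deterministic for a given ``spec.seed``. Sites are laid out along a
    shallow latitude/longitude gradient so distance-decay analyses have
    non-degenerate geography.
    """
    rng = np.random.default_rng(spec.seed)
    taxa = (
        [f"core_{i:03d}" for i in range(spec.n_core)]
        + [f"epi_{i:03d}" for i in range(spec.n_epidemic)]
        + [f"rare_{i:03d}" for i in range(spec.n_rare)]
    )
    labels = {t: t.split("_")[0].replace("epi", "epidemic") for t in taxa}
    n_taxa = len(taxa)

    # planted per-site prevalence matrix
    prev = np.zeros((spec.n_sites, n_taxa))
    prev[:, : spec.n_core] = spec.core_prevalence
    for j in range(spec.n_epidemic):
        col = spec.n_core + j
        prev[:, col] = spec.epidemic_background
        hot = rng.choice(spec.n_sites, size=spec.epidemic_sites, replace=False)
        prev[hot, col] = spec.epidemic_prevalence
    if spec.n_rare:
        mu = spec.rare_occupancy_mean / spec.rare_occupancy_max
        c = spec.rare_occupancy_conc
        occ = spec.rare_occupancy_max * rng.beta(c * mu, c * (1 - mu), size=spec.n_rare)
        occ = np.clip(occ, 1e-4, spec.rare_occupancy_max)
        prev[:, spec.n_core + spec.n_epidemic :] = occ[None, :]

    # per-taxon base abundance weight (log-normal around the class weight)
    base = np.concatenate(
        [
            _lognormal_weights(rng, spec.core_weight, 0.3 * np.ones(spec.n_core)),
            _lognormal_weights(rng, spec.epidemic_weight, 0.3 * np.ones(spec.n_epidemic)),
            _lognormal_weights(rng, spec.rare_weight, 0.5 * np.ones(spec.n_rare)),
        ]
    )

    n_samples = spec.n_sites * spec.samples_per_site
    nss = spec.samples_per_site
    counts = np.zeros((n_samples, n_taxa), dtype=np.int64)
    sample_ids, sites = [], []
    fallback = int(np.argmax(base))  # host for empty presence draws
    for s in range(spec.n_sites):
        site = f"site_{s:02d}"
        # fixed-count presence: realize planted prevalence with minimal variance
        present = np.zeros((nss, n_taxa), dtype=bool)
        for j in range(n_taxa):
            k_exact = prev[s, j] * nss
            k = int(np.floor(k_exact)) + int(rng.random() < (k_exact - np.floor(k_exact)))
            if k > 0:
                present[rng.choice(nss, size=min(k, nss), replace=False), j] = True
        for r in range(nss):
            row = s * nss + r
            pres = present[r]
            if not pres.any():
                pres = pres.copy()
                pres[fallback] = True
            w = pres * base * rng.lognormal(0.0, 1.0, size=n_taxa)
            p = spec.depth_dispersion / (spec.depth_dispersion + spec.depth_mean)
            depth = max(1, int(rng.negative_binomial(spec.depth_dispersion, p)))
            counts[row] = rng.multinomial(depth, w / w.sum())
            sample_ids.append(f"{site}_s{row:04d}")
            sites.append(site)

    table = CountTable(sample_ids, taxa, counts)
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "host": spec.host,
                "site": sites,
                "latitude": [31.0 + 0.5 * int(s.split("_")[1]) for s in sites],
                "longitude": [34.8 + 0.2 * int(s.split("_")[1]) for s in sites],
            }
        )
    )
    truth = GroundTruth(
        labels, pd.DataFrame(prev, index=[f"site_{s:02d}" for s in range(spec.n_sites)], columns=taxa)
    )
    return table, meta, truth


def simulate_ncm_community(
    m: float,
    n_reads: int,
    source_abundances: np.ndarray,
    n_samples: int,
    seed: int,
) -> CountTable:
    """Communities assembled under the Sloan neutral model.

    For each sample, each taxon's local relative abundance is drawn from
    ``Beta(N*m*p_i, N*m*(1-p_i))`` with ``N = n_reads`` and ``p_i`` the
    source-pool abundance. A taxon is observed when its proportion exceeds
    the detection limit ``d = 1/n_reads`` (one individual). The observed
    community is compositionally closed — detected proportions are
    renormalized to sum 1 before being expressed as rounded counts of
    ``n_reads`` individuals — so library sizes stay at ``n_reads``. The
    occurrence frequency of taxon *i* over many samples is exactly
    ``1 - BetaCDF(1/n_reads; N*m*p_i, N*m*(1-p_i))``, the curve the
    neutral-model fit estimates.
    """
    if not (0 < m < 1):
        raise ValueError("migration probability m must lie in (0, 1)")
    p = np.asarray(source_abundances, dtype=float)
    if np.any(p <= 0):
        raise ValueError("source abundances must be strictly positive")
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    nm = n_reads * m
    props = rng.beta(nm * p[None, :], nm * (1 - p)[None, :], size=(n_samples, p.size))
    detected = props > 1.0 / n_reads
    kept = props * detected
    totals = kept.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    kept /= totals
    counts = np.where(detected, np.maximum(1, np.rint(kept * n_reads)), 0).astype(np.int64)
    return CountTable(
        [f"s{i:04d}" for i in range(n_samples)],
        [f"t{j:04d}" for j in range(p.size)],
        counts,
    )


def simulate_doc_regimes(
    regime: str,
    n_samples: int = 40,
    n_taxa: int = 60,
    noise: float = 1.0,
    seed: int = 0,
) -> AbundanceTable:
    """Relative-abundance tables with or without universal dynamics.

    ``universal``: all samples are noisy perturbations of one shared
    composition. Each sample sits at a position ``lam`` in (0, 1] along an
    approach to the shared state: samples with high ``lam`` carry more of
    the shared taxa (higher pairwise overlap) and proportionally less
    multiplicative noise (lower dissimilarity), so dissimilarity falls with
    overlap at high overlap — the signature a dissimilarity-overlap curve
    detects. With ``noise=0`` every sample is exactly proportional to the
    shared composition on its own support, so any pair's dissimilarity over
    shared taxa is 0.

    ``independent``: every sample's composition is drawn independently, so
    overlap carries no information about dissimilarity.
    """
    if n_taxa < 10:
        raise ValueError("need at least 10 taxa")
    rng = np.random.default_rng(seed)
    if regime == "universal":
        q = rng.lognormal(0.0, 1.5, size=n_taxa)
        q /= q.sum()
        anchor = int(np.argmax(q))
        lam = rng.uniform(0.2, 1.0, size=n_samples)
        values = np.zeros((n_samples, n_taxa))
        for k in range(n_samples):
            present = rng.random(n_taxa) < (0.25 + 0.7 * lam[k])
            present[anchor] = True
            w = present * q * np.exp(noise * (1 - lam[k]) * rng.normal(size=n_taxa))
            values[k] = w / w.sum()
    elif regime == "independent":
        sigma = max(noise, 0.5)
        values = np.zeros((n_samples, n_taxa))
        for k in range(n_samples):
            present = rng.random(n_taxa) < 0.5
            if not present.any():
                present[0] = True
            w = present * rng.lognormal(0.0, sigma, size=n_taxa)
            values[k] = w / w.sum()
    else:
        raise ValueError(f"unknown regime {regime!r}; use 'universal' or 'independent'")
    return AbundanceTable(
        [f"s{i:04d}" for i in range(n_samples)],
        [f"t{j:04d}" for j in range(n_taxa)],
        values,
    )


def plant_correlated_pairs(
    t: CountTable,
    pairs: list[tuple[str, str, int]],
    seed: int = 0,
    noise: float = 0.0,
) -> CountTable:
    """Rewrite selected taxa as monotone functions of partner taxa.

    For each ``(a, b, sign)``, taxon ``b``'s column is replaced with a
    monotone (sign=+1) or anti-monotone (sign=-1) noisy function of taxon
    ``a``'s column. With ``noise=0`` the map preserves the tie pattern of
    ``a`` exactly, so Spearman rho is exactly +/-1. All other columns are
    untouched.
    """
    rng = np.random.default_rng(seed)
    pos = {tax: j for j, tax in enumerate(t.taxon_ids)}
    counts = t.counts.copy()
    for a, b, sign in pairs:
        if a not in pos or b not in pos:
            missing = a if a not in pos else b
            raise KeyError(f"pair references missing taxon {missing!r}")
        x = counts[:, pos[a]].astype(float)
        if sign >= 0:
            y = 2.0 * x + 1.0
        else:
            y = x.max() - x
        if noise > 0:
            scale = noise * max(x.std(), 1.0)
            y = np.maximum(0.0, y + rng.normal(0.0, scale, size=x.size))
        counts[:, pos[b]] = np.rint(y).astype(np.int64)
    return CountTable(list(t.sample_ids), list(t.taxon_ids), counts)


def beta_occurrence_curve(p: np.ndarray, n_reads: int, m: float) -> np.ndarray:
    """Analytic occurrence-frequency curve of the Sloan neutral model."""
    nm = n_reads * m
    return 1.0 - stats.beta.cdf(1.0 / n_reads, nm * p, nm * (1 - p))
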
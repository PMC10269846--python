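"""Tiered, prevalence-based core-microbiota diagnosis.

A taxon is core' within a subcommunity when its occurrence fraction
strictly exceeds a threshold; it is core in the meta-community when it is
core' in a fraction of subcommunities strictly exceeding the same
threshold. Sweeping the threshold over every integer percent 0..99 for
both the real site subcommunities and bootstrap-subsampled ("simulated")
subcommunities yields, at each threshold, a real and a simulated core set
and their Jaccard agreement. Maximal contiguous threshold runs with
J = 1 and a constant, nonempty core set are *tiers*, numbered from the
highest threshold downward; the tier whose cumulative relative abundance
is closest to a target (50% by default) defines the core/noncore
partition used by the downstream assembly analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import AbundanceTable, CountTable, SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class SubcommunityView:
    """A labelled subset of a count table's samples.

    Presence is always derived from the stored counts (count > 0), never
    stored separately, so the two can never disagree.
    """

    label: str
    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray  # samples x taxa

    @classmethod
    def from_table(cls, t: CountTable, indices, label: str) -> "SubcommunityView":
        idx = np.asarray(indices)
        return cls(
            label,
            [t.sample_ids[i] for i in idx],
            list(t.taxon_ids),
            t.counts[idx],
        )

    @property
    def presence(self) -> np.ndarray:
        return self.counts > 0

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    def occurrence_fraction(self) -> np.ndarray:
        return self.presence.mean(axis=0)


def subcommunities_by_site(t: CountTable, m: SampleMetadata) -> list[SubcommunityView]:
    """One view per site (host x location population), in site order."""
    sites = m.sites_for(t.sample_ids)
    views = []
    for site in sorted(sites.unique()):
        idx = np.flatnonzero((sites == site).to_numpy())
        views.append(SubcommunityView.from_table(t, idx, str(site)))
    return views


def core_prime(sub: SubcommunityView, thres: float) -> set[str]:
    """Taxa whose occurrence fraction strictly exceeds ``thres`` in ``sub``."""
    if sub.n_samples < 1:
        raise ValueError("subcommunity has no samples")
    if not (0 <= thres < 1):
        raise ValueError("threshold must lie in [0, 1)")
    frac = sub.occurrence_fraction()
    return {sub.taxon_ids[j] for j in np.flatnonzero(frac > thres)}


def core_set(subs: list[SubcommunityView], thres: float) -> set[str]:
    """Taxa that are core' in a fraction of subcommunities strictly above ``thres``.

    The same threshold is applied at both levels: within each subcommunity
    (occurrence fraction) and across subcommunities (core' recurrence).
    """
    if not subs:
        raise ValueError("need at least one subcommunity")
    universe = subs[0].taxon_ids
    for s in subs[1:]:
        if s.taxon_ids != universe:
            raise ValueError("subcommunities must share one taxon universe")
    occ = np.stack([s.occurrence_fraction() for s in subs])  # subs x taxa
    recurrence = (occ > thres).mean(axis=0)
    return {universe[j] for j in np.flatnonzero(recurrence > thres)}


def jaccard(a: set, b: set) -> float:
    """Jaccard index |a&b|/|a|b|; J(empty, empty) is defined as 1."""
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def simulate_subcommunities(
    meta: CountTable,
    n_samples: int = 30,
    reps: int = 100,
    seed: int = 0,
    replace: bool = False,
) -> list[SubcommunityView]:
    """Bootstrap subcommunities: ``reps`` uniform subsamples of the pooled meta-community.

    Default draws ``n_samples`` samples *without* replacement per
    replicate; with-replacement draws are available behind ``replace``.
    """
    if not replace and n_samples > meta.n_samples:
        raise ValueError(
            f"cannot draw {n_samples} samples from {meta.n_samples} without replacement"
        )
    rng = np.random.default_rng(seed)
    views = []
    for r in range(reps):
        idx = rng.choice(meta.n_samples, size=n_samples, replace=replace)
        views.append(SubcommunityView.from_table(meta, idx, f"sim_{r:03d}"))
    return views


@dataclass
class CoreSweep:
    """Real and simulated core sets with Jaccard agreement, per integer threshold."""

    thresholds: np.ndarray  # integer percents 0..99
    core_real: dict[int, frozenset]
    core_sim: dict[int, frozenset]
    jaccard: dict[int, float]
    abundance_real: dict[int, float]  # summed relative abundance of the real core set
    abundance_sim: dict[int, float]
    taxon_universe: tuple[str, ...]

    def to_dataframe(self) -> pd.DataFrame:
        th = [int(t) for t in self.thresholds]
        return pd.DataFrame(
            {
                "threshold": th,
                "n_core_real": [len(self.core_real[t]) for t in th],
                "abund_real": [self.abundance_real[t] for t in th],
                "n_core_sim": [len(self.core_sim[t]) for t in th],
                "abund_sim": [self.abundance_sim[t] for t in th],
                "jaccard": [self.jaccard[t] for t in th],
            }
        )


def _set_abundance(taxa: frozenset, abundance: AbundanceTable) -> float:
    """Share of the table's total (transformed) abundance held by ``taxa``."""
    total = abundance.values.sum()
    if total == 0 or not taxa:
        return 0.0
    cols = [j for j, t in enumerate(abundance.taxon_ids) if t in taxa]
    return float(abundance.values[:, cols].sum() / total)


def threshold_sweep(
    real_subs: list[SubcommunityView],
    sim_subs: list[SubcommunityView],
    meta_abundance: AbundanceTable,
) -> CoreSweep:
    """Core sets and Jaccard agreement at every integer threshold 0..99."""
    if not real_subs or not sim_subs:
        raise ValueError("both subcommunity lists must be nonempty")
    thresholds = np.arange(100)
    core_real, core_sim, jac, ab_real, ab_sim = {}, {}, {}, {}, {}
    for th in thresholds:
        thres = th / 100.0
        cr = frozenset(core_set(real_subs, thres))
        cs = frozenset(core_set(sim_subs, thres))
        core_real[int(th)] = cr
        core_sim[int(th)] = cs
        jac[int(th)] = jaccard(set(cr), set(cs))
        ab_real[int(th)] = _set_abundance(cr, meta_abundance)
        ab_sim[int(th)] = _set_abundance(cs, meta_abundance)
    return CoreSweep(
        thresholds,
        core_real,
        core_sim,
        jac,
        ab_real,
        ab_sim,
        tuple(real_subs[0].taxon_ids),
    )


@dataclass
class Tier:
    index: int  # 1 = highest-threshold tier
    interval: tuple[int, int]  # primary (lo, hi) threshold percents, inclusive
    extra_intervals: list[tuple[int, int]]  # non-adjacent runs yielding the same set
    taxa: frozenset
    abundance: float


@dataclass
class TierTable:
    tiers: list[Tier] = field(default_factory=list)
    taxon_universe: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return bool(self.tiers)

    def is_nested(self) -> bool:
        """Lower tiers (lower thresholds) must contain every higher tier's set."""
        for hi, lo in zip(self.tiers, self.tiers[1:]):
            if not hi.taxa <= lo.taxa:
                return False
        return True

    def to_records(self) -> list[dict]:
        return [
            {
                "tier": t.index,
                "threshold_lo": t.interval[0],
                "threshold_hi": t.interval[1],
                "extra_intervals": t.extra_intervals,
                "n_taxa": len(t.taxa),
                "abundance": t.abundance,
                "taxa": sorted(t.taxa),
            }
            for t in self.tiers
        ]


def identify_tiers(sweep: CoreSweep) -> TierTable:
    """Extract tiers: maximal J=1 runs with a constant, nonempty core set.

    Thresholds are scanned from 99 downward. A run qualifies when the real
    and simulated core sets agree exactly (J = 1) and the (shared) set is
    nonempty and unchanged across the run. Non-adjacent runs that reproduce
    a set already seen at higher thresholds are merged into that tier's
    record rather than numbered again.
    """
    tiers: list[Tier] = []
    by_set: dict[frozenset, Tier] = {}
    run_set, run_hi = None, None
    ths = sorted(int(t) for t in sweep.thresholds)

    def close_run(lo: int, hi: int, taxa: frozenset) -> None:
        if taxa in by_set:
            by_set[taxa].extra_intervals.append((lo, hi))
            return
        tier = Tier(len(tiers) + 1, (lo, hi), [], taxa, sweep.abundance_real[hi])
        tiers.append(tier)
        by_set[taxa] = tier

    prev_th = None
    for th in reversed(ths):
        cr = sweep.core_real[th]
        qualifies = sweep.jaccard[th] == 1.0 and len(cr) > 0
        if qualifies and cr == run_set and prev_th == th + 1:
            pass  # run continues
        else:
            if run_set is not None:
                close_run(prev_th, run_hi, run_set)
            run_set, run_hi = (cr, th) if qualifies else (None, None)
        prev_th = th
    if run_set is not None:
        close_run(prev_th, run_hi, run_set)

    if not tiers:
        logger.warning("no threshold interval yields J=1 with a nonempty core set")
    return TierTable(tiers, sweep.taxon_universe)


@dataclass
class Partition:
    """Binary core/noncore split of the taxon universe from a chosen tier."""

    core: frozenset
    noncore: frozenset
    tier_index: int
    host: str | None = None

    def label_of(self, taxon: str) -> str:
        return "core" if taxon in self.core else "noncore"

    def to_series(self) -> pd.Series:
        taxa = sorted(self.core | self.noncore)
        return pd.Series(
            ["core" if t in self.core else "noncore" for t in taxa],
            index=taxa,
            name="partition",
        )


def select_tier(
    tiers: TierTable, target_abundance: float = 0.5, host: str | None = None
) -> Partition:
    """Pick the tier whose core-set abundance is closest to ``target_abundance``.

    Exact ties go to the higher tier (higher threshold, smaller index).
    """
    if not tiers:
        raise ValueError("tier table is empty; no tier to select")
    best = min(tiers.tiers, key=lambda t: (abs(t.abundance - target_abundance), t.index))
    universe = set(tiers.taxon_universe)
    return Partition(
        core=best.taxa,
        noncore=frozenset(universe - set(best.taxa)),
        tier_index=best.index,
        host=host,
    )
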
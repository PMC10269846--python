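"""Filtering, transformation, ordination and spatial distance decay.

Pipeline order for a raw count table: drop low-total taxa (singletons and
doubletons by default), drop shallow samples (< 1000 reads by default),
Hellinger-transform, then Bray-Curtis + NMDS for ordination and an OLS
distance-decay fit of community dissimilarity against geographic distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats
from sklearn.manifold import MDS

from .tables import AbundanceTable, CountTable, SampleMetadata, TableValidationError

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088


class EmptyResultError(ValueError):
    """Filtering removed every sample or every taxon."""


class DegenerateInputError(ValueError):
    """Input carries no usable signal (e.g. all pairwise distances zero)."""


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise TableValidationError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise TableValidationError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise TableValidationError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise TableValidationError("distances must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class Ordination:
    ids: list[str]
    coordinates: np.ndarray  # ids x k
    stress: float  # Kruskal stress-1
    n_restarts: int
    seed: int


@dataclass
class DistanceDecayFit:
    slope: float  # dissimilarity per km
    intercept: float
    r_squared: float
    n_pairs: int


def filter_table(
    t: CountTable, min_depth: int = 1000, drop_max_total: int = 2
) -> CountTable:
    """Drop rare taxa, then shallow samples.

    Taxa whose total count over all samples is <= ``drop_max_total``
    (singletons and doubletons by default) are removed first; samples whose
    remaining depth is < ``min_depth`` are removed second. Surviving row and
    column order is preserved. Applied once, not iterated.
    """
    col_totals = t.counts.sum(axis=0)
    keep_taxa = np.flatnonzero(col_totals > drop_max_total)
    if keep_taxa.size == 0:
        raise EmptyResultError("no taxa survive the low-total filter")
    counts = t.counts[:, keep_taxa]
    keep_samples = np.flatnonzero(counts.sum(axis=1) >= min_depth)
    if keep_samples.size == 0:
        raise EmptyResultError(f"no samples with depth >= {min_depth} remain")
    return CountTable(
        [t.sample_ids[i] for i in keep_samples],
        [t.taxon_ids[j] for j in keep_taxa],
        counts[keep_samples],
    )


def hellinger(t: CountTable) -> AbundanceTable:
    """Hellinger transform: sqrt of within-sample relative abundance.

    Every transformed sample row has unit L2 norm, which tempers the
    dominance of highly abundant taxa in downstream dissimilarities.
    """
    rowsums = t.counts.sum(axis=1)
    if np.any(rowsums == 0):
        bad = t.sample_ids[int(np.argmax(rowsums == 0))]
        raise DegenerateInputError(
            f"sample {bad!r} has zero total count; run filter_table first"
        )
    values = np.sqrt(t.counts / rowsums[:, None])
    return AbundanceTable(list(t.sample_ids), list(t.taxon_ids), values)


def scale_round(a: AbundanceTable, factor: int = 1000) -> CountTable:
    """Scale abundances by ``factor`` and round to integers.

    Used ahead of the neutral-model fit, which operates on integer counts.
    Taxa whose column becomes all-zero are retained (and logged), so the
    taxon universe is unchanged.
    """
    if factor <= 0:
        raise ValueError("factor must be a positive integer")
    counts = np.rint(a.values * factor).astype(np.int64)
    n_lost = int(np.sum((counts.sum(axis=0) == 0) & (a.values.sum(axis=0) > 0)))
    if n_lost:
        logger.info("scale_round: %d taxa rounded to all-zero columns", n_lost)
    return CountTable(list(a.sample_ids), list(a.taxon_ids), counts)


def bray_curtis(a: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample rows."""
    if a.n_samples < 2:
        raise ValueError("need at least two samples")
    zero_rows = np.flatnonzero(a.values.sum(axis=1) == 0)
    if zero_rows.size >= 2:
        raise DegenerateInputError(
            "Bray-Curtis undefined for pairs of all-zero samples: "
            f"{[a.sample_ids[i] for i in zero_rows[:5]]}"
        )
    d = squareform(pdist(a.values, metric="braycurtis"))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(a.sample_ids), d)


def _stress1(coords: np.ndarray, target: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against monotone-regressed targets."""
    from sklearn.isotonic import IsotonicRegression

    d_hat = pdist(coords)
    d_tgt = squareform(target, checks=False)
    iso = IsotonicRegression()
    disp = iso.fit_transform(d_tgt, d_hat)
    denom = np.sum(d_hat**2)
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d_hat - disp) ** 2) / denom))


def nmds(d: DistanceMatrix, k: int = 2, n_restarts: int = 20, seed: int = 0) -> Ordination:
    """Non-metric multidimensional scaling with random restarts.

    Runs SMACOF-based non-metric MDS ``n_restarts`` times with seeds
    ``seed, seed+1, ...`` and keeps the configuration with the lowest
    Kruskal stress-1. Deterministic for a given seed; more restarts can
    only improve (never worsen) the returned stress.
    """
    n = len(d.ids)
    if k >= n:
        raise ValueError("embedding dimension must be below the number of ids")
    best_coords, best_stress = None, np.inf
    for i in range(n_restarts):
        mds = MDS(
            n_components=k,
            metric_mds=False,
            metric="precomputed",
            init="random",
            n_init=1,
            max_iter=500,
            eps=1e-9,
            random_state=(seed + i) % (2**31),
            normalized_stress=True,
        )
        coords = mds.fit_transform(d.values)
        stress = _stress1(coords, d.values)
        if stress < best_stress:
            best_coords, best_stress = coords, stress
    if best_coords is None:
        raise RuntimeError("NMDS failed to produce any configuration")
    return Ordination(list(d.ids), best_coords, best_stress, n_restarts, seed)


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (Earth radius 6371.0088 km)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def distance_decay(d: DistanceMatrix, m: SampleMetadata) -> DistanceDecayFit:
    """OLS fit of community dissimilarity against geographic distance.

    Every distinct sample pair contributes one point: the haversine
    distance (km) between the two samples' site coordinates against their
    community dissimilarity. Same-site pairs (0 km) are included. A slope
    near zero with low R-squared indicates negligible spatial structuring
    at the scale sampled.
    """
    coords = m.coords_for(d.ids)
    iu = np.triu_indices(len(d.ids), k=1)
    geo = haversine_km(
        coords[iu[0], 0], coords[iu[0], 1], coords[iu[1], 0], coords[iu[1], 1]
    )
    dis = d.values[iu]
    if np.all(geo == 0):
        raise DegenerateInputError("all sample pairs are 0 km apart; cannot fit decay")
    res = stats.linregress(geo, dis)
    return DistanceDecayFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_pairs=len(geo),
    )


def rarefy(t: CountTable, depth: int | None = None, seed: int = 0) -> CountTable:
    """Subsample every sample to a common depth without replacement.

    ``depth`` defaults to the minimum retained library size. Samples
    shallower than ``depth`` are dropped.
    """
    rng = np.random.default_rng(seed)
    depths = t.depths
    if depth is None:
        depth = int(depths.min())
    keep = np.flatnonzero(depths >= depth)
    if keep.size == 0:
        raise EmptyResultError(f"no samples with depth >= {depth}")
    out = np.zeros((keep.size, t.n_taxa), dtype=np.int64)
    for r, i in enumerate(keep):
        pool = np.repeat(np.arange(t.n_taxa), t.counts[i])
        picked = rng.choice(pool, size=depth, replace=False)
        out[r] = np.bincount(picked, minlength=t.n_taxa)
    return CountTable([t.sample_ids[i] for i in keep], list(t.taxon_ids), out)
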
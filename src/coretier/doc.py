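"""Dissimilarity-overlap curves (DOC) with bootstrap bands and a permutation null.

For every unordered sample pair, overlap is the average total relative
abundance the two samples carry on their shared taxa, and dissimilarity is
the root Jensen-Shannon divergence (log base 2, so rJSD is in [0, 1]) of
the two compositions renormalized to the shared support. A LOWESS smooth
of dissimilarity on overlap that turns downward at high overlap indicates
host-independent ("universal") dynamics; the change point is the start of
the maximal suffix over which the smoothed slope stays negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .tables import AbundanceTable

GRID_SIZE = 50


@dataclass
class DOCPoints:
    pairs: pd.DataFrame = field(repr=False)  # sample_a, sample_b, overlap, dissimilarity
    n_skipped: int = 0  # pairs with empty shared support

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class DOCResult:
    grid: np.ndarray  # overlap grid
    curve: np.ndarray  # lowess-smoothed dissimilarity on the grid
    band_low: np.ndarray
    band_high: np.ndarray
    change_point: float | None  # overlap value, or None when the curve never turns down
    fraction_negative_slope: float
    n_boot: int
    seed: int
    lowess_frac: float


def _pair_stats(x: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    shared = (x > 0) & (y > 0)
    if not shared.any():
        return None
    overlap = float((x[shared].sum() + y[shared].sum()) / 2.0)
    xs = x[shared] / x[shared].sum()
    ys = y[shared] / y[shared].sum()
    with np.errstate(invalid="ignore"):  # sqrt of a tiny negative rounding residue
        rjsd = float(jensenshannon(xs, ys, base=2))
    if np.isnan(rjsd):  # identical (or one-taxon) restricted compositions
        rjsd = 0.0
    return overlap, rjsd


def doc_points(a: AbundanceTable, renormalize: bool = True) -> DOCPoints:
    """Overlap and rJSD for every unordered sample pair with shared taxa.

    Rows are renormalized to sum 1 (over the table's taxa — for a
    partition-restricted table this is the within-partition composition)
    unless ``renormalize=False``, in which case rows must already sum to 1.
    """
    if a.n_samples < 3:
        raise ValueError("need at least 3 samples")
    values = a.values
    if renormalize:
        values = values / values.sum(axis=1, keepdims=True)
    rows = []
    n_skipped = 0
    n = values.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            res = _pair_stats(values[i], values[j])
            if res is None:
                n_skipped += 1
                continue
            rows.append((a.sample_ids[i], a.sample_ids[j], res[0], res[1]))
    return DOCPoints(
        pd.DataFrame(rows, columns=["sample_a", "sample_b", "overlap", "dissimilarity"]),
        n_skipped,
    )


def _lowess_on_grid(
    overlap: np.ndarray, dis: np.ndarray, grid: np.ndarray, frac: float
) -> np.ndarray:
    return sm_lowess(dis, overlap, frac=frac, xvals=grid, return_sorted=False)


def find_change_point(grid: np.ndarray, curve: np.ndarray) -> float | None:
    """Start of the maximal suffix with strictly negative smoothed slope.

    Returns ``None`` when the final segment's slope is non-negative (the
    curve never turns downward through the maximum observed overlap); the
    conventional rendering then places the change-point line at the
    rightmost overlap.
    """
    slopes = np.diff(curve)
    valid = ~np.isnan(slopes)
    if not valid.any() or not (slopes[valid][-1] < 0):
        return None
    j = len(slopes) - 1
    while j >= 0 and (np.isnan(slopes[j]) or slopes[j] < 0):
        if np.isnan(slopes[j]):
            break
        j -= 1
    return float(grid[j + 1])


def fit_doc(
    points: DOCPoints,
    lowess_frac: float = 2.0 / 3.0,
    n_boot: int = 100,
    seed: int = 0,
) -> DOCResult:
    """LOWESS curve, sample-bootstrap band and change point for DOC points.

    The bootstrap resamples *samples* (not pairs) with replacement and
    refits the smoother on the pairs induced by each resample; pairs formed
    by two copies of the same original sample are excluded.
    """
    if len(points) < 20:
        raise ValueError("need at least 20 sample pairs")
    df = points.pairs
    overlap = df["overlap"].to_numpy()
    dis = df["dissimilarity"].to_numpy()
    grid = np.linspace(overlap.min(), overlap.max(), GRID_SIZE)
    curve = _lowess_on_grid(overlap, dis, grid, lowess_frac)

    samples = sorted(set(df["sample_a"]) | set(df["sample_b"]))
    pair_value: dict[tuple[str, str], tuple[float, float]] = {}
    for row in df.itertuples(index=False):
        pair_value[(row.sample_a, row.sample_b)] = (row.overlap, row.dissimilarity)
        pair_value[(row.sample_b, row.sample_a)] = (row.overlap, row.dissimilarity)

    rng = np.random.default_rng(seed)
    boot_curves = np.full((n_boot, GRID_SIZE), np.nan)
    for b in range(n_boot):
        drawn = rng.choice(samples, size=len(samples), replace=True)
        ov, di = [], []
        for i in range(len(drawn)):
            for j in range(i + 1, len(drawn)):
                if drawn[i] == drawn[j]:
                    continue
                val = pair_value.get((drawn[i], drawn[j]))
                if val is not None:
                    ov.append(val[0])
                    di.append(val[1])
        if len(ov) >= 5:
            boot_curves[b] = _lowess_on_grid(np.array(ov), np.array(di), grid, lowess_frac)
    if n_boot and np.isfinite(boot_curves).any():
        band_low = np.nanpercentile(boot_curves, 2.5, axis=0)
        band_high = np.nanpercentile(boot_curves, 97.5, axis=0)
    else:
        band_low = band_high = curve.copy()

    cp = find_change_point(grid, curve)
    frac_neg = float(np.mean(overlap > cp)) if cp is not None else 0.0
    return DOCResult(
        grid=grid,
        curve=curve,
        band_low=band_low,
        band_high=band_high,
        change_point=cp,
        fraction_negative_slope=frac_neg,
        n_boot=n_boot,
        seed=seed,
        lowess_frac=lowess_frac,
    )


def doc_null(
    a: AbundanceTable,
    reps: int = 100,
    seed: int = 0,
    lowess_frac: float = 2.0 / 3.0,
    grid: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Null DOC curves from taxon-wise permutation of abundances across samples.

    Each replicate independently shuffles every taxon's abundance vector
    over samples (preserving each taxon's value multiset), recomputes the
    pair statistics, and smooths on the shared ``grid`` (defaults to the
    grid of the observed overlap range).
    """
    rng = np.random.default_rng(seed)
    values = a.values / a.values.sum(axis=1, keepdims=True)
    curves = []
    for _ in range(reps):
        perm = values.copy()
        for j in range(perm.shape[1]):
            rng.shuffle(perm[:, j])
        rowsum = perm.sum(axis=1, keepdims=True)
        rowsum[rowsum == 0] = 1.0
        perm = perm / rowsum
        ov, di = [], []
        n = perm.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                res = _pair_stats(perm[i], perm[j])
                if res is not None:
                    ov.append(res[0])
                    di.append(res[1])
        ov, di = np.array(ov), np.array(di)
        if grid is None:
            g = np.linspace(ov.min(), ov.max(), GRID_SIZE)
        else:
            g = grid
        curves.append(_lowess_on_grid(ov, di, g, lowess_frac))
    return curves


def terminal_slope(grid: np.ndarray, curve: np.ndarray, top_frac: float = 0.2) -> float:
    """OLS slope of the smoothed curve over the top ``top_frac`` of the overlap range."""
    lo = grid.max() - top_frac * (grid.max() - grid.min())
    mask = (grid >= lo) & np.isfinite(curve)
    if mask.sum() < 2:
        return float("nan")
    coef = np.polyfit(grid[mask], curve[mask], 1)
    return float(coef[0])
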
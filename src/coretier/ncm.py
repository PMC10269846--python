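"""Sloan neutral community model: fit, bands, classification, partition summary.

The model predicts a taxon's occurrence frequency across samples from its
mean relative abundance ``p`` via ``f(p) = 1 - BetaCDF(d; N*m*p,
N*m*(1-p))`` where ``N`` is the average community size (mean row sum of
the integer table), ``m`` the migration probability and ``d`` the
detection limit (one individual, ``d = 1/N``). ``m`` is fitted by least
squares in frequency space; confidence bands come from a percentile
bootstrap over taxa (Wilson score intervals on the predicted frequency are
available as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

from .core_tiers import CoreSweep
from .tables import CountTable


class NCMFitError(RuntimeError):
    pass


def predicted_frequency(p: np.ndarray, N: float, m: float, d: float) -> np.ndarray:
    """Neutral occurrence-frequency curve, monotone non-decreasing in ``p``."""
    nm = N * m
    return 1.0 - stats.beta.cdf(d, nm * p, nm * (1.0 - p))


@dataclass
class NCMFit:
    m: float
    N: float
    r_squared: float
    detection_limit: float
    m_ci: tuple[float, float]
    taxa: pd.DataFrame = field(repr=False)  # taxon, p, f, predicted, band_low, band_high, label, fitted
    n_boot: int
    seed: int
    band_method: str = "bootstrap"

    @property
    def Nm(self) -> float:
        return self.N * self.m


def _fit_m(p: np.ndarray, f: np.ndarray, N: float, d: float) -> float:
    def sse(m: float) -> float:
        resid = f - predicted_frequency(p, N, m, d)
        return float(np.dot(resid, resid))

    res = optimize.minimize_scalar(
        sse, bounds=(1e-6, 1 - 1e-6), method="bounded", options={"xatol": 1e-10}
    )
    if not res.success:
        raise NCMFitError(f"migration-rate optimisation failed: {res}")
    return float(res.x)


def fit_ncm(t: CountTable, seed: int = 0, n_boot: int = 1000, band_method: str = "bootstrap") -> NCMFit:
    """Fit the neutral model to an integer (scaled) count table.

    Taxa observed in zero samples are excluded from the fit but retained
    in the per-taxon report. ``band_method`` is ``"bootstrap"`` (95%
    percentile band of the prediction over taxon-resampled refits, the
    default) or ``"wilson"`` (Wilson score interval of the predicted
    frequency at the sample count).
    """
    counts = t.counts
    if t.n_samples < 5:
        raise NCMFitError("need at least 5 samples")
    depths = counts.sum(axis=1)
    if np.any(depths == 0):
        raise NCMFitError("samples with zero totals present; filter first")
    rel = counts / depths[:, None]
    p = rel.mean(axis=0)
    f = (counts > 0).mean(axis=0)
    N = float(depths.mean())
    d = 1.0 / N

    fitted_mask = (f > 0) & (p > 0)
    if fitted_mask.sum() < 10:
        raise NCMFitError("need at least 10 taxa with nonzero totals")
    pf, ff = p[fitted_mask], f[fitted_mask]
    if np.all(ff == 1.0) or np.all(ff == 0.0):
        raise NCMFitError("degenerate occurrence data: all taxa present or absent everywhere")

    m_hat = _fit_m(pf, ff, N, d)
    pred_fit = predicted_frequency(pf, N, m_hat, d)
    sse = float(np.sum((ff - pred_fit) ** 2))
    sst = float(np.sum((ff - ff.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")

    pred_all = predicted_frequency(np.clip(p, 1e-12, 1), N, m_hat, d)

    rng = np.random.default_rng(seed)
    if band_method == "bootstrap":
        boot_m = np.empty(n_boot)
        boot_pred = np.empty((n_boot, p.size))
        idx_all = np.arange(pf.size)
        for b in range(n_boot):
            idx = rng.choice(idx_all, size=pf.size, replace=True)
            mb = _fit_m(pf[idx], ff[idx], N, d)
            boot_m[b] = mb
            boot_pred[b] = predicted_frequency(np.clip(p, 1e-12, 1), N, mb, d)
        if n_boot:
            m_ci = (float(np.percentile(boot_m, 2.5)), float(np.percentile(boot_m, 97.5)))
            band_low = np.percentile(boot_pred, 2.5, axis=0)
            band_high = np.percentile(boot_pred, 97.5, axis=0)
        else:
            m_ci = (m_hat, m_hat)
            band_low = band_high = pred_all
    elif band_method == "wilson":
        S = t.n_samples
        band_low, band_high = proportion_confint(
            np.rint(pred_all * S), S, alpha=0.05, method="wilson"
        )
        m_ci = (m_hat, m_hat)
    else:
        raise ValueError(f"unknown band_method {band_method!r}")

    # the band must always bracket the point prediction
    band_low = np.minimum(band_low, pred_all)
    band_high = np.maximum(band_high, pred_all)

    labels = np.where(f > band_high, "above", np.where(f < band_low, "below", "neutral"))
    taxa = pd.DataFrame(
        {
            "taxon": t.taxon_ids,
            "p": p,
            "f": f,
            "predicted": pred_all,
            "band_low": band_low,
            "band_high": band_high,
            "label": labels,
            "fitted": fitted_mask,
        }
    )
    return NCMFit(
        m=m_hat,
        N=N,
        r_squared=r2,
        detection_limit=d,
        m_ci=m_ci,
        taxa=taxa,
        n_boot=n_boot,
        seed=seed,
        band_method=band_method,
    )


def classify_taxa(fit: NCMFit) -> dict[str, str]:
    """Per-taxon neutral-fit label: above / neutral / below the 95% band."""
    df = fit.taxa
    above = df["f"] > df["band_high"]
    below = df["f"] < df["band_low"]
    labels = np.where(above, "above", np.where(below, "below", "neutral"))
    return dict(zip(df["taxon"], labels))


def partition_proportions(labels: dict[str, str], sweep: CoreSweep) -> pd.DataFrame:
    """Label proportions within core and noncore partitions across thresholds.

    At each integer threshold the sweep's real core set splits the taxon
    universe; within each side the proportions of above/neutral/below taxa
    are reported (NaN, flagged via ``core_empty``/``noncore_empty``, for an
    empty side).
    """
    universe = list(sweep.taxon_universe)
    missing = [t for t in universe if t not in labels]
    if missing:
        raise ValueError(f"labels missing for taxa: {missing[:5]}")
    lab = np.array([labels[t] for t in universe])
    rows = []
    for th in (int(t) for t in sweep.thresholds):
        core = sweep.core_real[th]
        in_core = np.array([t in core for t in universe])
        row = {"threshold": th, "core_empty": not in_core.any(), "noncore_empty": in_core.all()}
        for side, mask in (("core", in_core), ("noncore", ~in_core)):
            n = mask.sum()
            for what in ("above", "neutral", "below"):
                row[f"{side}_{what}"] = (
                    float((lab[mask] == what).sum() / n) if n else float("nan")
                )
        rows.append(row)
    return pd.DataFrame(rows)
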
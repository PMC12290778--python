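"""Resting-state metrics and prediction evaluation.

RSFA (resting-state fluctuation amplitude) is the temporal standard
deviation of the mean-normalized series after Tukey-fence outlier removal.
Functional connectivity (FC) is the signed extremum of the normalized
cross-correlation over a small lag window; simulated FC values are
sigma-weighted (multiplied by the target voxel's RSFA-like sigma) to act
as an SNR surrogate before comparison with noisy measurements.  Predicted
and measured values are compared through fixed-count binned averages and
ordinary least squares, summarized by R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TimeSeriesStats",
    "FcRecord",
    "RegressionResult",
    "rsfa",
    "cross_corr_fc",
    "sigma_weight",
    "pairwise_fc_table",
    "fc_table_to_frame",
    "binned_regression",
]


@dataclass(frozen=True)
class TimeSeriesStats:
    """Summary statistics of one mean-normalized voxel series."""

    mean: float
    sigma: float  # std of the mean-normalized series, no outlier removal
    rsfa: float  # std after Tukey-fence outlier removal
    n_used: int


@dataclass(frozen=True)
class FcRecord:
    """One voxel-pair functional-connectivity record."""

    i: int
    j: int
    class_pair: str
    r: float
    lag: int
    sigma_i: float = float("nan")
    sigma_j: float = float("nan")
    weighted: float = float("nan")


@dataclass(frozen=True)
class RegressionResult:
    """Binned predicted-vs-measured regression summary."""

    bin_size: int
    n_bins: int
    slope: float
    intercept: float
    r_squared: float
    bin_means_x: np.ndarray
    bin_means_y: np.ndarray


def rsfa(values: np.ndarray, iqr_factor: float = 1.5) -> TimeSeriesStats:
    """RSFA of a series: normalize by the mean, drop Tukey outliers, take std.

    Outlier frames are those beyond ``iqr_factor`` interquartile ranges
    outside [Q1, Q3] of the normalized series.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 8:
        raise ValueError("need a 1D series of at least 8 frames")
    m = x.mean()
    if m == 0:
        raise ValueError("series mean is zero; cannot mean-normalize")
    z = x / m
    q1, q3 = np.percentile(z, [25, 75])
    iqr = q3 - q1
    keep = (z >= q1 - iqr_factor * iqr) & (z <= q3 + iqr_factor * iqr)
    return TimeSeriesStats(
        mean=float(m),
        sigma=float(z.std()),
        rsfa=float(z[keep].std()),
        n_used=int(keep.sum()),
    )


def _norm_xcorr(a: np.ndarray, b: np.ndarray, max_lag: int) -> np.ndarray:
    """Normalized cross-correlation r(l) for l in [-max_lag, max_lag].

    r(l) correlates a[t] with b[t + l]; normalization is such that the
    zero-lag autocorrelation of any series is exactly 1.
    """
    n = len(a)
    az = (a - a.mean()) / a.std()
    bz = (b - b.mean()) / b.std()
    full = np.correlate(bz, az, mode="full") / n  # index n-1 <-> lag 0
    mid = n - 1
    return full[mid - max_lag : mid + max_lag + 1]


def cross_corr_fc(
    a: np.ndarray, b: np.ndarray, max_lag: int = 5, i: int = -1, j: int = -1,
    class_pair: str = "",
) -> FcRecord:
    """Signed-extremum cross-correlation FC between two series.

    Over lags in [-max_lag, max_lag], returns the maximum if the largest-
    magnitude extremum is positive and the minimum if negative (ties favour
    the positive extremum); the lag at the extremum is reported.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1D and of equal length")
    if max_lag >= len(a) / 4:
        raise ValueError("max_lag must be below a quarter of the series length")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance series has undefined correlation")
    r = _norm_xcorr(a, b, max_lag)
    lags = np.arange(-max_lag, max_lag + 1)
    if r.max() >= -r.min():
        k = int(np.argmax(r))
    else:
        k = int(np.argmin(r))
    return FcRecord(
        i=i, j=j, class_pair=class_pair, r=float(r[k]), lag=int(lags[k])
    )


def sigma_weight(
    rec: FcRecord,
    stats_i: TimeSeriesStats,
    stats_j: TimeSeriesStats,
    mode: str = "target",
) -> FcRecord:
    """Attach the sigma-weighted FC value ``r * sigma``.

    ``mode='target'`` multiplies by the target voxel's sigma (the default);
    ``mode='geometric'`` by sqrt(sigma_i * sigma_j).
    """
    if mode == "target":
        w = stats_j.rsfa
    elif mode == "geometric":
        w = float(np.sqrt(stats_i.rsfa * stats_j.rsfa))
    else:
        raise ValueError("mode must be 'target' or 'geometric'")
    return replace(
        rec,
        sigma_i=stats_i.rsfa,
        sigma_j=stats_j.rsfa,
        weighted=rec.r * w,
    )


_CLASS_CODE = {"artery": "A", "vein": "V"}


def pairwise_fc_table(
    run: np.ndarray,
    masks: Mapping[str, np.ndarray],
    max_lag: int = 5,
    pairs: Sequence[tuple[str, str]] | None = None,
    weight_mode: str = "target",
) -> list[FcRecord]:
    """All voxel-pair FC records within and between mask classes.

    ``run`` is a 4D (x, y, z, frame) array; ``masks`` maps class names
    (e.g. 'artery'/'vein', or shell names) to boolean volumes.  Same-class
    masks yield the n(n-1)/2 unordered pairs; cross-class masks the full
    product.  Voxels are indexed by flat position in the volume, and each
    record carries sigma statistics and the sigma-weighted value.
    """
    names = list(masks)
    for name in names:
        if not masks[name].any():
            raise ValueError(f"mask {name!r} is empty")
    if pairs is None:
        pairs = list(combinations(names, 2)) + [(n, n) for n in names]

    flat = run.reshape(-1, run.shape[-1])
    vox: dict[str, np.ndarray] = {
        name: np.flatnonzero(masks[name].reshape(-1)) for name in names
    }
    series = {name: flat[vox[name]] for name in names}
    stat = {
        name: [rsfa(s) for s in series[name]] for name in names
    }

    records: list[FcRecord] = []
    for na, nb in pairs:
        if na in _CLASS_CODE and nb in _CLASS_CODE:
            code = "".join(sorted(_CLASS_CODE[x] for x in (na, nb)))
        else:
            code = na if na == nb else f"{na}-{nb}"
        if na == nb:
            pairs_idx = list(combinations(range(len(vox[na])), 2))
        else:
            pairs_idx = [
                (p, q)
                for p in range(len(vox[na]))
                for q in range(len(vox[nb]))
            ]
        for p, q in pairs_idx:
            rec = cross_corr_fc(
                series[na][p],
                series[nb][q],
                max_lag=max_lag,
                i=int(vox[na][p]),
                j=int(vox[nb][q]),
                class_pair=code,
            )
            records.append(
                sigma_weight(rec, stat[na][p], stat[nb][q], mode=weight_mode)
            )
    return records


def fc_table_to_frame(records: Sequence[FcRecord]) -> pd.DataFrame:
    """FC records as a tidy DataFrame (TSV-ready)."""
    return pd.DataFrame(
        {
            "voxel_i": [r.i for r in records],
            "voxel_j": [r.j for r in records],
            "class": [r.class_pair for r in records],
            "r": [r.r for r in records],
            "lag": [r.lag for r in records],
            "sigma_i": [r.sigma_i for r in records],
            "sigma_j": [r.sigma_j for r in records],
            "weighted": [r.weighted for r in records],
        }
    )


def binned_regression(
    sim: np.ndarray, exp: np.ndarray, bin_size: int
) -> RegressionResult:
    """OLS of measured on predicted values after fixed-count binning.

    Pairs are sorted by the simulated (predicted) value, grouped into
    consecutive bins of ``bin_size`` (the remainder is dropped), per-bin
    means taken on both axes, and a least-squares line fit through the bin
    means; R^2 of that fit quantifies prediction quality.
    """
    sim = np.asarray(sim, float)
    exp = np.asarray(exp, float)
    if sim.shape != exp.shape or sim.ndim != 1:
        raise ValueError("sim and exp must be 1D of equal length")
    n = len(sim)
    if n < 2 * bin_size:
        raise ValueError(
            f"need at least {2 * bin_size} pairs for bin_size={bin_size}, got {n}"
        )
    order = np.argsort(sim, kind="stable")
    n_bins = n // bin_size
    use = order[: n_bins * bin_size]
    xs = sim[use].reshape(n_bins, bin_size).mean(axis=1)
    ys = exp[use].reshape(n_bins, bin_size).mean(axis=1)
    if np.ptp(xs) == 0:
        # degenerate abscissa: fall back to a flat fit
        slope, intercept = 0.0, float(ys.mean())
        ss_res = float(((ys - ys.mean()) ** 2).sum())
        ss_tot = ss_res
        r2 = 1.0 if ss_res == 0 else 0.0
    else:
        res = stats.linregress(xs, ys)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue**2)
    return RegressionResult(
        bin_size=bin_size,
        n_bins=n_bins,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        bin_means_x=xs,
        bin_means_y=ys,
    )
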
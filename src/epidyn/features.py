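"""Compact per-region time-series feature battery with robust normalization.

Each regional BOLD series is summarized by ~42 named statistics spanning
four families — distributional shape, autocorrelation/spectral structure,
entropy and variability, and nonlinear/model-based properties. Feature
rows are then normalized across regions with an outlier-robust sigmoid,

    y_i = 1 / (1 + exp(-(x_i - median(x)) / (1.35 * IQR(x)))),

(1.35 * IQR approximates the sd for Gaussian data) followed by a linear
rescale to span [0, 1] over regions. The battery deliberately stays small:
the downstream gradient analysis is battery-agnostic.
"""
from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy import signal, stats
from statsmodels.tsa.stattools import acf as _sm_acf

from .io import RegionalTimeSeries

FAMILIES = ("distribution", "autocorrelation", "entropy-variability", "nonlinear-model")

MIN_FRAMES = 64
_ACF_NLAGS = 20


@dataclasses.dataclass
class FeatureMatrix:
    """features x regions matrix of time-series summary statistics."""

    values: np.ndarray
    feature_names: list[str]
    families: list[str]
    valid_mask: np.ndarray
    subject_id: str = ""
    group: str = ""

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def select(self, mask: np.ndarray) -> "FeatureMatrix":
        mask = np.asarray(mask, dtype=bool)
        return FeatureMatrix(
            self.values[mask],
            [n for n, m in zip(self.feature_names, mask) if m],
            [f for f, m in zip(self.families, mask) if m],
            self.valid_mask[mask],
            self.subject_id,
            self.group,
        )


# ---------------------------------------------------------------- battery

def _acf_vector(x: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _sm_acf(x, nlags=_ACF_NLAGS, fft=True)


def _first_crossing(ac: np.ndarray, level: float) -> float:
    for lag in range(1, len(ac)):
        if not np.isfinite(ac[lag]):
            return np.nan
        if ac[lag] <= level:
            return float(lag)
    return float(len(ac) - 1)


def _sample_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    sd = x.std()
    if sd == 0:
        return np.nan
    r = r_frac * sd
    n = len(x)

    def count(mm: int) -> int:
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=2)
        mask = d <= r
        return int(mask.sum() - len(emb))  # exclude self-matches

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return np.nan
    return float(-np.log(a / b))


def _permutation_entropy(x: np.ndarray, order: int = 3) -> float:
    emb = np.lib.stride_tricks.sliding_window_view(x, order)
    patterns = np.argsort(emb, axis=1, kind="stable")
    codes = patterns @ (order ** np.arange(order))
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    ent = float(-(p * np.log(p)).sum())
    return ent / np.log(float(math.factorial(order)))


def _statav(x: np.ndarray, n_seg: int = 5) -> float:
    sd = x.std()
    if sd == 0:
        return np.nan
    seg = len(x) // n_seg
    means = [x[i * seg:(i + 1) * seg].mean() for i in range(n_seg)]
    return float(np.std(means) / sd)


def _sliding_sd_ratio(x: np.ndarray, n_seg: int = 5) -> float:
    sd = x.std()
    if sd == 0:
        return np.nan
    seg = len(x) // n_seg
    sds = [x[i * seg:(i + 1) * seg].std() for i in range(n_seg)]
    return float(np.mean(sds) / sd)


def _hist_entropy(x: np.ndarray, bins: int = 10) -> float:
    if x.std() == 0:
        return np.nan
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _ar_fit(x: np.ndarray, order: int):
    xc = x - x.mean()
    if xc.std() == 0:
        return None
    y = xc[order:]
    X = np.column_stack([xc[order - k - 1: len(xc) - k - 1] for k in range(order)])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid.var())


def _trev(x: np.ndarray, lag: int) -> float:
    d = x[lag:] - x[:-lag]
    denom = np.mean(d**2)
    if denom == 0:
        return np.nan
    return float(np.mean(d**3) / denom**1.5)


def _spectral(x: np.ndarray, tr: float):
    f, p = signal.periodogram(x - x.mean(), fs=1.0 / tr)
    pos = f > 0
    f, p = f[pos], p[pos]
    total = p.sum()
    out = {}
    bands = {"low": (0.01, 0.027), "mid": (0.027, 0.073), "high": (0.073, 0.1)}
    for name, (lo, hi) in bands.items():
        sel = (f >= lo) & (f < hi)
        out[f"spec_frac_{name}"] = float(p[sel].sum() / total) if total > 0 else np.nan
    out["spec_centroid"] = float((f * p).sum() / total) if total > 0 else np.nan
    ok = p > 0
    if ok.sum() >= 3:
        slope = np.polyfit(np.log(f[ok]), np.log(p[ok]), 1)[0]
        out["spec_loglog_slope"] = float(slope)
    else:
        out["spec_loglog_slope"] = np.nan
    return out


def _region_features(x: np.ndarray, tr: float) -> dict[str, tuple[str, float]]:
    """All features of one series as {name: (family, value)}."""
    out: dict[str, tuple[str, float]] = {}
    sd = x.std()

    def dist(name, val):
        out[name] = ("distribution", float(val))

    dist("mean", x.mean())
    dist("sd", sd)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dist("skewness", stats.skew(x) if sd > 0 else np.nan)
        dist("kurtosis", stats.kurtosis(x) if sd > 0 else np.nan)
    q = np.percentile(x, [5, 25, 50, 75, 95])
    for pct, val in zip((5, 25, 50, 75, 95), q):
        dist(f"quantile_{pct:02d}", val)
    dist("iqr", q[3] - q[1])
    dist("mad", np.median(np.abs(x - q[2])))
    dist("range", x.max() - x.min())
    dist("outlier_frac_2sd", np.mean(np.abs(x - x.mean()) > 2 * sd) if sd > 0 else np.nan)

    ac = _acf_vector(x) if sd > 0 else np.full(_ACF_NLAGS + 1, np.nan)
    for lag in range(1, 11):
        out[f"acf_lag_{lag:02d}"] = ("autocorrelation", float(ac[lag]))
    out["acf_first_zero_lag"] = ("autocorrelation", _first_crossing(ac, 0.0))
    out["acf_decay_time"] = ("autocorrelation", _first_crossing(ac, 1.0 / np.e))
    for name, val in (_spectral(x, tr).items() if sd > 0 else []):
        out[name] = ("autocorrelation", val)
    if sd == 0:
        for name in ("spec_frac_low", "spec_frac_mid", "spec_frac_high",
                     "spec_centroid", "spec_loglog_slope"):
            out[name] = ("autocorrelation", np.nan)

    out["sample_entropy_m2"] = ("entropy-variability", _sample_entropy(x))
    out["perm_entropy_o3"] = ("entropy-variability",
                              _permutation_entropy(x) if sd > 0 else np.nan)
    out["statav_5"] = ("entropy-variability", _statav(x))
    out["sliding_sd_ratio"] = ("entropy-variability", _sliding_sd_ratio(x))
    out["hist_entropy_10"] = ("entropy-variability", _hist_entropy(x))
    rmssd = float(np.sqrt(np.mean(np.diff(x) ** 2)))
    out["rmssd"] = ("entropy-variability", rmssd)

    ar1 = _ar_fit(x, 1)
    ar2 = _ar_fit(x, 2)
    out["ar1_coef"] = ("nonlinear-model", float(ar1[0][0]) if ar1 else np.nan)
    out["ar2_coef1"] = ("nonlinear-model", float(ar2[0][0]) if ar2 else np.nan)
    out["ar2_coef2"] = ("nonlinear-model", float(ar2[0][1]) if ar2 else np.nan)
    out["ar2_resid_var"] = ("nonlinear-model", ar2[1] if ar2 else np.nan)
    out["trev_lag1"] = ("nonlinear-model", _trev(x, 1))
    out["trev_lag2"] = ("nonlinear-model", _trev(x, 2))
    return out


def battery_feature_names() -> tuple[list[str], list[str]]:
    """Names and family tags of the full battery, in canonical order."""
    probe = np.sin(np.linspace(0, 20, 128)) + 0.1 * np.cos(np.linspace(0, 3, 128))
    feats = _region_features(probe, 2.0)
    return list(feats.keys()), [fam for fam, _ in feats.values()]


def extract_features(ts: RegionalTimeSeries) -> FeatureMatrix:
    """Compute the full battery per region of one subject.

    Constant or otherwise degenerate series yield NaN features recorded in
    ``valid_mask`` rather than raised; a feature is valid when it is finite
    for every region and non-constant across regions.
    """
    if ts.n_frames < MIN_FRAMES:
        raise ValueError(f"need at least {MIN_FRAMES} frames, got {ts.n_frames}")
    names, families = battery_feature_names()
    values = np.empty((len(names), ts.n_regions))
    for r in range(ts.n_regions):
        feats = _region_features(ts.data[r], ts.tr_seconds)
        for i, name in enumerate(names):
            values[i, r] = feats[name][1]
    finite = np.all(np.isfinite(values), axis=1)
    nonconstant = np.zeros(len(names), dtype=bool)
    nonconstant[finite] = np.ptp(values[finite], axis=1) > 0
    return FeatureMatrix(values, names, families, finite & nonconstant,
                         ts.subject_id, ts.group)


def filter_shared_features(matrices: list[FeatureMatrix]) -> list[FeatureMatrix]:
    """Keep only features valid in every subject; identical ordering for all."""
    if not matrices:
        raise ValueError("no feature matrices given")
    names0 = matrices[0].feature_names
    for fm in matrices[1:]:
        if fm.feature_names != names0:
            raise ValueError("subjects carry different feature batteries")
    shared = np.logical_and.reduce([fm.valid_mask for fm in matrices])
    if not shared.any():
        raise ValueError("no feature survives the shared-validity filter")
    return [fm.select(shared) for fm in matrices]


def robust_sigmoid_normalize(row: np.ndarray, return_raw: bool = False) -> np.ndarray:
    """Outlier-robust sigmoid across regions, then linear rescale to [0, 1]."""
    row = np.asarray(row, dtype=float)
    if len(row) < 3:
        raise ValueError("need at least 3 regions")
    med = np.median(row)
    iqr = np.percentile(row, 75) - np.percentile(row, 25)
    if iqr == 0:
        raise ValueError("zero IQR: feature cannot be robustly normalized")
    y = 1.0 / (1.0 + np.exp(-(row - med) / (1.35 * iqr)))
    if return_raw:
        return y
    return (y - y.min()) / (y.max() - y.min())


def normalize_feature_matrix(fm: FeatureMatrix) -> FeatureMatrix:
    """Apply the robust sigmoid row-wise; rows with zero IQR are dropped."""
    keep = np.ones(fm.n_features, dtype=bool)
    values = np.empty_like(fm.values)
    for i in range(fm.n_features):
        try:
            values[i] = robust_sigmoid_normalize(fm.values[i])
        except ValueError:
            keep[i] = False
    out = FeatureMatrix(values, fm.feature_names, fm.families,
                        fm.valid_mask.copy(), fm.subject_id, fm.group)
    return out.select(keep)
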
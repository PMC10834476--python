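"""Empirical/simulated agreement terms: static FC, sliding-window FCD, KS cost.

The model fit maximizes the Pearson correlation r between empirical and
simulated static FC while minimizing the two-sample Kolmogorov-Smirnov
distance between the distributions of upper-triangular FCD entries:

    cost = (1 - r) + KS

FCD uses a 30-frame (60 s at TR = 2 s) sliding window advanced one frame
at a time, so a 240-frame session yields a 211 x 211 FCD matrix. The KS
statistic is computed exactly from the two empirical CDFs (sorted
samples), not from binned histograms.
"""
from __future__ import annotations

import dataclasses

import numpy as np

DEFAULT_WINDOW_FRAMES = 30
DEFAULT_STEP_FRAMES = 1


@dataclasses.dataclass(frozen=True)
class FCDMatrix:
    """Window-by-window correlation of sliding-window FC patterns."""

    values: np.ndarray
    window_frames: int
    step_frames: int = 1

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_windows, k=1)
        return self.values[iu]


def compute_fc(ts: np.ndarray) -> np.ndarray:
    """Region-by-region Pearson correlation matrix of a regions x frames series."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 3:
        raise ValueError("need a 2-D regions x frames matrix with at least 3 frames")
    sd = ts.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"zero-variance region(s) {bad.tolist()}")
    fc = np.corrcoef(ts)
    np.fill_diagonal(fc, 1.0)
    return fc


def _windowed_fc_vectors(ts: np.ndarray, window: int, step: int):
    """Vectorized upper-triangular FC per sliding window.

    Returns (vectors, n_windows) where vectors is windows x pairs, with NaN
    for pairs involving a zero-variance region within that window.
    """
    n, frames = ts.shape
    n_windows = (frames - window) // step + 1
    iu, ju = np.triu_indices(n, k=1)
    # sliding-window sums via cumulative sums over frames
    cs = np.cumsum(ts, axis=1)
    cs2 = np.cumsum(ts * ts, axis=1)
    starts = np.arange(n_windows) * step
    ends = starts + window

    def wsum(c):
        tot = c[:, ends - 1]
        tot = tot - np.where(starts > 0, c[:, starts - 1], 0.0)
        return tot  # regions x windows

    sx = wsum(cs)
    sxx = wsum(cs2)
    var = np.maximum(sxx - sx * sx / window, 0.0)  # guard catastrophic cancellation
    # cross products per pair
    prods = ts[iu] * ts[ju]  # pairs x frames
    cp = np.cumsum(prods, axis=1)
    tot = cp[:, ends - 1] - np.where(starts > 0, cp[:, starts - 1], 0.0)
    cov = tot - sx[iu] * sx[ju] / window  # pairs x windows
    denom = np.sqrt(var[iu] * var[ju])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / denom
    r[~np.isfinite(r)] = np.nan
    return r.T, n_windows  # windows x pairs


def compute_fcd(
    ts: np.ndarray,
    window_frames: int = DEFAULT_WINDOW_FRAMES,
    step_frames: int = DEFAULT_STEP_FRAMES,
    on_degenerate: str = "fallback",
) -> FCDMatrix:
    """Functional connectivity dynamics matrix of a regions x frames series.

    A window in which some region has zero variance contributes only its
    nonzero-variance pairs. ``on_degenerate="raise"`` turns such windows
    into an error instead — fitting loops use this to reject pathological
    simulations cheaply rather than pay for the pairwise fallback.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("need a 2-D regions x frames matrix")
    n, frames = ts.shape
    if frames < window_frames + 1:
        raise ValueError("need at least window_frames + 1 frames")
    vecs, n_windows = _windowed_fc_vectors(ts, window_frames, step_frames)
    valid = np.isfinite(vecs)
    if not valid.any(axis=1).all():
        raise ValueError("a window has no nonzero-variance region pair")
    if not valid.all() and on_degenerate == "raise":
        raise ValueError("degenerate window: a region has zero variance")
    if valid.all():
        vm = vecs - vecs.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(vm, axis=1)
        fcd = (vm @ vm.T) / np.outer(norms, norms)
    else:
        # degenerate windows: correlate over pairs finite in both windows
        fcd = np.empty((n_windows, n_windows))
        for u in range(n_windows):
            for w in range(u, n_windows):
                mask = valid[u] & valid[w]
                if mask.sum() < 2:
                    raise ValueError("too few shared valid pairs between windows")
                r = np.corrcoef(vecs[u, mask], vecs[w, mask])[0, 1]
                fcd[u, w] = fcd[w, u] = r
    fcd = np.clip(fcd, -1.0, 1.0)
    np.fill_diagonal(fcd, 1.0)
    fcd = (fcd + fcd.T) / 2.0
    return FCDMatrix(fcd, window_frames, step_frames)


def _ks_from_sorted(a_sorted: np.ndarray, b_sorted: np.ndarray) -> float:
    """Exact two-sample KS statistic from two pre-sorted sample vectors."""
    allv = np.concatenate([a_sorted, b_sorted])
    cdf_a = np.searchsorted(a_sorted, allv, side="right") / len(a_sorted)
    cdf_b = np.searchsorted(b_sorted, allv, side="right") / len(b_sorted)
    return float(np.abs(cdf_a - cdf_b).max())


def fcd_ks_distance(fcd_a: FCDMatrix | np.ndarray, fcd_b: FCDMatrix | np.ndarray) -> float:
    """Exact two-sample KS statistic between upper-triangular FCD entry sets."""
    a = fcd_a.upper_triangle() if isinstance(fcd_a, FCDMatrix) else np.asarray(fcd_a).ravel()
    b = fcd_b.upper_triangle() if isinstance(fcd_b, FCDMatrix) else np.asarray(fcd_b).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty FCD upper triangle")
    return _ks_from_sorted(np.sort(a), np.sort(b))


def model_cost(
    emp_fc: np.ndarray,
    sim_fc: np.ndarray,
    emp_fcd: FCDMatrix | list[FCDMatrix],
    sim_fcd: FCDMatrix,
    emp_fcd_sorted: list[np.ndarray] | None = None,
) -> tuple[float, float, float]:
    """Fit cost (1 - r) + KS; returns (cost, r, ks).

    ``emp_fcd`` may be a list of per-subject FCD matrices, in which case the
    KS term is the mean KS distance across subjects (the FCD target is
    per-participant while the FC target is a group average).
    ``emp_fcd_sorted`` optionally supplies the pre-sorted upper-triangular
    entry vectors of ``emp_fcd`` so a fitting loop can sort them once.
    """
    emp_fc = np.asarray(emp_fc, dtype=float)
    sim_fc = np.asarray(sim_fc, dtype=float)
    if emp_fc.shape != sim_fc.shape:
        raise ValueError("FC matrices must share shape")
    iu = np.triu_indices(emp_fc.shape[0], k=1)
    r = float(np.corrcoef(emp_fc[iu], sim_fc[iu])[0, 1])
    if emp_fcd_sorted is not None:
        sim_sorted = np.sort(sim_fcd.upper_triangle())
        ks = float(np.mean([_ks_from_sorted(e, sim_sorted) for e in emp_fcd_sorted]))
    elif isinstance(emp_fcd, (list, tuple)):
        ks = float(np.mean([fcd_ks_distance(e, sim_fcd) for e in emp_fcd]))
    else:
        ks = fcd_ks_distance(emp_fcd, sim_fcd)
    return (1.0 - r) + ks, r, ks
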
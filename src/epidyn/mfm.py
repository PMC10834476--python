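"""Parametric mean-field model (pMFM) forward simulation.

A reduced Wong-Wang neural mass per cortical region, coupled through a
structural connectome, with three regional parameters — recurrent
connection strength RC, external input I, and noise amplitude sigma —
each a linear function of a cortical gradient (the FC gradient in the
empirical pipeline):

    RC_i    = a_w     * FCG_i + b_w
    I_i     = a_I     * FCG_i + b_I
    sigma_i = a_sigma * FCG_i + b_sigma

Together with the global coupling G this gives exactly 7 free
coefficients. Synaptic gating S_i evolves by Euler-Maruyama:

    dS_i = [-S_i/tau_s + gamma (1 - S_i) H(x_i)] dt + sigma_i sqrt(dt) xi
    x_i  = RC_i J S_i + G J sum_j SC_ij S_j + I_i

with the sigmoidal-linear transfer function
H(x) = (a x - b) / (1 - exp(-d (a x - b))). Neural activity drives a
Balloon-Windkessel hemodynamic model to produce BOLD.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from numba import njit

from . import constants as C


class SimulationDivergenceError(RuntimeError):
    """Non-finite or physically invalid state during integration."""


@dataclasses.dataclass(frozen=True)
class MFMCoefficients:
    """The 7 free coefficients: global coupling plus three (slope, intercept) pairs."""

    G: float
    a_w: float
    b_w: float
    a_I: float
    b_I: float
    a_sigma: float
    b_sigma: float

    N_FREE = 7

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.G, self.a_w, self.b_w, self.a_I, self.b_I, self.a_sigma, self.b_sigma]
        )

    @classmethod
    def from_array(cls, arr) -> "MFMCoefficients":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (7,):
            raise ValueError("coefficient vector must have exactly 7 entries")
        return cls(*arr)


@dataclasses.dataclass(frozen=True)
class RegionalParameters:
    """Per-region recurrent connection RC, external input I (nA), noise sd sigma."""

    rc: np.ndarray
    external_input: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        for name in ("rc", "external_input", "sigma"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.rc)
        if len(self.external_input) != n or len(self.sigma) != n:
            raise ValueError("regional parameter vectors must share length")
        if np.any(self.sigma <= 0):
            raise ValueError("all noise amplitudes sigma must be positive")

    @property
    def n_regions(self) -> int:
        return len(self.rc)

    def in_bounds(self) -> bool:
        return bool(
            np.all((self.rc >= C.RC_BOUNDS[0]) & (self.rc <= C.RC_BOUNDS[1]))
            and np.all(
                (self.external_input >= C.I_BOUNDS[0])
                & (self.external_input <= C.I_BOUNDS[1])
            )
            and np.all((self.sigma > C.SIGMA_BOUNDS[0]) & (self.sigma <= C.SIGMA_BOUNDS[1]))
        )


def regional_parameters(
    coeffs: MFMCoefficients, fcg: np.ndarray, check_bounds: bool = True
) -> RegionalParameters:
    """Map the 7 coefficients onto per-region RC / I / sigma along a gradient."""
    fcg = np.asarray(fcg, dtype=float)
    if not np.all(np.isfinite(fcg)):
        raise ValueError("gradient must be finite")
    rc = coeffs.a_w * fcg + coeffs.b_w
    ext = coeffs.a_I * fcg + coeffs.b_I
    sigma = coeffs.a_sigma * fcg + coeffs.b_sigma
    if np.any(sigma <= 0):
        raise ValueError("coefficients produce non-positive noise amplitude")
    params = RegionalParameters(rc, ext, sigma)
    if check_bounds and not params.in_bounds():
        raise ValueError("regional parameters fall outside the estimation bounds box")
    return params


def transfer_function(x):
    """Firing-rate transfer H(x) = (a x - b) / (1 - exp(-d (a x - b))), Hz.

    Continuous at a x = b with limit 1/d; strictly increasing; nonnegative.
    """
    x = np.asarray(x, dtype=float)
    y = C.A_NC * x - C.B_HZ
    dy = C.D_S * y
    with np.errstate(over="ignore", invalid="ignore"):
        out = np.where(
            np.abs(dy) < 1e-8,
            1.0 / C.D_S + y / 2.0,  # second-order series about the removable singularity
            y / (1.0 - np.exp(-dy)),
        )
    return out if out.ndim else float(out)


@njit(cache=True, fastmath=True)
def _neural_kernel(sc, rc, ext, sigma, G, dt, noise, s0, a, b, d, gamma, tau_s, J):
    n, steps = noise.shape
    S = np.empty((n, steps))
    s = s0.copy()
    s_new = np.empty(n)
    sqdt = np.sqrt(dt)
    for t in range(steps):
        for i in range(n):
            c = 0.0
            for j in range(n):
                c += sc[i, j] * s[j]
            x = rc[i] * J * s[i] + G * J * c + ext[i]
            y = a * x - b
            dy = d * y
            if abs(dy) < 1e-8:
                h = 1.0 / d + y / 2.0
            else:
                h = y / (1.0 - np.exp(-dy))
            si = s[i] + (-s[i] / tau_s + gamma * (1.0 - s[i]) * h) * dt \
                + sigma[i] * sqdt * noise[i, t]
            if not np.isfinite(si):
                return S, t
            # gating variable: clamp to [0, 1] after each step
            if si < 0.0:
                si = 0.0
            elif si > 1.0:
                si = 1.0
            s_new[i] = si
        for i in range(n):
            s[i] = s_new[i]
            S[i, t] = s[i]
    return S, -1


@njit(cache=True, fastmath=True)
def _hemo_kernel(S, dt, kappa, gamma_h, tau_h, alpha, rho, V0, k1, k2, k3):
    n, steps = S.shape
    bold = np.empty((n, steps))
    sv = np.zeros(n)
    f = np.ones(n)
    v = np.ones(n)
    q = np.ones(n)
    ia = 1.0 / alpha
    for t in range(steps):
        for i in range(n):
            dsv = S[i, t] - kappa * sv[i] - gamma_h * (f[i] - 1.0)
            df = sv[i]
            v_ia = v[i] ** ia  # reused: v**(1/alpha - 1) = v**(1/alpha) / v
            dv = (f[i] - v_ia) / tau_h
            dq = (
                f[i] * (1.0 - (1.0 - rho) ** (1.0 / f[i])) / rho
                - q[i] * v_ia / v[i]
            ) / tau_h
            sv[i] += dsv * dt
            f[i] += df * dt
            v[i] += dv * dt
            q[i] += dq * dt
            if f[i] <= 0.0 or v[i] <= 0.0 or q[i] <= 0.0 or not np.isfinite(q[i]):
                return bold, t
            bold[i, t] = V0 * (k1 * (1.0 - q[i]) + k2 * (1.0 - q[i] / v[i]) + k3 * (1.0 - v[i]))
    return bold, -1


def simulate_neural(
    sc: np.ndarray,
    params: RegionalParameters,
    G: float,
    dt_seconds: float,
    duration_seconds: float,
    seed: int | None = None,
    noise: np.ndarray | None = None,
    s_init: float = 0.001,
) -> np.ndarray:
    """Euler-Maruyama integration of the gating dynamics; returns S (regions x steps)."""
    sc = np.asarray(sc, dtype=float)
    n = params.n_regions
    if sc.shape != (n, n):
        raise ValueError("structural connectome shape does not match parameter length")
    if not np.allclose(sc, sc.T):
        raise ValueError("structural connectome must be symmetric")
    if np.any(np.abs(np.diag(sc)) > 0):
        raise ValueError("structural connectome must have a zero diagonal")
    steps = int(round(duration_seconds / dt_seconds))
    if noise is None:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal((n, steps))
    else:
        noise = np.ascontiguousarray(noise, dtype=float)
        if noise.shape != (n, steps):
            raise ValueError("noise array has wrong shape")
    s0 = np.full(n, float(s_init))
    S, bad = _neural_kernel(
        np.ascontiguousarray(sc), params.rc, params.external_input, params.sigma,
        float(G), float(dt_seconds), noise, s0,
        C.A_NC, C.B_HZ, C.D_S, C.GAMMA_KINETIC, C.TAU_S, C.J_NA,
    )
    if bad >= 0:
        raise SimulationDivergenceError(f"neural state non-finite at step {bad}")
    return S


def hemodynamic_bold(S: np.ndarray, dt_seconds: float) -> np.ndarray:
    """Balloon-Windkessel transform of gating activity to BOLD, same Euler step.

    Resting fixed point (s, f, v, q) = (0, 1, 1, 1) is preserved exactly:
    zero input yields identically zero BOLD.
    """
    S = np.ascontiguousarray(S, dtype=float)
    if S.ndim != 2:
        raise ValueError("S must be regions x steps")
    bold, bad = _hemo_kernel(
        S, float(dt_seconds),
        C.KAPPA, C.GAMMA_H, C.TAU_H, C.ALPHA_GRUBB, C.RHO_O2, C.V0, C.K1, C.K2, C.K3,
    )
    if bad >= 0:
        raise SimulationDivergenceError(f"hemodynamic state invalid at step {bad}")
    return bold


STAGE_DT = {"train": 0.05, "eval": 0.01}


def simulate_bold_session(
    sc: np.ndarray,
    params: RegionalParameters,
    G: float,
    stage: str = "eval",
    seed: int | None = None,
    noise: np.ndarray | None = None,
    duration_seconds: float = 600.0,
    discard_seconds: float = 120.0,
    tr_seconds: float = 2.0,
    dt_seconds: float | None = None,
) -> np.ndarray:
    """Simulate a BOLD session: 10 min, first 2 min discarded, sampled at TR.

    ``stage`` selects the Euler step: 50 ms for training (cheap) and 10 ms
    for evaluation (accurate); ``dt_seconds`` overrides either. Default
    timing yields (600 - 120) / 2 = 240 frames per region.
    """
    if dt_seconds is None:
        try:
            dt_seconds = STAGE_DT[stage]
        except KeyError:
            raise ValueError(f"unknown stage {stage!r}") from None
    S = simulate_neural(sc, params, G, dt_seconds, duration_seconds, seed=seed, noise=noise)
    bold = hemodynamic_bold(S, dt_seconds)
    steps_per_tr = int(round(tr_seconds / dt_seconds))
    start = int(round(discard_seconds / dt_seconds))
    n_frames = int(round((duration_seconds - discard_seconds) / tr_seconds))
    idx = start + np.arange(n_frames) * steps_per_tr
    if idx[-1] >= bold.shape[1]:
        idx = idx[idx < bold.shape[1]]
    return bold[:, idx]
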
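"""Synthetic parcellations, connectomes, and multi-group BOLD cohorts.

Everything downstream is testable without downloads: centroids are placed
on two hemispheric spherical caps (so hemisphere-wise statistics are
exercisable), structural connectomes emulate log-transformed
streamline-count matrices with exponential distance decay, and cohorts
are forward-simulated from the mean-field model with known ground-truth
regional parameters, per-subject heterogeneity, and additive Gaussian
measurement noise. Patient-like groups carry planted effects expressed
directly on regional parameters (RC or I), so effect maps can be
arbitrary spatial patterns.

The default dimensions emulate a typical resting-state study: 68 cortical
regions, 240 frames at TR = 2 s, three groups.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy.sparse.csgraph import connected_components

from . import constants as C
from .io import Parcellation, RegionalTimeSeries, VALID_NETWORKS, child_seeds
from .mfm import (
    MFMCoefficients,
    RegionalParameters,
    SimulationDivergenceError,
    regional_parameters,
    simulate_bold_session,
)


@dataclasses.dataclass
class SyntheticCohortSpec:
    """Dimensions, planted effect, and noise settings of a synthetic cohort."""

    n_regions: int = 68
    n_subjects_per_group: int = 10
    frames: int = 240
    tr_seconds: float = 2.0
    effect: np.ndarray | None = None  # per-region offset for the patient group
    effect_parameter: str = "rc"      # which regional parameter carries the effect
    input_jitter_fraction: float = 0.05  # subject sd as fraction of the I span
    snr: float = 5.0                   # sd(signal) / sd(measurement noise)
    dt_seconds: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 8:
            raise ValueError("need at least 8 regions")
        if self.n_subjects_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.effect is not None:
            self.effect = np.asarray(self.effect, dtype=float)
            if len(self.effect) != self.n_regions:
                raise ValueError("effect vector length must equal n_regions")
        if self.frames * self.tr_seconds < 240.0:
            raise ValueError("cohort too short for FCD at the default window")


def generate_parcellation(n_regions: int, seed: int = 0, radius_mm: float = 60.0
                          ) -> Parcellation:
    """Centroids on two hemispheric spherical caps with balanced network labels."""
    rng = np.random.default_rng(seed)
    n_left = n_regions // 2
    names, hemi, network, cent = [], [], [], []
    networks = [n for n in VALID_NETWORKS if n != "unassigned"]
    for side, count, x_sign in (("left", n_left, -1), ("right", n_regions - n_left, 1)):
        # quasi-uniform points on a cap (polar angle < 75 deg) facing outward
        theta = np.arccos(rng.uniform(np.cos(np.deg2rad(75)), 1.0, count))
        phi = rng.uniform(0, 2 * np.pi, count)
        x = x_sign * radius_mm * np.cos(theta)
        y = radius_mm * np.sin(theta) * np.cos(phi)
        z = radius_mm * np.sin(theta) * np.sin(phi) * 0.8
        for i in range(count):
            names.append(f"{side[0].upper()}_region_{i:03d}")
            hemi.append(side)
            network.append(networks[i % len(networks)])
            cent.append([x[i], y[i], z[i]])
    return Parcellation(tuple(names), np.array(hemi), np.array(network),
                        np.array(cent))


def generate_structural_connectome(
    n_regions: int,
    density: float = 0.35,
    decay_mm: float = 60.0,
    seed: int = 0,
    parcellation: Parcellation | None = None,
) -> np.ndarray:
    """Symmetric nonnegative connectome with log(1 + count) weights, max 1.

    Streamline-like counts decay exponentially with centroid distance
    (times lognormal multiplicative noise); the strongest edges are kept
    to reach the requested density, and the result must be a connected
    graph (density is relaxed in 0.05 steps if thresholding disconnects it).
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    if parcellation is None:
        parcellation = generate_parcellation(n_regions, seed=seed)
    if parcellation.n_regions != n_regions:
        raise ValueError("parcellation size mismatch")
    dist = parcellation.distance_matrix()
    rng = np.random.default_rng(seed)
    n = n_regions
    iu = np.triu_indices(n, k=1)
    counts = 5000.0 * np.exp(-dist[iu] / decay_mm) * rng.lognormal(0.0, 0.5, len(iu[0]))
    n_pairs = len(iu[0])
    requested = density
    while True:
        keep = max(n - 1, int(round(requested * n_pairs)))
        thresh = np.partition(counts, n_pairs - keep)[n_pairs - keep]
        kept = np.where(counts >= thresh, counts, 0.0)
        sc = np.zeros((n, n))
        sc[iu] = np.log1p(kept)
        sc = sc + sc.T
        n_comp, _ = connected_components((sc > 0).astype(int), directed=False)
        if n_comp == 1:
            break
        requested += 0.05
        if requested > 1.0:
            raise RuntimeError("could not produce a connected connectome")
    return sc / sc.max()


def default_coefficients() -> MFMCoefficients:
    """Ground-truth coefficients in the stable low-activity regime near the
    bifurcation edge, where noise propagating through the connectome yields
    structured FC (off-diagonal mean ~0.1-0.2, FC-SC correlation ~0.5)."""
    return MFMCoefficients(G=1.5, a_w=0.5, b_w=1.0, a_I=0.02, b_I=0.235,
                           a_sigma=0.0003, b_sigma=0.004)


def default_gradient(parcellation: Parcellation) -> np.ndarray:
    """A smooth sensory-association-like axis: z-scored anterior-posterior coordinate."""
    y = parcellation.centroids[:, 1]
    return (y - y.mean()) / y.std()


def generate_ground_truth(
    coeffs: MFMCoefficients, fc_gradient: np.ndarray,
    effect: np.ndarray | None = None, effect_parameter: str = "rc",
) -> RegionalParameters:
    """Regional RC / I / sigma from coefficients, clipped to the estimation box.

    An optional additive ``effect`` on RC or I plants a group difference.
    """
    fcg = np.asarray(fc_gradient, dtype=float)
    params = regional_parameters(coeffs, fcg, check_bounds=False)
    rc = params.rc.copy()
    ext = params.external_input.copy()
    sigma = params.sigma.copy()
    if effect is not None:
        effect = np.asarray(effect, dtype=float)
        if len(effect) != len(fcg):
            raise ValueError("effect length must equal the gradient length")
        if effect_parameter == "rc":
            rc = rc + effect
        elif effect_parameter in ("i", "external_input"):
            ext = ext + effect
        else:
            raise ValueError(f"unknown effect parameter {effect_parameter!r}")
    rc = np.clip(rc, *C.RC_BOUNDS)
    ext = np.clip(ext, *C.I_BOUNDS)
    sigma = np.clip(sigma, None, C.SIGMA_BOUNDS[1])
    if np.any(sigma <= 0):
        raise ValueError("ground-truth noise amplitude non-positive")
    return RegionalParameters(rc, ext, sigma)


def generate_cohort(
    spec: SyntheticCohortSpec,
    sc: np.ndarray,
    true_params_by_group: dict[str, RegionalParameters],
    G: float,
) -> list[RegionalTimeSeries]:
    """Forward-simulate one BOLD session per pseudo-subject.

    Each subject gets an independent noise seed; subject heterogeneity is
    Gaussian jitter on the external input I (sd = ``input_jitter_fraction``
    of that group's I span); additive Gaussian measurement noise at the
    configured SNR is applied after the hemodynamics. Identical spec and
    seed reproduce the cohort bit-identically.
    """
    groups = list(true_params_by_group)
    n_total = len(groups) * spec.n_subjects_per_group
    seeds = child_seeds(spec.seed, 2 * n_total)
    duration = spec.frames * spec.tr_seconds + 120.0
    subjects: list[RegionalTimeSeries] = []
    idx = 0
    for group in groups:
        base = true_params_by_group[group]
        if base.n_regions != spec.n_regions:
            raise ValueError(f"group {group!r}: parameter length mismatch")
        span = float(base.external_input.max() - base.external_input.min())
        jitter_sd = spec.input_jitter_fraction * (span if span > 0 else C.I_BOUNDS[1])
        for s in range(spec.n_subjects_per_group):
            sim_seed, noise_seed = seeds[2 * idx], seeds[2 * idx + 1]
            rng = np.random.default_rng(noise_seed)
            ext = np.clip(
                base.external_input + rng.normal(0.0, jitter_sd, spec.n_regions),
                *C.I_BOUNDS,
            )
            params = RegionalParameters(base.rc, ext, base.sigma)
            try:
                bold = simulate_bold_session(
                    sc, params, G, seed=sim_seed,
                    duration_seconds=duration, discard_seconds=120.0,
                    tr_seconds=spec.tr_seconds, dt_seconds=spec.dt_seconds,
                )
            except SimulationDivergenceError as err:
                raise SimulationDivergenceError(
                    f"subject {group}_{s:03d} (seed {sim_seed}): {err}"
                ) from err
            if spec.snr > 0:
                # SNR is defined against temporal fluctuation, not regional offsets
                noise_sd = float(bold.std(axis=1).mean()) / spec.snr
                bold = bold + rng.normal(0.0, noise_sd, bold.shape)
            subjects.append(
                RegionalTimeSeries(f"{group}_{s:03d}", group, bold, spec.tr_seconds)
            )
            idx += 1
    return subjects
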
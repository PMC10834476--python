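"""Self-contained synthetic experiments exercising the pipeline end to end.

Each function builds its own inputs from the synthetic-cohort module,
runs one stage of the pipeline under known ground truth, and returns the
measured quantity: candidate counts, parameter-recovery correlations,
type-I-error calibration rates, and surrogate variogram fidelity. They
are used by both the test suite and the results-reproduction script.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from . import synthetic
from .estimation import (
    FitProtocol,
    build_fit_targets,
    evaluate_test,
    fit_cmaes,
    select_candidates,
)
from .gradients import group_difference_map
from .io import child_seeds
from .surrogates import (
    corrected_spearman,
    gaussian_random_field,
    generate_surrogates,
    variogram_relative_error,
)


def candidate_counter_experiment(
    n_iterations: int, n_initializations: int, seed: int, n_regions: int = 8,
) -> int:
    """Run the CMA-ES stage on a small synthetic target and count candidates."""
    s_parc, s_sc, s_cohort, s_fit = child_seeds(seed, 4)
    parc = synthetic.generate_parcellation(n_regions, seed=s_parc)
    sc = synthetic.generate_structural_connectome(n_regions, density=0.6,
                                                  seed=s_sc, parcellation=parc)
    fcg = synthetic.default_gradient(parc)
    coeffs = synthetic.default_coefficients()
    truth = synthetic.generate_ground_truth(coeffs, fcg)
    spec = synthetic.SyntheticCohortSpec(n_regions=n_regions,
                                         n_subjects_per_group=2,
                                         seed=s_cohort, dt_seconds=0.05)
    cohort = synthetic.generate_cohort(spec, sc, {"HC": truth}, coeffs.G)
    target = build_fit_targets(cohort, sc, fcg=fcg)
    protocol = FitProtocol(n_iterations=n_iterations,
                           n_initializations=n_initializations, seed=s_fit)
    return len(fit_cmaes(target, protocol))


# the recovery benchmark is one fixed problem instance — geometry, ground
# truth, and cohort — exactly as an empirical study fits one dataset; the
# experiment seed drives optimizer initialization and evaluation noise
BENCHMARK_GEOMETRY_SEED = 1
BENCHMARK_CONNECTOME_SEED = 2
BENCHMARK_COHORT_SEED = 7


def parameter_recovery_experiment(
    seed: int,
    n_regions: int = 12,
    n_iterations: int = 50,
    n_initializations: int = 10,
) -> dict:
    """Fit the benchmark cohort generated by known coefficients; correlate
    the recovered regional maps with truth.

    This is a self-consistency check of the estimator: the cohort is pure
    model output (no subject-level parameter jitter, no measurement noise),
    so the only source of between-subject variability is the neuronal noise
    realization. Subject heterogeneity breaks the model's single-parameter
    assumption and, at this scale, destroys sign identifiability of the
    hierarchy slope (see the methods note). The generating gradient is
    passed to the fit targets, so the experiment isolates coefficient
    estimation from gradient re-estimation.
    """
    parc = synthetic.generate_parcellation(n_regions,
                                           seed=BENCHMARK_GEOMETRY_SEED)
    sc = synthetic.generate_structural_connectome(
        n_regions, density=0.4, seed=BENCHMARK_CONNECTOME_SEED,
        parcellation=parc)
    fcg = synthetic.default_gradient(parc)
    coeffs = synthetic.default_coefficients()
    truth = synthetic.generate_ground_truth(coeffs, fcg)
    s_cohort = child_seeds(BENCHMARK_COHORT_SEED, 1)[0]
    spec = synthetic.SyntheticCohortSpec(n_regions=n_regions,
                                         n_subjects_per_group=12, seed=s_cohort,
                                         input_jitter_fraction=0.0, snr=0.0)
    cohort = synthetic.generate_cohort(spec, sc, {"HC": truth}, coeffs.G)
    targets = {
        "train": build_fit_targets(cohort[:4], sc, fcg=fcg),
        "val": build_fit_targets(cohort[4:8], sc, fcg=fcg),
        "test": build_fit_targets(cohort[8:], sc, fcg=fcg),
    }
    protocol = FitProtocol(n_iterations=n_iterations,
                           n_initializations=n_initializations,
                           top_k_validation=10, seed=seed)
    candidates = fit_cmaes(targets["train"], protocol)
    top = select_candidates(candidates, targets["val"],
                            min(10, len(candidates)), protocol)
    best, params = evaluate_test(top, targets["test"], protocol)
    return {
        "r_rc": float(np.corrcoef(params.rc, truth.rc)[0, 1]),
        "r_i": float(np.corrcoef(params.external_input, truth.external_input)[0, 1]),
        "cost_test": best.cost_test,
        "n_candidates": len(candidates),
    }


def group_difference_calibration(
    n_reps: int = 200,
    seed: int = 0,
    n_regions: int = 12,
    n_per_group: int = 12,
    n_perm: int = 200,
    alpha: float = 0.05,
) -> float:
    """Family-wise rejection rate of the permutation map test under the null.

    Each repetition draws null maps and nuisance covariates with no group
    effect; the rate is the fraction of (repetition, hemisphere) families
    with at least one FWE-significant region. Expected ~= alpha.
    """
    rng = np.random.default_rng(seed)
    hemis = np.array(["left"] * (n_regions // 2)
                     + ["right"] * (n_regions - n_regions // 2))
    groups = np.array(["A"] * n_per_group + ["B"] * n_per_group)
    hits = []
    for _ in range(n_reps):
        maps = rng.standard_normal((2 * n_per_group, n_regions))
        cov = np.column_stack([rng.normal(30, 8, 2 * n_per_group),
                               rng.integers(0, 2, 2 * n_per_group)])
        res = group_difference_map(maps, groups, cov, hemis, n_perm=n_perm,
                                   alpha=alpha, seed=int(rng.integers(2**31 - 1)))
        for side in ("left", "right"):
            hits.append(bool(res["significant"][hemis == side].any()))
    return float(np.mean(hits))


def corrected_spearman_calibration(
    n_reps: int = 200,
    seed: int = 0,
    n_regions: int = 30,
    length_scale: float = 40.0,
    n_surrogates: int = 99,
    alpha: float = 0.05,
) -> dict:
    """Rejection rates for independent smooth maps: surrogate-corrected vs naive.

    Smooth maps are independent Gaussian-process samples; the naive rate
    uses a plain permutation null on the same pairs and is inflated by
    spatial autocorrelation, while the variogram-matched surrogate null
    should reject at ~= alpha.
    """
    rng = np.random.default_rng(seed)
    parc = synthetic.generate_parcellation(n_regions, seed=seed)
    dist = parc.distance_matrix()
    corrected_hits, naive_hits = [], []
    for _ in range(n_reps):
        x = gaussian_random_field(dist, length_scale,
                                  np.random.default_rng(int(rng.integers(2**31 - 1))))
        y = gaussian_random_field(dist, length_scale,
                                  np.random.default_rng(int(rng.integers(2**31 - 1))))
        rho, p = corrected_spearman(x, y, dist, n_surrogates=n_surrogates,
                                    seed=int(rng.integers(2**31 - 1)))
        corrected_hits.append(p < alpha)
        null = np.array([
            stats.spearmanr(np.random.default_rng(int(rng.integers(2**31 - 1))).permutation(x),
                            y).statistic
            for _ in range(n_surrogates)
        ])
        p_naive = (1 + int((np.abs(null) >= abs(rho)).sum())) / (n_surrogates + 1)
        naive_hits.append(p_naive < alpha)
    return {"corrected_rate": float(np.mean(corrected_hits)),
            "naive_rate": float(np.mean(naive_hits))}


def surrogate_contract_experiment(
    seed: int = 0,
    n_regions: int = 68,
    n_surrogates: int = 1000,
    length_scale: float = 40.0,
) -> dict:
    """Variogram fidelity of matched surrogates vs plain shuffles on a smooth map."""
    s_parc, s_map, s_surr, s_shuf = child_seeds(seed, 4)
    parc = synthetic.generate_parcellation(n_regions, seed=s_parc)
    dist = parc.distance_matrix()
    x = gaussian_random_field(dist, length_scale, np.random.default_rng(s_map))
    surr = generate_surrogates(x, dist, n_surrogates, seed=s_surr)
    rng = np.random.default_rng(s_shuf)
    shuffles = np.array([rng.permutation(x) for _ in range(n_surrogates)])
    return {
        "matched_error": variogram_relative_error(surr, x, dist),
        "shuffle_error": variogram_relative_error(shuffles, x, dist),
    }
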
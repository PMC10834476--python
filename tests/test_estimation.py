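import numpy as np
import pytest

import epidyn as ed
from epidyn.cmaes import CMAES
from epidyn.estimation import (
    FitProtocol,
    _Evaluator,
    _eval_seed,
    build_fit_targets,
    evaluate_test,
    fisher_z_mean_fc,
    fit_cmaes,
    parameter_difference_permutation,
    select_candidates,
)


@pytest.fixture(scope="module")
def small_problem(coeffs):
    """8-region cohort and targets for cheap protocol tests."""
    parc = ed.generate_parcellation(8, seed=21)
    sc = ed.generate_structural_connectome(8, density=0.6, seed=21,
                                           parcellation=parc)
    fcg = ed.default_gradient(parc)
    truth = ed.generate_ground_truth(coeffs, fcg)
    spec = ed.SyntheticCohortSpec(n_regions=8, n_subjects_per_group=6,
                                  seed=22, dt_seconds=0.05)
    cohort = ed.generate_cohort(spec, sc, {"HC": truth}, coeffs.G)
    targets = {
        "train": build_fit_targets(cohort[:2], sc, fcg=fcg),
        "val": build_fit_targets(cohort[2:4], sc, fcg=fcg),
        "test": build_fit_targets(cohort[4:], sc, fcg=fcg),
    }
    return sc, fcg, truth, targets


class TestCMAESOptimizer:
    def test_minimizes_a_shifted_quadratic(self):
        target = np.array([0.3, -0.7, 1.2, 0.0, 0.5])
        es = CMAES(np.zeros(5), 0.5, seed=0)
        best = np.inf
        for _ in range(150):
            X = es.ask()
            f = ((X - target) ** 2).sum(axis=1)
            es.tell(X, f)
            best = min(best, f.min())
        assert best < 1e-8

    def test_population_size_default_for_seven_dimensions(self):
        es = CMAES(np.zeros(7), 0.3, seed=1)
        assert es.lam == 4 + int(3 * np.log(7)) == 9


class TestFitCMAES:
    def test_candidate_count_identity_and_monotone_best(self, small_problem):
        _, _, _, targets = small_problem
        proto = FitProtocol(n_iterations=5, n_initializations=2, seed=31)
        cands = fit_cmaes(targets["train"], proto)
        assert len(cands) == 10 == proto.n_candidates
        for init_id in (0, 1):
            run = [c.cost_train for c in cands if c.initialization_id == init_id]
            best_so_far = np.minimum.accumulate(run)
            assert np.all(np.diff(best_so_far) <= 0)

    def test_same_seed_gives_identical_candidate_lists(self, small_problem):
        _, _, _, targets = small_problem
        proto = FitProtocol(n_iterations=3, n_initializations=2, seed=33)
        a = fit_cmaes(targets["train"], proto)
        b = fit_cmaes(targets["train"], proto)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.coefficients.as_array(),
                                          cb.coefficients.as_array())
            assert ca.cost_train == cb.cost_train

    def test_out_of_box_coefficients_are_penalized_not_clipped(self, small_problem):
        _, _, _, targets = small_problem
        proto = FitProtocol(seed=0)
        ev = _Evaluator(targets["train"], proto, proto.dt_train, noise_seed=1)
        bad = ed.default_coefficients().as_array().copy()
        bad[2] = 50.0  # b_w far outside any admissible recurrent strength
        cost, _, _, valid = ev(bad)
        assert not valid and cost > 3.0


class TestSelection:
    def test_k_equal_to_length_returns_all_sorted(self, small_problem):
        _, _, _, targets = small_problem
        proto = FitProtocol(n_iterations=3, n_initializations=1, seed=35)
        cands = fit_cmaes(targets["train"], proto)
        top = select_candidates(cands, targets["val"], len(cands), proto)
        costs = [c.cost_val for c in top]
        assert costs == sorted(costs)

    def test_selection_matches_independent_reevaluation_oracle(self, small_problem):
        _, _, _, targets = small_problem
        proto = FitProtocol(n_iterations=3, n_initializations=2, seed=36)
        cands = fit_cmaes(targets["train"], proto)
        top = select_candidates(cands, targets["val"], 3, proto)
        oracle_ev = _Evaluator(targets["val"], proto, proto.dt_eval,
                               noise_seed=_eval_seed(proto, "val"))
        oracle = sorted(
            ((oracle_ev(c.coefficients.as_array())[0], c.cost_train, c.candidate_id)
             for c in cands),
        )[:3]
        assert [c.cost_val for c in top] == [o[0] for o in oracle]

    def test_single_candidate_returned_unchanged_by_test_stage(self, small_problem):
        _, _, _, targets = small_problem
        proto = FitProtocol(n_iterations=2, n_initializations=1, seed=37)
        cands = fit_cmaes(targets["train"], proto)
        top = select_candidates(cands, targets["val"], 1, proto)
        best, params = evaluate_test(top, targets["test"], proto)
        assert best.candidate_id == top[0].candidate_id
        np.testing.assert_array_equal(best.coefficients.as_array(),
                                      top[0].coefficients.as_array())
        assert params.n_regions == 8

    def test_test_winner_matches_argmin_of_oracle_test_costs(self, small_problem):
        _, _, _, targets = small_problem
        proto = FitProtocol(n_iterations=4, n_initializations=2, seed=38)
        cands = fit_cmaes(targets["train"], proto)
        top = select_candidates(cands, targets["val"], 5, proto)
        best, _ = evaluate_test(top, targets["test"], proto)
        oracle_ev = _Evaluator(targets["test"], proto, proto.dt_eval,
                               noise_seed=_eval_seed(proto, "test"),
                               n_repeats=proto.n_test_repeats)
        oracle_costs = [oracle_ev(c.coefficients.as_array())[0] for c in top]
        assert best.cost_test == pytest.approx(min(oracle_costs))


class TestFisherZAverage:
    def test_average_of_identical_fcs_is_identity(self):
        rng = np.random.default_rng(40)
        fc = np.corrcoef(rng.standard_normal((6, 100)))
        avg = fisher_z_mean_fc([fc, fc, fc])
        np.testing.assert_allclose(avg, fc, atol=1e-10)

    def test_fisher_z_average_of_two_values(self):
        a, b = 0.2, 0.6
        fc1 = np.array([[1.0, a], [a, 1.0]])
        fc2 = np.array([[1.0, b], [b, 1.0]])
        avg = fisher_z_mean_fc([fc1, fc2])
        expected = np.tanh((np.arctanh(a) + np.arctanh(b)) / 2)
        assert avg[0, 1] == pytest.approx(expected)


class TestParameterDifferencePermutation:
    def _cohorts(self, coeffs, effect=None):
        parc = ed.generate_parcellation(8, seed=41)
        sc = ed.generate_structural_connectome(8, density=0.6, seed=41,
                                               parcellation=parc)
        fcg = ed.default_gradient(parc)
        hc = ed.generate_ground_truth(coeffs, fcg)
        pat = ed.generate_ground_truth(coeffs, fcg, effect=effect) if effect is not None else hc
        spec = ed.SyntheticCohortSpec(n_regions=8, n_subjects_per_group=6,
                                      seed=42, dt_seconds=0.05)
        cohort = ed.generate_cohort(spec, sc, {"HC": hc, "PAT": pat}, coeffs.G)
        hc_subs = [s for s in cohort if s.group == "HC"]
        pat_subs = [s for s in cohort if s.group == "PAT"]
        split = lambda subs: {"train": subs[:2], "val": subs[2:4], "test": subs[4:]}
        return split(pat_subs), split(hc_subs), sc, fcg

    def test_n_perm_zero_returns_observed_differences_only(self, coeffs):
        patients, controls, sc, fcg = self._cohorts(coeffs)
        proto = FitProtocol(n_iterations=2, n_initializations=1,
                            top_k_validation=2, seed=43)
        out = parameter_difference_permutation(patients, controls, sc, proto,
                                               n_perm=0, fcg=fcg)
        assert set(out) == {"delta_rc", "delta_i", "n_perm"}
        assert out["delta_rc"].shape == (8,)

    def test_permutation_mode_produces_valid_pvalues(self, coeffs):
        patients, controls, sc, fcg = self._cohorts(coeffs)
        proto = FitProtocol(n_iterations=2, n_initializations=1,
                            top_k_validation=2, seed=44)
        out = parameter_difference_permutation(patients, controls, sc, proto,
                                               n_perm=3, fcg=fcg, seed=45)
        for key in ("p_rc", "p_i", "q_rc", "q_i"):
            assert np.all((out[key] > 0) & (out[key] <= 1))

    def test_missing_subset_rejected(self, coeffs):
        patients, controls, sc, fcg = self._cohorts(coeffs)
        del patients["val"]
        proto = FitProtocol(n_iterations=1, n_initializations=1, seed=46)
        with pytest.raises(ValueError, match="val"):
            parameter_difference_permutation(patients, controls, sc, proto,
                                             n_perm=0, fcg=fcg)
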
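"""EM estimation: recovery, monotonicity, dimension reduction, degeneracies."""

import numpy as np
import pytest

from irtcal.core_model import (
    MISSING,
    GRMParameters,
    ParameterError,
    ResponseMatrix,
)
from irtcal.estimation import (
    ModelSpec,
    QuadratureSpec,
    _FullLayout,
    _forward,
    _item_grid_theta,
    _item_logprobs,
    fit,
    fit_bifactor,
    merge_empty_categories,
    model1_spec,
    model2_spec,
    model3_spec,
    model4_spec,
    total_loglik,
)
from irtcal.synthetic_data import generate

from conftest import SEED, fit_study_replicate, make_codebook, one_wave_plan


class TestSpecs:
    def test_quadrature_defaults_by_dimension(self):
        q = QuadratureSpec()
        assert q.resolve(1) == 21 and q.resolve(2) == 21 and q.resolve(3) == 9
        with pytest.raises(ValueError):
            QuadratureSpec(n_nodes=3).resolve(1)

    def test_model_factor_structures(self):
        from irtcal.core_model import default_study_codebook

        cb = default_study_codebook()
        m1 = model1_spec(cb)
        assert m1.pattern.shape == (31, 1) and m1.pattern.all()
        m3 = model3_spec(cb)
        assert m3.n_factors == 4
        assert m3.pattern[:, m3.factor_names.index("general")].all()
        m4 = model4_spec(cb)
        assert m4.n_factors == 6
        # every item: general + at most two group factors
        non_gen = np.delete(m4.pattern, m4.factor_names.index("general"), axis=1)
        assert non_gen.sum(axis=1).max() == 2

    def test_two_specific_factors_per_item_rejected(self):
        pattern = np.ones((4, 3), dtype=bool)
        with pytest.raises(ParameterError, match="specific"):
            ModelSpec("custom", ["g", "s1", "s2"], ["general", "specific", "specific"],
                      pattern)


class TestEMRecovery:
    def test_one_factor_recovery_and_monotone_ll(self, unifactor_toy):
        """n = 5000 draws from a known 1-factor GRM: slopes back within
        +-0.15, thresholds within +-0.1, LL non-decreasing over EM."""
        res = fit(unifactor_toy.data, model1_spec(unifactor_toy.codebook,
                                                  max_iter=500, tol=1e-4))
        assert res.converged
        diffs = np.diff(res.ll_history)
        assert diffs.min() > -1e-8 * abs(res.log_likelihood)
        slope_err = np.abs(res.params.slopes - unifactor_toy.truth.slopes)
        thr_err = np.abs(
            np.array(res.params.thresholds) - np.array(unifactor_toy.truth.thresholds)
        )
        # mean absolute error inside the tolerance; individual items may sit
        # 2-3 sampling s.e. out at n = 5000
        assert slope_err.mean() < 0.15 and slope_err.max() < 0.3
        assert thr_err.mean() < 0.1 and thr_err.max() < 0.2

    def test_reflection_makes_dominant_loadings_positive(self, unifactor_toy):
        """The GRM is invariant to flipping a factor's sign; fits are
        reported with positive dominant loadings."""
        res = fit(unifactor_toy.data, model1_spec(unifactor_toy.codebook, max_iter=50))
        assert res.params.slopes.sum() > 0

    def test_mean_bias_of_general_loadings_small_at_n2000(self, n2000_model4):
        """Three study-shaped replicates at n = 2000: general-factor
        standardized loadings recovered with small mean absolute bias."""
        lam_true = n2000_model4.truth.standardized_loadings().loadings[:, 0]
        biases = [n2000_model4.result.loadings.loadings[:, 0] - lam_true]
        for rep in (1, 2):
            res, truth = fit_study_replicate((760, 760, 480), SEED + 10 + rep)
            biases.append(res.loadings.loadings[:, 0]
                          - truth.standardized_loadings().loadings[:, 0])
        mean_bias = np.abs(np.mean(biases, axis=0)).mean()
        assert mean_bias < 0.05


class TestBifactor:
    def test_reduced_equals_dense_quadrature(self, bifactor_toy):
        """Dimension-reduced likelihood equals the full 3-d tensor grid."""
        truth, data = bifactor_toy.truth, bifactor_toy.data
        ll_reduced = total_loglik(truth, data, QuadratureSpec(n_nodes=15))
        # dense oracle: same nodes, one tensor grid over all three factors
        layout = _FullLayout(truth.slopes != 0, 15)
        pattern = truth.slopes != 0
        free_cols = [list(np.where(pattern[j])[0]) for j in range(6)]
        lps = [
            _item_logprobs(
                truth.effective_slopes()[j, free_cols[j]],
                truth.thresholds[j],
                _item_grid_theta(layout, layout.blocks[0], free_cols[j]),
            )
            for j in range(6)
        ]
        ll_dense = float(_forward(layout, data.values, lps)[0].sum())
        assert ll_reduced == pytest.approx(ll_dense, abs=1e-5)

    def test_bifactor_requires_general_factor(self, bifactor_toy):
        spec = model3_spec(bifactor_toy.codebook)
        no_general = ModelSpec("custom", ["a", "b"], ["specific", "method"],
                               spec.pattern[:, 1:3])
        with pytest.raises(ParameterError):
            fit_bifactor(bifactor_toy.data, no_general)

    def test_model3_beats_model1_on_bifactor_truth(self, bifactor_toy):
        """Data generated under a bifactor truth: BIC prefers the bifactor
        model over the unidimensional one."""
        plan = one_wave_plan(bifactor_toy.codebook, bifactor_toy.truth, 5000, seed=SEED + 3)
        data, _ = generate(plan)
        r1 = fit(data, model1_spec(bifactor_toy.codebook, max_iter=200, tol=1e-3))
        r3 = fit_bifactor(data, model3_spec(bifactor_toy.codebook, max_iter=200, tol=1e-3))
        assert r3.bic < r1.bic

    def test_quadrature_doubling_changes_ll_little(self, n2000_model4):
        """Quadrature adequacy: doubling the nodes moves the fitted LL by
        less than 0.1 on study-shaped data."""
        res = n2000_model4.result
        from conftest import scaled_study_plan

        data, _ = generate(scaled_study_plan((760, 760, 480), SEED + 1))
        from irtcal.estimation import EVAL_NODES

        ll_report = total_loglik(res.params, data, QuadratureSpec(n_nodes=EVAL_NODES))
        ll_double = total_loglik(res.params, data, QuadratureSpec(n_nodes=2 * EVAL_NODES))
        assert abs(ll_report - ll_double) < 0.1
        assert res.log_likelihood == pytest.approx(ll_report, abs=1e-6)


class TestDegenerateInputs:
    def test_empty_category_merged_with_recorded_mapping(self):
        cb = make_codebook(2, 4)
        vals = np.array([[0, 0], [1, 1], [3, 2], [3, 1], [0, 2], [1, 3]])
        vals[:, 0][vals[:, 0] == 2] = 3          # category 2 of item 0 never seen
        rm = ResponseMatrix(values=vals, item_ids=cb.item_ids, codebook=cb)
        values, cats, merges, _ = merge_empty_categories(rm)
        assert cats == [3, 4]
        assert merges["i00"] == [0, 1, 1, 2]
        res = fit(rm, model1_spec(cb, max_iter=30))
        assert res.category_merges == merges
        assert len(res.params.thresholds[0]) == 2

    def test_single_observed_category_flagged_at_bound(self):
        """2-category item answered identically by everyone: the threshold
        escapes to the box constraint and the fit is flagged, not aborted."""
        cb = make_codebook(3, 2)
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 2, size=(200, 3))
        vals[:, 0] = 0
        rm = ResponseMatrix(values=vals, item_ids=cb.item_ids, codebook=cb)
        res = fit(rm, model1_spec(cb, max_iter=60))
        assert any("box constraint" in m or "one observed category" in m
                   for m in res.messages)

    def test_person_with_no_responses_contributes_zero(self):
        cb = make_codebook(2, 3)
        vals = np.array([[0, 1], [MISSING, MISSING], [2, 2], [1, 0]])
        rm = ResponseMatrix(values=vals, item_ids=cb.item_ids, codebook=cb)
        res = fit(rm, model1_spec(cb, max_iter=30))
        rm_drop = rm.subset_persons(np.array([0, 2, 3]))
        res_drop = fit(rm_drop, model1_spec(cb, max_iter=30))
        assert res.log_likelihood == pytest.approx(res_drop.log_likelihood, abs=1e-6)
        assert res.n_obs == res_drop.n_obs == 3

    def test_non_convergence_is_flagged_not_raised(self, unifactor_toy):
        res = fit(unifactor_toy.data, model1_spec(unifactor_toy.codebook,
                                                  max_iter=2, tol=1e-12))
        assert not res.converged
        assert any("did not converge" in m for m in res.messages)
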
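"""Domain types and the graded response model primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from irtcal.core_model import (
    MISSING,
    Codebook,
    CodebookError,
    Factor,
    GRMParameters,
    Instrument,
    Item,
    ParameterError,
    ResponseError,
    ResponseMatrix,
    category_probabilities,
    default_study_codebook,
    grm_probs,
    item_information,
    person_loglik,
)

from conftest import make_codebook


# ---------------------------------------------------------------------------
# Codebook
# ---------------------------------------------------------------------------

class TestCodebook:
    def test_study_codebook_structure(self):
        cb = default_study_codebook()
        assert cb.n_items == 31
        cats = [it.n_categories for it in cb.items]
        assert cats.count(4) == 12 and cats.count(5) == 14 and cats.count(3) == 5
        assert {f.kind for f in cb.factors} == {"general", "specific", "method"}
        wording = cb.factor("meth_wording")
        social = cb.factor("meth_social")
        assert len(wording.item_ids) == 6 and len(social.item_ids) == 5
        # the second wave omits the GHQ-12 (planned missingness design)
        assert "GHQ-12" not in cb.waves[1].instruments

    @pytest.mark.parametrize(
        "mutation",
        ["two_instruments", "unknown_factor_item", "one_category", "orphan_item"],
    )
    def test_validation_rejects_malformed_codebooks(self, mutation):
        ids = ("a", "b")
        kw = dict(
            instruments=[Instrument("X", ids)],
            items=[Item("a", 3), Item("b", 3)],
            factors=[Factor("g", "general", ids)],
        )
        if mutation == "two_instruments":
            kw["instruments"] = [Instrument("X", ids), Instrument("Y", ("b",))]
        elif mutation == "unknown_factor_item":
            kw["factors"] = [Factor("g", "general", ("a", "zz"))]
        elif mutation == "one_category":
            kw["items"] = [Item("a", 1), Item("b", 3)]
        else:
            kw["instruments"] = [Instrument("X", ("a",))]
        with pytest.raises(CodebookError):
            Codebook(**kw)

    def test_yaml_roundtrip(self, tmp_path):
        cb = default_study_codebook()
        path = tmp_path / "cb.yaml"
        cb.to_yaml(path)
        cb2 = Codebook.from_yaml(path)
        assert cb2.to_dict() == cb.to_dict()


# ---------------------------------------------------------------------------
# ResponseMatrix
# ---------------------------------------------------------------------------

class TestResponseMatrix:
    def test_rejects_out_of_range_codes(self):
        cb = make_codebook(2, 3)
        with pytest.raises(ResponseError):
            ResponseMatrix(values=[[0, 3]], item_ids=cb.item_ids, codebook=cb)

    def test_structural_missingness_check(self):
        cb = default_study_codebook()
        vals = np.full((2, 31), MISSING, dtype=int)
        ghq_col = cb.item_index("ghq01")
        vals[0, ghq_col] = 1
        rm = ResponseMatrix(values=vals, item_ids=cb.item_ids, codebook=cb,
                            waves=np.array(["wave2", "wave1"]))
        with pytest.raises(ResponseError, match="wave2"):
            rm.check_structural_missingness()
        rm_ok = ResponseMatrix(values=vals, item_ids=cb.item_ids, codebook=cb,
                               waves=np.array(["wave1", "wave2"]))
        rm_ok.check_structural_missingness()

    def test_csv_roundtrip_with_missing_and_one_based(self, tmp_path):
        cb = make_codebook(3, 4)
        vals = np.array([[0, MISSING, 3], [2, 1, MISSING]])
        rm = ResponseMatrix(values=vals, item_ids=cb.item_ids, codebook=cb,
                            household_ids=np.array([5, 5]),
                            waves=np.array(["w", "w"]))
        path = tmp_path / "resp.csv"
        rm.to_csv(path)
        back = ResponseMatrix.from_csv(path, cb)
        assert np.array_equal(back.values, vals)
        assert np.array_equal(back.household_ids, rm.household_ids)
        # 1-based files shift codes down on read
        import pandas as pd

        df = rm.to_frame()
        df[cb.item_ids] = df[cb.item_ids] + 1
        df.to_csv(path, index=False)
        back1 = ResponseMatrix.from_csv(path, cb, one_based=True)
        assert np.array_equal(back1.values, vals)

    def test_nonempty_count(self):
        cb = make_codebook(2, 3)
        vals = np.array([[0, 1], [MISSING, MISSING], [MISSING, 2]])
        rm = ResponseMatrix(values=vals, item_ids=cb.item_ids, codebook=cb)
        assert rm.n_nonempty() == 2


# ---------------------------------------------------------------------------
# Category probabilities
# ---------------------------------------------------------------------------

def _single_item_params(a, b, n_factors=1):
    slopes = np.zeros((1, n_factors))
    slopes[0, : len(np.atleast_1d(a))] = a
    return GRMParameters(
        slopes=slopes,
        thresholds=[np.asarray(b, dtype=float)],
        item_ids=["x"],
        factor_names=[f"f{k}" for k in range(n_factors)],
    )


class TestCategoryProbabilities:
    def test_zero_slope_symmetry(self):
        p = _single_item_params(0.0, [0.0])
        for theta in (-3.0, 0.0, 2.5):
            np.testing.assert_allclose(
                category_probabilities(p, "x", [theta]), [0.5, 0.5], atol=1e-12
            )

    def test_logistic_three_category_values(self):
        # sigma(1) = 0.7311, sigma(-1) = 0.2689 at theta = 0
        p = _single_item_params(1.0, [-1.0, 1.0])
        probs = category_probabilities(p, "x", [0.0])
        np.testing.assert_allclose(probs, [0.2689, 0.4621, 0.2689], atol=5e-5)

    def test_unknown_item_and_dimension_mismatch(self):
        p = _single_item_params(1.0, [0.0])
        with pytest.raises(ParameterError):
            category_probabilities(p, "nope", [0.0])
        with pytest.raises(ParameterError):
            category_probabilities(p, "x", [0.0, 0.0])

    @settings(max_examples=50, derandomize=True)
    @given(
        a=st.lists(st.floats(-3, 3), min_size=2, max_size=2),
        gaps=st.lists(st.floats(0.05, 2.0), min_size=3, max_size=3),
        b0=st.floats(-4, 4),
        theta=st.lists(st.floats(-6, 6), min_size=2, max_size=2),
    )
    def test_probabilities_form_a_simplex(self, a, gaps, b0, theta):
        b = b0 + np.concatenate(([0.0], np.cumsum(gaps)))
        P = grm_probs(np.array(a), b, np.array([theta]))
        assert np.all(P >= 0)
        assert abs(P.sum() - 1.0) < 1e-12


# ---------------------------------------------------------------------------
# Person log-likelihood
# ---------------------------------------------------------------------------

class TestPersonLoglik:
    def test_all_missing_contributes_zero(self):
        p = _single_item_params(1.0, [0.0])
        assert person_loglik(p, [MISSING], 21) == 0.0

    def test_zero_slope_equals_marginal_category_probability(self):
        # integrand constant in theta: marginal = threshold-implied probability
        p = _single_item_params(0.0, [-0.5, 1.0])
        probs = category_probabilities(p, "x", [0.0])
        for c in range(3):
            assert person_loglik(p, [c], 21) == pytest.approx(np.log(probs[c]), abs=1e-10)

    def test_matches_dense_trapezoid_integration(self):
        """2-item, 2-factor toy against brute-force numerical integration."""
        params = GRMParameters(
            slopes=np.array([[1.1, 0.7], [0.9, -0.4]]),
            thresholds=[np.array([-0.8, 0.6]), np.array([0.2])],
            item_ids=["x", "y"],
            factor_names=["f1", "f2"],
        )
        resp = np.array([2, 0])
        grid = np.linspace(-8, 8, 1000)
        t1, t2 = np.meshgrid(grid, grid, indexing="ij")
        theta = np.column_stack([t1.ravel(), t2.ravel()])
        dens = np.exp(-0.5 * (theta**2).sum(axis=1)) / (2 * np.pi)
        f = dens.copy()
        for j in range(2):
            f *= grm_probs(params.slopes[j], params.thresholds[j], theta)[:, resp[j]]
        oracle = np.log(np.trapezoid(np.trapezoid(f.reshape(1000, 1000), grid), grid))
        assert person_loglik(params, resp, 31) == pytest.approx(oracle, abs=1e-6)

    def test_additive_over_items_when_slopes_zero(self):
        params = GRMParameters(
            slopes=np.zeros((3, 1)),
            thresholds=[np.array([-1.0]), np.array([0.3, 1.2]), np.array([0.0])],
            item_ids=["a", "b", "c"],
            factor_names=["g"],
        )
        total = person_loglik(params, [1, 0, 1], 21)
        parts = sum(
            person_loglik(params, resp, 21)
            for resp in ([1, MISSING, MISSING], [MISSING, 0, MISSING], [MISSING, MISSING, 1])
        )
        assert total == pytest.approx(parts, abs=1e-10)


# ---------------------------------------------------------------------------
# Item information
# ---------------------------------------------------------------------------

class TestItemInformation:
    def test_zero_loading_gives_zero_information(self):
        p = GRMParameters(
            slopes=np.array([[0.0, 1.3]]),
            thresholds=[np.array([-0.5, 0.5])],
            item_ids=["x"],
            factor_names=["target", "other"],
        )
        theta = np.linspace(-4, 4, 17)
        np.testing.assert_allclose(item_information(p, "x", theta, "target"), 0.0, atol=1e-14)

    def test_matches_expected_negative_second_derivative(self):
        """Fisher information vs a finite-difference oracle on E[-d2 logP]."""
        p = _single_item_params([1.4, 0.6], [-1.0, 0.2, 1.5], n_factors=2)
        h = 1e-4
        for theta in (-1.5, 0.0, 0.8):
            def logprobs(t):
                return np.log(category_probabilities(p, "x", [t, 0.0]))
            lp0, lpm, lpp = logprobs(theta), logprobs(theta - h), logprobs(theta + h)
            d2 = (lpp - 2 * lp0 + lpm) / h**2
            P = category_probabilities(p, "x", [theta, 0.0])
            oracle = -(P * d2).sum()
            assert item_information(p, "x", theta, "f0") == pytest.approx(oracle, abs=1e-4)

    def test_invariant_to_category_reversal_with_negated_slope(self):
        a, b = 1.2, np.array([-0.9, 0.4, 1.1])
        p = _single_item_params(a, b)
        p_rev = _single_item_params(-a, -b[::-1])
        theta = np.linspace(-3, 3, 13)
        np.testing.assert_allclose(
            item_information(p, "x", theta, "f0"),
            item_information(p_rev, "x", theta, "f0"),
            rtol=1e-10,
        )


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

class TestGRMParameters:
    def test_thresholds_must_increase(self):
        with pytest.raises(ParameterError):
            GRMParameters(
                slopes=[[1.0]], thresholds=[np.array([0.5, 0.5])],
                item_ids=["x"], factor_names=["g"],
            )

    def test_json_roundtrip(self, tmp_path):
        p = GRMParameters(
            slopes=np.array([[1.0, 0.5]]),
            thresholds=[np.array([-1.0, 1.0])],
            item_ids=["x"],
            factor_names=["g", "s"],
            factor_variances=np.array([1.0, 1.3]),
        )
        path = tmp_path / "p.json"
        p.to_json(path)
        q = GRMParameters.from_json(path)
        np.testing.assert_allclose(q.slopes, p.slopes)
        np.testing.assert_allclose(q.factor_variances, p.factor_variances)

    def test_standardized_loadings_inverse_map(self):
        # lambda -> a -> lambda round trip in the D = 1.7 bridge
        lam = np.array([[0.7, 0.3], [0.5, 0.0]])
        comm = (lam**2).sum(axis=1, keepdims=True)
        a = 1.7 * lam / np.sqrt(1 - comm)
        p = GRMParameters(
            slopes=a, thresholds=[np.array([0.0])] * 2,
            item_ids=["x", "y"], factor_names=["g", "s"],
        )
        np.testing.assert_allclose(p.standardized_loadings().loadings, lam, atol=1e-12)

    def test_variances_fold_into_effective_slopes(self):
        p = GRMParameters(
            slopes=np.array([[2.0]]), thresholds=[np.array([0.0])],
            item_ids=["x"], factor_names=["g"], factor_variances=np.array([4.0]),
        )
        np.testing.assert_allclose(p.effective_slopes(), [[4.0]])
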
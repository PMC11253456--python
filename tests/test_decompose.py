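"""Logit MLE and twofold decomposition: designs, fits, identities, SEs."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from chegap import benchmarks
from chegap.decompose import (
    Design,
    DesignSpec,
    SeparationError,
    bootstrap_se,
    build_design,
    build_group_designs,
    decompose,
    decompose_groups,
    detailed_weights,
    fit_logit,
)
from chegap.synthetic import OUTCOME_COVARIATES, SyntheticConfig, generate_outcome_level
from conftest import outcome_frame


def _frame(**cols):
    return pd.DataFrame(cols)


class TestBuildDesign:
    def test_binary_covariate_two_columns(self):
        frame = _frame(x=["a", "b", "a", "b"], che=[1, 0, 1, 0])
        d = build_design(frame, DesignSpec(covariates=(("x", "a"),)))
        assert d.X.shape == (4, 2)
        assert d.terms == [("intercept", ""), ("x", "b")]
        np.testing.assert_array_equal(d.X[:, 0], 1.0)

    def test_five_level_variable_gets_four_dummies(self):
        levels = ["single", "married", "separated", "divorced", "widowed"]
        frame = _frame(marital_status=levels * 2, che=[0, 1] * 5)
        d = build_design(
            frame, DesignSpec(covariates=(("marital_status", "single"),))
        )
        assert d.X.shape[1] == 1 + 4

    def test_full_covariate_set_has_twenty_columns(self):
        # ten categoricals: 1 + 1+3+4+1+1+2+4+1+1+1 columns
        rng = np.random.default_rng(0)
        n = 400
        marg = benchmarks.marginal_probabilities("non_insured")
        cols = {
            var: rng.choice(list(p), size=n, p=list(p.values()))
            for var, p in marg.items()
        }
        cols["che"] = rng.integers(0, 2, n)
        frame = pd.DataFrame(cols)
        variables = [
            "head_sex", "head_age_group", "marital_status", "u5_present",
            "family_size_group", "occupation", "wealth", "ownership",
            "chronic_condition", "traditional_medicine",
        ]
        spec = DesignSpec.from_frame(frame, variables)
        d = build_design(frame, spec)
        assert d.X.shape[1] == 20

    def test_unobserved_reference_level_rejected(self):
        frame = _frame(x=["b", "b"], che=[0, 1])
        with pytest.raises(ValueError, match="reference"):
            build_design(frame, DesignSpec(covariates=(("x", "a"),)))

    def test_level_absent_in_one_group_is_named(self):
        frame = _frame(
            insurance=["insured"] * 3 + ["non_insured"] * 3,
            x=["a", "b", "c", "a", "b", "b"],
            che=[0, 1, 0, 1, 0, 1],
        )
        with pytest.raises(ValueError, match="'c'"):
            build_group_designs(frame, DesignSpec(covariates=(("x", "a"),)))


class TestFitLogit:
    def test_intercept_only_equals_logit_of_proportion(self):
        y = np.r_[np.ones(148), np.zeros(483)]
        X = np.ones((len(y), 1))
        fit = fit_logit(X, y)
        assert fit.converged
        assert fit.beta[0] == pytest.approx(np.log(148 / 483), abs=1e-10)

    def test_constant_outcome_raises(self):
        X = np.ones((20, 1))
        with pytest.raises(SeparationError):
            fit_logit(X, np.ones(20))

    def test_perfect_separation_names_covariate(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        y = (x > 0).astype(float)
        X = np.column_stack([np.ones(200), x])
        with pytest.raises(SeparationError, match="slope"):
            fit_logit(X, y, terms=[("intercept", ""), ("slope", "")])

    def test_parameter_recovery_large_sample(self):
        rng = np.random.default_rng(2)
        n = 100_000
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.integers(0, 2, n)])
        beta = np.array([-1.0, 0.7, -0.4])
        y = (rng.random(n) < expit(X @ beta)).astype(float)
        fit = fit_logit(X, y)
        se = np.sqrt(np.diag(fit.vcov))
        assert np.all(np.abs(fit.beta - beta) < 3 * se)

    def test_matches_statsmodels_irls(self, large_outcome_sample):
        """Independent IRLS oracle agrees to 1e-6 on a realistic design."""
        import statsmodels.api as sm

        records, _, _ = large_outcome_sample
        frame = outcome_frame(records[:825])
        spec = DesignSpec.from_frame(frame, list(OUTCOME_COVARIATES))
        d = build_design(frame, spec)
        fit = fit_logit(d.X, d.y)
        oracle = sm.Logit(d.y, d.X).fit(disp=0, method="newton", tol=1e-10)
        np.testing.assert_allclose(fit.beta, oracle.params, atol=1e-6)


def _group_fit(frame, variables, **kw):
    return decompose_groups(frame, variables, **kw)


@pytest.fixture(scope="module")
def fitted(large_outcome_sample):
    records, truth, _ = large_outcome_sample
    frame = outcome_frame(records)
    result, fit_a, fit_b, d_a, d_b = decompose_groups(
        frame, list(OUTCOME_COVARIATES)
    )
    return result, fit_a, fit_b, d_a, d_b, truth


class TestDecompose:
    def test_twofold_identity(self, fitted):
        result = fitted[0]
        assert abs(result.E + result.C - result.R) < 1e-10

    def test_detailed_terms_exhaust_aggregates(self, fitted):
        result = fitted[0]
        assert sum(t.E_k for t in result.detailed) == pytest.approx(result.E, abs=1e-10)
        assert sum(t.C_k for t in result.detailed) == pytest.approx(result.C, abs=1e-10)

    def test_percent_components_sum_to_hundred(self, fitted):
        result = fitted[0]
        assert result.pct_E + result.pct_C == pytest.approx(100.0, abs=1e-8)

    def test_estimates_near_generating_truth(self, fitted):
        result, *_, truth = fitted
        assert abs(result.E - truth.true_E) < 3 * result.se_E
        assert abs(result.C - truth.true_C) < 3 * result.se_C

    def test_equal_coefficients_force_zero_C(self, fitted):
        _, fit_a, fit_b, d_a, d_b, _ = fitted
        res = decompose(fit_a, fit_a, d_a, d_b)
        assert res.C == 0.0
        assert res.E == res.R
        assert all(t.C_k == 0.0 for t in res.detailed)

    def test_identical_designs_force_zero_E(self, fitted):
        _, fit_a, fit_b, d_a, d_b, _ = fitted
        res = decompose(fit_a, fit_b, d_a, d_a)
        assert res.E == 0.0
        assert res.C == res.R

    def test_group_swap_negates_the_gap(self, fitted):
        _, fit_a, fit_b, d_a, d_b, _ = fitted
        res = decompose(fit_a, fit_b, d_a, d_b)
        dual = decompose(fit_b, fit_a, d_b, d_a)
        assert dual.R == pytest.approx(-res.R, abs=1e-15)

    def test_intercept_contributes_only_to_C(self, fitted):
        result = fitted[0]
        intercept = next(t for t in result.detailed if t.variable == "intercept")
        assert intercept.E_k == 0.0

    def test_ci_half_width_is_1_96_se(self, fitted):
        result = fitted[0]
        lo, hi = result.ci(result.E, result.se_E)
        assert hi - lo == pytest.approx(2 * 1.96 * result.se_E)


class TestDetailedWeights:
    def test_single_covariate_weight_is_one(self):
        w_e, w_c, e_ok, c_ok = detailed_weights(
            beta_a=np.array([0.5, 1.2]), beta_b=np.array([0.1, 0.4]),
            xbar_a=np.array([1.0, 0.6]), xbar_b=np.array([1.0, 0.3]),
        )
        assert w_e[1] == pytest.approx(1.0)  # intercept difference is zero
        assert w_e.sum() == pytest.approx(1.0)
        assert w_c.sum() == pytest.approx(1.0)
        assert e_ok and c_ok

    def test_vanishing_denominator_flagged_unstable(self):
        w_e, _, e_ok, _ = detailed_weights(
            beta_a=np.array([0.5, 1.0, 1.0]),
            beta_b=np.array([0.1, 1.0, 1.0]),
            xbar_a=np.array([1.0, 0.4, 0.4]),
            xbar_b=np.array([1.0, 0.2, 0.6]),
        )
        # b1*dx1 + b2*dx2 = 0.2 - 0.2 = 0 while terms are nonzero
        assert not e_ok and np.all(w_e == 0.0)

    def test_substitution_oracle_two_covariates(self):
        """Yun weights agree with sequential covariate substitution.

        The oracle replaces one covariate's composition at a time in the
        mean design (averaged over both substitution orders) — a
        first-order-equivalent attribution; agreement is required to 10%
        relative, the linearisation tolerance at these effect sizes.
        """
        rng = np.random.default_rng(3)
        n = 4000
        frames = {}
        p_by_group = {
            "insured": {"x1": 0.35, "x2": 0.55},
            "non_insured": {"x1": 0.50, "x2": 0.40},
        }
        beta = {
            "insured": np.array([-1.2, 0.5, 0.7]),
            "non_insured": np.array([-1.0, 0.6, 0.8]),
        }
        designs, fits = {}, {}
        for g, probs in p_by_group.items():
            x1 = (rng.random(n) < probs["x1"]).astype(float)
            x2 = (rng.random(n) < probs["x2"]).astype(float)
            X = np.column_stack([np.ones(n), x1, x2])
            y = (rng.random(n) < expit(X @ beta[g])).astype(float)
            frame = pd.DataFrame(
                {"x1": np.where(x1 > 0, "b", "a"), "x2": np.where(x2 > 0, "b", "a"),
                 "che": y}
            )
            d = build_design(
                frame, DesignSpec(covariates=(("x1", "a"), ("x2", "a")))
            )
            designs[g] = d
            fits[g] = fit_logit(d.X, d.y)
        res = decompose(
            fits["non_insured"], fits["insured"],
            designs["non_insured"], designs["insured"],
        )
        bA = fits["non_insured"].beta
        xa = designs["non_insured"].X.mean(axis=0)
        xb = designs["insured"].X.mean(axis=0)

        def seq(order):
            cur = xb.copy()
            out = {}
            for k in order:
                before = expit(cur @ bA)
                cur[k] = xa[k]
                out[k] = expit(cur @ bA) - before
            return out

        sub = {
            k: 0.5 * (seq([1, 2])[k] + seq([2, 1])[k]) for k in (1, 2)
        }
        # rescale the oracle to the aggregate E measured over full designs
        total = sum(sub.values())
        for k, term in ((1, res.detailed[1]), (2, res.detailed[2])):
            oracle = sub[k] / total * res.E
            assert term.E_k == pytest.approx(oracle, rel=0.10)


class TestNormalization:
    def test_reference_choice_invariance_three_levels(self):
        """Deviation-from-mean contributions ignore the reference level."""
        rng = np.random.default_rng(4)
        n = 3000
        levels = np.array(["lo", "mid", "hi"])
        results = {}
        frame_rows = {}
        for g, (p, beta) in {
            "insured": ([0.5, 0.3, 0.2], [-1.5, 0.4, 0.9]),
            "non_insured": ([0.3, 0.4, 0.3], [-1.0, 0.6, 1.1]),
        }.items():
            x = rng.choice(levels, size=n, p=p)
            eta = beta[0] + beta[1] * (x == "mid") + beta[2] * (x == "hi")
            y = (rng.random(n) < expit(eta)).astype(int)
            frame_rows[g] = pd.DataFrame(
                {"x": x, "che": y, "insurance": g}
            )
        frame = pd.concat(frame_rows.values(), ignore_index=True)
        for ref in levels:
            res, *_ = decompose_groups(
                frame, ["x"], references={"x": ref},
                normalization="deviation-from-mean",
            )
            results[ref] = {
                (t.variable, t.level): (t.E_k, t.C_k) for t in res.detailed
            }
        base = results["lo"]
        for ref in ("mid", "hi"):
            for key, val in base.items():
                assert results[ref][key] == pytest.approx(val, abs=1e-10)

    def test_normalized_aggregates_match_treatment_coding(self, large_outcome_sample):
        records, _, _ = large_outcome_sample
        frame = outcome_frame(records)
        plain, *_ = decompose_groups(frame, list(OUTCOME_COVARIATES))
        norm, *_ = decompose_groups(
            frame, list(OUTCOME_COVARIATES), normalization="deviation-from-mean"
        )
        assert norm.R == pytest.approx(plain.R, abs=1e-12)
        assert norm.E == pytest.approx(plain.E, abs=1e-12)
        assert sum(t.E_k for t in norm.detailed) == pytest.approx(norm.E, abs=1e-10)


class TestStandardErrors:
    def test_degenerate_reference_vcov_isolates_comparison_uncertainty(
        self, large_outcome_sample
    ):
        records, _, _ = large_outcome_sample
        frame = outcome_frame(records)
        _, fit_a, fit_b, d_a, d_b = decompose_groups(frame, ["chronic_condition"])
        fit_b.vcov = np.zeros_like(fit_b.vcov)
        res = decompose(fit_a, fit_b, d_a, d_b, design_variance=False)
        # with vcov_B = 0, var(C) only propagates the first-bracket beta_A part
        XB = d_b.X
        pBA = expit(XB @ fit_a.beta)
        g = (pBA * (1 - pBA))[:, None] * XB
        expected = float(g.mean(0) @ fit_a.vcov @ g.mean(0))
        assert res.se_C == pytest.approx(np.sqrt(expected), rel=1e-12)

    def test_delta_and_bootstrap_agree(self, large_outcome_sample):
        records, _, _ = large_outcome_sample
        frame = outcome_frame(records)
        res, fit_a, fit_b, d_a, d_b = decompose_groups(
            frame, ["chronic_condition", "head_age_group", "ownership"]
        )
        boot = bootstrap_se(d_a, d_b, n_boot=400, seed=99)
        for key, delta in (("se_E", res.se_E), ("se_C", res.se_C), ("se_R", res.se_R)):
            ratio = delta / boot[key]
            assert 0.8 <= ratio <= 1.25, (key, ratio)
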
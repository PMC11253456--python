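"""Synthetic generator: determinism, marginal recovery, calibration, truth."""

import numpy as np
import pytest

from chegap import benchmarks
from chegap.che import che_headcount
from chegap.survey import records_to_frame, write_survey
from chegap.synthetic import (
    OUTCOME_COVARIATES,
    CalibrationError,
    SyntheticConfig,
    generate_expenditure_level,
    generate_outcome_level,
    population_incidence,
)


class TestDeterminism:
    def test_same_seed_gives_byte_identical_output(self, tmp_path):
        cfg = SyntheticConfig(seed=5, n_insured=50, n_non_insured=80)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_survey(generate_expenditure_level(cfg), p1)
        write_survey(generate_expenditure_level(SyntheticConfig(
            seed=5, n_insured=50, n_non_insured=80)), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_outcome_mode_deterministic(self):
        r1, t1 = generate_outcome_level(SyntheticConfig(seed=9, n_insured=30,
                                                        n_non_insured=40))
        r2, t2 = generate_outcome_level(SyntheticConfig(seed=9, n_insured=30,
                                                        n_non_insured=40))
        assert r1 == r2 and t1.true_E == t2.true_E


class TestOutcomeLevel:
    def test_configured_group_sizes_are_exact(self):
        records, _ = generate_outcome_level(SyntheticConfig(seed=20220524))
        frame = records_to_frame(records)
        counts = frame["insurance"].value_counts()
        assert counts["insured"] == 194 and counts["non_insured"] == 631

    def test_symmetric_construction_gives_null_gap(self):
        """Equal coefficients and marginals leave the gap at Monte-Carlo zero."""
        base = SyntheticConfig(seed=13)
        marg = base.covariate_marginals["insured"]
        cfg = SyntheticConfig(
            seed=13, n_insured=10_000, n_non_insured=10_000,
            covariate_marginals={"insured": marg, "non_insured": marg},
            beta_insured=base.beta_insured,
            beta_non_insured=base.beta_insured,
        )
        records, truth = generate_outcome_level(cfg)
        assert truth.population_R == 0.0
        ins = che_headcount(records, stratum="insured").within_stratum_proportion
        non = che_headcount(records, stratum="non_insured").within_stratum_proportion
        p = 0.5 * (ins + non)
        mc_se = np.sqrt(2 * p * (1 - p) / 10_000)
        assert abs(non - ins) < 3 * mc_se

    def test_identical_marginals_zero_population_endowment(self):
        base = SyntheticConfig(seed=17)
        marg = base.covariate_marginals["insured"]
        beta_b = dict(base.beta_insured)
        beta_a = dict(beta_b, intercept=beta_b["intercept"] + 0.5)
        cfg = SyntheticConfig(
            seed=17, n_insured=5000, n_non_insured=5000,
            covariate_marginals={"insured": marg, "non_insured": marg},
            beta_insured=beta_b, beta_non_insured=beta_a,
        )
        _, truth = generate_outcome_level(cfg)
        assert truth.population_E == 0.0
        # realized-design truth carries only covariate sampling noise
        assert abs(truth.true_E) < 0.02

    def test_marginal_recovery_at_large_n(self):
        cfg = SyntheticConfig(seed=23, n_insured=100_000, n_non_insured=1)
        records, _ = generate_outcome_level(cfg)
        frame = records_to_frame(records)
        frame = frame[frame["insurance"] == "insured"]
        n = len(frame)
        for var in OUTCOME_COVARIATES:
            probs = cfg.covariate_marginals["insured"][var]
            observed = frame[var].value_counts(normalize=True)
            for level, p in probs.items():
                tol = 3 * np.sqrt(p * (1 - p) / n)
                assert abs(observed.get(level, 0.0) - p) < tol, (var, level)

    def test_truth_matches_brute_force_counterfactual(self):
        """E and C are recomputable from the betas and realized designs."""
        from scipy.special import expit

        from chegap.decompose import DesignSpec, build_design
        from chegap.synthetic import DEFAULT_REFERENCES, _beta_vector
        from conftest import outcome_frame

        cfg = SyntheticConfig(seed=29, n_insured=400, n_non_insured=600)
        records, truth = generate_outcome_level(cfg)
        frame = outcome_frame(records)
        spec = DesignSpec(covariates=tuple(DEFAULT_REFERENCES.items()))
        d_a = build_design(frame[frame.insurance == "non_insured"], spec)
        d_b = build_design(frame[frame.insurance == "insured"], spec)
        bA = _beta_vector(cfg.beta_non_insured, d_a.term_labels())
        bB = _beta_vector(cfg.beta_insured, d_b.term_labels())
        E = expit(d_a.X @ bA).mean() - expit(d_b.X @ bA).mean()
        C = expit(d_b.X @ bA).mean() - expit(d_b.X @ bB).mean()
        assert truth.true_E == pytest.approx(E, abs=1e-12)
        assert truth.true_C == pytest.approx(C, abs=1e-12)

    def test_mismatched_coefficient_vector_is_config_error(self):
        cfg = SyntheticConfig(seed=1, n_insured=10, n_non_insured=10)
        cfg.beta_insured = {"intercept": -2.0}  # missing all covariate terms
        with pytest.raises(ValueError, match="does not match design"):
            generate_outcome_level(cfg)


class TestExpenditureLevel:
    def test_calibrated_headcount_hits_target(self):
        cfg = SyntheticConfig(
            seed=31,
            target_che_prevalence={"insured": 0.2994, "non_insured": 0.2994},
        )
        records = generate_expenditure_level(cfg)
        headcount = che_headcount(records).proportion
        assert 0.2894 <= headcount <= 0.3094

    def test_zero_target_forces_zero_headcount(self):
        cfg = SyntheticConfig(
            seed=37, n_insured=100, n_non_insured=100,
            target_che_prevalence={"insured": 0.0, "non_insured": 0.0},
        )
        records = generate_expenditure_level(cfg)
        assert che_headcount(records).count == 0
        assert all(r.expenditure.direct_medical == 0.0 for r in records)

    def test_unattainable_target_raises_calibration_error(self):
        # indirect costs alone exceed 10% of the budget for most households,
        # so a near-zero target cannot be reached by scaling medical costs
        cfg = SyntheticConfig(
            seed=41, n_insured=100, n_non_insured=100,
            target_che_prevalence={"insured": 0.001, "non_insured": 0.001},
            lost_days_mean=200.0, daily_valuation=5000.0,
        )
        with pytest.raises(CalibrationError):
            generate_expenditure_level(cfg)

    def test_asset_inventory_present_with_one_factor_structure(self):
        cfg = SyntheticConfig(seed=43, n_insured=200, n_non_insured=200)
        records = generate_expenditure_level(cfg)
        assert all(len(r.assets) == cfg.n_assets for r in records)


class TestConfigValidation:
    def test_marginals_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to"):
            SyntheticConfig(
                seed=1,
                covariate_marginals={
                    "insured": {"head_sex": {"male": 0.6, "female": 0.3}},
                    "non_insured": {"head_sex": {"male": 0.5, "female": 0.5}},
                },
            )

    def test_population_incidence_closed_form_single_covariate(self):
        from scipy.special import expit as F

        marg = {var: {"x": 1.0} for var in OUTCOME_COVARIATES}
        betas = {"intercept": -1.0}
        # degenerate marginals put all mass on unmodelled levels
        assert population_incidence(marg, betas) == pytest.approx(F(-1.0))
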
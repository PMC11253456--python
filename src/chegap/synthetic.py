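"""Synthetic household-survey generator.

Two modes emulate the statistical structure the analysis assumes:

* **outcome-level** — covariates are drawn independently within each
  insurance stratum from configurable category marginals, and the CHE flag
  is drawn Bernoulli with probability logistic(x'beta_group) under known
  group-specific logit coefficients.  The generating truth (coefficients
  and the analytically implied endowment/coefficient components over the
  realized designs) is returned alongside the records, so decomposition
  recovery can be tested against a known answer.

* **expenditure-level** — expenditure components are drawn lognormal and
  the direct-medical scale is calibrated by bisection so the realized CHE
  headcount matches a target prevalence; the asset inventory is drawn from
  Bernoullis whose probabilities are logistic in a latent standard-normal
  wealth score, giving a one-factor structure the wealth index can recover.

Default covariate marginals are the reference survey's per-stratum
proportions (n=194 insured / 631 non-insured); default coefficients give
within-stratum CHE prevalences near 0.22 (insured) and 0.30 (non-insured),
an overall gap of about 0.08.  All output is fully determined by the
config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from . import benchmarks
from .che import che_flag
from .survey import ExpenditureProfile, HouseholdRecord

__all__ = [
    "SyntheticConfig",
    "TrueParameters",
    "CalibrationError",
    "generate_outcome_level",
    "generate_expenditure_level",
    "default_betas",
]

_AGE_RANGES = {"<=30": (18, 30), "31-45": (31, 45), "46-60": (46, 60), ">60": (61, 90)}

#: Default reference level per covariate (first level of the design).
DEFAULT_REFERENCES = {
    "head_sex": "male",
    "head_age_group": "<=30",
    "marital_status": "single",
    "u5_present": "no",
    "family_size_group": "<=4",
    "occupation": "self_employed",
    "ownership": "private",
    "chronic_condition": "no",
    "traditional_medicine": "no",
}

#: Generating covariates for the outcome-level mode, in design order.
OUTCOME_COVARIATES = tuple(DEFAULT_REFERENCES)


def default_betas() -> tuple[dict[str, float], dict[str, float]]:
    """Default group logit coefficients (insured, non_insured).

    Chronic illness and traditional-medicine use raise CHE risk strongly,
    risk rises with head age, larger families and renting carry moderate
    effects; intercepts were solved (independent-marginal convolution of
    the linear predictor) so within-stratum prevalence under the default
    marginals is 0.22 insured / 0.30 non-insured.
    The groups differ in intercept and in the ownership and traditional-
    medicine effects, so both endowment and coefficient components of the
    gap are non-zero by construction.
    """
    shared = {
        "head_sex=female": 0.15,
        "head_age_group=31-45": 0.35,
        "head_age_group=46-60": 0.75,
        "head_age_group=>60": 1.10,
        "marital_status=married": 0.30,
        "marital_status=separated": 0.40,
        "marital_status=divorced": 0.80,
        "marital_status=widowed": 0.70,
        "u5_present=yes": 0.10,
        "family_size_group=>4": 0.45,
        "occupation=government": -0.20,
        "occupation=private_sector": 0.25,
        "chronic_condition=yes": 1.40,
    }
    insured = {
        "intercept": -3.17,
        **shared,
        "ownership=rent": -0.10,
        "traditional_medicine=yes": 0.60,
    }
    non_insured = {
        "intercept": -2.61,
        **shared,
        "ownership=rent": 0.35,
        "traditional_medicine=yes": 1.00,
    }
    return insured, non_insured


@dataclass
class SyntheticConfig:
    """Configuration for both generator modes; the seed fixes all output."""

    n_insured: int = benchmarks.N_INSURED
    n_non_insured: int = benchmarks.N_NON_INSURED
    seed: int = 20220524
    #: per-group, per-covariate category probability tables
    covariate_marginals: dict[str, dict[str, dict[str, float]]] = dc_field(
        default_factory=dict
    )
    beta_insured: dict[str, float] = dc_field(default_factory=dict)
    beta_non_insured: dict[str, float] = dc_field(default_factory=dict)
    #: lognormal (mean, sigma of log) per expenditure component
    expenditure_model: dict[str, tuple[float, float]] = dc_field(
        default_factory=lambda: {
            "food": (10.6, 0.45),            # median ~ 40e3 currency/year
            "nonfood_nonhealth": (10.1, 0.6),
            "direct_medical": (7.6, 1.1),
            "direct_nonmedical": (5.8, 1.0),
        }
    )
    target_che_prevalence: dict[str, float] = dc_field(
        default_factory=lambda: {"insured": 0.22, "non_insured": 0.30}
    )
    che_threshold: float = 0.10
    n_assets: int = 35
    #: per-asset (intercept, loading) of the latent-wealth logistic link
    asset_intercepts: np.ndarray | None = None
    asset_loadings: np.ndarray | None = None
    lost_days_mean: float = 6.0
    daily_valuation: float = 150.0

    def __post_init__(self) -> None:
        if self.n_insured < 1 or self.n_non_insured < 1:
            raise ValueError("group sizes must be >= 1")
        if not self.covariate_marginals:
            self.covariate_marginals = {
                g: benchmarks.marginal_probabilities(g)
                for g in ("insured", "non_insured")
            }
        for g, per_var in self.covariate_marginals.items():
            for var, probs in per_var.items():
                total = sum(probs.values())
                if abs(total - 1.0) > 1e-12:
                    raise ValueError(
                        f"marginals of {var!r} in group {g!r} sum to {total!r}"
                    )
        if not self.beta_insured or not self.beta_non_insured:
            ins, non = default_betas()
            self.beta_insured = self.beta_insured or ins
            self.beta_non_insured = self.beta_non_insured or non
        if self.asset_intercepts is None:
            # prevalences span ~0.03..0.97 so both filters have work to do
            self.asset_intercepts = np.linspace(-3.5, 3.5, self.n_assets)
        if self.asset_loadings is None:
            self.asset_loadings = np.full(self.n_assets, 1.2)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        for key in ("asset_intercepts", "asset_loadings"):
            if key in doc and doc[key] is not None:
                doc[key] = np.asarray(doc[key], dtype=float)
        if "expenditure_model" in doc:
            doc["expenditure_model"] = {
                k: tuple(v) for k, v in doc["expenditure_model"].items()
            }
        return cls(**doc)


@dataclass
class TrueParameters:
    """Generating truth of an outcome-level sample.

    ``true_*`` are counterfactual means over the *realized* per-group
    designs (the estimand the decomposition targets conditional on the
    drawn covariates); ``population_*`` are the same quantities computed
    exactly over the configured marginals by enumerating the independent
    covariate distribution, free of covariate sampling noise.
    """

    beta_insured: dict[str, float]
    beta_non_insured: dict[str, float]
    true_R: float
    true_E: float
    true_C: float
    population_R: float
    population_E: float
    population_C: float
    term_labels: list[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "beta_insured": self.beta_insured,
                    "beta_non_insured": self.beta_non_insured,
                    "true_R": self.true_R,
                    "true_E": self.true_E,
                    "true_C": self.true_C,
                    "population_R": self.population_R,
                    "population_E": self.population_E,
                    "population_C": self.population_C,
                    "term_labels": self.term_labels,
                },
                indent=1,
            ),
            encoding="utf-8",
        )


class CalibrationError(RuntimeError):
    """The target CHE prevalence is unattainable by scaling medical costs."""


def population_incidence(
    marginals: Mapping[str, Mapping[str, float]], betas: Mapping[str, float]
) -> float:
    """Exact E[F(x'beta)] under independent categorical marginals.

    Convolves the per-covariate effect distributions of the linear
    predictor, then averages the logistic transform; used for the
    sampling-noise-free population decomposition components.
    """
    dist: dict[float, float] = {float(betas["intercept"]): 1.0}
    for var in OUTCOME_COVARIATES:
        new: dict[float, float] = {}
        for level, p in marginals[var].items():
            eff = float(betas.get(f"{var}={level}", 0.0))
            for s, q in dist.items():
                key = s + eff
                new[key] = new.get(key, 0.0) + p * q
        dist = new
    s = np.array(list(dist))
    w = np.array(list(dist.values()))
    return float((w * expit(s)).sum())


def _beta_vector(betas: Mapping[str, float], labels: list[str]) -> np.ndarray:
    missing = [l for l in labels if l not in betas]
    extra = [k for k in betas if k not in labels]
    if missing or extra:
        raise ValueError(
            f"coefficient vector does not match design: missing {missing}, "
            f"unexpected {extra}"
        )
    return np.array([betas[l] for l in labels])


def _design_matrix(
    config: SyntheticConfig, group: str, frame: pd.DataFrame
) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design from the configured marginals (not the
    realized levels, so rare categories absent in a small draw still get
    their column)."""
    marg = config.covariate_marginals[group]
    cols = [np.ones(len(frame))]
    labels = ["intercept"]
    for var in OUTCOME_COVARIATES:
        ref = DEFAULT_REFERENCES[var]
        if ref not in marg[var]:
            raise ValueError(f"reference level {ref!r} missing from marginals of {var!r}")
        for level in (l for l in marg[var] if l != ref):
            cols.append((frame[var] == level).to_numpy(dtype=float))
            labels.append(f"{var}={level}")
    return np.column_stack(cols), labels


def _draw_covariate_frame(
    config: SyntheticConfig, group: str, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    marginals = config.covariate_marginals[group]
    data = {"insurance": [group] * n}
    for var in OUTCOME_COVARIATES:
        probs = marginals[var]
        levels = list(probs)
        data[var] = rng.choice(levels, size=n, p=[probs[l] for l in levels])
    return pd.DataFrame(data)


def _frame_to_records(
    frame: pd.DataFrame,
    che: np.ndarray,
    assets: np.ndarray,
    asset_names: list[str],
    rng: np.random.Generator,
    profiles: list[ExpenditureProfile] | None = None,
    id_offset: int = 0,
) -> list[HouseholdRecord]:
    records = []
    cols = {c: frame[c].tolist() for c in frame.columns}
    for i in range(len(frame)):
        row = {c: values[i] for c, values in cols.items()}
        lo, hi = _AGE_RANGES[row["head_age_group"]]
        fam = (
            int(rng.integers(1, 5))
            if row["family_size_group"] == "<=4"
            else int(rng.integers(5, 10))
        )
        profile = (
            profiles[i]
            if profiles is not None
            else benchmarks.profile_for_flag(bool(che[i]))
        )
        records.append(
            HouseholdRecord(
                household_id=f"syn{id_offset + i:05d}",
                kebele=str(rng.choice(["01", "03", "04"])),
                head_sex=row["head_sex"],
                head_age=int(rng.integers(lo, hi + 1)),
                marital_status=row["marital_status"],
                occupation=row["occupation"],
                family_size=fam,
                u5_present=row["u5_present"],
                ownership=row["ownership"],
                insurance=row["insurance"],
                chronic_condition=row["chronic_condition"],
                traditional_medicine=row["traditional_medicine"],
                referral_history="no",
                expenditure=profile,
                assets=dict(zip(asset_names, assets[i].astype(bool))),
            )
        )
    return records


def _draw_assets(
    config: SyntheticConfig, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    z = rng.standard_normal(n)
    probs = expit(config.asset_intercepts[None, :] + config.asset_loadings[None, :] * z[:, None])
    assets = rng.random((n, config.n_assets)) < probs
    names = [f"a{j:02d}" for j in range(config.n_assets)]
    return assets, z, names


def generate_outcome_level(
    config: SyntheticConfig,
) -> tuple[list[HouseholdRecord], TrueParameters]:
    """Draw records with a known-coefficient Bernoulli CHE outcome.

    Returns the realized records plus the generating coefficients and the
    analytically implied (counterfactual-mean) endowment and coefficient
    components over the realized per-group designs; expenditure profiles
    are synthesised to encode each household's flag at the 10% threshold.
    """
    rng = np.random.default_rng(config.seed)
    frames, matrices, betas, flags = {}, {}, {}, {}
    labels: list[str] = []
    sizes = {"insured": config.n_insured, "non_insured": config.n_non_insured}
    for group in ("insured", "non_insured"):
        frame = _draw_covariate_frame(config, group, sizes[group], rng)
        X, labels = _design_matrix(config, group, frame)
        beta_map = (
            config.beta_insured if group == "insured" else config.beta_non_insured
        )
        beta = _beta_vector(beta_map, labels)
        p = expit(X @ beta)
        flags[group] = rng.random(sizes[group]) < p
        frames[group], matrices[group], betas[group] = frame, X, beta

    # analytic truth over the realized designs (A = non-insured comparison)
    XA, XB = matrices["non_insured"], matrices["insured"]
    bA, bB = betas["non_insured"], betas["insured"]
    pAA = expit(XA @ bA).mean()
    pBA = expit(XB @ bA).mean()
    pBB = expit(XB @ bB).mean()
    mA = config.covariate_marginals["non_insured"]
    mB = config.covariate_marginals["insured"]
    qAA = population_incidence(mA, config.beta_non_insured)
    qBA = population_incidence(mB, config.beta_non_insured)
    qBB = population_incidence(mB, config.beta_insured)
    truth = TrueParameters(
        beta_insured=dict(config.beta_insured),
        beta_non_insured=dict(config.beta_non_insured),
        true_R=float(pAA - pBB),
        true_E=float(pAA - pBA),
        true_C=float(pBA - pBB),
        population_R=qAA - qBB,
        population_E=qAA - qBA,
        population_C=qBA - qBB,
        term_labels=labels,
    )

    records: list[HouseholdRecord] = []
    for group in ("insured", "non_insured"):
        n = sizes[group]
        assets, _, names = _draw_assets(config, n, rng)
        records.extend(
            _frame_to_records(
                frames[group], flags[group], assets, names, rng,
                id_offset=len(records),
            )
        )
    return records, truth


def _draw_profiles(
    config: SyntheticConfig, n: int, scale: float, draws: dict[str, np.ndarray]
) -> list[ExpenditureProfile]:
    return [
        ExpenditureProfile(
            food=float(draws["food"][i]),
            nonfood_nonhealth=float(draws["nonfood_nonhealth"][i]),
            direct_medical=float(scale * draws["direct_medical"][i]),
            direct_nonmedical=float(draws["direct_nonmedical"][i]),
            lost_days=float(draws["lost_days"][i]),
            daily_valuation=config.daily_valuation,
        )
        for i in range(n)
    ]


def _headcount_at_scale(
    config: SyntheticConfig, n: int, scale: float, draws: dict[str, np.ndarray]
) -> float:
    profiles = _draw_profiles(config, n, scale, draws)
    flags = [
        che_flag(p, config.che_threshold).catastrophic for p in profiles
    ]
    return sum(flags) / n


def generate_expenditure_level(config: SyntheticConfig) -> list[HouseholdRecord]:
    """Draw records with lognormal expenditures calibrated to a target CHE.

    Within each insurance stratum the direct-medical scale is found by
    bisection so the realized headcount at the configured threshold is
    within one percentage point of the stratum target; an unattainable
    target raises :class:`CalibrationError` after bounded iterations.
    """
    rng = np.random.default_rng(config.seed)
    records: list[HouseholdRecord] = []
    sizes = {"insured": config.n_insured, "non_insured": config.n_non_insured}
    for group in ("insured", "non_insured"):
        n = sizes[group]
        frame = _draw_covariate_frame(config, group, n, rng)
        draws = {
            name: rng.lognormal(mu, sigma, n)
            for name, (mu, sigma) in config.expenditure_model.items()
        }
        draws["lost_days"] = rng.poisson(config.lost_days_mean, n).astype(float)
        target = config.target_che_prevalence[group]
        scale = _calibrate_scale(config, n, draws, target)
        profiles = _draw_profiles(config, n, scale, draws)
        flags = np.array(
            [che_flag(p, config.che_threshold).catastrophic for p in profiles]
        )
        assets, _, names = _draw_assets(config, n, rng)
        records.extend(
            _frame_to_records(
                frame, flags, assets, names, rng,
                profiles=profiles, id_offset=len(records),
            )
        )
    return records


def _calibrate_scale(
    config: SyntheticConfig,
    n: int,
    draws: dict[str, np.ndarray],
    target: float,
    tol: float = 0.01,
    max_iter: int = 100,
) -> float:
    if target == 0.0:
        draws["direct_medical"] = np.zeros(n)
        draws["direct_nonmedical"] = np.zeros(n)
        draws["lost_days"] = np.zeros(n)
        return 0.0
    lo, hi = 0.0, 1.0
    for _ in range(60):  # find an upper bracket
        if _headcount_at_scale(config, n, hi, draws) >= target:
            break
        hi *= 2.0
    else:
        raise CalibrationError(
            f"target prevalence {target} unattainable by scaling medical costs"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        h = _headcount_at_scale(config, n, mid, draws)
        if abs(h - target) <= tol:
            return mid
        if h < target:
            lo = mid
        else:
            hi = mid
    h = _headcount_at_scale(config, n, 0.5 * (lo + hi), draws)
    if abs(h - target) <= tol:
        return 0.5 * (lo + hi)
    raise CalibrationError(
        f"bisection did not reach target {target} within {max_iter} "
        f"iterations (closest headcount {h:.4f})"
    )
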
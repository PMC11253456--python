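"""Logit MLE and twofold (endowment/coefficient) decomposition of a
binary-outcome gap between two groups.

The gap in outcome incidence between a comparison group A (non-insured by
convention) and a reference group B (insured) is

    R = mean_i F(x_Ai' b_A) - mean_j F(x_Bj' b_B)
      = [mean_i F(x_Ai' b_A) - mean_j F(x_Bj' b_A)]          (E, endowments)
      + [mean_j F(x_Bj' b_A) - mean_j F(x_Bj' b_B)]          (C, coefficients)

with F the logistic function and b_A, b_B the group-wise logit MLEs; the
decomposition is on the probability scale, averaging the transformed linear
predictors over each group's observed rows.  E is the part of the gap
attributable to differences in covariate composition (evaluated at the
comparison group's coefficients) and C the part attributable to differences
in covariate effects (evaluated at the reference group's composition).

Detailed per-covariate attribution uses first-order (Yun) weights

    E_k = E * b_Ak (xbar_Ak - xbar_Bk) / sum_j b_Aj (xbar_Aj - xbar_Bj)
    C_k = C * xbar_Bk (b_Ak - b_Bk)   / sum_j xbar_Bj (b_Aj - b_Bj)

(the intercept contributes to the C family with composition 1).  Standard
errors for aggregates and detailed terms are delta-method propagations of
the two coefficient covariance matrices; a household-resampling bootstrap
is provided for cross-validation.  With deviation-from-mean normalisation,
dummy coefficients of each categorical variable are re-expressed to sum to
zero across all its levels, making detailed contributions invariant to the
choice of reference level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "DesignSpec",
    "Design",
    "LogitFit",
    "DecompositionResult",
    "DetailedTerm",
    "SeparationError",
    "CollinearityError",
    "build_design",
    "build_group_designs",
    "fit_logit",
    "decompose",
    "decompose_groups",
    "detailed_weights",
    "decomposition_se",
    "bootstrap_se",
]

_IDENTITY_TOL = 1e-10
_SEPARATION_BOUND = 15.0


class SeparationError(RuntimeError):
    """The MLE diverges: a covariate pattern separates the outcome."""


class CollinearityError(RuntimeError):
    """The information matrix is singular (aliased columns)."""


@dataclass(frozen=True)
class DesignSpec:
    """Ordered covariates with reference levels, treatment (dummy) coded.

    ``covariates`` maps each categorical variable to its reference level;
    the intercept is always included as the first column.
    """

    covariates: tuple[tuple[str, str], ...]

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, variables: Sequence[str],
        references: dict[str, str] | None = None,
    ) -> "DesignSpec":
        """Spec over ``variables`` with given (or modal) reference levels."""
        references = references or {}
        pairs = []
        for var in variables:
            ref = references.get(var)
            if ref is None:
                ref = frame[var].astype(str).mode().iloc[0]
            pairs.append((var, str(ref)))
        return cls(covariates=tuple(pairs))


@dataclass
class Design:
    """Treatment-coded design matrix with its term map and source frame."""

    X: np.ndarray
    y: np.ndarray
    terms: list[tuple[str, str]]          # (variable, level); terms[0]=("intercept","")
    variable_levels: dict[str, list[str]]  # all levels, reference first
    frame: pd.DataFrame                    # categorical source columns (+ outcome)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def term_labels(self) -> list[str]:
        return [
            "intercept" if v == "intercept" else f"{v}={l}" for v, l in self.terms
        ]


def build_design(
    frame: pd.DataFrame,
    spec: DesignSpec,
    outcome: str = "che",
) -> Design:
    """Treatment-coded design matrix (intercept first) plus outcome vector.

    Raises if a declared reference level is unobserved in ``frame`` —
    silent aliasing of a reference is never allowed.
    """
    n = len(frame)
    columns = [np.ones(n)]
    terms: list[tuple[str, str]] = [("intercept", "")]
    variable_levels: dict[str, list[str]] = {}
    for var, ref in spec.covariates:
        values = frame[var].astype(str)
        observed = sorted(values.unique())
        if ref not in observed:
            raise ValueError(
                f"reference level {ref!r} of {var!r} unobserved "
                f"(observed: {observed})"
            )
        levels = [ref] + [l for l in observed if l != ref]
        variable_levels[var] = levels
        for level in levels[1:]:
            columns.append((values == level).to_numpy(dtype=float))
            terms.append((var, level))
    y = frame[outcome].to_numpy()
    if y.dtype == object or y.dtype.kind in "US":
        y = (frame[outcome].astype(str) == "yes").to_numpy()
    y = y.astype(float)
    keep = [outcome] + [v for v, _ in spec.covariates]
    return Design(
        X=np.column_stack(columns), y=y, terms=terms,
        variable_levels=variable_levels, frame=frame[keep].reset_index(drop=True),
    )


def build_group_designs(
    frame: pd.DataFrame,
    spec: DesignSpec,
    group_variable: str = "insurance",
    group_a: str = "non_insured",
    group_b: str = "insured",
    outcome: str = "che",
) -> tuple[Design, Design]:
    """Per-group designs with identical term maps.

    Errors listing any covariate level absent in one group, which would
    otherwise alias silently into that group's reference cell.
    """
    frames = {
        g: frame[frame[group_variable].astype(str) == g] for g in (group_a, group_b)
    }
    for g, sub in frames.items():
        if sub.empty:
            raise ValueError(f"no rows in group {g!r}")
    for var, _ in spec.covariates:
        levels = {g: set(sub[var].astype(str).unique()) for g, sub in frames.items()}
        union = levels[group_a] | levels[group_b]
        for g in (group_a, group_b):
            absent = sorted(union - levels[g])
            if absent:
                raise ValueError(
                    f"level(s) {absent} of {var!r} absent in group {g!r}"
                )
    d_a = build_design(frames[group_a], spec, outcome)
    d_b = build_design(frames[group_b], spec, outcome)
    return d_a, d_b


@dataclass
class LogitFit:
    """Group-wise logistic maximum-likelihood fit."""

    beta: np.ndarray
    vcov: np.ndarray
    loglik: float
    n: int
    iterations: int
    converged: bool
    group_label: str = ""
    terms: list[tuple[str, str]] = field(default_factory=list)


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logit(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    terms: list[tuple[str, str]] | None = None,
    group_label: str = "",
) -> LogitFit:
    """Logistic MLE by Newton iteration (IRLS) with step-halving.

    Convergence requires the max-norm of the score to fall below ``tol``.
    Diverging coefficients (|beta_j| > 15 with a non-vanishing score) raise
    :class:`SeparationError` naming the covariate; a singular information
    matrix raises :class:`CollinearityError`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > columns, got n={n}, p={p}")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise SeparationError("outcome is constant; the MLE does not exist")

    def name(j: int) -> str:
        if terms and j < len(terms):
            v, l = terms[j]
            return v if v == "intercept" else f"{v}={l}"
        return f"column {j}"

    beta = np.zeros(p)
    ll = _loglik(X @ beta, y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as err:
            raise CollinearityError(f"singular information matrix: {err}") from None
        # step-halving keeps the log-likelihood non-decreasing
        scale = 1.0
        for _ in range(30):
            candidate = beta + scale * step
            ll_new = _loglik(X @ candidate, y)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        ll = _loglik(X @ beta, y)
        big = np.abs(beta) > _SEPARATION_BOUND
        if np.any(big) and np.max(np.abs(X.T @ (y - expit(X @ beta)))) >= tol:
            j = int(np.argmax(np.abs(beta)))
            raise SeparationError(
                f"coefficient for {name(j)} diverged (|beta|="
                f"{abs(beta[j]):.1f}): likely perfect separation"
            )
    eta = X @ beta
    mu = expit(eta)
    if not converged and np.max(np.abs(X.T @ (y - mu))) < tol:
        converged = True
    w = mu * (1.0 - mu)
    H = X.T @ (X * w[:, None])
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError as err:
        raise CollinearityError(f"singular information at optimum: {err}") from None
    return LogitFit(
        beta=beta, vcov=vcov, loglik=_loglik(eta, y), n=n,
        iterations=it, converged=converged, group_label=group_label,
        terms=list(terms) if terms else [],
    )


@dataclass(frozen=True)
class DetailedTerm:
    """Per-term contribution to the endowment and coefficient components."""

    variable: str
    level: str
    E_k: float
    se_E_k: float
    pct_E_k: float
    p_E_k: float
    C_k: float
    se_C_k: float
    pct_C_k: float
    p_C_k: float


@dataclass
class DecompositionResult:
    """Twofold decomposition R = E + C with detailed attribution."""

    group_a: str
    group_b: str
    R: float
    E: float
    C: float
    se_R: float
    se_E: float
    se_C: float
    p_R: float
    p_E: float
    p_C: float
    pct_E: float
    pct_C: float
    detailed: list[DetailedTerm]
    xbar_a: np.ndarray
    xbar_b: np.ndarray
    normalization: str = "off"
    e_weights_stable: bool = True
    c_weights_stable: bool = True

    def ci(self, value: float, se: float) -> tuple[float, float]:
        return (value - 1.96 * se, value + 1.96 * se)

    def to_frame(self) -> pd.DataFrame:
        """Detailed table shaped like published decomposition tables."""
        rows = []
        for t in self.detailed:
            lo_e, hi_e = self.ci(t.E_k, t.se_E_k)
            lo_c, hi_c = self.ci(t.C_k, t.se_C_k)
            rows.append(
                {
                    "variable": t.variable,
                    "level": t.level,
                    "E_coef": t.E_k, "E_ci_low": lo_e, "E_ci_high": hi_e,
                    "E_pct": round(t.pct_E_k, 2), "E_p": t.p_E_k,
                    "C_coef": t.C_k, "C_ci_low": lo_c, "C_ci_high": hi_c,
                    "C_pct": round(t.pct_C_k, 2), "C_p": t.p_C_k,
                }
            )
        return pd.DataFrame(rows)


def _wald_p(value: float, se: float) -> float:
    if se == 0.0:
        return 0.0 if value != 0.0 else 1.0
    return float(2.0 * norm.sf(abs(value) / se))


def _normalization_map(design: Design) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Linear map L: treatment-coded beta -> deviation-from-mean beta.

    The extended coefficient vector has the intercept followed by one entry
    per level of each categorical variable (reference included); within
    each variable the entries sum to zero, with the grand level-mean folded
    into the intercept.
    """
    terms_ext: list[tuple[str, str]] = [("intercept", "")]
    for var, levels in design.variable_levels.items():
        terms_ext.extend((var, l) for l in levels)
    p = len(design.terms)
    L = np.zeros((len(terms_ext), p))
    L[0, 0] = 1.0
    col_of = {t: j for j, t in enumerate(design.terms)}
    row = 1
    for var, levels in design.variable_levels.items():
        k = len(levels)
        dummy_cols = [col_of[(var, l)] for l in levels[1:]]
        for c in dummy_cols:
            L[0, c] += 1.0 / k  # intercept absorbs the level mean
        for l in levels:
            for c in dummy_cols:
                L[row, c] -= 1.0 / k
            if l != levels[0]:
                L[row, col_of[(var, l)]] += 1.0
            row += 1
    return L, terms_ext


def _extended_design(design: Design) -> np.ndarray:
    """Indicator matrix matching the deviation-from-mean coefficient map."""
    cols = [np.ones(design.n)]
    for var, levels in design.variable_levels.items():
        values = design.frame[var].astype(str)
        for l in levels:
            cols.append((values == l).to_numpy(dtype=float))
    return np.column_stack(cols)


def detailed_weights(
    beta_a: np.ndarray,
    beta_b: np.ndarray,
    xbar_a: np.ndarray,
    xbar_b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, bool, bool]:
    """First-order (Yun) weight vectors for the E and C families.

    Returns (w_E, w_C, e_stable, c_stable); each weight family sums to one
    when its denominator is away from zero, and is flagged unstable (with
    zero weights returned) when the denominator vanishes while the
    corresponding aggregate does not.
    """
    d = xbar_a - xbar_b
    num_e = beta_a * d
    S = num_e.sum()
    db = beta_a - beta_b
    num_c = xbar_b * db
    T = num_c.sum()
    scale_e = float(np.max(np.abs(num_e))) if num_e.size else 0.0
    scale_c = float(np.max(np.abs(num_c))) if num_c.size else 0.0
    # a denominator that is float-fuzz relative to its terms is treated as
    # vanished: attribution would be arbitrary, so weights are zeroed
    e_stable = scale_e == 0.0 or abs(S) > 1e-10 * scale_e
    c_stable = scale_c == 0.0 or abs(T) > 1e-10 * scale_c
    w_e = num_e / S if (e_stable and S != 0.0) else np.zeros_like(num_e)
    w_c = num_c / T if (c_stable and T != 0.0) else np.zeros_like(num_c)
    if scale_e == 0.0:
        e_stable = True  # identical compositions: all contributions are zero
    if scale_c == 0.0:
        c_stable = True  # identical coefficients
    return w_e, w_c, e_stable, c_stable


def decompose(
    fit_a: LogitFit,
    fit_b: LogitFit,
    design_a: Design,
    design_b: Design,
    normalization: str = "off",
    design_variance: bool = True,
) -> DecompositionResult:
    """Twofold decomposition of the incidence gap with delta-method SEs.

    Group A is the comparison group (its coefficients weight the endowment
    bracket) and group B the reference.  The identities E + C = R and
    sum(detailed) = aggregate hold to 1e-10 by construction and are
    asserted on every call.

    By default the aggregate SEs treat the covariate composition as
    sampled (households are random draws), adding the sampling variance of
    the per-group means of the transformed linear predictors to the
    coefficient-propagation term; this matches a household-resampling
    bootstrap.  With ``design_variance=False`` inference is conditional on
    the observed designs (coefficient uncertainty only).  Detailed-term
    SEs are always conditional.
    """
    if design_a.terms != design_b.terms:
        raise ValueError("designs have different term maps")
    if normalization not in ("off", "deviation-from-mean"):
        raise ValueError(f"unknown normalization {normalization!r}")

    bA, bB = fit_a.beta, fit_b.beta
    XA, XB = design_a.X, design_b.X
    pAA = expit(XA @ bA)
    pBA = expit(XB @ bA)
    pBB = expit(XB @ bB)
    R = float(pAA.mean() - pBB.mean())
    E = float(pAA.mean() - pBA.mean())
    C = float(pBA.mean() - pBB.mean())

    fAA = pAA * (1.0 - pAA)
    fBA = pBA * (1.0 - pBA)
    fBB = pBB * (1.0 - pBB)
    gE_A = (fAA[:, None] * XA).mean(axis=0) - (fBA[:, None] * XB).mean(axis=0)
    gC_A = (fBA[:, None] * XB).mean(axis=0)
    gC_B = -(fBB[:, None] * XB).mean(axis=0)
    VA, VB = fit_a.vcov, fit_b.vcov
    var_E = float(gE_A @ VA @ gE_A)
    var_C = float(gC_A @ VA @ gC_A + gC_B @ VB @ gC_B)
    gR_A = gE_A + gC_A
    var_R = float(gR_A @ VA @ gR_A + gC_B @ VB @ gC_B)
    if design_variance:
        nA, nB = len(pAA), len(pBA)
        v_AA = float(np.var(pAA, ddof=1)) / nA if nA > 1 else 0.0
        v_BA = float(np.var(pBA, ddof=1)) / nB if nB > 1 else 0.0
        v_BB = float(np.var(pBB, ddof=1)) / nB if nB > 1 else 0.0
        v_Bdiff = float(np.var(pBA - pBB, ddof=1)) / nB if nB > 1 else 0.0
        var_E += v_AA + v_BA
        var_C += v_Bdiff
        var_R += v_AA + v_BB
    se_R, se_E, se_C = (np.sqrt(max(v, 0.0)) for v in (var_R, var_E, var_C))

    # Detailed attribution, optionally in the deviation-from-mean basis.
    if normalization == "deviation-from-mean":
        L, terms_use = _normalization_map(design_a)
        bA_u, bB_u = L @ bA, L @ bB
        VA_u, VB_u = L @ VA @ L.T, L @ VB @ L.T
        XA_u, XB_u = _extended_design(design_a), _extended_design(design_b)
    else:
        terms_use = design_a.terms
        bA_u, bB_u, VA_u, VB_u = bA, bB, VA, VB
        XA_u, XB_u = XA, XB
    xbar_a = XA_u.mean(axis=0)
    xbar_b = XB_u.mean(axis=0)
    w_e, w_c, e_stable, c_stable = detailed_weights(bA_u, bB_u, xbar_a, xbar_b)
    E_k = E * w_e
    C_k = C * w_c

    # Delta-method gradients of the detailed terms in the working basis.
    gE_A_u = (fAA[:, None] * XA_u).mean(axis=0) - (fBA[:, None] * XB_u).mean(axis=0)
    gC_A_u = (fBA[:, None] * XB_u).mean(axis=0)
    gC_B_u = -(fBB[:, None] * XB_u).mean(axis=0)
    d = xbar_a - xbar_b
    S = float((bA_u * d).sum())
    db = bA_u - bB_u
    T = float((xbar_b * db).sum())
    q = len(terms_use)
    se_E_k = np.zeros(q)
    se_C_k = np.zeros(q)
    for k in range(q):
        if e_stable and S != 0.0:
            dw = -(bA_u[k] * d[k] / S ** 2) * d
            dw[k] += d[k] / S
            uA = gE_A_u * w_e[k] + E * dw
            se_E_k[k] = np.sqrt(max(float(uA @ VA_u @ uA), 0.0))
        if c_stable and T != 0.0:
            dv = -(xbar_b[k] * db[k] / T ** 2) * xbar_b
            dv[k] += xbar_b[k] / T
            uA = gC_A_u * w_c[k] + C * dv
            uB = gC_B_u * w_c[k] - C * dv
            se_C_k[k] = np.sqrt(
                max(float(uA @ VA_u @ uA + uB @ VB_u @ uB), 0.0)
            )

    detailed = []
    for k, (var, level) in enumerate(terms_use):
        detailed.append(
            DetailedTerm(
                variable=var, level=level,
                E_k=float(E_k[k]), se_E_k=float(se_E_k[k]),
                pct_E_k=float(100.0 * E_k[k] / R) if R != 0.0 else float("nan"),
                p_E_k=_wald_p(float(E_k[k]), float(se_E_k[k])),
                C_k=float(C_k[k]), se_C_k=float(se_C_k[k]),
                pct_C_k=float(100.0 * C_k[k] / R) if R != 0.0 else float("nan"),
                p_C_k=_wald_p(float(C_k[k]), float(se_C_k[k])),
            )
        )

    assert abs((E + C) - R) < _IDENTITY_TOL, "twofold identity violated"
    if e_stable and abs(w_e.sum() - 1.0) < 1e-6:
        assert abs(sum(t.E_k for t in detailed) - E) < max(
            _IDENTITY_TOL, 1e-10 * abs(E)
        ), "detailed E terms do not exhaust the aggregate"
    if c_stable and abs(w_c.sum() - 1.0) < 1e-6:
        assert abs(sum(t.C_k for t in detailed) - C) < max(
            _IDENTITY_TOL, 1e-10 * abs(C)
        ), "detailed C terms do not exhaust the aggregate"

    pct_E = float(100.0 * E / R) if R != 0.0 else float("nan")
    pct_C = float(100.0 * C / R) if R != 0.0 else float("nan")
    return DecompositionResult(
        group_a=fit_a.group_label or "A",
        group_b=fit_b.group_label or "B",
        R=R, E=E, C=C,
        se_R=float(se_R), se_E=float(se_E), se_C=float(se_C),
        p_R=_wald_p(R, float(se_R)),
        p_E=_wald_p(E, float(se_E)),
        p_C=_wald_p(C, float(se_C)),
        pct_E=pct_E, pct_C=pct_C,
        detailed=detailed,
        xbar_a=xbar_a, xbar_b=xbar_b,
        normalization=normalization,
        e_weights_stable=e_stable, c_weights_stable=c_stable,
    )


def decompose_groups(
    frame: pd.DataFrame,
    variables: Sequence[str],
    references: dict[str, str] | None = None,
    group_variable: str = "insurance",
    group_a: str = "non_insured",
    group_b: str = "insured",
    outcome: str = "che",
    normalization: str = "off",
) -> tuple[DecompositionResult, LogitFit, LogitFit, Design, Design]:
    """Fit both group logits on an analysis frame and decompose the gap."""
    spec = DesignSpec.from_frame(frame, variables, references)
    d_a, d_b = build_group_designs(
        frame, spec, group_variable, group_a, group_b, outcome
    )
    fit_a = fit_logit(d_a.X, d_a.y, terms=d_a.terms, group_label=group_a)
    fit_b = fit_logit(d_b.X, d_b.y, terms=d_b.terms, group_label=group_b)
    result = decompose(fit_a, fit_b, d_a, d_b, normalization=normalization)
    return result, fit_a, fit_b, d_a, d_b


def decomposition_se(
    fit_a: LogitFit,
    fit_b: LogitFit,
    design_a: Design,
    design_b: Design,
    method: str = "delta",
    n_boot: int = 500,
    seed: int | None = None,
) -> dict[str, float]:
    """Standard errors for (R, E, C) by delta method or bootstrap."""
    if method == "delta":
        res = decompose(fit_a, fit_b, design_a, design_b)
        return {"se_R": res.se_R, "se_E": res.se_E, "se_C": res.se_C}
    if method == "bootstrap":
        return bootstrap_se(design_a, design_b, n_boot=n_boot, seed=seed)
    raise ValueError(f"unknown SE method {method!r}")


def bootstrap_se(
    design_a: Design,
    design_b: Design,
    n_boot: int = 500,
    seed: int | None = None,
) -> dict[str, float]:
    """Nonparametric bootstrap SEs for (R, E, C).

    Households are resampled with replacement within each group and both
    logits refit per replicate; replicates where a fit fails to converge or
    separates are dropped (their count is reported).
    """
    rng = np.random.default_rng(seed)
    stats_r, stats_e, stats_c = [], [], []
    failures = 0
    for _ in range(n_boot):
        ia = rng.integers(0, design_a.n, design_a.n)
        ib = rng.integers(0, design_b.n, design_b.n)
        try:
            fa = fit_logit(design_a.X[ia], design_a.y[ia])
            fb = fit_logit(design_b.X[ib], design_b.y[ib])
        except (SeparationError, CollinearityError):
            failures += 1
            continue
        pAA = expit(design_a.X[ia] @ fa.beta).mean()
        pBA = expit(design_b.X[ib] @ fa.beta).mean()
        pBB = expit(design_b.X[ib] @ fb.beta).mean()
        stats_r.append(pAA - pBB)
        stats_e.append(pAA - pBA)
        stats_c.append(pBA - pBB)
    if len(stats_r) < 2:
        raise RuntimeError("bootstrap produced fewer than 2 usable replicates")
    return {
        "se_R": float(np.std(stats_r, ddof=1)),
        "se_E": float(np.std(stats_e, ddof=1)),
        "se_C": float(np.std(stats_c, ddof=1)),
        "n_failures": float(failures),
    }
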
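"""Asset-based wealth index: filtering, first-PC scoring, quintile ranking.

The index follows the DHS-style construction: a binary asset inventory is
pruned by a prevalence filter (assets nearly universal or nearly absent
carry no information) and a correlation filter, the surviving indicators
are standardised and the first principal component of their correlation
matrix provides the household score, which is ranked into quintiles.

The correlation filter is stated in the source methodology as removing
correlation-matrix entries outside [0.1, 0.9]; since entries cannot be
removed from a PCA input, it is implemented as greedy iterative removal of
the variable with the most out-of-range pairwise correlations (|r| < low
or |r| > high), recomputing each round, with every removal logged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WealthModel",
    "filter_by_prevalence",
    "filter_by_correlation",
    "fit_wealth_model",
    "assign_quintiles",
    "WEALTH_LABELS",
]

WEALTH_LABELS = ("poorest", "poorer", "middle", "richer", "richest")


@dataclass
class WealthModel:
    """Fitted wealth index: retained assets, loadings, quintile cutpoints."""

    candidate_variables: list[str]
    retained_variables: list[str]
    removal_log: dict[str, str]
    loadings: np.ndarray          # unit-norm first-PC coefficients
    score_center: np.ndarray      # per-variable means used to standardise
    score_scale: np.ndarray       # per-variable SDs
    quintile_cutpoints: np.ndarray  # 20/40/60/80th percentiles of scores
    orientation_anchor: str

    def score(self, assets: pd.DataFrame) -> np.ndarray:
        """Wealth score per household (standardised assets x loadings)."""
        missing = [v for v in self.retained_variables if v not in assets.columns]
        if missing:
            raise KeyError(f"asset variables missing from input: {missing}")
        Z = (
            assets[self.retained_variables].to_numpy(dtype=float) - self.score_center
        ) / self.score_scale
        return Z @ self.loadings

    def to_json(self, path: str | Path) -> None:
        doc = {
            "candidate_variables": self.candidate_variables,
            "retained_variables": self.retained_variables,
            "removal_log": self.removal_log,
            "loadings": self.loadings.tolist(),
            "score_center": self.score_center.tolist(),
            "score_scale": self.score_scale.tolist(),
            "quintile_cutpoints": self.quintile_cutpoints.tolist(),
            "orientation_anchor": self.orientation_anchor,
        }
        Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "WealthModel":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            candidate_variables=doc["candidate_variables"],
            retained_variables=doc["retained_variables"],
            removal_log=doc["removal_log"],
            loadings=np.asarray(doc["loadings"]),
            score_center=np.asarray(doc["score_center"]),
            score_scale=np.asarray(doc["score_scale"]),
            quintile_cutpoints=np.asarray(doc["quintile_cutpoints"]),
            orientation_anchor=doc["orientation_anchor"],
        )


def filter_by_prevalence(
    assets: pd.DataFrame, low: float = 0.05, high: float = 0.95
) -> tuple[list[str], dict[str, str]]:
    """Keep assets whose ownership frequency p satisfies low <= p <= high.

    Boundary values are retained (the exclusion rule is strict: frequency
    *greater than* high or *less than* low).
    """
    if not low < high:
        raise ValueError(f"need low < high, got {low} >= {high}")
    retained, log = [], {}
    for name in assets.columns:
        p = float(assets[name].mean())
        if p > high:
            log[name] = f"prevalence>{high}"
        elif p < low:
            log[name] = f"prevalence<{low}"
        else:
            retained.append(name)
    return retained, log


def _violation_counts(corr: np.ndarray, low: float, high: float) -> np.ndarray:
    a = np.abs(corr)
    bad = (a < low) | (a > high)
    np.fill_diagonal(bad, False)
    return bad.sum(axis=0)


def filter_by_correlation(
    assets: pd.DataFrame,
    low: float = 0.1,
    high: float = 0.9,
    min_variables: int = 3,
) -> tuple[list[str], dict[str, str]]:
    """Iteratively drop the asset with most pairwise |r| outside [low, high].

    Ties are broken by lower ownership prevalence first, then by name.
    Stops when no out-of-range pair remains or ``min_variables`` is
    reached; fewer than three survivors triggers a warning, not an error.
    """
    if assets.shape[1] < 2:
        raise ValueError("correlation filtering needs at least 2 variables")
    names = list(assets.columns)
    prevalence = assets.mean()
    log: dict[str, str] = {}
    step = 0
    while len(names) > min_variables:
        X = assets[names].to_numpy(dtype=float)
        sd = X.std(axis=0)
        if np.any(sd == 0):
            raise AssertionError(
                f"zero-variance variable after prevalence filtering: "
                f"{[n for n, s in zip(names, sd) if s == 0]}"
            )
        corr = np.corrcoef(X, rowvar=False)
        counts = _violation_counts(corr, low, high)
        worst = counts.max()
        if worst == 0:
            break
        step += 1
        candidates = [n for n, c in zip(names, counts) if c == worst]
        victim = min(candidates, key=lambda n: (prevalence[n], n))
        log[victim] = (
            f"step {step}: {worst} pairwise |r| outside [{low}, {high}]"
        )
        names.remove(victim)
    if len(names) < 3:
        warnings.warn(
            f"correlation filter left only {len(names)} variables", stacklevel=2
        )
    return names, log


def fit_wealth_model(
    assets: pd.DataFrame,
    anchor: str | None = None,
    prevalence_bounds: tuple[float, float] = (0.05, 0.95),
    correlation_bounds: tuple[float, float] = (0.1, 0.9),
    filter_variables: bool = True,
) -> WealthModel:
    """Fit the wealth index on a household x asset boolean matrix.

    Applies both filters (unless ``filter_variables`` is off), standardises
    the retained columns, extracts the first eigenvector of their
    correlation matrix, and orients it so the anchor asset (default: the
    highest-prevalence retained asset) loads positively.  Quintile
    cutpoints are the 20/40/60/80th percentiles of the in-sample scores.
    """
    candidates = list(assets.columns)
    removal_log: dict[str, str] = {}
    names = candidates
    if filter_variables:
        names, log1 = filter_by_prevalence(assets, *prevalence_bounds)
        removal_log.update(log1)
        names, log2 = filter_by_correlation(assets[names], *correlation_bounds)
        removal_log.update(log2)
    if len(names) < 3:
        raise ValueError(f"need >= 3 retained assets, have {len(names)}")
    if len(assets) < 10:
        raise ValueError(f"need >= 10 households, have {len(assets)}")

    X = assets[names].to_numpy(dtype=float)
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    if np.any(scale == 0):
        raise np.linalg.LinAlgError(
            f"constant asset column(s): {[n for n, s in zip(names, scale) if s == 0]}"
        )
    Z = (X - center) / scale
    corr = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    loadings = eigvecs[:, -1]
    loadings = loadings / np.linalg.norm(loadings)

    if anchor is None:
        anchor = max(names, key=lambda n: (float(assets[n].mean()), n))
    elif anchor not in names:
        raise ValueError(f"anchor {anchor!r} not among retained variables {names}")
    if loadings[names.index(anchor)] < 0:
        loadings = -loadings

    scores = Z @ loadings
    cutpoints = np.percentile(scores, [20, 40, 60, 80])
    return WealthModel(
        candidate_variables=candidates,
        retained_variables=names,
        removal_log=removal_log,
        loadings=loadings,
        score_center=center,
        score_scale=scale,
        quintile_cutpoints=cutpoints,
        orientation_anchor=anchor,
    )


def assign_quintiles(model: WealthModel, assets: pd.DataFrame) -> pd.Series:
    """Label each household poorest...richest by its wealth score.

    Binning is rank-based at the fitted 20/40/60/80 percentile cutpoints
    with all tied scores kept in the same bin (a score exactly at a
    cutpoint falls in the lower bin), so bin sizes may be unequal when
    scores cluster.  Labels are ascending in score.
    """
    scores = model.score(assets)
    idx = np.searchsorted(model.quintile_cutpoints, scores, side="left")
    # searchsorted(side="left") puts score == cutpoint into the lower bin
    if np.all(scores == scores[0]):
        warnings.warn("all households share one wealth score", stacklevel=2)
    labels = pd.Series(
        pd.Categorical.from_codes(idx, categories=list(WEALTH_LABELS), ordered=True),
        index=assets.index,
        name="wealth",
    )
    return labels
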
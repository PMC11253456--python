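"""End-to-end orchestration: survey (or synthetic) input through CHE
measurement, wealth index, chi-square screening, and decomposition, with a
reproducibility manifest.

Also provides the single-population-proportion sample-size calculator used
to design this kind of cross-sectional survey.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .che import che_flags
from .decompose import decompose_groups
from .screening import screen_variables
from .survey import MISSING, read_survey, records_to_frame
from .synthetic import SyntheticConfig, generate_outcome_level
from .wealth import assign_quintiles, fit_wealth_model

log = logging.getLogger("chegap")

__all__ = ["RunConfig", "run_pipeline", "sample_size", "analysis_frame"]

DEFAULT_CANDIDATES = [
    "head_sex",
    "head_age_group",
    "marital_status",
    "u5_present",
    "family_size_group",
    "occupation",
    "wealth",
    "ownership",
    "chronic_condition",
    "traditional_medicine",
    "referral_history",
]


def sample_size(
    p: float,
    d: float,
    z: float = 1.96,
    nonresponse: float = 0.0,
    design_effect: float = 1.0,
) -> int:
    """Single-population-proportion sample size, survey-design arithmetic.

    The base n = z^2 p(1-p)/d^2 is truncated to an integer, inflated by the
    non-response fraction with the sum rounded up, then multiplied by the
    design effect (p=0.5, d=0.05, z=1.96 gives the familiar base of 384;
    10% non-response and a design effect of 2 give 846).
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if d <= 0.0:
        raise ValueError(f"d must be positive, got {d}")
    base = int(z * z * p * (1.0 - p) / (d * d))
    inflated = math.ceil(base * (1.0 + nonresponse))
    return int(round(inflated * design_effect))


@dataclass
class RunConfig:
    """Config of one pipeline run; exactly one input source must be set."""

    survey_path: str | None = None
    synthetic_config_path: str | None = None
    output_dir: str = "chegap_run"
    threshold: float = 0.10
    denominator_kind: str = "total"
    include_health_in_denominator: bool = True
    candidates: list[str] = field(default_factory=lambda: list(DEFAULT_CANDIDATES))
    references: dict[str, str] = field(default_factory=dict)
    screening_alpha: float = 0.05
    missing_mode: str = "listwise"  # or "drop_variable"
    se_method: str = "delta"
    bootstrap_replicates: int = 500
    normalization: str = "off"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.survey_path is None) == (self.synthetic_config_path is None):
            raise ValueError(
                "exactly one of survey_path / synthetic_config_path must be set"
            )
        if self.missing_mode not in ("listwise", "drop_variable"):
            raise ValueError(f"unknown missing_mode {self.missing_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**doc)


def analysis_frame(records, config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Categorical analysis frame with CHE flag and wealth quintile.

    Returns the frame plus stage row counts (households excluded for an
    undefined expenditure share are itemized).
    """
    frame = records_to_frame(records)
    results = []
    kept = []
    for i, rec in enumerate(records):
        try:
            res = che_flags(
                [rec], config.threshold, config.denominator_kind,
                config.include_health_in_denominator,
            )[0]
        except Exception:
            continue
        results.append(res)
        kept.append(i)
    frame = frame.iloc[kept].reset_index(drop=True)
    frame["che"] = ["yes" if r.catastrophic else "no" for r in results]
    frame["share"] = [r.share for r in results]
    counts = {"input": len(records), "with_defined_share": len(frame)}

    if records and records[0].assets:
        assets = pd.DataFrame([records[i].assets for i in kept]).astype(float)
        model = fit_wealth_model(assets)
        frame["wealth"] = assign_quintiles(model, assets).astype(str)
        counts["wealth_model_retained"] = len(model.retained_variables)
    else:
        model = None
    return frame, {"counts": counts, "wealth_model": model, "che_results": results}


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and write artifacts plus a reproducibility manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_outputs: list[str] = []
    truth = None
    if config.survey_path:
        log.info("stage read: %s", config.survey_path)
        result = read_survey(config.survey_path)
        records = result.records
        n_rejected = len(result.rejected)
    else:
        log.info("stage simulate: %s", config.synthetic_config_path)
        syn = SyntheticConfig.from_yaml(config.synthetic_config_path)
        syn.seed = syn.seed if config.seed == 0 else config.seed
        records, truth = generate_outcome_level(syn)
        n_rejected = 0

    frame, extra = analysis_frame(records, config)
    counts = {"rejected_rows": n_rejected, **extra["counts"]}

    log.info("stage che: %d households flagged", (frame["che"] == "yes").sum())
    che_table = frame[["household_id", "insurance", "share", "che"]]
    che_path = out / "che_table.csv"
    che_table.to_csv(che_path, index=False)
    stage_outputs.append(che_path.name)

    if extra["wealth_model"] is not None:
        wm_path = out / "wealth_model.json"
        extra["wealth_model"].to_json(wm_path)
        stage_outputs.append(wm_path.name)

    candidates = [c for c in config.candidates if c in frame.columns]
    constant = [c for c in candidates if frame[c].nunique() < 2]
    if constant:
        log.info("stage screen: skipping constant variable(s) %s", constant)
        candidates = [c for c in candidates if c not in constant]
    if config.missing_mode == "drop_variable":
        candidates = [
            c for c in candidates if not (frame[c] == MISSING).any()
        ]
    else:
        has_missing = [c for c in candidates if (frame[c] == MISSING).any()]
        if has_missing:
            keep = ~(frame[has_missing] == MISSING).any(axis=1)
            frame = frame[keep].reset_index(drop=True)
            counts["after_listwise_deletion"] = len(frame)

    report = screen_variables(
        frame, candidates, outcome="che", alpha=config.screening_alpha
    )
    log.info("stage screen: selected %s", report.selected)
    screen_path = out / "screening.csv"
    report.to_frame().to_csv(screen_path, index=False)
    stage_outputs.append(screen_path.name)

    result, fit_a, fit_b, d_a, d_b = decompose_groups(
        frame,
        report.selected,
        references=config.references,
        normalization=config.normalization,
    )
    counts["decomposition_n_non_insured"] = d_a.n
    counts["decomposition_n_insured"] = d_b.n
    dec_path = out / "decomposition.csv"
    result.to_frame().to_csv(dec_path, index=False)
    summary = {
        "R": result.R, "E": result.E, "C": result.C,
        "se_R": result.se_R, "se_E": result.se_E, "se_C": result.se_C,
        "pct_E": result.pct_E, "pct_C": result.pct_C,
        "p_R": result.p_R, "p_E": result.p_E, "p_C": result.p_C,
        "covariates": report.selected,
    }
    if config.se_method == "bootstrap":
        from .decompose import bootstrap_se

        summary["bootstrap"] = bootstrap_se(
            d_a, d_b, n_boot=config.bootstrap_replicates, seed=config.seed
        )
    (out / "decomposition.json").write_text(
        json.dumps(summary, indent=1), encoding="utf-8"
    )
    stage_outputs += [dec_path.name, "decomposition.json"]

    config_doc = asdict(config)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config_doc,
        "config_hash": hashlib.sha256(
            json.dumps(config_doc, sort_keys=True).encode()
        ).hexdigest(),
        "stage_outputs": stage_outputs,
        "row_counts": counts,
        "true_parameters": (
            {"true_R": truth.true_R, "true_E": truth.true_E, "true_C": truth.true_C}
            if truth
            else None
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest
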
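"""End-to-end analysis pipeline: preprocess, filter, test, report.

Thin orchestration over :class:`~ghrelkit.model.ReliabilityModel`: parse an
:class:`AnalysisConfig`, apply assay censoring and subgroup filters
(participant exclusions; split by between-assessment weight change), run the
permutation tests and ICC / adjusted-ICC stages, and emit a reproducible
report (JSON, TSV, or forest-plot CSV). Identical config and seed give a
byte-identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple, Optional, Sequence, Union

import pandas as pd

from .assay import AssayConfig, DEFAULT_ASSAYS
from .model import DEFAULT_COVARIATES, ReliabilityModel, ReliabilityResults
from .simulate import long_to_cohort

__all__ = [
    "AnalysisConfig",
    "run_pipeline",
    "weight_change_split",
    "WeightSplit",
    "report_to_tsv",
    "report_to_forest_csv",
]

log = logging.getLogger("ghrelkit")


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run (JSON-serialisable)."""

    hormones: Sequence[str] = ("ghrelin", "leptin", "glp1", "pp")
    covariates: Sequence[str] = DEFAULT_COVARIATES
    permutation_iterations: int = 100_000
    bootstrap_reps: int = 500
    conf_level: float = 0.95
    exclude_participants: Sequence[str] = ()
    weight_change_threshold: Optional[float] = None  # kg
    weight_change_group: Optional[str] = None  # "stable" | "changed"
    log_transform: bool = False
    apply_assays: bool = True
    assays: dict = field(default_factory=dict)  # overrides of DEFAULT_ASSAYS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.conf_level < 1:
            raise ValueError("conf_level must be in (0, 1)")
        if self.weight_change_group not in (None, "stable", "changed"):
            raise ValueError("weight_change_group must be 'stable' or 'changed'")
        if self.weight_change_group is not None and self.weight_change_threshold is None:
            raise ValueError("weight_change_group requires weight_change_threshold")

    def assay_configs(self) -> dict[str, AssayConfig]:
        out = dict(DEFAULT_ASSAYS)
        for name, raw in self.assays.items():
            out[name] = raw if isinstance(raw, AssayConfig) else AssayConfig(hormone=name, **raw)
        return out

    def config_hash(self) -> str:
        canon = json.dumps(
            {k: (list(v) if isinstance(v, (tuple, list)) else v)
             for k, v in asdict(self).items()},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


class WeightSplit(NamedTuple):
    """Partition of a cohort by absolute between-assessment weight change."""

    stable: pd.DataFrame
    changed: pd.DataFrame
    unknown: pd.DataFrame  # participants with missing weight at either assessment


def weight_change_split(
    cohort: pd.DataFrame, threshold: float, weight_col: str = "weight_kg"
) -> WeightSplit:
    """Split a wide cohort by |weight_FU - weight_BL| > threshold (kg).

    The stable/changed partitions are disjoint and exhaustive over the
    participants with weight at both assessments; participants missing a
    weight go to an explicit ``unknown`` bucket rather than being dropped
    silently.
    """
    if weight_col not in cohort.columns:
        raise KeyError(f"cohort has no {weight_col!r} column")
    wide = cohort.pivot(index="participant_id", columns="assessment", values=weight_col)
    delta = (wide.iloc[:, -1] - wide.iloc[:, 0]).abs()
    unknown_ids = set(delta[delta.isna()].index)
    changed_ids = set(delta[delta > threshold].dropna().index)
    stable_ids = set(delta.dropna().index) - changed_ids
    by = cohort["participant_id"]
    return WeightSplit(
        stable=cohort[by.isin(stable_ids)].reset_index(drop=True),
        changed=cohort[by.isin(changed_ids)].reset_index(drop=True),
        unknown=cohort[by.isin(unknown_ids)].reset_index(drop=True),
    )


def _load_cohort(path: Union[str, Path]) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"value_pgml": str} if "value_pgml" in
                        pd.read_csv(path, nrows=0).columns else None)
    if "hormone" in frame.columns and "value_pgml" in frame.columns:
        return long_to_cohort(frame)
    return frame


def run_pipeline(
    config: AnalysisConfig,
    cohort: Union[pd.DataFrame, str, Path],
) -> dict:
    """Run the full analysis and return the report as a JSON-ready dict.

    Stages run in order — preprocess (assay censoring), subgroup filtering,
    per-variable permutation tests, ICC(A,1), mixed model + adjusted ICC —
    and any stage failure aborts the run with a stage-named error; no
    partial report is produced.
    """
    t0 = time.perf_counter()
    if not isinstance(cohort, pd.DataFrame):
        cohort = _load_cohort(cohort)
    cohort = cohort.copy()

    stage = "preprocess"
    try:
        assays = config.assay_configs() if config.apply_assays else None
        excluded = [p for p in config.exclude_participants
                    if p in set(cohort["participant_id"])]
        missing_excl = sorted(set(config.exclude_participants) - set(excluded))
        if missing_excl:
            raise ValueError(f"exclude_participants not in cohort: {missing_excl}")
        if excluded:
            cohort = cohort[~cohort["participant_id"].isin(excluded)]

        stage = "subgroup_filter"
        weight_split_info = None
        if config.weight_change_group is not None:
            split = weight_change_split(cohort, config.weight_change_threshold)
            weight_split_info = {
                "threshold_kg": config.weight_change_threshold,
                "group": config.weight_change_group,
                "n_stable": int(split.stable["participant_id"].nunique()),
                "n_changed": int(split.changed["participant_id"].nunique()),
                "n_unknown": int(split.unknown["participant_id"].nunique()),
            }
            cohort = getattr(split, config.weight_change_group)
        log.info("stage %-16s done (%.2fs)", stage, time.perf_counter() - t0)

        stage = "model_build"
        model = ReliabilityModel(
            cohort,
            hormones=list(config.hormones),
            covariates=list(config.covariates),
            assays=assays,
            log_transform=config.log_transform,
        )

        stage = "fit"
        results = model.fit(
            permutation_iterations=config.permutation_iterations,
            bootstrap_reps=config.bootstrap_reps,
            conf=config.conf_level,
            seed=config.seed,
        )
        log.info("stage %-16s done (%.2fs)", stage, time.perf_counter() - t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = results.to_dict()
    report["metadata"].update(
        config_hash=config.config_hash(),
        excluded_participants=excluded,
        weight_change_split=weight_split_info,
    )
    if len(report["hormones"]) != len(config.hormones):
        raise RuntimeError("pipeline dropped a configured hormone from the report")
    return report


def report_to_tsv(report: dict) -> str:
    """Flatten a report to a per-hormone TSV table."""
    cols = ["hormone", "icc", "icc_ci_low", "icc_ci_high", "icc_p", "category",
            "adj_icc", "adj_ci_low", "adj_ci_high", "adj_category", "perm_p"]
    lines = ["\t".join(cols)]
    for h, res in report["hormones"].items():
        icc = res["icc"]
        adj = res.get("adjusted_icc", {})
        row = [
            h,
            _fmt(icc["estimate"]), _fmt(icc["ci_low"]), _fmt(icc["ci_high"]),
            _fmt(icc["p_value"]), str(icc["category"]),
            _fmt(adj.get("estimate")), _fmt(adj.get("ci_low")),
            _fmt(adj.get("ci_high")), str(adj.get("category")),
            _fmt(res["permutation"]["p_value"]),
        ]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def report_to_forest_csv(report: dict) -> str:
    """Forest-plot export: ``label,estimate,ci_low,ci_high,panel`` rows, one
    panel per estimator (unadjusted vs adjusted)."""
    lines = ["label,estimate,ci_low,ci_high,panel"]
    for h, res in report["hormones"].items():
        icc = res["icc"]
        lines.append(
            f"{h},{_fmt(icc['estimate'])},{_fmt(icc['ci_low'])},"
            f"{_fmt(icc['ci_high'])},\"ICC(A,1)\""  # panel quoted: contains a comma
        )
        if "adjusted_icc" in res:
            adj = res["adjusted_icc"]
            lines.append(
                f"{h},{_fmt(adj['estimate'])},{_fmt(adj['ci_low'])},"
                f"{_fmt(adj['ci_high'])},Adjusted ICC"
            )
    return "\n".join(lines) + "\n"


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)
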
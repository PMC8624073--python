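"""Model/Results objects for the full reliability analysis.

:class:`ReliabilityModel` is built from a cohort table (wide format: one row
per participant x assessment) and, on :meth:`~ReliabilityModel.fit`, runs
for every hormone the paired permutation test (baseline vs follow-up), the
ICC(A,1) estimate with its F-based confidence interval and Koo & Li
category, and — when covariates are configured — the random-intercept mixed
model and the covariate-adjusted ICC with a parametric-bootstrap interval.
Covariates themselves also get baseline-vs-follow-up permutation tests.

The returned :class:`ReliabilityResults` carries the per-hormone estimates,
a ``summary()`` table, a tidy :meth:`~ReliabilityResults.frame`, and a
forest-plot-ready export. All randomness is driven by one master seed with
named substreams, so identical data + seed give identical results.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__ as _version
from .assay import AssayConfig, DEFAULT_ASSAYS, censor_series
from .icc import (
    ICCEstimate,
    VarianceComponents,
    adjusted_icc,
    fit_random_intercept_lmm,
    icc_a1,
)
from .permutation import PairedMatrix, PermutationResult, paired_permutation_test
from .simulate import COVARIATE_COLUMNS, long_to_cohort

__all__ = ["ReliabilityModel", "ReliabilityResults", "HormoneResult"]

DEFAULT_COVARIATES = ("glucose_mmol_l", "hba1c_pct", "activity_h_week", "diet_index")


def _derive_seed(master: Optional[int], label: str) -> Optional[int]:
    if master is None:
        return None
    digest = hashlib.sha256(f"{master}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


@dataclass
class HormoneResult:
    """All per-hormone outputs: unadjusted ICC, adjusted ICC, variance
    components and the BL-vs-FU permutation test."""

    hormone: str
    icc: ICCEstimate
    permutation: PermutationResult
    adjusted: Optional[ICCEstimate] = None
    variance_components: Optional[VarianceComponents] = None

    def to_dict(self) -> dict:
        out = {
            "hormone": self.hormone,
            "icc": self.icc.to_dict(),
            "permutation": self.permutation.to_dict(),
        }
        if self.adjusted is not None:
            out["adjusted_icc"] = self.adjusted.to_dict()
        if self.variance_components is not None:
            out["variance_components"] = self.variance_components.to_dict()
        return out


class ReliabilityModel:
    """Test-retest reliability model for a two-assessment hormone panel.

    Parameters
    ----------
    cohort
        Wide-format table with ``participant_id``, ``assessment`` (two
        levels, baseline first alphabetically unless ``assessments`` is
        given) plus one column per hormone and the covariate columns.
    hormones
        Hormone columns to analyse (default: the canonical four that are
        present).
    covariates
        Fixed-effect covariates for the adjusted ICC; empty disables the
        mixed-model stage.
    assays
        Optional per-hormone :class:`AssayConfig` used to censor raw values
        (detection limit / upper standard, ``"BDL"`` sentinel) before
        analysis.
    log_transform
        Analyse log-concentrations instead of raw pg/mL. Off by default:
        the reference analysis operated on raw concentrations.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        hormones: Optional[Sequence[str]] = None,
        covariates: Sequence[str] = DEFAULT_COVARIATES,
        assessments: Optional[tuple[str, str]] = None,
        assays: Optional[dict[str, AssayConfig]] = None,
        log_transform: bool = False,
    ) -> None:
        cohort = cohort.copy()
        required = {"participant_id", "assessment"}
        if not required.issubset(cohort.columns):
            raise KeyError(f"cohort table must contain columns {sorted(required)}")
        if hormones is None:
            hormones = [h for h in ("ghrelin", "leptin", "glp1", "pp") if h in cohort.columns]
            if not hormones:
                raise ValueError("no hormone columns found; pass hormones= explicitly")
        missing = [h for h in hormones if h not in cohort.columns]
        if missing:
            raise KeyError(f"hormone columns missing from cohort: {missing}")
        bad_cov = [c for c in covariates if c not in cohort.columns]
        if bad_cov:
            raise KeyError(f"covariate columns missing from cohort: {bad_cov}")
        if cohort.duplicated(["participant_id", "assessment"]).any():
            raise ValueError("duplicated (participant, assessment) rows in cohort")

        levels = sorted(cohort["assessment"].unique())
        if assessments is None:
            if set(levels) == {"BL", "FU"}:
                assessments = ("BL", "FU")
            elif len(levels) == 2:
                assessments = (levels[0], levels[1])
            else:
                raise ValueError(
                    f"expected exactly 2 assessment levels, found {levels}; "
                    "pass assessments=(baseline, followup)"
                )

        if assays:
            for h in hormones:
                if h in assays:
                    cohort[h] = censor_series(cohort[h], assays[h])
        for h in hormones:
            cohort[h] = pd.to_numeric(cohort[h])

        self.cohort = cohort
        self.hormones = list(hormones)
        self.covariates = list(covariates)
        self.assessments = assessments
        self.log_transform = bool(log_transform)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_long_csv(
        cls,
        path: Union[str, Path],
        apply_assays: bool = True,
        **kwargs,
    ) -> "ReliabilityModel":
        """Build from a long-format CSV
        (``participant_id,assessment,hormone,value_pgml,...``); the ``BDL``
        sentinel is honoured and, with ``apply_assays``, the default
        detection/ceiling censoring is applied."""
        long = pd.read_csv(path, dtype={"value_pgml": str})
        wide = long_to_cohort(long)
        assays = kwargs.pop("assays", DEFAULT_ASSAYS if apply_assays else None)
        hormones = kwargs.pop(
            "hormones",
            [h for h in ("ghrelin", "leptin", "glp1", "pp") if h in wide.columns]
            or [c for c in wide.columns if c not in
                ("participant_id", "assessment", *COVARIATE_COLUMNS)],
        )
        if assays is None:
            for h in hormones:
                wide[h] = pd.to_numeric(wide[h].replace({"BDL": "0"}))
        return cls(wide, hormones=hormones, assays=assays, **kwargs)

    # -- internals ----------------------------------------------------------

    def paired_matrix(self, column: str) -> PairedMatrix:
        """The complete-pairs n x 2 matrix of *column* (baseline, follow-up)."""
        wide = self.cohort.pivot(
            index="participant_id", columns="assessment", values=column
        )[list(self.assessments)].dropna()
        values = wide.to_numpy(dtype=float)
        if self.log_transform and column in self.hormones:
            if (values <= 0).any():
                raise ValueError(
                    f"log transform requested but {column} has non-positive values "
                    "(censored zeros cannot be log-transformed)"
                )
            values = np.log(values)
        return PairedMatrix(values, participant_ids=tuple(wide.index))

    def _analysis_frame(self, hormone: str) -> pd.DataFrame:
        cols = ["participant_id", "assessment", hormone, *self.covariates]
        frame = self.cohort[cols].dropna().copy()
        if self.log_transform:
            if (frame[hormone] <= 0).any():
                raise ValueError(f"non-positive {hormone} values under log transform")
            frame[hormone] = np.log(frame[hormone])
        counts = frame.groupby("participant_id").size()
        keep = counts[counts >= 2].index
        return frame[frame["participant_id"].isin(keep)]

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        permutation_iterations: int = 100_000,
        bootstrap_reps: int = 500,
        conf: float = 0.95,
        seed: Optional[int] = None,
    ) -> "ReliabilityResults":
        """Run the full analysis and return a :class:`ReliabilityResults`.

        ``seed`` drives every Monte Carlo component (permutation draws and
        the adjusted-ICC bootstrap) through named substreams.
        """
        hormone_results: dict[str, HormoneResult] = {}
        for h in self.hormones:
            pm = self.paired_matrix(h)
            perm = paired_permutation_test(
                pm, iterations=permutation_iterations,
                seed=_derive_seed(seed, f"perm:{h}"),
            )
            est = icc_a1(pm, conf=conf)
            adj = None
            vc = None
            if self.covariates:
                vc = fit_random_intercept_lmm(
                    self._analysis_frame(h), h, self.covariates
                )
                adj = adjusted_icc(
                    vc, bootstrap_reps=bootstrap_reps,
                    seed=_derive_seed(seed, f"boot:{h}"), conf=conf,
                )
            hormone_results[h] = HormoneResult(h, est, perm, adj, vc)

        covariate_tests: dict[str, PermutationResult] = {}
        for c in self.covariates:
            try:
                pm = self.paired_matrix(c)
            except ValueError:
                continue
            covariate_tests[c] = paired_permutation_test(
                pm, iterations=permutation_iterations,
                seed=_derive_seed(seed, f"perm:{c}"),
            )
        return ReliabilityResults(
            model=self,
            hormone_results=hormone_results,
            covariate_tests=covariate_tests,
            seed=seed,
            permutation_iterations=permutation_iterations,
            bootstrap_reps=bootstrap_reps,
            conf=conf,
        )


class ReliabilityResults:
    """Fitted reliability analysis for a hormone panel."""

    def __init__(
        self,
        model: ReliabilityModel,
        hormone_results: dict[str, HormoneResult],
        covariate_tests: dict[str, PermutationResult],
        seed: Optional[int],
        permutation_iterations: int,
        bootstrap_reps: int,
        conf: float,
    ) -> None:
        self.model = model
        self.hormone_results = hormone_results
        self.covariate_tests = covariate_tests
        self.seed = seed
        self.permutation_iterations = permutation_iterations
        self.bootstrap_reps = bootstrap_reps
        self.conf = conf

    def __getitem__(self, hormone: str) -> HormoneResult:
        return self.hormone_results[hormone]

    def frame(self) -> pd.DataFrame:
        """Tidy per-hormone table: ICC, CI, p, category, adjusted ICC, CI,
        permutation p — one row per hormone."""
        rows = []
        for h, res in self.hormone_results.items():
            row = {
                "hormone": h,
                "icc": res.icc.estimate,
                "icc_ci_low": res.icc.ci_low,
                "icc_ci_high": res.icc.ci_high,
                "icc_p": res.icc.p_value,
                "category": res.icc.category,
                "perm_p": res.permutation.p_value,
            }
            if res.adjusted is not None:
                row.update(
                    adj_icc=res.adjusted.estimate,
                    adj_ci_low=res.adjusted.ci_low,
                    adj_ci_high=res.adjusted.ci_high,
                    adj_category=res.adjusted.category,
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def forest_frame(self) -> pd.DataFrame:
        """Forest-plot-ready rows: ``label,estimate,ci_low,ci_high,panel``
        with one panel for the ICC and one for the adjusted ICC."""
        rows = []
        for h, res in self.hormone_results.items():
            rows.append(
                {"label": h, "estimate": res.icc.estimate,
                 "ci_low": res.icc.ci_low, "ci_high": res.icc.ci_high,
                 "panel": "ICC(A,1)"}
            )
            if res.adjusted is not None:
                rows.append(
                    {"label": h, "estimate": res.adjusted.estimate,
                     "ci_low": res.adjusted.ci_low, "ci_high": res.adjusted.ci_high,
                     "panel": "Adjusted ICC"}
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "hormones": {h: r.to_dict() for h, r in self.hormone_results.items()},
            "covariate_permutation_tests": {
                c: r.to_dict() for c, r in self.covariate_tests.items()
            },
            "metadata": {
                "n_participants": int(self.model.cohort["participant_id"].nunique()),
                "assessments": list(self.model.assessments),
                "covariates": self.model.covariates,
                "log_transform": self.model.log_transform,
                "seed": self.seed,
                "permutation_iterations": self.permutation_iterations,
                "bootstrap_reps": self.bootstrap_reps,
                "conf_level": self.conf,
                "version": _version,
            },
        }

    def to_json(self, path: Optional[Union[str, Path]] = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def summary(self) -> str:
        """Human-readable summary table in the spirit of a fitted-model
        summary: one row per hormone with estimates, intervals and tests."""
        lines = [
            "Test-retest reliability of repeated hormone measurements",
            f"participants: {self.model.cohort['participant_id'].nunique()}"
            f"   assessments: {' vs '.join(self.model.assessments)}"
            f"   scale: {'log' if self.model.log_transform else 'raw pg/mL'}",
            f"covariates (adjusted ICC): {', '.join(self.model.covariates) or 'none'}",
            "-" * 78,
            f"{'hormone':<10}{'ICC(A,1)':>9}{'95% CI':>16}{'p':>9}"
            f"{'category':>11}{'adj ICC':>9}{'95% CI':>16}",
            "-" * 78,
        ]
        for h, res in self.hormone_results.items():
            ci = f"[{res.icc.ci_low:.2f}, {res.icc.ci_high:.2f}]"
            p = "n/a" if res.icc.p_value is None else f"{res.icc.p_value:.4f}"
            if res.adjusted is not None:
                adj = f"{res.adjusted.estimate:9.2f}"
                adj_ci = f"[{res.adjusted.ci_low:.2f}, {res.adjusted.ci_high:.2f}]"
            else:
                adj, adj_ci = f"{'--':>9}", "--"
            lines.append(
                f"{h:<10}{res.icc.estimate:9.2f}{ci:>16}{p:>9}"
                f"{res.icc.category or 'n/a':>11}{adj}{adj_ci:>16}"
            )
        lines.append("-" * 78)
        lines.append(
            f"{'hormone':<10}{'BL vs FU permutation p':>25}   "
            f"({self.permutation_iterations} iterations, two-sided)"
        )
        for h, res in self.hormone_results.items():
            lines.append(f"{h:<10}{res.permutation.p_value:>25.4f}")
        if self.covariate_tests:
            for c, res in self.covariate_tests.items():
                lines.append(f"{c:<18}{res.p_value:>17.4f}")
        return "\n".join(lines)
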
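"""Deterministic ELISA post-processing: dilution correction and censoring.

Plasma hormone concentrations come off the plate reader already interpolated
from the standard curve, but two deterministic rules are applied before any
statistics: samples flagged below the kit's detection limit are reported as
0 pg/mL, and samples above the highest calibrator are censored to that
calibrator's concentration (a ceiling is defined only for kits that need one,
e.g. pancreatic polypeptide at 2276.02 pg/mL).  Because samples are diluted
in assay buffer before the run, plate-level readings are multiplied back by
the dilution factor first; censoring always operates on the final reported
concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "AssayConfig",
    "BDL",
    "is_below_detection",
    "apply_dilution",
    "apply_assay_limits",
    "process_measurement",
    "censor_series",
    "DEFAULT_ASSAYS",
]

#: Sentinel accepted in input files for a sample below the detection limit.
#: An explicit flag is used instead of a magic number because 0 is also a
#: legal *output* of the censoring rule.
BDL = "BDL"


@dataclass(frozen=True)
class AssayConfig:
    """Per-hormone assay settings.

    Parameters
    ----------
    hormone
        Analyte name (lower-case canonical: ``ghrelin``, ``leptin``,
        ``glp1``, ``pp``).
    detection_limit
        Kit detection limit in pg/mL. Values below it are reported as 0.
        Kits do not always publish one; 0 disables the floor.
    upper_standard
        Highest calibrator in pg/mL, or ``None`` when no ceiling applies.
        Values above it are censored to it.
    dilution_factor
        Dimensionless dilution ratio (10 for a 1:10 dilution).
    """

    hormone: str
    detection_limit: float = 0.0
    upper_standard: Optional[float] = None
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.detection_limit < 0:
            raise ValueError("detection_limit must be >= 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if self.upper_standard is not None and self.upper_standard <= self.detection_limit:
            raise ValueError("upper_standard must exceed detection_limit")


#: Dilutions used for the four gastrointestinal hormones (ghrelin 1:10,
#: leptin 1:50, GLP-1 1:6, PP 1:2); only the PP kit defines a ceiling.
DEFAULT_ASSAYS: dict[str, AssayConfig] = {
    "ghrelin": AssayConfig("ghrelin", dilution_factor=10),
    "leptin": AssayConfig("leptin", dilution_factor=50),
    "glp1": AssayConfig("glp1", dilution_factor=6),
    "pp": AssayConfig("pp", dilution_factor=2, upper_standard=2276.02),
}


def is_below_detection(value: Union[float, str, None]) -> bool:
    """True if *value* is the below-detection flag (``"BDL"``, empty, None)."""
    if value is None:
        return True
    if isinstance(value, str):
        return value.strip().upper() in {BDL, ""}
    return False


def _check_concentration(value: float, what: str) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{what} must be a finite non-negative concentration, got {value!r}")
    return value


def apply_dilution(measured: float, config: AssayConfig) -> float:
    """Back-correct a plate-level reading for its dilution in assay buffer."""
    return _check_concentration(measured, "measured") * config.dilution_factor


def apply_assay_limits(value: Union[float, str, None], config: AssayConfig) -> float:
    """Censor a reported concentration at the kit's detection limit and
    highest standard.

    A below-detection flag, or any value under ``detection_limit``, maps to
    0; anything above ``upper_standard`` maps to the upper standard; values
    in range pass through unchanged.  Idempotent.
    """
    if is_below_detection(value):
        return 0.0
    value = _check_concentration(value, "value")  # type: ignore[arg-type]
    if value < config.detection_limit:
        return 0.0
    if config.upper_standard is not None and value > config.upper_standard:
        return config.upper_standard
    return value


def process_measurement(
    measured: Union[float, str, None], config: AssayConfig
) -> float:
    """Full plate-to-report pathway: dilution correction, then censoring."""
    if is_below_detection(measured):
        return 0.0
    return apply_assay_limits(apply_dilution(measured, config), config)  # type: ignore[arg-type]


def censor_series(values: pd.Series, config: AssayConfig) -> pd.Series:
    """Vectorised :func:`apply_assay_limits` over a pandas Series.

    String entries equal to the BDL sentinel (or empty) become 0; NaN marks
    a genuinely missing sample and is preserved as NaN, not censored.
    """
    out = np.empty(len(values), dtype=float)
    for i, v in enumerate(values.to_numpy()):
        if isinstance(v, float) and math.isnan(v):
            out[i] = math.nan
        else:
            out[i] = apply_assay_limits(v, config)
    return pd.Series(out, index=values.index, name=values.name)
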
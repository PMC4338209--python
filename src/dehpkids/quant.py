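"""Urinary metabolite quantification: calibration QC, censoring, normalization.

Raw HPLC-ESI-MS results enter as peak areas (calibration standards) or as
concentrations in μg/L. This module turns them into analysis-ready values:

* :func:`fit_calibration` / :func:`quantify` — ordinary least-squares
  calibration lines with an r² quality gate.
* :func:`censor` — assign a detection status from the assay's limit of
  detection (LOD) and limit of quantification (LOQ).
* :func:`normalize_creatinine` — dilution correction to μg analyte per g
  urinary creatinine.
* :func:`process_cohort` / :func:`detectability_table` — cohort-level
  application, including the per-group percent-detectable summary.

Non-detects propagate downstream as missing values (complete-case analysis);
LOD/√2 substitution is available behind ``impute_nondetects=True``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

#: Canonical metabolite keys, hydrolytic product first.
METABOLITES: tuple[str, ...] = (
    "MEHP",
    "5-OH-MEHP",
    "5-oxo-MEHP",
    "5-Cx-MEHP",
    "6-OH-MEHP",
)

#: Assay limits of detection in urine, μg/L.
LOD_UG_L: dict[str, float] = {
    "MEHP": 0.014,
    "5-OH-MEHP": 0.016,
    "5-oxo-MEHP": 0.016,
    "5-Cx-MEHP": 0.019,
    "6-OH-MEHP": 0.002,
}

#: Assay lower limits of quantification, μg/L.  A LOQ can never sit below its
#: LOD; the 5-Cx-MEHP figure circulates with a shifted decimal (0.0051) and is
#: stored here corrected to 0.051.
LOQ_UG_L: dict[str, float] = {
    "MEHP": 0.042,
    "5-OH-MEHP": 0.048,
    "5-oxo-MEHP": 0.049,
    "5-Cx-MEHP": 0.051,
    "6-OH-MEHP": 0.008,
}

BELOW_LOD = "below_LOD"
BETWEEN_LOD_LOQ = "between_LOD_LOQ"
QUANTIFIED = "quantified"

#: Default calibration acceptance threshold on r².
QC_R2_THRESHOLD = 0.998


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line of peak area on standard concentration (ng/mL)."""

    slope: float
    intercept: float
    r2: float
    qc_pass: bool


def fit_calibration(
    standards: Sequence[tuple[float, float]],
    qc_threshold: float = QC_R2_THRESHOLD,
) -> CalibrationCurve:
    """Fit a calibration line to (concentration ng/mL, peak area) standards.

    The line is ordinary least squares of area on concentration; ``r2`` is the
    squared Pearson correlation of the points and the curve passes QC when
    ``r2 > qc_threshold`` (default 0.998).
    """
    pts = np.asarray(standards, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (concentration, area) standards")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise ValueError("degenerate calibration design: all concentrations identical")
    fit = _sps.linregress(x, y)
    r2 = float(fit.rvalue**2)
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=r2,
        qc_pass=bool(r2 > qc_threshold),
    )


def quantify(peak_area: float, curve: CalibrationCurve) -> float:
    """Invert a calibration line: concentration = (area − intercept) / slope.

    Negative back-calculated concentrations are floored to 0 with a warning.
    """
    if not curve.qc_pass:
        raise ValueError(f"calibration failed QC (r2={curve.r2:.6f})")
    if curve.slope == 0:
        raise ValueError("calibration slope is zero")
    conc = (peak_area - curve.intercept) / curve.slope
    if conc < 0:
        warnings.warn(
            f"negative back-calculated concentration {conc:.4g} floored to 0",
            stacklevel=2,
        )
        return 0.0
    return float(conc)


def censor(
    conc: float,
    metabolite_key: str,
    lod: Mapping[str, float] | None = None,
    loq: Mapping[str, float] | None = None,
) -> str:
    """Detection status of a raw concentration (μg/L).

    Bands are half-open: strictly below LOD → ``below_LOD``; [LOD, LOQ) →
    ``between_LOD_LOQ``; at or above LOQ → ``quantified``.
    """
    lod = LOD_UG_L if lod is None else lod
    loq = LOQ_UG_L if loq is None else loq
    if metabolite_key not in lod or metabolite_key not in loq:
        raise KeyError(f"no LOD/LOQ configured for {metabolite_key!r}")
    if conc < 0 or not math.isfinite(conc):
        raise ValueError(f"concentration must be finite and non-negative, got {conc}")
    if conc < lod[metabolite_key]:
        return BELOW_LOD
    if conc < loq[metabolite_key]:
        return BETWEEN_LOD_LOQ
    return QUANTIFIED


def normalize_creatinine(conc_ug_l: float, creatinine_g_l: float) -> float:
    """Creatinine dilution correction: μg/L ÷ g/L → μg analyte per g creatinine."""
    if not creatinine_g_l > 0:
        raise ValueError(f"creatinine must be positive, got {creatinine_g_l}")
    return conc_ug_l / creatinine_g_l


def process_cohort(
    cohort: pd.DataFrame,
    impute_nondetects: bool = False,
    lod: Mapping[str, float] | None = None,
    loq: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Add normalized concentrations and detection statuses to a cohort table.

    Expects the wide cohort dialect: per metabolite a ``<met>_ugL`` column and
    a ``<met>_detected`` flag (non-detects carry the LOD in the value column),
    plus ``creatinine_gL``.  Adds ``<met>_status`` and ``<met>_ug_per_g``;
    non-detects become NaN unless ``impute_nondetects`` substitutes LOD/√2.
    """
    lod = LOD_UG_L if lod is None else lod
    out = cohort.copy()
    creat = out["creatinine_gL"].to_numpy(dtype=float)
    if np.any(creat <= 0):
        raise ValueError("creatinine must be positive for every subject")
    for met in METABOLITES:
        raw = out[f"{met}_ugL"].to_numpy(dtype=float)
        detected = out[f"{met}_detected"].to_numpy(dtype=bool)
        status = np.array(
            [
                censor(c, met, lod=lod, loq=loq) if d else BELOW_LOD
                for c, d in zip(raw, detected)
            ]
        )
        value = np.where(detected, raw, lod[met] / math.sqrt(2) if impute_nondetects else np.nan)
        out[f"{met}_status"] = status
        out[f"{met}_ug_per_g"] = value / creat
    return out


def detectability_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Percent of subjects per group with each metabolite at or above LOD.

    Rows are groups, columns metabolites; denominators are the full group
    sizes and percentages are rounded to one decimal.  Empty groups are
    omitted with a warning.
    """
    if "group" not in cohort.columns:
        raise ValueError("cohort table lacks a 'group' column")
    rows = {}
    for grp, sub in cohort.groupby("group", sort=True):
        if len(sub) == 0:  # pragma: no cover - groupby never yields empties
            warnings.warn(f"group {grp!r} is empty; omitted", stacklevel=2)
            continue
        rows[grp] = {
            met: round(100.0 * sub[f"{met}_detected"].sum() / len(sub), 1)
            for met in METABOLITES
        }
    if not rows:
        warnings.warn("no non-empty groups; detectability table is empty", stacklevel=2)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(METABOLITES))
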
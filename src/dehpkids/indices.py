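"""OGTT-derived insulin sensitivity and resistance indices.

All functions are pure and operate on a five-point oral glucose tolerance
test (samples at 0, 30, 60, 90 and 120 min): glucose in mg/dl, insulin in
mIU/L (≡ μU/mL).

* HOMA-IR = G₀(mmol/L) · I₀(mIU/L) / 22.5
* FGIR    = G₀(mg/dl) / I₀(μU/mL)            (lower = more resistant)
* insulinogenic index = ΔI(0–30) / ΔG(0–30)  (β-cell function proxy)
* WBISI (Matsuda composite) = 10000 / √(G₀·I₀·Ḡ·Ī) with unweighted means
  over all five sampling times
* AUCG / AUCI by trapezoidal integration, reported in raw value·min

Insulin-resistance classification compares HOMA-IR against age/puberty
cutoffs supplied as configuration; no cutoffs are hard-coded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Protocol sampling times, minutes after the glucose load.
OGTT_TIMES: tuple[int, ...] = (0, 30, 60, 90, 120)

#: mg/dl per mmol/L for glucose (molar mass 180.16 g/mol).
MG_DL_PER_MMOL_L = 18.016


@dataclass(frozen=True)
class OGTTCurve:
    """Paired glucose/insulin series over the five protocol time points."""

    times: tuple[float, ...]
    glucose: tuple[float, ...]  # mg/dl
    insulin: tuple[float, ...]  # mIU/L

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.glucose) or len(self.times) != len(self.insulin):
            raise ValueError("times, glucose and insulin must have equal length")
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must start at 0 and increase strictly")
        if min(self.glucose) <= 0 or min(self.insulin) <= 0:
            raise ValueError("glucose and insulin must be strictly positive")


@dataclass(frozen=True)
class InsulinIndices:
    homa_ir: float
    fgir: float
    insulinogenic: float  # NaN when the glucose excursion is zero
    wbisi: float
    aucg: float  # mg·min/dl
    auci: float  # mIU·min/L
    ir_flag: bool | None  # None when no threshold rule matches


def glucose_to_mmol(glucose_mg_dl: float) -> float:
    """Convert glucose from mg/dl to mmol/L."""
    if glucose_mg_dl < 0:
        raise ValueError("glucose cannot be negative")
    return glucose_mg_dl / MG_DL_PER_MMOL_L


def homa_ir(g0_mg_dl: float, i0_miu_l: float) -> float:
    """Homeostasis model assessment of insulin resistance."""
    if g0_mg_dl <= 0 or i0_miu_l <= 0:
        raise ValueError("fasting glucose and insulin must be positive")
    return glucose_to_mmol(g0_mg_dl) * i0_miu_l / 22.5


def fgir(g0_mg_dl: float, i0_uu_ml: float) -> float:
    """Fasting glucose-to-insulin ratio, G₀(mg/dl)/I₀(μU/mL)."""
    if i0_uu_ml <= 0:
        raise ValueError("fasting insulin must be positive")
    return g0_mg_dl / i0_uu_ml


def insulinogenic_index(curve: OGTTCurve) -> float:
    """ΔI(0–30)/ΔG(0–30); NaN with a warning when ΔG is zero."""
    if 30 not in curve.times:
        raise ValueError("insulinogenic index requires the 30-min sample")
    i30 = curve.insulin[curve.times.index(30)]
    g30 = curve.glucose[curve.times.index(30)]
    dg = g30 - curve.glucose[0]
    if dg == 0:
        warnings.warn("zero 0-30 min glucose excursion; insulinogenic index undefined", stacklevel=2)
        return math.nan
    return (i30 - curve.insulin[0]) / dg


def auc_trapezoid(times: Sequence[float], values: Sequence[float]) -> float:
    """Trapezoidal area under a sampled curve, in value·min."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2 or t.size != v.size:
        raise ValueError("need at least two (time, value) points of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(v, t))


def wbisi(curve: OGTTCurve, time_weighted: bool = False) -> float:
    """Matsuda–DeFronzo whole-body insulin sensitivity index.

    10000/√(G₀·I₀·Ḡ·Ī).  By default Ḡ and Ī are the unweighted means of all
    five sampling times; ``time_weighted`` switches to trapezoid-weighted
    means (AUC divided by the sampling span).
    """
    if len(curve.times) != len(OGTT_TIMES) or tuple(curve.times) != OGTT_TIMES:
        raise ValueError(f"WBISI requires the full {OGTT_TIMES} min curve")
    if time_weighted:
        span = curve.times[-1] - curve.times[0]
        g_mean = auc_trapezoid(curve.times, curve.glucose) / span
        i_mean = auc_trapezoid(curve.times, curve.insulin) / span
    else:
        g_mean = float(np.mean(curve.glucose))
        i_mean = float(np.mean(curve.insulin))
    prod = curve.glucose[0] * curve.insulin[0] * g_mean * i_mean
    return 10000.0 / math.sqrt(prod)


def classify_ir(
    homa: float,
    age: float,
    pubertal: bool,
    thresholds: Sequence[Mapping] | None,
) -> bool | None:
    """True iff HOMA-IR exceeds the matching age/puberty cutoff.

    ``thresholds`` is a sequence of rules ``{"pubertal": bool|None,
    "age_min": float, "age_max": float, "cutoff": float}`` (missing bounds
    are open); the first matching rule applies.  Returns None with a warning
    when nothing matches or no table is supplied.
    """
    if thresholds:
        for rule in thresholds:
            want_pub = rule.get("pubertal")
            if want_pub is not None and bool(want_pub) != bool(pubertal):
                continue
            if age < rule.get("age_min", -math.inf) or age > rule.get("age_max", math.inf):
                continue
            return bool(homa > rule["cutoff"])
    warnings.warn(
        f"no insulin-resistance cutoff matches age={age}, pubertal={pubertal}",
        stacklevel=2,
    )
    return None


def tune_ir_thresholds(homa_values: Sequence[float], prevalence: float) -> list[dict]:
    """Single global cutoff such that round(prevalence·n) subjects exceed it.

    Convenience for studies that report an insulin-resistance prevalence but
    not the cutoff table itself; the returned rule list plugs straight into
    :func:`classify_ir`.
    """
    h = np.sort(np.asarray([x for x in homa_values if math.isfinite(x)], dtype=float))
    if h.size == 0:
        raise ValueError("no finite HOMA values to tune against")
    if not 0 <= prevalence <= 1:
        raise ValueError("prevalence must lie in [0, 1]")
    k = int(round(prevalence * h.size))  # number flagged
    if k <= 0:
        cutoff = float(h[-1])  # nobody exceeds the maximum
    elif k >= h.size:
        cutoff = float(h[0] - 1.0)
    else:
        cutoff = float(0.5 * (h[-k] + h[-k - 1]))
    return [{"pubertal": None, "cutoff": cutoff}]


def prevalence_percent(count: int, total: int) -> int:
    """Prevalence as a whole-number percentage, e.g. 9 of 39 → 23."""
    if total <= 0 or count < 0 or count > total:
        raise ValueError("need 0 <= count <= total with total > 0")
    return int(round(100.0 * count / total))


def compute_indices(
    curve: OGTTCurve,
    age: float | None = None,
    pubertal: bool | None = None,
    ir_thresholds: Sequence[Mapping] | None = None,
) -> InsulinIndices:
    """All indices for one subject; ir_flag only when a threshold table is given."""
    h = homa_ir(curve.glucose[0], curve.insulin[0])
    flag = None
    if ir_thresholds is not None and age is not None and pubertal is not None:
        flag = classify_ir(h, age, pubertal, ir_thresholds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-subject NaN flags surface in the table
        igi = insulinogenic_index(curve)
    return InsulinIndices(
        homa_ir=h,
        fgir=fgir(curve.glucose[0], curve.insulin[0]),
        insulinogenic=igi,
        wbisi=wbisi(curve),
        aucg=auc_trapezoid(curve.times, curve.glucose),
        auci=auc_trapezoid(curve.times, curve.insulin),
        ir_flag=flag,
    )


def curve_from_row(row: Mapping) -> OGTTCurve:
    """Build an OGTT curve from the wide cohort-CSV dialect."""
    return OGTTCurve(
        times=tuple(float(t) for t in OGTT_TIMES),
        glucose=tuple(float(row[f"glucose_{t}"]) for t in OGTT_TIMES),
        insulin=tuple(float(row[f"insulin_{t}"]) for t in OGTT_TIMES),
    )


def indices_table(
    cohort: pd.DataFrame,
    ir_thresholds: Sequence[Mapping] | None = None,
) -> pd.DataFrame:
    """Per-subject index table for a wide cohort table."""
    records = []
    for _, row in cohort.iterrows():
        idx = compute_indices(
            curve_from_row(row),
            age=row.get("age"),
            pubertal=row.get("pubertal"),
            ir_thresholds=ir_thresholds,
        )
        records.append(
            {
                "subject_id": row["subject_id"],
                "group": row["group"],
                "homa_ir": idx.homa_ir,
                "fgir": idx.fgir,
                "insulinogenic": idx.insulinogenic,
                "wbisi": idx.wbisi,
                "aucg": idx.aucg,
                "auci": idx.auci,
                "ir_flag": idx.ir_flag,
            }
        )
    return pd.DataFrame.from_records(records)


def group_summary(indices: pd.DataFrame) -> pd.DataFrame:
    """Median (25th–75th percentile) of each index per group."""
    cols = ["homa_ir", "fgir", "insulinogenic", "wbisi", "aucg", "auci"]
    rows = {}
    for grp, sub in indices.groupby("group", sort=True):
        rows[grp] = {
            col: "{:.2f} ({:.2f}-{:.2f})".format(
                sub[col].median(), sub[col].quantile(0.25), sub[col].quantile(0.75)
            )
            for col in cols
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)
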
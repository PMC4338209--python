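"""Seeded synthetic paediatric cohorts for the DEHP/insulin-sensitivity pipeline.

The study population this emulates is 41 obese and 31 normal-weight children
(comparable age and sex mix, ~2/3 pubertal), with first-morning urinary DEHP
metabolite panels and a five-point OGTT.  The generator reproduces the
published summary structure — per-(group × puberty) metabolite medians,
group contrasts in fasting insulin, detectability censoring at the assay
LODs — and injects chosen rank correlations through a Gaussian copula on the
latent normal scales (Spearman ρ_s converted to latent Pearson via
ρ_p = 2·sin(π·ρ_s/6)).

Marginals: metabolite concentrations and fasting insulin are log-normal
(positive, right-skewed, multiplicative group/puberty median shifts); ages,
SDS values and fasting glucose are normal; urinary creatinine is log-uniform
over its configured range (median = geometric midpoint).  OGTT excursions
follow a fixed shape template (per-time multipliers of the fasting value)
with log-normal subject noise.

Everything is driven by one seed through splittable `numpy` SeedSequence
streams, so identical configs give byte-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .quant import LOD_UG_L, METABOLITES

GROUPS = ("obese", "control")
OGTT_TIMES = (0, 30, 60, 90, 120)

#: Latent variables tied together by the Gaussian copula, in fixed order.
LATENT_VARS = ("age", *METABOLITES, "insulin_0")

# Raw-concentration medians (μg/L) per metabolite per (group, pubertal) cell.
# With creatinine log-uniform around a median of 1 g/L these coincide with the
# creatinine-normalized μg/g cell medians of the study population.
_DEFAULT_CELL_MEDIANS: dict[str, dict[tuple[str, bool], float]] = {
    "MEHP": {("control", False): 0.15, ("control", True): 0.04,
             ("obese", False): 0.27, ("obese", True): 0.10},
    "5-OH-MEHP": {("control", False): 0.14, ("control", True): 0.10,
                  ("obese", False): 1.24, ("obese", True): 0.43},
    "5-Cx-MEHP": {("control", False): 1.46, ("control", True): 0.78,
                  ("obese", False): 0.76, ("obese", True): 0.60},
    "5-oxo-MEHP": {("control", False): 0.14, ("control", True): 0.14,
                   ("obese", False): 0.35, ("obese", True): 0.30},
    "6-OH-MEHP": {("control", False): 0.41, ("control", True): 0.25,
                  ("obese", False): 1.05, ("obese", True): 0.56},
}


def _default_target_spearman() -> pd.DataFrame:
    """Default injected rank correlations on the latent scale.

    MEHP falls with age (ρ_s = −0.35); the five metabolites share a common
    exposure/metabolism source (pairwise 0.4); 6-OH-MEHP rises with fasting
    insulin (0.365).  Signs follow the study's correlation tables.
    """
    k = len(LATENT_VARS)
    m = pd.DataFrame(np.eye(k), index=LATENT_VARS, columns=LATENT_VARS)
    m.loc["age", "MEHP"] = m.loc["MEHP", "age"] = -0.35
    for i, a in enumerate(METABOLITES):
        for b in METABOLITES[i + 1:]:
            m.loc[a, b] = m.loc[b, a] = 0.40
    m.loc["6-OH-MEHP", "insulin_0"] = m.loc["insulin_0", "6-OH-MEHP"] = 0.365
    return m


def spearman_to_pearson(rho_s: np.ndarray) -> np.ndarray:
    """Bivariate-normal conversion ρ_p = 2·sin(π·ρ_s/6) (elementwise)."""
    return 2.0 * np.sin(np.pi * np.asarray(rho_s, dtype=float) / 6.0)


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults emulate the study population."""

    n_obese: int = 41
    n_control: int = 31
    prop_pubertal: dict = field(
        default_factory=lambda: {"obese": 27 / 41, "control": 20 / 31}
    )
    prop_male: dict = field(
        default_factory=lambda: {"obese": 22 / 41, "control": 19 / 31}
    )
    # (mean, SD) in years; SDs back-computed from reported SEMs (SEM·√n).
    age_mean_sd: dict = field(
        default_factory=lambda: {"obese": (12.53, 3.07), "control": (12.69, 3.67)}
    )
    ht_sds_mean_sd: dict = field(
        default_factory=lambda: {"obese": (0.91, 1.02), "control": (-0.91, 1.67)}
    )
    bmi_sds_mean_sd: dict = field(
        default_factory=lambda: {"obese": (3.41, 0.41), "control": (-0.12, 1.21)}
    )
    bw_sds_mean_sd: dict = field(
        default_factory=lambda: {"obese": (0.20, 0.90), "control": (-0.30, 0.90)}
    )
    waist_cm_mean_sd: tuple = (107.0, 16.3)        # obese only
    waist_to_height_mean_sd: tuple = (0.68, 0.064)  # obese only
    age_onset_mean_sd: tuple = (5.2, 3.2)           # obese only, years
    metabolite_log_medians: dict = field(
        default_factory=lambda: {m: dict(v) for m, v in _DEFAULT_CELL_MEDIANS.items()}
    )
    metabolite_log_sd: float = 1.0
    creatinine_range: tuple = (0.5, 2.0)  # g/L, log-uniform
    glucose_baseline_mean_sd: dict = field(
        default_factory=lambda: {"obese": (82.8, 6.4), "control": (80.2, 6.7)}
    )
    insulin_log_median: dict = field(
        default_factory=lambda: {"obese": 15.9, "control": 8.5}  # mIU/L
    )
    insulin_log_sd: float = 0.5
    # Per-time multipliers of the fasting value at 0/30/60/90/120 min.
    ogtt_shape_glucose: tuple = (1.0, 1.55, 1.40, 1.20, 1.10)
    ogtt_shape_insulin: tuple = (1.0, 6.0, 5.5, 4.0, 3.0)
    ogtt_noise_log_sd: float = 0.08
    glucose_floor: float = 40.0  # mg/dl clamp
    target_spearman: pd.DataFrame = field(default_factory=_default_target_spearman)
    ir_prevalence_obese: float = 9 / 39
    mets_prevalence_obese: float = 18 / 39
    lod: dict = field(default_factory=lambda: dict(LOD_UG_L))
    seed: int = 0

    def validate(self) -> None:
        if self.n_obese <= 0 or self.n_control <= 0:
            raise ValueError("group sizes must be positive")
        for name, frac_map in (("prop_pubertal", self.prop_pubertal),
                               ("prop_male", self.prop_male)):
            for g, f in frac_map.items():
                if not 0 <= f <= 1:
                    raise ValueError(f"{name}[{g!r}] must lie in [0, 1]")
        for f in (self.ir_prevalence_obese, self.mets_prevalence_obese):
            if not 0 <= f <= 1:
                raise ValueError("prevalences must lie in [0, 1]")
        if self.metabolite_log_sd < 0 or self.insulin_log_sd < 0:
            raise ValueError("log-SDs must be non-negative")
        unknown = set(self.metabolite_log_medians) - set(METABOLITES)
        if unknown:
            raise ValueError(f"unknown metabolite keys in config: {sorted(unknown)}")
        missing = set(METABOLITES) - set(self.metabolite_log_medians)
        if missing:
            raise ValueError(f"metabolite medians missing for: {sorted(missing)}")
        if not (0 < self.creatinine_range[0] < self.creatinine_range[1]):
            raise ValueError("creatinine_range must be 0 < lo < hi")
        self._pearson_corr()  # raises on invalid targets

    def _pearson_corr(self) -> np.ndarray:
        m = self.target_spearman.loc[list(LATENT_VARS), list(LATENT_VARS)].to_numpy(dtype=float)
        if not np.allclose(m, m.T):
            raise ValueError("target_spearman must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("target_spearman must have unit diagonal")
        off = m[~np.eye(m.shape[0], dtype=bool)]
        if off.size and (off.min() <= -1 or off.max() >= 1):
            raise ValueError("off-diagonal Spearman targets must lie in (−1, 1)")
        pearson = spearman_to_pearson(m)
        np.fill_diagonal(pearson, 1.0)
        eig = np.linalg.eigvalsh(pearson)
        if eig.min() < -1e-10:
            raise ValueError(
                "target correlation is not positive semi-definite after "
                f"rank-to-Pearson conversion (smallest eigenvalue {eig.min():.6g})"
            )
        return pearson


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str  # {"obese", "control"}
    sex: str  # {"M", "F"}
    age: float
    pubertal: bool
    ht_sds: float
    bmi_sds: float
    birth_weight_sds: float
    waist_cm: float | None
    waist_to_height: float | None
    age_onset_obesity: float | None
    mets_flag: bool

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.waist_to_height is not None and not (0.3 < self.waist_to_height < 1.0):
            raise ValueError("waist-to-height ratio outside (0.3, 1.0)")
        if self.age_onset_obesity is not None:
            if self.group == "control":
                raise ValueError("controls carry no age at onset of obesity")
            if self.age_onset_obesity > self.age:
                raise ValueError("age at onset of obesity exceeds current age")


def generate_ogtt(
    subject: SubjectRecord,
    rng: np.random.Generator,
    config: SyntheticConfig,
    z_insulin: float | None = None,
) -> dict[str, float]:
    """Five-point OGTT for one subject: glucose_0..120 (mg/dl), insulin_0..120 (mIU/L).

    The fasting values anchor the curve; later time points are fasting ×
    shape multiplier × log-normal noise, clamped at a positive floor.
    ``z_insulin`` is the copula latent for fasting insulin (fresh iid normal
    when absent).
    """
    g_mean, g_sd = config.glucose_baseline_mean_sd[subject.group]
    g0 = max(config.glucose_floor, g_mean + g_sd * rng.standard_normal())
    if z_insulin is None:
        z_insulin = rng.standard_normal()
    i0 = config.insulin_log_median[subject.group] * math.exp(
        config.insulin_log_sd * z_insulin
    )
    out: dict[str, float] = {}
    for k, t in enumerate(OGTT_TIMES):
        if t == 0:
            g, i = g0, i0
        else:
            g = g0 * config.ogtt_shape_glucose[k] * math.exp(
                config.ogtt_noise_log_sd * rng.standard_normal()
            )
            i = i0 * config.ogtt_shape_insulin[k] * math.exp(
                config.ogtt_noise_log_sd * rng.standard_normal()
            )
        out[f"glucose_{t}"] = max(config.glucose_floor, g)
        out[f"insulin_{t}"] = max(1e-3, i)
    return out


def generate_metabolites(
    subject: SubjectRecord,
    rng: np.random.Generator,
    config: SyntheticConfig,
    z: Mapping[str, float] | None = None,
) -> dict[str, float | bool]:
    """Urinary panel for one subject: raw μg/L, detect flags and creatinine.

    Concentrations are log-normal around the subject's (group × pubertal)
    cell median; draws below the LOD are emitted as non-detects carrying the
    LOD value.  ``z`` maps metabolite → copula latent (iid when absent).
    """
    cell = (subject.group, subject.pubertal)
    out: dict[str, float | bool] = {}
    for met in METABOLITES:
        median = config.metabolite_log_medians[met][cell]
        z_m = z[met] if z is not None else rng.standard_normal()
        draw = median * math.exp(config.metabolite_log_sd * z_m)
        detected = draw >= config.lod[met]
        out[f"{met}_ugL"] = draw if detected else config.lod[met]
        out[f"{met}_detected"] = bool(detected)
    lo, hi = config.creatinine_range
    out["creatinine_gL"] = math.exp(rng.uniform(math.log(lo), math.log(hi)))
    return out


def _draw_subject(
    group: str, idx: int, rng: np.random.Generator, config: SyntheticConfig,
    z_age: float,
) -> SubjectRecord:
    prefix = "O" if group == "obese" else "C"
    mean, sd = config.age_mean_sd[group]
    age = float(np.clip(mean + sd * z_age, 2.0, 18.0))
    pubertal = bool(rng.random() < config.prop_pubertal[group])
    sex = "M" if rng.random() < config.prop_male[group] else "F"
    ht = config.ht_sds_mean_sd[group]
    bmi = config.bmi_sds_mean_sd[group]
    bw = config.bw_sds_mean_sd[group]
    if group == "obese":
        waist = float(max(50.0, rng.normal(*config.waist_cm_mean_sd)))
        w2h = float(np.clip(rng.normal(*config.waist_to_height_mean_sd), 0.35, 0.95))
        onset = float(np.clip(rng.normal(*config.age_onset_mean_sd), 0.5, age))
        mets = bool(rng.random() < config.mets_prevalence_obese)
    else:
        waist = w2h = onset = None
        mets = False
    return SubjectRecord(
        subject_id=f"{prefix}{idx:03d}",
        group=group,
        sex=sex,
        age=age,
        pubertal=pubertal,
        ht_sds=float(rng.normal(*ht)),
        bmi_sds=float(rng.normal(*bmi)),
        birth_weight_sds=float(rng.normal(*bw)),
        waist_cm=waist,
        waist_to_height=w2h,
        age_onset_obesity=onset,
        mets_flag=mets,
    )


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """One wide table: subject attributes + OGTT columns + metabolite panel.

    Deterministic for a fixed seed.  The copula latents couple age, the five
    metabolites and fasting insulin across every subject; all remaining
    attributes are drawn from independent per-group marginals.
    """
    config.validate()
    pearson = config._pearson_corr()
    chol = np.linalg.cholesky(pearson + 1e-12 * np.eye(pearson.shape[0]))

    ss = np.random.SeedSequence(config.seed)
    rng_subj, rng_copula, rng_ogtt, rng_met = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    n_total = config.n_obese + config.n_control
    latents = rng_copula.standard_normal((n_total, len(LATENT_VARS))) @ chol.T
    z_cols = {name: latents[:, k] for k, name in enumerate(LATENT_VARS)}

    rows = []
    for row_i in range(n_total):
        group = "obese" if row_i < config.n_obese else "control"
        idx = row_i + 1 if group == "obese" else row_i - config.n_obese + 1
        subject = _draw_subject(group, idx, rng_subj, config, z_age=z_cols["age"][row_i])
        rec: dict = {
            "subject_id": subject.subject_id,
            "group": subject.group,
            "sex": subject.sex,
            "age": subject.age,
            "pubertal": subject.pubertal,
            "ht_sds": subject.ht_sds,
            "bmi_sds": subject.bmi_sds,
            "birth_weight_sds": subject.birth_weight_sds,
            "waist_cm": subject.waist_cm,
            "waist_to_height": subject.waist_to_height,
            "age_onset_obesity": subject.age_onset_obesity,
            "mets_flag": subject.mets_flag,
        }
        rec.update(
            generate_ogtt(subject, rng_ogtt, config, z_insulin=z_cols["insulin_0"][row_i])
        )
        rec.update(
            generate_metabolites(
                subject, rng_met, config,
                z={m: z_cols[m][row_i] for m in METABOLITES},
            )
        )
        rows.append(rec)
    return pd.DataFrame.from_records(rows)


def homogeneous_medians(median: float = 0.5) -> dict:
    """Cell-median table with one shared value per metabolite.

    Removes the between-cell median shifts so that pooled rank correlations
    reflect the injected copula alone — used to validate copula fidelity.
    """
    cells = [(g, p) for g in GROUPS for p in (False, True)]
    return {m: {c: median for c in cells} for m in METABOLITES}


def config_with_spearman(pairs: Mapping[tuple[str, str], float], **kwargs) -> SyntheticConfig:
    """Convenience: default config with specific injected Spearman targets only."""
    k = len(LATENT_VARS)
    m = pd.DataFrame(np.eye(k), index=LATENT_VARS, columns=LATENT_VARS)
    for (a, b), r in pairs.items():
        m.loc[a, b] = m.loc[b, a] = r
    return SyntheticConfig(target_spearman=m, **kwargs)
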
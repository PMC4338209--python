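"""End-to-end orchestration of the analysis stages with a manifest.

Stage chain (prefix-closed): simulate → quant → indices → stats → autocm.
Each stage reads the previous stage's CSV/TSV outputs from the output
directory and writes its own; a JSON manifest records the seed, the config
and a SHA-256 per output so reruns can be verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import autocm, indices, quant, stats, synth

log = logging.getLogger("dehpkids")

STAGES = ("simulate", "quant", "indices", "stats", "autocm")

#: Dependencies: each stage requires these earlier stages' outputs.
_REQUIRES = {
    "simulate": (),
    "quant": ("simulate",),
    "indices": ("simulate",),
    "stats": ("quant", "indices"),
    "autocm": ("quant", "indices"),
}

_STAGE_OUTPUTS = {
    "simulate": ("cohort.csv",),
    "quant": ("quantified.csv", "detectability.tsv"),
    "indices": ("indices.csv", "indices_summary.tsv"),
    "stats": ("kruskal_wallis.tsv", "spearman_obese_rho.tsv", "spearman_obese_p.tsv",
              "spearman_control_rho.tsv", "spearman_control_p.tsv",
              "regression_mehp_obese.tsv"),
    "autocm": ("map.graphml", "map.dot", "map_edges.tsv"),
}

#: The 11 continuous variables entering the connectivity map.
MAP_VARIABLES = (
    "MEHP_ug_per_g",
    "6-OH-MEHP_ug_per_g",
    "5-oxo-MEHP_ug_per_g",
    "5-OH-MEHP_ug_per_g",
    "5-Cx-MEHP_ug_per_g",
    "fgir",
    "homa_ir",
    "insulinogenic",
    "ht_sds",
    "bmi_sds",
    "birth_weight_sds",
)


@dataclass
class RunConfig:
    stages: tuple[str, ...] = STAGES
    outdir: str = "results/pipeline"
    seed: int = 0
    synthetic: synth.SyntheticConfig | None = None
    impute_nondetects: bool = False
    normality_alpha: float = 0.05
    autocm_params: dict = field(default_factory=dict)

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if "simulate" in self.stages and self.seed is None:
            raise ValueError("simulate requires a seed")

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        synth_cfg = None
        if "synthetic" in raw:
            synth_cfg = synth.SyntheticConfig(**raw.pop("synthetic"))
        stages = tuple(raw.pop("stages", STAGES))
        return cls(stages=stages, synthetic=synth_cfg, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(outdir: Path, stage: str, done: set[str]) -> None:
    for dep in _REQUIRES[stage]:
        if dep in done:
            continue
        if all((outdir / f).exists() for f in _STAGE_OUTPUTS[dep]):
            continue
        raise FileNotFoundError(
            f"stage {stage!r} needs outputs of stage {dep!r}; run {dep!r} first"
        )


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested stages; return the manifest (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    done: set[str] = set()
    produced: list[Path] = []

    for stage in STAGES:  # canonical order regardless of request order
        if stage not in config.stages:
            continue
        _require(outdir, stage, done)
        log.info("[%s] running", stage)
        if stage == "simulate":
            cfg = config.synthetic or synth.SyntheticConfig()
            cfg.seed = config.seed
            cohort = synth.generate_cohort(cfg)
            cohort.to_csv(outdir / "cohort.csv", index=False)
            produced.append(outdir / "cohort.csv")
        elif stage == "quant":
            cohort = pd.read_csv(outdir / "cohort.csv")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                quantified = quant.process_cohort(cohort, impute_nondetects=config.impute_nondetects)
                detect = quant.detectability_table(cohort)
            quantified.to_csv(outdir / "quantified.csv", index=False)
            _write_tsv(detect, outdir / "detectability.tsv")
            produced += [outdir / "quantified.csv", outdir / "detectability.tsv"]
        elif stage == "indices":
            cohort = pd.read_csv(outdir / "cohort.csv")
            idx = indices.indices_table(cohort)
            idx.to_csv(outdir / "indices.csv", index=False)
            _write_tsv(indices.group_summary(idx), outdir / "indices_summary.tsv")
            produced += [outdir / "indices.csv", outdir / "indices_summary.tsv"]
        elif stage == "stats":
            merged = _merged(outdir)
            _write_tsv(_kw_table(merged), outdir / "kruskal_wallis.tsv")
            produced.append(outdir / "kruskal_wallis.tsv")
            corr_vars = [f"{m}_ug_per_g" for m in quant.METABOLITES] + [
                "age", "ht_sds", "bmi_sds", "insulin_0", "fgir", "homa_ir",
                "insulinogenic", "auci",
            ]
            for grp in ("obese", "control"):
                sub = merged[merged["group"] == grp]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rho, p = stats.spearman_matrix(sub, corr_vars)
                _write_tsv(rho, outdir / f"spearman_{grp}_rho.tsv")
                _write_tsv(p, outdir / f"spearman_{grp}_p.tsv")
                produced += [outdir / f"spearman_{grp}_rho.tsv", outdir / f"spearman_{grp}_p.tsv"]
            reg = _mehp_regression(merged)
            _write_tsv(reg, outdir / "regression_mehp_obese.tsv")
            produced.append(outdir / "regression_mehp_obese.tsv")
        elif stage == "autocm":
            merged = _merged(outdir)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cmap = autocm.build_connectivity_map(
                    merged, MAP_VARIABLES, **config.autocm_params
                )
            autocm.export_graphml(cmap, str(outdir / "map.graphml"))
            autocm.export_dot(cmap, str(outdir / "map.dot"))
            autocm.edges_frame(cmap).to_csv(outdir / "map_edges.tsv", sep="\t", index=False)
            produced += [outdir / "map.graphml", outdir / "map.dot", outdir / "map_edges.tsv"]
        done.add(stage)

    manifest = {
        "seed": config.seed,
        "stages": [s for s in STAGES if s in config.stages],
        "outputs": {p.name: _sha256(p) for p in produced},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _merged(outdir: Path) -> pd.DataFrame:
    quantified = pd.read_csv(outdir / "quantified.csv")
    idx = pd.read_csv(outdir / "indices.csv")
    return quantified.merge(idx.drop(columns=["group"]), on="subject_id")


def _kw_table(merged: pd.DataFrame) -> pd.DataFrame:
    """Per-metabolite four-cell (group × puberty) Kruskal-Wallis summary."""
    cells = [
        ("A", "control", False), ("B", "control", True),
        ("C", "obese", False), ("D", "obese", True),
    ]
    rows = []
    for met in quant.METABOLITES:
        col = f"{met}_ug_per_g"
        samples, medians = [], {}
        for label, grp, pub in cells:
            vals = merged.loc[
                (merged["group"] == grp) & (merged["pubertal"] == pub), col
            ].dropna()
            samples.append(vals.to_numpy())
            medians[label] = (
                f"{vals.median():.2f} ({vals.quantile(0.25):.2f}-{vals.quantile(0.75):.2f})"
                if len(vals) else "NA"
            )
        if any(len(s) < 2 for s in samples):
            rows.append({"metabolite": met, **medians, "p": np.nan, "significant": ""})
            continue
        res = stats.kruskal_wallis_posthoc(samples, labels=[c[0] for c in cells])
        rows.append({
            "metabolite": met, **medians,
            "p": res.p_value, "significant": "; ".join(res.extra["significant"]),
        })
    return pd.DataFrame(rows).set_index("metabolite")


def _mehp_regression(merged: pd.DataFrame) -> pd.DataFrame:
    """Determinants of MEHP concentration in the obese group (OLS)."""
    obese = merged[merged["group"] == "obese"].copy()
    obese["pubertal_num"] = obese["pubertal"].astype(float)
    predictors = [
        "ht_sds", "bmi_sds", "pubertal_num", "waist_cm", "waist_to_height",
        "age_onset_obesity", "homa_ir", "wbisi", "aucg", "auci", "insulinogenic",
    ]
    res = stats.ols_regression(obese, "MEHP_ug_per_g", predictors)
    out = pd.DataFrame({"coef": res.params, "se": res.bse, "p": res.pvalues})
    out.attrs["r_squared"] = res.r_squared
    return out
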
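"""Generate the study-sized synthetic cohort (41 obese, 31 normal-weight).

Writes results/pipeline/cohort.csv and reports the basic group structure and
the obese/control contrast in fasting insulin the generator is built around.
"""

import pandas as pd

from dehpkids import pipeline

SEED = 7
OUTDIR = "results/pipeline"


def main() -> None:
    pipeline.run_pipeline(pipeline.RunConfig(stages=("simulate",), outdir=OUTDIR, seed=SEED))
    cohort = pd.read_csv(f"{OUTDIR}/cohort.csv")
    print(f"cohort: {len(cohort)} subjects "
          f"({(cohort.group == 'obese').sum()} obese, {(cohort.group == 'control').sum()} controls)")
    for grp, sub in cohort.groupby("group"):
        print(f"  {grp}: {sub.pubertal.sum()} pubertal, "
              f"median fasting insulin {sub.insulin_0.median():.1f} mIU/L, "
              f"median age {sub.age.median():.1f} yr")
    print("finding: the obese group carries the expected fasting hyperinsulinaemia "
          "relative to controls.")


if __name__ == "__main__":
    main()
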
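"""Simulate the synthetic study cohort.

Builds the 98-trial two-domain task and a 120-agent, two-phase cohort with
known generative (alpha, beta, gamma) parameters, then writes the raw study
tables (trials/choices/ratings/participants/truth) to results/study.
"""

import pandas as pd

from study_config import OUTDIR, study_config
from riskamb.pipeline import run

if __name__ == "__main__":
    run(study_config(["simulate"]))
    choices = pd.read_csv(OUTDIR / "choices.csv")
    truth = pd.read_csv(OUTDIR / "truth.csv")
    print(f"wrote {len(choices)} choice rows "
          f"({choices['participant_id'].nunique()} participants x 2 phases x 98 trials)")
    print("generative parameter summary (phase 1, monetary):")
    cell = truth.query("phase == 1 and domain == 'monetary'")
    print(cell[["alpha", "beta", "gamma"]].describe().loc[["mean", "50%", "std"]])
    print("planted roles:", truth.drop_duplicates("participant_id")["role"]
          .value_counts().to_dict())
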
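"""Apply the four exclusion rules and report per-rule tallies.

Duplicate worker ids and implausible follow-up age gaps drop participants;
choosing the dominated catch lottery on more than half the catch trials
drops a participant's domain; never choosing the uncertain option removes
a unit from model fitting only.  Writes exclusions.csv plus the retained
analysis/modeling choice sets.
"""

import pandas as pd

from study_config import OUTDIR, study_config
from riskamb.pipeline import run

if __name__ == "__main__":
    run(study_config(["filter"]))
    report = pd.read_csv(OUTDIR / "exclusions.csv")
    print("exclusions by rule:")
    print(report.groupby("rule").size().to_string())
    analysis = pd.read_csv(OUTDIR / "analysis_choices.csv")
    modeling = pd.read_csv(OUTDIR / "modeling_choices.csv")
    print(f"\nanalysis set: {len(analysis)} rows; modeling set: {len(modeling)} rows")
    units = lambda df: df.groupby(["participant_id", "phase"]).ngroups
    print(f"participant-phases retained: analysis {units(analysis)}, "
          f"modeling {units(modeling)}")
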
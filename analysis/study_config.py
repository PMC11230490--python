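"""Shared configuration for the numbered analysis drivers.

One synthetic two-phase cohort of 120 agents stands in for the study
population: mostly typical softmax decision-makers with moderately
persistent attitudes, plus small planted fractions of aberrant responders
so every exclusion rule has work to do.  All drivers write into
results/study and are safe to re-run (each stage is deterministic in the
seed).
"""

from pathlib import Path

from riskamb.cohort import CohortSpec
from riskamb.pipeline import RunConfig

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "study"

SEED = 20240901


def study_config(stages) -> RunConfig:
    return RunConfig(
        seed=SEED,
        outdir=str(OUTDIR),
        stages=tuple(stages),
        cohort=CohortSpec(
            n_agents=120,
            catch_failer_fraction=0.05,
            never_uncertain_fraction=0.05,
            duplicate_id_fraction=0.03,
            age_gap_fraction=0.03,
        ),
        grid_step=1.5,  # 9-start grid; the 144-start default is overkill here
    )
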
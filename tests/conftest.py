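import pandas as pd
import pytest

from riskamb.cohort import CohortSpec, simulate_cohort
from riskamb.trials import build_default_trialset


@pytest.fixture(scope="session")
def trialset():
    return build_default_trialset(0)


@pytest.fixture(scope="session")
def small_cohort(trialset):
    """5 clean agents, both phases/domains — cheap shared fixture."""
    return simulate_cohort(CohortSpec(n_agents=5, seed=11), trialset)


@pytest.fixture(scope="session")
def aberrant_cohort(trialset):
    """Cohort with every aberrant role planted."""
    spec = CohortSpec(
        n_agents=40,
        catch_failer_fraction=0.10,
        never_uncertain_fraction=0.10,
        duplicate_id_fraction=0.05,
        age_gap_fraction=0.05,
        seed=7,
    )
    return simulate_cohort(spec, trialset)


@pytest.fixture()
def monetary_choices(small_cohort, trialset):
    ch = small_cohort["choices"]
    mon_ids = {t.trial_id for t in trialset.domain("monetary")}
    return ch[
        (ch["participant_id"] == "P0000")
        & (ch["phase"] == 1)
        & (ch["trial_id"].isin(mon_ids))
    ].reset_index(drop=True)


def make_choices(trials, chose):
    """Tiny helper: a choices frame for one participant/phase."""
    return pd.DataFrame(
        {
            "participant_id": "P0000",
            "phase": 1,
            "trial_id": [t.trial_id for t in trials],
            "chose_lottery": list(chose),
        }
    )
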
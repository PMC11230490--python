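"""Fit the ordinal subjective-value model to every retained unit.

Multistart Nelder-Mead maximum likelihood of (alpha, beta, gamma) per
participant x phase x domain; writes fits.csv and reports how well the
fitted parameters recover the generative ones (possible here because the
cohort is synthetic and the truth table is on disk).
"""

import pandas as pd
from scipy.stats import spearmanr

from study_config import OUTDIR, study_config
from riskamb.pipeline import run

if __name__ == "__main__":
    run(study_config(["fit"]))
    fits = pd.read_csv(OUTDIR / "fits.csv")
    truth = pd.read_csv(OUTDIR / "truth.csv")
    print(f"{len(fits)} units fitted; "
          f"{int(fits['boundary_flag'].sum())} boundary-flagged")
    m = fits.merge(truth, on=["participant_id", "phase", "domain"])
    for param in ("alpha", "beta", "gamma"):
        rho = spearmanr(m[param], m[f"{param}_hat"]).statistic
        print(f"  rank recovery rho({param}) = {rho:.2f}")
    print("recovery is noise-limited at 49 trials/unit; see docs/methods.md")
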
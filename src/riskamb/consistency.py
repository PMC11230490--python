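"""Cross-domain / cross-phase association analyses and manipulation checks.

All associations are Spearman rank correlations (average ranks for ties,
two-sided p from the t approximation, listwise deletion of incomplete
pairs).  The suite emits the full grid the study design supports:

* cross-domain, per phase: monetary vs medical values of each measure;
* cross-phase, per domain: phase 1 vs phase 2 (test-retest reliability);
* model vs model-free, per phase x domain: fitted alpha vs the risky
  choice proportion, fitted beta vs the corrected ambiguity proportion
  (expected negative: beta > 0 is aversion, corrected < 0 is aversion).

Model-based cells use the raw fitted beta; the fits table separately
carries -beta as the reported attitude.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .trials import DOMAINS

PHASES = (1, 2)

MODELFREE_MEASURES = {
    "risk_prop": "risk_attitude",
    "corrected_amb_prop": "ambiguity_attitude",
}
MODEL_MEASURES = {"alpha": "alpha_hat", "beta": "beta_hat"}

CORRELATION_COLUMNS = [
    "measure",
    "axis",
    "context",
    "rho",
    "p_value",
    "n",
    "n_dropped",
]


def spearman(x, y) -> tuple[float, float, int]:
    """Spearman rho with listwise deletion; (nan, nan, n) when degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan"), float("nan"), n
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), n


def _wide(df: pd.DataFrame, value: str, index, columns: str) -> pd.DataFrame:
    return df.pivot_table(index=index, columns=columns, values=value, aggfunc="first")


def _corr_row(measure, axis, context, x, y, n_total) -> dict:
    try:
        rho, p, n = spearman(x, y)
    except ValueError:
        rho, p, n = float("nan"), float("nan"), int(np.sum(np.isfinite(x) & np.isfinite(y)))
    return {
        "measure": measure,
        "axis": axis,
        "context": context,
        "rho": rho,
        "p_value": p,
        "n": n,
        "n_dropped": int(n_total - n),
    }


def run_consistency_suite(
    modelfree: pd.DataFrame, fits: pd.DataFrame | None = None
) -> pd.DataFrame:
    """The full correlation grid over model-free and model-based measures."""
    rows = []
    sources = [("modelfree", modelfree, MODELFREE_MEASURES)]
    if fits is not None and len(fits):
        sources.append(("model", fits, MODEL_MEASURES))

    for _, table, measures in sources:
        for measure, column in measures.items():
            for phase in PHASES:
                sub = table[table["phase"] == phase]
                wide = _wide(sub, column, "participant_id", "domain")
                if set(DOMAINS) <= set(wide.columns):
                    rows.append(
                        _corr_row(
                            measure, "cross_domain", f"phase{phase}",
                            wide[DOMAINS[0]], wide[DOMAINS[1]], len(wide),
                        )
                    )
            for domain in DOMAINS:
                sub = table[table["domain"] == domain]
                wide = _wide(sub, column, "participant_id", "phase")
                if set(PHASES) <= set(wide.columns):
                    rows.append(
                        _corr_row(
                            measure, "cross_phase", domain,
                            wide[1], wide[2], len(wide),
                        )
                    )

    if fits is not None and len(fits):
        merged = fits.merge(
            modelfree, on=["participant_id", "phase", "domain"], how="inner"
        )
        pairs = [
            ("alpha_vs_risk_prop", "alpha_hat", "risk_attitude"),
            ("beta_vs_corrected_prop", "beta_hat", "ambiguity_attitude"),
        ]
        for name, mcol, fcol in pairs:
            for phase in PHASES:
                for domain in DOMAINS:
                    sub = merged[
                        (merged["phase"] == phase) & (merged["domain"] == domain)
                    ]
                    if len(sub) >= 3:
                        rows.append(
                            _corr_row(
                                name, "model_vs_modelfree",
                                f"phase{phase}/{domain}",
                                sub[mcol], sub[fcol], len(sub),
                            )
                        )
    return pd.DataFrame(rows, columns=CORRELATION_COLUMNS)


CHECKS_COLUMNS = ["check", "domain", "phase", "passed", "detail"]


def _monotone(values: pd.Series) -> bool:
    v = values.to_numpy(dtype=float)
    return bool(np.all(np.diff(v) >= 0))


def manipulation_checks(
    modelfree: pd.DataFrame, ratings: pd.DataFrame
) -> pd.DataFrame:
    """Group-level monotonicity of ratings and choice proportions in outcome.

    Both checks pass when the group mean is non-decreasing in the outcome
    ordinal; cells with fewer than two outcome levels are reported as
    not applicable (passed = NA).
    """
    rows = []
    for domain in DOMAINS:
        for phase in PHASES:
            sub = ratings[(ratings["domain"] == domain) & (ratings["phase"] == phase)]
            if sub["outcome_ordinal"].nunique() < 2:
                rows.append({"check": "rating_monotone", "domain": domain,
                             "phase": phase, "passed": pd.NA,
                             "detail": "not applicable: <2 outcome levels"})
            else:
                means = sub.groupby("outcome_ordinal")["rating"].mean().sort_index()
                rows.append({
                    "check": "rating_monotone", "domain": domain, "phase": phase,
                    "passed": _monotone(means),
                    "detail": "mean ratings " + "/".join(f"{m:.2f}" for m in means),
                })

            mf = modelfree[(modelfree["domain"] == domain) & (modelfree["phase"] == phase)]
            prop_cols = sorted(c for c in mf.columns if c.startswith("prop_outcome_"))
            if len(prop_cols) < 2 or mf.empty:
                rows.append({"check": "choice_monotone", "domain": domain,
                             "phase": phase, "passed": pd.NA,
                             "detail": "not applicable: <2 outcome levels"})
            else:
                means = mf[prop_cols].mean()
                rows.append({
                    "check": "choice_monotone", "domain": domain, "phase": phase,
                    "passed": _monotone(means),
                    "detail": "mean proportions " + "/".join(f"{m:.2f}" for m in means),
                })
    return pd.DataFrame(rows, columns=CHECKS_COLUMNS)
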
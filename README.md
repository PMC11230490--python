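# riskamb

Estimation and analysis of individual **risk** and **ambiguity** attitudes
from binary lottery choices, for outcomes that are quantitative (money) or
merely *rankable* (levels of recovery from a medical condition).

People routinely choose between a safe option and a gamble whose outcome
is better but uncertain — and the uncertainty itself comes in two kinds:
*risk* (the winning probability is known, e.g. 50%) and *ambiguity* (the
probability is only partly known, e.g. somewhere between 25% and 75%).
When outcomes have no natural numeric scale, standard expected-utility
machinery does not apply directly. This package implements a two-domain
choice task (monetary and medical), an ordinal subjective-value model that
handles qualitative outcomes, and the full analysis pipeline around it:
exclusion rules, model-free choice-proportion attitudes, maximum-likelihood
model fitting, BIC/cross-validation model comparison, and cross-domain /
test–retest consistency analyses. A synthetic cohort generator with known
ground truth makes every stage testable end to end.

## The model

Each option's subjective value is

```
SV = (P − β·A/2) · v^α          P(choose lottery) = 1 / (1 + e^{−γ(SV_L − SV_C)})
```

where P is the winning probability, A the ambiguity level, and v the
outcome value — the outcome's **ordinal rank** (0–4) in the ordinal
variant, or the participant's own 0–10 rating in the rating variant.
α captures risk attitude (α < 1: averse), β ambiguity attitude (β > 0:
averse; the reported attitude is −β), and γ is choice noise. At β = 0 an
ambiguous lottery is valued exactly like a 50% risky one — the anchor
behind the model-free *corrected ambiguity proportion* (choice proportion
under ambiguity minus the proportion at 50% risk; 0 = neutral, negative =
averse). Fitting is per participant × domain × phase, by Nelder–Mead from
a 144-point start grid on the negative log-likelihood.

## Worked example

```python
import riskamb as ra

trialset = ra.build_default_trialset(seed=0)            # 98 trials, 49/domain
cohort = ra.simulate_cohort(ra.CohortSpec(n_agents=50, seed=7), trialset)

kept = ra.apply_exclusions(cohort["choices"], cohort["participants"], trialset)
summary = ra.choice_proportions(kept.analysis_choices, trialset)
print(summary[["domain", "risk_attitude", "ambiguity_attitude"]]
      .groupby("domain").mean().round(3))
```

prints

```
          risk_attitude  ambiguity_attitude
domain
medical           0.551              -0.025
monetary          0.545              -0.077
```

i.e. this simulated cohort takes the risky lottery on about half of the
risky trials and shows ambiguity *aversion* (negative corrected
proportions) in both domains, as expected from its generative β
distribution centred above zero. The `analysis/` scripts run the same
pipeline as a six-step narrative (simulate → exclusions → model-free →
fit → compare → consistency) and write their tables under `results/`;
the `riskamb` command-line tool exposes the identical stages
(`riskamb run-all --seed 0 --outdir results/run`).

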
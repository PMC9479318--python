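# moralargs

Tools for studying how political discussion shapes moral opinions through
the *moral argument* mechanism: opinions that are easier to justify with
generally acceptable moral arguments — those appealing to **h**arm,
**v**iolence, **f**airness and **l**iberty (HVFL) — spread at the expense
of opinions that rely on arguments only conservatives accept (purity,
loyalty, authority).  The package is aimed at computational social
scientists who want to (a) score the HVFL argument advantage of opinions
from argument-endorsement data, (b) derive population-level predictions
from an agent-based discussion model, and (c) test those predictions with
hierarchical logistic survey models — all reproducibly on synthetic data
with known ground truth, with loaders for delimited exports of real
surveys (e.g. ANES and GSS extracts).

## The quantities at the core

**HVFL argument advantage.**  Each judge ticks, for both sides of an
issue, which of seven argument kinds justify that side.  The judge-level
advantage of the "yes" opinion is

    (yes:harm + yes:violence + yes:fairness + yes:liberty)/4
  − (no:harm  + no:violence  + no:fairness  + no:liberty)/4  ∈ [−1, 1],

and the item's advantage is the mean over judges (SE = sample SD/√n).

**Agent-based discussion model.**  Liberal and conservative agents hold a
binary opinion with advantage *A*.  Per step an agent with discussion rate
*f* initiates a discussion, meeting an ingroup partner with probability
*b(f)*.  Each party presents an argument for its opinion — an HVFL-kind
argument with probability (1 + A)/2 for the advantaged side — and a
listener of opposite opinion switches with probability *s* if the argument
kind is relevant to it (liberals: HVFL only; conservatives: any kind).
In a large liberal population the advantaged share x drifts by
2·s·A·x(1−x)·f per step.  Under the *calibrated* bias b(f) = 1 − κ/f
(κ = slowest rate) cross-ideology contact is equal across rate classes and
the conservative discussion-frequency effect vanishes.

**Survey models.**  With Opinion = 1 for the advantaged side, DF the
standardized discussion frequency and X demographic controls:

    per issue/group:  logit(Opinionᵢ) = β₀ + β₁·DFᵢ + βXᵢ
    pooled M1:        logit(Opinionᵢⱼₖ) = (β₀ + u_i00 + u_0jk + u_00k) + β₁·DFᵢ + βXᵢ
    pooled M2:        ... + β₂·HVFLₖ + β₃·DFᵢ×HVFLₖ

with crossed Gaussian random intercepts for individual, issue-wave and
issue, fitted by maximum likelihood with a Laplace approximation.  The
advantage enters M2 centered and ×10, so β₃ is the shift in the DF effect
per 0.1 advantage.  Opinion change rates are logistic slopes on time in
decades (log-odds per 10 years).

## Worked example

```python
import moralargs as ma
from moralargs.synthetic import SurveyDGP, gen_survey

# judge endorses fairness+harm for "yes", liberty for "no"
ma.participant_advantage({
    "yes_fairness": 1, "yes_harm": 1, "yes_violence": 0, "yes_liberty": 0,
    "no_liberty": 1, "no_harm": 0, "no_violence": 0, "no_fairness": 0})
# 0.25   (half of the yes-side kinds minus a quarter of the no-side kinds)

# synthetic survey with a known liberal DF effect of 0.12
dgp = SurveyDGP(n_respondents=3000, n_issues=12,
                beta1_by_group={"liberal": 0.12, "moderate": 0.06,
                                "conservative": 0.0},
                re_sd_individual=0.8, re_sd_issuewave=0.3, re_sd_issue=0.5,
                seed=1)
table, truth = gen_survey(dgp)
print(ma.fit_pooled_m1(table, group="liberal").summary())
```

```
Model: M1   method: laplace (joint Newton, Schur-eliminated crossed intercepts)
n = 9984   groups: individual=832, issue_wave=48, issue=12
converged: True
term                        coef        se  ci95_low ci95_high    odds
const                     0.1690    0.1842   -0.1920    0.5301   1.184
df_std                    0.1182    0.0338    0.0520    0.1845   1.125
...
random-intercept SDs: individual=0.741, issue_wave=0.234, issue=0.599
```

`df_std` recovers the generating 0.12 within its standard error: one SD
more discussion is associated with exp(0.118) ≈ 1.13× the odds of holding
the advantaged opinion among liberals.  The full five-prediction pipeline
(judgment scoring → survey recoding → mixed-model estimation → prediction
tests) runs with `ma.run_pipeline(ma.PipelineConfig(seed=1))` or

```bash
moralargs predict --seed 1 --out report/
```

A CLI mirrors every stage: `moralargs synth survey|judgments`,
`moralargs score`, `moralargs simulate`, `moralargs estimate`,
`moralargs predict` (see `--help`).

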
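# Methods

This note documents the models implemented in `moralargs`, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical decisions behind the estimators.

## 1. HVFL argument-advantage scoring

A judgment row carries 14 binary endorsement dummies (7 argument kinds ×
2 sides).  The judge-level advantage of the "yes" opinion is the mean of
the yes-side HVFL dummies minus the mean of the no-side HVFL dummies; the
three non-HVFL kinds (authority, loyalty, purity) are parsed and retained
but never enter the score.  Item-level estimates average judge scores;
the SE uses the n−1 sample SD.  Judges of "other" ideology contribute to
the overall mean but to neither ideology sub-mean, and an undefined
sub-mean is reported as missing, never as 0.  Ideology-split reliability
is the Pearson correlation between liberal-based and conservative-based
item means with a Fisher-z 95% interval.  The `threshold_filter` keeps
items with |advantage| ≥ 0.1 (inclusive) — below that the sign of the
advantage, and hence the coding of the "advantaged" opinion, is not
reliably identified — and records each kept item's coding direction.

Because each endorsement dummy is Bernoulli under the synthetic profile,
the exact SD of a judge's score is √(Σ p(1−p)/16) over the eight HVFL
dummies; this closed form is the oracle for all SE recovery tests.  At
the default profile (base endorsement rate 0.3, advantage 0.2 split
evenly over the four kinds) and 98 judges per item it gives SE ≈ 0.032.

## 2. Agent-based discussion model

Agents: fixed ideology (liberal/conservative), fixed discussion-frequency
class, binary opinion.  Per time step each agent initiates a discussion
with probability equal to its class rate f; the partner is drawn from the
agent's own ideology with probability b(f), otherwise from the other
group, uniformly within the chosen group (self-draws are possible and are
no-ops).  Both parties present one argument for their current opinion:
HVFL-kind with probability (1 + A)/2 when arguing the advantaged side,
(1 − A)/2 otherwise.  A listener holding the opposite opinion switches
with probability s if the argument kind is relevant to it — liberals
respond to HVFL arguments only, conservatives to any kind.  Both parties
are evaluated on pre-encounter opinions; all switches apply
simultaneously, and an agent triggered by several encounters in one step
flips once.

Drift law.  In a large single-class liberal population each agent takes
part in 2f expected encounters per step (f initiated + f received), and a
mixed-opinion encounter moves the listener toward the advantaged side at
net probability s·A, giving dx = 2·s·A·x(1−x)·f.  This is the
leading-order law for small f: when an agent can take part in two or more
encounters per step, single-flip resolution suppresses the drift by
roughly f·s/8 in relative terms (measured ≈ 1.7% at f = 0.1, < 1% at
f = 0.02).  The oracle tests therefore run at the default rates, where
the correction is far below Monte-Carlo resolution.

Parameters and defaults:

| parameter | default | meaning / rationale |
|---|---|---|
| n_agents | 2000 | population size; two ideologies of equal share |
| advantage A | 0.2 | mid-range of the empirically observed scale (items span roughly −0.25..0.3) |
| persuade_prob s | 0.5 | switch probability given a relevant argument |
| rates (f) | 0.004 / 0.02 | per-step discussion probabilities of the infrequent/frequent halves.  Chosen as a time-scale normalization: with s = 0.5 and the largest advantage studied (0.3), the fastest class completes its ≈3–4 logit-unit transition within the 500-step horizon while slower classes do not, which is the regime where frequency gaps are visible and ordered in A.  Decided from the drift law before any simulation was run. |
| ingroup bias | calibrated | b(f) = 1 − κ/f with κ the slowest rate, making cross-ideology contact f(1−b(f)) equal across classes — the regime with an exactly null conservative frequency effect.  A constant b or an explicit map are alternatives. |
| init_prevalence | 0.1 | the advantaged opinion starts as a minority, matching the liberalization framing of a rising opinion |
| horizon, replicates | 500, 200 | long enough for the slow classes to move measurably; replicate count sets Monte-Carlo CI width ≈ 0.003 on prevalence gaps |

All replicates evolve in one vectorized (replicates × agents) state array
driven by a single PCG64 stream: replicates are i.i.d. and the whole run
is reproducible from one seed, and this is what keeps 200-replicate runs
in the tens of seconds.  The ideology and class composition is assigned
deterministically from the configured proportions (rounded cumulative
shares) and shared across replicates; replicate randomness lives in
initial opinions and dynamics.

Why the conservative frequency effect vanishes under calibration: within-
conservative discussions are neutral in expectation (conservatives accept
every argument kind, so arguments for either side persuade equally),
received contacts are uniform within group and hence class-independent,
and initiated cross-ideology contact f(1−b(f)) is equalized by
construction.  The only systematic force on conservatives — contact with
(more advantaged-holding) liberals — is then identical across frequency
classes.  Under a constant bias instead, frequent conservatives meet
liberals more often and acquire a small same-direction effect, always
smaller than the liberal one.

## 3. Synthetic survey generator

`SurveyDGP` draws respondent × issue records from the generative twin of
the pooled estimation model: per-issue intercepts; Gaussian random
intercepts for individual, issue and issue-wave (a conventional GLMM
choice on the log-odds scale); a group-specific DF slope applied to DF
standardized over the generated sample; optional advantage main effect
and DF × advantage interaction (per 0.1 advantage, optionally
group-specific — theory-consistent data localize the interaction among
liberals); optional ideology lean and time trend proportional to the
issue advantage, the trend optionally steepening with DF.  Raw DF is an
integer 0–7 (days-per-week style); standardization happens downstream in
each fit, mirroring the analysis convention.  Covariates are independent
standard normals plus binary dummies with zero effects by default — they
are controls, not quantities of interest.  DF is generated independently
of ideology; the joint distribution in real samples is unknown, and this
independence is a stated simplification.

Each respondent belongs to one wave (cross-sections, not a panel) and
answers every issue.  A JSON truth record echoes every parameter so
recovery tests never reverse-engineer them.  What the generator does not
emulate: survey nonresponse, sampling design and weighting construction
(weights default to 1), item-specific response scales beyond the binary
advantaged coding, panel attrition, or any dependence of DF on ideology.
Passing recovery tests therefore show correctness of the estimators under
the stated DGP, not robustness to design features real surveys add.

## 4. Estimators

Per-issue and change-rate models are plain logistic regressions
(statsmodels GLM/IRLS).  Change rates regress the advantaged opinion on
time in decades ((year − reference)/10, reference = earliest wave by
default), giving log-odds per 10 years.  Separation (including constant
outcomes) is flagged — `separated=True`, no estimate — never silently
reported.

The pooled models M1/M2 use crossed Gaussian random intercepts
(individual, issue-wave, issue).  The fitter is written for this package:
a Laplace approximation to the marginal likelihood in which, for each
candidate vector of log-SDs, the joint penalized log-likelihood is
maximized over (β, u) by Newton's method, exploiting the one-hot design:
the largest level (individuals) has a diagonal Hessian block and is
eliminated by a Schur complement, leaving a small dense system over the
remaining levels and the fixed effects.  The log-SDs are profiled out by
L-BFGS-B on bounds [−6, 3] (start log 0.5); the Laplace objective adds
−½ log det of the u-block Hessian and the Gaussian normalizers.  Wald
SEs for β come from the β block of the inverse joint Hessian at the
optimum (conditional on the estimated SDs, as in standard GLMM practice);
95% CIs are estimate ± 1.96·SE throughout.  Contract tests pin the method
down: with zero generating variances it matches the plain logistic MLE to
< 0.01, it recovers generating slopes within 2 SE across seeds, and
integer weights reproduce row duplication exactly.  Levels with a single
group are dropped with a warning (their variance is unidentified).  A
clearly labeled fallback — pooled logistic with cluster-robust SEs by
individual — is available via `PooledOpinionModel.fit_pooled_logit()` for
data where the mixed fit cannot be used.

Weights are treated as observation-level frequency-style
pseudo-likelihood multipliers, normalized to mean 1 so SE scales stay
comparable; zero weights equal deletion and unit weights reproduce the
unweighted fit.  Mixed fits apply weights at the observation level only.
Standardization of continuous predictors is computed within each fit's
estimation sample, so a coefficient is always per SD of the fitted
sample; with heterogeneous multi-wave DF items, each
wave's ordinal scale should be standardized within wave before pooling —
the package's stated harmonization choice.  M2 centers the advantage over
the distinct items entering the fit and multiplies by 10, so β₃ is per
0.1 advantage.

## 5. Prediction report

* P1 counts items whose advantage sign matches the liberal−conservative
  prevalence gap, computed on pooled-over-waves prevalences in raw
  (yes-side) coding against *signed* advantage estimates; ties count as
  non-aligned and are logged.
* P2 is the Pearson correlation of advantage with change rate
  (Fisher-z CI) across all scored items.
* P3/P5 compare pooled M1 DF effects by group: liberal CI above zero,
  conservative CI covering zero, and |β₁ᶜᵒⁿˢ| < β₁ˡⁱᵇ.
* P4 is β₃ from M2 among liberals.  The companion display splits liberals
  at their median standardized DF (the split rule is a package choice and
  is configurable; when the median equals the maximum of a coarse scale
  the median group joins the frequent half), estimates per-item change
  rates in each half and compares the change-rate-on-advantage slopes via
  a stacked interaction regression with heteroskedasticity-robust (HC1)
  SEs; items are unweighted by default, precision weighting is available.

The end-to-end pipeline generates judgments and survey data from one
seed, scores items, reverse-codes opinions using *estimated* advantage
signs (so sign errors on near-zero items propagate realistically),
filters at |advantage| ≥ 0.1, fits the models and emits the report as
JSON plus CSV tables.  Default study conditions: 40 items × 98 judges,
advantage SD 0.16, 2000 respondents over 4 waves, β₁ = 0.12/0.06/0.00
for liberals/moderates/conservatives, β₃ = 0.10 among liberals, random-
intercept SDs 0.8/0.3/0.5 (individual/issue-wave/issue), ideology lean 4
and time trend 2 log-odds per decade per unit advantage.

## 6. Known limitations

* The Laplace approximation can bias variance components at extreme
  cluster sparsity (few observations per individual); the recovery tests
  cover the 3–20 observations-per-individual range used here.
* The simulator has no network topology, exactly two ideologies, and no
  coupling between issues; ideology is fixed over time.
* The drift law is first-order in the discussion rates (see §2).
* Real-survey loaders accept delimited exports with configurable column
  maps; proprietary container formats are out of scope.
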
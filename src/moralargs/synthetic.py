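"""Synthetic argument-judgment and survey data with known ground truth.

Two generators make every downstream stage testable without external data:

* :func:`gen_argument_judgments` draws Bernoulli endorsement dummies per
  participant x item from an :class:`EndorsementProfile`, emulating the
  judgment instrument (each participant ticks, for each side of an issue,
  which of seven argument kinds apply).

* :func:`gen_survey` draws respondent x issue x wave opinion records from
  a hierarchical logistic data-generating process — the generative twin of
  the pooled estimation model: per-issue intercepts, Gaussian random
  intercepts for individual / issue / issue-wave, a group-specific
  discussion-frequency (DF) slope, and a DF x advantage interaction.  The
  returned truth record echoes every parameter for recovery tests.

Raw DF is generated as integers 0-7 (days-per-week style); slopes apply to
DF standardized within the generated sample, matching how the estimation
stage standardizes.  Covariates default to inert controls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .scoring import ARGUMENT_KINDS, DUMMY_COLUMNS, HVFL_KINDS

IDEOLOGY_LABELS: tuple[str, ...] = ("liberal", "moderate", "conservative")


def _check_probs(p: Mapping[str, float], name: str) -> None:
    missing = [k for k in ARGUMENT_KINDS if k not in p]
    if missing:
        raise ValidationError(f"{name} lacks argument kind(s): {missing}")
    for k, v in p.items():
        if not (0.0 <= float(v) <= 1.0):
            raise ValidationError(f"{name}[{k}]={v} is not a probability")


@dataclass(frozen=True)
class EndorsementProfile:
    """Per-item Bernoulli endorsement probabilities for both sides.

    ``true_advantage`` is the implied population advantage score: the mean
    over the four HVFL kinds of p_yes[k] - p_no[k].
    """

    item_id: object
    p_yes: Mapping[str, float]
    p_no: Mapping[str, float]

    def __post_init__(self) -> None:
        _check_probs(self.p_yes, "p_yes")
        _check_probs(self.p_no, "p_no")

    @property
    def true_advantage(self) -> float:
        return float(
            np.mean([self.p_yes[k] - self.p_no[k] for k in HVFL_KINDS])
        )

    def score_sd(self) -> float:
        """Exact SD of one participant's advantage score under this profile.

        Each dummy is an independent Bernoulli, so the per-participant score
        variance is sum of p(1-p)/16 over the eight HVFL dummies.  Used as
        the oracle for SE-of-the-mean checks.
        """
        var = sum(
            self.p_yes[k] * (1 - self.p_yes[k]) + self.p_no[k] * (1 - self.p_no[k])
            for k in HVFL_KINDS
        ) / 16.0
        return float(np.sqrt(var))


def profile_with_advantage(
    item_id: object, advantage: float, base: float = 0.3
) -> EndorsementProfile:
    """Convenience profile realizing a target advantage.

    Splits the advantage evenly over the four HVFL kinds around a base
    endorsement rate; non-HVFL kinds get the base rate on both sides.
    """
    if abs(advantage) > 1:
        raise ValidationError(f"advantage {advantage} outside [-1, 1]")
    d = advantage / 2.0
    py = {k: min(1.0, max(0.0, base + d)) for k in HVFL_KINDS}
    pn = {k: min(1.0, max(0.0, base - d)) for k in HVFL_KINDS}
    for k in ARGUMENT_KINDS:
        py.setdefault(k, base)
        pn.setdefault(k, base)
    prof = EndorsementProfile(item_id=item_id, p_yes=py, p_no=pn)
    if abs(prof.true_advantage - advantage) > 1e-9:
        raise ValidationError(
            f"advantage {advantage} not realizable at base rate {base}"
        )
    return prof


def gen_argument_judgments(
    profiles: Sequence[EndorsementProfile],
    n_participants: int,
    ideology_mix: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a judgment table: one row per participant x item.

    Every dummy is an independent Bernoulli draw from the item's profile;
    each participant receives an ideology label drawn from ``ideology_mix``
    (default: half liberal, half conservative, as in a prescreened judge
    pool balanced on ideology).
    """
    if len(profiles) == 0:
        raise ValidationError("profiles must be non-empty")
    if n_participants < 1:
        raise ValidationError(f"n_participants must be >= 1, got {n_participants}")
    mix = dict(ideology_mix or {"liberal": 0.5, "conservative": 0.5})
    labels = list(mix)
    p = np.array([mix[l] for l in labels], dtype=float)
    if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"ideology_mix must be proportions summing to 1: {mix}")
    rng = np.random.default_rng(seed)
    ideology = rng.choice(labels, size=n_participants, p=p)
    rows = []
    for prof in profiles:
        probs = np.array(
            [prof.p_yes[k] for k in ARGUMENT_KINDS]
            + [prof.p_no[k] for k in ARGUMENT_KINDS]
        )
        draws = rng.random((n_participants, 14)) < probs
        block = pd.DataFrame(draws.astype(int), columns=list(DUMMY_COLUMNS))
        block.insert(0, "participant_id", np.arange(n_participants))
        block.insert(1, "item_id", prof.item_id)
        block.insert(2, "ideology", ideology)
        # own answer: side with more endorsed HVFL args, ties broken at random
        yes_cnt = draws[:, :4].sum(axis=1)
        no_cnt = draws[:, 7:11].sum(axis=1)
        ans = np.where(
            yes_cnt > no_cnt, "yes", np.where(no_cnt > yes_cnt, "no", "")
        ).astype(object)
        tie = ans == ""
        ans[tie] = rng.choice(["yes", "no"], size=int(tie.sum()))
        block.insert(3, "answer", ans)
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class SurveyDGP:
    """Parameters of the hierarchical logistic opinion-generating process.

    Slopes are on the log-odds scale: ``beta1_by_group`` per SD of DF,
    ``beta2``/``beta3`` per 0.1 of HVFL advantage (the advantage enters
    centered and multiplied by 10, as in the pooled estimation models).
    """

    n_respondents: int
    n_issues: int
    waves: Sequence[int] = (1984, 1994, 2004, 2014)
    group_mix: Mapping[str, float] = field(
        default_factory=lambda: {"liberal": 0.27, "moderate": 0.33, "conservative": 0.40}
    )
    df_levels: int = 8  # raw DF drawn uniformly from {0..df_levels-1}
    beta0_issue: Sequence[float] | float = 0.0
    beta1_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"liberal": 0.12, "moderate": 0.06, "conservative": 0.0}
    )
    beta2: float = 0.0
    beta3: float = 0.0
    #: optional group-specific DF x advantage interaction; overrides beta3
    #: per group when given (the theory localizes the moderation among
    #: liberals, so theory-consistent data use e.g. {liberal: 0.1,
    #: conservative: 0}).
    beta3_by_group: Mapping[str, float] | None = None
    #: log-odds gap between liberal and conservative intercepts per unit of
    #: issue advantage (moderates sit halfway); theory-consistent data have
    #: this positive so advantaged opinions lean liberal.
    lean_per_advantage: float = 0.0
    #: time trend of the advantaged opinion, log-odds per decade per unit
    #: of issue advantage (speed proportional to advantage).
    trend_per_advantage: float = 0.0
    #: extra trend per decade per unit advantage per SD of DF — lets
    #: frequent discussers change faster, as the theory's moderation
    #: prediction describes.
    trend_per_advantage_df: float = 0.0
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    re_sd_individual: float = 0.0
    re_sd_issue: float = 0.0
    re_sd_issuewave: float = 0.0
    advantage_per_issue: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 1 or self.n_issues < 1:
            raise ValidationError(
                "n_respondents and n_issues must be positive counts"
            )
        for nm in ("re_sd_individual", "re_sd_issue", "re_sd_issuewave"):
            if getattr(self, nm) < 0:
                raise ValidationError(f"{nm} must be >= 0")
        tot = sum(self.group_mix.values())
        if abs(tot - 1.0) > 1e-9 or min(self.group_mix.values()) < 0:
            raise ValidationError(f"group_mix proportions must sum to 1: {self.group_mix}")
        if len(self.waves) < 1:
            raise ValidationError("waves must be non-empty")


#: Covariate columns generated for every survey record.
COVARIATE_COLUMNS = ("education_std", "age_std", "media_std", "woman", "eth_black", "eth_other")


def gen_survey(dgp: SurveyDGP) -> tuple[pd.DataFrame, dict]:
    """Draw a survey table and its ground-truth record.

    Each respondent belongs to one wave and answers every issue.  The
    linear predictor is

        beta0_issue[k] + u_ind[i] + u_issue[k] + u_issuewave[jk]
        + beta1[group(i)] * DFstd_i + beta2 * adv10_k
        + beta3 * DFstd_i * adv10_k + covariate effects

    where adv10 is the issue advantage centered at its mean and scaled by
    10, and DFstd is raw DF standardized over the generated sample.
    Opinions are Bernoulli(logistic(lp)).
    """
    rng = np.random.default_rng(dgp.seed)
    n, m = dgp.n_respondents, dgp.n_issues
    waves = list(dgp.waves)

    groups = rng.choice(
        list(dgp.group_mix), size=n, p=np.array(list(dgp.group_mix.values()))
    )
    wave_of = rng.choice(waves, size=n)
    df_raw = rng.integers(0, dgp.df_levels, size=n)
    df_std_pop = (df_raw - df_raw.mean()) / df_raw.std(ddof=0)

    if dgp.advantage_per_issue is None:
        advantage = np.clip(rng.normal(0.0, 0.16, size=m), -1, 1)
    else:
        advantage = np.asarray(dgp.advantage_per_issue, dtype=float)
        if advantage.shape != (m,):
            raise ValidationError(
                f"advantage_per_issue must have length n_issues={m}"
            )
    adv10 = (advantage - advantage.mean()) * 10.0

    beta0 = np.broadcast_to(
        np.asarray(dgp.beta0_issue, dtype=float), (m,)
    ).copy()
    u_ind = rng.normal(0.0, dgp.re_sd_individual, size=n)
    u_issue = rng.normal(0.0, dgp.re_sd_issue, size=m)
    u_iw = rng.normal(0.0, dgp.re_sd_issuewave, size=(len(waves), m))

    education = rng.normal(size=n)
    age = rng.normal(size=n)
    media = rng.normal(size=n)
    woman = rng.integers(0, 2, size=n)
    eth = rng.choice(["white", "black", "other"], size=n, p=[0.7, 0.15, 0.15])
    cov = {
        "education_std": education,
        "age_std": age,
        "media_std": media,
        "woman": woman,
        "eth_black": (eth == "black").astype(int),
        "eth_other": (eth == "other").astype(int),
    }
    cov_lp = np.zeros(n)
    for name, eff in dgp.covariate_effects.items():
        if name not in cov:
            raise ValidationError(f"unknown covariate effect {name!r}")
        cov_lp += eff * cov[name]

    beta1 = np.array([dgp.beta1_by_group.get(g, 0.0) for g in groups])
    if dgp.beta3_by_group is None:
        beta3 = np.full(n, dgp.beta3)
    else:
        beta3 = np.array([dgp.beta3_by_group.get(g, 0.0) for g in groups])
    # map each respondent's wave year to its index in the `waves` list
    wave_pos = np.empty(n, dtype=int)
    for j, w in enumerate(waves):
        wave_pos[wave_of == w] = j

    # long table: respondent-major blocks of m issues
    group_sign = np.select(
        [groups == "liberal", groups == "conservative"], [0.5, -0.5], default=0.0
    )
    decades = (wave_of - np.mean(waves)) / 10.0

    resp = np.repeat(np.arange(n), m)
    issue = np.tile(np.arange(m), n)
    lp = (
        beta0[issue]
        + u_ind[resp]
        + u_issue[issue]
        + u_iw[wave_pos[resp], issue]
        + beta1[resp] * df_std_pop[resp]
        + dgp.beta2 * adv10[issue]
        + beta3[resp] * df_std_pop[resp] * adv10[issue]
        + dgp.lean_per_advantage * group_sign[resp] * advantage[issue]
        + (
            dgp.trend_per_advantage
            + dgp.trend_per_advantage_df * df_std_pop[resp]
        )
        * advantage[issue]
        * decades[resp]
        + cov_lp[resp]
    )
    p = 1.0 / (1.0 + np.exp(-lp))
    opinion = (rng.random(n * m) < p).astype(int)

    table = pd.DataFrame(
        {
            "respondent_id": resp,
            "item_id": issue,
            "wave_year": wave_of[resp],
            "opinion_adv": opinion,
            "ideology3": groups[resp],
            "df_raw": df_raw[resp],
            "df_std": df_std_pop[resp],
            "education_std": education[resp],
            "age_std": age[resp],
            "media_std": media[resp],
            "woman": woman[resp],
            "eth_black": cov["eth_black"][resp],
            "eth_other": cov["eth_other"][resp],
            "weight": 1.0,
            "advantage": advantage[issue],
        }
    )
    truth = {
        "n_respondents": n,
        "n_issues": m,
        "waves": waves,
        "beta0_issue": beta0.tolist(),
        "beta1_by_group": dict(dgp.beta1_by_group),
        "beta2": dgp.beta2,
        "beta3": dgp.beta3,
        "beta3_by_group": dict(dgp.beta3_by_group)
        if dgp.beta3_by_group is not None
        else None,
        "lean_per_advantage": dgp.lean_per_advantage,
        "trend_per_advantage": dgp.trend_per_advantage,
        "trend_per_advantage_df": dgp.trend_per_advantage_df,
        "covariate_effects": dict(dgp.covariate_effects),
        "re_sd_individual": dgp.re_sd_individual,
        "re_sd_issue": dgp.re_sd_issue,
        "re_sd_issuewave": dgp.re_sd_issuewave,
        "advantage_per_issue": advantage.tolist(),
        "seed": dgp.seed,
    }
    return table, truth


def write_survey(table: pd.DataFrame, truth: dict, out_dir: str | Path) -> None:
    """Write the survey table as CSV with a JSON truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "survey.csv", index=False)
    (out / "truth.json").write_text(json.dumps(truth, indent=2))


def write_judgments(table: pd.DataFrame, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "judgments.csv", index=False)
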
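"""Five prediction tests of the moral-argument theory, and the end-to-end
synthetic pipeline that exercises score -> prep -> estimate -> test.

The predictions, in the order reported:

1. Opinions with HVFL argument advantage are more common among liberals
   than among conservatives (sign alignment over items).
2. The advantage correlates with the opinion change rate (log-odds per
   decade) across items.
3. Among liberals, discussion frequency (DF) has a positive pooled effect
   on holding advantaged opinions.
4. That DF effect grows with the size of the advantage (the DF x
   advantage interaction), also visible as a steeper change-rate-on-
   advantage slope among frequent than infrequent discussers.
5. Among conservatives the DF effect is near zero, and always smaller in
   magnitude than among liberals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .estimation import (
    Z95,
    ChangeRateModel,
    Coef,
    FitResult,
    fit_pooled_m1,
    fit_pooled_m2,
)
from .exceptions import InsufficientDataError, ValidationError
from .scoring import fisher_z_ci, score_items, threshold_filter
from .synthetic import (
    SurveyDGP,
    gen_argument_judgments,
    gen_survey,
    profile_with_advantage,
)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    n: int


def test_prediction1(
    advantages: Mapping[object, float], prevalences: pd.DataFrame
) -> tuple[int, int]:
    """Count items where the advantage sign matches the liberal lean.

    ``prevalences`` needs columns item_id, prev_liberal, prev_conservative.
    Ties in prevalence count as non-aligned and are logged.
    """
    n_aligned = 0
    n_total = 0
    for _, row in prevalences.iterrows():
        iid = row["item_id"]
        if iid not in advantages:
            raise ValidationError(f"no advantage for item {iid!r}")
        diff = row["prev_liberal"] - row["prev_conservative"]
        n_total += 1
        if diff == 0:
            warnings.warn(
                f"item {iid!r}: equal liberal/conservative prevalence; "
                "counted as non-aligned",
                UserWarning,
                stacklevel=2,
            )
            continue
        if np.sign(advantages[iid]) == np.sign(diff):
            n_aligned += 1
    return n_aligned, n_total


def group_prevalences(records: pd.DataFrame) -> pd.DataFrame:
    """Pooled-over-waves prevalence of opinion_adv per item for liberals
    and conservatives."""
    sub = records.dropna(subset=["opinion_adv"])
    out = []
    for iid, grp in sub.groupby("item_id"):
        lib = grp.loc[grp["ideology3"] == "liberal", "opinion_adv"]
        con = grp.loc[grp["ideology3"] == "conservative", "opinion_adv"]
        out.append(
            {
                "item_id": iid,
                "prev_liberal": float(lib.mean()) if len(lib) else np.nan,
                "prev_conservative": float(con.mean()) if len(con) else np.nan,
            }
        )
    return pd.DataFrame(out)


def test_prediction2(
    advantages: Sequence[float], change_rates: Sequence[float]
) -> CorrelationResult:
    """Pearson correlation (with Fisher-z CI) of advantage with change
    rate across items."""
    a = np.asarray(advantages, dtype=float)
    c = np.asarray(change_rates, dtype=float)
    ok = np.isfinite(a) & np.isfinite(c)
    a, c = a[ok], c[ok]
    if len(a) < 4:
        raise InsufficientDataError("prediction 2 needs >= 4 items")
    if a.std(ddof=0) == 0 or c.std(ddof=0) == 0:
        raise ValidationError("zero variance in advantages or change rates")
    r = float(np.corrcoef(a, c)[0, 1])
    lo, hi = fisher_z_ci(r, len(a))
    return CorrelationResult(r=r, ci_low=lo, ci_high=hi, n=len(a))


@dataclass(frozen=True)
class DFEffectVerdict:
    """Pooled DF effects per group with the P3/P5 comparisons."""

    beta1_liberal: Coef
    beta1_conservative: Coef
    beta1_moderate: Coef | None
    p3_positive: bool
    p5_covers_zero: bool
    ordering_holds: bool  # |beta1_cons| < beta1_lib


def test_df_effects(m1_fits: Mapping[str, FitResult]) -> DFEffectVerdict:
    """Sign and magnitude comparison of pooled DF effects across groups."""
    for g in ("liberal", "conservative"):
        if g not in m1_fits:
            raise ValidationError(f"missing M1 fit for group {g!r}")
    lib = m1_fits["liberal"]["df_std"]
    con = m1_fits["conservative"]["df_std"]
    mod = m1_fits["moderate"]["df_std"] if "moderate" in m1_fits else None
    return DFEffectVerdict(
        beta1_liberal=lib,
        beta1_conservative=con,
        beta1_moderate=mod,
        p3_positive=lib.ci95[0] > 0,
        p5_covers_zero=con.ci95[0] <= 0 <= con.ci95[1],
        ordering_holds=abs(con.estimate) < lib.estimate,
    )


@dataclass(frozen=True)
class Fig5Result:
    """Change-rate-on-advantage slopes for frequent vs infrequent
    discussers and their difference (stacked regression, robust SEs)."""

    slope_frequent: float
    slope_infrequent: float
    difference: float
    diff_se: float
    n_items: int

    @property
    def diff_ci95(self) -> tuple[float, float]:
        return (
            self.difference - Z95 * self.diff_se,
            self.difference + Z95 * self.diff_se,
        )


def fig5_slope_difference(
    liberal_records: pd.DataFrame,
    advantages: Mapping[object, float],
    df_col: str = "df_std",
    weight_items: bool = False,
) -> Fig5Result:
    """Split liberals at their median DF, estimate per-item change rates in
    each half, and compare the least-squares slopes of change rate on
    advantage via a stacked interaction regression with HC1 SEs."""
    med = liberal_records[df_col].median()
    hi = liberal_records[liberal_records[df_col] > med]
    lo = liberal_records[liberal_records[df_col] <= med]
    if len(hi) == 0:  # median equals the maximum (coarse DF scales)
        hi = liberal_records[liberal_records[df_col] >= med]
        lo = liberal_records[liberal_records[df_col] < med]
    if len(hi) == 0 or len(lo) == 0:
        raise InsufficientDataError("median DF split left an empty half")
    rows = []
    for name, split in (("frequent", hi), ("infrequent", lo)):
        rates = ChangeRateModel(split).fit()
        for _, rrow in rates.iterrows():
            if rrow["separated"] or not np.isfinite(rrow["slope"]):
                continue
            iid = rrow["item_id"]
            if iid not in advantages:
                continue
            rows.append(
                {
                    "item_id": iid,
                    "split": name,
                    "slope": rrow["slope"],
                    "se": rrow["se"],
                    "advantage": advantages[iid],
                }
            )
    stacked = pd.DataFrame(rows)
    n_items = stacked["item_id"].nunique()
    if n_items < 4 or stacked["split"].nunique() < 2:
        raise InsufficientDataError(
            "fig5 slope comparison needs change rates in both splits for >= 4 items"
        )
    freq = (stacked["split"] == "frequent").astype(float).to_numpy()
    adv = stacked["advantage"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(stacked)), adv, freq, adv * freq])
    w = 1.0 / stacked["se"].to_numpy() ** 2 if weight_items else None
    model = sm.WLS(stacked["slope"].to_numpy(), X, weights=w) if w is not None else sm.OLS(
        stacked["slope"].to_numpy(), X
    )
    res = model.fit(cov_type="HC1")
    slope_infreq = float(res.params[1])
    diff = float(res.params[3])
    return Fig5Result(
        slope_frequent=slope_infreq + diff,
        slope_infrequent=slope_infreq,
        difference=diff,
        diff_se=float(res.bse[3]),
        n_items=n_items,
    )


# ----------------------------------------------------------------------
# end-to-end synthetic pipeline


@dataclass(frozen=True)
class PipelineConfig:
    """Study conditions for the synthetic end-to-end run.

    Defaults mirror the empirical setting: ~100 items judged by ~98 judges
    each, item advantages spread with SD 0.16, pooled liberal DF effect
    0.12 (moderates 0.06, conservatives 0), DF x advantage interaction
    0.10 per 0.1 advantage, random-intercept SDs 0.8 / 0.3 / 0.5 for
    individual / issue-wave / issue.
    """

    n_items: int = 40
    n_judges: int = 98
    advantage_sd: float = 0.16
    n_respondents: int = 2000
    waves: tuple[int, ...] = (1985, 1995, 2005, 2015)
    beta1_liberal: float = 0.12
    beta1_moderate: float = 0.06
    beta1_conservative: float = 0.0
    beta3: float = 0.10
    lean_per_advantage: float = 4.0
    trend_per_advantage: float = 2.0
    trend_per_advantage_df: float = 0.2
    re_sd_individual: float = 0.8
    re_sd_issuewave: float = 0.3
    re_sd_issue: float = 0.5
    min_abs_advantage: float = 0.1
    seed: int = 0


@dataclass
class PredictionReport:
    """Aggregated outcome of the five prediction tests."""

    p1_aligned: int
    p1_total: int
    p2: CorrelationResult
    p3_p5: DFEffectVerdict
    p4_beta3: Coef
    fig5: Fig5Result | None
    n_items_kept: int
    n_items_scored: int
    seed: int

    def to_dict(self) -> dict:
        d = {
            "p1": {"n_aligned": self.p1_aligned, "n_total": self.p1_total},
            "p2": asdict(self.p2),
            "p3": {
                "beta1_liberal": asdict(self.p3_p5.beta1_liberal),
                "ci95": self.p3_p5.beta1_liberal.ci95,
                "positive": bool(self.p3_p5.p3_positive),
            },
            "p4": {
                "beta3": asdict(self.p4_beta3),
                "ci95": self.p4_beta3.ci95,
            },
            "p5": {
                "beta1_conservative": asdict(self.p3_p5.beta1_conservative),
                "ci95": self.p3_p5.beta1_conservative.ci95,
                "covers_zero": bool(self.p3_p5.p5_covers_zero),
                "ordering_holds": bool(self.p3_p5.ordering_holds),
            },
            "n_items_kept": self.n_items_kept,
            "n_items_scored": self.n_items_scored,
            "seed": self.seed,
        }
        if self.fig5 is not None:
            d["fig5"] = asdict(self.fig5)
            d["fig5"]["diff_ci95"] = self.fig5.diff_ci95
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def recode_to_advantaged(
    records: pd.DataFrame, estimates: pd.DataFrame
) -> tuple[pd.DataFrame, dict[object, float]]:
    """Reverse-code items whose estimated advantage is negative so that
    opinion 1 and a nonnegative advantage always refer to the advantaged
    side.  Returns the recoded records and item -> |advantage| map."""
    sign = {
        row["item_id"]: (1 if row["advantage"] >= 0 else -1)
        for _, row in estimates.iterrows()
    }
    adv = {row["item_id"]: abs(row["advantage"]) for _, row in estimates.iterrows()}
    out = records.copy()
    flip = out["item_id"].map(sign) == -1
    out.loc[flip, "opinion_adv"] = 1 - out.loc[flip, "opinion_adv"]
    out["advantage"] = out["item_id"].map(adv)
    return out, adv


def run_pipeline(
    config: PipelineConfig | Mapping | None = None, out_dir=None
) -> PredictionReport:
    """Generate judgments and survey data with known ground truth, run
    scoring, recoding, estimation and the five prediction tests.

    The survey is generated in advantaged-opinion coding, then re-expressed
    in raw yes-side coding and recoded back using the *estimated* advantage
    signs, so the full scoring -> recoding path is exercised.
    """
    if config is None:
        cfg = PipelineConfig()
    elif isinstance(config, PipelineConfig):
        cfg = config
    else:
        if not config:
            raise ValidationError("empty pipeline configuration")
        cfg = PipelineConfig(**dict(config))

    rng = np.random.default_rng(cfg.seed)
    true_adv = np.clip(rng.normal(0.0, cfg.advantage_sd, size=cfg.n_items), -0.9, 0.9)
    item_ids = [f"item{k:03d}" for k in range(cfg.n_items)]

    # stage 1: argument judgments and scoring
    profiles = [
        profile_with_advantage(iid, a) for iid, a in zip(item_ids, true_adv)
    ]
    judgments = gen_argument_judgments(
        profiles, n_participants=cfg.n_judges, seed=int(rng.integers(2**31))
    )
    estimates = score_items(judgments)
    kept, _ = threshold_filter(estimates, min_abs=cfg.min_abs_advantage)

    # stage 2: survey generation in advantaged coding, then raw coding
    dgp = SurveyDGP(
        n_respondents=cfg.n_respondents,
        n_issues=cfg.n_items,
        waves=cfg.waves,
        beta1_by_group={
            "liberal": cfg.beta1_liberal,
            "moderate": cfg.beta1_moderate,
            "conservative": cfg.beta1_conservative,
        },
        beta3=cfg.beta3,
        beta3_by_group={
            "liberal": cfg.beta3,
            "moderate": cfg.beta3 / 2.0,
            "conservative": 0.0,
        },
        lean_per_advantage=cfg.lean_per_advantage,
        trend_per_advantage=cfg.trend_per_advantage,
        trend_per_advantage_df=cfg.trend_per_advantage_df,
        re_sd_individual=cfg.re_sd_individual,
        re_sd_issue=cfg.re_sd_issue,
        re_sd_issuewave=cfg.re_sd_issuewave,
        advantage_per_issue=np.abs(true_adv),
        seed=int(rng.integers(2**31)),
    )
    survey, truth = gen_survey(dgp)
    survey["item_id"] = survey["item_id"].map(dict(enumerate(item_ids)))
    # raw yes-side coding: flip items whose true advantage is negative
    neg = {iid: a < 0 for iid, a in zip(item_ids, true_adv)}
    flip = survey["item_id"].map(neg)
    survey.loc[flip, "opinion_adv"] = 1 - survey.loc[flip, "opinion_adv"]
    survey = survey.drop(columns=["advantage"])

    # stage 3: recode to advantaged coding from *estimated* signs
    records, adv_map = recode_to_advantaged(survey, estimates)
    kept_ids = set(kept["item_id"])
    analysis = records[records["item_id"].isin(kept_ids)]

    # stage 4: estimation
    m1_fits = {
        g: fit_pooled_m1(analysis, group=g)
        for g in ("liberal", "moderate", "conservative")
    }
    m2_lib = fit_pooled_m2(analysis, group="liberal")

    rates = ChangeRateModel(records).fit()
    rate_map = dict(zip(rates["item_id"], rates["slope"]))
    signed_adv = dict(zip(estimates["item_id"], estimates["advantage"]))

    # stage 5: prediction tests.  Prediction 1 compares the *signed*
    # estimated advantage against the liberal lean in raw (yes-side)
    # coding, before any reverse-coding.
    prev = group_prevalences(survey)
    p1 = test_prediction1(signed_adv, prev)
    p2 = test_prediction2(
        [adv_map[i] for i in rates["item_id"]], rates["slope"].tolist()
    )
    verdict = test_df_effects(m1_fits)
    fig5 = None
    try:
        fig5 = fig5_slope_difference(
            analysis[analysis["ideology3"] == "liberal"], adv_map
        )
    except InsufficientDataError:
        pass

    report = PredictionReport(
        p1_aligned=p1[0],
        p1_total=p1[1],
        p2=p2,
        p3_p5=verdict,
        p4_beta3=m2_lib["df_std:adv10"],
        fig5=fig5,
        n_items_kept=len(kept),
        n_items_scored=len(estimates),
        seed=cfg.seed,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        estimates.to_csv(out / "advantage_estimates.csv", index=False)
        rates.to_csv(out / "change_rates.csv", index=False)
        analysis.to_csv(out / "analysis_records.csv", index=False)
        report.to_json(out / "prediction_report.json")
    return report
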
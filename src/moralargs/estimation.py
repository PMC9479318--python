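"""Discussion-frequency effect estimation on survey records.

Three model families, all on the log-odds scale:

* :class:`IssueLogit` — plain logistic regression of holding the
  HVFL-advantaged opinion on standardized discussion frequency (DF) plus
  demographic controls, for one issue within one ideology group.
* :class:`PooledOpinionModel` — the pooled specification across issues and
  waves with crossed Gaussian random intercepts for individual, issue and
  issue-wave; model "M1" has the DF main effect only, "M2" adds the HVFL
  advantage of the issue (centered, x10 so one unit = 0.1 advantage) and
  its interaction with DF.
* :class:`ChangeRateModel` — per-issue logistic regression of the
  advantaged opinion on time in decades, yielding opinion change rates in
  log-odds per 10 years.

Survey weights are treated as frequency-style pseudo-likelihood weights,
normalized to mean 1; unit weights reproduce the unweighted fit and
integer weights reproduce row duplication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import (
    DegenerateInputError,
    EstimationError,
    InsufficientDataError,
    ValidationError,
)
from .glmm import CrossedLogisticGLMM
from .prep import decade_time, standardize

#: Wald 95% multiplier used throughout.
Z95 = 1.96

#: Default demographic controls (standardized or dummy-coded upstream).
CONTROL_COLUMNS: tuple[str, ...] = (
    "education_std",
    "age_std",
    "media_std",
    "woman",
    "eth_black",
    "eth_other",
)


@dataclass(frozen=True)
class Coef:
    estimate: float
    se: float

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.estimate - Z95 * self.se, self.estimate + Z95 * self.se)

    @property
    def odds_factor(self) -> float:
        """exp of the log-odds coefficient — the multiplicative change in
        odds per unit of the predictor."""
        return float(np.exp(self.estimate))


@dataclass
class FitResult:
    """Unified results container for all estimation models."""

    model_tag: str
    coefficients: dict[str, Coef]
    re_sd: dict[str, float] = field(default_factory=dict)
    n_rows: int = 0
    n_groups: dict[str, int] = field(default_factory=dict)
    method: str = ""
    converged: bool = True
    separated: bool = False

    def __getitem__(self, name: str) -> Coef:
        return self.coefficients[name]

    def summary(self) -> str:
        lines = [
            f"Model: {self.model_tag}   method: {self.method}",
            f"n = {self.n_rows}"
            + (
                "   groups: "
                + ", ".join(f"{k}={v}" for k, v in self.n_groups.items())
                if self.n_groups
                else ""
            ),
            f"converged: {self.converged}" + ("   SEPARATION" if self.separated else ""),
            f"{'term':<22}{'coef':>10}{'se':>10}{'ci95_low':>10}{'ci95_high':>10}{'odds':>8}",
        ]
        for name, c in self.coefficients.items():
            lo, hi = c.ci95
            lines.append(
                f"{name:<22}{c.estimate:>10.4f}{c.se:>10.4f}{lo:>10.4f}{hi:>10.4f}"
                f"{c.odds_factor:>8.3f}"
            )
        if self.re_sd:
            lines.append(
                "random-intercept SDs: "
                + ", ".join(f"{k}={v:.3f}" for k, v in self.re_sd.items())
            )
        return "\n".join(lines)


def normalize_weights(weights: np.ndarray) -> np.ndarray:
    """Scale nonnegative weights to mean 1 (keeps SE scales comparable)."""
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValidationError("weights must be nonnegative")
    m = w.mean()
    if m <= 0:
        raise ValidationError("weights sum to zero")
    return w / m


def _complete_cases(df: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    sub = df.dropna(subset=[c for c in cols if c in df.columns])
    dropped = len(df) - len(sub)
    if dropped:
        warnings.warn(
            f"dropping {dropped} incomplete rows (complete-case analysis)",
            UserWarning,
            stacklevel=3,
        )
    return sub


def _design(
    df: pd.DataFrame,
    controls: Sequence[str],
    extra: Mapping[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, list[str]]:
    cols: dict[str, np.ndarray] = {"const": np.ones(len(df))}
    cols["df_std"] = standardize(df["df_raw"] if "df_raw" in df.columns else df["df_std"])
    if extra:
        cols.update(extra)
    for c in controls:
        if c not in df.columns:
            raise ValidationError(f"missing control column {c!r}")
        cols[c] = df[c].to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    return X, list(cols)


def _glm_logit(y, X, names, weights, tag, method) -> FitResult:
    if len(np.unique(y)) < 2:
        return FitResult(
            model_tag=tag,
            coefficients={},
            n_rows=len(y),
            method=method,
            converged=False,
            separated=True,
        )
    model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=weights)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*[Pp]erfect separation.*")
        try:
            res = model.fit(maxiter=200)
        except Exception as exc:  # PerfectSeparationError and kin
            return FitResult(
                model_tag=tag,
                coefficients={},
                n_rows=len(y),
                method=method,
                converged=False,
                separated=True,
            )
    separated = bool(np.any(np.abs(res.params) > 20))
    coefs = {
        nm: Coef(float(b), float(se))
        for nm, b, se in zip(names, res.params, res.bse)
    }
    return FitResult(
        model_tag=tag,
        coefficients=coefs,
        n_rows=len(y),
        method=method,
        converged=bool(res.converged) and not separated,
        separated=separated,
    )


class IssueLogit:
    """Per-issue, per-group logistic model of the advantaged opinion on DF.

    ``from_dataframe`` subsets one item and one ideology group, drops
    incomplete rows, standardizes DF within the estimation sample, and
    attaches controls.
    """

    def __init__(self, endog, exog, exog_names, weights=None):
        self.y = np.asarray(endog, dtype=float)
        self.X = np.asarray(exog, dtype=float)
        self.names = list(exog_names)
        self.w = (
            normalize_weights(weights) if weights is not None else np.ones(len(self.y))
        )

    @classmethod
    def from_dataframe(
        cls,
        records: pd.DataFrame,
        item_id: object | None = None,
        group: str | None = None,
        controls: Sequence[str] = CONTROL_COLUMNS,
        include_year: bool = False,
        weight_col: str | None = "weight",
    ) -> "IssueLogit":
        df = records
        if item_id is not None:
            df = df[df["item_id"] == item_id]
        if group is not None:
            df = df[df["ideology3"] == group]
        if len(df) == 0:
            raise InsufficientDataError("empty group/item subset")
        need = ["opinion_adv"] + (
            ["df_raw"] if "df_raw" in df.columns else ["df_std"]
        ) + list(controls)
        df = _complete_cases(df, need)
        if len(df) == 0:
            raise InsufficientDataError("no complete cases in subset")
        extra = {}
        if include_year:
            extra["year_std"] = standardize(df["wave_year"])
        X, names = _design(df, controls, extra)
        w = (
            df[weight_col].to_numpy(dtype=float)
            if weight_col and weight_col in df.columns
            else None
        )
        return cls(df["opinion_adv"].to_numpy(dtype=float), X, names, w)

    def fit(self) -> FitResult:
        return _glm_logit(
            self.y, self.X, self.names, self.w, "per_issue", "ML logistic (GLM/IRLS)"
        )


def fit_issue_logistic(
    records: pd.DataFrame,
    item_id: object | None = None,
    group: str | None = None,
    **kwargs,
) -> FitResult:
    """Functional wrapper over :class:`IssueLogit`."""
    return IssueLogit.from_dataframe(records, item_id=item_id, group=group, **kwargs).fit()


class PooledOpinionModel:
    """Pooled DF-effect model with crossed random intercepts.

    ``spec`` selects "m1" (DF only) or "m2" (DF + advantage main effect +
    DF x advantage interaction; advantage centered over distinct items and
    scaled so one unit = 0.1 advantage).
    """

    def __init__(self, endog, exog, exog_names, groups, weights=None):
        self.y = np.asarray(endog, dtype=float)
        self.X = np.asarray(exog, dtype=float)
        self.names = list(exog_names)
        self.groups = groups
        self.w = (
            normalize_weights(weights) if weights is not None else np.ones(len(self.y))
        )

    @classmethod
    def from_dataframe(
        cls,
        records: pd.DataFrame,
        group: str | None = None,
        spec: str = "m1",
        advantage: Mapping[object, float] | None = None,
        controls: Sequence[str] = CONTROL_COLUMNS,
        include_year: bool = False,
        weight_col: str | None = "weight",
    ) -> "PooledOpinionModel":
        if spec not in ("m1", "m2"):
            raise ValidationError(f"spec must be 'm1' or 'm2', got {spec!r}")
        df = records
        if group is not None:
            df = df[df["ideology3"] == group]
        if len(df) == 0:
            raise InsufficientDataError(f"no rows for group {group!r}")
        need = ["opinion_adv"] + (
            ["df_raw"] if "df_raw" in df.columns else ["df_std"]
        ) + list(controls)
        df = _complete_cases(df, need)
        extra: dict[str, np.ndarray] = {}
        if spec == "m2":
            if advantage is not None:
                adv = df["item_id"].map(dict(advantage)).to_numpy(dtype=float)
                if np.isnan(adv).any():
                    missing = df.loc[np.isnan(adv), "item_id"].unique()
                    raise ValidationError(
                        f"advantage missing for item(s) {list(missing)[:5]}"
                    )
            elif "advantage" in df.columns:
                adv = df["advantage"].to_numpy(dtype=float)
            else:
                raise ValidationError("m2 needs per-item advantage values")
            item_means = pd.Series(adv, index=df["item_id"].to_numpy()).groupby(
                level=0
            ).mean()
            if float(item_means.std(ddof=0)) <= 1e-10 * max(
                1.0, float(np.abs(item_means).max())
            ):
                raise DegenerateInputError(
                    "advantage constant across items; DF x advantage "
                    "interaction is inestimable"
                )
            adv10 = (adv - item_means.mean()) * 10.0
            df_std = standardize(
                df["df_raw"] if "df_raw" in df.columns else df["df_std"]
            )
            extra["adv10"] = adv10
            extra["df_std:adv10"] = df_std * adv10
        if include_year:
            extra["year_std"] = standardize(df["wave_year"])
        X, names = _design(df, controls, extra)
        groups = {
            "individual": df["respondent_id"].to_numpy(),
            "issue_wave": (
                df["item_id"].astype(str) + "@" + df["wave_year"].astype(str)
            ).to_numpy(),
            "issue": df["item_id"].to_numpy(),
        }
        w = (
            df[weight_col].to_numpy(dtype=float)
            if weight_col and weight_col in df.columns
            else None
        )
        mdl = cls(df["opinion_adv"].to_numpy(dtype=float), X, names, groups, w)
        mdl.spec = spec
        return mdl

    def fit(self) -> FitResult:
        glmm = CrossedLogisticGLMM(
            self.y, self.X, self.groups, weights=self.w, exog_names=self.names
        )
        res = glmm.fit()
        coefs = {
            nm: Coef(res.params[nm], res.bse[nm]) for nm in self.names
        }
        return FitResult(
            model_tag=getattr(self, "spec", "m1").upper(),
            coefficients=coefs,
            re_sd=res.re_sd,
            n_rows=res.n_obs,
            n_groups=res.n_groups,
            method=res.method,
            converged=res.converged,
        )

    def fit_pooled_logit(self) -> FitResult:
        """Fallback: pooled logistic with cluster-robust (by individual)
        SEs — for data where the GLMM cannot be fitted.  Clearly labeled
        in the result's ``method``."""
        model = sm.GLM(
            self.y, self.X, family=sm.families.Binomial(), freq_weights=self.w
        )
        res = model.fit(
            cov_type="cluster", cov_kwds={"groups": self.groups["individual"]}
        )
        coefs = {
            nm: Coef(float(b), float(se))
            for nm, b, se in zip(self.names, res.params, res.bse)
        }
        return FitResult(
            model_tag=getattr(self, "spec", "m1").upper() + "-fallback",
            coefficients=coefs,
            n_rows=len(self.y),
            method="pooled logistic, cluster-robust SEs (no random effects)",
            converged=bool(res.converged),
        )


def fit_pooled_m1(records: pd.DataFrame, group: str | None = None, **kwargs) -> FitResult:
    """Pooled DF effect (model M1) for one ideology group."""
    return PooledOpinionModel.from_dataframe(records, group=group, spec="m1", **kwargs).fit()


def fit_pooled_m2(
    records: pd.DataFrame,
    group: str | None = None,
    advantage: Mapping[object, float] | None = None,
    **kwargs,
) -> FitResult:
    """Pooled DF x advantage moderation (model M2) for one ideology group."""
    return PooledOpinionModel.from_dataframe(
        records, group=group, spec="m2", advantage=advantage, **kwargs
    ).fit()


@dataclass(frozen=True)
class ChangeRate:
    """Opinion change rate for one issue: log-odds per decade."""

    item_id: object
    slope: float
    se: float
    n: int
    separated: bool = False

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.slope - Z95 * self.se, self.slope + Z95 * self.se)


class ChangeRateModel:
    """Logistic trend of the advantaged opinion on time in decades."""

    def __init__(self, records: pd.DataFrame, reference_year: float | None = None,
                 weight_col: str | None = "weight"):
        self.records = records
        self.reference_year = reference_year
        self.weight_col = weight_col

    def fit_item(self, item_id: object) -> ChangeRate:
        df = self.records[self.records["item_id"] == item_id].dropna(
            subset=["opinion_adv"]
        )
        years = df["wave_year"].unique()
        if len(years) < 2:
            raise InsufficientDataError(
                f"change rate for item {item_id!r} needs >= 2 distinct waves"
            )
        ref = self.reference_year if self.reference_year is not None else years.min()
        dec = decade_time(df["wave_year"].to_numpy(), ref)
        X = np.column_stack([np.ones(len(df)), dec])
        w = (
            normalize_weights(df[self.weight_col].to_numpy(dtype=float))
            if self.weight_col and self.weight_col in df.columns
            else np.ones(len(df))
        )
        res = _glm_logit(
            df["opinion_adv"].to_numpy(dtype=float),
            X,
            ["const", "decades"],
            w,
            "change_rate",
            "ML logistic trend (GLM/IRLS)",
        )
        if res.separated or "decades" not in res.coefficients:
            return ChangeRate(item_id, np.nan, np.nan, len(df), separated=True)
        c = res.coefficients["decades"]
        return ChangeRate(item_id, c.estimate, c.se, len(df))

    def fit(self, items: Sequence[object] | None = None) -> pd.DataFrame:
        ids = (
            list(items)
            if items is not None
            else sorted(self.records["item_id"].unique())
        )
        rows = []
        for iid in ids:
            cr = self.fit_item(iid)
            rows.append(
                {
                    "item_id": cr.item_id,
                    "slope": cr.slope,
                    "se": cr.se,
                    "n": cr.n,
                    "separated": cr.separated,
                }
            )
        return pd.DataFrame(rows)


def fit_change_rate(records: pd.DataFrame, item_id: object, **kwargs) -> ChangeRate:
    """Functional wrapper: change rate for one issue."""
    return ChangeRateModel(records, **kwargs).fit_item(item_id)
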
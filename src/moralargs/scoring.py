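"""HVFL argument-advantage scoring of moral opinions.

Each judged item carries 14 binary endorsement dummies: for each of seven
argument kinds (harm, violence, fairness, liberty, authority, loyalty,
purity) a participant marks whether that kind of argument justifies the
"yes" opinion and whether it justifies the "no" opinion.  Only the four
generally acceptable kinds — harm, violence, fairness, liberty (HVFL) —
enter the score.  The per-participant advantage of the "yes" opinion is

    (yes:harm + yes:violence + yes:fairness + yes:liberty)/4
  - (no:harm  + no:violence  + no:fairness  + no:liberty)/4

with theoretical range [-1, 1].  An item's advantage estimate is the mean
of per-participant scores; its SE is the sample SD over sqrt(n).  Liberal-
and conservative-based sub-means support an ideology-split reliability
check (Pearson r with a Fisher-z interval).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, ValidationError

ARGUMENT_KINDS: tuple[str, ...] = (
    "harm",
    "violence",
    "fairness",
    "liberty",
    "authority",
    "loyalty",
    "purity",
)
#: The four generally acceptable kinds that define the advantage score.
HVFL_KINDS: tuple[str, ...] = ("harm", "violence", "fairness", "liberty")
SIDES: tuple[str, ...] = ("yes", "no")

#: Canonical dummy column names, e.g. ``yes_harm`` ... ``no_purity``.
DUMMY_COLUMNS: tuple[str, ...] = tuple(
    f"{side}_{kind}" for side in SIDES for kind in ARGUMENT_KINDS
)
_HVFL_YES = tuple(f"yes_{k}" for k in HVFL_KINDS)
_HVFL_NO = tuple(f"no_{k}" for k in HVFL_KINDS)


@dataclass(frozen=True)
class AdvantageEstimate:
    """Per-item HVFL argument-advantage estimate.

    ``mean_liberal_based`` / ``mean_conservative_based`` are NaN when the
    item has no judges of that ideology (missing, never coerced to 0).
    ``se`` is NaN for a single judge.
    """

    item_id: object
    mean: float
    se: float
    n_judges: int
    mean_liberal_based: float = math.nan
    mean_conservative_based: float = math.nan

    def __post_init__(self) -> None:
        if abs(self.mean) > 1 + 1e-12:
            raise ValidationError(f"advantage mean out of [-1, 1]: {self.mean}")


def normalize_dummy_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Accept the ``yes:harm`` colon dialect used by the public advantage
    repository and rename to canonical ``yes_harm`` columns."""
    ren = {c: c.replace(":", "_") for c in df.columns if ":" in c}
    return df.rename(columns=ren) if ren else df


def _check_dummies(values: Mapping[str, object], columns: Iterable[str]) -> None:
    for col in columns:
        if col not in values:
            side, kind = col.split("_", 1)
            raise ValidationError(f"missing endorsement dummy side={side} kind={kind}")
        v = values[col]
        if v not in (0, 1, 0.0, 1.0, False, True):
            raise ValidationError(f"non-binary endorsement dummy {col}={v!r}")


def participant_advantage(judgment: Mapping[str, object]) -> float:
    """Advantage score of the "yes" opinion for one participant x item.

    Parameters
    ----------
    judgment : mapping
        Must contain the eight HVFL dummies (``yes_harm`` ... ``no_liberty``;
        the ``yes:harm`` spelling is also accepted).  Non-HVFL dummies are
        ignored.

    Returns
    -------
    float in [-1, 1].
    """
    j = {str(k).replace(":", "_"): v for k, v in dict(judgment).items()}
    _check_dummies(j, _HVFL_YES + _HVFL_NO)
    yes = sum(float(j[c]) for c in _HVFL_YES) / 4.0
    no = sum(float(j[c]) for c in _HVFL_NO) / 4.0
    return yes - no


def score_judgments(judgments: pd.DataFrame) -> pd.Series:
    """Vectorized per-row advantage scores for a judgment table."""
    df = normalize_dummy_columns(judgments)
    missing = [c for c in _HVFL_YES + _HVFL_NO if c not in df.columns]
    if missing:
        side, kind = missing[0].split("_", 1)
        raise ValidationError(f"missing endorsement dummy side={side} kind={kind}")
    sub = df[list(_HVFL_YES + _HVFL_NO)]
    vals = sub.to_numpy(dtype=float)
    if not np.isin(vals, (0.0, 1.0)).all():
        bad = sub.columns[np.argmax(~np.isin(vals, (0.0, 1.0)).all(axis=0))]
        raise ValidationError(f"non-binary endorsement dummy in column {bad}")
    yes = vals[:, :4].mean(axis=1)
    no = vals[:, 4:].mean(axis=1)
    return pd.Series(yes - no, index=df.index, name="advantage")


def item_advantage(judgments: pd.DataFrame, item_id: object | None = None) -> AdvantageEstimate:
    """Advantage estimate for a single item from its judgment rows.

    The mean is the arithmetic mean of per-participant scores; the SE uses
    the n-1 sample SD.  Ideology sub-means cover liberal-only and
    conservative-only judges; 'other' judges enter the overall mean only.
    """
    if len(judgments) == 0:
        raise InsufficientDataError("no judgments supplied for item_advantage")
    df = normalize_dummy_columns(judgments)
    if item_id is None:
        ids = df["item_id"].unique() if "item_id" in df.columns else [None]
        if len(ids) > 1:
            raise ValidationError(
                f"item_advantage expects one item; got {len(ids)} item_ids"
            )
        item_id = ids[0]
    scores = score_judgments(df)
    n = len(scores)
    mean = float(scores.mean())
    se = float(scores.std(ddof=1) / math.sqrt(n)) if n >= 2 else math.nan

    def _sub(label: str) -> float:
        if "ideology" not in df.columns:
            return math.nan
        s = scores[df["ideology"] == label]
        return float(s.mean()) if len(s) else math.nan

    return AdvantageEstimate(
        item_id=item_id,
        mean=mean,
        se=se,
        n_judges=n,
        mean_liberal_based=_sub("liberal"),
        mean_conservative_based=_sub("conservative"),
    )


def score_items(judgments: pd.DataFrame) -> pd.DataFrame:
    """Advantage estimates for every item in a judgment table.

    Returns a DataFrame with one row per item: columns ``item_id``,
    ``advantage``, ``se``, ``n_judges``, ``advantage_liberal``,
    ``advantage_conservative``.
    """
    df = normalize_dummy_columns(judgments)
    if "item_id" not in df.columns:
        raise ValidationError("judgment table lacks an item_id column")
    rows = []
    for iid, grp in df.groupby("item_id", sort=True):
        est = item_advantage(grp, item_id=iid)
        rows.append(
            {
                "item_id": est.item_id,
                "advantage": est.mean,
                "se": est.se,
                "n_judges": est.n_judges,
                "advantage_liberal": est.mean_liberal_based,
                "advantage_conservative": est.mean_conservative_based,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ReliabilityResult:
    """Pearson correlation between ideology-based sub-means with Fisher-z CI."""

    r: float
    ci_low: float
    ci_high: float
    n_items: int


def fisher_z_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation."""
    if n < 4:
        raise InsufficientDataError("Fisher-z CI needs n >= 4")
    z = math.atanh(max(min(r, 1 - 1e-15), -1 + 1e-15))
    zcrit = stats.norm.ppf(0.5 + level / 2)
    h = zcrit / math.sqrt(n - 3)
    return math.tanh(z - h), math.tanh(z + h)


def ideology_split_reliability(
    estimates: pd.DataFrame | Iterable[AdvantageEstimate],
) -> ReliabilityResult:
    """Correlate liberal-based with conservative-based item advantages.

    Items lacking either sub-mean are dropped; at least 3 complete pairs
    are required.
    """
    if isinstance(estimates, pd.DataFrame):
        lib = estimates["advantage_liberal"].to_numpy(dtype=float)
        con = estimates["advantage_conservative"].to_numpy(dtype=float)
    else:
        ests = list(estimates)
        lib = np.array([e.mean_liberal_based for e in ests], dtype=float)
        con = np.array([e.mean_conservative_based for e in ests], dtype=float)
    ok = np.isfinite(lib) & np.isfinite(con)
    lib, con = lib[ok], con[ok]
    n = len(lib)
    if n < 3:
        raise InsufficientDataError(
            f"ideology_split_reliability needs >= 3 complete pairs, got {n}"
        )
    r = float(np.corrcoef(lib, con)[0, 1])
    if n >= 4:
        lo, hi = fisher_z_ci(r, n)
    else:
        lo, hi = math.nan, math.nan
    return ReliabilityResult(r=r, ci_low=lo, ci_high=hi, n_items=n)


def threshold_filter(
    estimates: pd.DataFrame, min_abs: float = 0.1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep items whose |advantage| is at least ``min_abs`` (inclusive).

    Adds an ``advantaged_sign`` column (+1/-1) to the kept table recording
    which opinion is coded as advantaged.  Returns (kept, dropped).
    """
    if len(estimates) == 0:
        raise ValidationError("threshold_filter received an empty estimate table")
    adv = estimates["advantage"].to_numpy(dtype=float)
    keep = np.abs(adv) >= min_abs
    kept = estimates.loc[keep].copy()
    kept["advantaged_sign"] = np.sign(kept["advantage"]).astype(int)
    dropped = estimates.loc[~keep].copy()
    if len(kept) == 0:
        warnings.warn(
            f"no items pass |advantage| >= {min_abs}; kept set is empty",
            UserWarning,
            stacklevel=2,
        )
    return kept, dropped
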
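"""Deterministic recoding of raw survey exports into analysis-ready records.

Covers the recodes used throughout the estimation stage: collapsing 7-point
ideology to liberal/moderate/conservative terciles, dichotomizing graded
opinion responses onto the HVFL-advantaged side (neutral responses become
missing), combining newspaper and TV news exposure into a single media-use
score, within-sample standardization, and decade-scaled time.  All
operations are pure: shuffling input rows never changes per-row outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import DegenerateInputError, ValidationError

POLARITY_LABELS = ("advantaged", "disadvantaged", "neutral", "missing")


def ternary_ideology(score7):
    """Collapse 7-point ideology to liberal (1-3) / moderate (4) /
    conservative (5-7); missing propagates."""
    if score7 is None or (isinstance(score7, float) and math.isnan(score7)):
        return None
    s = int(score7)
    if s != score7 or not (1 <= s <= 7):
        raise ValidationError(f"ideology score {score7!r} outside 1..7")
    if s <= 3:
        return "liberal"
    if s == 4:
        return "moderate"
    return "conservative"


def ternary_ideology_series(scores: pd.Series) -> pd.Series:
    """Vectorized :func:`ternary_ideology` over a column."""
    return scores.map(lambda v: ternary_ideology(v) if pd.notna(v) else None)


@dataclass(frozen=True)
class ItemPolarityMap:
    """Raw response code -> side mapping for one item.

    ``codes`` maps each raw response value to one of 'advantaged',
    'disadvantaged', 'neutral' or 'missing'; ``advantage`` carries the
    item's HVFL advantage estimate for downstream models.
    """

    item_id: object
    codes: Mapping[object, str]
    advantage: float = math.nan

    def __post_init__(self) -> None:
        sides = set(self.codes.values())
        bad = sides - set(POLARITY_LABELS)
        if bad:
            raise ValidationError(f"unknown polarity labels {bad} for {self.item_id}")
        if "advantaged" not in sides or "disadvantaged" not in sides:
            raise ValidationError(
                f"polarity map for {self.item_id} must map at least one code "
                "to each of advantaged/disadvantaged"
            )


def dichotomize_opinion(raw, polarity: ItemPolarityMap):
    """Collapse a graded response to {1, 0, missing}.

    1 = the HVFL-advantaged opinion; graded codes fold into their side;
    neutral responses are omitted (missing).
    """
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    if raw not in polarity.codes:
        raise ValidationError(
            f"response code {raw!r} not in polarity map for item {polarity.item_id}"
        )
    side = polarity.codes[raw]
    if side == "advantaged":
        return 1
    if side == "disadvantaged":
        return 0
    return None


def media_use_combine(newspaper_days, tv_news_days):
    """Combine days-per-week newspaper and TV-news exposure as their max;
    a single missing source falls back to the other."""
    def _ok(v):
        return v is not None and not (isinstance(v, float) and math.isnan(v))

    for v in (newspaper_days, tv_news_days):
        if _ok(v) and not (0 <= v <= 7):
            raise ValidationError(f"media-use days {v!r} outside 0..7")
    if _ok(newspaper_days) and _ok(tv_news_days):
        return max(newspaper_days, tv_news_days)
    if _ok(newspaper_days):
        return newspaper_days
    if _ok(tv_news_days):
        return tv_news_days
    return None


def standardize(values) -> np.ndarray:
    """Z-score a column over its non-missing entries (ddof=0).

    Standardization is computed over the rows entering the specific fit,
    so callers should subset before standardizing.
    """
    x = np.asarray(values, dtype=float)
    ok = np.isfinite(x)
    if ok.sum() < 2:
        raise DegenerateInputError("standardize needs >= 2 non-missing values")
    mu = x[ok].mean()
    sd = x[ok].std(ddof=0)
    if sd == 0:
        raise DegenerateInputError("standardize: zero standard deviation")
    out = np.full_like(x, np.nan)
    out[ok] = (x[ok] - mu) / sd
    return out


def decade_time(year, reference_year):
    """Time in decades since ``reference_year``: (year - ref) / 10."""
    return (np.asarray(year, dtype=float) - reference_year) / 10.0


def load_polarity_maps(path) -> dict[object, ItemPolarityMap]:
    """Read polarity maps from YAML: ``{item_id: {advantage: x, codes: {...}}}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for iid, spec in raw.items():
        out[iid] = ItemPolarityMap(
            item_id=iid,
            codes=spec["codes"],
            advantage=float(spec.get("advantage", math.nan)),
        )
    return out


def read_survey_export(
    path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a delimited survey export (CSV/TSV), renaming columns to the
    canonical layout via ``column_map`` ({source_name: canonical_name}).

    The delimiter is sniffed from the extension unless ``sep`` is given.
    """
    p = str(path)
    if sep is None:
        sep = "\t" if p.endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(p, sep=sep)
    if column_map:
        missing = [c for c in column_map if c not in df.columns]
        if missing:
            raise ValidationError(
                f"export lacks mapped column(s): {missing}"
            )
        df = df.rename(columns=dict(column_map))
    return df


def prepare_survey_table(
    df: pd.DataFrame,
    polarity: Mapping[object, ItemPolarityMap] | None = None,
    ideology_col: str = "ideology7",
    opinion_col: str = "opinion_raw",
    standardize_cols: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Recode a raw respondent x item x wave export into SurveyRecord form.

    Applies ternary ideology, per-item dichotomization (when ``polarity``
    given), and within-table standardization of the named columns (written
    to ``<col>_std`` alongside the raw column).
    """
    out = df.copy()
    if ideology_col in out.columns:
        out["ideology3"] = ternary_ideology_series(out[ideology_col])
    if polarity is not None and opinion_col in out.columns:
        vals = []
        for iid, raw in zip(out["item_id"], out[opinion_col]):
            if iid not in polarity:
                raise ValidationError(f"no polarity map for item {iid!r}")
            vals.append(dichotomize_opinion(raw, polarity[iid]))
        out["opinion_adv"] = pd.array(
            [v if v is not None else pd.NA for v in vals], dtype="Int64"
        )
    for col in standardize_cols:
        out[f"{col}_std"] = standardize(out[col])
    return out
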
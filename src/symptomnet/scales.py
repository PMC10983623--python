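"""Instrument definitions, scoring, and prevalence classification.

Two ordinal self-report instruments are built in: the 15-item Maslach
Burnout Inventory – General Survey (MBI-GS, items scored 0–6) and the
9-item Patient Health Questionnaire (PHQ-9, items scored 0–3). A
respondent screens positive for burnout when the MBI-GS sum score
exceeds 34 and for clinically relevant depressive symptoms when the
PHQ-9 total is 5 or higher.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScaleDefinition",
    "ResponseMatrix",
    "ExclusionReport",
    "PrevalenceReport",
    "MBI_GS",
    "PHQ9",
    "DEFAULT_SCALES",
    "DEFAULT_ITEM_ORDER",
    "EmptyCohortError",
    "SchemaError",
    "validate_responses",
    "score_totals",
    "prevalence",
    "read_responses_csv",
    "write_responses_csv",
]


class SchemaError(ValueError):
    """Input table does not match the expected item schema."""


class EmptyCohortError(ValueError):
    """Every respondent was excluded; nothing left to analyse."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 at the last digit always rounds away from zero)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class ScaleDefinition:
    """An ordinal instrument: its items, category bounds, and screening cutoff.

    ``cutoff_inclusive`` selects between "total >= cutoff" (inclusive)
    and "total > cutoff" (strict). ``reverse_items`` are mapped
    ``x -> category_max - x`` before summation.
    """

    scale_id: str
    item_ids: tuple[str, ...]
    category_min: int
    category_max: int
    cutoff_value: float
    cutoff_inclusive: bool = False
    reverse_items: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if len(self.item_ids) == 0:
            raise ValueError("scale must have at least one item")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValueError("duplicate item ids")
        if self.category_min >= self.category_max:
            raise ValueError("category_min must be < category_max")
        unknown = set(self.reverse_items) - set(self.item_ids)
        if unknown:
            raise ValueError(f"reverse items not in scale: {sorted(unknown)}")
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        object.__setattr__(self, "reverse_items", frozenset(self.reverse_items))

    @property
    def n_categories(self) -> int:
        return self.category_max - self.category_min + 1

    def is_positive(self, total: float) -> bool:
        if self.cutoff_inclusive:
            return total >= self.cutoff_value
        return total > self.cutoff_value

    def to_dict(self) -> dict:
        return {
            "scale_id": self.scale_id,
            "item_ids": list(self.item_ids),
            "category_min": self.category_min,
            "category_max": self.category_max,
            "cutoff_value": self.cutoff_value,
            "cutoff_inclusive": self.cutoff_inclusive,
            "reverse_items": sorted(self.reverse_items),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScaleDefinition":
        return cls(
            scale_id=d["scale_id"],
            item_ids=tuple(d["item_ids"]),
            category_min=int(d["category_min"]),
            category_max=int(d["category_max"]),
            cutoff_value=float(d["cutoff_value"]),
            cutoff_inclusive=bool(d.get("cutoff_inclusive", False)),
            reverse_items=frozenset(d.get("reverse_items", ())),
        )


#: Burnout positive iff sum > 34 (strict). No items are reverse scored by
#: default; pass ``reverse_items=frozenset({"MBI10", ..., "MBI15"})`` to
#: reverse the positively worded personal-accomplishment items.
MBI_GS = ScaleDefinition(
    scale_id="mbi_gs",
    item_ids=tuple(f"MBI{i}" for i in range(1, 16)),
    category_min=0,
    category_max=6,
    cutoff_value=34,
    cutoff_inclusive=False,
)

#: Depression positive iff total >= 5 (inclusive).
PHQ9 = ScaleDefinition(
    scale_id="phq9",
    item_ids=tuple(f"PHQ{i}" for i in range(1, 10)),
    category_min=0,
    category_max=3,
    cutoff_value=5,
    cutoff_inclusive=True,
)

DEFAULT_SCALES: tuple[ScaleDefinition, ...] = (MBI_GS, PHQ9)
DEFAULT_ITEM_ORDER: tuple[str, ...] = MBI_GS.item_ids + PHQ9.item_ids


@dataclass
class ResponseMatrix:
    """Respondent-by-item ordinal scores with per-item category bounds.

    ``data`` holds one row per respondent; missing values are NaN until
    :func:`validate_responses` removes them. ``bounds`` maps item id to
    its (min, max) admissible score.
    """

    data: pd.DataFrame
    bounds: dict[str, tuple[int, int]]

    def __post_init__(self):
        if self.data.columns.duplicated().any():
            raise SchemaError("duplicate item columns")
        unknown = [c for c in self.data.columns if c not in self.bounds]
        if unknown:
            raise SchemaError(f"items without category bounds: {unknown}")
        arr = self.data.to_numpy(dtype=float)
        for j, item in enumerate(self.data.columns):
            lo, hi = self.bounds[item]
            col = arr[:, j]
            ok = np.isnan(col) | ((col >= lo) & (col <= hi) & (col == np.floor(col)))
            if not ok.all():
                bad = self.data.index[~ok][0]
                raise SchemaError(
                    f"value out of bounds for item {item!r} "
                    f"(respondent {bad!r}, allowed {lo}..{hi})"
                )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, scales: tuple[ScaleDefinition, ...] = DEFAULT_SCALES
    ) -> "ResponseMatrix":
        bounds: dict[str, tuple[int, int]] = {}
        for sc in scales:
            for item in sc.item_ids:
                bounds[item] = (sc.category_min, sc.category_max)
        missing = [i for i in bounds if i not in df.columns]
        if missing:
            raise SchemaError(f"missing expected items: {missing}")
        unknown = [c for c in df.columns if c not in bounds]
        if unknown:
            raise SchemaError(f"unknown item labels: {unknown}")
        order = [i for sc in scales for i in sc.item_ids]
        return cls(data=df[order].astype(float), bounds=bounds)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def respondent_ids(self) -> tuple:
        return tuple(self.data.index)

    @property
    def n_respondents(self) -> int:
        return len(self.data)

    def is_complete(self) -> bool:
        return not self.data.isna().any().any()


@dataclass(frozen=True)
class ExclusionReport:
    """Listwise-deletion audit trail."""

    n_input: int
    n_retained: int
    dropped_ids: tuple

    @property
    def retention_percent(self) -> int:
        return int(round_half_up(100.0 * self.n_retained / self.n_input, 0))


@dataclass(frozen=True)
class PrevalenceReport:
    scale_id: str
    n_total: int
    n_positive: int

    def __post_init__(self):
        if not 0 <= self.n_positive <= self.n_total:
            raise ValueError("need 0 <= n_positive <= n_total")

    @property
    def percent(self) -> float:
        return round_half_up(100.0 * self.n_positive / self.n_total, 1)


def validate_responses(raw: ResponseMatrix) -> tuple[ResponseMatrix, ExclusionReport]:
    """Drop every respondent with any missing item (listwise deletion).

    Raises :class:`EmptyCohortError` when nobody is left.
    """
    if raw.n_respondents == 0:
        raise EmptyCohortError("input has no respondents")
    keep = ~raw.data.isna().any(axis=1)
    dropped = tuple(raw.data.index[~keep])
    if not keep.any():
        raise EmptyCohortError("listwise deletion removed every respondent")
    clean = ResponseMatrix(data=raw.data.loc[keep].astype(int).astype(float), bounds=dict(raw.bounds))
    report = ExclusionReport(
        n_input=raw.n_respondents, n_retained=int(keep.sum()), dropped_ids=dropped
    )
    return clean, report


def score_totals(responses: ResponseMatrix, scale: ScaleDefinition) -> pd.Series:
    """Per-respondent instrument total, reverse-mapping listed items first."""
    missing = [i for i in scale.item_ids if i not in responses.data.columns]
    if missing:
        raise SchemaError(f"responses lack scale items: {missing}")
    block = responses.data[list(scale.item_ids)]
    if block.isna().any().any():
        raise ValueError("responses must be complete for scoring; run validate_responses")
    arr = block.to_numpy(dtype=float)
    for j, item in enumerate(scale.item_ids):
        if item in scale.reverse_items:
            arr[:, j] = scale.category_max - arr[:, j]
    return pd.Series(arr.sum(axis=1), index=block.index, name=f"{scale.scale_id}_total")


def prevalence(totals, scale: ScaleDefinition, n_total: int | None = None) -> PrevalenceReport:
    """Classify totals against the scale cutoff and report the positive rate.

    ``n_total`` defaults to ``len(totals)``; passing it explicitly allows
    prevalence among a denominator larger than the scored subset.
    """
    totals = np.asarray(totals, dtype=float)
    if totals.size == 0:
        raise ValueError("no totals to classify")
    n_total = int(n_total) if n_total is not None else totals.size
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    pos = int(sum(scale.is_positive(t) for t in totals))
    return PrevalenceReport(scale_id=scale.scale_id, n_total=n_total, n_positive=pos)


def read_responses_csv(
    path, scales: tuple[ScaleDefinition, ...] = DEFAULT_SCALES, sep: str = ","
) -> ResponseMatrix:
    """Read a respondent-per-row delimited table; empty cells or 'NA' are missing."""
    df = pd.read_csv(path, sep=sep, na_values=["NA", ""], index_col=None)
    if df.columns[0].lower() in ("respondent", "respondent_id", "id"):
        df = df.set_index(df.columns[0])
    return ResponseMatrix.from_dataframe(df, scales=scales)


def write_responses_csv(responses: ResponseMatrix, path, sep: str = ",") -> None:
    out = responses.data.copy()
    if responses.is_complete():
        out = out.astype(int)
    out.to_csv(path, sep=sep, index_label="respondent_id", na_rep="NA")
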
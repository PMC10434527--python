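"""Questionnaire ingestion, completeness filtering, scoring, and reliability.

The study design measures three instruments per respondent:

* TIPI-C — ten personality items on a 1-7 Likert scale, two per Big-Five
  dimension, one of each pair reverse-keyed;
* GAD-7 — seven anxiety items on a 0-3 scale;
* PHQ-9 — nine depression items on a 0-3 scale.

Scoring produces one network node per personality *dimension* (the mean of
its two recoded items, staying on the 1-7 scale) and one node per anxiety or
depression *item*, for 21 nodes in two theory-given communities.

The exact TIPI-C item-to-dimension map and reverse-key set are instrument
conventions rather than published facts for this dataset; the shipped
default (:func:`default_codebook`) follows the original ten-item inventory
(items 1/6 extraversion, 2/7 agreeableness, 3/8 conscientiousness, 4/9
neuroticism, 5/10 openness; the first of each pair keyed so that a higher
dimension score means more of the trait).  Supply your own codebook if your
administration differs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .exceptions import EmptyDataError, SchemaError, ValidationError

#: Fixed node order used in every output table.
NODE_IDS: tuple[str, ...] = (
    "EXT", "AGR", "CON", "NEU", "OPE",
    "A1", "A2", "A3", "A4", "A5", "A6", "A7",
    "D1", "D2", "D3", "D4", "D5", "D6", "D7", "D8", "D9",
)

PERSONALITY_COMMUNITY = "personality"
SYMPTOM_COMMUNITY = "anxiety_depression"

#: node id -> community, in fixed node order.
NODE_COMMUNITIES: dict[str, str] = {
    nid: (PERSONALITY_COMMUNITY if nid in NODE_IDS[:5] else SYMPTOM_COMMUNITY)
    for nid in NODE_IDS
}


@dataclass(frozen=True)
class CodebookItem:
    item_id: str
    scale: str  # TIPI-C | GAD-7 | PHQ-9
    reverse_keyed: bool
    min_value: int
    max_value: int
    dimension: str | None = None  # TIPI-C only: EXT/AGR/CON/NEU/OPE


@dataclass(frozen=True)
class Codebook:
    items: tuple[CodebookItem, ...]

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def __post_init__(self) -> None:
        ids = self.item_ids
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate item_ids in codebook")
        for it in self.items:
            if it.scale not in ("TIPI-C", "GAD-7", "PHQ-9"):
                raise SchemaError(f"unknown scale {it.scale!r} for {it.item_id}")
            if it.scale == "TIPI-C" and it.dimension not in NODE_IDS[:5]:
                raise SchemaError(
                    f"TIPI-C item {it.item_id} needs a dimension in {NODE_IDS[:5]}"
                )

    def by_scale(self, scale: str) -> list[CodebookItem]:
        return [it for it in self.items if it.scale == scale]


def default_codebook() -> Codebook:
    """Codebook for the standard TIPI-C + GAD-7 + PHQ-9 administration."""
    dims = ("EXT", "AGR", "CON", "NEU", "OPE")
    # original ten-item inventory pairing: item k and k+5 share a dimension,
    # with one member of each pair reverse-keyed
    reversed_items = {6, 2, 8, 4, 10}
    items = [
        CodebookItem(
            item_id=f"TIPI{k}",
            scale="TIPI-C",
            dimension=dims[(k - 1) % 5],
            reverse_keyed=k in reversed_items,
            min_value=1,
            max_value=7,
        )
        for k in range(1, 11)
    ]
    items += [
        CodebookItem(f"GAD{k}", "GAD-7", False, 0, 3) for k in range(1, 8)
    ]
    items += [
        CodebookItem(f"PHQ{k}", "PHQ-9", False, 0, 3) for k in range(1, 10)
    ]
    return Codebook(tuple(items))


def read_codebook(path: str) -> Codebook:
    """Load a codebook from a YAML file (a list of item records)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise SchemaError("codebook file must contain a list of item records")
    items = []
    for rec in raw:
        try:
            items.append(
                CodebookItem(
                    item_id=str(rec["item_id"]),
                    scale=str(rec["scale"]),
                    reverse_keyed=bool(rec.get("reverse_keyed", False)),
                    min_value=int(rec["min"]),
                    max_value=int(rec["max"]),
                    dimension=rec.get("dimension"),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"codebook record missing key {exc}") from exc
    return Codebook(tuple(items))


@dataclass
class ItemResponseTable:
    """Respondent x item ordinal matrix plus its codebook.

    ``values`` is a float DataFrame whose NaN entries mark missing answers;
    every non-missing entry respects its item's declared range.
    """

    values: pd.DataFrame
    codebook: Codebook

    @property
    def n(self) -> int:
        return len(self.values)

    def __post_init__(self) -> None:
        cb_ids = self.codebook.item_ids
        cols = list(self.values.columns)
        unknown = [c for c in cols if c not in cb_ids]
        missing = [c for c in cb_ids if c not in cols]
        if unknown:
            raise SchemaError(f"columns not in codebook: {unknown}")
        if missing:
            raise SchemaError(f"codebook items absent from data: {missing}")
        self.values = self.values[cb_ids]  # canonical column order


@dataclass(frozen=True)
class RetentionSummary:
    """Questionnaire completeness accounting."""

    n_submitted: int
    n_valid: int

    @property
    def percent_valid(self) -> float:
        return 100.0 * self.n_valid / self.n_submitted


@dataclass
class NodeScoreTable:
    """Respondent x node matrix of scored values; the network's data.

    21 nodes in fixed order: five personality dimensions on [1, 7] and the
    16 symptom items on {0..3}.  Always complete (no missing entries).
    """

    values: pd.DataFrame
    community: dict[str, str] = field(default_factory=lambda: dict(NODE_COMMUNITIES))

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def node_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class ReliabilityResult:
    scale: str
    alpha: float
    k: int


def read_responses(path: str, codebook: Codebook) -> ItemResponseTable:
    """Read a delimited item-response file, validating against the codebook.

    The delimiter is inferred from the extension (``.tsv``/``.tab`` -> tab,
    anything else -> comma).  Blank cells become missing; any non-numeric or
    out-of-range cell raises :class:`ValidationError` naming its location.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise").astype("float64")
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"non-numeric entry in column {col!r}: {exc}") from exc
    table = ItemResponseTable(values=df, codebook=codebook)
    vals = table.values
    for it in codebook.items:
        col = vals[it.item_id]
        bad = col[(col.notna()) & ((col < it.min_value) | (col > it.max_value))]
        if len(bad):
            row = int(bad.index[0])
            raise ValidationError(
                f"value {bad.iloc[0]:g} out of range [{it.min_value}, "
                f"{it.max_value}] at row {row}, column {it.item_id!r}"
            )
    return table


def filter_complete(table: ItemResponseTable) -> tuple[ItemResponseTable, RetentionSummary]:
    """Keep only fully answered questionnaires.

    Returns the complete-case table and a :class:`RetentionSummary`.  An
    all-incomplete input yields a zero-row table; downstream scoring refuses
    such input.
    """
    mask = table.values.notna().all(axis=1)
    kept = table.values.loc[mask].reset_index(drop=True)
    summary = RetentionSummary(n_submitted=len(table.values), n_valid=int(mask.sum()))
    return ItemResponseTable(values=kept, codebook=table.codebook), summary


def recode_reverse(x, min_value: int, max_value: int):
    """Reverse-key recode: x -> min + max - x (an involution)."""
    return min_value + max_value - x


def score_nodes(table: ItemResponseTable) -> NodeScoreTable:
    """Score the 21 network nodes from a complete item-response table.

    Reverse-keyed items are recoded, each personality dimension becomes the
    mean of its two items, and each symptom item passes through unchanged.
    """
    if table.n == 0:
        raise EmptyDataError("cannot score an empty response table")
    if table.values.isna().any().any():
        raise ValidationError(
            "response table contains missing entries; run filter_complete first"
        )
    recoded = table.values.copy()
    for it in table.codebook.items:
        if it.reverse_keyed:
            recoded[it.item_id] = recode_reverse(
                recoded[it.item_id], it.min_value, it.max_value
            )
    out = pd.DataFrame(index=recoded.index)
    for dim in NODE_IDS[:5]:
        cols = [
            it.item_id for it in table.codebook.by_scale("TIPI-C") if it.dimension == dim
        ]
        if not cols:
            raise SchemaError(f"codebook defines no TIPI-C items for dimension {dim}")
        out[dim] = recoded[cols].mean(axis=1)
    for k, it in enumerate(table.codebook.by_scale("GAD-7"), start=1):
        out[f"A{k}"] = recoded[it.item_id]
    for k, it in enumerate(table.codebook.by_scale("PHQ-9"), start=1):
        out[f"D{k}"] = recoded[it.item_id]
    return NodeScoreTable(values=out[list(NODE_IDS)])


def descriptives(scores: NodeScoreTable) -> pd.DataFrame:
    """Per-node sample mean and SD (n-1 denominator), in fixed node order."""
    if scores.n < 2:
        raise ValidationError("descriptives need at least 2 respondents")
    return pd.DataFrame(
        {
            "node": scores.node_ids,
            "community": [scores.community[n] for n in scores.node_ids],
            "mean": scores.values.mean(axis=0).to_numpy(),
            "sd": scores.values.std(axis=0, ddof=1).to_numpy(),
        }
    )


def cronbach_alpha(items: np.ndarray | pd.DataFrame, scale: str = "") -> ReliabilityResult:
    """Cronbach's alpha: k/(k-1) * (1 - sum(var_i) / var(total)).

    Sample variances use the n-1 denominator.  Requires at least two items,
    two respondents, no missing entries, and a non-degenerate total score.
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValidationError("Cronbach's alpha needs at least 2 items")
    if X.shape[0] < 2:
        raise ValidationError("Cronbach's alpha needs at least 2 respondents")
    if np.isnan(X).any():
        raise ValidationError("Cronbach's alpha requires complete data")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValidationError("total-score variance is zero; alpha undefined")
    alpha = k / (k - 1) * (1.0 - X.var(axis=0, ddof=1).sum() / total_var)
    return ReliabilityResult(scale=scale, alpha=float(alpha), k=k)
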
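"""Distillation of gene annotations into genome-inferred functional traits.

Scoring rule: a pathway step is satisfied by the clause that is best covered
by the genome's annotated identifiers; its fullness is the fraction of that
clause's identifiers present.  For the common two-identifier clause this
reduces to the full (1) / half (0.5) / empty (0) rule.  A GIFT's score is the
unweighted mean of its step fullness values, so every GIFT lies in [0, 1]:
zero when no pathway gene is present, one when every step is complete.  The
Metabolic Capacity Index (MCI) of a genome is the unweighted mean of its GIFT
values, and genomes are classed as low (< 0.15), medium (0.15-0.30) or high
(> 0.30) capacity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, SchemaError
from .trait_db import GiftDefinition, PathwayStep, TraitDB

__all__ = [
    "AnnotationSet",
    "read_annotations",
    "step_fullness",
    "gift_score",
    "distill_catalogue",
    "mci",
    "classify_capacity",
    "mci_table",
    "aggregate_categories",
]

MCI_LOW = 0.15
MCI_HIGH = 0.30


@dataclass(frozen=True)
class AnnotationSet:
    """The set of function identifiers observed among one genome's genes."""

    genome_id: str
    present_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise InputError("genome_id must be non-empty")


def read_annotations(path: str | Path) -> list[AnnotationSet]:
    """Read a ``genome,gene,identifier`` TSV (one row per gene-identifier pair)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"genome", "gene", "identifier"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for genome, sub in df.groupby("genome", sort=True):
        ids = frozenset(x for x in sub["identifier"].dropna().astype(str) if x)
        out.append(AnnotationSet(str(genome), ids))
    return out


def step_fullness(step: PathwayStep, present: Iterable[str]) -> float:
    """Best clause coverage: max over clauses of the fraction of its identifiers present."""
    present = frozenset(present)
    return max(len(c.required_ids & present) / len(c.required_ids) for c in step.clauses)


def gift_score(definition: GiftDefinition, present: Iterable[str]) -> float:
    """Pathway fullness: mean step fullness over the pathway's ordered steps."""
    if not definition.steps:
        raise InputError(f"GIFT {definition.code} has no steps")
    present = frozenset(present)
    return float(np.mean([step_fullness(s, present) for s in definition.steps]))


def distill_catalogue(annotations: Sequence[AnnotationSet], db: TraitDB) -> pd.DataFrame:
    """Score every genome against every GIFT element.

    Returns a genomes x GIFT-codes DataFrame of fullness values in [0, 1]
    with one column per catalogue element.
    """
    genome_ids = [a.genome_id for a in annotations]
    if len(set(genome_ids)) != len(genome_ids):
        dup = sorted({g for g in genome_ids if genome_ids.count(g) > 1})
        raise InputError(f"duplicate genome ids: {dup}")
    values = np.empty((len(annotations), len(db)), dtype=float)
    for i, ann in enumerate(annotations):
        for j, element in enumerate(db.elements):
            values[i, j] = gift_score(element, ann.present_ids)
    return pd.DataFrame(values, index=pd.Index(genome_ids, name="genome"), columns=list(db.codes))


def mci(gift_row: Sequence[float] | pd.Series) -> float:
    """Metabolic Capacity Index: unweighted mean of a genome's GIFT values."""
    arr = np.asarray(gift_row, dtype=float)
    if arr.size == 0:
        raise InputError("cannot compute MCI of an empty GIFT vector")
    if np.any((arr < 0) | (arr > 1)):
        raise InputError("GIFT values must lie in [0, 1]")
    return float(arr.mean())


def classify_capacity(mci_value: float, low: float = MCI_LOW, high: float = MCI_HIGH) -> str:
    """Capacity class of an MCI value; both boundaries belong to ``medium``."""
    if not 0.0 <= mci_value <= 1.0:
        raise InputError(f"MCI value {mci_value} outside [0, 1]")
    if mci_value < low:
        return "low"
    if mci_value > high:
        return "high"
    return "medium"


def mci_table(gifts: pd.DataFrame, low: float = MCI_LOW, high: float = MCI_HIGH) -> pd.DataFrame:
    """Per-genome MCI and capacity class from a GIFT matrix."""
    values = gifts.apply(mci, axis=1)
    classes = values.map(lambda v: classify_capacity(v, low, high))
    return pd.DataFrame({"mci": values, "capacity_class": classes})


def aggregate_categories(gifts: pd.DataFrame, db: TraitDB) -> pd.DataFrame:
    """Merge GIFT columns into functional categories (mean of member GIFTs).

    When the catalogue carries an explicit category map, every GIFT column
    must appear in it; otherwise function codes act as categories.
    """
    if db.category_map:
        unmapped = [c for c in gifts.columns if c not in db.category_map]
        if unmapped:
            raise SchemaError(f"GIFT columns without a category: {unmapped}")
    groups: dict[str, list[str]] = {}
    for code in gifts.columns:
        groups.setdefault(db.category_of(code), []).append(code)
    out = pd.DataFrame(
        {cat: gifts[cols].mean(axis=1) for cat, cols in sorted(groups.items())},
        index=gifts.index,
    )
    return out
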
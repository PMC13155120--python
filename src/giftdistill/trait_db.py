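"""Hierarchical trait (GIFT) database: parsing, validation and category lookup.

A genome-inferred functional trait (GIFT) is a curated metabolic pathway or
module broken into ordered *steps*.  Each step holds one or more *clauses*
(alternative gene sets); a clause lists the function identifiers (KEGG
orthologs, EC numbers, ...) that are jointly required for full credit.  Codes
are positional: the first character is the domain ("B" biosynthesis, "D"
degradation), the first three characters the function (e.g. "B04" for SCFA
biosynthesis) and the full code the element (e.g. "B0403").

The on-disk dialect is a UTF-8 CSV/TSV with header ``code,name,step,clause``
where the clause string joins jointly-required identifiers with ``&`` and
separates alternative clauses with ``|`` (no nesting).  A second optional
table ``code,category`` maps elements to functional categories; when absent,
the function code (first three characters) acts as the category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import InputError, TableParseError

__all__ = [
    "StepClause",
    "PathwayStep",
    "GiftDefinition",
    "TraitDB",
    "parse_clause",
    "parse_trait_db",
    "serialize_trait_db",
    "validate_trait_db",
    "elements_of_category",
]


def _check_identifier(code: str) -> str:
    if not code or any(ch.isspace() for ch in code):
        raise InputError(f"invalid function identifier {code!r}: must be non-empty, no whitespace")
    return code


@dataclass(frozen=True)
class StepClause:
    """A set of identifiers that are jointly required to fully satisfy a step."""

    required_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.required_ids:
            raise InputError("a step clause requires at least one identifier")
        for code in self.required_ids:
            _check_identifier(code)

    def serialize(self) -> str:
        return "&".join(sorted(self.required_ids))


@dataclass(frozen=True)
class PathwayStep:
    """One ordered step of a pathway; its clauses are scoring alternatives."""

    index: int
    clauses: tuple[StepClause, ...]

    def __post_init__(self) -> None:
        if not self.clauses:
            raise InputError(f"step {self.index} has no clauses")
        # clause order is irrelevant for scoring; store canonically sorted
        object.__setattr__(self, "clauses", tuple(sorted(self.clauses, key=StepClause.serialize)))

    def serialize(self) -> str:
        return "|".join(c.serialize() for c in self.clauses)


@dataclass(frozen=True)
class GiftDefinition:
    """A single GIFT element: a coded pathway with ordered steps."""

    code: str
    name: str
    steps: tuple[PathwayStep, ...]

    def __post_init__(self) -> None:
        if not self.code or len(self.code) < 3:
            raise InputError(f"GIFT code {self.code!r} too short for domain/function prefixes")
        object.__setattr__(self, "steps", tuple(sorted(self.steps, key=lambda s: s.index)))

    @property
    def domain_code(self) -> str:
        return self.code[0]

    @property
    def function_code(self) -> str:
        return self.code[:3]

    @property
    def identifiers(self) -> frozenset[str]:
        """Union of all identifiers referenced anywhere in the pathway."""
        out: set[str] = set()
        for step in self.steps:
            for clause in step.clauses:
                out |= clause.required_ids
        return frozenset(out)


@dataclass(frozen=True)
class TraitDB:
    """A catalogue of GIFT definitions plus an optional code -> category map."""

    elements: tuple[GiftDefinition, ...]
    category_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(sorted(self.elements, key=lambda e: e.code)))
        object.__setattr__(self, "category_map", dict(self.category_map))

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(e.code for e in self.elements)

    def get(self, code: str) -> GiftDefinition:
        for element in self.elements:
            if element.code == code:
                return element
        raise KeyError(code)

    def category_of(self, code: str) -> str:
        """Category of an element; falls back to the function code when unmapped."""
        if self.category_map:
            return self.category_map.get(code, code[:3])
        return code[:3]

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(sorted({self.category_of(c) for c in self.codes}))

    @property
    def identifier_pool(self) -> tuple[str, ...]:
        pool: set[str] = set()
        for element in self.elements:
            pool |= element.identifiers
        return tuple(sorted(pool))

    def identifier_to_codes(self) -> dict[str, tuple[str, ...]]:
        """Invert the catalogue: identifier -> codes of every GIFT that lists it."""
        inv: dict[str, list[str]] = {}
        for element in self.elements:
            for ident in element.identifiers:
                inv.setdefault(ident, []).append(element.code)
        return {k: tuple(sorted(v)) for k, v in inv.items()}


def parse_clause(text: str, where: str = "<clause>") -> tuple[StepClause, ...]:
    """Parse a serialized clause string (``A&B|C``) into alternative clauses."""
    if text is None or (isinstance(text, float) and text != text) or not str(text).strip():
        raise TableParseError(f"{where}: empty clause field")
    clauses = []
    for part in str(text).split("|"):
        ids = [p.strip() for p in part.split("&")]
        if any(not p for p in ids):
            raise TableParseError(f"{where}: malformed clause string {text!r}")
        try:
            clauses.append(StepClause(frozenset(ids)))
        except InputError as exc:
            raise TableParseError(f"{where}: {exc}") from exc
    return tuple(clauses)


def _read_any_sep(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str)


def parse_trait_db(path: str | Path, category_path: str | Path | None = None) -> TraitDB:
    """Parse a trait-definition table (and optional category map) into a TraitDB.

    Duplicate ``(code, step, clause)`` rows are collapsed; the same ``(code,
    step)`` appearing with conflicting clause strings is an error, as the row
    already carries every alternative for that step.
    """
    path = Path(path)
    if not path.exists():
        raise TableParseError(f"trait-definition table not found: {path}")
    df = _read_any_sep(path)
    required = {"code", "name", "step", "clause"}
    missing = required - set(df.columns)
    if missing:
        raise TableParseError(f"{path}: missing columns {sorted(missing)}")

    steps_by_code: dict[str, dict[int, PathwayStep]] = {}
    names: dict[str, str] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        where = f"{path.name} line {i}"
        code = str(row.code).strip()
        if not code:
            raise TableParseError(f"{where}: empty code")
        try:
            step_ix = int(row.step)
        except (TypeError, ValueError):
            raise TableParseError(f"{where}: non-integer step {row.step!r}") from None
        clauses = parse_clause(row.clause, where)
        step = PathwayStep(step_ix, clauses)
        names.setdefault(code, str(row.name))
        seen = steps_by_code.setdefault(code, {})
        if step_ix in seen:
            if seen[step_ix].serialize() != step.serialize():
                raise TableParseError(
                    f"{where}: code {code} step {step_ix} redefined with conflicting clauses"
                )
            continue  # exact duplicate row: collapse
        seen[step_ix] = step

    elements = tuple(
        GiftDefinition(code, names[code], tuple(steps.values()))
        for code, steps in steps_by_code.items()
    )

    category_map: dict[str, str] = {}
    if category_path is not None:
        cdf = _read_any_sep(category_path)
        if not {"code", "category"} <= set(cdf.columns):
            raise TableParseError(f"{category_path}: expected columns code,category")
        category_map = dict(zip(cdf["code"].astype(str), cdf["category"].astype(str)))

    return TraitDB(elements, category_map)


def serialize_trait_db(db: TraitDB) -> str:
    """Render the catalogue in its canonical TSV form (sorted, tab-separated)."""
    lines = ["code\tname\tstep\tclause"]
    for element in db.elements:
        for step in element.steps:
            lines.append(f"{element.code}\t{element.name}\t{step.index}\t{step.serialize()}")
    return "\n".join(lines) + "\n"


def validate_trait_db(db: TraitDB) -> list[str]:
    """Return one human-readable finding per invariant violation (empty when clean)."""
    findings: list[str] = []
    seen: set[str] = set()
    for element in db.elements:
        if element.code in seen:
            findings.append(f"duplicate GIFT code {element.code}")
        seen.add(element.code)
        if not element.steps:
            findings.append(f"GIFT {element.code} has no steps")
    for key in db.category_map:
        if key not in seen:
            findings.append(f"category map key {key} not present among elements")
    return findings


def elements_of_category(db: TraitDB, category: str) -> list[str]:
    """All GIFT codes mapped to ``category`` (case-sensitive), sorted by code."""
    valid = {db.category_of(code) for code in db.codes}
    if category not in valid:
        raise InputError(f"unknown functional category {category!r}")
    return sorted(code for code in db.codes if db.category_of(code) == category)
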
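"""Bundled trait catalogues.

`synthetic_reference_db` is a synthetic stand-in for a full published
170-element GIFT catalogue: the code hierarchy, the anchor elements that the
pipeline's downstream rules refer to by code (nucleic-acid biosynthesis
B0101-B0103, lysine B0211, the SCFA family B04, thiamine B0701,
indole-3-acetate B0805, arginine degradation D0509) and the element count are
real; the identifiers populating the remaining pathways are generated
deterministically and carry no curated biochemical meaning.
"""

from __future__ import annotations

import zlib

from .trait_db import GiftDefinition, PathwayStep, StepClause, TraitDB

__all__ = ["synthetic_reference_db", "default_trait_db", "ANCHOR_CODES"]

# (function code, category label, number of elements); 170 elements in total
_FAMILIES: tuple[tuple[str, str, int], ...] = (
    ("B01", "Nucleic acid biosynthesis", 6),
    ("B02", "Amino acid biosynthesis", 21),
    ("B03", "Amino acid derivative biosynthesis", 10),
    ("B04", "SCFA biosynthesis", 6),
    ("B05", "Organic anion biosynthesis", 8),
    ("B06", "Polyamine biosynthesis", 6),
    ("B07", "Vitamin biosynthesis", 12),
    ("B08", "Aromatic compound biosynthesis", 10),
    ("B09", "Polysaccharide biosynthesis", 6),
    ("B10", "Lipid biosynthesis", 8),
    ("D01", "Polysaccharide degradation", 12),
    ("D02", "Sugar degradation", 10),
    ("D03", "Lipid degradation", 7),
    ("D04", "Nitrogen compound degradation", 8),
    ("D05", "Amino acid degradation", 20),
    ("D06", "Alcohol degradation", 8),
    ("D07", "Xenobiotic degradation", 6),
    ("D08", "Aromatic compound degradation", 6),
)

_NAMED_ELEMENTS = {
    "B0101": "Purine biosynthesis",
    "B0102": "Pyrimidine biosynthesis",
    "B0103": "Deoxyribonucleotide biosynthesis",
    "B0211": "Lysine biosynthesis",
    "B0401": "Acetate biosynthesis",
    "B0402": "Propionate biosynthesis",
    "B0403": "Butyrate biosynthesis",
    "B0701": "Thiamine (vitamin B1) biosynthesis",
    "B0805": "Indole-3-acetate biosynthesis",
    "D0509": "Arginine degradation",
}

# codes that downstream rules / the simulator address explicitly
ANCHOR_CODES: tuple[str, ...] = tuple(sorted(_NAMED_ELEMENTS))


def _build_element(code: str, name: str, next_id: list[int]) -> GiftDefinition:
    """Deterministically synthesise a pathway with 2-5 steps.

    Step shapes cycle through the three clause patterns found in curated
    catalogues: a two-identifier joint requirement, two alternative
    single-identifier clauses, and a single required identifier.  Roughly one
    identifier in thirteen is reused from earlier in the catalogue so that
    some genes feed several GIFTs.
    """
    h = zlib.crc32(code.encode())
    n_steps = 2 + h % 4

    def fresh() -> str:
        next_id[0] += 1
        if next_id[0] % 13 == 0 and next_id[0] > 20:
            # deterministically reuse an earlier identifier
            return f"K{10000 + (next_id[0] * 7) % (next_id[0] - 10):05d}"
        return f"K{10000 + next_id[0]:05d}"

    steps = []
    for s in range(1, n_steps + 1):
        pattern = (h + s) % 3
        if pattern == 0:  # joint requirement of two identifiers
            clauses = (StepClause(frozenset({fresh(), fresh()})),)
        elif pattern == 1:  # two alternative routes through the step
            clauses = (StepClause(frozenset({fresh()})), StepClause(frozenset({fresh()})))
        else:  # single required identifier
            clauses = (StepClause(frozenset({fresh()})),)
        steps.append(PathwayStep(s, clauses))
    return GiftDefinition(code, name, tuple(steps))


def synthetic_reference_db() -> TraitDB:
    """The 170-element synthetic reference catalogue (see module docstring)."""
    next_id = [0]
    elements: list[GiftDefinition] = []
    category_map: dict[str, str] = {}
    for func, category, count in _FAMILIES:
        for k in range(1, count + 1):
            code = f"{func}{k:02d}"
            name = _NAMED_ELEMENTS.get(code, f"{category} pathway {k:02d}")
            elements.append(_build_element(code, name, next_id))
            category_map[code] = category
    return TraitDB(tuple(elements), category_map)


def default_trait_db(n_gifts: int = 40) -> TraitDB:
    """A compact catalogue for simulation: all anchor elements plus a spread
    of further elements drawn evenly across the families of the reference DB."""
    full = synthetic_reference_db()
    if not len(ANCHOR_CODES) <= n_gifts <= len(full):
        raise ValueError(f"n_gifts must lie in [{len(ANCHOR_CODES)}, {len(full)}]")
    chosen = set(ANCHOR_CODES)
    # round-robin over families for the remainder
    by_family: dict[str, list[str]] = {}
    for code in full.codes:
        by_family.setdefault(code[:3], []).append(code)
    families = sorted(by_family)
    i = 0
    while len(chosen) < n_gifts:
        fam = families[i % len(families)]
        for code in by_family[fam]:
            if code not in chosen:
                chosen.add(code)
                break
        i += 1
    elements = tuple(e for e in full.elements if e.code in chosen)
    category_map = {c: full.category_map[c] for c in chosen}
    return TraitDB(elements, category_map)
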
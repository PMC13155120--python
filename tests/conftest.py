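import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from giftdistill.community import AbundanceTable
from giftdistill.trait_db import GiftDefinition, PathwayStep, StepClause, TraitDB

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def clause(*ids: str) -> StepClause:
    return StepClause(frozenset(ids))


def step(index: int, *clauses: StepClause) -> PathwayStep:
    return PathwayStep(index, tuple(clauses))


@pytest.fixture
def tiny_db() -> TraitDB:
    """Three hand-built pathways with every clause shape the scorer handles."""
    lysine = GiftDefinition(
        "B0211",
        "lysine biosynthesis",
        (
            step(1, clause("K00928", "K00133")),  # joint requirement
            step(2, clause("K01714"), clause("K00215")),  # alternatives
            step(3, clause("K00290")),
        ),
    )
    purine = GiftDefinition("B0101", "purine biosynthesis", (step(1, clause("K00759")),))
    acetate = GiftDefinition(
        "B0401",
        "acetate biosynthesis",
        (step(1, clause("K00625"), clause("K13788")), step(2, clause("K00925"))),
    )
    categories = {
        "B0211": "Amino acid biosynthesis",
        "B0101": "Nucleic acid biosynthesis",
        "B0401": "SCFA biosynthesis",
    }
    return TraitDB((lysine, purine, acetate), categories)


def make_abundance(
    counts: np.ndarray,
    breadth: np.ndarray | None = None,
    lengths=None,
    total=None,
    mapped=None,
) -> AbundanceTable:
    counts = np.asarray(counts)
    n, m = counts.shape
    genomes = [f"g{i + 1}" for i in range(n)]
    samples = [f"s{j + 1}" for j in range(m)]
    breadth = np.ones_like(counts, dtype=float) if breadth is None else np.asarray(breadth, float)
    lengths = np.full(n, 2_000_000.0) if lengths is None else np.asarray(lengths, float)
    mapped = counts.sum(axis=0) if mapped is None else np.asarray(mapped)
    total = mapped * 2 if total is None else np.asarray(total)
    gi = pd.Index(genomes, name="genome")
    si = pd.Index(samples, name="sample")
    return AbundanceTable(
        pd.DataFrame(counts, index=gi, columns=si),
        pd.DataFrame(breadth, index=gi, columns=si),
        pd.Series(lengths, index=gi, name="length_bp"),
        pd.Series(total, index=si, name="total_read_pairs"),
        pd.Series(mapped, index=si, name="mapped_read_pairs"),
    )
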
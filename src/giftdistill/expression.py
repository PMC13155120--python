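"""Gene-level transcript counts to per-MAG GIFT expression profiles.

Expression GIFTs are abundance-weighted sums of member-gene expression: a
gene's length-normalized expression (TPM-style, per-sample totals rescaled
to one million) contributes to every GIFT whose definition lists one of the
gene's identifiers.  A fullness-over-expressed-genes variant is available
for parity with capacity-style scoring.  Genome-reduced taxa are detected
from *raw* counts: a genome is flagged when it shows no transcription at all
across the three nucleic-acid biosynthesis elements (B0101, B0102, B0103).
Expression profiles are ordinated by PCoA of Bray-Curtis dissimilarities on
Hellinger-transformed rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .community import pcoa
from .distill import gift_score
from .errors import InputError, SchemaError
from .trait_db import TraitDB

__all__ = [
    "TranscriptTable",
    "read_transcripts",
    "normalize_transcripts",
    "expression_by_gift",
    "gift_raw_counts",
    "detect_genome_reduced",
    "hellinger",
    "expression_ordination",
    "NUCLEIC_ACID_CODES",
]

NUCLEIC_ACID_CODES: tuple[str, ...] = ("B0101", "B0102", "B0103")


@dataclass(frozen=True)
class TranscriptTable:
    """Gene x sample transcript counts plus the gene -> genome/identifier maps.

    ``genes`` is indexed by gene id with columns ``genome``, ``length_bp``
    and ``identifiers`` (a tuple of function identifiers per gene).
    """

    counts: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.genes.index):
            raise InputError("counts and gene metadata must share the same gene index")
        required = {"genome", "length_bp", "identifiers"}
        if not required <= set(self.genes.columns):
            raise InputError(f"gene metadata must carry columns {sorted(required)}")
        if (self.genes["length_bp"] <= 0).any():
            raise InputError("gene lengths must be positive")
        if (np.asarray(self.counts) < 0).any():
            raise InputError("transcript counts must be non-negative")

    @property
    def genome_ids(self) -> pd.Index:
        return pd.Index(sorted(self.genes["genome"].unique()), name="genome")


def read_transcripts(path: str | Path) -> TranscriptTable:
    """Read a ``gene,genome,identifier,length_bp,<sample...>`` TSV.

    Multiple identifiers on one gene are ';'-joined in the identifier column.
    """
    df = pd.read_csv(path, sep="\t")
    fixed = ["gene", "genome", "identifier", "length_bp"]
    missing = set(fixed) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    samples = [c for c in df.columns if c not in fixed]
    if not samples:
        raise SchemaError(f"{path}: no sample columns")
    df = df.set_index("gene")
    genes = pd.DataFrame(
        {
            "genome": df["genome"].astype(str),
            "length_bp": df["length_bp"].astype(float),
            "identifiers": df["identifier"]
            .fillna("")
            .map(lambda s: tuple(x for x in str(s).split(";") if x)),
        }
    )
    counts = df[samples].astype(int)
    return TranscriptTable(counts, genes)


def normalize_transcripts(t: TranscriptTable) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Length-normalized, depth-rescaled expression (TPM-style).

    Counts are divided by gene length in kb and each sample rescaled to sum
    to 1e6.  Zero-total samples are emitted as NaN columns and flagged.
    """
    rate = t.counts.div(t.genes["length_bp"] / 1e3, axis=0)
    totals = rate.sum(axis=0)
    flagged = tuple(totals[totals <= 0].index.astype(str))
    if flagged:
        warnings.warn(f"samples with no transcripts flagged: {list(flagged)}")
    return rate.div(totals.replace(0, np.nan), axis=1) * 1e6, flagged


def _gene_gift_incidence(t: TranscriptTable, db: TraitDB) -> tuple[pd.DataFrame, int]:
    """0/1 gene x GIFT incidence (a gene feeds every GIFT listing one of its
    identifiers) plus the number of genes assigned to no GIFT."""
    inv = db.identifier_to_codes()
    code_ix = {c: j for j, c in enumerate(db.codes)}
    inc = np.zeros((len(t.genes), len(db.codes)))
    unassigned = 0
    for i, ids in enumerate(t.genes["identifiers"]):
        codes = {c for ident in ids for c in inv.get(ident, ())}
        if not codes:
            unassigned += 1
        for c in codes:
            inc[i, code_ix[c]] = 1.0
    return pd.DataFrame(inc, index=t.genes.index, columns=list(db.codes)), unassigned


def _aggregate(values: pd.DataFrame, genomes: pd.Series, inc: pd.DataFrame) -> pd.DataFrame:
    """Sum gene-level values into genome x GIFT cells via the incidence matrix."""
    out = {}
    for genome, sub in values.groupby(genomes):
        out[genome] = sub.T.values @ inc.loc[sub.index].values  # (samples, gifts)
    return out


def expression_by_gift(
    t: TranscriptTable,
    db: TraitDB,
    pooling: str = "pooled",
    method: str = "sum",
) -> tuple[pd.DataFrame | dict[str, pd.DataFrame], int]:
    """Per-MAG GIFT expression profiles.

    ``method='sum'`` (default): abundance-weighted sum of the normalized
    expression of member genes.  ``method='fullness'``: pathway fullness
    scored over the identifiers with any (pooled) expression.  ``pooling``
    is ``'pooled'`` (sum over samples; genome x GIFT frame) or
    ``'per-sample'`` (dict of sample -> genome x GIFT frame; sum method
    only).  Returns the profiles and the count of genes assigned to no GIFT.
    """
    if pooling not in {"pooled", "per-sample"}:
        raise InputError(f"unknown pooling {pooling!r}")
    inc, unassigned = _gene_gift_incidence(t, db)
    genomes = t.genes["genome"]
    all_genomes = t.genome_ids

    if method == "fullness":
        norm, _ = normalize_transcripts(t)
        expressed = norm.fillna(0).sum(axis=1) > 0
        rows = {}
        for genome in all_genomes:
            ids = {
                ident
                for gene in t.genes.index[(genomes == genome) & expressed]
                for ident in t.genes.loc[gene, "identifiers"]
            }
            rows[genome] = [gift_score(e, ids) for e in db.elements]
        return pd.DataFrame.from_dict(rows, orient="index", columns=list(db.codes)), unassigned
    if method != "sum":
        raise InputError(f"unknown method {method!r}")

    norm, _ = normalize_transcripts(t)
    norm = norm.fillna(0.0)
    per_genome = _aggregate(norm, genomes, inc)
    if pooling == "pooled":
        data = {g: per_genome[g].sum(axis=0) if g in per_genome else np.zeros(len(db.codes)) for g in all_genomes}
        out = pd.DataFrame.from_dict(data, orient="index")
        out.columns = list(db.codes)
        out.index.name = "genome"
        return out, unassigned
    result = {}
    for j, sample in enumerate(norm.columns):
        frame = pd.DataFrame(
            {g: per_genome[g][j] for g in per_genome}, index=list(db.codes)
        ).T
        frame.index.name = "genome"
        result[sample] = frame.reindex(all_genomes, fill_value=0.0)
    return result, unassigned


def gift_raw_counts(t: TranscriptTable, db: TraitDB) -> pd.DataFrame:
    """Genome x GIFT summed *raw* transcript counts (pooled over samples)."""
    inc, _ = _gene_gift_incidence(t, db)
    raw = t.counts.sum(axis=1).to_frame("total")
    per_genome = _aggregate(raw, t.genes["genome"], inc)
    data = {g: per_genome[g][0] for g in per_genome}
    out = pd.DataFrame.from_dict(data, orient="index")
    out.columns = list(db.codes)
    out = out.reindex(t.genome_ids, fill_value=0.0)
    out.index.name = "genome"
    return out


def detect_genome_reduced(
    raw_gift_counts: pd.DataFrame,
    codes: Sequence[str] = NUCLEIC_ACID_CODES,
    genomes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Flag genomes with zero raw transcription across the nucleic-acid codes.

    ``genomes`` optionally names the full catalogue; genomes absent from the
    transcript data are flagged with a ``no_data`` caveat.
    """
    missing = [c for c in codes if c not in raw_gift_counts.columns]
    if missing:
        raise SchemaError(f"required GIFT columns absent from expression data: {missing}")
    flag = raw_gift_counts[list(codes)].sum(axis=1) == 0
    out = pd.DataFrame({"genome_reduced": flag, "no_data": False})
    if genomes is not None:
        absent = [g for g in genomes if g not in out.index]
        if absent:
            extra = pd.DataFrame(
                {"genome_reduced": True, "no_data": True}, index=pd.Index(absent, name="genome")
            )
            out = pd.concat([out, extra]).sort_index()
    out.index.name = "genome"
    return out


def hellinger(rows: pd.DataFrame) -> pd.DataFrame:
    """Square root of row-wise proportions; rows then have unit sum of squares."""
    totals = rows.sum(axis=1)
    if (totals <= 0).any():
        raise InputError("hellinger transform undefined for all-zero rows")
    return np.sqrt(rows.div(totals, axis=0))


def expression_ordination(expr: pd.DataFrame, k: int | None = None):
    """PCoA of Bray-Curtis dissimilarities on Hellinger-transformed profiles.

    All-zero rows are excluded with a warning; at least two nonzero rows are
    required.
    """
    nonzero = expr.sum(axis=1) > 0
    if (~nonzero).any():
        warnings.warn(f"excluding all-zero expression rows: {list(expr.index[~nonzero])}")
    sub = expr.loc[nonzero]
    if len(sub) < 2:
        raise InputError("need at least two genomes with nonzero expression")
    h = hellinger(sub)
    d = squareform(pdist(h.values, metric="braycurtis"))
    return pcoa(pd.DataFrame(d, index=sub.index, columns=sub.index), k=k)
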
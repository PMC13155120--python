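"""Abundance normalization and community-level trait and diversity metrics.

Read-mapping counts per MAG and sample are first filtered cell-wise by
breadth of coverage (cells covering < 30% of the genome are zeroed), then
normalized to RPMM -- reads per million bases of genome, per million mapped
read pairs:

    RPMM[i, j] = counts[i, j] / (length_i / 1e6) / (mapped_j / 1e6)

Relative abundances are length-standardized counts renormalized per sample.
Community-weighted GIFT values are the abundance-weighted means of the trait
matrix, and the community MCI is their average.  Diversities are Hill numbers
at q = 1 (the exponential-entropy limit) in their neutral, phylogenetic
(branch-length weighted) and functional (trait-distance weighted) variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from .errors import DegenerateDataError, InputError

__all__ = [
    "AbundanceTable",
    "RelativeAbundance",
    "CommunityProfiles",
    "filter_by_coverage",
    "percent_mapped",
    "rpmm",
    "relative_abundance",
    "community_weighted_gifts",
    "hill_neutral_q1",
    "hill_phylo_q1",
    "hill_functional_q1",
    "trait_distance",
    "pcoa",
    "diversity_table",
]

COVERAGE_THRESHOLD = 0.30


@dataclass(frozen=True)
class AbundanceTable:
    """MAG x sample read-pair counts plus the sidecars needed to normalize them."""

    counts: pd.DataFrame
    breadth: pd.DataFrame
    genome_length_bp: pd.Series
    total_read_pairs: pd.Series
    mapped_read_pairs: pd.Series

    def __post_init__(self) -> None:
        c, b = self.counts, self.breadth
        if not (c.index.equals(b.index) and c.columns.equals(b.columns)):
            raise InputError("counts and breadth must share MAG rows and sample columns")
        if not c.index.equals(self.genome_length_bp.index):
            raise InputError("genome lengths must be indexed by the count matrix rows")
        for s in (self.total_read_pairs, self.mapped_read_pairs):
            if not c.columns.equals(s.index):
                raise InputError("per-sample totals must be indexed by the sample columns")
        if (np.asarray(c) < 0).any():
            raise InputError("counts must be non-negative")
        barr = np.asarray(b, dtype=float)
        if ((barr < 0) | (barr > 1)).any():
            raise InputError("breadth values must lie in [0, 1]")
        if (self.genome_length_bp <= 0).any():
            raise InputError("genome lengths must be positive")
        if (self.mapped_read_pairs > self.total_read_pairs).any():
            raise InputError("mapped read pairs cannot exceed total read pairs")

    @property
    def genome_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass(frozen=True)
class RelativeAbundance:
    """Length-standardized proportions; empty samples are NaN columns."""

    values: pd.DataFrame
    empty_samples: tuple[str, ...] = ()


@dataclass(frozen=True)
class CommunityProfiles:
    """Per-sample community-weighted GIFT vectors and scalar community MCI."""

    cw_gifts: pd.DataFrame  # samples x GIFT codes
    community_mci: pd.Series  # per sample


def filter_by_coverage(table: AbundanceTable, threshold: float = COVERAGE_THRESHOLD) -> AbundanceTable:
    """Zero count cells whose breadth of coverage is strictly below ``threshold``."""
    if not 0.0 < threshold <= 1.0:
        raise InputError(f"coverage threshold {threshold} outside (0, 1]")
    kept = table.counts.where(table.breadth >= threshold, 0)
    return AbundanceTable(
        kept.astype(table.counts.dtypes.iloc[0] if len(table.counts.dtypes.unique()) == 1 else float),
        table.breadth,
        table.genome_length_bp,
        table.total_read_pairs,
        table.mapped_read_pairs,
    )


def percent_mapped(table: AbundanceTable) -> pd.Series:
    """Percentage of each sample's total read pairs retained in the count matrix."""
    if (table.total_read_pairs <= 0).any():
        raise InputError("total read pairs must be positive for every sample")
    return 100.0 * table.counts.sum(axis=0) / table.total_read_pairs


def rpmm(table: AbundanceTable) -> pd.DataFrame:
    """Reads per million bases of genome, per million mapped read pairs.

    Samples with a zero mapped total are emitted as all-NaN columns with a
    warning rather than failing the batch.
    """
    mapped = table.mapped_read_pairs.astype(float)
    bad = mapped[mapped <= 0].index
    if len(bad):
        warnings.warn(f"samples with no mapped reads emitted as missing: {list(bad)}")
        mapped = mapped.replace(0, np.nan)
    out = table.counts.div(table.genome_length_bp / 1e6, axis=0).div(mapped / 1e6, axis=1)
    return out


def relative_abundance(table: AbundanceTable) -> RelativeAbundance:
    """Length-standardized counts renormalized so each sample sums to one."""
    std = table.counts.div(table.genome_length_bp, axis=0)
    totals = std.sum(axis=0)
    empty = tuple(totals[totals <= 0].index.astype(str))
    if empty:
        warnings.warn(f"samples with no retained counts flagged empty: {list(empty)}")
    values = std.div(totals.replace(0, np.nan), axis=1)
    return RelativeAbundance(values, empty)


def community_weighted_gifts(rel: RelativeAbundance, gifts: pd.DataFrame) -> CommunityProfiles:
    """Abundance-weighted GIFT vector and community MCI for every sample."""
    if set(rel.values.index) != set(gifts.index):
        raise InputError("relative abundance and GIFT matrix must cover the same genomes")
    aligned = gifts.loc[rel.values.index]
    cw = pd.DataFrame(  # NaN (empty-sample) columns propagate to NaN profiles
        rel.values.T.values @ aligned.values, index=rel.values.columns, columns=aligned.columns
    )
    cw.index.name = "sample"
    return CommunityProfiles(cw, cw.mean(axis=1).rename("community_mci"))


def _check_proportions(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise InputError("abundance vector has negative entries")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise InputError(f"abundance vector must sum to 1 (got {p.sum()!r})")
    return p


def hill_neutral_q1(p: np.ndarray) -> float:
    """Effective number of taxa at q = 1: exp of Shannon entropy (zeros skipped)."""
    p = _check_proportions(p)
    nz = p[p > 0]
    return float(np.exp(-np.sum(nz * np.log(nz))))


def hill_phylo_q1(p: pd.Series, tree: TreeNode) -> float:
    """Phylogenetic Hill number at q = 1 (mean effective lineages).

    With branch set B, branch abundance ``a_b`` (sum of descendant tip
    abundances) and mean branch depth ``T = sum L_b a_b``, returns
    ``exp(-sum (L_b / T) a_b ln a_b)``.
    """
    if not isinstance(p, pd.Series):
        raise InputError("phylogenetic Hill requires a tip-labelled pandas Series")
    _check_proportions(p.values)
    tips = {t.name for t in tree.tips()}
    missing = set(p.index) - tips
    if missing:
        raise InputError(f"taxa missing from the tree: {sorted(missing)}")
    abund = dict(p)
    branch: list[tuple[float, float]] = []  # (length, branch abundance)
    totals: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_tip():
            a = float(abund.get(node.name, 0.0))
        else:
            a = sum(totals[id(ch)] for ch in node.children)
        totals[id(node)] = a
        if node.parent is not None:  # root carries no branch
            length = node.length or 0.0
            if length < 0:
                raise InputError(f"negative branch length on {node.name!r}")
            branch.append((length, a))
    arr = np.array(branch, dtype=float)
    T = float((arr[:, 0] * arr[:, 1]).sum())
    if T <= 0:
        raise DegenerateDataError("tree has no branch length supporting abundance")
    nz = arr[arr[:, 1] > 0]
    return float(np.exp(-np.sum(nz[:, 0] / T * nz[:, 1] * np.log(nz[:, 1]))))


def hill_functional_q1(p: np.ndarray, d: np.ndarray) -> float:
    """Functional Hill number at q = 1 from a pairwise trait distance matrix.

    Rao's quadratic entropy ``Q = sum d_ij p_i p_j`` scales the distances;
    returns ``exp(-sum (d_ij / Q) p_i p_j ln(p_i p_j))`` over pairs with
    nonzero abundance product.  All-identical taxa (Q = 0) are degenerate.
    """
    p = _check_proportions(p)
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != p.size:
        raise InputError("distance matrix must be square and match the abundance vector")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0) or not np.isfinite(d).all():
        raise InputError("distance matrix must be symmetric, finite, with zero diagonal")
    pp = np.outer(p, p)
    Q = float((d * pp).sum())
    if Q <= 0:
        raise DegenerateDataError("Rao quadratic entropy is zero: taxa are functionally identical")
    mask = pp > 0
    return float(np.exp(-np.sum(d[mask] / Q * pp[mask] * np.log(pp[mask]))))


def trait_distance(traits: pd.DataFrame, metric: str = "euclidean") -> pd.DataFrame:
    """Pairwise distances between genome trait rows (default Euclidean)."""
    d = squareform(pdist(traits.values, metric=metric))
    return pd.DataFrame(d, index=traits.index, columns=traits.index)


def pcoa(dist: pd.DataFrame | np.ndarray, k: int | None = None) -> tuple[pd.DataFrame, pd.Series]:
    """Principal coordinates analysis (classical scaling via double centering).

    Returns coordinates on the positive-eigenvalue axes (ordered by
    descending eigenvalue, at most ``k``) together with the full eigenvalue
    spectrum; negative eigenvalues are reported but their axes dropped.
    """
    labels = None
    if isinstance(dist, pd.DataFrame):
        labels = dist.index
        dist = dist.values
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InputError("distance matrix must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise InputError("distance matrix must be symmetric with zero diagonal")
    n = d.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (d**2) @ J
    eigvals, eigvecs = scipy.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    if k is not None:
        coords = coords[:, :k]
    labels = labels if labels is not None else pd.RangeIndex(n)
    coords_df = pd.DataFrame(
        coords, index=labels, columns=[f"PCo{i + 1}" for i in range(coords.shape[1])]
    )
    return coords_df, pd.Series(eigvals, name="eigenvalue")


def diversity_table(
    rel: RelativeAbundance,
    tree: TreeNode | None = None,
    traits: pd.DataFrame | None = None,
    trait_metric: str = "euclidean",
) -> pd.DataFrame:
    """Neutral (and optionally phylogenetic/functional) q = 1 Hill numbers per sample.

    Samples flagged empty are excluded with a warning; samples degenerate for
    the functional metric (a single taxon, or identical trait rows) yield NaN.
    """
    dmat = None
    if traits is not None:
        dmat = trait_distance(traits, trait_metric)
    rows = {}
    for sample in rel.values.columns:
        if sample in rel.empty_samples:
            continue
        p = rel.values[sample].fillna(0.0)
        p = p / p.sum()
        row: dict[str, float] = {"neutral": hill_neutral_q1(p.values)}
        if tree is not None:
            row["phylogenetic"] = hill_phylo_q1(p, tree)
        if dmat is not None:
            sub = p[p > 0]
            try:
                row["functional"] = hill_functional_q1(
                    sub.values, dmat.loc[sub.index, sub.index].values
                )
            except DegenerateDataError:
                warnings.warn(f"sample {sample}: functional diversity degenerate, emitting NaN")
                row["functional"] = np.nan
        rows[sample] = row
    if rel.empty_samples:
        warnings.warn(f"excluded empty samples from diversity: {list(rel.empty_samples)}")
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample"
    return out
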
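"""Synthetic study generator: genomes, abundances, weights and transcripts.

The generator emulates the statistical structure of an early-life caecal
microbiome succession experiment so that every pipeline stage is testable
without sequencing data:

* a pure-birth phylogeny of MAGs;
* a generalist-specialist gradient evolved on the tree (Brownian motion on
  the logit of a gene-retention probability), so metabolic capacity is
  phylogenetically structured and genome length grows with gene count;
* per-taxon temporal slopes drawn with a planted (negative by default)
  correlation with MCI, so communities drift from high- toward low-capacity
  taxa as animals age;
* multinomial read-pair counts per sample with Lander-Waterman breadth of
  coverage, realistic mapping rates and per-sample totals;
* body weights at slaughter age built from planted positively and
  negatively associated taxa;
* transcript counts with two planted genome-reduced lineages whose active
  pathway sets differ (SCFA/vitamin-B1 only, versus additionally lysine,
  indole-3-acetate and arginine degradation), both silent on the
  nucleic-acid biosynthesis elements.

Everything is deterministic under (config, seed).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.special import expit, logit
from skbio import TreeNode

from .community import AbundanceTable
from .datasets import default_trait_db
from .distill import AnnotationSet, distill_catalogue
from .errors import InputError
from .expression import TranscriptTable
from .trait_db import TraitDB

__all__ = [
    "ScenarioConfig",
    "GenomeSet",
    "CountsSim",
    "Scenario",
    "simulate_tree",
    "brownian_tips",
    "simulate_genomes",
    "simulate_counts",
    "simulate_weights",
    "simulate_transcripts",
    "simulate_scenario",
    "active_gift_sets",
]

# Study scale used to translate the planted body-weight association counts
# (10 positive / 190 negative out of 822 genomes) to smaller catalogues.
_STUDY_N_TAXA = 822
_STUDY_N_POSITIVE = 10
_STUDY_N_NEGATIVE = 190


@dataclass
class ScenarioConfig:
    """Default conditions of the synthetic study (see docs/methods.md)."""

    n_taxa: int = 150
    n_samples_per_day: int = 40
    days: tuple[int, ...] = (7, 21, 35)
    n_gifts: int = 40
    # genome model
    generalist_fraction: float = 0.35  # root gene-retention probability
    bm_sigma: float = 0.55  # Brownian sd per unit branch length (logit scale)
    genome_base_bp: int = 1_000_000
    bp_per_gene: int = 15_000
    # abundance model
    mci_slope_correlation: float = -0.6
    slope_mean: float = 0.28  # ~68% of taxa get a positive temporal slope
    slope_sd: float = 0.6
    intercept_sd: float = 1.2
    # early communities are dominated by high-capacity generalists, which is
    # what lets most taxa gain *relative* representation as those decline
    intercept_mci_coupling: float = 1.5
    animal_noise_sd: float = 0.3
    depth: int = 4_000_000  # read pairs mapped to the catalogue per sample
    mapping_rate_mean: float = 0.67
    mapping_rate_sd: float = 0.06
    read_pair_bp: int = 300  # 2 x 150 bp chemistry
    breadth_noise_sd: float = 0.03
    # body-weight model
    n_positive_assoc: int | None = None  # scaled from 10/822 when None
    n_negative_assoc: int | None = None  # scaled from 190/822 when None
    weight_baseline_g: float = 2200.0
    weight_noise_sd_g: float = 120.0
    pos_effect_mult: float = 2.0  # planted effect sd in units of noise sd
    neg_effect_mult: float = 0.5
    # transcript model
    n_transcript_samples: int = 6
    n_reduced_pos: int = 5
    n_reduced_neg: int = 5
    transcript_mean: float = 30.0
    transcript_dispersion: float = 0.5
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_taxa < 2 or self.n_samples_per_day < 1 or self.n_gifts < 10:
            raise InputError("counts must be positive (n_taxa >= 2, n_gifts >= 10)")
        if not -1 < self.mci_slope_correlation < 1:
            raise InputError("mci_slope_correlation must lie in (-1, 1)")
        if self.n_positive_assoc is None:
            self.n_positive_assoc = max(1, round(_STUDY_N_POSITIVE * self.n_taxa / _STUDY_N_TAXA))
        if self.n_negative_assoc is None:
            self.n_negative_assoc = max(1, round(_STUDY_N_NEGATIVE * self.n_taxa / _STUDY_N_TAXA))
        if self.n_positive_assoc + self.n_negative_assoc > self.n_taxa:
            raise InputError("planted association counts exceed n_taxa")
        if self.n_reduced_pos + self.n_reduced_neg > self.n_taxa:
            raise InputError("planted genome-reduced counts exceed n_taxa")


@dataclass(frozen=True)
class GenomeSet:
    db: TraitDB
    annotations: tuple[AnnotationSet, ...]
    genome_length_bp: pd.Series
    gifts: pd.DataFrame
    true_mci: pd.Series
    retention: pd.Series
    reduced_pos: tuple[str, ...]  # UBA660-like planted group
    reduced_neg: tuple[str, ...]  # UBA1242-like planted group
    tree_newick: str


@dataclass(frozen=True)
class CountsSim:
    table: AbundanceTable
    metadata: pd.DataFrame
    true_slopes: pd.Series  # absolute-scale planted slopes
    # planted slopes minus the community drift: the expected trend of each
    # taxon's *relative* abundance, which is what count data can recover
    true_relative_slopes: pd.Series


@dataclass(frozen=True)
class Scenario:
    config: ScenarioConfig
    tree_newick: str
    genomes: GenomeSet
    counts: CountsSim
    metadata: pd.DataFrame  # with body_weight_g
    positive_taxa: tuple[str, ...]
    negative_taxa: tuple[str, ...]
    transcripts: TranscriptTable
    transcript_groups: pd.Series


def simulate_tree(n_taxa: int, seed: int) -> str:
    """Pure-birth (Yule) tree with ``n_taxa`` extant tips; newick string."""
    if n_taxa < 2:
        raise InputError("need at least 2 taxa")
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=random.Random(int(seed)),
    )
    for i, leaf in enumerate(sorted(tree.leaf_node_iter(), key=lambda n: n.taxon.label)):
        leaf.taxon.label = f"t{i + 1:04d}"
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def brownian_tips(
    tree: TreeNode, sigma: float, rng: np.random.Generator, root_value: float = 0.0
) -> pd.Series:
    """Brownian motion along the tree; returns the trait value at each tip."""
    values: dict[int, float] = {id(tree): root_value}
    out = {}
    for node in tree.preorder(include_self=False):
        step = rng.normal(0.0, sigma * np.sqrt(max(node.length or 0.0, 0.0)))
        values[id(node)] = values[id(node.parent)] + step
        if node.is_tip():
            out[node.name] = values[id(node)]
    return pd.Series(out).sort_index()


def active_gift_sets(db: TraitDB) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Planted active GIFT sets of the two genome-reduced groups.

    The positively associated group expresses SCFA production (B04 family),
    thiamine (B0701), lysine (B0211), indole-3-acetate (B0805) and arginine
    degradation (D0509); the negatively associated group only the first two.
    """
    scfa = tuple(c for c in db.codes if c.startswith("B04"))
    group_a = scfa + tuple(c for c in ("B0701", "B0211", "B0805", "D0509") if c in db.codes)
    group_b = scfa + (("B0701",) if "B0701" in db.codes else ())
    return group_a, group_b


def _first_clause_ids(db: TraitDB, code: str) -> frozenset[str]:
    element = db.get(code)
    return element.steps[0].clauses[0].required_ids


def simulate_genomes(tree_newick: str, config: ScenarioConfig, seed: int | None = None) -> GenomeSet:
    """Genomes along a generalist-specialist gradient evolved on the tree."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    db = default_trait_db(config.n_gifts)
    tree = TreeNode.read([tree_newick])
    z = brownian_tips(tree, config.bm_sigma, rng, root_value=float(logit(config.generalist_fraction)))
    retention = pd.Series(expit(z), index=z.index, name="retention")
    taxa = list(retention.index)

    pool = list(db.identifier_pool)
    keep = rng.random((len(taxa), len(pool))) < retention.values[:, None]
    universal = sorted(_first_clause_ids(db, "B0101"))[0]
    keep[:, pool.index(universal)] = True  # nucleic-acid synthesis is universal

    # the ten most gene-poor taxa become the planted genome-reduced lineages;
    # they retain (at least partially) their planted active pathways
    order = retention.sort_values(kind="stable").index
    reduced_pos = tuple(order[: config.n_reduced_pos])
    reduced_neg = tuple(order[config.n_reduced_pos : config.n_reduced_pos + config.n_reduced_neg])
    group_a, group_b = active_gift_sets(db)
    for group, codes in ((reduced_pos, group_a), (reduced_neg, group_b)):
        forced = {i for code in codes for i in _first_clause_ids(db, code)}
        for taxon in group:
            row = taxa.index(taxon)
            for ident in forced:
                keep[row, pool.index(ident)] = True

    annotations = tuple(
        AnnotationSet(taxon, frozenset(np.array(pool)[keep[i]]))
        for i, taxon in enumerate(taxa)
    )
    lengths = pd.Series(
        config.genome_base_bp + config.bp_per_gene * keep.sum(axis=1),
        index=pd.Index(taxa, name="genome"),
        name="length_bp",
        dtype=float,
    )
    gifts = distill_catalogue(annotations, db)
    return GenomeSet(
        db,
        annotations,
        lengths,
        gifts,
        gifts.mean(axis=1).rename("mci"),
        retention,
        reduced_pos,
        reduced_neg,
        tree_newick,
    )


def simulate_counts(genomes: GenomeSet, config: ScenarioConfig, seed: int | None = None) -> CountsSim:
    """Multinomial read-pair counts over a planted temporal succession."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    taxa = list(genomes.true_mci.index)
    n = len(taxa)

    zm = (genomes.true_mci - genomes.true_mci.mean()) / genomes.true_mci.std()
    rho = config.mci_slope_correlation
    eps = rng.normal(size=n)
    slopes = pd.Series(
        config.slope_mean + config.slope_sd * (rho * zm.values + np.sqrt(1 - rho**2) * eps),
        index=genomes.true_mci.index,
        name="true_slope",
    )
    intercepts = config.intercept_mci_coupling * zm.values + rng.normal(
        0.0, config.intercept_sd, size=n
    )

    samples, days_col, animals = [], [], []
    for d in config.days:
        for k in range(config.n_samples_per_day):
            i = len(samples)
            samples.append(f"s{i + 1:03d}")
            animals.append(f"a{i + 1:03d}")
            days_col.append(d)
    meta = pd.DataFrame(
        {
            "sample": samples,
            "animal": animals,
            "trial": [("A" if i % 2 == 0 else "B") for i in range(len(samples))],
            "pen": [1 + i % 24 for i in range(len(samples))],
            "day": days_col,
            "sex": [("male" if (i // 2) % 2 == 0 else "female") for i in range(len(samples))],
            "line": [("cobb" if (i // 4) % 2 == 0 else "ross") for i in range(len(samples))],
            "treatment": [f"T{1 + i % 3}" for i in range(len(samples))],
        }
    ).set_index("sample")

    dscale = (meta["day"].values - 21) / 14.0
    eta = (
        intercepts[:, None]
        + slopes.values[:, None] * dscale[None, :]
        + rng.normal(0.0, config.animal_noise_sd, size=(n, len(samples)))
    )
    p = np.exp(eta - eta.max(axis=0))
    p /= p.sum(axis=0)

    counts = np.column_stack([rng.multinomial(config.depth, p[:, j]) for j in range(len(samples))])
    counts_df = pd.DataFrame(counts, index=pd.Index(taxa, name="genome"), columns=meta.index)

    cov_depth = counts * config.read_pair_bp / genomes.genome_length_bp.values[:, None]
    breadth = 1.0 - np.exp(-cov_depth)
    breadth = np.clip(breadth + rng.normal(0.0, config.breadth_noise_sd, breadth.shape), 0, 1)
    breadth[counts == 0] = 0.0
    breadth_df = pd.DataFrame(breadth, index=counts_df.index, columns=counts_df.columns)

    rate = np.clip(
        rng.normal(config.mapping_rate_mean, config.mapping_rate_sd, len(samples)), 0.3, 0.95
    )
    mapped = pd.Series(counts.sum(axis=0), index=meta.index, name="mapped_read_pairs")
    total = pd.Series(
        np.ceil(mapped.values / rate).astype(int), index=meta.index, name="total_read_pairs"
    )
    table = AbundanceTable(counts_df, breadth_df, genomes.genome_length_bp, total, mapped)

    # expected community drift between the first and last day (on dscale)
    d_lo, d_hi = (min(config.days) - 21) / 14.0, (max(config.days) - 21) / 14.0
    log_total = lambda d: np.log(np.sum(np.exp(intercepts + slopes.values * d)))
    drift = (log_total(d_hi) - log_total(d_lo)) / (d_hi - d_lo)
    rel_slopes = (slopes - drift).rename("true_relative_slope")
    return CountsSim(table, meta, slopes, rel_slopes)


def simulate_weights(
    counts: CountsSim, genomes: GenomeSet, config: ScenarioConfig, seed: int | None = None
) -> tuple[pd.DataFrame, tuple[str, ...], tuple[str, ...]]:
    """Body weights with planted positive / negative taxon associations.

    Only slaughter-age (last day) weights carry the planted structure; the
    positively associated taxa are drawn from the genome-reduced planted
    group (falling back to the lowest-MCI abundant taxa), the negatively
    associated ones from the remaining planted group plus the highest-MCI
    abundant taxa.  Effects act through standardized slaughter-age relative
    abundances, scaled by the weight noise sd.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    meta = counts.metadata.copy()
    last_day = max(config.days)
    day35 = meta.index[meta["day"] == last_day]
    if len(day35) == 0:
        raise InputError("no slaughter-age samples to attach weights to")

    rel = counts.table.counts[day35].astype(float)
    rel = rel.div(rel.sum(axis=0), axis=1)
    mean_rel = rel.mean(axis=1)
    # planted association taxa are detectable but not community dominants:
    # effects on dominant taxa would propagate to every taxon through the
    # shared compositional denominator
    lo, hi = mean_rel.median(), mean_rel.quantile(0.90)
    eligible = set(mean_rel.index[(mean_rel > lo) & (mean_rel <= hi)])

    by_mci = genomes.true_mci.sort_values(kind="stable")
    positive = [t for t in genomes.reduced_pos if t in eligible]
    positive += [t for t in by_mci.index if t in eligible and t not in positive]
    positive = tuple(positive[: config.n_positive_assoc])
    negative = [t for t in genomes.reduced_neg if t in eligible and t not in positive]
    negative += [
        t for t in by_mci.index[::-1] if t in eligible and t not in positive and t not in negative
    ]
    negative = tuple(negative[: config.n_negative_assoc])

    # dose-response acts on standardized CLR (centered log-ratio) abundance:
    # per-animal centering removes the shared compositional mode, so a
    # taxon's planted effect reflects its own variation rather than the
    # community denominator
    lrel = np.log(rel + 1e-8)
    lrel = lrel.sub(lrel.mean(axis=0), axis=1)
    sd = lrel.std(axis=1).replace(0, np.nan)
    zrel = lrel.sub(lrel.mean(axis=1), axis=0).div(sd, axis=0).fillna(0.0)
    sigma = config.weight_noise_sd_g
    effect = sigma * (
        config.pos_effect_mult * zrel.loc[list(positive)].sum(axis=0)
        - config.neg_effect_mult * zrel.loc[list(negative)].sum(axis=0)
    )
    sex_eff = meta.loc[day35, "sex"].map({"male": 80.0, "female": 0.0})
    line_eff = meta.loc[day35, "line"].map({"cobb": 0.0, "ross": 40.0})
    w35 = config.weight_baseline_g + sex_eff + line_eff + effect + rng.normal(0, sigma, len(day35))

    weights = pd.Series(np.nan, index=meta.index, name="body_weight_g")
    weights.loc[day35] = w35
    day_baseline = {7: 180.0, 21: 950.0}
    for d, base in day_baseline.items():
        ix = meta.index[meta["day"] == d]
        weights.loc[ix] = base + rng.normal(0, base * 0.08, len(ix))
    meta["body_weight_g"] = weights.round(1)
    return meta, positive, negative


def simulate_transcripts(
    genomes: GenomeSet, config: ScenarioConfig, seed: int | None = None
) -> tuple[TranscriptTable, pd.Series]:
    """Negative-binomial transcript counts with planted genome-reduced groups.

    Both planted groups are silent on B0101-B0103; the positively associated
    group additionally expresses lysine, indole-3-acetate and arginine
    degradation pathways on top of the SCFA/thiamine core.  Background taxa
    express all their annotated genes.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    db = genomes.db
    group_a, group_b = active_gift_sets(db)
    nucleic_ids = {
        i for code in ("B0101", "B0102", "B0103") if code in db.codes
        for i in db.get(code).identifiers
    }
    ids_of = lambda codes: {i for c in codes for i in db.get(c).identifiers}
    active_a, active_b = ids_of(group_a) - nucleic_ids, ids_of(group_b) - nucleic_ids

    samples = [f"r{j + 1:02d}" for j in range(config.n_transcript_samples)]
    size_factors = np.exp(rng.normal(0.0, 0.3, len(samples)))

    gene_rows, count_rows = [], []
    r = config.transcript_dispersion
    for ann in genomes.annotations:
        if ann.genome_id in genomes.reduced_pos:
            active = active_a
        elif ann.genome_id in genomes.reduced_neg:
            active = active_b
        else:
            active = ann.present_ids
        for k, ident in enumerate(sorted(ann.present_ids)):
            gene_rows.append(
                {
                    "gene": f"{ann.genome_id}_g{k + 1:03d}",
                    "genome": ann.genome_id,
                    "length_bp": float(rng.integers(600, 2400)),
                    "identifiers": (ident,),
                }
            )
            if ident in active:
                mu = config.transcript_mean * size_factors
                counts = rng.negative_binomial(r, r / (r + mu))
            else:
                counts = np.zeros(len(samples), dtype=int)
            count_rows.append(counts)
    genes = pd.DataFrame(gene_rows).set_index("gene")
    counts = pd.DataFrame(np.vstack(count_rows), index=genes.index, columns=samples)
    table = TranscriptTable(counts, genes)
    groups = pd.Series("background", index=genomes.true_mci.index, name="group")
    groups.loc[list(genomes.reduced_pos)] = "reduced_pos"
    groups.loc[list(genomes.reduced_neg)] = "reduced_neg"
    return table, groups


def simulate_scenario(config: ScenarioConfig | None = None) -> Scenario:
    """Generate the full input bundle for one synthetic study."""
    config = config or ScenarioConfig()
    rng = np.random.default_rng(config.seed)
    stage_seed = lambda: int(rng.integers(0, 2**31 - 1))
    tree = simulate_tree(config.n_taxa, stage_seed())
    genomes = simulate_genomes(tree, config, stage_seed())
    counts = simulate_counts(genomes, config, stage_seed())
    meta, positive, negative = simulate_weights(counts, genomes, config, stage_seed())
    transcripts, groups = simulate_transcripts(genomes, config, stage_seed())
    return Scenario(config, tree, genomes, counts, meta, positive, negative, transcripts, groups)
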
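# giftdistill

Functional-trait analysis of genome-resolved gut microbiomes: from gene
annotations of metagenome-assembled genomes (MAGs) to quantitative metabolic
traits, community-level capacity metrics, diversity, taxon–phenotype
associations and pathway expression.

The package targets the kind of question asked in early-life succession
studies of production-animal gut microbiota (e.g. the caecal microbiome of
broiler chickens between hatching and slaughter age): as communities
diversify, do they shift from metabolically versatile *generalists* toward
genome-reduced *specialists*, and which taxa matter for host growth?

## What it computes

**Genome-inferred functional traits (GIFTs).** A trait database defines each
pathway as ordered steps; a step holds alternative clauses of jointly
required function identifiers (KEGG orthologs, EC numbers). Step fullness is

```
fullness(step) = max over clauses c of |ids(c) ∩ genome| / |ids(c)|
```

so a two-identifier clause is scored full (1), half (0.5) or empty (0). A
GIFT is the mean step fullness of its pathway, hence GIFT ∈ [0, 1]: 0 when
no pathway gene is present, 1 when the pathway is complete. The **Metabolic
Capacity Index (MCI)** of a genome is the unweighted mean of its GIFTs;
genomes are classed as low (< 0.15), medium (0.15–0.30) or high (> 0.30)
capacity.

**Abundance normalization.** Read-mapping counts are filtered cell-wise
(breadth of coverage < 30 % → removed), converted to percent-mapped per
sample, and normalized to **RPMM** (reads per million bases of genome, per
million mapped read pairs):

```
RPMM[i, j] = counts[i, j] / (length_i / 10^6) / (mapped_j / 10^6)
```

**Community metrics.** Community-weighted GIFTs (Σᵢ pᵢ·GIFTᵢ), community
MCI, and Hill-number diversities of order q = 1 — neutral `exp(−Σ p ln p)`,
phylogenetic (branch-length-weighted, mean effective lineages) and
functional (trait-distance-weighted) — plus PCoA ordinations (Euclidean on
traits; Bray–Curtis on Hellinger-transformed expression).

**Taxon responses.** Per-taxon least squares of log1p abundance on age or
body weight with covariates, classified increasing/decreasing when the
bootstrap sign support reaches 0.9; community direction fractions; the
MCI–response correlation with a permutation test; a phylogenetic
correlogram (Moran's I over patristic distance classes); and percentile
bootstrap 95 % CIs for group comparisons (non-overlap ⇒ distinct).

**Expression.** Gene-level transcript counts become per-MAG GIFT expression
profiles (TPM-style normalization, summed into every GIFT listing the
gene's identifier). Genome-reduced taxa are detected by a complete lack of
transcription of the nucleic-acid biosynthesis elements B0101–B0103.

**Synthetic data.** `giftdistill.synthetic` generates every pipeline input —
phylogeny, annotations, counts, breadths, metadata, weights, transcripts —
with a planted generalist→specialist succession, so the whole pipeline is
testable without sequencing data.

## Worked example

```python
from giftdistill import synthetic, community, distill, dynamics

sc = synthetic.simulate_scenario(synthetic.ScenarioConfig(seed=1))
filtered = community.filter_by_coverage(sc.counts.table)   # breadth < 30% removed
rpmm = community.rpmm(filtered)

mci = distill.mci_table(sc.genomes.gifts)
print(mci["capacity_class"].value_counts().to_dict())

rel = community.relative_abundance(filtered)
profile = community.community_weighted_gifts(rel, sc.genomes.gifts)
print(profile.community_mci.groupby(sc.metadata["day"]).mean().round(3).to_dict())

modelled = dynamics.prevalent_taxa(rpmm)
resp = dynamics.taxon_responses(rpmm.loc[modelled], sc.metadata["day"],
                                sc.metadata[["trial", "sex", "line", "treatment"]],
                                n_boot=500, seed=1)
print({k: round(v, 2) for k, v in dynamics.classify_community(resp).items()})
r, p = dynamics.mci_response_correlation(sc.genomes.true_mci.loc[modelled],
                                         resp["slope"], seed=1)
print(f"MCI-response r = {r:.2f}, permutation p = {p:.3f}")
```

prints

```
{'high': 94, 'medium': 52, 'low': 4}
{7: 0.714, 21: 0.66, 35: 0.603}
{'increase': 0.75, 'decrease': 0.19, 'none': 0.06}
MCI-response r = -0.68, permutation p = 0.001
```

Reading the output: most simulated genomes are high/medium capacity, yet the
community-weighted MCI falls from 0.71 at day 7 to 0.60 at day 35 — the
rising taxa are the low-capacity specialists. Three quarters of modelled
taxa increase in relative abundance with age, and a taxon's metabolic
capacity predicts its temporal response negatively (r = −0.68) with a
permutation p-value at the resolution floor of 999 permutations.

A shell interface wraps the same stages:

```bash
giftdistill simulate --out-dir demo --seed 1
giftdistill run --config pipeline.yaml
```

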
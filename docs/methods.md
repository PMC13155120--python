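# Methods

This note documents the models implemented in `giftdistill`, the choices
made where the design was genuinely open, the synthetic-data generator's
assumptions, and the limits of what the test suite demonstrates.

## Trait distillation

A trait database is a catalogue of pathway definitions. Each pathway
(`GiftDefinition`) has ordered steps; each step has one or more clauses,
and a clause is a set of function identifiers that are jointly required.
Codes are positional: domain (first character, `B` biosynthesis / `D`
degradation), function (first three characters, e.g. `B04` = SCFA
biosynthesis), element (full code, e.g. `B0403` = butyrate biosynthesis).

Scoring generalizes the full/half/empty rule for two-identifier steps: step
fullness is the best clause coverage (fraction of a clause's identifiers
present, maximized over clauses), and the GIFT is the unweighted mean of
step fullness. This reduces exactly to 1 / 0.5 / 0 for a single clause of
two identifiers. Identifiers are matched exactly; no EC wildcard expansion
is attempted, so behaviour is deterministic and auditable. Alternative
whole-pathway routes are expressed as alternative clauses within steps;
nested clause grammars are deliberately unsupported (`&` binds tighter than
`|`, no parentheses).

MCI is the unweighted mean over *all* catalogue elements. No hierarchy
weighting is applied because none is defined by the trait framework; merging
into functional categories (mean of member GIFTs) is available separately.
Class boundaries: low < 0.15, 0.15 ≤ medium ≤ 0.30, high > 0.30 — both
boundary values belong to medium, which is the only assignment consistent
with strict "< 0.15" and "> 0.30" outer classes.

The bundled `synthetic_reference_db()` reproduces the *shape* of a full
curated catalogue — 170 elements across 18 function families, including the
anchor elements the pipeline addresses by code (B0101–B0103 nucleic-acid
biosynthesis, B0211 lysine, B04xx SCFAs, B0701 thiamine, B0805
indole-3-acetate, D0509 arginine degradation) — but its identifier content
is generated, not curated. It is a synthetic stand-in: suitable for
contracts that depend on structure and cardinality, meaningless for real
annotation data.

## Abundance normalization

* Coverage filter: cell-wise (MAG × sample), strict `breadth < threshold`
  with threshold 0.30 by default. Counts only ever decrease.
* Percent mapped: 100 × retained counts / total read pairs, per sample.
* RPMM: counts / (genome length / 10⁶) / (mapped read pairs / 10⁶). The
  denominator is the per-sample count of read pairs mapped to the MAG
  catalogue, following the metric's name ("per million mapped reads");
  nominal read length is not part of the formula. Counts are read pairs;
  single-end data is out of scope.
* Relative abundance: length-standardized counts renormalized per sample.
  All-zero samples are flagged and emitted as missing rather than failing
  the batch.

## Diversity

Hill numbers are computed at q = 1 only, always via the analytic limit
(exponential of entropy-type forms), never a plug-in at q = 1:

* neutral: `exp(−Σ p ln p)`, zeros skipped;
* phylogenetic: with branch set B, branch abundance `a_b` and
  `T = Σ L_b a_b`, returns `exp(−Σ (L_b/T) a_b ln a_b)` (mean effective
  lineages). On a star tree with equal branch lengths this equals the
  neutral Hill number for every abundance vector — a property test and an
  acceptance identity;
* functional: with Rao `Q = Σ d_ij p_i p_j`,
  returns `exp(−Σ (d_ij/Q) p_i p_j ln(p_i p_j))`. Scaling the distance
  matrix leaves the value unchanged; functionally identical taxa (Q = 0)
  raise a degenerate-input error. The trait matrix behind `d` is a run-time
  parameter (default: Euclidean distances on the GIFT matrix).

PCoA is classical scaling (double-centering + symmetric eigendecomposition
via `scipy.linalg.eigh`). Negative eigenvalues are reported in the spectrum
but their axes are dropped; axis signs follow the eigensolver and are not
canonicalized. `skbio.stats.ordination.pcoa` is used as an independent
cross-check in the test suite, not as the implementation, so that the
negative-eigenvalue contract stays explicit.

## Taxon responses and group comparisons

The joint Bayesian species-distribution machinery usually applied to these
questions is replaced by a deliberately simple per-taxon stand-in:

1. response = `log1p(RPMM)`; predictor = age in days or body weight in g;
   categorical covariates (trial, sex, line, treatment) enter dummy-coded.
   Pen effects are not modelled.
2. ordinary least squares for the slope; nonparametric case-resampling
   bootstrap (percentile flavour throughout);
3. support = largest fraction of bootstrap slopes sharing a sign
   (∈ [0.5, 1]); a taxon is classified increasing/decreasing only when
   support ≥ 0.9.

Two statistical facts shape expectations here. First, under a true null the
sign support is approximately Uniform(0.5, 1), so ~20 % of null taxa are
classified in some direction and ~10 % in any given direction at the 0.9
threshold; this is a floor of the method, not a tuning artifact. Second,
response models are fitted only to taxa detected in ≥ 25 % of samples
(`prevalent_taxa`); mostly-absent taxa produce slopes that reflect
coverage-filter threshold crossings rather than dynamics.

Body-weight associations use slaughter-age (last-day) samples only. Group
comparisons report percentile bootstrap CIs of group means (default
B = 10 000, level 0.95) with disjoint intervals read as a distinct
difference; single-member groups are rejected. The phylogenetic correlogram
bins patristic tip distances into equal-frequency classes and reports
Moran's I with binary within-class weights, alongside the null expectation
−1/(n−1). All bootstrap and permutation machinery is bit-reproducible under
an explicit seed; batched response fitting shares one set of resampling
draws across taxa for speed (the single-taxon entry point draws its own).

## Expression

Gene counts are normalized TPM-style (per-kb rate, sample sum rescaled to
10⁶). A gene contributes its normalized expression to every GIFT whose
definition lists one of the gene's identifiers; per-genome profiles are
sums over member genes (pooled over samples by default; per-sample output
available). A fullness-style variant — pathway fullness over the
identifiers with any expression — is provided for parity with
capacity-style scoring. Whether profiles should be row-scaled for display
is left to the caller; the pipeline emits both raw and row-scaled tables.

Genome reduction is detected from *raw* counts: a genome is flagged when
its summed transcription across B0101, B0102 and B0103 is exactly zero. No
depth threshold is applied, because the criterion is absence of
transcription, and normalization must not affect it. Genomes absent from
the transcript data are flagged with an explicit `no_data` caveat.
Expression ordination is PCoA of Bray–Curtis dissimilarities on
Hellinger-transformed (square-root of row proportions) profiles; all-zero
rows are excluded with a warning.

## Synthetic study generator

The generator (`giftdistill.synthetic`) emulates a two-trial broiler caecum
study at desk scale. Default conditions: 150 taxa; 40 animals per day at
days 7, 21 and 35 (120 animals, one sample each); 40-element trait
catalogue; 4 × 10⁶ mapped read pairs per sample (a scaled-down stand-in for
production-scale sequencing, chosen so the 30 % breadth filter bites
realistically); mapping rate ~ N(0.67, 0.06); transcript counts
negative-binomial (mean 30, dispersion 0.5) over 6 samples.

Structure planted by construction:

* **Generalist–specialist gradient.** Brownian motion on the logit of a
  gene-retention probability along a pure-birth tree (root retention 0.35,
  σ = 0.55 per unit branch length); genomes keep each catalogue identifier
  with their retention probability, and genome length = 1 Mb + 15 kb per
  retained gene. Capacity is therefore phylogenetically structured and
  genome length tracks MCI. One nucleic-acid-biosynthesis identifier is
  retained universally, since that function is ubiquitous outside
  genome-reduced lineages.
* **Succession.** Per-taxon temporal slopes are drawn with a planted
  correlation of −0.6 with MCI (slope mean 0.28, sd 0.6 on the scaled-day
  axis, i.e. ~68 % of taxa slope upward), and baseline abundances are
  coupled to MCI (+1.5 standardized units), so early communities are
  dominated by high-capacity generalists. This coupling matters:
  relative-abundance data can only recover trends *relative to the
  community drift*, and without early generalist dominance the recovered
  increase fraction bears no resemblance to the planted one. The generator
  exposes both the absolute planted slopes and the drift-corrected
  relative trends (`true_relative_slopes`); recovery tests compare against
  the latter.
* **Body-weight associations.** Planted positive and negative taxa (10/822
  and 190/822 of the catalogue, scaled to n_taxa: 2 and 35 by default) act
  on slaughter-age weight through standardized CLR (centered log-ratio)
  abundance, with effect scales of 2× and 0.5× the 120 g weight noise.
  CLR, rather than raw relative abundance, because the shared compositional
  denominator otherwise injects the planted effects into every taxon's
  apparent association; for the same reason planted taxa are drawn from the
  50th–90th abundance percentile, not from the community dominants.
* **Genome-reduced lineages.** The ten most gene-poor taxa form two planted
  groups: one expresses SCFA production, thiamine, lysine, indole-3-acetate
  and arginine-degradation pathways; the other only the SCFA/thiamine core.
  Both are transcriptionally silent on B0101–B0103; background taxa express
  all their annotated genes.

Everything is deterministic under (config, seed); stage seeds derive from
the scenario seed.

What the generator does **not** emulate: sequence content and read-level
error, pen-level dependence (pens are labels, not random effects), varying
per-sample depth, taxon–taxon interaction dynamics, diet phases, and any
real taxonomic identity. Passing recovery tests therefore demonstrates that
the pipeline's estimators recover the generator's statistical structure at
realistic noise levels — not that they would recover effects in any
particular real dataset.

## Numerical and procedural choices

* Problem sizes in the test suite: recovery experiments run the default
  scenario over seeds 1–20; bootstrap calibration uses 1000 replicates of
  n = 30 with B = 2000; the score-bounds fuzz uses 10 000 random annotation
  sets. These sizes give Monte-Carlo error comfortably below the asserted
  margins.
* Bootstrap linear algebra uses batched normal equations with a
  pseudo-inverse, so resamples that drop a covariate level remain defined.
* Proportion vectors must sum to 1 within 1e-6; Hill computations skip
  exact zeros rather than adding pseudocounts.
* Equal-frequency correlogram classes use quantile edges; tied patristic
  distances can yield empty classes, reported as NaN rather than an error.
* TSV is the canonical dialect (UTF-8, header, "." decimal); trait-database
  serialization is canonical (sorted codes/steps, sorted identifiers within
  clauses) so that parse→serialize round-trips byte-identically.

## Known limitations

* The bootstrap-support classifier is a stand-in, not a reimplementation,
  of hierarchical joint species-distribution modelling; its null
  classification rate (~20 % at threshold 0.9) is higher than a shrinkage
  estimator would give, and its false-positive rate for a single direction
  has a ~10 % floor under true nulls.
* MCI averages all catalogue elements equally; whether a study would prefer
  domain-restricted averages is a catalogue decision, not a package one.
* The clause grammar cannot express nested alternatives of multi-step
  routes; such pathways must be flattened into per-step alternatives.
* Phylogenetic diversity assumes non-negative branch lengths and a rooted
  tree; unrooted inputs are rejected rather than auto-rooted.
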
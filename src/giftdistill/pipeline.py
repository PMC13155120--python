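"""Full pipeline runner: distill -> abundance -> diversity -> dynamics -> expression.

Each stage reads validated inputs, writes its TSV outputs under the
configured output directory and aborts with the stage name on error.  Runs
are idempotent for fixed inputs and seed.
"""

from __future__ import annotations

import json
from contextlib import contextmanager
from pathlib import Path

import pandas as pd

from . import community, distill, dynamics, expression, io, trait_db
from .errors import GiftDistillError, StageError


@contextmanager
def _stage(name: str):
    try:
        yield
    except GiftDistillError as exc:
        raise StageError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(config: io.PipelineConfig) -> dict[str, object]:
    """Execute every configured stage; returns the in-memory results."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, object] = {}

    with _stage("distill"):
        db = trait_db.parse_trait_db(config.trait_db, config.categories)
        findings = trait_db.validate_trait_db(db)
        if findings:
            raise GiftDistillError(f"trait DB invalid: {findings[:3]}")
        annotations = distill.read_annotations(config.annotations)
        gifts = distill.distill_catalogue(annotations, db)
        mci_df = distill.mci_table(gifts, config.mci_low, config.mci_high)
        categories = distill.aggregate_categories(gifts, db)
        io.write_table(gifts, out / "gift_matrix.tsv")
        io.write_table(mci_df, out / "mci.tsv")
        io.write_table(categories, out / "gift_categories_matrix.tsv")
        results.update(db=db, gifts=gifts, mci=mci_df, categories=categories)

    with _stage("abundance"):
        table = io.read_abundance_inputs(
            config.counts, config.breadth, config.genome_metadata, config.sample_totals
        )
        filtered = community.filter_by_coverage(table, config.coverage_threshold)
        pm = community.percent_mapped(filtered)
        rpmm_df = community.rpmm(filtered)
        rel = community.relative_abundance(filtered)
        io.write_table(pm.rename("percent_mapped").to_frame(), out / "percent_mapped.tsv")
        io.write_table(rpmm_df, out / "rpmm.tsv")
        io.write_table(rel.values, out / "relative_abundance.tsv")
        results.update(abundance=filtered, percent_mapped=pm, rpmm=rpmm_df, rel=rel)

    with _stage("diversity"):
        tree = io.read_tree(Path(config.tree))
        div = community.diversity_table(rel, tree=tree, traits=gifts)
        profiles = community.community_weighted_gifts(rel, gifts)
        coords, eigvals = community.pcoa(community.trait_distance(gifts), k=4)
        io.write_table(div, out / "diversity.tsv")
        io.write_table(profiles.cw_gifts, out / "community_gifts.tsv")
        io.write_table(profiles.community_mci.to_frame(), out / "community_mci.tsv")
        io.write_table(coords, out / "genome_pcoa.tsv")
        results.update(diversity=div, profiles=profiles, genome_pcoa=(coords, eigvals))

    with _stage("dynamics"):
        meta = io.read_table(config.sample_metadata, io.SAMPLE_METADATA_SCHEMA).set_index("sample")
        meta = meta.loc[rpmm_df.columns]
        covars = meta[["trial", "sex", "line", "treatment"]]
        modelled = dynamics.prevalent_taxa(rpmm_df, config.min_prevalence)
        resp_time = dynamics.taxon_responses(
            rpmm_df.loc[modelled],
            meta["day"],
            covars,
            n_boot=config.n_boot_response,
            seed=config.seed,
            threshold=config.support_threshold,
        )
        fractions = dynamics.classify_community(resp_time)
        r, p = dynamics.mci_response_correlation(
            results["mci"]["mci"].loc[resp_time.index],
            resp_time["slope"],
            n_perm=config.n_perm,
            seed=config.seed,
        )
        correlogram = dynamics.phylo_correlogram(
            resp_time["slope"], tree, n_classes=config.n_distance_classes
        )
        last_day = int(meta["day"].max())
        d35 = meta.index[meta["day"] == last_day]
        modelled35 = dynamics.prevalent_taxa(rpmm_df[d35], config.min_prevalence)
        resp_weight = dynamics.taxon_responses(
            rpmm_df.loc[modelled35, d35],
            meta.loc[d35, "body_weight_g"],
            covars.loc[d35],
            n_boot=config.n_boot_response,
            seed=config.seed + 1,
            threshold=config.support_threshold,
        )
        assoc_group = resp_weight["direction"].map(
            {"increase": "positive", "decrease": "negative", "none": "none"}
        )
        big_enough = assoc_group.map(assoc_group.value_counts()) >= 2
        compare = None
        if assoc_group[big_enough].nunique() >= 2:
            compare = dynamics.group_compare_bootstrap(
                results["mci"]["mci"].loc[assoc_group.index[big_enough]],
                assoc_group[big_enough],
                n_boot=config.n_boot_group,
                level=config.ci_level,
                seed=config.seed + 2,
            )
        io.write_table(resp_time, out / "responses_time.tsv")
        io.write_table(resp_weight, out / "responses_weight.tsv")
        io.write_table(correlogram, out / "correlogram.tsv")
        if compare is not None:
            io.write_table(compare.table, out / "group_compare_mci.tsv")
        (out / "dynamics_summary.json").write_text(
            json.dumps(
                {
                    "fractions": fractions,
                    "mci_slope_correlation": r,
                    "mci_slope_permutation_p": p,
                },
                indent=2,
            )
            + "\n"
        )
        results.update(
            responses_time=resp_time,
            responses_weight=resp_weight,
            fractions=fractions,
            mci_slope=(r, p),
            correlogram=correlogram,
            group_compare=compare,
        )

    if config.transcripts:
        with _stage("expression"):
            t = expression.read_transcripts(config.transcripts)
            expr, unassigned = expression.expression_by_gift(t, db, pooling="pooled")
            raw = expression.gift_raw_counts(t, db)
            reduced = expression.detect_genome_reduced(
                raw, genomes=list(gifts.index)
            )
            row_scaled = expr.div(expr.sum(axis=1).replace(0, pd.NA), axis=0).fillna(0.0)
            coords, eigvals = expression.expression_ordination(expr)
            io.write_table(expr, out / "expression_gifts.tsv")
            io.write_table(row_scaled, out / "expression_gifts_rowscaled.tsv")
            io.write_table(reduced, out / "genome_reduced.tsv")
            io.write_table(coords, out / "expression_pcoa.tsv")
            results.update(
                expression=expr, genome_reduced=reduced, expression_pcoa=(coords, eigvals),
                unassigned_genes=unassigned,
            )

    io.write_manifest(out, config.to_dict(), extra={"stages": sorted(results.keys())})
    return results
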
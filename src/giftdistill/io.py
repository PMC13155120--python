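"""Table and tree readers/writers, pipeline configuration and run manifests.

The canonical on-disk dialect is UTF-8 TSV with a header row, "." decimal
and unquoted numerics, matching the output conventions of the annotation and
read-mapping tools whose tables this pipeline consumes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .community import AbundanceTable
from .errors import InputError, SchemaError

logger = logging.getLogger("giftdistill")

__all__ = [
    "TableSchema",
    "read_table",
    "read_matrix",
    "write_table",
    "read_tree",
    "read_abundance_inputs",
    "write_scenario",
    "PipelineConfig",
    "config_hash",
    "write_manifest",
    "SAMPLE_METADATA_SCHEMA",
    "GENOME_METADATA_SCHEMA",
    "SAMPLE_TOTALS_SCHEMA",
]


@dataclass(frozen=True)
class TableSchema:
    """Declarative column contract for a TSV table."""

    name: str
    columns: dict[str, str]  # column -> dtype kind: "str" | "int" | "float"
    key: tuple[str, ...] = ()
    non_negative: tuple[str, ...] = ()


SAMPLE_METADATA_SCHEMA = TableSchema(
    "sample_metadata",
    {
        "sample": "str",
        "animal": "str",
        "trial": "str",
        "pen": "int",
        "day": "int",
        "sex": "str",
        "line": "str",
        "treatment": "str",
        "body_weight_g": "float",
    },
    key=("sample",),
    non_negative=("day",),
)
GENOME_METADATA_SCHEMA = TableSchema(
    "genome_metadata",
    {"genome": "str", "length_bp": "int", "taxonomy": "str"},
    key=("genome",),
    non_negative=("length_bp",),
)
SAMPLE_TOTALS_SCHEMA = TableSchema(
    "sample_totals",
    {"sample": "str", "total_read_pairs": "int", "mapped_read_pairs": "int"},
    key=("sample",),
    non_negative=("total_read_pairs", "mapped_read_pairs"),
)

_CASTERS = {"str": str, "int": "int64", "float": "float64"}


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a TSV against its schema (typed columns, unique key)."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{schema.name}: file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    missing = set(schema.columns) - set(df.columns)
    if missing:
        raise SchemaError(f"{schema.name} ({path.name}): missing columns {sorted(missing)}")
    for col, kind in schema.columns.items():
        if kind == "str":
            df[col] = df[col].astype(str)
            continue
        try:
            df[col] = df[col].astype(_CASTERS[kind])
        except (ValueError, TypeError):
            raise SchemaError(
                f"{schema.name} ({path.name}): column {col!r} is not {kind}"
            ) from None
    for col in schema.non_negative:
        if (df[col].dropna() < 0).any():
            raise SchemaError(f"{schema.name} ({path.name}): negative values in {col!r}")
    if schema.key:
        dup = df.duplicated(list(schema.key))
        if dup.any():
            raise SchemaError(
                f"{schema.name} ({path.name}): duplicate key "
                f"{df.loc[dup, list(schema.key)].iloc[0].tolist()}"
            )
    digest = hashlib.sha256(path.read_bytes()).hexdigest()[:12]
    logger.info("read %s: %d rows from %s (sha256 %s)", schema.name, len(df), path, digest)
    return df


def read_matrix(path: str | Path, index_name: str = "genome") -> pd.DataFrame:
    """Read a labelled numeric matrix (first column holds row labels)."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"matrix file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != index_name:
        raise SchemaError(f"{path}: first column must be {index_name!r}, got {df.index.name!r}")
    try:
        values = df.astype(float)
    except ValueError:
        raise SchemaError(f"{path}: non-numeric cell in matrix") from None
    if (np.asarray(values) < 0).any():
        raise SchemaError(f"{path}: negative values in count/abundance matrix")
    values.columns.name = "sample"
    return values


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def read_tree(source: str | Path) -> TreeNode:
    """Read a rooted newick tree with branch lengths; validate tips and lengths."""
    if isinstance(source, Path) or (isinstance(source, str) and not source.strip().startswith("(")):
        tree = TreeNode.read(str(source))
    else:
        tree = TreeNode.read([source])
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        dup = sorted({t for t in tips if tips.count(t) > 1})
        raise InputError(f"duplicate tip labels in tree: {dup}")
    if len(tree.children) != 2:
        raise InputError(
            f"tree root has {len(tree.children)} children; root the tree (bifurcating root required)"
        )
    for node in tree.preorder(include_self=False):
        if node.length is None:
            raise InputError(f"missing branch length above {node.name or 'internal node'!r}")
        if node.length < 0:
            raise InputError(f"negative branch length above {node.name or 'internal node'!r}")
    return tree


def read_abundance_inputs(
    counts_path: str | Path,
    breadth_path: str | Path,
    genome_metadata_path: str | Path,
    totals_path: str | Path,
) -> AbundanceTable:
    """Assemble an AbundanceTable from its four on-disk pieces."""
    counts = read_matrix(counts_path).astype(int)
    breadth = read_matrix(breadth_path)
    gmeta = read_table(genome_metadata_path, GENOME_METADATA_SCHEMA).set_index("genome")
    totals = read_table(totals_path, SAMPLE_TOTALS_SCHEMA).set_index("sample")
    breadth = breadth.loc[counts.index, counts.columns]
    return AbundanceTable(
        counts,
        breadth,
        gmeta["length_bp"].astype(float).loc[counts.index],
        totals["total_read_pairs"].loc[counts.columns],
        totals["mapped_read_pairs"].loc[counts.columns],
    )


def write_scenario(scenario, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic scenario as the full pipeline input bundle."""
    from .trait_db import serialize_trait_db  # local import to avoid cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def p(name: str) -> Path:
        paths[name] = outdir / name
        return paths[name]

    p("gift_definitions.tsv").write_text(serialize_trait_db(scenario.genomes.db))
    cat = pd.DataFrame(
        sorted(scenario.genomes.db.category_map.items()), columns=["code", "category"]
    )
    write_table(cat, p("gift_categories.tsv"), index=False)

    ann_rows = [
        {"genome": a.genome_id, "gene": f"{a.genome_id}_g{k + 1:03d}", "identifier": ident}
        for a in scenario.genomes.annotations
        for k, ident in enumerate(sorted(a.present_ids))
    ]
    write_table(pd.DataFrame(ann_rows), p("annotations.tsv"), index=False)

    gmeta = pd.DataFrame(
        {
            "genome": scenario.genomes.genome_length_bp.index,
            "length_bp": scenario.genomes.genome_length_bp.astype(int).values,
            "taxonomy": [
                f"d__Bacteria;g__{g}" for g in scenario.genomes.genome_length_bp.index
            ],
        }
    )
    write_table(gmeta, p("genome_metadata.tsv"), index=False)

    table = scenario.counts.table
    write_table(table.counts, p("counts.tsv"))
    write_table(table.breadth, p("breadth.tsv"))
    totals = pd.DataFrame(
        {
            "sample": table.sample_ids,
            "total_read_pairs": table.total_read_pairs.values,
            "mapped_read_pairs": table.mapped_read_pairs.values,
        }
    )
    write_table(totals, p("sample_totals.tsv"), index=False)
    write_table(scenario.metadata.reset_index(), p("sample_metadata.tsv"), index=False)
    p("tree.nwk").write_text(scenario.tree_newick + "\n")

    t = scenario.transcripts
    tdf = pd.DataFrame(
        {
            "gene": t.genes.index,
            "genome": t.genes["genome"].values,
            "identifier": [";".join(ids) for ids in t.genes["identifiers"]],
            "length_bp": t.genes["length_bp"].astype(int).values,
        }
    )
    tdf = pd.concat([tdf.set_index("gene"), t.counts], axis=1).reset_index()
    write_table(tdf, p("transcripts.tsv"), index=False)

    manifest = {
        "seed": scenario.config.seed,
        "config": dataclasses.asdict(scenario.config),
        "config_hash": config_hash(dataclasses.asdict(scenario.config)),
        "planted": {
            "positive_taxa": list(scenario.positive_taxa),
            "negative_taxa": list(scenario.negative_taxa),
            "reduced_pos": list(scenario.genomes.reduced_pos),
            "reduced_neg": list(scenario.genomes.reduced_neg),
        },
    }
    p("scenario_manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return paths


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for a full pipeline run."""

    trait_db: str
    annotations: str
    counts: str
    breadth: str
    genome_metadata: str
    sample_totals: str
    sample_metadata: str
    tree: str
    output_dir: str
    categories: str | None = None
    transcripts: str | None = None
    coverage_threshold: float = 0.30
    support_threshold: float = 0.9
    mci_low: float = 0.15
    mci_high: float = 0.30
    ci_level: float = 0.95
    n_boot_response: int = 500
    n_boot_group: int = 10000
    n_perm: int = 999
    n_distance_classes: int = 10
    min_prevalence: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.coverage_threshold <= 1:
            raise InputError("coverage_threshold must lie in (0, 1]")
        if not 0.5 <= self.support_threshold <= 1:
            raise InputError("support_threshold must lie in [0.5, 1]")
        if not 0 <= self.mci_low <= self.mci_high <= 1:
            raise InputError("MCI class bounds must satisfy 0 <= low <= high <= 1")
        if not 0 < self.ci_level < 1:
            raise InputError("ci_level must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def config_hash(config: dict) -> str:
    """Stable hash of a configuration mapping (changes iff any value changes)."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(outdir: str | Path, config: dict, extra: dict | None = None) -> Path:
    from . import __version__

    manifest = {
        "package": "giftdistill",
        "version": __version__,
        "seed": config.get("seed"),
        "config": config,
        "config_hash": config_hash(config),
    }
    if extra:
        manifest.update(extra)
    path = Path(outdir) / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return path
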
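"""End-to-end pipeline: trees -> matrix -> direct pairs -> indirect pairs.

Outputs are a deterministic function of (inputs, config, seed): files carry
no timestamps, every table is sorted, and the YAML config snapshot written
to the output directory uses sorted keys, so two runs with the same config
produce byte-identical output directories.  The run log records per-stage
counts and skip reasons (timestamps go to stderr only).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import yaml

from . import direct as direct_mod
from . import indirect as indirect_mod
from .io import (
    load_catalog,
    load_complexes,
    load_model,
    load_proteome,
    write_gene_tree,
    write_pairs,
)
from .matrix import build_matrix
from .search import (
    DEFAULT_ROUNDS,
    FilterCriteria,
    GeneTree,
    RoundConfig,
    iterate_search,
)
from .stats import reciprocal_fraction

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs and tunables of one pipeline run."""

    proteome_fasta: str
    annotations: str
    complexes: Optional[str] = None
    model: Optional[str] = None
    catalog: Optional[str] = None
    root_organism: str = "eco"
    rounds: Sequence[RoundConfig] = DEFAULT_ROUNDS
    growth_epsilon: float = 1e-6
    minimal_medium: str = "M9"
    rich_medium: str = "rich"
    with_topology: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rounds"] = [
            {
                "criteria": dataclasses.asdict(r.criteria),
                "cluster_identity": r.cluster_identity,
                "trim_occupancy": r.trim_occupancy,
            }
            for r in self.rounds
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "rounds" in d:
            d["rounds"] = tuple(
                RoundConfig(
                    criteria=FilterCriteria(**r["criteria"]),
                    cluster_identity=r.get("cluster_identity", 0.90),
                    trim_occupancy=r.get("trim_occupancy", 0.50),
                )
                for r in d["rounds"]
            )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PipelineResult:
    trees: List[GeneTree]
    matrix: object
    direct_pairs: list
    indirect_pairs: list
    rescue_results: list
    outdir: Path


class _RunLog:
    """Line-oriented stage log; deterministic file, timestamped stderr."""

    def __init__(self, path: Path):
        self.path = path
        self.lines: List[str] = []

    def info(self, stage: str, message: str) -> None:
        line = f"{stage}\tINFO\t{message}"
        self.lines.append(line)
        logger.info("%s: %s", stage, message)

    def flush(self) -> None:
        self.path.write_text("".join(line + "\n" for line in self.lines))


def build_trees(
    proteome,
    roots: Sequence[str],
    rounds: Sequence[RoundConfig] = DEFAULT_ROUNDS,
    with_topology: bool = False,
) -> List[GeneTree]:
    trees = []
    for root_id in sorted(roots):
        trees.append(
            iterate_search(
                proteome.records[root_id],
                proteome,
                rounds=rounds,
                with_topology=with_topology,
            )
        )
    return trees


def run_pipeline(config: PipelineConfig, outdir) -> PipelineResult:
    """Execute search -> matrix -> direct -> indirect -> stats.

    Any stage error aborts with the stage name; partial outputs written so
    far remain on disk and a ``FAILED_<stage>`` marker file is left.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(outdir / "run.log")
    stage = "setup"
    try:
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

        stage = "load"
        catalog = load_catalog(config.catalog) if config.catalog else {}
        proteome = load_proteome(
            config.proteome_fasta, config.annotations, catalog=catalog or None
        )
        complexes = (
            load_complexes(config.complexes) if config.complexes else []
        )
        model = load_model(config.model) if config.model else None
        log.info(stage, f"{len(proteome)} protein records loaded")
        log.info(stage, f"{len(complexes)} enzyme complexes loaded")
        log.info(stage, f"{len(catalog)} catalog functions loaded")

        stage = "search"
        roots = [
            g
            for g in proteome.metabolic_genes(config.root_organism)
            if g in proteome.records
        ]
        trees = build_trees(
            proteome, roots, config.rounds, config.with_topology
        )
        tree_dir = outdir / "trees"
        tree_dir.mkdir(exist_ok=True)
        for tree in trees:
            write_gene_tree(
                tree,
                tree_dir / f"{tree.root_gene_id}.json",
                newick_path=(
                    tree_dir / f"{tree.root_gene_id}.nwk"
                    if tree.newick
                    else None
                ),
            )
        n_nontrivial = sum(1 for t in trees if len(t.member_gene_ids) > 1)
        log.info(
            stage,
            f"{len(trees)} trees built; {n_nontrivial} recruited homologs",
        )

        stage = "matrix"
        matrix = build_matrix(trees, proteome.annotations, complexes)
        matrix.write(outdir / "matrix.tsv")
        log.info(stage, f"{len(matrix.entries)} promiscuous entries")

        stage = "direct"
        pairs = direct_mod.predict_direct_pairs(
            matrix, roots, proteome.annotations
        )
        write_pairs(pairs, outdir / "direct_pairs.tsv")
        counts, hist = direct_mod.replacers_per_target(pairs)
        hist.to_csv(outdir / "replacers_per_target.tsv", sep="\t", index=False)
        reciprocal = direct_mod.find_reciprocal(pairs)
        log.info(
            stage,
            f"{len(pairs)} direct pairs for {len(counts)} targets; "
            f"{len(reciprocal)} reciprocal",
        )

        stage = "indirect"
        indirect_pairs: list = []
        rescue_results: list = []
        if model is not None and catalog:
            model_genes = model.genes
            targets = [g for g in roots if g in model_genes]
            indirect_pairs, rescue_results = indirect_mod.predict_indirect_pairs(
                model,
                matrix,
                catalog,
                targets,
                medium=config.minimal_medium,
                rich_medium=config.rich_medium,
                growth_epsilon=config.growth_epsilon,
                scope=roots,
            )
            indirect_mod.rescue_table(rescue_results).to_csv(
                outdir / "rescue_results.tsv",
                sep="\t",
                index=False,
                float_format="%.6g",
            )
            log.info(
                stage,
                f"{len(indirect_pairs)} indirect pairs from "
                f"{len(rescue_results)} rescue tests over "
                f"{len(targets)} candidate targets",
            )
        else:
            log.info(stage, "skipped: no model or empty catalog")
        write_pairs(indirect_pairs, outdir / "indirect_pairs.tsv")

        stage = "stats"
        stats = {
            "n_trees": len(trees),
            "n_matrix_entries": len(matrix.entries),
            "n_direct_pairs": len(pairs),
            "n_reciprocal_pairs": len(reciprocal),
            "reciprocal_fraction": reciprocal_fraction(pairs),
            "n_indirect_pairs": len(indirect_pairs),
        }
        with open(outdir / "stats.json", "w") as fh:
            json.dump(stats, fh, indent=1, sort_keys=True)
            fh.write("\n")
        log.info(stage, f"summary: {stats}")
        log.flush()
    except Exception as exc:
        log.info(stage, f"FAILED: {exc}")
        log.flush()
        (outdir / f"FAILED_{stage}").write_text(f"{exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResult(
        trees=trees,
        matrix=matrix,
        direct_pairs=pairs,
        indirect_pairs=indirect_pairs,
        rescue_results=rescue_results,
        outdir=outdir,
    )
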
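"""Readers and writers for on-disk artifacts.

Formats handled here:

* protein FASTA, header ``gene_id|organism_id`` (first ``|``-separated token
  is the gene id; the organism may instead come from the annotation table);
* gene-annotation TSV with columns ``gene_id, organism_id, function_id,
  function_name, reaction_ids`` (reaction ids semicolon-joined, may be empty);
* enzyme-complex TSV with columns ``function_id, subunit_role_id``;
* metabolic-model JSON (see :func:`load_model`);
* reaction-catalog JSON mapping ``function_id`` to reaction definitions;
* prediction-pair TSV (see :data:`PAIR_COLUMNS`);
* gene-tree JSON with an optional Newick sidecar.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .alphabet import VALID_RESIDUES

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with gene and organism identity."""

    gene_id: str
    organism_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for gene {self.gene_id!r}")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.gene_id!r} contains non-amino-acid characters: "
                f"{sorted(bad)}"
            )


@dataclass(frozen=True)
class GeneAnnotation:
    """Functional annotation of one gene.

    ``is_metabolic`` is true iff at least one of the gene's functions maps to
    one or more metabolic reactions (via the annotation table's reaction_ids
    column or a reaction catalog).
    """

    gene_id: str
    organism_id: str
    function_ids: frozenset
    is_metabolic: bool


@dataclass(frozen=True)
class ComplexDefinition:
    """An enzyme complex: a whole-complex function and its subunit roles."""

    function_id: str
    subunit_role_ids: frozenset

    def __post_init__(self) -> None:
        if len(self.subunit_role_ids) < 2:
            raise ValueError(
                f"complex {self.function_id!r} needs >=2 subunit roles"
            )


@dataclass
class ReactionDefinition:
    """A stoichiometric reaction with flux bounds and an optional GPR rule."""

    reaction_id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.reaction_id!r} has empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.reaction_id!r}: lower_bound "
                f"{self.lower_bound} > upper_bound {self.upper_bound}"
            )

    def copy(self) -> "ReactionDefinition":
        return ReactionDefinition(
            self.reaction_id,
            dict(self.stoichiometry),
            self.lower_bound,
            self.upper_bound,
            self.gpr,
        )


@dataclass
class ProteomeSet:
    """All protein records plus annotations, keyed by gene id.

    ``annotations`` may contain genes without a sequence record (annotation
    rows whose gene lacks a FASTA entry are retained for matrix use).
    """

    records: Dict[str, ProteinRecord] = field(default_factory=dict)
    annotations: Dict[str, GeneAnnotation] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def genes_of_organism(self, organism_id: str) -> List[str]:
        return sorted(
            g for g, r in self.records.items() if r.organism_id == organism_id
        )

    def metabolic_genes(self, organism_id: Optional[str] = None) -> List[str]:
        out = []
        for gid, ann in self.annotations.items():
            if not ann.is_metabolic:
                continue
            if organism_id is not None and ann.organism_id != organism_id:
                continue
            out.append(gid)
        return sorted(out)


# ---------------------------------------------------------------------------
# proteome / annotations
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "gene_id",
    "organism_id",
    "function_id",
    "function_name",
    "reaction_ids",
]


def read_annotation_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table {path} missing columns {sorted(missing)}")
    return df


def annotations_from_table(
    df: pd.DataFrame,
    catalog: Optional[Mapping[str, Sequence[ReactionDefinition]]] = None,
) -> Dict[str, GeneAnnotation]:
    """Collapse one-row-per-function annotation rows into per-gene records."""
    out: Dict[str, GeneAnnotation] = {}
    for gene_id, grp in df.groupby("gene_id", sort=True):
        organisms = sorted(set(grp["organism_id"]))
        if len(organisms) > 1:
            raise ValueError(f"gene {gene_id!r} annotated with several organisms")
        functions = frozenset(f for f in grp["function_id"] if f)
        metabolic = False
        for _, row in grp.iterrows():
            if str(row["reaction_ids"]).strip():
                metabolic = True
            if catalog and row["function_id"] in catalog and catalog[row["function_id"]]:
                metabolic = True
        out[gene_id] = GeneAnnotation(
            gene_id=gene_id,
            organism_id=organisms[0],
            function_ids=functions,
            is_metabolic=metabolic,
        )
    return out


def load_proteome(
    fasta_path,
    annotation_path,
    catalog: Optional[Mapping[str, Sequence[ReactionDefinition]]] = None,
) -> ProteomeSet:
    """Load a FASTA proteome together with its annotation table.

    FASTA headers are ``gene_id|organism_id`` or a plain gene id resolvable
    via the annotation table.  Genes present in the FASTA but absent from the
    table get an empty function set and ``is_metabolic=False``; annotation
    rows without a FASTA record are kept (with a warning) for matrix use.
    """
    ann_df = read_annotation_table(annotation_path)
    annotations = annotations_from_table(ann_df, catalog=catalog)

    records: Dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        tokens = rec.id.split("|")
        gene_id = tokens[0]
        if gene_id in records:
            raise ValueError(f"duplicate gene_id {gene_id!r} in {fasta_path}")
        if len(tokens) > 1:
            organism_id = tokens[1]
        elif gene_id in annotations:
            organism_id = annotations[gene_id].organism_id
        else:
            organism_id = "unknown"
        records[gene_id] = ProteinRecord(
            gene_id=gene_id,
            organism_id=organism_id,
            sequence=str(rec.seq).upper(),
        )
        if gene_id not in annotations:
            annotations[gene_id] = GeneAnnotation(
                gene_id=gene_id,
                organism_id=organism_id,
                function_ids=frozenset(),
                is_metabolic=False,
            )

    orphans = sorted(set(annotations) - set(records))
    if orphans:
        logger.warning(
            "%d annotation rows have no FASTA record (kept for matrix use): %s",
            len(orphans),
            ", ".join(orphans[:5]) + ("..." if len(orphans) > 5 else ""),
        )
    return ProteomeSet(records=records, annotations=annotations)


def write_proteome(proteome: ProteomeSet, fasta_path) -> None:
    with open(fasta_path, "w") as fh:
        for gid in sorted(proteome.records):
            rec = proteome.records[gid]
            fh.write(f">{rec.gene_id}|{rec.organism_id}\n{rec.sequence}\n")


def load_complexes(path) -> List[ComplexDefinition]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"function_id", "subunit_role_id"} - set(df.columns)
    if missing:
        raise ValueError(f"complex table {path} missing columns {sorted(missing)}")
    out = []
    for fn, grp in df.groupby("function_id", sort=True):
        out.append(
            ComplexDefinition(
                function_id=fn,
                subunit_role_ids=frozenset(grp["subunit_role_id"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# metabolic model & reaction catalog JSON
# ---------------------------------------------------------------------------

def _reaction_from_dict(d: Mapping) -> ReactionDefinition:
    return ReactionDefinition(
        reaction_id=d["id"],
        stoichiometry={m: float(c) for m, c in d["stoichiometry"].items()},
        lower_bound=float(d.get("lower_bound", 0.0)),
        upper_bound=float(d.get("upper_bound", 1000.0)),
        gpr=d.get("gpr", "") or "",
    )


def _reaction_to_dict(r: ReactionDefinition) -> dict:
    return {
        "id": r.reaction_id,
        "stoichiometry": dict(sorted(r.stoichiometry.items())),
        "lower_bound": r.lower_bound,
        "upper_bound": r.upper_bound,
        "gpr": r.gpr,
    }


def load_model(path):
    """Load a metabolic model from the package's JSON dialect.

    Schema::

        {"metabolites": [{"id": ...}, ...],
         "reactions": [{"id", "stoichiometry": {met: coef}, "lower_bound",
                        "upper_bound", "gpr"}, ...],
         "biomass_reaction": "id",
         "media": {"M9": {exchange_id: uptake_bound, ...}, "rich": {...}}}
    """
    from .fba import MetabolicModel  # late import to avoid a cycle

    with open(path) as fh:
        data = json.load(fh)
    if "biomass_reaction" not in data or not data["biomass_reaction"]:
        raise ValueError(f"model {path} lacks a biomass_reaction id")
    if "media" not in data or not data["media"]:
        raise ValueError(
            f"model {path} lacks a 'media' block; at least one named medium "
            "(e.g. 'M9', 'rich') mapping exchange ids to uptake bounds is required"
        )
    reactions = [_reaction_from_dict(d) for d in data.get("reactions", [])]
    metabolites = [m["id"] for m in data.get("metabolites", [])]
    model = MetabolicModel(
        reactions=reactions,
        metabolites=metabolites,
        biomass_reaction=data["biomass_reaction"],
        media={
            name: {k: float(v) for k, v in med.items()}
            for name, med in data["media"].items()
        },
    )
    model.validate()
    return model


def write_model(model, path) -> None:
    data = {
        "metabolites": [{"id": m} for m in model.metabolites],
        "reactions": [_reaction_to_dict(r) for r in model.reactions],
        "biomass_reaction": model.biomass_reaction,
        "media": {n: dict(sorted(m.items())) for n, m in sorted(model.media.items())},
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_catalog(path) -> Dict[str, List[ReactionDefinition]]:
    """Load a reaction catalog: ``{function_id: [reaction, ...], ...}``."""
    with open(path) as fh:
        data = json.load(fh)
    return {
        fn: [_reaction_from_dict(d) for d in rxns] for fn, rxns in data.items()
    }


def write_catalog(catalog: Mapping[str, Sequence[ReactionDefinition]], path) -> None:
    data = {
        fn: [_reaction_to_dict(r) for r in rxns]
        for fn, rxns in sorted(catalog.items())
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# prediction pairs
# ---------------------------------------------------------------------------

PAIR_COLUMNS = [
    "target_gene",
    "replacer_gene",
    "mode",
    "promiscuous_function",
    "evidence_gene",
    "evidence_organism",
    "identity",
    "positives",
    "coverage",
    "rescued_growth",
]


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return repr(x)  # full precision so written pairs round-trip exactly
    return str(x)


def write_pairs(pairs: Iterable, path) -> None:
    """Write replacer pairs as a TSV, sorted by (target, replacer, function)."""
    rows = sorted(
        pairs,
        key=lambda p: (p.target_gene, p.replacer_gene, p.promiscuous_function),
    )
    with open(path, "w") as fh:
        fh.write("\t".join(PAIR_COLUMNS) + "\n")
        for p in rows:
            fh.write(
                "\t".join(
                    _fmt(v)
                    for v in (
                        p.target_gene,
                        p.replacer_gene,
                        p.mode,
                        p.promiscuous_function,
                        p.evidence_gene,
                        p.evidence_organism,
                        p.identity,
                        p.positives,
                        p.coverage,
                        p.rescued_growth,
                    )
                )
                + "\n"
            )


def read_pairs(path) -> list:
    from .direct import ReplacerPair  # late import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        out.append(
            ReplacerPair(
                target_gene=row["target_gene"],
                replacer_gene=row["replacer_gene"],
                mode=row["mode"],
                promiscuous_function=row["promiscuous_function"],
                evidence_gene=row["evidence_gene"],
                evidence_organism=row["evidence_organism"],
                identity=float(row["identity"]) if row["identity"] else None,
                positives=float(row["positives"]) if row["positives"] else None,
                coverage=float(row["coverage"]) if row["coverage"] else None,
                rescued_growth=(
                    float(row["rescued_growth"]) if row["rescued_growth"] else None
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# gene trees
# ---------------------------------------------------------------------------

def write_gene_tree(tree, path, newick_path=None) -> None:
    data = {
        "root": tree.root_gene_id,
        "members": [
            {
                "gene_id": m,
                "organism_id": tree.organisms.get(m, ""),
                "identity": tree.hits[m].identity if m in tree.hits else None,
                "positives": tree.hits[m].positives if m in tree.hits else None,
                "coverage": tree.hits[m].query_coverage if m in tree.hits else None,
            }
            for m in sorted(tree.member_gene_ids)
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)
        fh.write("\n")
    if newick_path is not None and tree.newick:
        Path(newick_path).write_text(tree.newick + "\n")
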
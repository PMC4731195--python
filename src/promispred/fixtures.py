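"""Deterministic synthetic fixtures for the whole pipeline.

Two generators emulate the real inputs at desk scale:

* :func:`generate_proteome` -- a multi-organism annotated proteome of
  i.i.d.-random background proteins (mutual identity ~5% at length >= 150,
  far below the 0.15 identity gate) with *planted* homolog links: foreign
  genes derived from a source gene by controlled mutation to a target
  percent identity, carrying a foreign function.  A ground-truth table
  records which (root, function) matrix entries and which direct
  target-replacer pairs the pipeline should recover.

* :func:`generate_toy_gem` -- a toy metabolic model with a conditionally
  essential linear vitamin-synthesis pathway (the vitamin is required in
  small amounts by biomass, absent from minimal medium, supplied by rich
  medium) plus a reaction catalog containing exactly one planted bypass
  reaction that rescues growth after knocking out the first pathway gene,
  and decoy reactions that do not.

All generators are pure functions of their spec (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alphabet import AA_ORDER, BLOSUM62_CONDITIONAL
from .fba import MetabolicModel
from .io import (
    ProteinRecord,
    ProteomeSet,
    ReactionDefinition,
    annotations_from_table,
    write_catalog,
    write_model,
    write_proteome,
)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedLink:
    """A foreign homolog planted at a controlled percent identity.

    ``foreign_gene`` receives a mutated copy of ``source_gene``'s sequence
    and is annotated with ``function_id`` only; if ``target_gene`` is set,
    that gene's primary annotation becomes ``function_id`` so the planted
    link should surface as a direct (target, source) replacer pair.
    """

    source_gene: str
    foreign_gene: str
    identity: float
    function_id: str
    target_gene: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.identity <= 1.0:
            raise ValueError("planted identity must be in (0,1]")


@dataclass(frozen=True)
class GemSpec:
    """Layout of the toy metabolic model and its reaction catalog."""

    target_gene: str = "eco_g06"          # first pathway step; the KO target
    chain_genes: Tuple[str, ...] = ("eco_g09", "eco_g10")  # downstream steps
    glc_transport_gene: str = "eco_g07"
    vit_transport_gene: str = "eco_g08"
    replacer_gene: str = "eco_g05"        # gene carrying the bypass function
    bypass_function: str = "fn_bypass"
    vit_coefficient: float = 0.01         # vitamin demand per biomass unit
    glc_uptake: float = 10.0


@dataclass(frozen=True)
class FixtureSpec:
    """Everything needed to generate one synthetic study."""

    seed: int = 0
    organisms: Tuple[str, ...] = ("eco", "orgB", "orgC")
    n_genes_per_organism: int = 50
    gene_length: int = 150
    planted_links: Tuple[PlantedLink, ...] = ()
    complexes: Tuple[Tuple[str, Tuple[str, ...]], ...] = ()
    gem: Optional[GemSpec] = None

    @property
    def root_organism(self) -> str:
        return self.organisms[0]


#: the four graded planted links: identities 0.45 / 0.35 / 0.25 / 0.20
_GRADED_LINKS = (
    PlantedLink("eco_g01", "orgB_g01", 0.45, "fn_p1", "eco_g11"),
    PlantedLink("eco_g02", "orgB_g02", 0.35, "fn_p2", "eco_g12"),
    PlantedLink("eco_g03", "orgC_g01", 0.25, "fn_p3", "eco_g13"),
    PlantedLink("eco_g04", "orgC_g02", 0.20, "fn_p4", "eco_g14"),
)

#: foreign functions feeding the toy-model rescue screen: one true bypass
#: plus decoys exercising every rejection path
_GEM_LINKS = (
    PlantedLink("eco_g05", "orgB_g03", 0.40, "fn_bypass"),
    PlantedLink("eco_g15", "orgB_g04", 0.45, "fn_decoy_dup"),
    PlantedLink("eco_g16", "orgC_g03", 0.45, "fn_decoy_rev"),
    PlantedLink("eco_g17", "orgC_g04", 0.45, "fn_decoy_up"),
    PlantedLink("eco_g18", "orgB_g05", 0.45, "fn_decoy_new"),
)


def default_spec(seed: int = 0) -> FixtureSpec:
    """3 organisms x 50 genes with the four graded planted links."""
    return FixtureSpec(seed=seed, planted_links=_GRADED_LINKS)


def bundle_spec(seed: int = 0) -> FixtureSpec:
    """Default proteome plus the toy-model bypass and decoy links."""
    return FixtureSpec(
        seed=seed,
        planted_links=_GRADED_LINKS + _GEM_LINKS,
        gem=GemSpec(),
    )


def stepping_stone_spec(seed: int = 0) -> FixtureSpec:
    """A root -> A -> B homolog chain for multi-round recruitment tests.

    A sits at ~0.5 identity to the root, B at ~0.5 to A and therefore
    ~0.25 to the root: close enough to pass the final-round criteria only
    once A has joined the profile, and too distant for a stringent
    single-sequence search.  Longer proteins than the default keep the
    realized chain identities tightly concentrated around their targets.
    """
    return FixtureSpec(
        seed=seed,
        n_genes_per_organism=8,
        gene_length=300,
        planted_links=(
            # two ~0.45 hops compose to ~0.25 root-to-B identity once
            # convergent conservative substitutions are accounted for
            PlantedLink("eco_g01", "orgB_g01", 0.45, "fn_stoneA"),
            PlantedLink("orgB_g01", "orgC_g01", 0.45, "fn_stoneB"),
        ),
    )


# ---------------------------------------------------------------------------
# sequence generation
# ---------------------------------------------------------------------------

def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(AA_ORDER[i] for i in rng.integers(0, 20, size=length))


def mutate_sequence(seq: str, target_identity: float, seed: int) -> str:
    """Mutate a sequence to an expected fraction of preserved positions.

    Each position is independently preserved with probability
    ``target_identity`` or replaced by a *different* residue drawn from the
    BLOSUM62-implied conditional substitution distribution (so substitutions
    are biased toward conservative changes, as in real homologs), making the
    realized identity binomially concentrated around the target.
    Deterministic per seed; identity 1.0 returns the input.
    """
    if not 0.0 < target_identity <= 1.0:
        raise ValueError("target_identity must be in (0,1]")
    rng = np.random.default_rng(seed)
    keep = rng.random(len(seq)) < target_identity
    aa_index = {aa: i for i, aa in enumerate(AA_ORDER)}
    out = []
    for i, ch in enumerate(seq):
        if keep[i] or ch not in aa_index:
            out.append(ch)
        else:
            probs = BLOSUM62_CONDITIONAL[aa_index[ch]].copy()
            probs[aa_index[ch]] = 0.0
            probs /= probs.sum()
            out.append(AA_ORDER[rng.choice(20, p=probs)])
    return "".join(out)


# ---------------------------------------------------------------------------
# proteome fixture
# ---------------------------------------------------------------------------

@dataclass
class ProteomeFixture:
    proteome: ProteomeSet
    annotation_table: pd.DataFrame
    complex_table: pd.DataFrame
    truth: pd.DataFrame

    def expected_direct_pairs(self) -> List[Tuple[str, str]]:
        """(target, replacer) pairs the pipeline should recover."""
        return sorted(
            (row["target_gene"], row["source_gene"])
            for _, row in self.truth.iterrows()
            if row["target_gene"]
        )

    def write(self, outdir) -> Dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "proteome.fasta",
            "annotations": outdir / "annotations.tsv",
            "complexes": outdir / "complexes.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_proteome(self.proteome, paths["fasta"])
        self.annotation_table.to_csv(paths["annotations"], sep="\t", index=False)
        self.complex_table.to_csv(paths["complexes"], sep="\t", index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def generate_proteome(spec: FixtureSpec) -> ProteomeFixture:
    """Generate the annotated multi-organism proteome of a fixture spec."""
    rng = np.random.default_rng(spec.seed)
    sequences: Dict[str, str] = {}
    organisms: Dict[str, str] = {}
    for org in spec.organisms:
        for i in range(1, spec.n_genes_per_organism + 1):
            gid = f"{org}_g{i:02d}"
            sequences[gid] = random_sequence(spec.gene_length, rng)
            organisms[gid] = org

    # plant homolog links in order so chains (root -> A -> B) are possible
    for li, link in enumerate(spec.planted_links):
        if link.source_gene not in sequences:
            raise ValueError(f"planted source {link.source_gene!r} not generated")
        if link.foreign_gene not in sequences:
            raise ValueError(f"planted gene {link.foreign_gene!r} not generated")
        child_seed = int(
            np.random.SeedSequence([spec.seed, 1000 + li]).generate_state(1)[0]
        )
        sequences[link.foreign_gene] = mutate_sequence(
            sequences[link.source_gene], link.identity, child_seed
        )

    # annotations: every background gene gets a unique metabolic function;
    # planted foreign genes carry only their foreign function; planted
    # target genes take the planted function as their primary annotation
    special: Dict[str, str] = {}
    for link in spec.planted_links:
        special[link.foreign_gene] = link.function_id
        if link.target_gene is not None:
            if link.target_gene not in sequences:
                raise ValueError(
                    f"planted target {link.target_gene!r} not generated"
                )
            special[link.target_gene] = link.function_id
    rows = []
    for gid in sorted(sequences):
        fn = special.get(gid, f"fn_{gid}")
        rows.append(
            {
                "gene_id": gid,
                "organism_id": organisms[gid],
                "function_id": fn,
                "function_name": f"enzyme {fn}",
                "reaction_ids": f"rxn_{fn}",
            }
        )
    annotation_table = pd.DataFrame(
        rows,
        columns=["gene_id", "organism_id", "function_id", "function_name",
                 "reaction_ids"],
    )

    complex_rows = [
        {"function_id": cfn, "subunit_role_id": role}
        for cfn, roles in spec.complexes
        for role in roles
    ]
    complex_table = pd.DataFrame(
        complex_rows, columns=["function_id", "subunit_role_id"]
    )

    truth = pd.DataFrame(
        [
            {
                "source_gene": link.source_gene,
                "foreign_gene": link.foreign_gene,
                "function_id": link.function_id,
                "planted_identity": link.identity,
                "target_gene": link.target_gene or "",
            }
            for link in spec.planted_links
        ],
        columns=["source_gene", "foreign_gene", "function_id",
                 "planted_identity", "target_gene"],
    )

    records = {
        gid: ProteinRecord(gid, organisms[gid], sequences[gid])
        for gid in sorted(sequences)
    }
    annotations = annotations_from_table(annotation_table)
    return ProteomeFixture(
        proteome=ProteomeSet(records=records, annotations=annotations),
        annotation_table=annotation_table,
        complex_table=complex_table,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# toy metabolic model fixture
# ---------------------------------------------------------------------------

@dataclass
class GemFixture:
    model: MetabolicModel
    catalog: Dict[str, List[ReactionDefinition]]
    truth: pd.DataFrame

    def write(self, outdir) -> Dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "model": outdir / "model.json",
            "catalog": outdir / "catalog.json",
            "truth": outdir / "gem_truth.tsv",
        }
        write_model(self.model, paths["model"])
        write_catalog(self.catalog, paths["catalog"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def generate_toy_gem(spec: FixtureSpec) -> GemFixture:
    """Toy model: glucose feeds biomass directly and, via a linear chain,
    a vitamin that biomass needs in catalytic amounts.

    Minimal medium supplies only glucose, rich medium also the vitamin, so
    the first chain gene is conditionally essential.  The catalog holds one
    bypass reaction (glucose -> vitamin in one step) that rescues its
    knockout, plus decoys: a duplicate of an existing gene-associated
    chain step, two dead-end/wrong-direction reactions, and a reaction over
    metabolites the model does not contain.
    """
    gem = spec.gem or GemSpec()
    n_chain = 1 + len(gem.chain_genes)
    mets = ["glc_e", "glc_c", "vit_e", "vit_c"] + [
        f"i{k}_c" for k in range(1, n_chain)
    ]
    chain_nodes = ["glc_c"] + [f"i{k}_c" for k in range(1, n_chain)] + ["vit_c"]
    chain_gprs = [gem.target_gene] + list(gem.chain_genes)
    reactions = [
        ReactionDefinition("EX_glc", {"glc_e": -1.0}, 0.0, 1000.0),
        ReactionDefinition("EX_vit", {"vit_e": -1.0}, 0.0, 1000.0),
        ReactionDefinition(
            "PTS", {"glc_e": -1.0, "glc_c": 1.0}, 0.0, 1000.0,
            gem.glc_transport_gene,
        ),
        ReactionDefinition(
            "VUP", {"vit_e": -1.0, "vit_c": 1.0}, 0.0, 1000.0,
            gem.vit_transport_gene,
        ),
    ]
    for k in range(n_chain):
        reactions.append(
            ReactionDefinition(
                f"CHAIN{k + 1}",
                {chain_nodes[k]: -1.0, chain_nodes[k + 1]: 1.0},
                0.0,
                1000.0,
                chain_gprs[k],
            )
        )
    reactions.append(
        ReactionDefinition(
            "BIOMASS",
            {"glc_c": -1.0, "vit_c": -gem.vit_coefficient},
            0.0,
            1000.0,
        )
    )
    model = MetabolicModel(
        reactions=reactions,
        biomass_reaction="BIOMASS",
        media={
            "M9": {"EX_glc": gem.glc_uptake},
            "rich": {"EX_glc": gem.glc_uptake, "EX_vit": gem.glc_uptake},
        },
        metabolites=mets,
    )

    mid = f"i{max(1, n_chain - 1)}_c"  # last chain intermediate
    catalog: Dict[str, List[ReactionDefinition]] = {
        gem.bypass_function: [
            ReactionDefinition(
                "RXN_BYPASS", {"glc_c": -1.0, "vit_c": 1.0}, 0.0, 1000.0
            )
        ],
        "fn_decoy_dup": [
            # same stoichiometry as an existing gene-associated chain step
            # downstream of the knockout: already carried, and useless once
            # the first step is gone
            ReactionDefinition(
                "RXN_DECOY_DUP",
                {chain_nodes[1]: -1.0, chain_nodes[2]: 1.0},
                0.0,
                1000.0,
            )
        ],
        "fn_decoy_rev": [
            ReactionDefinition(
                "RXN_DECOY_REV", {"vit_c": -1.0, mid: 1.0}, 0.0, 1000.0
            )
        ],
        "fn_decoy_up": [
            ReactionDefinition(
                "RXN_DECOY_UP", {mid: -1.0, chain_nodes[1]: 1.0}, 0.0, 1000.0
            )
        ],
        "fn_decoy_new": [
            ReactionDefinition(
                "RXN_DECOY_NEW", {"x1_c": -1.0, "x2_c": 1.0}, 0.0, 1000.0
            )
        ],
    }

    truth = pd.DataFrame(
        [
            {
                "target_gene": gem.target_gene,
                "expected_class": "conditionally_essential",
                "rescuing_function": gem.bypass_function,
                "replacer_gene": gem.replacer_gene,
            }
        ]
    )
    return GemFixture(model=model, catalog=catalog, truth=truth)
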
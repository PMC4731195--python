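"""Gene x promiscuous-function matrix built from gene similarity trees.

Every function annotated on any member of a root gene's similarity tree is
a candidate promiscuous function of the root; the root's own primary
functions are excluded.  When a candidate function is a single subunit role
of an enzyme complex, the whole-complex function is credited to the root as
well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .io import ComplexDefinition, GeneAnnotation
from .search import GeneTree


@dataclass(frozen=True)
class Provenance:
    """Best evidence supporting one promiscuous gene-function entry."""

    evidence_gene: str
    evidence_organism: str
    identity: float
    positives: Optional[float] = None
    coverage: Optional[float] = None


@dataclass
class PromiscuityMatrix:
    """Sparse boolean gene x function assignments with provenance.

    ``entries`` maps (root_gene_id, function_id) to the highest-identity
    evidence; ``primary`` maps every annotated gene to its primary function
    set.  A gene's primary functions never appear among its own entries.
    """

    entries: Dict[Tuple[str, str], Provenance]
    primary: Dict[str, frozenset]

    def functions_of(self, gene_id: str) -> Dict[str, Provenance]:
        return {
            fn: prov
            for (g, fn), prov in self.entries.items()
            if g == gene_id
        }

    def genes_with_function(self, function_id: str) -> List[str]:
        return sorted(g for (g, fn) in self.entries if fn == function_id)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "root_gene": g,
                "function_id": fn,
                "evidence_gene": p.evidence_gene,
                "evidence_organism": p.evidence_organism,
                "identity": p.identity,
            }
            for (g, fn), p in sorted(self.entries.items())
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "root_gene",
                "function_id",
                "evidence_gene",
                "evidence_organism",
                "identity",
            ],
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def collect_tree_functions(
    tree: GeneTree,
    annotations: Mapping[str, GeneAnnotation],
) -> Dict[str, Provenance]:
    """Candidate promiscuous functions of a tree's root with best evidence.

    Union of member function annotations minus the root's primary
    functions; for each function the evidence is the member carrying it
    with the highest recruitment identity (ties to the lexicographically
    smallest gene id).  Members without annotation rows contribute nothing.
    """
    root_ann = annotations.get(tree.root_gene_id)
    root_primary = root_ann.function_ids if root_ann else frozenset()
    best: Dict[str, Provenance] = {}
    for member in sorted(tree.member_gene_ids):
        if member == tree.root_gene_id:
            continue
        ann = annotations.get(member)
        if ann is None:
            continue
        hit = tree.hits.get(member)
        identity = hit.identity if hit else 0.0
        prov = Provenance(
            evidence_gene=member,
            evidence_organism=ann.organism_id,
            identity=identity,
            positives=hit.positives if hit else None,
            coverage=hit.query_coverage if hit else None,
        )
        for fn in ann.function_ids:
            if fn in root_primary:
                continue
            cur = best.get(fn)
            if cur is None or identity > cur.identity:
                best[fn] = prov
    return best


def expand_complexes(
    fns: Mapping[str, Provenance],
    complexes: Sequence[ComplexDefinition],
) -> Dict[str, Provenance]:
    """Credit whole-complex functions when a subunit role is matched.

    An entry that matches any subunit role of a complex adds the complex's
    full function (with the best evidence among matching subunit entries);
    existing entries pass through unchanged, so the operation is idempotent.
    """
    out = dict(fns)
    for cx in complexes:
        matching = [fn for fn in fns if fn in cx.subunit_role_ids]
        if not matching:
            continue
        best = max(matching, key=lambda fn: (fns[fn].identity, fn))
        cur = out.get(cx.function_id)
        if cur is None or fns[best].identity > cur.identity:
            out[cx.function_id] = fns[best]
    return out


def build_matrix(
    trees: Iterable[GeneTree],
    annotations: Mapping[str, GeneAnnotation],
    complexes: Sequence[ComplexDefinition] = (),
) -> PromiscuityMatrix:
    """Union the per-tree promiscuous functions into one matrix."""
    entries: Dict[Tuple[str, str], Provenance] = {}
    seen_roots = set()
    for tree in trees:
        root = tree.root_gene_id
        if root in seen_roots:
            raise ValueError(f"duplicate root gene {root!r} across trees")
        seen_roots.add(root)
        fns = collect_tree_functions(tree, annotations)
        fns = expand_complexes(fns, complexes)
        root_ann = annotations.get(root)
        root_primary = root_ann.function_ids if root_ann else frozenset()
        for fn, prov in fns.items():
            if fn in root_primary:
                continue
            entries[(root, fn)] = prov
    primary = {
        gid: ann.function_ids for gid, ann in annotations.items()
    }
    return PromiscuityMatrix(entries=entries, primary=primary)


def read_matrix(path, primary: Optional[Mapping[str, frozenset]] = None) -> PromiscuityMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"identity": float}, keep_default_na=False)
    entries = {
        (row["root_gene"], row["function_id"]): Provenance(
            evidence_gene=row["evidence_gene"],
            evidence_organism=row["evidence_organism"],
            identity=float(row["identity"]),
        )
        for _, row in df.iterrows()
    }
    return PromiscuityMatrix(entries=entries, primary=dict(primary or {}))
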
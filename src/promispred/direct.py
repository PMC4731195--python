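"""Direct target-replacer prediction and descriptive statistics.

A replacer gene whose promiscuous function set contains the primary
annotated function of another (target) gene forms a predicted direct
target-replacer pair: over-expressing the replacer should compensate for
loss of the target.  The search is restricted to genes whose primary
functions are metabolic.  A plain single-sequence search at a conventional
stringent threshold is provided as the comparison baseline.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set, Tuple

import pandas as pd

from .io import GeneAnnotation, ProteomeSet
from .matrix import PromiscuityMatrix
from .search import (
    FilterCriteria,
    filter_hits,
    search_profile,
    single_sequence_profile,
)


@dataclass(frozen=True)
class ReplacerPair:
    """A predicted (target, replacer) gene pair with its evidence."""

    target_gene: str
    replacer_gene: str
    mode: str  # "direct" | "indirect"
    promiscuous_function: str
    evidence_gene: str = ""
    evidence_organism: str = ""
    identity: Optional[float] = None
    positives: Optional[float] = None
    coverage: Optional[float] = None
    rescued_growth: Optional[float] = None
    isozyme_by_annotation: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.target_gene == self.replacer_gene:
            raise ValueError("target and replacer must differ")
        if self.mode not in ("direct", "indirect"):
            raise ValueError(f"unknown mode {self.mode!r}")


#: baseline single-sequence search keep thresholds: the conventional
#: stringent homology cutoff (35% identity, 50% positives, 80% coverage);
#: configurable
BLAST_CONTROL_CRITERIA = FilterCriteria(
    max_uncovered=50, min_coverage=0.80, min_identity=0.35, min_positives=0.50
)


def predict_direct_pairs(
    matrix: PromiscuityMatrix,
    scope: Iterable[str],
    annotations: Mapping[str, GeneAnnotation],
) -> List[ReplacerPair]:
    """All (target, replacer) pairs whose functions match through the matrix.

    For every metabolic target gene in scope and each of its primary
    functions, every other metabolic scope gene holding that function as a
    promiscuous matrix entry is a predicted direct replacer.  Pairs are
    deduplicated per (target, replacer, function); self-pairs are excluded.
    Pairs whose replacer already carries the target's function as a primary
    annotation (isozymes by annotation) are retained and flagged.
    """
    scope_metabolic = sorted(
        g
        for g in scope
        if g in annotations and annotations[g].is_metabolic
    )
    by_function: Dict[str, List[str]] = collections.defaultdict(list)
    for (gene, fn) in matrix.entries:
        by_function[fn].append(gene)
    scope_set = set(scope_metabolic)

    pairs: Dict[Tuple[str, str, str], ReplacerPair] = {}
    for target in scope_metabolic:
        for fn in sorted(annotations[target].function_ids):
            for replacer in sorted(by_function.get(fn, ())):
                if replacer == target or replacer not in scope_set:
                    continue
                prov = matrix.entries[(replacer, fn)]
                key = (target, replacer, fn)
                if key in pairs:
                    continue
                pairs[key] = ReplacerPair(
                    target_gene=target,
                    replacer_gene=replacer,
                    mode="direct",
                    promiscuous_function=fn,
                    evidence_gene=prov.evidence_gene,
                    evidence_organism=prov.evidence_organism,
                    identity=prov.identity,
                    positives=prov.positives,
                    coverage=prov.coverage,
                    isozyme_by_annotation=(
                        fn in matrix.primary.get(replacer, frozenset())
                    ),
                )
    return [pairs[k] for k in sorted(pairs)]


def replacers_per_target(
    pairs: Iterable[ReplacerPair],
) -> Tuple[Dict[str, int], pd.DataFrame]:
    """Distinct replacers per target plus a histogram table for plotting."""
    per_target: Dict[str, Set[str]] = collections.defaultdict(set)
    for p in pairs:
        per_target[p.target_gene].add(p.replacer_gene)
    counts = {t: len(rs) for t, rs in per_target.items()}
    hist = collections.Counter(counts.values())
    table = pd.DataFrame(
        sorted(hist.items()), columns=["n_replacers", "n_targets"]
    )
    return counts, table


def find_reciprocal(pairs: Iterable[ReplacerPair]) -> Set[FrozenSet[str]]:
    """Unordered gene pairs present in both pair orientations."""
    ordered = {(p.target_gene, p.replacer_gene) for p in pairs}
    return {
        frozenset((a, b))
        for (a, b) in ordered
        if (b, a) in ordered and a != b
    }


def blast_control_pairs(
    proteome: ProteomeSet,
    targets: Iterable[str],
    criteria: FilterCriteria = BLAST_CONTROL_CRITERIA,
    scope: Optional[Iterable[str]] = None,
) -> List[ReplacerPair]:
    """Single-round, single-sequence search baseline.

    Each target sequence is searched (no clustering, trimming or
    iteration) against the metabolic genes of its own organism by default,
    keeping hits above a conventional stringent threshold.  Used only to
    contrast against the iterative profile search.
    """
    targets = sorted(set(targets))
    pairs: List[ReplacerPair] = []
    for target in targets:
        rec = proteome.records.get(target)
        if rec is None:
            continue
        if scope is None:
            db_genes = [
                g
                for g in proteome.metabolic_genes(rec.organism_id)
                if g in proteome.records
            ]
        else:
            db_genes = sorted(set(scope) & set(proteome.records))
        db = ProteomeSet(
            records={g: proteome.records[g] for g in db_genes},
            annotations={
                g: proteome.annotations[g]
                for g in db_genes
                if g in proteome.annotations
            },
        )
        profile = single_sequence_profile(rec)
        hits = filter_hits(search_profile(profile, db), criteria)
        ann = proteome.annotations.get(target)
        fn = min(ann.function_ids) if ann and ann.function_ids else ""
        for h in hits:
            if h.subject_gene_id == target:
                continue
            pairs.append(
                ReplacerPair(
                    target_gene=target,
                    replacer_gene=h.subject_gene_id,
                    mode="direct",
                    promiscuous_function=fn,
                    evidence_gene=h.subject_gene_id,
                    evidence_organism=proteome.records[
                        h.subject_gene_id
                    ].organism_id,
                    identity=h.identity,
                    positives=h.positives,
                    coverage=h.query_coverage,
                )
            )
    pairs.sort(key=lambda p: (p.target_gene, p.replacer_gene))
    return pairs
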
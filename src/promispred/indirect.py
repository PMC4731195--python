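"""Indirect target-replacer prediction via promiscuous-reaction addition.

For every target gene that is conditionally essential in silico, the target
is knocked out on minimal medium and each candidate promiscuous function
(a matrix entry whose function is foreign to the organism and maps to
catalog reactions) is added to the model in turn; a candidate whose added
reactions restore biomass flux above the growth epsilon predicts the
carrying gene as an indirect, pathway-bypassing replacer of the target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .direct import ReplacerPair
from .fba import (
    DEFAULT_GROWTH_EPSILON,
    MetabolicModel,
    add_reaction,
    apply_medium,
    essentiality_class,
    fba,
    knockout_genes,
)
from .io import ReactionDefinition
from .matrix import PromiscuityMatrix

logger = logging.getLogger(__name__)


@dataclass
class RescueResult:
    """Outcome of one (target knockout, candidate function) rescue test."""

    target_gene: str
    replacer_gene: str
    function_id: str
    reaction_ids: Tuple[str, ...]
    growth_before: float
    growth_after: float
    rescued: bool


def _proportional(a: Mapping[str, float], b: Mapping[str, float]) -> bool:
    """True when two stoichiometries are identical up to a positive scale."""
    if set(a) != set(b):
        return False
    ratio = None
    for m in a:
        if b[m] == 0:
            return False
        r = a[m] / b[m]
        if ratio is None:
            ratio = r
        elif abs(r - ratio) > 1e-9 * max(1.0, abs(ratio)):
            return False
    return ratio is not None and ratio > 0


def candidate_functions(
    matrix: PromiscuityMatrix,
    model: MetabolicModel,
    catalog: Mapping[str, Sequence[ReactionDefinition]],
    scope: Optional[Iterable[str]] = None,
) -> List[Tuple[str, str, List[ReactionDefinition]]]:
    """Matrix entries offering reactions the model does not already carry.

    A function is *non-native* when it is not among the primary annotations
    of any scope gene (scope defaults to all genes in the matrix's primary
    map).  A candidate must have at least one catalog reaction that is not
    already carried -- same stoichiometry up to positive scaling -- by a
    gene-associated model reaction.  Functions without catalog reactions are
    excluded with a logged reason.
    """
    scope_genes = set(scope) if scope is not None else set(matrix.primary)
    native_functions: Set[str] = set()
    for g in scope_genes:
        native_functions |= matrix.primary.get(g, frozenset())

    carried = [r.stoichiometry for r in model.reactions if r.gpr]
    out: List[Tuple[str, str, List[ReactionDefinition]]] = []
    for (gene, fn) in sorted(matrix.entries):
        if fn in native_functions:
            continue
        rxns = list(catalog.get(fn, ()))
        if not rxns:
            logger.info(
                "function %s (gene %s) has no catalog reaction; excluded",
                fn, gene,
            )
            continue
        novel = [
            r
            for r in rxns
            if not any(_proportional(r.stoichiometry, c) for c in carried)
        ]
        if not novel:
            continue
        out.append((gene, fn, rxns))
    return out


def _try_rescue(
    ko_model: MetabolicModel,
    rxns: Sequence[ReactionDefinition],
) -> Optional[MetabolicModel]:
    """Add candidate reactions to a knockout model.

    Reactions referencing metabolites absent from the model are skipped
    (the candidate is dropped with a logged reason): a bypass must connect
    existing chemistry, and admitting unknown metabolites risks spurious
    mass-from-nothing rescues.
    """
    m = ko_model
    known = set(ko_model.metabolites)
    for r in rxns:
        missing = set(r.stoichiometry) - known
        if missing:
            logger.info(
                "candidate reaction %s skipped: unknown metabolites %s",
                r.reaction_id, sorted(missing),
            )
            return None
        m = add_reaction(m, r)
    return m


def predict_indirect_pairs(
    model: MetabolicModel,
    matrix: PromiscuityMatrix,
    catalog: Mapping[str, Sequence[ReactionDefinition]],
    targets: Iterable[str],
    medium: str = "M9",
    rich_medium: str = "rich",
    growth_epsilon: float = DEFAULT_GROWTH_EPSILON,
    per_reaction: bool = False,
    scope: Optional[Iterable[str]] = None,
) -> Tuple[List[ReplacerPair], List[RescueResult]]:
    """Growth-rescue screen over (conditionally essential target, candidate).

    For each target that is conditionally essential in silico (others are
    skipped with a logged reason), the target is knocked out on ``medium``
    and every candidate function's reactions are added; a pair is emitted
    iff the addition restores growth.  When a function maps to several
    catalog reactions all are added together unless ``per_reaction`` is
    set.  Deterministic ordering.
    """
    wt = apply_medium(model, medium)
    if fba(wt).objective < growth_epsilon:
        raise RuntimeError(
            f"baseline wild type does not grow on medium {medium!r}"
        )
    candidates = candidate_functions(matrix, model, catalog, scope=scope)

    pairs: List[ReplacerPair] = []
    results: List[RescueResult] = []
    for target in sorted(set(targets)):
        cls = essentiality_class(
            model, target, (medium, rich_medium), growth_epsilon
        )
        if cls != "conditionally_essential":
            logger.info(
                "target %s skipped: %s in silico (rescue test requires "
                "conditional essentiality)", target, cls,
            )
            continue
        ko = knockout_genes(wt, {target})
        growth_before = fba(ko).objective
        for gene, fn, rxns in candidates:
            if gene == target:
                continue
            groups = [[r] for r in rxns] if per_reaction else [list(rxns)]
            for group in groups:
                rescued_model = _try_rescue(ko, group)
                if rescued_model is None:
                    continue
                growth_after = fba(rescued_model).objective
                rescued = growth_before < growth_epsilon <= growth_after
                results.append(
                    RescueResult(
                        target_gene=target,
                        replacer_gene=gene,
                        function_id=fn,
                        reaction_ids=tuple(r.reaction_id for r in group),
                        growth_before=growth_before,
                        growth_after=growth_after,
                        rescued=rescued,
                    )
                )
                if rescued:
                    prov = matrix.entries[(gene, fn)]
                    pairs.append(
                        ReplacerPair(
                            target_gene=target,
                            replacer_gene=gene,
                            mode="indirect",
                            promiscuous_function=fn,
                            evidence_gene=prov.evidence_gene,
                            evidence_organism=prov.evidence_organism,
                            identity=prov.identity,
                            positives=prov.positives,
                            coverage=prov.coverage,
                            rescued_growth=growth_after,
                        )
                    )
    pairs.sort(
        key=lambda p: (p.target_gene, p.replacer_gene, p.promiscuous_function)
    )
    return pairs, results


def rescue_table(results: Iterable[RescueResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "target": r.target_gene,
                "replacer": r.replacer_gene,
                "function": r.function_id,
                "reactions": ";".join(r.reaction_ids),
                "growth_before": r.growth_before,
                "growth_after": r.growth_after,
                "rescued": r.rescued,
            }
            for r in results
        ],
        columns=[
            "target",
            "replacer",
            "function",
            "reactions",
            "growth_before",
            "growth_after",
            "rescued",
        ],
    )
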
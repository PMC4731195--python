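"""Flux balance analysis: media, biomass optimization, knockouts.

A metabolic model is a list of stoichiometric reactions with flux bounds,
boolean gene-protein-reaction (GPR) rules, a biomass objective and named
media.  FBA maximizes biomass flux subject to steady state (S v = 0) and
the bounds; gene knockouts close every reaction whose GPR evaluates false.
Growth calls use an epsilon on the biomass flux ("nominal production of
biomass"); a gene is conditionally essential when its knockout abolishes
growth on minimal medium but not on rich medium.

Exchange convention: uptake is a negative lower bound on the exchange
reaction; media store uptake magnitudes and :func:`apply_medium` applies
the sign.
"""

from __future__ import annotations

import copy
import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Set, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .io import ReactionDefinition

logger = logging.getLogger(__name__)

#: biomass flux at or above which the model counts as growing
DEFAULT_GROWTH_EPSILON = 1e-6
#: steady-state feasibility tolerance
MASS_BALANCE_TOL = 1e-9


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def gpr_genes(gpr: str) -> Set[str]:
    """Gene tokens of a GPR expression (keywords excluded)."""
    return {
        t
        for t in _GPR_TOKEN.findall(gpr)
        if t not in ("(", ")") and t.lower() not in ("and", "or")
    }


def evaluate_gpr(gpr: str, knocked_out: Set[str]) -> bool:
    """Evaluate a GPR boolean rule with the given genes absent.

    Grammar: gene tokens, ``and``, ``or`` (case-insensitive) and
    parentheses.  A gene not in ``knocked_out`` is present; an empty rule is
    always true (the reaction cannot be knocked out).
    """
    tokens = _GPR_TOKEN.findall(gpr)
    if not tokens:
        return True
    pos = 0

    def parse_or() -> bool:
        nonlocal pos
        v = parse_and()
        while pos < len(tokens) and tokens[pos].lower() == "or":
            pos += 1
            v = parse_and() or v
        return v

    def parse_and() -> bool:
        nonlocal pos
        v = parse_atom()
        while pos < len(tokens) and tokens[pos].lower() == "and":
            pos += 1
            v = parse_atom() and v
        return v

    def parse_atom() -> bool:
        nonlocal pos
        if pos >= len(tokens):
            raise ValueError(f"malformed GPR {gpr!r}")
        tok = tokens[pos]
        if tok == "(":
            pos += 1
            v = parse_or()
            if pos >= len(tokens) or tokens[pos] != ")":
                raise ValueError(f"unbalanced parentheses in GPR {gpr!r}")
            pos += 1
            return v
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ValueError(f"malformed GPR {gpr!r}")
        pos += 1
        return tok not in knocked_out

    result = parse_or()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in GPR {gpr!r}")
    return result


# ---------------------------------------------------------------------------
# model & solutions
# ---------------------------------------------------------------------------

@dataclass
class MetabolicModel:
    """Stoichiometric network with bounds, GPR rules, biomass and media."""

    reactions: List[ReactionDefinition]
    biomass_reaction: str
    media: Dict[str, Dict[str, float]]
    metabolites: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        declared = set(self.metabolites)
        for r in self.reactions:
            for m in r.stoichiometry:
                if m not in declared:
                    declared.add(m)
                    self.metabolites.append(m)

    def validate(self) -> None:
        ids = [r.reaction_id for r in self.reactions]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate reaction ids in model")
        if self.biomass_reaction not in set(ids):
            raise ValueError(
                f"biomass reaction {self.biomass_reaction!r} not in model"
            )
        # dead-end metabolites are legal but suspicious
        seen: Dict[str, int] = {}
        for r in self.reactions:
            for m in r.stoichiometry:
                seen[m] = seen.get(m, 0) + 1
        for m, n in sorted(seen.items()):
            if n == 1:
                logger.warning(
                    "metabolite %s participates in a single reaction "
                    "(dead end)", m
                )

    @property
    def reaction_ids(self) -> List[str]:
        return [r.reaction_id for r in self.reactions]

    def reaction(self, reaction_id: str) -> ReactionDefinition:
        for r in self.reactions:
            if r.reaction_id == reaction_id:
                return r
        raise KeyError(reaction_id)

    @property
    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for r in self.reactions:
            out |= gpr_genes(r.gpr)
        return out

    def exchange_ids(self) -> Set[str]:
        """Reaction ids governed by any medium definition."""
        out: Set[str] = set()
        for med in self.media.values():
            out |= set(med)
        return out

    def stoichiometric_matrix(self) -> Tuple[sparse.csr_matrix, List[str]]:
        met_index = {m: i for i, m in enumerate(self.metabolites)}
        rows, cols, vals = [], [], []
        for j, r in enumerate(self.reactions):
            for m, c in r.stoichiometry.items():
                rows.append(met_index[m])
                cols.append(j)
                vals.append(float(c))
        S = sparse.csr_matrix(
            (vals, (rows, cols)),
            shape=(len(self.metabolites), len(self.reactions)),
        )
        return S, list(self.metabolites)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            reactions=[r.copy() for r in self.reactions],
            biomass_reaction=self.biomass_reaction,
            media=copy.deepcopy(self.media),
            metabolites=list(self.metabolites),
        )


@dataclass
class FluxSolution:
    """Outcome of one FBA solve."""

    status: str  # "optimal" | "infeasible"
    objective: float
    fluxes: Dict[str, float]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            sorted(self.fluxes.items()), columns=["reaction_id", "flux"]
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def apply_medium(model: MetabolicModel, medium_name: str) -> MetabolicModel:
    """Close all exchange uptakes, then open those listed in the medium.

    Pure: returns a new model.  Secretion (upper) bounds are untouched.
    Idempotent for a fixed medium.
    """
    if medium_name not in model.media:
        raise KeyError(
            f"unknown medium {medium_name!r}; available: "
            f"{sorted(model.media)}"
        )
    out = model.copy()
    exchange = out.exchange_ids()
    medium = out.media[medium_name]
    for r in out.reactions:
        if r.reaction_id in exchange:
            r.lower_bound = 0.0
        if r.reaction_id in medium:
            r.lower_bound = -abs(medium[r.reaction_id])
    return out


def fba(model: MetabolicModel) -> FluxSolution:
    """Maximize biomass flux subject to S v = 0 and the flux bounds."""
    S, _ = model.stoichiometric_matrix()
    n = len(model.reactions)
    c = np.zeros(n)
    c[model.reaction_ids.index(model.biomass_reaction)] = -1.0
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
    )
    if res.status == 3:
        raise RuntimeError(
            "unbounded biomass objective: an exchange constraint is missing"
        )
    if res.status != 0:
        return FluxSolution(status="infeasible", objective=0.0, fluxes={})
    # "+ 0.0" normalizes IEEE negative zeros out of reported values
    fluxes = {rid: float(v) + 0.0 for rid, v in zip(model.reaction_ids, res.x)}
    return FluxSolution(
        status="optimal", objective=float(-res.fun) + 0.0, fluxes=fluxes
    )


def knockout_genes(
    model: MetabolicModel, genes: Iterable[str]
) -> MetabolicModel:
    """Close every reaction whose GPR evaluates false without ``genes``.

    Reactions with empty GPRs are untouched; knocking out the empty set is
    the identity and knockouts commute (set semantics).  Pure operation.
    """
    knocked = set(genes)
    out = model.copy()
    for r in out.reactions:
        if r.gpr and not evaluate_gpr(r.gpr, knocked):
            r.lower_bound = 0.0
            r.upper_bound = 0.0
    return out


def growth(
    model: MetabolicModel, growth_epsilon: float = DEFAULT_GROWTH_EPSILON
) -> bool:
    obj = fba(model).objective
    if growth_epsilon / 10.0 <= obj < growth_epsilon:
        logger.warning(
            "biomass flux %.3g falls in the ambiguous band below the growth "
            "epsilon %.3g", obj, growth_epsilon,
        )
    return obj >= growth_epsilon


def essentiality_class(
    model: MetabolicModel,
    gene: str,
    media_pair: Tuple[str, str] = ("M9", "rich"),
    growth_epsilon: float = DEFAULT_GROWTH_EPSILON,
) -> str:
    """Classify a gene knockout across a (minimal, rich) media pair.

    Returns ``"nonessential"`` (growth on both), ``"conditionally_essential"``
    (growth on rich only) or ``"always_essential"`` (growth on neither).
    The wild type must grow on the minimal medium, else the classification
    is undefined and an error is raised.
    """
    minimal, rich = media_pair
    wt_min = apply_medium(model, minimal)
    if not growth(wt_min, growth_epsilon):
        raise RuntimeError(
            f"model infeasible baseline: wild type does not grow on {minimal!r}"
        )
    ko = knockout_genes(model, {gene})
    grows_min = growth(apply_medium(ko, minimal), growth_epsilon)
    grows_rich = growth(apply_medium(ko, rich), growth_epsilon)
    if grows_min and grows_rich:
        return "nonessential"
    if grows_rich and not grows_min:
        return "conditionally_essential"
    if not grows_rich and not grows_min:
        return "always_essential"
    # grows on minimal but not rich: treat as nonessential on the tested
    # medium, but flag it -- a rich medium should be a superset of minimal
    logger.warning(
        "gene %s grows on %s but not on %s after knockout", gene, minimal, rich
    )
    return "nonessential"


def add_reaction(
    model: MetabolicModel,
    rxn: ReactionDefinition,
    new_metabolites: Iterable[str] = (),
) -> MetabolicModel:
    """Append a reaction; pure operation, fresh id on collision.

    Metabolites of the reaction must resolve to model metabolites by id
    unless explicitly declared in ``new_metabolites``; otherwise an error
    lists the unresolvable ids.
    """
    out = model.copy()
    declared = set(out.metabolites) | set(new_metabolites)
    missing = sorted(set(rxn.stoichiometry) - declared)
    if missing:
        raise ValueError(
            f"reaction {rxn.reaction_id!r} references unknown metabolites: "
            f"{missing}"
        )
    new = rxn.copy()
    existing = set(out.reaction_ids)
    if new.reaction_id in existing:
        k = 1
        while f"{rxn.reaction_id}_added{k}" in existing:
            k += 1
        new.reaction_id = f"{rxn.reaction_id}_added{k}"
    out.reactions.append(new)
    for m in new.stoichiometry:
        if m not in out.metabolites:
            out.metabolites.append(m)
    return out
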
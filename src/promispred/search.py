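"""Iterative align -> cluster -> trim -> profile -> search -> filter engine.

Around each root gene a "gene similarity tree" is grown: the current member
set is multiply aligned, redundant members are collapsed to representatives,
non-conserved alignment ends are trimmed away, a position-specific scoring
profile is built from the trimmed alignment, the profile is searched against
the whole proteome by gapped local alignment, and hits passing the round's
keep criteria join the member set.  Three rounds with progressively relaxed
criteria recruit distant homologs that a single stringent sequence search
misses; the final round's criteria are::

    uncovered query region <= 100 residues
    query coverage        >= 0.60
    percent identity      >= 0.15
    percent positives     >= 0.30   (identical pairs included)

All thresholds are inclusive.  Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .alphabet import (
    AA_ORDER,
    ALPHABET,
    BLOSUM62,
    BLOSUM62_CONDITIONAL,
    X_INDEX,
    encode,
)
from .io import ProteinRecord, ProteomeSet

# affine gap penalties (positive magnitudes), PSI-BLAST defaults
DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0
#: uniform residue background used by the profile log-odds
BACKGROUND_FREQ = 1.0 / 20.0
#: score assigned to the ambiguity code X in every profile column
X_SCORE = -1.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """A multiple alignment: rows of (gene_id, gapped sequence)."""

    rows: List[Tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment needs >=1 row")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def gene_ids(self) -> List[str]:
        return [g for g, _ in self.rows]

    def ungapped(self, gene_id: str) -> str:
        for g, s in self.rows:
            if g == gene_id:
                return s.replace("-", "")
        raise KeyError(gene_id)


@dataclass
class Profile:
    """Position-specific scores derived from a (trimmed) alignment.

    ``scores`` is (length, 21): one log-odds score per canonical residue per
    column plus a fixed score for X.  ``consensus`` holds the majority
    residue index per column (ties to the lexicographically smallest
    residue; all-gap columns get -1).
    """

    length: int
    scores: np.ndarray
    consensus: np.ndarray
    source_gene_ids: frozenset

    def column_scores(self, i: int) -> Dict[str, float]:
        return {ALPHABET[j]: float(self.scores[i, j]) for j in range(21)}


@dataclass(frozen=True)
class SearchHit:
    """One best local alignment of a profile against a database sequence."""

    subject_gene_id: str
    aligned_interval_query: Tuple[int, int]
    aligned_interval_subject: Tuple[int, int]
    identity: float
    positives: float
    query_coverage: float
    uncovered_query: int
    raw_score: float


@dataclass(frozen=True)
class FilterCriteria:
    """The four keep criteria applied to search hits (inclusive bounds)."""

    max_uncovered: int = 100
    min_coverage: float = 0.60
    min_identity: float = 0.15
    min_positives: float = 0.30

    def __post_init__(self) -> None:
        for name in ("min_coverage", "min_identity", "min_positives"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0,1], got {v}")

    def is_stricter_or_equal(self, other: "FilterCriteria") -> bool:
        """True if `self` never keeps a hit that `other` rejects."""
        return (
            self.max_uncovered <= other.max_uncovered
            and self.min_coverage >= other.min_coverage
            and self.min_identity >= other.min_identity
            and self.min_positives >= other.min_positives
        )


@dataclass(frozen=True)
class RoundConfig:
    """Per-round parameters of the iterative search."""

    criteria: FilterCriteria
    cluster_identity: float = 0.90
    trim_occupancy: float = 0.50


#: three-round default schedule; only the last round's criteria are the
#: published keep thresholds, earlier rounds are progressively stricter
#: configurable defaults.
DEFAULT_ROUNDS = (
    RoundConfig(FilterCriteria(max_uncovered=50, min_coverage=0.70,
                               min_identity=0.30, min_positives=0.45)),
    RoundConfig(FilterCriteria(max_uncovered=75, min_coverage=0.65,
                               min_identity=0.22, min_positives=0.37)),
    RoundConfig(FilterCriteria(max_uncovered=100, min_coverage=0.60,
                               min_identity=0.15, min_positives=0.30)),
)


@dataclass
class GeneTree:
    """Recruited homolog set around one root gene."""

    root_gene_id: str
    member_gene_ids: set
    hits: Dict[str, SearchHit]
    organisms: Dict[str, str] = field(default_factory=dict)
    newick: Optional[str] = None

    def __post_init__(self) -> None:
        if self.root_gene_id not in self.member_gene_ids:
            raise ValueError("root gene must be a tree member")


# ---------------------------------------------------------------------------
# multiple alignment (deterministic center-star around the first record)
# ---------------------------------------------------------------------------

def _pairwise_aligner():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -DEFAULT_GAP_OPEN
    aligner.extend_gap_score = -DEFAULT_GAP_EXTEND
    return aligner


def align_sequences(records: Sequence[ProteinRecord]) -> Alignment:
    """Progressive center-star multiple alignment anchored on the first record.

    Every other sequence is globally aligned to the center under BLOSUM62
    with affine gaps; pairwise gaps are merged "once a gap, always a gap"
    relative to the center, so ungapping any row reproduces its input
    sequence exactly.  Deterministic for fixed input order.
    """
    if not records:
        raise ValueError("need >=1 record")
    center = records[0]
    if len(records) == 1:
        return Alignment(rows=[(center.gene_id, center.sequence)])

    aligner = _pairwise_aligner()
    n_center = len(center.sequence)
    # per pairwise alignment: inserts[k] = run of subject-only columns before
    # center residue k (k == n_center: trailing inserts)
    pair_cols: List[List[Tuple[str, str]]] = []
    for rec in records[1:]:
        aln = aligner.align(center.sequence, rec.sequence)[0]
        g_center, g_other = str(aln[0]), str(aln[1])
        pair_cols.append(list(zip(g_center, g_other)))

    max_ins = [0] * (n_center + 1)
    for cols in pair_cols:
        k = 0
        run = 0
        for c, _ in cols:
            if c == "-":
                run += 1
            else:
                max_ins[k] = max(max_ins[k], run)
                run = 0
                k += 1
        max_ins[n_center] = max(max_ins[n_center], run)

    def build_row(cols: List[Tuple[str, str]]) -> str:
        out = []
        k = 0
        run: List[str] = []
        for c, o in cols:
            if c == "-":
                run.append(o)
            else:
                out.append("".join(run) + "-" * (max_ins[k] - len(run)))
                run = []
                out.append(o)
                k += 1
        out.append("".join(run) + "-" * (max_ins[n_center] - len(run)))
        return "".join(out)

    center_cols = [(c, c) for c in center.sequence]
    rows = [(center.gene_id, build_row(center_cols))]
    for rec, cols in zip(records[1:], pair_cols):
        rows.append((rec.gene_id, build_row(cols)))
    return Alignment(rows=rows)


# ---------------------------------------------------------------------------
# clustering and trimming
# ---------------------------------------------------------------------------

def pairwise_identity(row_a: str, row_b: str) -> float:
    """Ungapped identity of two aligned rows.

    Identical aligned residue pairs over the shorter ungapped length;
    returns 0.0 when either row is all gaps.
    """
    matches = sum(
        1 for a, b in zip(row_a, row_b) if a != "-" and b != "-" and a == b
    )
    la = len(row_a) - row_a.count("-")
    lb = len(row_b) - row_b.count("-")
    denom = min(la, lb)
    return matches / denom if denom else 0.0


def cluster_representatives(
    aln: Alignment,
    identity_threshold: float,
    keep: Sequence[str] = (),
) -> Alignment:
    """Greedy incremental clustering; returns representative rows only.

    Rows are visited keep-listed first, then by descending ungapped length
    (ties by gene id); a row within ``identity_threshold`` of an existing
    representative is absorbed, otherwise it becomes a representative.
    Output preserves input row order and is a subset of input rows;
    idempotent at the same threshold.
    """
    order = {g: i for i, (g, _) in enumerate(aln.rows)}
    keep_set = list(dict.fromkeys(keep))

    def sort_key(row):
        g, s = row
        if g in keep_set:
            return (0, keep_set.index(g), "")
        return (1, -(len(s) - s.count("-")), g)

    reps: List[Tuple[str, str]] = []
    for g, s in sorted(aln.rows, key=sort_key):
        if any(pairwise_identity(s, rs) >= identity_threshold for _, rs in reps):
            continue
        reps.append((g, s))
    reps.sort(key=lambda row: order[row[0]])
    return Alignment(rows=reps)


def trim_alignment(aln: Alignment, min_occupancy: float = 0.50) -> Alignment:
    """Trim non-conserved alignment ends.

    Keeps the contiguous column interval from the first to the last column
    whose non-gap occupancy is >= ``min_occupancy``; interior columns are
    untouched.  Raises if no column qualifies ("empty profile").
    """
    n_rows = len(aln.rows)
    occ = [
        sum(1 for _, s in aln.rows if s[c] != "-") / n_rows
        for c in range(aln.length)
    ]
    qualifying = [c for c, o in enumerate(occ) if o >= min_occupancy]
    if not qualifying:
        raise ValueError("empty profile: no column reaches the occupancy threshold")
    i, j = qualifying[0], qualifying[-1] + 1
    return Alignment(rows=[(g, s[i:j]) for g, s in aln.rows])


# ---------------------------------------------------------------------------
# profile construction
# ---------------------------------------------------------------------------

def build_profile(aln: Alignment, pseudocount: float = 10.0) -> Profile:
    """Pseudocount-regularized log-odds profile from an alignment.

    Per column, with observed residue counts ``n_r`` over ``N`` non-gap
    residues (frequencies ``f_r = n_r / N``), data weight ``alpha = N - 1``,
    pseudocount weight ``beta``, uniform background ``q = 1/20`` and the
    substitution-matrix prior ``Q_r = sum_a f_a P(r|a)`` (``P(r|a)`` the
    conditional substitution probabilities implied by BLOSUM62)::

        p_r     = (alpha * f_r + beta * Q_r) / (alpha + beta)
        score_r = log2(p_r / q)

    A single-sequence profile (``alpha = 0``) therefore reduces to the
    BLOSUM62 row of each residue, in half-bit-derived units, and observed
    frequencies take over as the alignment deepens.  A column of a single
    residue scores that residue strictly highest.  ``X`` contributes no
    counts and scores a fixed small penalty in every column.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    L = aln.length
    counts = np.zeros((L, 20), dtype=np.float64)
    aa_index = {aa: i for i, aa in enumerate(AA_ORDER)}
    for _, s in aln.rows:
        for c, ch in enumerate(s):
            if ch != "-" and ch != "X":
                counts[c, aa_index[ch]] += 1.0
    n_col = counts.sum(axis=1, keepdims=True)
    occupied = n_col[:, 0] > 0
    q = BACKGROUND_FREQ
    f = np.divide(counts, n_col, out=np.zeros_like(counts), where=n_col > 0)
    prior = f @ BLOSUM62_CONDITIONAL
    alpha = np.maximum(n_col - 1.0, 0.0)
    p = (alpha * f + pseudocount * prior) / (alpha + pseudocount)
    scores = np.zeros((L, 21), dtype=np.float64)
    with np.errstate(divide="ignore"):
        scores[:, :20] = np.where(occupied[:, None], np.log2(p / q), 0.0)
    scores[:, X_INDEX] = X_SCORE

    consensus = np.full(L, -1, dtype=np.int64)
    consensus[occupied] = counts[occupied].argmax(axis=1)
    return Profile(
        length=L,
        scores=scores,
        consensus=consensus,
        source_gene_ids=frozenset(aln.gene_ids),
    )


def single_sequence_profile(record: ProteinRecord) -> Profile:
    """BLOSUM62 row profile of one sequence (plain-search control mode)."""
    idx = encode(record.sequence)
    scores = BLOSUM62[idx.astype(np.int64), :].astype(np.float64)
    scores[:, X_INDEX] = np.minimum(scores[:, X_INDEX], X_SCORE)
    return Profile(
        length=len(record.sequence),
        scores=scores,
        consensus=idx.astype(np.int64),
        source_gene_ids=frozenset({record.gene_id}),
    )


# ---------------------------------------------------------------------------
# gapped local search (Gotoh, profile columns vs subject residues)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _gotoh_local(S, consensus, subject, blosum, gap_open, gap_extend):  # pragma: no cover
    L = S.shape[0]
    M = subject.shape[0]
    NEG = -1e30
    H = np.zeros((L + 1, M + 1), dtype=np.float64)
    E = np.full((L + 1, M + 1), NEG, dtype=np.float64)  # gap in subject
    F = np.full((L + 1, M + 1), NEG, dtype=np.float64)  # gap in profile
    ptrH = np.zeros((L + 1, M + 1), dtype=np.uint8)  # 0 stop 1 diag 2 E 3 F
    ptrE = np.zeros((L + 1, M + 1), dtype=np.uint8)  # 1 from H, 0 from E
    ptrF = np.zeros((L + 1, M + 1), dtype=np.uint8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, L + 1):
        for j in range(1, M + 1):
            eo = H[i - 1, j] - gap_open
            ee = E[i - 1, j] - gap_extend
            if eo >= ee:
                E[i, j] = eo
                ptrE[i, j] = 1
            else:
                E[i, j] = ee
                ptrE[i, j] = 0
            fo = H[i, j - 1] - gap_open
            fe = F[i, j - 1] - gap_extend
            if fo >= fe:
                F[i, j] = fo
                ptrF[i, j] = 1
            else:
                F[i, j] = fe
                ptrF[i, j] = 0
            diag = H[i - 1, j - 1] + S[i - 1, subject[j - 1]]
            h = 0.0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    n_match = 0
    n_ident = 0
    n_pos = 0
    i = bi
    j = bj
    state = 0  # 0 in H, 1 in E, 2 in F
    while i > 0 and j > 0:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                n_match += 1
                s_idx = subject[j - 1]
                c_idx = consensus[i - 1]
                ident = c_idx == s_idx and s_idx != 20
                if ident:
                    n_ident += 1
                if ident or (c_idx >= 0 and blosum[c_idx, s_idx] > 0.0):
                    n_pos += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            if ptrE[i, j] == 1:
                state = 0
            i -= 1
        else:
            if ptrF[i, j] == 1:
                state = 0
            j -= 1
    return best, i, bi, j, bj, n_match, n_ident, n_pos


def align_profile_to_sequence(
    profile: Profile,
    record: ProteinRecord,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Optional[SearchHit]:
    """Best gapped local alignment of a profile against one sequence.

    Identity is the fraction of aligned columns whose subject residue equals
    the column consensus; positives additionally count conservative changes,
    i.e. columns whose (consensus, subject) substitution-matrix score is
    positive (identical pairs always count).  Returns None when the optimal
    local score is not positive.
    """
    subject = encode(record.sequence).astype(np.int64)
    score, qs, qe, ss, se, n_match, n_ident, n_pos = _gotoh_local(
        profile.scores, profile.consensus, subject, BLOSUM62,
        gap_open, gap_extend
    )
    if score <= 0.0 or n_match == 0:
        return None
    return SearchHit(
        subject_gene_id=record.gene_id,
        aligned_interval_query=(qs, qe),
        aligned_interval_subject=(ss, se),
        identity=n_ident / n_match,
        positives=n_pos / n_match,
        query_coverage=n_match / profile.length,
        uncovered_query=profile.length - n_match,
        raw_score=float(score),
    )


def search_profile(
    profile: Profile,
    db: ProteomeSet,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> List[SearchHit]:
    """One best local hit per database sequence with positive raw score."""
    hits = []
    for gid in sorted(db.records):
        hit = align_profile_to_sequence(
            profile, db.records[gid], gap_open, gap_extend
        )
        if hit is not None:
            hits.append(hit)
    hits.sort(key=lambda h: (-h.raw_score, h.subject_gene_id))
    return hits


def filter_hits(
    hits: Iterable[SearchHit], criteria: FilterCriteria
) -> List[SearchHit]:
    """Apply the four keep criteria; every bound is inclusive."""
    return [
        h
        for h in hits
        if h.uncovered_query <= criteria.max_uncovered
        and h.query_coverage >= criteria.min_coverage
        and h.identity >= criteria.min_identity
        and h.positives >= criteria.min_positives
    ]


# ---------------------------------------------------------------------------
# the iterative search
# ---------------------------------------------------------------------------

def _validate_rounds(rounds: Sequence[RoundConfig]) -> None:
    if not rounds:
        raise ValueError("need >=1 round")
    for prev, nxt in zip(rounds, rounds[1:]):
        if not prev.criteria.is_stricter_or_equal(nxt.criteria):
            raise ValueError(
                "round criteria must be monotonically non-stricter "
                "across rounds"
            )


def _members_newick(members: List[ProteinRecord]) -> str:
    """Decorative neighbor-joining topology on pairwise identity distances."""
    if len(members) == 1:
        return f"({members[0].gene_id});"
    aln = align_sequences(members)
    if len(members) == 2:
        a, b = aln.rows
        d = 1.0 - pairwise_identity(a[1], b[1])
        return f"({a[0]}:{d / 2:.4f},{b[0]}:{d / 2:.4f});"
    from skbio import DistanceMatrix
    from skbio.tree import nj

    ids = aln.gene_ids
    n = len(ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - pairwise_identity(aln.rows[i][1], aln.rows[j][1])
            dm[i, j] = dm[j, i] = d
    tree = nj(DistanceMatrix(dm, ids))
    return str(tree).strip()


def iterate_search(
    root: ProteinRecord,
    db: ProteomeSet,
    rounds: Sequence[RoundConfig] = DEFAULT_ROUNDS,
    pseudocount: float = 10.0,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    with_topology: bool = False,
) -> GeneTree:
    """Grow a gene similarity tree around ``root`` over the given rounds.

    Each round aligns the current members (root first), clusters them at the
    round's identity threshold (the root is always retained), trims ragged
    ends, builds a profile and searches the database; hits passing the
    round's criteria join the member set with the hit that recruited them.
    Deterministic given inputs and configuration.
    """
    _validate_rounds(rounds)
    members: Dict[str, ProteinRecord] = {root.gene_id: root}
    hits: Dict[str, SearchHit] = {}
    for rnd in rounds:
        recs = [root] + [
            members[g] for g in sorted(members) if g != root.gene_id
        ]
        aln = align_sequences(recs)
        aln = cluster_representatives(
            aln, rnd.cluster_identity, keep=(root.gene_id,)
        )
        aln = trim_alignment(aln, rnd.trim_occupancy)
        profile = build_profile(aln, pseudocount=pseudocount)
        found = search_profile(profile, db, gap_open, gap_extend)
        for hit in filter_hits(found, rnd.criteria):
            gid = hit.subject_gene_id
            if gid == root.gene_id:
                hits.setdefault(gid, hit)
            elif gid not in members:
                members[gid] = db.records[gid]
                hits[gid] = hit
    organisms = {g: members[g].organism_id for g in members}
    newick = None
    if with_topology:
        newick = _members_newick(
            [root] + [members[g] for g in sorted(members) if g != root.gene_id]
        )
    return GeneTree(
        root_gene_id=root.gene_id,
        member_gene_ids=set(members),
        hits=hits,
        organisms=organisms,
        newick=newick,
    )
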
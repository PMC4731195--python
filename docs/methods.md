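# Methods

This note documents the models, numerical choices and limitations behind
`promispred`. The pipeline has four stages — homolog recruitment,
promiscuity-matrix assembly, direct pairing, and FBA-based indirect
pairing — plus synthetic-data generators that make every stage testable
without external databases.

## Homolog recruitment (iterative profile search)

Around each root gene the engine runs, per round: multiple alignment →
clustering → end trimming → profile construction → gapped local search →
criterion filtering. The recruited member set is what downstream stages
consume; the optional Newick topology (neighbor joining on pairwise
identity distances) is decorative.

**Multiple alignment.** Deterministic center-star anchored on the root:
each member is globally aligned to the root under BLOSUM62 with affine
gaps (open 11, extend 1), and pairwise gaps are merged "once a gap, always
a gap" relative to the root. This is a classical O(k·n²) progressive
scheme whose accuracy is sufficient here because profiles are rebuilt
every round from re-recruited members; a full progressive aligner with a
guide tree would change nothing downstream on the fixtures this package
targets. Ungapping any row always reproduces the input sequence.

**Clustering.** Greedy incremental clustering at 90% ungapped identity
(identical aligned residue pairs over the shorter ungapped length). Rows
are visited root-first, then by descending length with lexicographic tie
break, so the operation is deterministic and idempotent; the root is
always retained. Purpose: stop near-identical variants from dominating
the profile (sampling-bias control).

**Trimming.** The retained columns form the contiguous interval from the
first to the last column with ≥ 50% non-gap occupancy. Interior columns
are never touched. Residues of ragged overhangs falling outside the
interval are dropped from the profile (that is the point of trimming — a
compact profile recruits distant homologs better); the underlying protein
records are unaffected. An alignment with no qualifying column is an
error ("empty profile").

**Profile scores.** Per column, with counts n_r over N non-gap residues,
frequencies f_r = n_r/N, data weight α = N−1 and pseudocount weight
β = 10:

    Q_r     = Σ_a f_a · P(r|a)          (BLOSUM62-implied conditionals)
    p_r     = (α·f_r + β·Q_r) / (α+β)
    score_r = log2(p_r / q),   q = 1/20

P(r|a) ∝ q_r·2^(B[a,r]/2) comes from reading BLOSUM62 as half-bit
log-odds of its target frequencies. Consequences: a single-sequence
profile (α = 0) is exactly the BLOSUM62 row of each residue in bits (the
classical first search round), and observed frequencies dominate as the
alignment deepens. A column of one residue always scores that residue
strictly highest. `X` contributes no counts and scores −1 in every
column. The alternative — uniform-background pseudocounts — was rejected
because it gives every mismatch the same mild penalty regardless of
conservativeness, which destroys the score drift needed to extend local
alignments through genuinely homologous low-identity regions.

**Local search.** Gotoh affine-gap local alignment of profile columns
against subject residues (gap open 11, extend 1), one best hit per
subject, implemented as a numba kernel. Per hit: identity = aligned
columns whose subject residue equals the column consensus (majority
count, ties to the lexicographically smallest residue) over aligned
columns; positives additionally count conservative changes, i.e. pairs
with BLOSUM62(consensus, subject) > 0, identical pairs always included;
coverage = aligned columns / profile length; uncovered = profile length −
aligned columns. Hits need a strictly positive raw score; there is no
E-value gate — acceptance is governed by the four keep criteria alone.

**Keep criteria and rounds.** All thresholds inclusive. The final round
uses uncovered ≤ 100, coverage ≥ 0.60, identity ≥ 0.15, positives ≥ 0.30.
Earlier rounds are configurable defaults chosen to relax monotonically
into the final gate (round 1: 50/0.70/0.30/0.45; round 2:
75/0.65/0.22/0.37); non-monotone schedules are rejected at run time.
Members accumulate across rounds and each non-root member stores the hit
that recruited it; since criteria only relax, every stored hit also passes
the final-round gate.

**Plain-search control.** The baseline mode searches each target's single
sequence (no clustering, trimming or iteration) and keeps hits at a
conventional stringent homology cutoff — identity ≥ 0.35, positives
≥ 0.50, coverage ≥ 0.80, uncovered ≤ 50, configurable. It exists to
quantify what the iterative permissive search adds.

## Promiscuity matrix

Candidate promiscuous functions of a root = union of its tree members'
annotated functions, minus the root's own primary functions (keeping
primaries would create self-predictions downstream). Each function keeps
the highest-recruitment-identity member as provenance. When a candidate
function matches a subunit role of a declared enzyme complex, the
whole-complex function is added as well (the subunit entry is kept; the
expansion is idempotent). Function identity is exact string match — no
fuzzy EC handling.

## Direct pairing

For every metabolic gene in scope (both target and replacer roles are
restricted to genes whose primary functions are metabolic), each of its
primary functions is matched against all promiscuous matrix entries;
matches yield (target, replacer, function) pairs, deduplicated, self-pairs
excluded. Pairs whose replacer already carries the target's function as a
primary annotation are retained and flagged `isozyme_by_annotation` — such
annotation-level isozymes are informative, not artifacts. Descriptive
statistics: distinct replacers per target (with histogram) and the set of
reciprocal pairs (both orientations present).

## Flux balance analysis and indirect pairing

The model is a plain stoichiometric list: reactions with bounds, boolean
GPR rules (`and`/`or`/parentheses, case-insensitive keywords; empty rule =
not knockable; genes absent from all GPRs simply cannot be knocked out),
a biomass reaction and named media. FBA maximizes biomass flux subject to
S·v = 0 and the bounds, solved with HiGHS via `scipy.optimize.linprog`;
optimal solutions satisfy ‖S·v‖∞ ≤ 1e-9. An unbounded objective raises
(it signals a missing exchange constraint). Media store uptake
magnitudes; applying a medium closes every exchange governed by any
medium and opens the listed ones as negative lower bounds, leaving
secretion bounds untouched.

Growth means biomass flux ≥ ε with ε = 1e-6 flux units ("nominal
production of biomass"); fluxes in [ε/10, ε) trigger a warning so
borderline calls are visible. A gene is *conditionally essential* when
its knockout abolishes growth on the minimal medium but not on the rich
one; the wild type must grow on minimal medium or classification errors
out.

The rescue screen considers matrix entries whose function is non-native
(not a primary annotation of any scope gene) and has at least one catalog
reaction not already carried — same stoichiometry up to positive scaling —
by a gene-associated model reaction. For each conditionally essential
target (others are skipped with a logged reason), the target is knocked
out on minimal medium and each candidate function's reactions are added
together (per-reaction mode available); added reactions keep their
catalog bounds rather than being opened to ±∞. Candidates referencing
metabolites absent from the model are skipped and logged: a bypass must
connect existing chemistry, and admitting unknown metabolites risks
mass-from-nothing rescues. A pair is emitted iff growth_before < ε ≤
growth_after.

## Significance tests

Overlap: upper-tail hypergeometric P(X ≥ k), summed in log space
(`logsumexp` over `hypergeom.logpmf`), exact against draw enumeration for
all N ≤ 12 in the test suite. The unit of the draw (genes or pairs) is
the caller's choice — both are supported because published analyses mix
the two. Reciprocity: P(all m pairs reciprocal) = rᵐ, with r estimated as
the fraction of ordered pairs whose reverse is also predicted when not
supplied. No multiple-testing machinery is attached to these tests.

## Synthetic data: what it emulates, what it does not

`generate_proteome` draws background proteins i.i.d. uniform over the 20
residues (length 150 by default), so chance pairwise identity stays near
5%, far below the 0.15 identity gate, and plants homologs by per-position
Bernoulli preservation at a target identity with replacements drawn from
the BLOSUM62 conditional substitution distribution. The conservative
replacement model matters: real distant homologs show elevated
"positives", and a uniform-replacement mutant at 20–25% identity would be
indistinguishable from noise under a substitution-matrix scorer — it
emulates random corruption, not divergence. The default study condition
is 3 organisms × 50 genes with planted links at 0.45/0.35/0.25/0.20
identity; a stepping-stone variant (two 0.45 hops, length 300 to
concentrate realized identities, composing to ~0.25 root-to-end identity)
exercises multi-round recruitment specifically. The generators do not
mimic real amino-acid composition, domain architecture, indels (planted
homologs are substitution-only), or realistic annotation noise — passing
tests demonstrate the machinery recovers planted signal under controlled
conditions, not field performance on real proteomes.

`generate_toy_gem` builds the canonical conditional-essentiality
topology: glucose feeds biomass directly and, through a three-step chain,
a vitamin that biomass needs at a catalytic coefficient (0.01); minimal
medium supplies only glucose, rich medium also the vitamin. The first
chain gene is the knockout target; the catalog holds exactly one
glucose→vitamin bypass (the planted rescue) and four decoys covering the
rejection paths: a duplicate of a downstream gene-associated step
(already carried), a wrong-direction and an unreachable internal
reaction, and a reaction over metabolites the model lacks.

## Determinism and reproducibility

Every stage is a pure function of (inputs, configuration, seed): fixed
iteration orders, sorted outputs, no timestamps in output files (the run
log file carries stage/level/message; timestamps appear only on the
stderr logger). Two runs with identical config produce byte-identical
output directories. Fixture generation derives all child seeds through
`numpy.random.SeedSequence`.

## Problem sizes

Defaults used by the test suite and the acceptance script: proteomes of
150 genes × 150 residues (3 organisms), 50 root trees × 3 rounds per
pipeline run, 10 fixture seeds for the recovery battery, a 9-reaction toy
model, and 1,000 randomized models for the reaction-addition monotonicity
property. These sizes make a full run take on the order of a minute on a
single CPU while keeping every planted-signal margin several standard
deviations wide.

## Known limitations

- The center-star aligner does not refine alignments iteratively; deep
  trees with many indels would benefit from a guide-tree aligner behind
  the same `align_sequences` seam.
- Identity/positives are measured against the column consensus, which
  understates identity to any single member of a diverse profile.
- The rescue screen adds candidate functions individually; synergistic
  multi-function rescues are out of scope, as is any flux-variability or
  minimization analysis beyond single-objective FBA.
- GPR evaluation treats unknown gene tokens as present; a knockout of a
  gene absent from all rules is silently a no-op.
- The published genome-scale counts (thousands of direct pairs, ~10²
  indirect pairs) require the full multi-organism annotation database and
  curated GEM and are not reproducible at fixture scale; the package
  demonstrates the method's properties, not those counts.
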
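# Methods

This note documents the models, conventions and numerical choices behind
`qsoxphylo`, and what its synthetic benchmarks do and do not demonstrate.

## Domain extraction

Domains are located with PROSITE-style patterns: ordered elements that are a
literal residue, a residue class `[...]`, or a wildcard `x(n)`/`x(n,m)`,
joined by `-` (upper- and lower-case `x` are equivalent).  The matcher is an
exact backtracking engine; its observable contract is fully specified so
results are reproducible:

* a match is a contiguous subsequence satisfying all elements in order;
* `mode="all"` returns one match per distinct (start, end) span, each carrying
  the lexicographically earliest wildcard expansion;
* `mode="first"` returns the leftmost match, ties broken by minimal total
  span, then by earlier (shorter) expansion of earlier wildcards —
  shortest-first keeps domain spans tight;
* the unknown residue `X` in a sequence satisfies wildcards only, never
  literals or classes.

The built-in Trx pattern spans 57–86 residues and the Erv pattern 109–221
(sums of element minima/maxima).  Family membership is pattern-defined: a
sequence is annotated only if it has a Trx match and an Erv match downstream
of it.  When an architecture contains a second, non-catalytic Trx copy, the
Trx annotation is the *first* match — the N-terminal catalytic copy, per the
family's domain-order convention.  The annotated "linker" is the gap between
the Trx match end and the Erv match start, which therefore includes a Trx2
insertion when present; the synthetic default architecture has no Trx2 so
that annotated and true linkers coincide.

## Percent similarity

"Similarity" between two sequences is defined here as
`100 × (aligned residue pairs with positive BLOSUM62 score) / (alignment
columns)` over a global affine-gap alignment.  This definition is declared in
output metadata; other tools report identities or tool-specific similarities,
so absolute values are comparable only within this package.

## Alignment

Pairwise alignment is global Needleman–Wunsch with affine gaps (Gotoh): a gap
of length L costs `gap_open + L·gap_extend`, defaults 10 and 1 with BLOSUM62.
Traceback ties prefer diagonal, then up, then left.  Multiple alignment is
progressive: a neighbor-joining guide tree on p-distances of all pairwise
alignments, then profile–profile affine alignment in guide-tree postorder,
scoring a column pair by the arithmetic mean of substitution scores over
residue pairs with gaps excluded — the simplest defensible profile score.
There is no iterative refinement; the aligner targets desk-scale families
whose conserved cores are ungapped, not heavily indeled datasets.

## Distances and trees

Built-in substitution models are `proportional` (equal exchangeabilities and
frequencies), `dayhoff` and `jtt`, the latter two loaded from packaged
PAML-style text files (lower-triangle exchangeabilities + frequencies).  The
rate matrix is `Q_ab = s_ab π_b`, normalised to one expected substitution per
site per unit time; `P(t) = exp(Qt)` is computed through the symmetric
eigendecomposition available for reversible models.

Pairwise distances use pairwise deletion (sites with a gap or `X` in either
row are dropped for that pair).  The proportional model has the closed form
`d = −(19/20)·ln(1 − (20/19)p)`; empirical models maximise
`Σ_sites ln(π_a P_ab(t))`.  For single pairs the optimum is located on a
log-spaced grid of 160 precomputed transition matrices and polished with
bounded Brent iteration (`xatol` 1e-10).  Distance *matrices* (including the
bootstrap loop) skip the polish and use a three-point parabola on the
log-grid instead; the residual error is ~1e-3 relative, far below bootstrap
noise, and keeps 100-replicate runs fast.  Saturated pairs (closed-form
argument ≤ 0, or optimum at the upper bound) return a configurable cap,
default 10 substitutions/site, with a flag.

Trees are built by Saitou–Nei neighbor joining on the Q-criterion; ties take
the lowest index pair in the current node list (new nodes appended last), and
negative branch-length estimates are clamped to zero with the deficit logged.
A full maximum-likelihood topology search is deliberately not implemented:
NJ over ML pairwise distances under the same named models is deterministic,
fast, and consistent on additive inputs, which the oracle suite verifies
exactly.  Bootstrap resamples alignment columns with replacement to the
original width.  Consensus supports are bipartition frequencies rounded to
integer percent (half up); `majority` keeps splits above 50%,
`majority_extended` greedily adds remaining compatible splits by descending
frequency with lexicographic tie-breaking.  Robinson–Foulds distance is the
symmetric difference of non-trivial bipartition sets.  Duplicate-genus
subsampling ("one representative per genus") is a preprocessing concern and
is not enforced by the tree layer.

## Conservation

The conservation score is sequence-logo information content,
`IC = log₂20 − H(column)` bits, with gaps and `X` excluded from counts and an
optional small-sample correction `e(n) = 19/(2·ln2·n)` (off by default for
large families).  This is an intentional simplification relative to Bayesian
evolutionary-rate estimation: it gives the same qualitative
conserved-versus-variable surface without a rate model.  Conserved regions
are maximal runs of columns with IC ≥ 3.0 bits, allowing at most 1
below-threshold column inside a run and discarding runs shorter than 4
columns; these defaults are calibration choices validated on synthetic
plants and are recorded in output metadata.  Scores map onto a structure via
an ungapped reference row (column → reference residue → chain residue) and
are written into the PDB temperature-factor field.

## Intron coordinates

An internal exon boundary at cumulative CDS offset c has phase `c mod 3` and
codon index `floor(c/3)` — a phase-1/2 intron is assigned to the codon it
interrupts.  This convention is explicit in all outputs because qualitative
descriptions ("at the end of the helix") do not fix it.  Sharing between two
groups of alignment-projected positions uses one-to-one greedy nearest-first
matching within ±tolerance columns, default tolerance 0 with equal phase
required; the tolerance is exposed rather than hard-coded because closely
situated positions are genuinely ambiguous in real data.

## The synthetic-family generator

The generator emulates the statistical structure the analysis assumes.  Each
protein is: N-extension (5–15 residues) + Trx domain (70) [+ optional
non-catalytic Trx2 in flagged clades] + linker (uniform 20–35, free
composition) + Erv domain (160) + C-extension (5–15).  Domains are concrete
expansions of the extraction patterns: slack above the minimum span is shared
among variable wildcards in proportion to their ranges.  Sequences evolve
along a Yule tree (default 40 taxa, birth rate 1, rescaled to root-to-tip
height 0.5 — a deep but alignable family; the real family's divergence is
unknown, so this is a calibration choice) under JTT by per-branch transition
matrices, one draw per site.  The Erv domain can evolve along a different
topology to plant domain discordance.  Indels are not simulated inside
domains, so the true alignment is trivial; length variation comes only from
linkers and extensions.

Invariable positions comprise: every literal and class position of the
patterns (class positions pinned to a deterministic representative residue,
preferring residues unique to their class), the fixed-offset scaffold
preceding each pattern's first variable wildcard, the motif cysteines, and
the clade-assigned motif interiors plus discriminant residue (overwritten per
clade).  Pinning the fixed-offset scaffold serves two purposes: it mimics the
conserved structural core of real domains, and it makes the planted
coordinates the *provable* first pattern match.  Because free wildcard sites
and random linkers can still, rarely, create a spurious earlier match, every
family is validated by scanning each sequence and comparing against truth;
on mismatch the family is regenerated from a derived sub-seed.  The loop is
deterministic in the configured seed and bounded; in practice one attempt
almost always suffices.

Clade labels are the k deepest clades of the Trx tree (repeatedly splitting
the group whose root is closest to the tree root), with default motif
interiors emulating lineage-structured variation: a metazoan-like clade
(CGHC/CRDC, Ser discriminant), a plant-like clade (CPAC/CEEC, His) and a
stramenopile-like clade (CPHC/CQEC, Thr).

Gene models plant `introns_per_gene` introns per gene; a configured fraction
sit at clade-characteristic anchors expressed relative to a domain start (so
they project to identical alignment columns within a clade), drawn without
replacement from a pool shared across clades — different clades therefore
never share an anchor by construction, which is the planted analogue of
lineages with disjoint intron repertoires.  The remainder are uniform per
gene.  Exon CDS lengths always sum to 3·(protein length)+3.

**What passing tests show — and don't.**  The generator has no indels inside
domains, no rate heterogeneity beyond invariable sites, no compositional
drift, and linkers/extensions with i.i.d. composition.  Success on these
families demonstrates correctness of the algorithms under their stated
assumptions (ungapped conserved cores, clade-structured motifs), not
robustness to alignment error or domain-boundary erosion in real data.

## Benchmark problem sizes

The test and acceptance workloads use: 40-taxon default families; 50
additive-matrix NJ recoveries on 8–12 taxa; 20 replicates of 10,000-site
pairs for distance recovery; 20 replicates of 12-taxon, 400-column per-domain
alignments for discordance (planted topologies are maximally discordant
caterpillars with 0.1-substitution internal edges); a 32-leaf balanced tree
(branch length 0.5) with six planted 5-column invariable blocks for region
detection; and two complete 40-taxon, 100-replicate pipeline runs for the
determinism check.  These sizes make every check exact or high-powered while
keeping a full run in tens of seconds.

## Known limitations

* No ML topology search, branch swapping, or Γ rate heterogeneity.
* The progressive aligner does not iterate and is not intended for
  heavily-indeled families.
* Conservation is information content, not an evolutionary-rate posterior.
* Intron detection from genomic DNA, EST assembly and splice-variant calling
  are out of scope; gene models are inputs.
* Secondary-structure elements for intron summaries are user-supplied
  annotations, not predictions.
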
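# Methods

## The model

The package treats a protein family as a modular system: a rigid, structurally
conserved framework plus a set of interchangeable segments delimited by
anchor residues. All conformational information is carried in backbone
torsion space — each residue contributes (phi, psi, omega) in degrees, IUPAC
sign convention, range (−180°, +180°] — and Cartesian coordinates are always
regenerated from torsions by sequential natural-extension-of-reference-frame
(NeRF) construction with fixed idealized internal coordinates:

| bond | Å | angle | degrees |
|---|---|---|---|
| N–CA | 1.458 | N–CA–C | 111.2 |
| CA–C | 1.525 | CA–C–N | 116.2 |
| C–N  | 1.329 | C–N–CA | 121.7 |
| C=O  | 1.231 | CA–C=O | 120.5 |
| CA–CB | 1.521 | C–CA–CB | 110.6 |

Idealization serves the same purpose as running a structure-idealization
protocol before design: it removes the bond-length/angle noise of
experimental coordinates so that torsions from different structures can be
recombined without accumulating strain. The stand-in makes no sequence
changes. The carbonyl O is placed trans to the next residue's N (terminal O
at a fixed 180° torsion from N); CB is placed by the standard improper
(torsion N–C–CA–CB = −122.6°) for every residue except glycine. The
round-trip extract∘rebuild is the identity to well under 0.01°.

Chain breaks are called where the peptide C–N distance leaves [1.2, 1.5] Å;
torsions spanning a break are undefined, and fragments containing a break are
rejected.

## Segmentation and alignment

Anchors are user-supplied template residue indices — the points of maximum
structural conservation; choosing them is a modelling decision, supported by
`anchor_deviation_report` (per-position mean CA deviation across aligned
homologs) but not automated. A scheme names one segment per consecutive
anchor pair, optionally plus single-anchor terminal tails. Shared anchors
belong to both neighbouring fragments for end-frame purposes; for sequence
and torsion assembly each anchor takes phi from the segment on its left and
psi/omega from the segment on its right, so no residue is duplicated.

Homologs are aligned to the template by global sequence alignment (BLOSUM62,
gap open −11 / extend −1) to seed residue pairs, then iterative Kabsch
superposition on paired CA atoms. After each round every seeded pair is
re-evaluated under the refined transform and kept iff its CA–CA distance is
≤3.5 Å; iteration stops when the kept set is stable (cap 50 rounds).
Re-evaluating all pairs (rather than only shrinking the kept set) lets a
skewed early superposition recover. A homolog is rejected, with the anchor
named, if any anchor ends up unmapped — including the case of an insertion
directly at an anchor.

## Graft-and-close and the database gate

Each fragment's torsions replace the template segment's torsions. Because the
fragment comes from a different structure, rebuilding it from the upstream
anchor frame leaves its far end displaced from the template's downstream
anchor. Closure follows the cut-and-reclose idea of cyclic-coordinate-descent
loop building with a deterministic geometry-only engine:

* the chain is cut at the middle fragment residue (`cut="middle"`; an integer
  index or a seeded `"random"` choice are available),
* the left half is built forward from the upstream anchor frame and the right
  half backward from the downstream anchor frame (so the downstream framework
  is never perturbed),
* damped least-squares inverse kinematics over the phi/psi torsions of *both*
  halves (omegas fixed) minimizes the junction mismatch of the cut residue's
  N, CA, C atoms, distributing small corrections over the whole fragment;
  budget 200 iterations, tolerance 0.05 Å per junction atom, with adaptive
  Levenberg damping and a stall cut-off.

Closure converges in a handful of iterations for realistic fragments and can
absorb multi-Ångström mismatches when asked to (the synthetic generator uses
it to plant arbitrary connector conformations). The **closure rmsd** is then
the N, CA, C, O rmsd between the closed fragment and its conformation in the
source structure after optimal superposition (O for the last fragment residue
uses the template-context psi; atoms missing on either side are skipped). A
record enters the database only if it converged *and* its closure rmsd is
strictly below the gate (default 0.2 Å). Non-converged grafts are never
admitted regardless of their rmsd, since their junction would break the
chain. Terminal tails are pinned at a single anchor and need no closure.

Choices the underlying protocol leaves open, fixed here: the rmsd atoms are
N, CA, C, O; superposition precedes the rmsd; both are configurable in code.

## Fragment comparison and clustering

Fragments of one segment are compared sequence-independently: equal lengths
give the backbone rmsd after optimal (Kabsch) superposition; unequal lengths
give the minimum over all contiguous ungapped placements of the shorter
fragment within the longer, with the length difference reported alongside.
This offset-minimum convention is this package's choice; the exact algorithm
of dedicated clustering tools is not reproduced. Clustering is agglomerative
with complete (maximum) linkage on the pairwise rmsd matrix
(scipy.cluster.hierarchy behind the module surface), cut at a radius of
1.0 Å by default — no cutoff is prescribed by the protocol, and 1.0 Å sits
comfortably between the within-group noise and the >3 Å between-group
separations of both the synthetic families and typical loop-conformation
clusters. The representative of a cluster is its member with minimum mean
rmsd to the cluster, ties broken by smallest source id, making the output
invariant to input order.

## Sequence constraints

Homolog filtering: each candidate is globally aligned to the query; identity
is matches over aligned columns excluding terminal gaps, coverage is aligned
query residues over query length. Defaults 35% identity, ≥75% coverage, and
truncation to the top 3,000 sequences ordered by identity descending (the
ordering of "top" is this package's documented choice). BLAST itself is not
run; candidate sets are supplied by the user or the fixture generator.

PSSM construction (the underlying protocol defers details to its stability-
design tooling; the scheme here is fixed so results are reproducible without
PSI-BLAST): Henikoff position-based sequence weights over the alignment (gap
as a 21st symbol), per-column weighted frequencies over the 20 amino acids,
background = BLOSUM62 marginal frequencies, pseudocount blend
f′ = (N·f + w·b)/(N + w) with N the number of contributing sequences and
w = 50 effective counts by default, score = 2·log₂(f′/b) rounded to integers
(half-bit units) and clipped to ±16. Rows cover exactly the reference row's
ungapped positions. Matrices serialize to the PSI-BLAST ASCII dialect and can
be imported from it, so externally generated profiles drop in. `allowed
residues` at a position are those scoring ≥0 by default and never empty (the
best-scoring residue is returned, with a warning, if the threshold excludes
everything).

## Assembly, catalytic fixation, steric screen

Because every database record stores torsions already closed onto the
template's anchor frames, assembling a recipe is a splice followed by one
idealized rebuild: candidates are continuous by construction (all peptide
bonds exactly 1.329 Å). Recipes are enumerated exhaustively in lexicographic
order when the combinatorial count fits the request, otherwise sampled
uniformly without replacement over the mixed-radix recipe index space from a
single seed. Sampling without replacement is this package's choice; the
fragment-choice distribution is not prescribed by the protocol.

Catalytic fixation re-states the design constraint that active-site residues
must not move: after superposing the candidate onto the template via the
shared anchor frames, every constrained residue's backbone atoms must lie
within tolerance (default 0.5 Å) of the template's; a constrained position
that fell inside a replaced segment fails the check with a reason. The steric
screen counts backbone/CB atom pairs at residue separation ≥3 closer than
2.5 Å (k-d tree); it is plumbing standing in for all-atom design, not an
energy model.

## The fuzzy-logic objective

Per criterion x with ensemble mean μ and *population* standard deviation σ
(the population/sample choice is not prescribed; population is used and a
constant ensemble is rejected), the fitness is f = 1/(1+e^((x−μ)/σ)), with x
and μ negated for undesirable criteria. f(μ) = 0.5 exactly; f is strictly
monotone; the exponent is saturated beyond |z| > 700 so f stays strictly
inside (0, 1) in floating point. The objective is the plain product of the
fitness terms. The exponent is read as (x−μ)/σ — the only reading consistent
with f(μ) = 0.5 and with fitness approaching 1 below the mean. Energy-mode
ranking sorts ascending on a named feature column; criteria like packing or
shape complementarity are supplied by the user as feature columns, not
computed here.

## The synthetic generator

`make_toy_family` emulates the situation the pipeline assumes: homologs with
identical helical anchor blocks (phi −57°, psi −47°, 5 residues per block,
conserved sequences) joined by variable loops. Per segment, each planted
conformational group has a base torsion string: group 0 is the template's own
loop; further groups are random motif strings (drawn from an 8-motif phi/psi
palette with ±10° jitter) *closed onto the template's anchor frames* at
generation time and accepted only if their backbone rmsd to every previously
planted group exceeds 3.5 Å. Homolog loops are group bases plus clipped
Gaussian angular noise (σ = bound/2, hard clip at the bound, so
`torsion_noise=5` means perturbations never exceed 5°), re-closed so that
every homolog presents the template's framework geometry, then each homolog
is assembled, rebuilt and given a random rigid motion. Defaults: 10
structures, 4 segments, loop lengths 6–12, 3 groups, 2° noise.

What the toys do not emulate: real loops are not random motif strings; real
frameworks flex; real sequences covary with structure (toy loop sequences are
random, so sequence constraints on loops are uninformative); there are no
side chains beyond CB and no energetics. Passing tests therefore demonstrate
the correctness of the geometric and combinatorial machinery — closure,
gating, clustering, assembly, ranking — not that designed proteins would
fold. `make_toy_msa` plants exact pairwise identities by substituting a
counted number of positions (error if a target is unreachable within 2
percentage points on a short reference).

## Numerical choices and degenerate inputs

Kabsch superposition rejects point sets with fewer than 3 points or collinear
geometry; the returned rotation is always proper. Alternate locations resolve
to the highest occupancy (ties toward altloc 'A'); residues missing any of
N/CA/C are dropped with a logged warning and a recorded break. The strict
'<' of the admission gate means a closure rmsd of exactly 0.2 Å is rejected,
and a gate of 0 admits nothing but exact-zero closures. Fragment databases
persist as a metadata file plus one JSON-lines file per segment (torsions to
0.001°, coordinates to 0.001 Å); saving the same database twice is
byte-identical, and a format-version mismatch on load fails naming both
versions. All stochastic steps (sampling, random cut choice, fixture
generation) consume explicit seeds.

## Scale of the shipped analyses

The test-suite and acceptance analyses run on families of 5–20 structures
with 2–4 segments and loops of 6–12 residues — ample to exercise every code
path, including the 20-fragments-per-segment configuration whose
combinatorial count is 160,000. The published application-scale inputs
(hundreds of family structures, thousands of sequences) differ only in size,
not in code path.

## Known limitations

* Closure quality is measured purely geometrically; there is no energy
  term, so a closed fragment can pass the gate while clashing (the steric
  screen catches this later, at assembly time).
* The unequal-length rmsd is an offset minimum, not an optimal
  sequence-independent alignment; for length differences much larger than
  those shipped it can overestimate similarity.
* Sequence-guided alignment assumes the framework is recognizably conserved
  in sequence; families with fully diverged framework sequences would need an
  external structural aligner.
* Single chains only; no insertion-code arithmetic beyond preservation for
  reporting; mmCIF is not read.
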
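# Methods

## Scope and model

`aaokit` operationalises a candidate-selection and characterisation workflow
for aryl-alcohol oxidases (AAOs) within the GMC oxidoreductase superfamily.
The homology search itself is out of scope: 12-column tabular hit files
(the common BLAST `outfmt 6` dialect) are inputs. Likewise, maximum-
likelihood tree inference and external aligners are not reimplemented; the
built-in progressive aligner and neighbor joining are desk-scale stand-ins,
and externally computed aligned FASTA or Newick files can be supplied
wherever an MSA or tree is consumed.

## Screening

Two predicates are composed:

* **Hit filter** — identity strictly > 35 % and e-value strictly < 10⁻¹⁰.
  The inequalities are strict by design. A subject passes if *any* of its
  hits passes (per-hit, not best-hit-only). Sequences absent from the hit
  table are screened on features alone and flagged `no_hit_evidence` rather
  than dropped, so the audit trail stays complete.
* **Feature check** — all four of: ADP-binding motif (`G-x-G-x(2)-G-x(18)-E`)
  and PS00623 with match *start* in the N-terminal window; PS00624 with
  start in the central window; histidine at both catalytic anchor
  positions. The region windows are fractions of query length — N-terminal
  = first 40 %, central = [30 %, 75 %) — deliberately permissive readings of
  "N-terminal region" and "central portion" (PS00623 sits near residue ~100
  and PS00624 in the central third-to-three-quarters of a ~560-residue
  enzyme); both are configurable. Sequences shorter than 100 residues are
  reported `too_short`, not raised.

Signature matching is exact (mismatch-free); no published mismatch allowance
exists for this screen, so none is invented.

## PROSITE engine

The parser covers residue literals, `x`, `[...]` alternative sets, `{...}`
exclusion sets, `(n)` / `(n,m)` repeats and `<` / `>` anchors. Scanning
reports every match start (overlaps included); at one start a range-repeat
pattern reports its non-greedy (leftmost-shortest) match — screening needs
existence and location, not maximal spans. Sequence letter `X` matches only
the wildcard element. An exhaustive width-enumeration scanner with the same
contract serves as the test oracle.

## Reference anchoring

Residue equivalences ("the query position equivalent to *Pe*AAO Y92") come
from pairwise global alignment (Needleman–Wunsch/Gotoh affine, BLOSUM62,
gap open 10, extend 0.5 — a gap of length k costs open + (k−1)·extend)
of query against the kingdom's reference, not through the MSA: pairwise
anchoring is order-independent and sufficient for the typing rules.
Numbering is 1-based on the reference *as supplied*; no signal-peptide
arithmetic is attempted, so callers must supply mature or full-length
sequences consistently. Kingdom routing uses the per-sequence kingdom
annotation when present, otherwise the best-scoring reference. A query gap
at an anchor column yields UNMAPPED and downstream `unclassified`.

## Typing rules

Position *a* (Y92-equivalent) is the primary classifier; position *b*
(F501-equivalent) only sets a consistency flag, because the available
evidence describes per-type *distributions* at *b*, not a second
independent rule. Residue classes are fixed artifact definitions:
aromatic {F,W,Y}; aliphatic {A,V,L,I,M} (glycine excluded — it anchors
fungal type III by itself); uncharged polar {S,T,N,Q,C}; positive {K,R,H}.
Rule order resolves class overlaps: bacterial A/G claim type I before the
aliphatic class is tested, and bacterial type II admits Y alongside F at
*a* (the Geminicoccaceae exception) without requiring taxonomy input.
Leucine at the fungal *a* position classifies as type II even though it is
common in basidiomycete AAOs; the call is recorded with its rule id so such
cases are auditable. Every residue pair maps to exactly one of
{I, II, III, arthropod, ambiguous}; UNMAPPED at either position gives
`unclassified`.

## Logo statistics

R = log₂20 − (H_obs + e(n)), e(n) = (s−1)/(2·ln2·n) with s = 20, clamped at
0; letter height = frequency × R. Gaps are excluded from counts rather than
treated as a 21st symbol, and the small-sample correction defaults to on
for columns with fewer than 50 observations (both configurable) — standard
WebLogo-style conventions, since no alternative settings are published for
this family. Logo columns are numbered in reference coordinates via the
reference row of the MSA.

## Progressive MSA

Guide tree: neighbor joining on 3-mer set distances
(1 − |shared|/min(|A|,|B|)). Merging: profile–profile Gotoh DP where the
column score is f_Aᵀ·BLOSUM62·f_B over residue frequencies (gap mass
contributes nothing, so gap-heavy columns score low); ties prefer the
diagonal, then a gap in the second profile. The DP kernel is optionally
numba-compiled; the pure-Python kernel is the reference implementation and
is used automatically when numba is unavailable. Two-sequence input
delegates to the pairwise aligner. The aligner makes no claim to match
MUSCLE/MAFFT output; it exists so the logo and tree stages run
self-contained, and degap(row) always reproduces the input sequences.

## Phylogeny

p-distance = mismatches / mutually ungapped columns; Poisson option
d = −ln(1−p), with p = 1 an error. Neighbor joining uses the Studier–Keppler
Q-criterion; ties are broken deterministically by the lowest (row, column)
index pair; the final three nodes are joined by the closed form. Negative
branch-length estimates are clamped to zero with the deficit moved to the
sibling so pair distances are preserved — on additive input no clamping
occurs and the unique generating tree (topology and lengths) is recovered
exactly. Outgroup rooting requires that a single edge separates outgroup
from ingroup; the separating branch is split equally. Monophyly of a label
is judged on its MRCA clade (single-member labels monophyletic by
convention), with purity = label leaves / clade leaves. An optional
column-resampling bootstrap (seeded) attaches support to reference-tree
bipartitions; ML inference and ultrafast bootstrap remain external-tool
territory.

## Structure comparison

Cα traces are read with gemmi (PDB/mmCIF; first model, first altloc,
longest protein chain unless a chain is named; residues lacking Cα are
skipped). Pairing is by global sequence alignment of the one-letter
sequences, excluding gap columns and non-standard residues. Superposition
is the Kabsch SVD fit with reflection correction, followed by iterative
rejection of pairs beyond `reject_multiplier` (default 2.0) × current RMSD,
at most 5 rounds — mirroring common align-and-refine protocols. Published
per-pair RMSD benchmarks for the crystal structures this protocol targets
depend on the (unnamed) superposition program and its settings, so pair
counts should be read as protocol-dependent; the test suite exercises the
protocol on synthetic rigid-motion/deletion constructions instead of
downloaded structures.

## Synthetic data generator

The generator emulates the screened population: GMC-like proteins of
~560 residues (~600 for arthropods, which run longer) carrying the ADP
motif near the N-terminus (start 5), PS00623 in the N-terminal window,
PS00624 in the central window, catalytic histidines and type-defining
residues at reference-equivalent positions. At default lengths the anchor
positions coincide with the published reference numbering (PeAAO
92/501/502/546; ShAAO 92/455/456/500; CpAAO 128/535); the CpAAO catalytic
positions are not individually published and are placed at b+1 and b+45 by
analogy with the other two references. At non-default lengths all positions
scale proportionally.

Generation is hierarchical: per kingdom, an independent random ancestor
(uniform background over the 20 residues; configurable table) that doubles
as the kingdom's reference sequence; per type, an ancestor diverged from it
at `type_divergence` (default 0.25 per site) so that types are separated in
sequence space and the monophyly stage has signal; per member, divergence
at `mutation_rate` (default 0.05; study conditions also use 0 and 0.2).
Mutation draws a uniform replacement that may equal the original, so the
effective substitution rate is 19/20 of nominal. Protected from mutation
are the *constrained* positions of each planted motif (wildcard positions
mutate freely — any residue still matches, and logo columns at wildcards
then show genuine erosion), the typing positions and the catalytic
positions; ground-truth labels therefore survive any mutation rate.
Sampled instances are drawn uniformly per pattern element; backgrounds are
rescanned and resampled until each signature matches only at its planted
coordinates. Decoys ablate exactly one feature: catalytic-His → alanine at
both positions, or a motif replaced by background verified by rescanning to
contain no match anywhere. Outgroup stand-ins (for rooting) are a separate
ancestor with the shared GMC features plus small within-pair divergence.
Everything is reproducible byte-for-byte from the seed.

What the generator does **not** model: indels, rate heterogeneity across
sites, realistic amino-acid composition, signal peptides, or database
search noise. Passing tests therefore demonstrate the pipeline's logic and
bookkeeping — exact feature detection, anchoring, rule application, tree
and superposition machinery — not performance on real proteomes, where
alignment ambiguity and compositional bias will lower recovery rates.

## Problem sizes and numerics

The test suite and the acceptance script use 315 planted sequences
(45 per kingdom/type cell) plus 60 decoys for screening and typing, 50
random 4–12-taxon additive matrices for neighbor joining, ≥100 random
pattern/sequence pairs for the motif engine, and 120–150-residue synthetic
chains for superposition — sizes chosen so every stage's behaviour is
measured on comfortably more cases than it has rules. Numeric tolerances:
NJ exactness and Kabsch orthonormality at 1e-9; logo worked values at 1e-3;
superposition RMSD on PDB-file fixtures at 5e-3 Å (three-decimal coordinate
precision). Typing recovery under 20 % background mutation is slightly
below 100 % because pairwise anchoring can occasionally misplace a typing
column between highly diverged sequences; this is a property of
alignment-based anchoring, not of the rules.
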
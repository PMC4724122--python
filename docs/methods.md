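# Methods

This note documents the models, formulas, numerical choices and known
limitations behind alnkit's engines, in the order a pipeline would use them:
alignment I/O, conservation, editing, phylogenetics, dot plots, and
GFF3-driven alignment stacking.

## Sequences and scoring

Residues are case-folded on ingest; `-` and `.` are both accepted as gaps
and normalised to `-` (Stockholm and MSF conventionally use `.`, FASTA `-`).
RNA input is normalised U→T. Nucleotide sequences may carry IUPAC ambiguity
codes; `N` is never treated as an exact match anywhere.

Protein scoring defaults to the published BLOSUM62 table (loaded from
biopython's copy); DNA scoring defaults to +5 match / −4 mismatch over the
IUPAC alphabet, with every ambiguity code — including N against itself —
scoring as a mismatch. Both defaults are replaceable by any NCBI-format
matrix file. A residue pair is called *conserved* when its substitution
score is strictly positive and the residues differ; this positive-score rule
is a design choice (the exact/conserved/mismatch trichotomy is conventional
but not formally standardised) and is applied consistently in the stack
classifier and the dot-plot/alignment-view colour logic.

Translation uses the standard codon table only; incomplete trailing codons
are dropped, stops are emitted as `*`, and codons containing ambiguity codes
or gaps become `X`. Alternative genetic codes are out of scope.

## Alignment formats

The four readers/writers (Stockholm 1.0, GCG MSF, Selex, aligned FASTA)
normalise to one in-memory structure: named, equal-length gapped rows with
optional 1-based inclusive `name/start-end` coordinates. Coordinates are
only parsed from a name suffix when they are consistent with the row's
non-gap residue count; otherwise the suffix stays part of the name. Writers
are deterministic byte-for-byte, which is what makes the four-way conversion
closure testable.

MSF specifics: 50 residues per line in 10-symbol groups, `.` as the gap on
write (translated back on read), and GCG checksums — per sequence,
`sum_i ((i mod 57) + 1) * ascii(c_i) mod 10000`, with the global checksum the
sum of the per-sequence ones mod 10000. Stockholm `#=GF/#=GS/#=GC/#=GR`
markup is preserved verbatim for round-trip (its semantics are not
interpreted), except that `#=GS <row> SC <value>` lines are additionally
parsed into per-row scores for score-based filtering. Selex is read as
whitespace-separated name/sequence lines, `#` comments ignored, multi-block
files concatenated by name. Duplicate full row names are an error rather
than a silent merge — a curation tool must not lose rows.

## Conservation

Percent identity of a column is the frequency of its modal residue; gaps are
never modal. The denominator includes or excludes gap rows depending on the
gap mode. BLOSUM62 similarity is the mean substitution score over all
unordered pairs of the column's non-gap residues, self-pairs excluded;
columns with fewer than two residues score 0. (Whether the original
similarity statistic used ordered pairs or included self-pairs is not
documented anywhere we could verify; unordered-without-self is the natural
U-statistic and is what the tests pin down.) The combined mode counts a
residue toward the modal class when it is identical to the modal residue or
scores positively against it — a formalisation choice, configurable, since
no formula for "combination of percent identity and BLOSUM62" is published.

Profiles are smoothed with a centred moving average; at the edges the window
is truncated to what exists, so the profile always has exactly one value per
column. Smoothed values therefore always stay within [min(raw), max(raw)].
The profile's reference "average" line is the mean of the *raw* values.
Threshold bands classify a value as high/mid/low/none by `value >=
threshold`; defaults are 0.5 / 1.5 / 3.0 for similarity (the conventional
low/mid/high split for BLOSUM62 colouring) and 30 / 60 / 80 for percent
identity (our choice).

## Editing operators

All removal thresholds are strict (`>`): a row with exactly 50 % gaps
survives a 50 % filter. Partial sequences are rows whose residue string
begins or ends with a gap. Redundancy removal is greedy first-wins in row
order — the earlier row of a too-similar pair is kept — with pairwise
identity computed over the *intersection* of non-gap columns (the union
denominator is the other defensible reading; intersection was chosen and is
what the invariant tests assume). Conservation-based column removal deletes
columns whose value lies in the half-open interval `[lower, upper)`, so
chained filters partition the columns cleanly and `lower == upper` is a
no-op.

After column removal, a coordinate-carrying row keeps its start and gets a
recomputed end (`start + remaining residues − 1`). If the removed columns
held the row's *leading* residues the start is no longer exact; this is a
known limitation of coordinate-carrying column edits and is documented
rather than guessed around.

Score-based sequence removal only works when rows carry scores parsed from
Stockholm `#=GS ... SC` annotations; the operator errors rather than
inventing scores.

## Distances and trees

The fractional difference p is mismatches over columns where both rows are
non-gap (an error when no columns are shared). Corrections:

* Jukes–Cantor: `d = -((a-1)/a) ln(1 - (a/(a-1)) p)`, a = 4 (nucleotide) or
  20 (protein);
* Kimura's protein approximation: `d = -ln(1 - p - 0.2 p²)`;
* Scoredist: over the shared columns, let σ be the observed BLOSUM62 score,
  σ_u the mean of the two self-scores, and σ_r the expected score of
  shuffled sequences with the same residue compositions
  (`σ_r = (1/l) Σ_ab n_a n_b s(a,b)`). Then
  `d = -c · ln((σ - σ_r) / (σ_u - σ_r))` with the published calibration
  constant c = 1.3370 for BLOSUM62 (a named config value), expressed in
  substitutions per site.

Every correction diverges at saturation; at or past the singularity the
distance is capped at a configurable maximum (default 10.0 substitutions per
site — the original tools' cap is undocumented, so the value is explicit and
adjustable). The Storm & Sonnhammer correction is reserved in the method
enum but raises NotImplementedError: its formula is not available in our
sources and is not guessed.

Neighbour joining is Saitou–Nei with two determinism rules: Q-criterion ties
break toward the lowest (i, j) pair in input label order, and negative limb
lengths are clamped to zero with the deficit moved to the sibling so the
pair's summed length is preserved. The algorithm terminates classically with
a trifurcating root joining the last three clusters via the three-point
formulas (two leaves give a binary root with the distance split evenly).
The trifurcation is what makes the three-leaf solution (branches 1, 1, 3 for
distances 2, 4, 4) representable; a forced binary root would split the third
branch across the root. UPGMA is size-weighted average linkage with node
height equal to half the merge distance, so its trees are binary and
ultrametric to 1e-9 by construction; ties break the same way.

Rerooting places the new root at the midpoint of the chosen node's parent
edge (or at the node with `midpoint=False`), dissolving the old degree-2
root by merging its two edges; leaf sets and pairwise path lengths are
invariant. Child swapping reverses a node's child order and changes nothing
metric. Newick output writes branch lengths to 6 significant digits and
bootstrap supports as internal-node labels; the parser reports the character
position of any syntax error. Numeric internal labels are read back as
supports.

Bootstrap resamples alignment columns with replacement using a single seeded
PCG64 generator per run, rebuilds a tree per replicate, and annotates each
internal edge of the full-alignment tree with the percentage of replicates
containing the same (unrooted) leaf bipartition. Fixed seed means
bit-identical replicate trees.

## Dot plots

The grid stores, per cell, the mean substitution score of a window of
residue pairs centred on the cell and running along the alignment diagonal;
odd windows only, and at the matrix edges the mean is taken over the
in-bounds part of the window (truncation, not padding, so corner cells are
means of shorter runs). Modes: protein–protein compares directly;
nucleotide–nucleotide also compares the reverse complement of the horizontal
sequence, stored column-flipped so reverse-strand alignments appear as
anti-diagonals; nucleotide–protein translates the horizontal sequence in
three frames and stores the best frame's score per cell (frame-resolved
grids are available through the library).

Raw windowed scores are quantised affinely from [0, matrix_max] to 0..255
and clamped; matrix_max is the largest self-score in the active matrix (11
for BLOSUM62, 5 for the DNA default). The scale is recorded in the matrix
metadata so saved files are self-describing. A zoom factor z reduces each
z×z block of raw scores by *maximum* — a deliberate choice so short strong
matches survive compression (a mean would wash them out).

The greyramp maps cells to pixel brightness: at or below the min cutoff →
white (255), at or above the max cutoff → black (0), linear in between with
half-up rounding; brightness is non-increasing in score, and equal cutoffs
give a binary image. Because the ramp operates on the stored 8-bit cells,
contrast is re-tunable after loading a saved matrix with no recomputation.

Persistence is a little-endian binary format: magic `DTR2`, format version,
mode/kind codes, window, zoom, grid dimensions, score scale, sequence
identifiers, then the raw cell bytes (both strand grids in nn mode). Load
validates magic, version and byte counts, so truncated files fail cleanly.
Image export is binary PGM (P5) always, PNG via Pillow.

Overlays map 1-based inclusive GFF coordinates into 0-based cell space by
floor division with the zoom factor: features with a Target on the vertical
sequence become diagonal segments, others become axis intervals; features
outside the plot are dropped (wholly) or clipped (partially) with a logged
warning. Multi-sequence self plots concatenate same-kind sequences and
return the cumulative boundary offsets used to draw the section grid.

## Alignment stacking (GFF3)

Coordinates are 1-based inclusive at every public boundary. Gap attributes
follow the GFF3 specification's reading — `I` is a gap in the *reference*
(extra target residues), `D` a gap in the *target* — stated explicitly
because tools disagree. `M` and `D` consume reference; `M` and `I` consume
target; in protein mode (a protein match on a nucleotide reference) each
M/D unit consumes three reference bases. Projection validates that the ops
consume exactly the feature's span and the Target's span, and reports
expected vs actual when they do not. A feature without a Gap attribute is a
single M block.

Classification per aligned pair: exact iff residues equal (never for N in
nucleotide mode), conserved iff protein mode and the substitution score is
positive, else mismatch; gap pairs are insertions/deletions. In protein mode
the reference codon is translated (reverse-complemented first on minus
strand) before comparison. Coverage counts M/D-consumed reference positions,
so a deletion still covers the deleted bases while insertions add nothing;
squashed representatives can contribute with their collapsed multiplicities,
which makes coverage invariant under squashing. Squashing groups by (seqid,
start, end, strand, Gap string, target id), keeps first-seen order and
conserves total read count.

Splice-site detection takes a transcript's exons (same strand,
non-overlapping), reads each intervening intron's first and last
dinucleotide on the transcript's strand (reverse complement for minus) and
classifies GT..AG as canonical, GC..AG and AT..AC as named variants, and
everything else as non-canonical.

Identity sorting uses the GFF score column and errors when scores are
missing — there is no principled fallback metric, so none is invented.
BAM/SAM is not read; read sets arrive as GFF3 (the fixture generator emits
them).

## Command line

The `alnkit msa` chain applies operations in one fixed, documented order —
read → sequence filters (gap fraction, partial, redundant) → column filters
→ sort → terminal operation (convert / distance matrix / tree / bootstrap)
→ write — so a single call composes like a pipeline and is byte-identical to
the equivalent library composition (asserted in tests). Usage errors exit 1
before any I/O; data errors exit 2; removal reports go to stderr.
`--seed` controls all bootstrap randomness.

## Synthetic data

The generators in `alnkit.fixtures` are pure functions of their parameters
and a seed (numpy PCG64), chosen for cross-platform reproducibility. They
emulate the *structural* features the operators care about — planted
duplicate/gappy/partial rows, all-gap columns and conserved blocks in MSAs
(interior columns only, so a planted all-gap column cannot accidentally make
every row "partial"); random tree topologies with branch lengths uniform in
[0.1, 1] (merge heights increasing for the ultrametric flag); mutated
sequence pairs with known edit scripts; exact-substring read sets with known
coverage and squash structure. They do not simulate evolution: residues are
uniform random rather than drawn from a substitution model, so passing tests
demonstrate the operators' contracts, not performance on realistic homology.

## Problem sizes and verification

The test suite and `scripts/acceptance.py` verify: NJ/UPGMA recovery on 100
random 6–8-leaf trees (topology via Robinson–Foulds 0, path lengths to
1e-9); Jukes–Cantor and Kimura against their closed forms to 1e-12 on
p = 0.05..0.6; the dot-matrix engine against an independent brute-force
double loop on 50 seeded pairs (windows 1/7/25, all three modes, mostly
40–140 residues with two 300-residue stress pairs — sizes chosen to keep the
brute-force oracle itself fast); greyramp monotonicity on random grids and
bit-exact matrix persistence; format closure on 20 generated alignments with
checksum verification; exact planted-truth removal for every editing
operator; GFF3 consumption accounting, squash conservation, an
interval-arithmetic coverage oracle and GT–AG/CT–AC splice fixtures; and
bootstrap determinism plus 100 % support for a planted two-clade split at
100 replicates.

## Known limitations

* Stockholm markup is round-tripped verbatim but not interpreted; per-column
  annotations are not remapped after column edits.
* Start coordinates can drift after removing a row's leading-residue columns
  (see Editing).
* The Storm & Sonnhammer distance is intentionally unimplemented.
* The nucleotide–protein dot-plot mode stores the best frame only by
  default; per-frame grids must be requested explicitly.
* No suffix-array acceleration: dot-matrix cost is O(len_a × len_b), aimed
  at the small-to-medium comparisons a curator inspects.
* The CLI detail view reconstructs target residues from the reference
  (exact-match model) when no match FASTA is supplied; mismatch glyphs only
  appear through the library API with real target sequences.
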
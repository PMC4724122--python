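# alnkit

Headless, scriptable engines for the three classic ways annotators look at
sequence alignments:

* **stack** — a many-to-one view: GFF3 match features (ESTs, proteins,
  short reads) projected onto a single FASTA reference via their
  `Target`/`Gap` (CIGAR-style) attributes, with per-base
  exact/conserved/mismatch classification, read squashing, coverage tracks
  and splice-site checks.
* **dotplot** — a windowed dot-matrix comparison of two sequences in
  nucleotide-nucleotide (both strands), nucleotide-protein (three-frame
  translated) or protein-protein mode, with greyramp rendering and a
  versioned binary matrix format so batch-computed plots re-open instantly.
* **msa / phylo** — multiple-alignment I/O (Stockholm, GCG MSF, Selex,
  aligned FASTA), per-column conservation scoring, automated curation
  operators (gappy/partial/redundant sequence removal, column filters,
  sorting), and distance-based trees (neighbour joining and UPGMA with
  uncorrected, Jukes–Cantor, Kimura and Scoredist distances, Newick I/O,
  bootstrap support).

It is aimed at curation pipelines: everything the GUI viewers in this
lineage do *computationally* is available as a library call and as a
composable command line, so batch jobs can convert, filter, and build trees
in one invocation.

## The core quantities

For aligned rows the fractional difference is `p` = mismatches / columns
where both rows are non-gap. Distance corrections:

* Jukes–Cantor: `d = -((a-1)/a) ln(1 - (a/(a-1)) p)` with alphabet size `a`
  (4 nucleotide, 20 protein);
* Kimura (protein): `d = -ln(1 - p - 0.2 p²)`;
* Scoredist: with `σ` the observed BLOSUM62 score over shared columns,
  `σ_r` the expected score of shuffled sequences of the same composition and
  `σ_u` the mean of the two self-scores,
  `d = -c · ln((σ - σ_r)/(σ_u - σ_r))`, calibration `c = 1.3370`.

Column conservation is either modal-residue percent identity (gaps counted
or ignored) or the mean pairwise BLOSUM62 score over the column's residues;
values are banded with low/mid/high thresholds (defaults 0.5 / 1.5 / 3.0 for
similarity) and may be smoothed with a centred moving window.

Dot-plot cells store the window-averaged substitution score, quantised to
8 bits over `[0, matrix_max]`; the greyramp maps cells to pixels with
adjustable min/max cutoffs without recomputation.

## Worked example

```python
from alnkit.msa_io import read_alignment, write_alignment
from alnkit.editing import remove_redundant_sequences, remove_columns_by_conservation
from alnkit.phylo import distance_matrix, nj_tree, to_newick

text = """# STOCKHOLM 1.0
human  MKVLAWCDEF
chimp  MKVLAWCDEF
mouse  MKVLSWCDDF
frog   MQVIAWCEDF
//
"""
aln = read_alignment(text, "stockholm")
aln, removed = remove_redundant_sequences(aln, 80)
print(removed)
aln, cols = remove_columns_by_conservation(aln, 0.0, 0.9)
print(cols, aln.length)
print(to_newick(nj_tree(distance_matrix(aln, "kimura"))))
```

prints

```
['chimp']
[] 10
(human:0.116597,mouse:0.116597,frog:0.449037);
```

`chimp` is dropped as >80 % identical to `human`; no column falls below 0.9
average BLOSUM62 similarity in this toy family, so the alignment keeps its
10 columns; and the Kimura-corrected neighbour-joining tree places `frog`
on the long branch — it differs from the others at four of ten sites
(p = 0.4, d = −ln(1 − 0.4 − 0.2·0.16) ≈ 0.566 to each), while
human and mouse differ at two (d ≈ 0.233).

The same chain on the command line:

```sh
alnkit msa family.sto --rm-redundant 80 --rm-cols-conservation-below 0.9 \
       --tree nj --dist-correction kimura
```

Dot plots and stacked views work the same way (`alnkit dotplot --seq-a a.fa
--seq-b b.fa --window 25 --save plot.dtr`, then `alnkit dotplot --load
plot.dtr --export-image plot.pgm --min 40 --max 100`; `alnkit stack ref.fa
reads.gff --squash --coverage-out cov.bedgraph`).

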
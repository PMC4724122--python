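"""Deterministic generators for test inputs with known ground truth.

Every generator is a pure function of its parameters and a seed (numpy's
PCG64 ``default_rng``), so goldens are portable across platforms:

* :func:`random_tree_and_matrix` — random additive or ultrametric trees and
  their exact path-length matrices, for tree-reconstruction oracles.
* :func:`planted_msa` — alignments where each editing operator's expected
  removal set is known by construction.
* :func:`mutated_pair` — a sequence and a mutated copy with the true
  alignment, for dot-plot diagonal checks.
* :func:`planted_read_set` — GFF3 read sets with known coverage and
  squash structure.

These emulate the *structure* real inputs have (gap runs, duplicate reads,
conserved blocks), not real evolutionary processes: residues are uniform
random, not drawn from a substitution model.
"""

from __future__ import annotations

import numpy as np

from .msa_io import MultipleAlignment, Row
from .phylo import DistanceMatrix, TreeNode
from .seqcore import GAP, NUCLEOTIDE, PROTEIN, Sequence
from .stack import GenomicFeature, parse_gff3

__all__ = [
    "random_tree_and_matrix",
    "planted_msa",
    "mutated_pair",
    "planted_read_set",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"


def random_tree_and_matrix(
    n_leaves: int, seed: int = 0, ultrametric: bool = False
) -> tuple[TreeNode, DistanceMatrix]:
    """A random binary tree and its exact leaf path-length matrix.

    Branch lengths are uniform in [0.1, 1].  With ``ultrametric=True`` the
    tree is built by successive merges at increasing heights so all
    root-to-leaf depths are equal (a molecular clock), which makes the
    matrix ultrametric; otherwise branch lengths are free and the matrix is
    additive.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    labels = [f"t{i}" for i in range(n_leaves)]

    if ultrametric:
        nodes = [TreeNode(l) for l in labels]
        height = {id(n): 0.0 for n in nodes}
        h = 0.0
        while len(nodes) > 1:
            h += rng.uniform(0.1, 1.0)
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            a, b = nodes[i], nodes[j]
            a.length = h - height[id(a)]
            b.length = h - height[id(b)]
            parent = TreeNode(children=[a, b])
            height[id(parent)] = h
            nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
            nodes.append(parent)
        tree = nodes[0]
    else:
        # grow by attaching each new leaf to a random existing edge
        tree = TreeNode(
            children=[
                TreeNode(labels[0], rng.uniform(0.1, 1.0)),
                TreeNode(labels[1], rng.uniform(0.1, 1.0)),
            ]
        )
        for label in labels[2:]:
            edges = [
                (parent, child)
                for parent in tree.walk()
                for child in parent.children
            ]
            parent, child = edges[rng.integers(len(edges))]
            split = rng.uniform(0.2, 0.8) * (child.length or 0.0)
            mid = TreeNode(length=(child.length or 0.0) - split)
            child.length = split
            new_leaf = TreeNode(label, rng.uniform(0.1, 1.0))
            mid.children = [child, new_leaf]
            parent.children[parent.children.index(child)] = mid
        tree = tree

    return tree, tree.path_length_matrix()


def planted_msa(
    n_rows: int = 8,
    n_cols: int = 40,
    seed: int = 0,
    n_gappy_rows: int = 0,
    gappy_row_gap_percent: float = 60.0,
    n_duplicate_rows: int = 0,
    n_partial_rows: int = 0,
    n_all_gap_cols: int = 0,
    conserved_block: tuple[int, int] | None = None,
    kind: str = PROTEIN,
) -> tuple[MultipleAlignment, dict]:
    """An alignment with planted structure and a truth dictionary.

    The first ``n_rows`` rows are clean random rows (pairwise identity kept
    low by construction); planted rows follow: ``dup<i>`` exact duplicates
    of row 0, ``gappy<i>`` rows with the requested gap percentage,
    ``partial<i>`` rows starting/ending with gap runs.  ``n_all_gap_cols``
    all-gap columns are planted at known indices, and ``conserved_block``
    (start, stop) columns are made identical across all rows.

    Returns ``(alignment, truth)`` with truth keys ``gappy``, ``duplicates``,
    ``partial``, ``all_gap_cols``, ``conserved_cols``.
    """
    rng = np.random.default_rng(seed)
    alpha = _AA if kind == PROTEIN else _NT
    base = rng.integers(0, len(alpha), size=(n_rows, n_cols))
    # decorrelate rows: each row gets its own random draw, identity ~5%
    rows = [["".join(alpha[c] for c in base[i])] for i in range(n_rows)]
    rows = [list(r[0]) for r in rows]

    conserved_cols = []
    if conserved_block is not None:
        lo, hi = conserved_block
        consensus = [alpha[c] for c in rng.integers(0, len(alpha), size=hi - lo)]
        for r in rows:
            r[lo:hi] = consensus
        conserved_cols = list(range(lo, hi))

    truth = {
        "gappy": [],
        "duplicates": [],
        "partial": [],
        "all_gap_cols": [],
        "conserved_cols": conserved_cols,
    }
    named = [(f"row{i}", rows[i]) for i in range(n_rows)]

    for i in range(n_duplicate_rows):
        name = f"dup{i}"
        named.append((name, list(rows[0])))
        truth["duplicates"].append(name)

    for i in range(n_gappy_rows):
        name = f"gappy{i}"
        r = [alpha[c] for c in rng.integers(0, len(alpha), size=n_cols)]
        n_gaps = int(np.ceil(gappy_row_gap_percent / 100.0 * n_cols))
        # keep first and last columns residues so the row is not "partial"
        inner = rng.choice(np.arange(1, n_cols - 1), size=n_gaps, replace=False)
        for c in inner:
            r[c] = GAP
        named.append((name, r))
        truth["gappy"].append(name)

    for i in range(n_partial_rows):
        name = f"partial{i}"
        r = [alpha[c] for c in rng.integers(0, len(alpha), size=n_cols)]
        run = int(rng.integers(1, max(2, n_cols // 4)))
        if i % 2 == 0:
            r[:run] = [GAP] * run
        else:
            r[n_cols - run :] = [GAP] * run
        named.append((name, r))
        truth["partial"].append(name)

    if n_all_gap_cols:
        # interior columns only: an all-gap first/last column would turn
        # every row into a "partial" sequence and corrupt that truth set
        cols = sorted(
            int(c)
            for c in rng.choice(
                [c for c in range(1, n_cols - 1) if c not in conserved_cols],
                size=n_all_gap_cols,
                replace=False,
            )
        )
        for _, r in named:
            for c in cols:
                r[c] = GAP
        truth["all_gap_cols"] = cols

    aln = MultipleAlignment(
        tuple(Row(name, "".join(r)) for name, r in named), kind
    )
    return aln, truth


def mutated_pair(
    length: int = 200,
    n_point_mutations: int = 5,
    n_indels: int = 0,
    indel_length: int = 10,
    seed: int = 0,
    kind: str = NUCLEOTIDE,
) -> tuple[Sequence, Sequence, list[tuple[str, int, int]]]:
    """A sequence, a mutated copy, and the true edit script.

    The edit script is a list of ``(op, position, length)`` entries with op
    in {"sub", "ins", "del"}; positions are 0-based on the original
    sequence.  Insertions shift the dot-plot diagonal down, deletions up.
    """
    rng = np.random.default_rng(seed)
    alpha = _NT if kind == NUCLEOTIDE else _AA
    original = [alpha[c] for c in rng.integers(0, len(alpha), size=length)]
    mutated = list(original)
    script: list[tuple[str, int, int]] = []

    pos = rng.choice(length, size=min(n_point_mutations, length), replace=False)
    for p in sorted(int(x) for x in pos):
        old = mutated[p]
        choices = [c for c in alpha if c != old]
        mutated[p] = choices[int(rng.integers(len(choices)))]
        script.append(("sub", p, 1))

    for k in range(n_indels):
        p = int(rng.integers(length // 4, 3 * length // 4))
        if k % 2 == 0:
            ins = [alpha[c] for c in rng.integers(0, len(alpha), size=indel_length)]
            mutated[p:p] = ins
            script.append(("ins", p, indel_length))
        else:
            del mutated[p : p + indel_length]
            script.append(("del", p, indel_length))

    return (
        Sequence("original", "".join(original), kind),
        Sequence("mutated", "".join(mutated), kind),
        script,
    )


def planted_read_set(
    ref_length: int = 120,
    n_reads: int = 10,
    read_length: int = 30,
    n_duplicates: int = 0,
    seed: int = 0,
) -> tuple[Sequence, str, list[GenomicFeature], dict]:
    """A reference, a GFF3 read set and its known coverage/squash truth.

    Reads are exact substrings of the reference placed at seeded positions;
    ``n_duplicates`` extra reads repeat the first read exactly (the squash
    operator must collapse them).  Truth keys: ``expected_depth`` (per-base
    list), ``n_distinct``, ``total_reads``.
    """
    rng = np.random.default_rng(seed)
    ref_res = "".join(_NT[c] for c in rng.integers(0, 4, size=ref_length))
    ref = Sequence("ref1", ref_res, NUCLEOTIDE)

    lines = ["##gff-version 3"]
    depth = [0] * ref_length
    starts = []
    for i in range(n_reads):
        start = int(rng.integers(1, ref_length - read_length + 1))
        starts.append(start)
    for extra in range(n_duplicates):
        starts.append(starts[0])
    for i, start in enumerate(starts):
        end = start + read_length - 1
        is_dup = i >= n_reads
        rid = "read0" if is_dup else f"read{i}"
        lines.append(
            f"ref1\ttest\tnucleotide_match\t{start}\t{end}\t100.0\t+\t.\t"
            f"ID=m{i};Target={rid} 1 {read_length};Gap=M{read_length}"
        )
        for p in range(start, end + 1):
            depth[p - 1] += 1
    gff = "\n".join(lines) + "\n"
    features = parse_gff3(gff)
    # duplicates share read0's squash key; every other read has a unique
    # target id and therefore its own key
    truth = {
        "expected_depth": depth,
        "n_distinct": n_reads,
        "total_reads": len(starts),
    }
    return ref, gff, features, truth
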
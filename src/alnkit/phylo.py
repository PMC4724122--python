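"""Distance-based phylogenetics: corrections, NJ/UPGMA, tree surgery, bootstrap.

Pairwise distances start from the fractional difference ``p`` (mismatches
over columns where both rows are non-gap) and may be corrected for multiple
substitutions:

* ``uncorrected``      d = p
* ``jukes_cantor``     d = -((a-1)/a) ln(1 - (a/(a-1)) p), alphabet size a
                       (4 for nucleotide, 20 for protein)
* ``kimura``           d = -ln(1 - p - 0.2 p^2)  (protein rule-of-thumb)
* ``scoredist``        logarithmically corrected normalised BLOSUM62 score
                       (see :func:`scoredist`)
* ``storm_sonnhammer`` reserved; raises NotImplementedError

All corrections diverge as p approaches saturation; at or beyond the
singularity the distance is capped at a configurable maximum
(``DEFAULT_MAX_DISTANCE``).

Tree construction is deterministic: ties in the NJ Q-criterion and the UPGMA
minimum are broken toward the lowest (i, j) pair in input label order, and
negative NJ branch lengths are clamped to zero with the deficit moved to the
sibling branch.  Trees serialise to New Hampshire (Newick) text with branch
lengths at six significant digits and bootstrap supports as internal-node
labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .seqcore import GAP, PROTEIN, ScoringMatrix, blosum62
from .msa_io import MultipleAlignment

__all__ = [
    "CORRECTIONS",
    "DEFAULT_MAX_DISTANCE",
    "SCOREDIST_CALIBRATION",
    "DistanceMatrix",
    "TreeNode",
    "fractional_difference",
    "corrected_distance",
    "scoredist",
    "distance_matrix",
    "nj_tree",
    "upgma_tree",
    "reroot",
    "swap_children",
    "to_newick",
    "from_newick",
    "export_distance_matrix",
    "import_distance_matrix",
    "bootstrap",
    "bipartitions",
    "robinson_foulds",
]

CORRECTIONS = (
    "uncorrected",
    "jukes_cantor",
    "kimura",
    "scoredist",
    "storm_sonnhammer",
)

DEFAULT_MAX_DISTANCE = 10.0
#: Scoredist calibration factor for BLOSUM62 (from its publication).
SCOREDIST_CALIBRATION = 1.3370


# ---------------------------------------------------------------------------
# distance matrix


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} != ({n}, {n})")
        if len(set(self.labels)) != n:
            raise ValueError("distance-matrix labels must be unique")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])


# ---------------------------------------------------------------------------
# trees


@dataclass
class TreeNode:
    """A rooted tree node; leaves carry labels, edges carry lengths.

    ``length`` is the branch length to the parent (None only at the root);
    ``support`` is an optional bootstrap percentage on the edge above an
    internal node.
    """

    label: str | None = None
    length: float | None = None
    support: float | None = None
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.label for l in self.leaves()]

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def copy(self) -> "TreeNode":
        return TreeNode(
            self.label,
            self.length,
            self.support,
            [c.copy() for c in self.children],
        )

    def path_length_matrix(self) -> DistanceMatrix:
        """Pairwise leaf-to-leaf path lengths."""
        names = self.leaf_names()
        idx = {n: i for i, n in enumerate(names)}
        n = len(names)
        d = np.zeros((n, n))

        def below(node):
            # returns {leaf: distance to node}; accumulates cross-child pairs
            if node.is_leaf:
                return {node.label: 0.0}
            seen: dict[str, float] = {}
            for child in node.children:
                sub = {
                    k: v + (child.length or 0.0) for k, v in below(child).items()
                }
                for a, da in seen.items():
                    for b, db in sub.items():
                        d[idx[a], idx[b]] = d[idx[b], idx[a]] = da + db
                seen.update(sub)
            return seen

        below(self)
        return DistanceMatrix(tuple(names), d)


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial leaf bipartitions (as the smaller/canonical side sets).

    Each internal edge splits the leaf set in two; the split is recorded as a
    frozenset of frozensets so it is orientation-free and comparable across
    differently rooted trees.
    """
    all_leaves = frozenset(tree.leaf_names())
    splits = set()
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        other = all_leaves - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset((side, other)))
    return splits


def robinson_foulds(a: TreeNode, b: TreeNode) -> int:
    """Unrooted Robinson–Foulds distance (symmetric split difference)."""
    if set(a.leaf_names()) != set(b.leaf_names()):
        raise ValueError("trees have different leaf sets")
    sa, sb = bipartitions(a), bipartitions(b)
    return len(sa ^ sb)


# ---------------------------------------------------------------------------
# distances


def _shared_columns(row_a: str, row_b: str):
    for a, b in zip(row_a, row_b):
        if a != GAP and b != GAP:
            yield a, b


def fractional_difference(row_a: str, row_b: str) -> float:
    """Mismatch fraction over columns where both rows are non-gap."""
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal (aligned) length")
    shared = diff = 0
    for a, b in _shared_columns(row_a, row_b):
        shared += 1
        if a != b:
            diff += 1
    if shared == 0:
        raise ValueError("no shared non-gap columns: distance undefined")
    return diff / shared


def _jukes_cantor(p: float, alphabet_size: int, cap: float) -> float:
    a = alphabet_size
    arg = 1.0 - (a / (a - 1.0)) * p
    if arg <= 0.0:
        return cap
    return min(cap, -((a - 1.0) / a) * math.log(arg))


def _kimura_protein(p: float, cap: float) -> float:
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0.0:
        return cap
    return min(cap, -math.log(arg))


def scoredist(
    row_a: str,
    row_b: str,
    matrix: ScoringMatrix | None = None,
    calibration: float = SCOREDIST_CALIBRATION,
    cap: float = DEFAULT_MAX_DISTANCE,
) -> float:
    """Scoredist: logarithmic correction of the normalised BLOSUM62 score.

    Over the columns where both rows are non-gap, compute the observed score
    sigma, the expected score sigma_r of shuffled sequences of the same
    compositions, and the upper limit sigma_u (mean of the two self-scores).
    The normalised score sigma_n = (sigma - sigma_r) / (sigma_u - sigma_r) is
    mapped to an evolutionary distance d = -c * ln(sigma_n) (substitutions
    per site) with the published calibration c for BLOSUM62.
    """
    matrix = matrix or blosum62()
    pairs = list(_shared_columns(row_a, row_b))
    if not pairs:
        raise ValueError("no shared non-gap columns: distance undefined")
    length = len(pairs)
    sigma = sum(matrix.scores[(a, b)] for a, b in pairs)
    self_a = sum(matrix.scores[(a, a)] for a, _ in pairs)
    self_b = sum(matrix.scores[(b, b)] for _, b in pairs)
    sigma_u = 0.5 * (self_a + self_b)
    # expected score of shuffled sequences with these compositions
    comp_a: dict[str, int] = {}
    comp_b: dict[str, int] = {}
    for a, b in pairs:
        comp_a[a] = comp_a.get(a, 0) + 1
        comp_b[b] = comp_b.get(b, 0) + 1
    sigma_r = (
        sum(
            na * nb * matrix.scores[(a, b)]
            for a, na in comp_a.items()
            for b, nb in comp_b.items()
        )
        / length
    )
    if sigma_u <= sigma_r:
        return 0.0 if sigma >= sigma_u else cap
    sigma_n = (sigma - sigma_r) / (sigma_u - sigma_r)
    if sigma_n <= 0.0:
        return cap
    return min(cap, max(0.0, -calibration * math.log(sigma_n)))


def corrected_distance(
    row_a: str,
    row_b: str,
    method: str = "uncorrected",
    kind: str = PROTEIN,
    matrix: ScoringMatrix | None = None,
    cap: float = DEFAULT_MAX_DISTANCE,
) -> float:
    """Pairwise distance between two aligned gapped rows."""
    if method == "scoredist":
        return scoredist(row_a, row_b, matrix, cap=cap)
    if method == "storm_sonnhammer":
        raise NotImplementedError(
            "the Storm & Sonnhammer correction is reserved but its formula "
            "is not configured"
        )
    p = fractional_difference(row_a, row_b)
    if method == "uncorrected":
        return p
    if method == "jukes_cantor":
        return _jukes_cantor(p, 4 if kind != PROTEIN else 20, cap)
    if method == "kimura":
        return _kimura_protein(p, cap)
    raise ValueError(f"unknown distance correction {method!r}")


def distance_matrix(
    aln: MultipleAlignment,
    method: str = "uncorrected",
    matrix: ScoringMatrix | None = None,
    cap: float = DEFAULT_MAX_DISTANCE,
) -> DistanceMatrix:
    """All-pairs corrected distances for the alignment rows."""
    if aln.n_rows < 2:
        raise ValueError("distance matrix needs at least 2 rows")
    names = tuple(aln.names())
    n = aln.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = corrected_distance(
                aln.rows[i].residues,
                aln.rows[j].residues,
                method,
                aln.kind,
                matrix,
                cap,
            )
    return DistanceMatrix(names, d)


# ---------------------------------------------------------------------------
# tree building


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbour joining, rooted at the final join.

    Deterministic: Q-criterion ties break toward the lowest (i, j) pair in
    label order; negative branch lengths are clamped to zero and the deficit
    transferred to the sibling so the pair's summed length is preserved.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("neighbour joining needs at least 2 taxa")
    nodes = [TreeNode(label) for label in dm.labels]
    d = dm.d.copy()
    active = list(range(n))

    if n == 2:
        i, j = active
        half = 0.5 * d[i, j]
        nodes[i].length = half
        nodes[j].length = half
        return TreeNode(children=[nodes[i], nodes[j]])

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0) + 0.0, max(lj, 0.0) + 0.0
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # grow the arrays with the new cluster at index i
        for k in active:
            if k not in (i, j):
                d[i, k] = d[k, i] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes[i] = parent
        active.remove(j)

    # classical NJ termination: the last three clusters join at an
    # unresolved (trifurcating) root with branch lengths from the
    # three-point formulas
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    nodes[i].length = max(li, 0.0) + 0.0
    nodes[j].length = max(lj, 0.0) + 0.0
    nodes[k].length = max(lk, 0.0) + 0.0
    return TreeNode(children=[nodes[i], nodes[j], nodes[k]])


def upgma_tree(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) tree; node height is half the merge distance.

    Output is ultrametric.  Minimum-distance ties break toward the lowest
    (i, j) pair in label order.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 taxa")
    nodes = [TreeNode(label) for label in dm.labels]
    height = [0.0] * n
    size = [1] * n
    d = dm.d.copy()
    active = list(range(n))

    while len(active) > 1:
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                if best is None or d[i, j] < best[0] - 1e-12:
                    best = (d[i, j], i, j)
        dist, i, j = best
        h = dist / 2.0
        nodes[i].length = h - height[i]
        nodes[j].length = h - height[j]
        parent = TreeNode(children=[nodes[i], nodes[j]])
        for k in active:
            if k not in (i, j):
                d[i, k] = d[k, i] = (
                    size[i] * d[i, k] + size[j] * d[j, k]
                ) / (size[i] + size[j])
        nodes[i] = parent
        height[i] = h
        size[i] += size[j]
        active.remove(j)

    return nodes[active[0]]


# ---------------------------------------------------------------------------
# tree surgery


def _find(tree: TreeNode, target) -> TreeNode:
    """Locate a node by identity, label, or path of child indices."""
    if isinstance(target, TreeNode):
        for node in tree.walk():
            if node is target:
                return node
        raise LookupError("node not in tree")
    if isinstance(target, (tuple, list)):
        node = tree
        for i in target:
            try:
                node = node.children[i]
            except IndexError:
                raise LookupError(f"no node at path {tuple(target)}") from None
        return node
    for node in tree.walk():
        if node.label == target:
            return node
    raise LookupError(f"no node labelled {target!r} in tree")


def swap_children(tree: TreeNode, target) -> TreeNode:
    """Reverse the child order of an internal node (metrics unchanged).

    ``target`` may be a node of ``tree``, a label, or a path of child
    indices (e.g. ``(0, 1)`` for the second child of the first child).
    """
    out = tree.copy()
    if isinstance(target, TreeNode):
        node = _path_equiv(tree, out, target)
    else:
        node = _find(out, target)
    if node.is_leaf:
        raise ValueError("cannot swap children of a leaf")
    node.children = list(reversed(node.children))
    return out


def _path_equiv(old_root: TreeNode, new_root: TreeNode, target: TreeNode):
    # map a node of the original tree onto the same position in its copy
    path = []

    def descend(node, trail):
        if node is target:
            path.extend(trail)
            return True
        return any(
            descend(c, trail + [i]) for i, c in enumerate(node.children)
        )

    if not descend(old_root, []):
        raise LookupError("node not in tree")
    node = new_root
    for i in path:
        node = node.children[i]
    return node


def reroot(tree: TreeNode, target, midpoint: bool = True) -> TreeNode:
    """Re-root the tree on the edge above ``target``.

    The new root is placed at the midpoint of that edge (or at the node
    itself with ``midpoint=False``).  Leaf set and pairwise path lengths are
    unchanged.  Rerooting at the current root returns a copy unchanged.
    """
    work = tree.copy()
    if isinstance(target, TreeNode):
        node = _path_equiv(tree, work, target)
    else:
        node = _find(work, target)
    if node is work:
        return work

    parent_of = {}
    for p in work.walk():
        for c in p.children:
            parent_of[id(c)] = p

    def detach_upward(child):
        """Rebuild the tree hanging above `child` as a subtree rooted at its parent."""
        p = parent_of[id(child)]
        siblings = [c for c in p.children if c is not child]
        if id(p) in parent_of:
            up = detach_upward(p)
            up.length = p.length
            siblings.append(up)
        # if p was the old degree-2 root, the resulting unary node is
        # collapsed afterwards by _suppress_unary (its two edges merge)
        return TreeNode(p.label, None, p.support, siblings)

    up = detach_upward(node)
    edge = node.length or 0.0
    if midpoint:
        node.length = edge / 2.0
        up.length = edge / 2.0
    else:
        node.length = 0.0
        up.length = edge
    new_root = TreeNode(children=[node, up])
    _suppress_unary(new_root)
    return new_root


def _suppress_unary(node: TreeNode) -> None:
    # collapse internal nodes left with a single child (old root remnants),
    # summing the two branch lengths
    for child in list(node.children):
        _suppress_unary(child)
    new_children = []
    for child in node.children:
        if not child.is_leaf and len(child.children) == 1:
            grand = child.children[0]
            grand.length = (grand.length or 0.0) + (child.length or 0.0)
            new_children.append(grand)
        else:
            new_children.append(child)
    node.children = new_children


# ---------------------------------------------------------------------------
# Newick / matrix I/O


def _fmt_len(x: float) -> str:
    return f"{x:.6g}"


def to_newick(tree: TreeNode) -> str:
    """New Hampshire text; supports as internal labels, lengths %.6g."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            s = node.label or ""
        else:
            s = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.support is not None:
                s += _fmt_len(node.support)
            elif node.label:
                s += node.label
        if node.length is not None:
            s += f":{_fmt_len(node.length)}"
        return s

    return render(tree) + ";"


class NewickError(ValueError):
    pass


def from_newick(text: str) -> TreeNode:
    """Parse New Hampshire text; internal numeric labels become supports."""
    s = text.strip()
    pos = 0

    def error(msg):
        raise NewickError(f"{msg} at position {pos}")

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            node.children.append(parse_node())
            while pos < len(s) and s[pos] == ",":
                pos += 1
                node.children.append(parse_node())
            if pos >= len(s) or s[pos] != ")":
                error("expected ')'")
            pos += 1
        label = _read_token()
        if label:
            if node.children:
                try:
                    node.support = float(label)
                except ValueError:
                    node.label = label
            else:
                node.label = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            tok = _read_token()
            try:
                node.length = float(tok)
            except ValueError:
                error(f"bad branch length {tok!r}")
        return node

    def _read_token() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos].strip()

    root = parse_node()
    if pos >= len(s) or s[pos] != ";":
        error("expected ';'")
    return root


def export_distance_matrix(dm: DistanceMatrix) -> str:
    """Plain-text square matrix: header row of labels, one row per label."""
    out = ["\t".join(dm.labels)]
    for i, label in enumerate(dm.labels):
        vals = "\t".join(f"{dm.d[i, j]:.9g}" for j in range(len(dm.labels)))
        out.append(f"{label}\t{vals}")
    return "\n".join(out) + "\n"


def import_distance_matrix(text: str) -> DistanceMatrix:
    """Parse the plain-text square matrix (whitespace-tolerant)."""
    lines = [l for l in text.splitlines() if l.strip()]
    if len(lines) < 2:
        raise ValueError("distance-matrix text too short")
    labels = tuple(lines[0].split())
    n = len(labels)
    d = np.zeros((n, n))
    if len(lines) != n + 1:
        raise ValueError(f"expected {n} matrix rows, found {len(lines) - 1}")
    for i, line in enumerate(lines[1:]):
        parts = line.split()
        if len(parts) != n + 1 or parts[0] != labels[i]:
            raise ValueError(f"malformed matrix row {i}: {line!r}")
        d[i] = [float(x) for x in parts[1:]]
    return DistanceMatrix(labels, d)  # symmetry is validated on construction


# ---------------------------------------------------------------------------
# bootstrap


def _resample_alignment(aln: MultipleAlignment, cols: np.ndarray) -> MultipleAlignment:
    rows = []
    for r in aln.rows:
        res = "".join(r.residues[c] for c in cols)
        rows.append(type(r)(r.name, res, None, None, r.score))
    # coordinates are meaningless after resampling; drop them
    return MultipleAlignment(tuple(rows), aln.kind)


def bootstrap(
    aln: MultipleAlignment,
    replicates: int = 100,
    seed: int = 0,
    method: str = "nj",
    correction: str = "uncorrected",
    matrix: ScoringMatrix | None = None,
) -> tuple[list[TreeNode], TreeNode]:
    """Column-resampling bootstrap with supports mapped onto the full tree.

    Returns (replicate trees, the tree from the full alignment annotated
    with percent support on each internal edge).
    """
    if replicates < 1:
        raise ValueError("need at least 1 replicate")
    build = nj_tree if method == "nj" else upgma_tree
    rng = np.random.default_rng(seed)
    base = build(distance_matrix(aln, correction, matrix))
    trees = []
    counts: dict[frozenset, int] = {}
    for _ in range(replicates):
        cols = rng.integers(0, aln.length, size=aln.length)
        rep = build(distance_matrix(_resample_alignment(aln, cols), correction, matrix))
        trees.append(rep)
        for split in bipartitions(rep):
            counts[split] = counts.get(split, 0) + 1
    all_leaves = frozenset(base.leaf_names())
    for node in base.walk():
        if node is base or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        other = all_leaves - side
        if len(side) >= 2 and len(other) >= 2:
            split = frozenset((side, other))
            node.support = 100.0 * counts.get(split, 0) / replicates
    return trees, base
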
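"""Automated curation operators: sequence/column removal and sorting.

These are the batch editing operations a curator applies to trim an
alignment down to a high-quality seed: drop gappy rows, fragmentary
(partial) rows, redundant near-duplicates, gappy or poorly conserved
columns, then sort for inspection.

Threshold semantics are strict: a row or column is removed when its gap
percentage (or pairwise identity) is strictly greater than the threshold.
Conservation-based column removal uses a half-open interval
``[lower, upper)`` so chained filters partition the columns cleanly.
All removal operators are idempotent and report what they removed.
"""

from __future__ import annotations

import logging
from dataclasses import replace

from .seqcore import GAP
from .msa_io import MultipleAlignment, Row
from .conservation import column_value

__all__ = [
    "remove_sequences_by_gap_fraction",
    "remove_partial_sequences",
    "remove_redundant_sequences",
    "remove_sequences_by_score",
    "remove_columns_by_gap_fraction",
    "remove_columns_by_conservation",
    "sort_alignment",
    "pairwise_percent_identity",
]

log = logging.getLogger("alnkit.editing")


def _rebuild_coords(row: Row, new_residues: str) -> Row:
    """Recompute the end coordinate after column removal.

    The start coordinate is kept; the end is re-derived from the surviving
    residue count.  (If the removed columns held the row's leading residues
    the start is no longer exact — a known limitation of coordinate-carrying
    column edits.)
    """
    if row.start is None or row.end is None:
        return replace(row, residues=new_residues)
    n_res = len(new_residues) - new_residues.count(GAP)
    if n_res == 0:
        return Row(row.name, new_residues, score=row.score)
    return Row(row.name, new_residues, row.start, row.start + n_res - 1, row.score)


def remove_sequences_by_gap_fraction(
    aln: MultipleAlignment, max_gap_percent: float
) -> tuple[MultipleAlignment, list[str]]:
    """Remove rows whose gap percentage is strictly above the threshold."""
    if not 0 <= max_gap_percent <= 100:
        raise ValueError("max_gap_percent must be in [0, 100]")
    kept, removed = [], []
    for r in aln.rows:
        if 100.0 * r.gap_fraction > max_gap_percent:
            removed.append(r.display_name)
        else:
            kept.append(r)
    _warn_if_empty(kept, "remove_sequences_by_gap_fraction")
    _report("gap-fraction filter", removed)
    return aln.with_rows(kept), removed


def remove_partial_sequences(
    aln: MultipleAlignment,
) -> tuple[MultipleAlignment, list[str]]:
    """Remove fragmentary rows: those starting or ending with a gap."""
    kept, removed = [], []
    for r in aln.rows:
        s = r.residues
        if s and (s[0] == GAP or s[-1] == GAP):
            removed.append(r.display_name)
        else:
            kept.append(r)
    _warn_if_empty(kept, "remove_partial_sequences")
    _report("partial-sequence filter", removed)
    return aln.with_rows(kept), removed


def pairwise_percent_identity(row_a: str, row_b: str) -> float:
    """Percent identity over columns where both rows are non-gap."""
    shared = ident = 0
    for a, b in zip(row_a, row_b):
        if a != GAP and b != GAP:
            shared += 1
            if a == b:
                ident += 1
    if shared == 0:
        return 0.0
    return 100.0 * ident / shared


def remove_redundant_sequences(
    aln: MultipleAlignment, identity_cutoff_percent: float
) -> tuple[MultipleAlignment, list[str]]:
    """Greedy first-wins removal of rows over the identity cutoff.

    Scanning in row order, a row is dropped when its pairwise identity to any
    already-retained row is strictly greater than the cutoff.
    """
    if not 0 < identity_cutoff_percent <= 100:
        raise ValueError("identity_cutoff_percent must be in (0, 100]")
    kept: list[Row] = []
    removed: list[str] = []
    for r in aln.rows:
        if any(
            pairwise_percent_identity(r.residues, k.residues)
            > identity_cutoff_percent
            for k in kept
        ):
            removed.append(r.display_name)
        else:
            kept.append(r)
    _report("redundancy filter", removed)
    return aln.with_rows(kept), removed


def remove_sequences_by_score(
    aln: MultipleAlignment, min_score: float
) -> tuple[MultipleAlignment, list[str]]:
    """Remove rows whose annotated score is below ``min_score``.

    Scores come from alignment annotations (Stockholm ``#=GS <row> SC``);
    rows without scores make this operator an error — scores are never
    invented.
    """
    missing = [r.display_name for r in aln.rows if r.score is None]
    if missing:
        raise ValueError(
            f"score-based removal needs per-row scores; missing for {missing}"
        )
    kept = [r for r in aln.rows if r.score >= min_score]
    removed = [r.display_name for r in aln.rows if r.score < min_score]
    _report("score filter", removed)
    return aln.with_rows(kept), removed


def _drop_columns(aln: MultipleAlignment, cols: set[int]) -> MultipleAlignment:
    keep = [c for c in range(aln.length) if c not in cols]
    rows = []
    for r in aln.rows:
        new_res = "".join(r.residues[c] for c in keep)
        rows.append(_rebuild_coords(r, new_res))
    return aln.with_rows(rows)


def remove_columns_by_gap_fraction(
    aln: MultipleAlignment, max_gap_percent: float
) -> tuple[MultipleAlignment, list[int]]:
    """Remove columns whose gap percentage is strictly above the threshold."""
    if not 0 <= max_gap_percent <= 100:
        raise ValueError("max_gap_percent must be in [0, 100]")
    n = aln.n_rows
    removed = []
    for c in range(aln.length):
        gaps = sum(1 for x in aln.column(c) if x == GAP)
        if n and 100.0 * gaps / n > max_gap_percent:
            removed.append(c)
    _report("column gap filter", removed)
    return _drop_columns(aln, set(removed)), removed


def remove_columns_by_conservation(
    aln: MultipleAlignment,
    lower: float,
    upper: float,
    mode: str = "blosum_similarity",
) -> tuple[MultipleAlignment, list[int]]:
    """Remove columns whose conservation value lies in ``[lower, upper)``."""
    if lower > upper:
        raise ValueError("lower must be <= upper")
    removed = [
        c
        for c in range(aln.length)
        if lower <= column_value(aln, c, mode) < upper
    ]
    _report("column conservation filter", removed)
    return _drop_columns(aln, set(removed)), removed


def sort_alignment(
    aln: MultipleAlignment,
    key: str = "alphabetical",
    reference: str | None = None,
    tree=None,
) -> MultipleAlignment:
    """Stable reorder: ``alphabetical``, ``similarity_to`` or ``tree_order``.

    ``similarity_to`` sorts descending by pairwise percent identity to the
    named reference row, placing the reference first.  ``tree_order`` follows
    the left-to-right leaf order of the supplied tree.
    """
    if key == "alphabetical":
        rows = sorted(
            aln.rows, key=lambda r: (r.display_name.lower(), r.display_name)
        )
        return aln.with_rows(rows)
    if key == "similarity_to":
        if reference is None:
            raise ValueError("similarity_to sort needs a reference row name")
        ref = aln.row(reference)  # raises LookupError when absent
        order = sorted(
            range(aln.n_rows),
            key=lambda i: (
                aln.rows[i] is not ref,
                -pairwise_percent_identity(ref.residues, aln.rows[i].residues),
                i,
            ),
        )
        return aln.with_rows([aln.rows[i] for i in order])
    if key == "tree_order":
        if tree is None:
            raise ValueError("tree_order sort needs a tree")
        leaf_rank = {name: i for i, name in enumerate(tree.leaf_names())}
        unknown = [r.display_name for r in aln.rows if r.display_name not in leaf_rank]
        order = sorted(
            range(aln.n_rows),
            key=lambda i: (
                leaf_rank.get(aln.rows[i].display_name, len(leaf_rank)),
                i,
            ),
        )
        if unknown:
            log.warning("tree_order: rows not in tree kept last: %s", unknown)
        return aln.with_rows([aln.rows[i] for i in order])
    raise ValueError(f"unknown sort key {key!r}")


def _warn_if_empty(kept: list, op: str) -> None:
    if not kept:
        log.warning("%s removed every sequence", op)


def _report(op: str, removed: list) -> None:
    if removed:
        log.info("%s removed %d item(s): %s", op, len(removed), removed)
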
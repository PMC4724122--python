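"""Per-column conservation metrics, smoothed profiles and threshold bands.

Four conservation modes are supported, matching the similarity/identity
colouring schemes used in curation viewers:

``percent_id_with_gaps`` / ``percent_id_no_gaps``
    100 x (count of the modal residue) / denominator, where the denominator
    is all rows or only non-gap rows.  Gaps are never the modal residue.
``blosum_similarity``
    Mean BLOSUM62 substitution score over all unordered pairs of non-gap
    residues in the column (self-pairs excluded); columns with fewer than two
    residues score 0.
``id_and_blosum``
    Like percent identity, but a residue also counts toward the modal class
    when it has a positive BLOSUM62 score against the modal residue.

The default threshold band (0.5, 1.5, 3.0) is the conventional
low/mid/high split for BLOSUM62 similarity colouring; percent-identity modes
default to (30, 60, 80).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .seqcore import GAP, ScoringMatrix, default_matrix_for, substitution_score
from .msa_io import MultipleAlignment

__all__ = [
    "MODES",
    "ConservationThresholds",
    "ConservationProfile",
    "column_percent_identity",
    "column_similarity_blosum",
    "column_value",
    "conservation_profile",
    "classify_conservation",
    "residue_band",
    "DEFAULT_SIMILARITY_THRESHOLDS",
    "DEFAULT_IDENTITY_THRESHOLDS",
]

MODES = (
    "blosum_similarity",
    "percent_id_with_gaps",
    "percent_id_no_gaps",
    "id_and_blosum",
)


@dataclass(frozen=True)
class ConservationThresholds:
    low: float
    mid: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.mid <= self.high):
            raise ValueError(
                f"thresholds must satisfy low <= mid <= high, got "
                f"({self.low}, {self.mid}, {self.high})"
            )


DEFAULT_SIMILARITY_THRESHOLDS = ConservationThresholds(0.5, 1.5, 3.0)
DEFAULT_IDENTITY_THRESHOLDS = ConservationThresholds(30.0, 60.0, 80.0)


def _modal_residue(column: list[str]) -> tuple[str | None, int]:
    counts: dict[str, int] = {}
    for c in column:
        if c != GAP:
            counts[c] = counts.get(c, 0) + 1
    if not counts:
        return None, 0
    # deterministic tie-break: highest count, then alphabetical
    best = min(counts, key=lambda r: (-counts[r], r))
    return best, counts[best]


def column_percent_identity(
    aln: MultipleAlignment, col: int, include_gaps: bool = True
) -> float:
    """Percent of rows carrying the column's modal (most frequent) residue."""
    column = aln.column(col)
    modal, count = _modal_residue(column)
    denom = len(column) if include_gaps else sum(c != GAP for c in column)
    if modal is None or denom == 0:
        return 0.0
    return 100.0 * count / denom


def column_similarity_blosum(
    aln: MultipleAlignment, col: int, matrix: ScoringMatrix | None = None
) -> float:
    """Mean pairwise substitution score of the column's non-gap residues."""
    matrix = matrix or default_matrix_for(aln.kind)
    residues = [c for c in aln.column(col) if c != GAP]
    if len(residues) < 2:
        return 0.0
    scores = [substitution_score(matrix, a, b) for a, b in combinations(residues, 2)]
    return float(np.mean(scores))


def _column_id_and_blosum(
    aln: MultipleAlignment, col: int, matrix: ScoringMatrix, include_gaps: bool
) -> float:
    column = aln.column(col)
    modal, _ = _modal_residue(column)
    denom = len(column) if include_gaps else sum(c != GAP for c in column)
    if modal is None or denom == 0:
        return 0.0
    count = sum(
        1
        for c in column
        if c != GAP and (c == modal or substitution_score(matrix, c, modal) > 0)
    )
    return 100.0 * count / denom


def column_value(
    aln: MultipleAlignment,
    col: int,
    mode: str,
    matrix: ScoringMatrix | None = None,
) -> float:
    """One column's conservation value under the given mode."""
    if mode == "blosum_similarity":
        return column_similarity_blosum(aln, col, matrix)
    if mode == "percent_id_with_gaps":
        return column_percent_identity(aln, col, include_gaps=True)
    if mode == "percent_id_no_gaps":
        return column_percent_identity(aln, col, include_gaps=False)
    if mode == "id_and_blosum":
        return _column_id_and_blosum(
            aln, col, matrix or default_matrix_for(aln.kind), include_gaps=False
        )
    raise ValueError(f"unknown conservation mode {mode!r}")


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column conservation values, optionally window-smoothed.

    ``values`` are the smoothed values (length == alignment length);
    ``raw`` are the unsmoothed per-column values; ``average`` is the mean of
    the raw values (the horizontal reference line on the profile plot).
    """

    mode: str
    values: tuple[float, ...]
    raw: tuple[float, ...]
    window: int
    average: float

    def to_tsv(self) -> str:
        lines = [f"{i}\t{v:.6g}" for i, v in enumerate(self.values)]
        return "\n".join(lines) + "\n"


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    # centred moving average; edges use the truncated window so the profile
    # keeps the alignment length
    if window == 1 or len(values) == 0:
        return values.copy()
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(values)))
    n = len(values)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def conservation_profile(
    aln: MultipleAlignment,
    mode: str = "blosum_similarity",
    window: int = 1,
    matrix: ScoringMatrix | None = None,
) -> ConservationProfile:
    """Compute the per-column conservation profile with optional smoothing."""
    if window < 1 or window % 2 == 0:
        raise ValueError(f"smoothing window must be odd and >= 1, got {window}")
    raw = np.array(
        [column_value(aln, c, mode, matrix) for c in range(aln.length)]
    )
    smoothed = _smooth(raw, window)
    average = float(np.mean(raw)) if len(raw) else 0.0
    return ConservationProfile(
        mode, tuple(smoothed.tolist()), tuple(raw.tolist()), window, average
    )


def classify_conservation(
    value: float, thresholds: ConservationThresholds = DEFAULT_SIMILARITY_THRESHOLDS
) -> str:
    """Band a conservation value: high / mid / low / none."""
    if value >= thresholds.high:
        return "high"
    if value >= thresholds.mid:
        return "mid"
    if value >= thresholds.low:
        return "low"
    return "none"


def residue_band(
    aln: MultipleAlignment,
    row: int,
    col: int,
    scheme: str = "by_conservation",
    id_threshold: float = 0.0,
    include_gaps: bool = True,
    thresholds: ConservationThresholds | None = None,
    matrix: ScoringMatrix | None = None,
) -> str:
    """Colour-band token for one residue cell.

    ``by_conservation`` returns the column's threshold band; ``by_type``
    returns ``"type"`` (meaning: colour by the residue's own scheme colour)
    only when the column percent identity reaches ``id_threshold``, else
    ``"neutral"``.  Gap cells are always neutral.
    """
    residue = aln.rows[row].residues[col]
    if residue == GAP:
        return "neutral"
    if scheme == "by_conservation":
        mode = "blosum_similarity"
        th = thresholds or DEFAULT_SIMILARITY_THRESHOLDS
        return classify_conservation(column_value(aln, col, mode, matrix), th)
    if scheme == "by_type":
        pid = column_percent_identity(aln, col, include_gaps=include_gaps)
        return "type" if pid >= id_threshold else "neutral"
    raise ValueError(f"unknown colouring scheme {scheme!r}")
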
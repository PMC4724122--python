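"""Windowed dot-matrix engine: three comparison modes, greyramp, persistence.

Every residue of one sequence is scored against every residue of the other;
scores are averaged over a sliding window along the alignment diagonal and
quantised to an 8-bit grid.  Greyscale rendering (the "greyramp") maps the
stored cells to pixels with adjustable min/max cutoffs, so contrast can be
re-tuned without recomputing the matrix.  Matrices persist to a small
versioned binary format (magic ``DTR2``) so a batch job can compute the grid
and a later session can render it instantly.

Modes
-----
``nn``  nucleotide vs nucleotide: two grids, one per strand of the
        horizontal sequence; reverse-strand alignments slope the other way.
``np``  nucleotide (horizontal) vs protein: the horizontal sequence is
        three-frame translated and each cell stores the best frame's score.
``pp``  protein vs protein: direct comparison.

Windows are odd and centred; at the edges the window is truncated to the
overlap that exists.  A zoom factor z maps z sequence positions per cell,
reducing the raw windowed scores within each zoom block by maximum.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate

from .seqcore import (
    NUCLEOTIDE,
    PROTEIN,
    ScoringMatrix,
    Sequence,
    default_matrix_for,
    reverse_complement,
    three_frame_translations,
)

__all__ = [
    "DotMatrix",
    "GreyrampParams",
    "DotFileError",
    "windowed_score",
    "compute_dot_matrix",
    "apply_greyramp",
    "save_dot_matrix",
    "load_dot_matrix",
    "overlay_segments",
    "OverlaySegment",
    "concatenate_for_multiplot",
    "write_pgm",
    "write_png",
]

MAGIC = b"DTR2"
FORMAT_VERSION = 1
_MODES = ("nn", "np", "pp")


class DotFileError(ValueError):
    """Bad magic, version or truncated dot-matrix file."""


@dataclass(frozen=True)
class GreyrampParams:
    min_cutoff: int = 40
    max_cutoff: int = 100

    def __post_init__(self) -> None:
        if not (0 <= self.min_cutoff <= 255 and 0 <= self.max_cutoff <= 255):
            raise ValueError("greyramp cutoffs must be in [0, 255]")
        if self.min_cutoff > self.max_cutoff:
            raise ValueError("min_cutoff must be <= max_cutoff")


@dataclass
class DotMatrix:
    """8-bit score grid plus the metadata needed to reinterpret it.

    ``cells[y, x]`` indexes vertical x horizontal cell space.  ``rev_cells``
    (nn mode only) holds the reverse-strand grid, stored so reverse-strand
    alignments appear as anti-diagonals: its cell (y, x) compares the
    reverse complement of the horizontal sequence at horizontal offset
    ``width*zoom - 1 - x`` against the vertical sequence at ``y``.
    """

    h_id: str
    v_id: str
    h_kind: str
    v_kind: str
    mode: str
    window: int
    zoom: int
    cells: np.ndarray
    score_scale: tuple[float, float]
    rev_cells: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.uint8)
        if self.rev_cells is not None:
            self.rev_cells = np.asarray(self.rev_cells, dtype=np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape


def _score_table(matrix: ScoringMatrix):
    lut = np.full((128, 128), np.nan)
    for (a, b), s in matrix.scores.items():
        lut[ord(a), ord(b)] = s
    return lut


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _pair_scores(a: str, b: str, matrix: ScoringMatrix) -> np.ndarray:
    """Full residue-by-residue score matrix S[j, i] = score(b[j], a[i])."""
    lut = _score_table(matrix)
    ea, eb = _encode(a), _encode(b)
    s = lut[np.ix_(eb, ea)]
    if np.isnan(s).any():
        raise LookupError(
            f"sequence contains symbols outside matrix {matrix.name}"
        )
    return s


def _window_mean_diagonal(s: np.ndarray, window: int) -> np.ndarray:
    """Mean of S over a length-`window` diagonal strip centred per cell.

    Edges where the window overhangs the matrix are averaged over the
    in-bounds part only (truncated window).
    """
    if window == 1:
        return s.astype(float)
    kernel = np.eye(window)
    sums = correlate(s, kernel, mode="constant", cval=0.0)
    counts = correlate(np.ones_like(s), kernel, mode="constant", cval=0.0)
    return sums / counts


def windowed_score(
    seq_a: Sequence,
    seq_b: Sequence,
    pos_a: int,
    pos_b: int,
    window: int,
    matrix: ScoringMatrix | None = None,
) -> float:
    """Mean substitution score of the window centred at (pos_a, pos_b).

    Positions are 0-based; the window must fit within both sequences.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    matrix = matrix or default_matrix_for(seq_a.kind)
    half = window // 2
    if not (half <= pos_a <= len(seq_a) - half - 1):
        raise IndexError(f"window around position {pos_a} exceeds sequence A")
    if not (half <= pos_b <= len(seq_b) - half - 1):
        raise IndexError(f"window around position {pos_b} exceeds sequence B")
    total = 0
    for k in range(-half, half + 1):
        total += matrix.scores[
            (seq_a.residues[pos_a + k], seq_b.residues[pos_b + k])
        ]
    return total / window


def _quantise(raw: np.ndarray, max_raw: float) -> np.ndarray:
    scaled = np.rint(255.0 * raw / max_raw) if max_raw > 0 else raw
    return np.clip(scaled, 0, 255).astype(np.uint8)


def _zoom_reduce(grid: np.ndarray, zoom: int) -> np.ndarray:
    if zoom == 1:
        return grid
    ny, nx = grid.shape
    out = np.zeros(((ny + zoom - 1) // zoom, (nx + zoom - 1) // zoom))
    for by in range(out.shape[0]):
        for bx in range(out.shape[1]):
            block = grid[by * zoom : (by + 1) * zoom, bx * zoom : (bx + 1) * zoom]
            out[by, bx] = block.max()
    return out


def compute_dot_matrix(
    seq_a: Sequence,
    seq_b: Sequence,
    mode: str | None = None,
    window: int = 25,
    matrix: ScoringMatrix | None = None,
    zoom: int = 1,
) -> DotMatrix:
    """All-vs-all windowed comparison of seq_a (horizontal) vs seq_b (vertical)."""
    if mode is None:
        mode = {
            (NUCLEOTIDE, NUCLEOTIDE): "nn",
            (NUCLEOTIDE, PROTEIN): "np",
            (PROTEIN, PROTEIN): "pp",
        }.get((seq_a.kind, seq_b.kind))
        if mode is None:
            raise ValueError(
                f"no comparison mode for kinds ({seq_a.kind}, {seq_b.kind})"
            )
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if zoom < 1:
        raise ValueError("zoom must be a positive integer")

    rev_cells = None
    if mode == "pp":
        if seq_a.kind != PROTEIN or seq_b.kind != PROTEIN:
            raise ValueError("pp mode requires two protein sequences")
        matrix = matrix or default_matrix_for(PROTEIN)
        raw = _window_mean_diagonal(
            _pair_scores(seq_a.residues, seq_b.residues, matrix), window
        )
    elif mode == "nn":
        if seq_a.kind != NUCLEOTIDE or seq_b.kind != NUCLEOTIDE:
            raise ValueError("nn mode requires two nucleotide sequences")
        matrix = matrix or default_matrix_for(NUCLEOTIDE)
        raw = _window_mean_diagonal(
            _pair_scores(seq_a.residues, seq_b.residues, matrix), window
        )
        rc = reverse_complement(seq_a)
        raw_rev = _window_mean_diagonal(
            _pair_scores(rc.residues, seq_b.residues, matrix), window
        )
        # store flipped so reverse-strand alignments run anti-diagonally
        raw_rev = raw_rev[:, ::-1]
    else:  # np: horizontal nucleotide is three-frame translated
        if seq_a.kind != NUCLEOTIDE or seq_b.kind != PROTEIN:
            raise ValueError(
                "np mode requires nucleotide (horizontal) vs protein (vertical)"
            )
        matrix = matrix or default_matrix_for(PROTEIN)
        frames = three_frame_translations(seq_a)
        width = max(len(f.residues) for f in frames)
        raw = np.full((len(seq_b.residues), width), -np.inf)
        for f in frames:
            if not f.residues:
                continue
            sub = _window_mean_diagonal(
                _pair_scores(f.residues, seq_b.residues, matrix), window
            )
            raw[:, : sub.shape[1]] = np.maximum(raw[:, : sub.shape[1]], sub)
        raw[~np.isfinite(raw)] = 0.0

    max_raw = float(matrix.max_score)
    cells = _quantise(_zoom_reduce(raw, zoom), max_raw)
    if mode == "nn":
        rev_cells = _quantise(_zoom_reduce(raw_rev, zoom), max_raw)
    return DotMatrix(
        seq_a.identifier,
        seq_b.identifier,
        seq_a.kind,
        seq_b.kind,
        mode,
        window,
        zoom,
        cells,
        (0.0, max_raw),
        rev_cells,
    )


def apply_greyramp(dm_or_cells, params: GreyrampParams) -> np.ndarray:
    """Map stored cells to pixel brightness (255 = white, 0 = black).

    Cells at or below the min cutoff render white (ignored); at or above the
    max cutoff render black (saturated); linear in between, rounded half-up.
    Brightness is non-increasing in cell score.
    """
    cells = dm_or_cells.cells if isinstance(dm_or_cells, DotMatrix) else dm_or_cells
    cells = np.asarray(cells, dtype=float)
    lo, hi = params.min_cutoff, params.max_cutoff
    if hi == lo:
        return np.where(cells <= lo, 255, 0).astype(np.uint8)
    frac = (hi - cells) / (hi - lo)
    pix = np.floor(255.0 * frac + 0.5)  # round half-up
    return np.clip(pix, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# persistence: "DTR2" versioned little-endian binary

_MODE_CODES = {"nn": 0, "np": 1, "pp": 2}
_KIND_CODES = {NUCLEOTIDE: 0, PROTEIN: 1}
_HEADER = "<4sHBBBHIIIddB"  # magic, version, mode, hkind, vkind, window,
# zoom, ny, nx, scale_min, scale_max, has_rev


def save_dot_matrix(dm: DotMatrix, path) -> None:
    ny, nx = dm.cells.shape
    head = struct.pack(
        _HEADER,
        MAGIC,
        FORMAT_VERSION,
        _MODE_CODES[dm.mode],
        _KIND_CODES[dm.h_kind],
        _KIND_CODES[dm.v_kind],
        dm.window,
        dm.zoom,
        ny,
        nx,
        dm.score_scale[0],
        dm.score_scale[1],
        1 if dm.rev_cells is not None else 0,
    )
    h_id = dm.h_id.encode()
    v_id = dm.v_id.encode()
    with open(path, "wb") as fh:
        fh.write(head)
        fh.write(struct.pack("<HH", len(h_id), len(v_id)))
        fh.write(h_id)
        fh.write(v_id)
        fh.write(dm.cells.tobytes())
        if dm.rev_cells is not None:
            fh.write(dm.rev_cells.tobytes())


def load_dot_matrix(path) -> DotMatrix:
    with open(path, "rb") as fh:
        data = fh.read()
    head_size = struct.calcsize(_HEADER)
    if len(data) < head_size + 4:
        raise DotFileError("truncated dot-matrix file (header incomplete)")
    (
        magic,
        version,
        mode_code,
        hk,
        vk,
        window,
        zoom,
        ny,
        nx,
        smin,
        smax,
        has_rev,
    ) = struct.unpack_from(_HEADER, data)
    if magic != MAGIC:
        raise DotFileError(f"bad magic {magic!r}; not a dot-matrix file")
    if version != FORMAT_VERSION:
        raise DotFileError(f"unsupported dot-matrix format version {version}")
    off = head_size
    hlen, vlen = struct.unpack_from("<HH", data, off)
    off += 4
    try:
        h_id = data[off : off + hlen].decode()
        off += hlen
        v_id = data[off : off + vlen].decode()
        off += vlen
    except UnicodeDecodeError as e:
        raise DotFileError(f"corrupt identifier block: {e}") from None
    n_cells = ny * nx
    expect = n_cells * (2 if has_rev else 1)
    if len(data) - off != expect:
        raise DotFileError(
            f"truncated dot-matrix file: expected {expect} cell bytes, "
            f"found {len(data) - off}"
        )
    cells = np.frombuffer(data[off : off + n_cells], dtype=np.uint8).reshape(ny, nx)
    rev = None
    if has_rev:
        rev = np.frombuffer(
            data[off + n_cells : off + 2 * n_cells], dtype=np.uint8
        ).reshape(ny, nx)
    modes = {v: k for k, v in _MODE_CODES.items()}
    kinds = {v: k for k, v in _KIND_CODES.items()}
    return DotMatrix(
        h_id,
        v_id,
        kinds[hk],
        kinds[vk],
        modes[mode_code],
        window,
        zoom,
        cells.copy(),
        (smin, smax),
        rev.copy() if rev is not None else None,
    )


# ---------------------------------------------------------------------------
# overlays and multi-sequence self plots


@dataclass(frozen=True)
class OverlaySegment:
    """A plot overlay in cell space: a diagonal HSP or an axis interval."""

    kind: str  # "hsp", "h_axis" or "v_axis"
    x0: int | None
    y0: int | None
    x1: int | None
    y1: int | None
    label: str = ""


def overlay_segments(dm: DotMatrix, features) -> list[OverlaySegment]:
    """Project GFF features into cell space for drawing over the plot.

    Features whose Target matches the vertical sequence become diagonal
    segments; features positioned on the horizontal or vertical sequence
    alone become axis intervals.  1-based inclusive sequence coordinates map
    to 0-based cells by floor-division with the zoom factor.  Features wholly
    outside the plot are dropped with a warning.
    """
    import logging

    log = logging.getLogger("alnkit.dotplot")
    ny, nx = dm.cells.shape
    z = dm.zoom
    out: list[OverlaySegment] = []
    for f in features:
        label = f.attributes.get("Name", f.attributes.get("ID", f.type))
        target = f.target
        if target is not None and f.seqid == dm.h_id and target[0] == dm.v_id:
            x0, x1 = (f.start - 1) // z, (f.end - 1) // z
            y0, y1 = (target[1] - 1) // z, (target[2] - 1) // z
            if x0 >= nx or y0 >= ny:
                log.warning("overlay feature %s outside plot range", label)
                continue
            clip = False
            if x1 >= nx or y1 >= ny:
                clip = True
                x1, y1 = min(x1, nx - 1), min(y1, ny - 1)
            if clip:
                log.warning("overlay feature %s clipped to plot range", label)
            out.append(OverlaySegment("hsp", x0, y0, x1, y1, label))
        elif f.seqid == dm.h_id:
            x0, x1 = (f.start - 1) // z, (f.end - 1) // z
            if x0 >= nx:
                log.warning("overlay feature %s outside plot range", label)
                continue
            out.append(
                OverlaySegment("h_axis", x0, None, min(x1, nx - 1), None, label)
            )
        elif f.seqid == dm.v_id:
            y0, y1 = (f.start - 1) // z, (f.end - 1) // z
            if y0 >= ny:
                log.warning("overlay feature %s outside plot range", label)
                continue
            out.append(
                OverlaySegment("v_axis", None, y0, None, min(y1, ny - 1), label)
            )
        else:
            log.warning("overlay feature %s matches neither axis", label)
    return out


def concatenate_for_multiplot(seqs: list[Sequence]) -> tuple[Sequence, list[int]]:
    """Concatenate same-kind sequences for an all-vs-all self plot.

    Returns the concatenated sequence and the cumulative boundary offsets
    ``[0, L1, L1+L2, ...]`` used to draw the section grid.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    kinds = {s.kind for s in seqs}
    if len(kinds) != 1:
        raise ValueError("all sequences must have the same kind")
    offsets = [0]
    for s in seqs:
        offsets.append(offsets[-1] + len(s.residues))
    ident = "+".join(s.identifier for s in seqs)
    cat = Sequence(ident, "".join(s.residues for s in seqs), seqs[0].kind)
    return cat, offsets


# ---------------------------------------------------------------------------
# image export


def write_pgm(pixels: np.ndarray, path) -> None:
    """Binary PGM (P5), maxval 255."""
    pixels = np.asarray(pixels, dtype=np.uint8)
    ny, nx = pixels.shape
    with open(path, "wb") as fh:
        fh.write(f"P5\n{nx} {ny}\n255\n".encode())
        fh.write(pixels.tobytes())


def write_png(pixels: np.ndarray, path) -> None:
    """Greyscale PNG via Pillow."""
    from PIL import Image

    Image.fromarray(np.asarray(pixels, dtype=np.uint8), mode="L").save(path)
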
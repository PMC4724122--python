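"""Multiple-alignment I/O: Stockholm 1.0, GCG MSF, Selex and aligned FASTA.

These are the four interchange formats used by Pfam-style curation.  All four
readers produce the same in-memory :class:`MultipleAlignment`; all four
writers are deterministic byte-for-byte, so conversion cycles through any
sequence of formats preserve names and residue strings exactly.

Row names may carry coordinates in the ``name/start-end`` convention
(1-based, inclusive); these are parsed into per-row ``start``/``end`` fields
and re-attached on write.  Stockholm ``#=GF/#=GS/#=GC/#=GR`` markup is
preserved verbatim for round-trip; ``#=GS <name> SC <value>`` lines are
additionally parsed into per-row scores (used by score-based filtering).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .seqcore import GAP, NUCLEOTIDE, PROTEIN

__all__ = [
    "AlignmentFormatError",
    "AlignmentLengthError",
    "Row",
    "MultipleAlignment",
    "read_alignment",
    "write_alignment",
    "detect_format",
    "gcg_checksum",
    "FORMATS",
]

FORMATS = ("stockholm", "msf", "selex", "fasta")

_NAME_COORD_RE = re.compile(r"^(?P<name>.+)/(?P<start>\d+)-(?P<end>\d+)$")


class AlignmentFormatError(ValueError):
    """Unreadable or unrecognised alignment text."""


class AlignmentLengthError(AlignmentFormatError):
    """Rows of unequal length (a ragged alignment)."""


@dataclass(frozen=True)
class Row:
    """One alignment row: a name, optional 1-based coordinates, gapped residues."""

    name: str
    residues: str
    start: int | None = None
    end: int | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "residues", self.residues.upper().replace(".", GAP)
        )
        n_res = len(self.residues) - self.residues.count(GAP)
        if self.start is not None and self.end is not None:
            if self.end - self.start + 1 != n_res:
                raise ValueError(
                    f"row {self.name!r}: coordinates {self.start}-{self.end} "
                    f"imply {self.end - self.start + 1} residues but the row "
                    f"has {n_res}"
                )

    @property
    def display_name(self) -> str:
        if self.start is not None and self.end is not None:
            return f"{self.name}/{self.start}-{self.end}"
        return self.name

    @property
    def gap_fraction(self) -> float:
        if not self.residues:
            return 0.0
        return self.residues.count(GAP) / len(self.residues)


def _guess_kind(rows: list[Row]) -> str:
    residues = "".join(r.residues for r in rows).replace(GAP, "")
    if residues and set(residues) <= set("ACGTUN"):
        return NUCLEOTIDE
    return PROTEIN


@dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length gapped rows with optional coordinates and annotations."""

    rows: tuple[Row, ...]
    kind: str = PROTEIN
    annotations: tuple[str, ...] = ()  # verbatim Stockholm markup lines

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))
        object.__setattr__(self, "annotations", tuple(self.annotations))
        if self.rows:
            width = len(self.rows[0].residues)
            for r in self.rows:
                if len(r.residues) != width:
                    raise AlignmentLengthError(
                        f"row {r.display_name!r} has length {len(r.residues)}, "
                        f"expected {width}"
                    )
        seen = set()
        for r in self.rows:
            if r.display_name in seen:
                raise AlignmentFormatError(
                    f"duplicate row name {r.display_name!r}"
                )
            seen.add(r.display_name)

    @property
    def length(self) -> int:
        return len(self.rows[0].residues) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def names(self) -> list[str]:
        return [r.display_name for r in self.rows]

    def row(self, name: str) -> Row:
        for r in self.rows:
            if r.display_name == name or r.name == name:
                return r
        raise LookupError(f"no row named {name!r}")

    def column(self, col: int) -> list[str]:
        return [r.residues[col] for r in self.rows]

    def with_rows(self, rows) -> "MultipleAlignment":
        return MultipleAlignment(tuple(rows), self.kind, self.annotations)

    @classmethod
    def from_rows(cls, named_rows, kind: str | None = None) -> "MultipleAlignment":
        """Build from ``(name, residues)`` pairs, parsing name/start-end."""
        rows = [_make_row(n, s) for n, s in named_rows]
        return cls(tuple(rows), kind or _guess_kind(rows))


def _make_row(raw_name: str, residues: str, score: float | None = None) -> Row:
    m = _NAME_COORD_RE.match(raw_name)
    if m:
        start, end = int(m.group("start")), int(m.group("end"))
        n_res = len(residues) - residues.count("-") - residues.count(".")
        if end - start + 1 == n_res:
            return Row(m.group("name"), residues, start, end, score)
    return Row(raw_name, residues, score=score)


# ---------------------------------------------------------------------------
# format detection


def detect_format(text: str) -> str:
    """Auto-detect one of the four supported formats from the text itself."""
    stripped = text.lstrip()
    if not stripped:
        raise AlignmentFormatError("empty alignment text")
    if stripped.startswith("# STOCKHOLM"):
        return "stockholm"
    first = stripped.splitlines()[0]
    if first.startswith("!!") or "MSF:" in first or _has_msf_header(text):
        return "msf"
    if stripped.startswith(">"):
        return "fasta"
    # fall through: Selex is plain two-column name/sequence lines
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if len(line.split()) >= 2:
            return "selex"
        raise AlignmentFormatError(
            f"cannot determine alignment format (first data line {line!r})"
        )
    raise AlignmentFormatError("cannot determine alignment format")


def _has_msf_header(text: str) -> bool:
    for line in text.splitlines()[:20]:
        if "MSF:" in line and "Check:" in line:
            return True
    return False


# ---------------------------------------------------------------------------
# readers


def read_alignment(text: str, fmt: str = "auto") -> MultipleAlignment:
    """Read alignment text in the given format (``auto`` to detect)."""
    if not text.strip():
        raise AlignmentFormatError("empty alignment text")
    if fmt == "auto":
        fmt = detect_format(text)
    if fmt == "stockholm":
        return _read_stockholm(text)
    if fmt == "msf":
        return _read_msf(text)
    if fmt == "selex":
        return _read_selex(text)
    if fmt == "fasta":
        return _read_fasta(text)
    raise AlignmentFormatError(f"unknown alignment format {fmt!r}")


def _read_stockholm(text: str) -> MultipleAlignment:
    order: list[str] = []
    chunks: dict[str, list[str]] = {}
    markup: list[str] = []
    scores: dict[str, float] = {}
    for line in text.splitlines():
        if line.startswith("# STOCKHOLM") or line.strip() == "//":
            continue
        if line.startswith("#="):
            markup.append(line.rstrip("\n"))
            parts = line.split()
            if len(parts) == 4 and parts[0] == "#=GS" and parts[2] == "SC":
                try:
                    scores[parts[1]] = float(parts[3])
                except ValueError:
                    pass
            continue
        if line.startswith("#") or not line.strip():
            continue
        parts = line.split()
        if len(parts) != 2:
            raise AlignmentFormatError(
                f"malformed Stockholm sequence line: {line!r}"
            )
        name, seq = parts
        if name not in chunks:
            order.append(name)
            chunks[name] = []
        chunks[name].append(seq)
    if not order:
        raise AlignmentFormatError("Stockholm text contains no sequence rows")
    rows = [
        _make_row(n, "".join(chunks[n]), scores.get(n)) for n in order
    ]
    return MultipleAlignment(tuple(rows), _guess_kind(rows), tuple(markup))


def _read_selex(text: str) -> MultipleAlignment:
    order: list[str] = []
    chunks: dict[str, list[str]] = {}
    for line in text.splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise AlignmentFormatError(f"malformed Selex line: {line!r}")
        name, seq = parts
        if name not in chunks:
            order.append(name)
            chunks[name] = []
        chunks[name].append(seq)
    if not order:
        raise AlignmentFormatError("Selex text contains no sequence rows")
    rows = [_make_row(n, "".join(chunks[n])) for n in order]
    return MultipleAlignment(tuple(rows), _guess_kind(rows))


def _read_fasta(text: str) -> MultipleAlignment:
    named: list[tuple[str, str]] = []
    name = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                named.append((name, "".join(chunks)))
            name = line[1:].split()[0] if len(line) > 1 else ""
            chunks = []
        elif name is None:
            raise AlignmentFormatError("FASTA text does not start with '>'")
        else:
            chunks.append(line)
    if name is not None:
        named.append((name, "".join(chunks)))
    if not named:
        raise AlignmentFormatError("FASTA text contains no records")
    return MultipleAlignment.from_rows(named)


def _read_msf(text: str) -> MultipleAlignment:
    lines = text.splitlines()
    try:
        sep = next(i for i, l in enumerate(lines) if l.strip() in ("//", "//\n"))
    except StopIteration:
        raise AlignmentFormatError("MSF text has no '//' separator") from None
    order: list[str] = []
    for line in lines[:sep]:
        m = re.search(r"Name:\s+(\S+)", line)
        if m:
            order.append(m.group(1))
    if not order:
        raise AlignmentFormatError("MSF header declares no sequences")
    chunks: dict[str, list[str]] = {n: [] for n in order}
    for line in lines[sep + 1 :]:
        parts = line.split()
        if not parts:
            continue
        if parts[0] in chunks and len(parts) > 1:
            chunks[parts[0]].extend(parts[1:])
    rows = [_make_row(n, "".join(chunks[n]).replace(".", "-")) for n in order]
    return MultipleAlignment(tuple(rows), _guess_kind(rows))


# ---------------------------------------------------------------------------
# writers


def write_alignment(aln: MultipleAlignment, fmt: str) -> str:
    """Serialise the alignment; output is byte-stable for a fixed input."""
    if fmt == "stockholm":
        return _write_stockholm(aln)
    if fmt == "msf":
        return _write_msf(aln)
    if fmt == "selex":
        return _write_selex(aln)
    if fmt == "fasta":
        return _write_fasta(aln)
    raise AlignmentFormatError(f"unknown alignment format {fmt!r}")


def _name_field_width(aln: MultipleAlignment) -> int:
    return max((len(r.display_name) for r in aln.rows), default=0)


def _write_stockholm(aln: MultipleAlignment) -> str:
    out = ["# STOCKHOLM 1.0"]
    gs = [l for l in aln.annotations if l.startswith(("#=GF", "#=GS"))]
    gc = [l for l in aln.annotations if not l.startswith(("#=GF", "#=GS"))]
    out.extend(gs)
    width = _name_field_width(aln)
    for r in aln.rows:
        out.append(f"{r.display_name:<{width}} {r.residues}")
    out.extend(gc)
    out.append("//")
    return "\n".join(out) + "\n"


def _write_selex(aln: MultipleAlignment) -> str:
    width = _name_field_width(aln)
    out = [f"{r.display_name:<{width}} {r.residues}" for r in aln.rows]
    return "\n".join(out) + "\n"


def _write_fasta(aln: MultipleAlignment) -> str:
    out = []
    for r in aln.rows:
        out.append(f">{r.display_name}")
        for i in range(0, len(r.residues), 60):
            out.append(r.residues[i : i + 60])
        if not r.residues:
            out.append("")
    return "\n".join(out) + "\n"


def gcg_checksum(residues: str) -> int:
    """GCG checksum: sum of ((i mod 57)+1) * ascii(residue), mod 10000."""
    return sum(((i % 57) + 1) * ord(c) for i, c in enumerate(residues)) % 10000


def _write_msf(aln: MultipleAlignment) -> str:
    # GCG dialect: '.' as the gap character, 50 residues per line in
    # 10-symbol groups, per-sequence and global checksums in the header.
    seqs = {r.display_name: r.residues.replace("-", ".") for r in aln.rows}
    names = [r.display_name for r in aln.rows]
    checks = {n: gcg_checksum(seqs[n]) for n in names}
    total = sum(checks.values()) % 10000
    kind_code = "N" if aln.kind == NUCLEOTIDE else "P"
    out = [
        "!!{}A_MULTIPLE_ALIGNMENT 1.0".format("N" if kind_code == "N" else "A"),
        "",
        f" alnkit.msf MSF: {aln.length} Type: {kind_code} Check: {total} ..",
        "",
    ]
    width = _name_field_width(aln)
    for n in names:
        out.append(
            f" Name: {n:<{width}} Len: {aln.length} "
            f"Check: {checks[n]:>5} Weight: 1.00"
        )
    out.append("")
    out.append("//")
    for block in range(0, aln.length, 50):
        out.append("")
        for n in names:
            chunk = seqs[n][block : block + 50]
            groups = " ".join(
                chunk[i : i + 10] for i in range(0, len(chunk), 10)
            )
            out.append(f"{n:<{width}} {groups}")
    return "\n".join(out) + "\n"
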
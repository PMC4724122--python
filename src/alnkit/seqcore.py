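"""Shared sequence primitives: alphabets, complementation, translation, scoring.

Everything downstream (alignment I/O, conservation scoring, dot plots,
match classification) builds on the two types defined here: :class:`Sequence`
(a named nucleotide or protein string, possibly gapped) and
:class:`ScoringMatrix` (a symmetric substitution-score table such as BLOSUM62).

Conventions
-----------
* Residues are case-folded to upper case on ingest; both ``-`` and ``.`` are
  accepted as gap characters and normalised to ``-``.
* Nucleotide sequences may contain IUPAC ambiguity codes.  ``N`` never counts
  as an exact match anywhere in the package.
* "Conserved" (as opposed to exact) means a positive substitution score; this
  is the trichotomy exact / conserved / mismatch used for per-base colouring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

__all__ = [
    "AlphabetError",
    "Sequence",
    "ScoringMatrix",
    "GAP",
    "NUCLEOTIDE",
    "PROTEIN",
    "reverse_complement",
    "translate",
    "three_frame_translations",
    "substitution_score",
    "blosum62",
    "dna_default_matrix",
    "load_matrix_file",
    "default_matrix_for",
    "read_fasta",
    "write_fasta",
    "is_gap",
]

GAP = "-"
NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

_IUPAC_NT = set("ACGTUNRYSWKMBDHV")
_PROTEIN_AA = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVN-",
    "TGCAAYRSWMKVHDBN-",
)

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


class AlphabetError(ValueError):
    """Residues outside the declared alphabet, or wrong sequence kind."""


def _normalise(residues: str, kind: str) -> str:
    norm = residues.upper().replace(".", GAP)
    if kind == NUCLEOTIDE:
        norm = norm.replace("U", "T")
    return norm


def is_gap(symbol: str) -> bool:
    return symbol in ("-", ".")


@dataclass(frozen=True)
class Sequence:
    """A named sequence over a nucleotide or protein alphabet.

    ``residues`` may contain gap characters; they are normalised to ``-``.
    RNA input is accepted and normalised with U -> T.
    """

    identifier: str
    residues: str
    kind: str = NUCLEOTIDE

    def __post_init__(self) -> None:
        if self.kind not in (NUCLEOTIDE, PROTEIN):
            raise AlphabetError(f"unknown sequence kind {self.kind!r}")
        norm = _normalise(self.residues, self.kind)
        object.__setattr__(self, "residues", norm)
        allowed = _IUPAC_NT if self.kind == NUCLEOTIDE else _PROTEIN_AA
        bad = set(norm) - allowed - {GAP}
        if bad:
            raise AlphabetError(
                f"sequence {self.identifier!r}: symbols {sorted(bad)} not in "
                f"{self.kind} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


def reverse_complement(seq: Sequence) -> Sequence:
    """Reverse-complement a nucleotide sequence (IUPAC codes included).

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    if seq.kind != NUCLEOTIDE:
        raise AlphabetError("reverse_complement requires a nucleotide sequence")
    rc = seq.residues.translate(_COMPLEMENT)[::-1]
    return replace(seq, residues=rc)


def translate(seq: Sequence, frame: int = 1, strand: str = "+") -> Sequence:
    """Translate one reading frame with the standard codon table.

    ``frame`` is 1, 2 or 3; ``strand='-'`` reverse-complements first.  The
    incomplete trailing codon is dropped, stop codons become ``*`` and codons
    containing ambiguity codes or gaps become ``X``.
    """
    if frame not in (1, 2, 3):
        raise ValueError(f"frame must be 1, 2 or 3, got {frame}")
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if seq.kind != NUCLEOTIDE:
        raise AlphabetError("translate requires a nucleotide sequence")
    if strand == "-":
        seq = reverse_complement(seq)
    nt = seq.residues[frame - 1 :]
    aa = []
    fwd = _STANDARD_TABLE.forward_table
    stops = set(_STANDARD_TABLE.stop_codons)
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if codon in stops:
            aa.append("*")
        else:
            aa.append(fwd.get(codon, "X"))
    ident = f"{seq.identifier}_frame{frame}{strand}"
    return Sequence(ident, "".join(aa), PROTEIN)


def three_frame_translations(seq: Sequence, strand: str = "+") -> list[Sequence]:
    """All three reading-frame translations of one strand, frames 1..3."""
    return [translate(seq, frame, strand) for frame in (1, 2, 3)]


@dataclass(frozen=True)
class ScoringMatrix:
    """A symmetric integer substitution-score table over an alphabet."""

    name: str
    alphabet: tuple[str, ...]
    scores: dict = field(repr=False)

    def __post_init__(self) -> None:
        for a in self.alphabet:
            for b in self.alphabet:
                if (a, b) not in self.scores:
                    raise ValueError(f"matrix {self.name}: missing pair ({a},{b})")
                if self.scores[(a, b)] != self.scores[(b, a)]:
                    raise ValueError(f"matrix {self.name}: asymmetric at ({a},{b})")

    @property
    def max_score(self) -> int:
        return max(self.scores[(a, a)] for a in self.alphabet)

    def score(self, a: str, b: str) -> int:
        return substitution_score(self, a, b)


def substitution_score(matrix: ScoringMatrix, a: str, b: str) -> int:
    """Symmetric score lookup; gaps and unknown symbols are rejected."""
    a, b = a.upper(), b.upper()
    for sym in (a, b):
        if is_gap(sym):
            raise LookupError(f"gap symbol {sym!r} has no substitution score")
        if (sym, sym) not in matrix.scores:
            raise LookupError(f"symbol {sym!r} not in matrix {matrix.name}")
    return matrix.scores[(a, b)]


def _from_biopython(name: str, arr) -> ScoringMatrix:
    alphabet = tuple(arr.alphabet)
    scores = {}
    for i, a in enumerate(alphabet):
        for j, b in enumerate(alphabet):
            scores[(a, b)] = int(arr[i, j])
    return ScoringMatrix(name, alphabet, scores)


_CACHE: dict = {}


def blosum62() -> ScoringMatrix:
    """The published BLOSUM62 protein matrix (via biopython's copy)."""
    if "BLOSUM62" not in _CACHE:
        _CACHE["BLOSUM62"] = _from_biopython(
            "BLOSUM62", substitution_matrices.load("BLOSUM62")
        )
    return _CACHE["BLOSUM62"]


def dna_default_matrix(match: int = 5, mismatch: int = -4) -> ScoringMatrix:
    """Default DNA matrix: +5 match / -4 mismatch over the IUPAC alphabet.

    Ambiguity codes (including N) always score as mismatches, even against
    themselves, so N can never look like a perfect match.
    """
    key = ("DNA", match, mismatch)
    if key not in _CACHE:
        alphabet = tuple("ACGT") + tuple(sorted(_IUPAC_NT - set("ACGTU")))
        scores = {}
        for a in alphabet:
            for b in alphabet:
                exact = a == b and a in "ACGT"
                scores[(a, b)] = match if exact else mismatch
        _CACHE[key] = ScoringMatrix(f"DNA+{match}/{mismatch}", alphabet, scores)
    return _CACHE[key]


def default_matrix_for(kind: str) -> ScoringMatrix:
    return blosum62() if kind == PROTEIN else dna_default_matrix()


def load_matrix_file(path: str) -> ScoringMatrix:
    """Load an NCBI-format substitution-matrix text file."""
    arr = substitution_matrices.read(path)
    import os

    return _from_biopython(os.path.basename(str(path)), arr)


def read_fasta(text: str, kind: str = NUCLEOTIDE) -> list[Sequence]:
    """Parse multi-record FASTA text into sequences of the given kind."""
    records: list[Sequence] = []
    name = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                records.append(Sequence(name, "".join(chunks), kind))
            name = line[1:].split()[0] if len(line) > 1 else ""
            chunks = []
        elif name is None:
            raise ValueError("FASTA text does not start with a '>' header")
        else:
            chunks.append(line)
    if name is not None:
        records.append(Sequence(name, "".join(chunks), kind))
    return records


def write_fasta(seqs: list[Sequence], width: int = 60) -> str:
    """Write sequences as FASTA, wrapped at ``width`` columns."""
    out = []
    for s in seqs:
        out.append(f">{s.identifier}")
        for i in range(0, len(s.residues), width):
            out.append(s.residues[i : i + width])
        if not s.residues:
            out.append("")
    return "\n".join(out) + "\n"
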
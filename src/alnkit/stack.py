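"""Many-to-one alignment stacking: GFF3 match features against one reference.

This is the headless engine behind a stacked alignment browser: a FASTA
reference plus a GFF3 file of match features (with ``Target`` and ``Gap``
attributes), gene models and other features.  It projects each match onto
the reference via its Gap CIGAR, classifies every aligned base
(exact / conserved / mismatch / insertion / deletion), computes coverage,
collapses identical reads ("squashing"), sorts, and checks splice sites.

Coordinates are 1-based inclusive at the GFF3 boundary and in all public
outputs.  Gap semantics follow the GFF3 specification: ``I`` is a gap in the
reference (extra target residues), ``D`` a gap in the target; in protein
mode (a protein match against a nucleotide reference) each M/D unit consumes
three reference bases per target residue.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from urllib.parse import unquote

from .seqcore import (
    NUCLEOTIDE,
    PROTEIN,
    ScoringMatrix,
    Sequence,
    default_matrix_for,
    reverse_complement,
    substitution_score,
    translate,
)

__all__ = [
    "Gff3Error",
    "GenomicFeature",
    "MatchAlignment",
    "CoverageTrack",
    "parse_gff3",
    "project_alignment",
    "classify_match_bases",
    "coverage_track",
    "coverage_bedgraph",
    "squash_identical_matches",
    "sort_features",
    "detect_splice_sites",
    "SpliceSite",
    "render_detail_view",
]

log = logging.getLogger("alnkit.stack")

_GAP_OPS = set("MIDFR")
_PROTEIN_MATCH_TYPES = {"protein_match"}


class Gff3Error(ValueError):
    """A malformed GFF3 line; carries the 1-based line number."""

    def __init__(self, line_no: int, message: str):
        super().__init__(f"GFF3 line {line_no}: {message}")
        self.line_no = line_no


@dataclass(frozen=True)
class GenomicFeature:
    """One GFF3 feature with parsed Target and Gap attributes."""

    seqid: str
    source: str
    type: str
    start: int
    end: int
    score: float | None
    strand: str
    phase: str
    attributes: dict = field(default_factory=dict)
    gap_ops: tuple[tuple[str, int], ...] | None = None
    line_no: int = 0

    @property
    def target(self) -> tuple[str, int, int, str] | None:
        """(target id, start, end, strand) from the Target attribute."""
        raw = self.attributes.get("Target")
        if raw is None:
            return None
        parts = raw.split()
        tid, tstart, tend = parts[0], int(parts[1]), int(parts[2])
        tstrand = parts[3] if len(parts) > 3 else "+"
        return tid, tstart, tend, tstrand

    @property
    def gap_string(self) -> str:
        if self.gap_ops is None:
            return ""
        return " ".join(f"{op}{n}" for op, n in self.gap_ops)

    @property
    def is_protein_match(self) -> bool:
        return self.type in _PROTEIN_MATCH_TYPES


def _parse_attributes(col: str, line_no: int) -> dict:
    attrs: dict = {}
    if col in (".", ""):
        return attrs
    for item in col.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise Gff3Error(line_no, f"attribute without '=': {item!r}")
        key, value = item.split("=", 1)
        attrs[unquote(key)] = unquote(value)
    return attrs


def _parse_gap(raw: str, line_no: int) -> tuple[tuple[str, int], ...]:
    ops = []
    for tok in raw.split():
        m = re.fullmatch(r"([A-Z])(\d+)", tok)
        if not m or m.group(1) not in _GAP_OPS:
            raise Gff3Error(line_no, f"bad Gap token {tok!r}")
        length = int(m.group(2))
        if length <= 0:
            raise Gff3Error(line_no, f"non-positive Gap op length in {tok!r}")
        ops.append((m.group(1), length))
    return tuple(ops)


def parse_gff3(text: str, strict: bool = True) -> list[GenomicFeature]:
    """Parse GFF3 text into features.

    ``strict=True`` raises on the first malformed line (with its line
    number); ``strict=False`` logs and skips malformed lines.  Unknown
    feature types are retained.
    """
    features: list[GenomicFeature] = []
    for line_no, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        try:
            features.append(_parse_line(line, line_no))
        except Gff3Error:
            if strict:
                raise
            log.warning("skipping malformed GFF3 line %d: %r", line_no, line)
    return features


def _parse_line(line: str, line_no: int) -> GenomicFeature:
    cols = line.split("\t")
    if len(cols) != 9:
        raise Gff3Error(line_no, f"expected 9 tab-separated columns, got {len(cols)}")
    seqid, source, ftype, start_s, end_s, score_s, strand, phase, attr_col = cols
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise Gff3Error(line_no, f"non-integer coordinates {start_s!r}/{end_s!r}")
    if start > end:
        raise Gff3Error(line_no, f"start {start} > end {end}")
    if strand not in ("+", "-", ".", "?"):
        raise Gff3Error(line_no, f"bad strand {strand!r}")
    score = None if score_s == "." else float(score_s)
    attrs = _parse_attributes(attr_col, line_no)
    gap_ops = None
    if "Gap" in attrs:
        gap_ops = _parse_gap(attrs["Gap"], line_no)
    feat = GenomicFeature(
        seqid, source, ftype, start, end, score, strand, phase, attrs, gap_ops, line_no
    )
    if feat.target is not None and gap_ops is not None:
        _check_gap_consistency(feat, line_no)
    return feat


def _consumptions(feat: GenomicFeature) -> tuple[int, int]:
    """(reference, target) units consumed by the Gap ops."""
    scale = 3 if feat.is_protein_match else 1
    ref = tgt = 0
    for op, n in feat.gap_ops or ():
        if op == "M":
            ref += n * scale
            tgt += n
        elif op == "I":
            tgt += n
        elif op == "D":
            ref += n * scale
        elif op == "F":
            ref += n  # frameshift forward: reference-only, single bases
        elif op == "R":
            ref -= n
    return ref, tgt


def _check_gap_consistency(feat: GenomicFeature, line_no: int) -> None:
    ref, tgt = _consumptions(feat)
    span = feat.end - feat.start + 1
    tid, tstart, tend, _ = feat.target
    tspan = tend - tstart + 1
    if ref != span:
        raise Gff3Error(
            line_no,
            f"Gap ops consume {ref} reference bases but the feature spans {span}",
        )
    if tgt != tspan:
        raise Gff3Error(
            line_no,
            f"Gap ops consume {tgt} target units but Target spans {tspan}",
        )


# ---------------------------------------------------------------------------
# projection


@dataclass(frozen=True)
class MatchAlignment:
    """A match feature expanded into per-position (reference, target) pairs.

    Each pair is ``(ref_pos | None, target_pos | None)`` in 1-based
    coordinates; ``None`` marks the gapped side (insertion: no ref position;
    deletion: no target position).  In protein mode each pair's reference
    position is the first base of the codon (three bases consumed per pair).
    """

    feature: GenomicFeature
    pairs: tuple[tuple[int | None, int | None], ...]
    mode: str  # nucleotide or protein

    @property
    def ref_unit(self) -> int:
        return 3 if self.mode == PROTEIN else 1


def project_alignment(feature: GenomicFeature, refseq: Sequence | None = None) -> MatchAlignment:
    """Expand a match feature's Gap CIGAR into aligned position pairs.

    Without a Gap attribute the whole span is one M block.  ``refseq`` is
    optional and only used for bounds checking.
    """
    target = feature.target
    if target is None:
        raise ValueError("feature has no Target attribute; not a match")
    tid, tstart, tend, tstrand = target
    mode = PROTEIN if feature.is_protein_match else NUCLEOTIDE
    scale = 3 if mode == PROTEIN else 1
    span = feature.end - feature.start + 1
    ops = feature.gap_ops
    if ops is None:
        if span != (tend - tstart + 1) * scale:
            raise ValueError(
                f"feature span {span} inconsistent with Target span "
                f"{tend - tstart + 1} (no Gap attribute)"
            )
        ops = (("M", tend - tstart + 1),)
    if refseq is not None and feature.end > len(refseq.residues):
        raise IndexError(
            f"feature {feature.start}-{feature.end} exceeds reference length "
            f"{len(refseq.residues)}"
        )
    pairs: list[tuple[int | None, int | None]] = []
    ref = feature.start
    tgt = tstart
    tstep = 1 if tstrand != "-" else -1
    if tstrand == "-":
        tgt = tend
    for op, n in ops:
        if op == "M":
            for _ in range(n):
                pairs.append((ref, tgt))
                ref += scale
                tgt += tstep
        elif op == "I":
            for _ in range(n):
                pairs.append((None, tgt))
                tgt += tstep
        elif op == "D":
            for _ in range(n):
                pairs.append((ref, None))
                ref += scale
        elif op == "F":
            ref += n
        elif op == "R":
            ref -= n
        else:
            raise ValueError(f"unsupported Gap op {op!r}")
    consumed = ref - feature.start
    if consumed != span:
        raise ValueError(
            f"Gap ops consume {consumed} reference bases, expected {span}"
        )
    return MatchAlignment(feature, tuple(pairs), mode)


def classify_match_bases(
    malign: MatchAlignment,
    refseq: Sequence,
    matchseq: Sequence,
    matrix: ScoringMatrix | None = None,
) -> list[str]:
    """Per-pair classification: exact / conserved / mismatch / insertion / deletion.

    Nucleotide mode has no conserved class, and ``N`` never counts as exact.
    Protein mode compares the translated reference codon against the target
    residue; conserved means unequal residues with a positive substitution
    score.
    """
    mode = malign.mode
    matrix = matrix or default_matrix_for(mode)
    out = []
    feature_strand = malign.feature.strand
    for ref_pos, tgt_pos in malign.pairs:
        if ref_pos is None:
            out.append("insertion")
            continue
        if tgt_pos is None:
            out.append("deletion")
            continue
        if mode == PROTEIN:
            codon = refseq.residues[ref_pos - 1 : ref_pos + 2]
            if len(codon) < 3:
                raise IndexError(f"codon at {ref_pos} exceeds reference")
            codon_seq = Sequence("codon", codon, NUCLEOTIDE)
            if feature_strand == "-":
                codon_seq = reverse_complement(codon_seq)
            ref_res = translate(codon_seq).residues
            ref_res = ref_res or "X"
        else:
            if ref_pos > len(refseq.residues):
                raise IndexError(f"reference position {ref_pos} out of range")
            ref_res = refseq.residues[ref_pos - 1]
            if feature_strand == "-":
                ref_res = reverse_complement(
                    Sequence("b", ref_res, NUCLEOTIDE)
                ).residues
        if tgt_pos > len(matchseq.residues):
            raise IndexError(f"target position {tgt_pos} out of range")
        tgt_res = matchseq.residues[tgt_pos - 1]
        if ref_res == tgt_res and not (mode == NUCLEOTIDE and ref_res == "N"):
            out.append("exact")
        elif mode == PROTEIN and substitution_score(matrix, ref_res, tgt_res) > 0:
            out.append("conserved")
        else:
            out.append("mismatch")
    return out


# ---------------------------------------------------------------------------
# coverage


@dataclass(frozen=True)
class CoverageTrack:
    """Per-base read depth over a reference interval (1-based inclusive)."""

    seqid: str
    start: int
    end: int
    depth: tuple[int, ...]

    @property
    def total(self) -> int:
        return sum(self.depth)


def _ref_covered_positions(feature: GenomicFeature):
    """Reference positions consumed by M/D ops (the aligned footprint)."""
    if feature.target is None or feature.gap_ops is None:
        yield from range(feature.start, feature.end + 1)
        return
    malign = project_alignment(feature)
    unit = malign.ref_unit
    for ref_pos, _ in malign.pairs:
        if ref_pos is not None:
            yield from range(ref_pos, ref_pos + unit)


def coverage_track(
    features,
    seqid: str,
    start: int,
    end: int,
    multiplicities: dict | None = None,
) -> CoverageTrack:
    """Depth per reference base, counting M/D-consumed positions.

    ``multiplicities`` (keyed by feature identity index) lets squashed
    representatives count with their collapsed read counts.
    """
    n = end - start + 1
    depth = [0] * n
    for i, f in enumerate(features):
        if f.seqid != seqid or f.target is None:
            continue
        weight = multiplicities.get(i, 1) if multiplicities else 1
        for pos in _ref_covered_positions(f):
            if start <= pos <= end:
                depth[pos - start] += weight
    return CoverageTrack(seqid, start, end, tuple(depth))


def coverage_bedgraph(track: CoverageTrack) -> str:
    """BedGraph text (0-based half-open intervals, constant-depth runs)."""
    out = []
    run_start = 0
    depth = track.depth
    for i in range(1, len(depth) + 1):
        if i == len(depth) or depth[i] != depth[run_start]:
            if depth[run_start] != 0:
                out.append(
                    f"{track.seqid}\t{track.start - 1 + run_start}\t"
                    f"{track.start - 1 + i}\t{depth[run_start]}"
                )
            run_start = i
    return "\n".join(out) + ("\n" if out else "")


# ---------------------------------------------------------------------------
# squashing & sorting


def squash_identical_matches(features) -> list[tuple[GenomicFeature, int]]:
    """Collapse identical reads onto one representative with a count.

    The grouping key is (seqid, start, end, strand, Gap string, target id);
    representatives keep first-seen order and counts sum to the input count.
    """
    groups: dict = {}
    order: list = []
    for f in features:
        tid = f.target[0] if f.target else None
        key = (f.seqid, f.start, f.end, f.strand, f.gap_string, tid)
        if key not in groups:
            groups[key] = [f, 0]
            order.append(key)
        groups[key][1] += 1
    return [(groups[k][0], groups[k][1]) for k in order]


def sort_features(features, key: str = "position") -> list[GenomicFeature]:
    """Stable sort by ``name``, ``position`` or ``identity`` (GFF score)."""
    feats = list(features)
    if key == "position":
        return sorted(feats, key=lambda f: (f.start, f.end))
    if key == "name":
        def name_of(f):
            t = f.target
            n = t[0] if t else f.attributes.get("Name", f.attributes.get("ID", ""))
            return (n.lower(), n)

        return sorted(feats, key=name_of)
    if key in ("identity", "score"):
        missing = [f.line_no for f in feats if f.score is None]
        if missing:
            raise ValueError(
                f"identity sort needs the GFF score column; missing on "
                f"line(s) {missing}"
            )
        return sorted(feats, key=lambda f: -f.score)
    raise ValueError(f"unknown sort key {key!r}")


# ---------------------------------------------------------------------------
# splice sites


@dataclass(frozen=True)
class SpliceSite:
    """One intron's donor/acceptor dinucleotides and classification."""

    intron_start: int  # 1-based, first intronic base on the reference
    intron_end: int
    donor: str
    acceptor: str
    status: str  # canonical / gc_ag / at_ac / non_canonical


_VARIANTS = {("GT", "AG"): "canonical", ("GC", "AG"): "gc_ag", ("AT", "AC"): "at_ac"}


def detect_splice_sites(refseq: Sequence, exons) -> list[SpliceSite]:
    """Classify the introns between consecutive exons of one transcript.

    ``exons`` are features on the same strand; introns are the gaps between
    them.  Donor/acceptor dinucleotides are read on the transcript's strand
    (reverse-complemented for minus-strand features); canonical means GT..AG.
    """
    exons = sorted(exons, key=lambda f: f.start)
    if len(exons) < 2:
        raise ValueError("need at least two exons to have an intron")
    strands = {f.strand for f in exons}
    if len(strands) != 1:
        raise ValueError("exons lie on different strands")
    strand = strands.pop()
    for a, b in zip(exons, exons[1:]):
        if b.start <= a.end:
            raise ValueError(
                f"exons overlap or touch: {a.start}-{a.end} and {b.start}-{b.end}"
            )
    out = []
    for a, b in zip(exons, exons[1:]):
        istart, iend = a.end + 1, b.start - 1
        intron = refseq.residues[istart - 1 : iend]
        if len(intron) < 4:
            out.append(SpliceSite(istart, iend, "", "", "non_canonical"))
            continue
        if strand == "-":
            rc = reverse_complement(Sequence("i", intron, NUCLEOTIDE)).residues
            donor, acceptor = rc[:2], rc[-2:]
        else:
            donor, acceptor = intron[:2], intron[-2:]
        status = _VARIANTS.get((donor, acceptor), "non_canonical")
        out.append(SpliceSite(istart, iend, donor, acceptor, status))
    return out


# ---------------------------------------------------------------------------
# text detail view (for golden-file tests and CLI output)


def render_detail_view(
    refseq: Sequence,
    entries,
    start: int,
    end: int,
    matrix: ScoringMatrix | None = None,
) -> str:
    """Plain-text stacked view of matches over a reference window.

    ``entries`` is a list of ``(feature, match Sequence, count)`` tuples.
    Exact matches render as the residue, conserved matches in lower case,
    mismatches as ``~`` and deletions as ``.``; insertions occupy no
    reference space and are omitted from the text row.
    """
    width = end - start + 1
    name_w = max(
        [len(refseq.identifier)]
        + [len(_entry_name(f, c)) for f, _, c in entries]
    )
    lines = [
        f"{refseq.identifier:<{name_w}} {refseq.residues[start - 1 : end]}"
    ]
    for feature, mseq, count in entries:
        malign = project_alignment(feature, refseq)
        classes = classify_match_bases(malign, refseq, mseq, matrix)
        row = [" "] * width
        for (ref_pos, tgt_pos), cls in zip(malign.pairs, classes):
            if ref_pos is None:
                continue
            for k in range(malign.ref_unit):
                col = ref_pos + k - start
                if not 0 <= col < width:
                    continue
                if cls == "exact":
                    row[col] = mseq.residues[tgt_pos - 1]
                elif cls == "conserved":
                    row[col] = mseq.residues[tgt_pos - 1].lower()
                elif cls == "mismatch":
                    row[col] = "~"
                elif cls == "deletion":
                    row[col] = "."
        lines.append(f"{_entry_name(feature, count):<{name_w}} {''.join(row)}")
    return "\n".join(lines) + "\n"


def _entry_name(feature: GenomicFeature, count: int) -> str:
    base = feature.target[0] if feature.target else feature.attributes.get("ID", "?")
    return f"{base} (x{count})" if count > 1 else base
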
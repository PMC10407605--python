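"""Readers/writers for the formats the toolkit exchanges.

FASTA, GFF3 (transposable-element features), AGP v2.1, BED and PAF, plus the
domain types every other module trades in.  Internal coordinates are 0-based
half-open everywhere; AGP and GFF3 are converted at this boundary (both are
1-based inclusive on disk).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO as _BioSeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC ambiguity codes other than N collapse to N on read.
_AMBIGUITY = str.maketrans({c: "N" for c in "RYSWKMBDHV"})

_VALID_RE = re.compile(r"^[ACGTN]*$")

#: TE class substrings treated as retrotransposons (case-insensitive).
RETRO_CLASSES = ("LTR", "LINE", "SINE", "RETROTRANSPOSON")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence, uppercase over {A,C,G,T,N}."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise ValueError(f"sequence id must be a non-empty token: {self.id!r}")
        if len(self.seq) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open 0-based interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"bad interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in "+-.":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def reciprocal_overlap(a: Interval, b: Interval) -> float:
    """min(overlap/len(a), overlap/len(b)); the span-comparison metric."""
    ov = a.overlap(b)
    if ov == 0:
        return 0.0
    return min(ov / len(a), ov / len(b))


@dataclass(frozen=True)
class AlignmentBlock:
    """One local alignment interval pair, PAF-style.

    Coordinates are 0-based half-open on the forward strand of each sequence;
    for '-' blocks the query interval still refers to the forward query strand
    (PAF convention).
    """

    query: str
    q_len: int
    q_start: int
    q_end: int
    strand: str
    target: str
    t_len: int
    t_start: int
    t_end: int
    matches: int
    block_len: int
    mapq: int

    def __post_init__(self) -> None:
        if not (0 <= self.q_start < self.q_end <= self.q_len):
            raise ValueError(f"bad query interval in block {self}")
        if not (0 <= self.t_start < self.t_end <= self.t_len):
            raise ValueError(f"bad target interval in block {self}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.matches > self.block_len:
            raise ValueError("matches exceed block length")

    @property
    def identity(self) -> float:
        return self.matches / self.block_len if self.block_len else 0.0

    def to_paf_line(self) -> str:
        return "\t".join(
            str(x)
            for x in (
                self.query, self.q_len, self.q_start, self.q_end, self.strand,
                self.target, self.t_len, self.t_start, self.t_end,
                self.matches, self.block_len, self.mapq,
            )
        )


@dataclass(frozen=True)
class AgpRow:
    """One AGP v2.1 row: a contig component (W) or a gap (U)."""

    object: str
    object_beg: int  # 1-based inclusive
    object_end: int
    part_number: int
    component_type: str  # W or U
    # W fields
    component_id: str = ""
    component_beg: int = 0
    component_end: int = 0
    orientation: str = "+"
    # U fields
    gap_length: int = 0
    gap_type: str = "scaffold"
    linkage: str = "yes"
    evidence: str = "align_genus"

    def __post_init__(self) -> None:
        if self.component_type not in ("W", "U"):
            raise ValueError(f"component_type must be W or U: {self.component_type}")
        if self.object_beg < 1 or self.object_end < self.object_beg:
            raise ValueError(f"bad object span in AGP row {self}")
        if self.component_type == "W":
            span = self.object_end - self.object_beg
            if self.component_end - self.component_beg != span:
                raise ValueError(
                    f"W row span mismatch for {self.component_id} in {self.object}"
                )

    def to_line(self) -> str:
        if self.component_type == "W":
            tail = (self.component_id, self.component_beg, self.component_end,
                    self.orientation)
        else:
            tail = (self.gap_length, self.gap_type, self.linkage, self.evidence)
        return "\t".join(
            str(x)
            for x in (self.object, self.object_beg, self.object_end,
                      self.part_number, self.component_type, *tail)
        )


@dataclass
class TeAnnotation:
    """Transposable-element intervals with a retrotransposon flag per feature."""

    intervals: list[tuple[Interval, str, bool]] = field(default_factory=list)

    def retro_intervals(self, seq_id: str | None = None) -> list[Interval]:
        return [
            iv for iv, _cls, is_retro in self.intervals
            if is_retro and (seq_id is None or iv.seq_id == seq_id)
        ]


def is_retrotransposon_class(te_class: str,
                             retro_classes: Sequence[str] = RETRO_CLASSES) -> bool:
    upper = te_class.upper()
    return any(tag in upper for tag in retro_classes)


# ---------------------------------------------------------------------------
# FASTA

def normalize_seq(raw: str, record_id: str) -> str:
    """Uppercase, map non-N ambiguity codes to N, reject anything else."""
    seq = raw.upper()
    mapped = seq.translate(_AMBIGUITY)
    if mapped != seq:
        logger.warning("record %s: IUPAC ambiguity codes mapped to N", record_id)
        seq = mapped
    if not _VALID_RE.match(seq):
        for pos, ch in enumerate(seq):
            if ch not in "ACGTN":
                raise ValueError(
                    f"record {record_id!r}: invalid residue {ch!r} at position {pos}"
                )
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into validated records, preserving file order."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty sequence under header {rec.id!r} in {path}")
        desc = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, normalize_seq(seq, rec.id), desc))
    return records


def read_fastx(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA or FASTQ (by extension); FASTQ qualities are discarded."""
    p = str(path)
    fmt = "fastq" if p.endswith((".fq", ".fastq")) else "fasta"
    if fmt == "fasta":
        return read_fasta(path)
    records = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(p, "fastq"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, normalize_seq(str(rec.seq), rec.id)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# gap runs

def find_gap_runs(record: SequenceRecord, min_run: int = 1) -> list[Interval]:
    """Maximal runs of N with length >= min_run, sorted, half-open."""
    if min_run < 1:
        raise ValueError("min_run must be positive")
    runs = []
    for m in re.finditer(r"N+", record.seq):
        if m.end() - m.start() >= min_run:
            runs.append(Interval(record.id, m.start(), m.end()))
    return runs


# ---------------------------------------------------------------------------
# GFF3 (TE features)

_GENERIC_TYPES = {"repeat_region", "transposable_element", "dispersed_repeat",
                  "mobile_genetic_element"}


def read_te_gff3(path: str | Path,
                 retro_classes: Sequence[str] = RETRO_CLASSES) -> TeAnnotation:
    """Read TE features from GFF3; 1-based inclusive coordinates converted.

    The TE class is the feature type (column 3); when the type is generic
    (e.g. ``repeat_region``) the ``Classification=`` attribute is used instead.
    """
    ann = TeAnnotation()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(
                    f"{path}:{lineno}: malformed GFF3 row "
                    f"({len(fields)} fields, expected >= 8)"
                )
            seq_id, _src, ftype, start, end, _score, strand, _frame = fields[:8]
            attrs = fields[8] if len(fields) > 8 else ""
            te_class = ftype
            if ftype.lower() in _GENERIC_TYPES:
                m = re.search(r"Classification=([^;]+)", attrs)
                if m:
                    te_class = m.group(1)
            iv = Interval(seq_id, int(start) - 1, int(end),
                          strand if strand in "+-" else ".")
            ann.intervals.append(
                (iv, te_class, is_retrotransposon_class(te_class, retro_classes))
            )
    return ann


def write_te_gff3(ann: TeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv, te_class, _ in ann.intervals:
            strand = iv.strand if iv.strand in "+-" else "."
            fh.write(
                f"{iv.seq_id}\tt2tkit\t{te_class}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{strand}\t.\t.\n"
            )


# ---------------------------------------------------------------------------
# AGP v2.1

def validate_agp(rows: Sequence[AgpRow]) -> None:
    """Rows for each object must tile [1, object_length] without gaps/overlap."""
    by_object: dict[str, list[AgpRow]] = {}
    for row in rows:
        by_object.setdefault(row.object, []).append(row)
    for obj, obj_rows in by_object.items():
        expected_beg = 1
        for k, row in enumerate(obj_rows, start=1):
            if row.part_number != k:
                raise ValueError(
                    f"AGP object {obj}: part_number {row.part_number} at row {k}"
                )
            if row.object_beg != expected_beg:
                raise ValueError(
                    f"AGP object {obj}: part {row.part_number} begins at "
                    f"{row.object_beg}, expected {expected_beg}"
                )
            expected_beg = row.object_end + 1


def write_agp(rows: Sequence[AgpRow], path: str | Path) -> None:
    validate_agp(rows)
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for row in rows:
            fh.write(row.to_line() + "\n")


def read_agp(path: str | Path) -> list[AgpRow]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if f[4] == "W":
                rows.append(AgpRow(f[0], int(f[1]), int(f[2]), int(f[3]), "W",
                                   component_id=f[5], component_beg=int(f[6]),
                                   component_end=int(f[7]), orientation=f[8]))
            elif f[4] in ("U", "N"):
                rows.append(AgpRow(f[0], int(f[1]), int(f[2]), int(f[3]), "U",
                                   gap_length=int(f[5]), gap_type=f[6],
                                   linkage=f[7], evidence=f[8]))
            else:
                raise ValueError(f"unsupported AGP component type {f[4]!r}")
    validate_agp(rows)
    return rows


def reconstruct_from_agp(rows: Sequence[AgpRow],
                         components: dict[str, str]) -> dict[str, str]:
    """Rebuild object sequences from AGP rows + component sequences."""
    validate_agp(rows)
    out: dict[str, list[str]] = {}
    for row in rows:
        parts = out.setdefault(row.object, [])
        if row.component_type == "U":
            parts.append("N" * row.gap_length)
        else:
            seg = components[row.component_id][row.component_beg - 1:row.component_end]
            if row.orientation == "-":
                seg = revcomp(seg)
            parts.append(seg)
    return {obj: "".join(parts) for obj, parts in out.items()}


# ---------------------------------------------------------------------------
# BED

def write_bed(intervals: Iterable[Interval], path: str | Path,
              names: Iterable[str] | None = None) -> None:
    with open(path, "w") as fh:
        names_list = list(names) if names is not None else None
        for i, iv in enumerate(intervals):
            if names_list is not None:
                fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{names_list[i]}\n")
            else:
                fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\n")


def read_bed(path: str | Path) -> list[Interval]:
    ivs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            ivs.append(Interval(f[0], int(f[1]), int(f[2])))
    return ivs


# ---------------------------------------------------------------------------
# PAF

def read_paf(path: str | Path) -> list[AlignmentBlock]:
    """Parse the 12 mandatory PAF columns; extra columns are ignored."""
    blocks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: PAF line has {len(f)} columns")
            blocks.append(AlignmentBlock(
                query=f[0], q_len=int(f[1]), q_start=int(f[2]), q_end=int(f[3]),
                strand=f[4],
                target=f[5], t_len=int(f[6]), t_start=int(f[7]), t_end=int(f[8]),
                matches=int(f[9]), block_len=int(f[10]), mapq=int(f[11]),
            ))
    return blocks


def write_paf(blocks: Iterable[AlignmentBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(b.to_paf_line() + "\n")
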
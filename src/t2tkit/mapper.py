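"""Reference-guided scaffolding of phased contigs into pseudo-chromosomes.

Contigs are split at N gaps, short fragments are dropped, the rest are
aligned to a closely related reference, assigned each to its best-matching
chromosome, ordered by reference coordinate, and joined with fixed-length N
spacers.  Every placed base is carried over verbatim (or reverse-complemented
for '-' placements); the module never edits sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

from .seqio import (
    AgpRow,
    AlignmentBlock,
    Interval,
    SequenceRecord,
    find_gap_runs,
    revcomp,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContigFragment:
    """A gap-free piece of an input contig, with provenance."""

    id: str
    parent_id: str
    parent_offset: int
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Placement:
    """Where one fragment lands: chromosome, orientation and sort anchor."""

    fragment_id: str
    chrom: str
    orientation: str
    anchor: int
    aligned_bases: int
    ambiguous_orientation: bool = False


@dataclass
class PseudoChromosome:
    id: str
    seq: str
    agp: list[AgpRow] = field(default_factory=list)
    gap_intervals: list[Interval] = field(default_factory=list)


def split_at_gaps(contigs: Sequence[SequenceRecord],
                  min_gap_run: int = 1) -> list[ContigFragment]:
    """Break contigs at N runs of length >= min_gap_run.

    A gap-free contig becomes a single fragment keeping its original id;
    otherwise fragments are named ``<parent>_frag1``, ``<parent>_frag2``, ...
    in parent order.
    """
    fragments: list[ContigFragment] = []
    for rec in contigs:
        gaps = find_gap_runs(rec, min_gap_run)
        if not gaps:
            if "N" not in rec.seq:
                fragments.append(ContigFragment(rec.id, rec.id, 0, rec.seq))
                continue
            # N runs shorter than the threshold stay inside the fragment
            fragments.append(ContigFragment(rec.id, rec.id, 0, rec.seq))
            continue
        pieces = []
        prev = 0
        for gap in gaps:
            if gap.start > prev:
                pieces.append((prev, rec.seq[prev:gap.start]))
            prev = gap.end
        if prev < len(rec.seq):
            pieces.append((prev, rec.seq[prev:]))
        pieces = [(off, s) for off, s in pieces if s.strip("N")]
        if len(pieces) == 1 and pieces[0][1] == rec.seq:
            fragments.append(ContigFragment(rec.id, rec.id, 0, rec.seq))
            continue
        for n, (off, s) in enumerate(pieces, start=1):
            fragments.append(ContigFragment(f"{rec.id}_frag{n}", rec.id, off, s))
    return fragments


def drop_short(fragments: Sequence[ContigFragment],
               min_len: int) -> tuple[list[ContigFragment], list[ContigFragment]]:
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    kept = [f for f in fragments if len(f) >= min_len]
    dropped = [f for f in fragments if len(f) < min_len]
    if fragments and not kept:
        raise ValueError(
            f"all {len(fragments)} fragments are shorter than min_len={min_len}; "
            "lower --min-len"
        )
    return kept, dropped


def filter_alignments(blocks: Sequence[AlignmentBlock], min_block_len: int = 5_000,
                      min_identity: float = 0.80,
                      min_mapq: int = 30) -> list[AlignmentBlock]:
    """Keep blocks passing all three quality thresholds."""
    return [
        b for b in blocks
        if b.block_len >= min_block_len
        and b.identity >= min_identity
        and b.mapq >= min_mapq
    ]


def _weighted_median(values: list[int], weights: list[int]) -> int:
    order = sorted(range(len(values)), key=lambda i: values[i])
    total = sum(weights)
    acc = 0
    for i in order:
        acc += weights[i]
        if acc * 2 >= total:
            return values[i]
    return values[order[-1]]


def assign_to_chromosome(fragment_id: str,
                         blocks: Sequence[AlignmentBlock],
                         ambiguity_margin: float = 0.05) -> Placement | None:
    """Pick the chromosome, orientation and sort anchor for one fragment.

    Chromosome: the target with the largest summed aligned query length
    (ties: longest single block, then lexicographically smallest id).
    Orientation: the strand carrying more aligned length on the winner; a
    strand vote within ``ambiguity_margin`` of 50/50 is flagged ambiguous.
    Anchor: aligned-length-weighted median of t_start on the winner.
    """
    mine = [b for b in blocks if b.query == fragment_id]
    if not mine:
        return None
    per_target: dict[str, int] = {}
    longest: dict[str, int] = {}
    for b in mine:
        span = b.q_end - b.q_start
        per_target[b.target] = per_target.get(b.target, 0) + span
        longest[b.target] = max(longest.get(b.target, 0), span)
    chrom = min(
        per_target,
        key=lambda t: (-per_target[t], -longest[t], t),
    )
    win = [b for b in mine if b.target == chrom]
    plus = sum(b.q_end - b.q_start for b in win if b.strand == "+")
    minus = sum(b.q_end - b.q_start for b in win if b.strand == "-")
    orientation = "+" if plus >= minus else "-"
    total = plus + minus
    ambiguous = total > 0 and abs(plus - minus) / total <= ambiguity_margin
    anchor = _weighted_median(
        [b.t_start for b in win], [b.q_end - b.q_start for b in win]
    )
    return Placement(fragment_id, chrom, orientation, anchor, total, ambiguous)


def _count_monomer_copies(seq: str, monomer_canonical: str, period: int) -> int:
    # non-overlapping occurrence count in canonical rotation/strand class
    from .telomere import canonical_form

    count = 0
    i = 0
    n = len(seq)
    while i + period <= n:
        kmer = seq[i:i + period]
        if "N" not in kmer and canonical_form(kmer) == monomer_canonical:
            count += 1
            i += period
        else:
            i += 1
    return count


def refine_orientations(placements: list[Placement],
                        fragments: dict[str, ContigFragment],
                        telomere_monomer: str | None = "TTTAGGG",
                        end_window: int = 10_000,
                        min_copies: int = 20) -> tuple[list[Placement], list[str]]:
    """Telomere-aware placement refinement.

    After ordering, a fragment whose telomeric end faces chromosome-interior
    is flagged; when its strand vote was ambiguous the telomere-outward
    orientation wins instead.  Returns (refined placements, flag messages).
    """
    if telomere_monomer is None:
        return placements, []
    from .telomere import canonical_form

    canon = canonical_form(telomere_monomer)
    p = len(telomere_monomer)
    flags: list[str] = []
    by_chrom: dict[str, list[Placement]] = {}
    for pl in placements:
        by_chrom.setdefault(pl.chrom, []).append(pl)
    refined = {pl.fragment_id: pl for pl in placements}
    for chrom, pls in by_chrom.items():
        pls = sorted(pls, key=lambda x: (x.anchor, x.fragment_id))
        for idx, pl in enumerate(pls):
            frag = fragments[pl.fragment_id]
            seq = frag.seq if pl.orientation == "+" else revcomp(frag.seq)
            left = _count_monomer_copies(seq[:end_window], canon, p)
            right = _count_monomer_copies(seq[-end_window:], canon, p)
            telo_left = left >= min_copies
            telo_right = right >= min_copies
            interior_left = telo_left and idx != 0
            interior_right = telo_right and idx != len(pls) - 1
            if interior_left or interior_right:
                msg = (f"{pl.fragment_id}: telomeric end faces interior of "
                       f"{chrom} (position {idx + 1}/{len(pls)})")
                if pl.ambiguous_orientation and (telo_left != telo_right):
                    flipped = replace(
                        pl, orientation="-" if pl.orientation == "+" else "+"
                    )
                    refined[pl.fragment_id] = flipped
                    flags.append(msg + "; orientation flipped (ambiguous strand vote)")
                else:
                    flags.append(msg)
    return [refined[pl.fragment_id] for pl in placements], flags


def build_pseudochromosomes(
    placements: Sequence[Placement],
    fragments: Sequence[ContigFragment],
    spacer_len: int = 100,
    name_prefix: str = "",
) -> tuple[list[PseudoChromosome], list[ContigFragment]]:
    """Join placed fragments per chromosome with spacer_len N between them.

    Fragments are sorted ascending by anchor (ties by fragment id); '-'
    placements are reverse-complemented.  Returns the pseudo-chromosomes and
    the unplaced fragments.
    """
    frag_by_id = {f.id: f for f in fragments}
    seen: set[str] = set()
    by_chrom: dict[str, list[Placement]] = {}
    for pl in placements:
        if pl.fragment_id in seen:
            raise ValueError(f"fragment {pl.fragment_id} placed more than once")
        seen.add(pl.fragment_id)
        by_chrom.setdefault(pl.chrom, []).append(pl)

    pseudos: list[PseudoChromosome] = []
    for chrom in sorted(by_chrom):
        pls = sorted(by_chrom[chrom], key=lambda x: (x.anchor, x.fragment_id))
        obj = f"{name_prefix}{chrom}"
        parts: list[str] = []
        agp: list[AgpRow] = []
        gaps: list[Interval] = []
        pos = 0  # 0-based running offset
        part_no = 0
        for i, pl in enumerate(pls):
            frag = frag_by_id[pl.fragment_id]
            if i > 0:
                part_no += 1
                agp.append(AgpRow(obj, pos + 1, pos + spacer_len, part_no, "U",
                                  gap_length=spacer_len))
                gaps.append(Interval(obj, pos, pos + spacer_len))
                parts.append("N" * spacer_len)
                pos += spacer_len
            seq = frag.seq if pl.orientation == "+" else revcomp(frag.seq)
            part_no += 1
            agp.append(AgpRow(obj, pos + 1, pos + len(seq), part_no, "W",
                              component_id=frag.id, component_beg=1,
                              component_end=len(seq),
                              orientation=pl.orientation))
            parts.append(seq)
            pos += len(seq)
        pseudos.append(PseudoChromosome(obj, "".join(parts), agp, gaps))
    unplaced = [f for f in fragments if f.id not in seen]
    return pseudos, unplaced


def assembly_stats(contigs: Sequence[SequenceRecord],
                   pseudos: Sequence[PseudoChromosome],
                   unplaced: Sequence[ContigFragment]) -> dict:
    """Headline assembly statistics, Table-style.

    The headline mapping rate is 100 * genome_size / contig_total rounded to
    one decimal; the placed-base percentage (spacers excluded) is reported
    alongside since spacer inflation can push the headline figure past 100.
    """
    contig_total = sum(len(c) for c in contigs)
    genome_size = sum(len(p.seq) for p in pseudos)
    spacer_bases = sum(len(iv) for p in pseudos for iv in p.gap_intervals)
    placed_bases = genome_size - spacer_bases
    gap_locations = [iv for p in pseudos for iv in p.gap_intervals]
    return {
        "contig_total_bp": contig_total,
        "genome_size_bp": genome_size,
        "chromosomes": len(pseudos),
        "mapping_rate_pct": mapping_rate(genome_size, contig_total),
        "placed_bases_bp": placed_bases,
        "placed_pct": round(100 * placed_bases / contig_total, 1)
        if contig_total else 0.0,
        "unplaced_fragments": len(unplaced),
        "unplaced_bp": sum(len(f) for f in unplaced),
        "gap_count": len(gap_locations),
        "gap_locations": gap_locations,
    }


def mapping_rate(genome_size: int, contig_total: int) -> float:
    """100 * genome_size / contig_total, rounded to one decimal."""
    if contig_total == 0:
        return 0.0
    return round(100.0 * genome_size / contig_total, 1)


def run_mapper(
    contigs: Sequence[SequenceRecord],
    reference: Sequence[SequenceRecord],
    aligner,
    min_gap_run: int = 1,
    min_len: int = 50_000,
    min_block_len: int = 5_000,
    min_identity: float = 0.80,
    min_mapq: int = 30,
    spacer_len: int = 100,
    name_prefix: str = "",
    telomere_monomer: str | None = "TTTAGGG",
    threads: int = 1,
) -> dict:
    """Full scaffolding pipeline; returns pseudos, unplaced, stats, report."""
    from .parallel import run_ordered

    fragments = split_at_gaps(contigs, min_gap_run)
    kept, dropped = drop_short(fragments, min_len)
    frag_records = [SequenceRecord(f.id, f.seq) for f in kept]
    aligner.index(list(reference))
    block_lists = run_ordered(lambda r: aligner.map([r]), frag_records, threads)
    blocks = [b for lst in block_lists for b in lst]
    blocks = filter_alignments(blocks, min_block_len, min_identity, min_mapq)
    placements = []
    unaligned = []
    for frag in kept:
        pl = assign_to_chromosome(frag.id, blocks)
        if pl is None:
            unaligned.append(frag.id)
        else:
            placements.append(pl)
    frag_map = {f.id: f for f in kept}
    placements, telo_flags = refine_orientations(
        placements, frag_map, telomere_monomer
    )
    pseudos, unplaced = build_pseudochromosomes(
        placements, kept, spacer_len, name_prefix
    )
    stats = assembly_stats(contigs, pseudos, unplaced)
    return {
        "pseudochromosomes": pseudos,
        "unplaced": unplaced,
        "placements": placements,
        "dropped_short": [f.id for f in dropped],
        "unaligned": unaligned,
        "telomere_flags": telo_flags,
        "stats": stats,
    }
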
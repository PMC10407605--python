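"""Gap closing with ultra-long reads via gap-flank anchor alignment.

The flanks immediately adjacent to each N gap are extracted as anchors and
aligned to the ultra-long reads; when both anchors of a gap hit the same
read, in the same orientation and in proper left-before-right order, the
read sequence between the two hits is a fill candidate.  The best candidate
per gap (highest combined anchor homology) replaces the N run verbatim.
The strategy is conservative: no base outside a filled N run is ever
altered, and the raw read subsequence is used without polishing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .mapper import filter_alignments
from .seqio import (
    AlignmentBlock,
    Interval,
    SequenceRecord,
    find_gap_runs,
    revcomp,
)


@dataclass(frozen=True)
class GapAnchorPair:
    gap_id: str
    chrom: str
    gap: Interval
    left_anchor: str
    right_anchor: str


@dataclass(frozen=True)
class FillCandidate:
    gap_id: str
    read_id: str
    orientation: str  # read strand relative to the chromosome
    insert: str       # chromosome-forward fill sequence
    read_span: tuple[int, int]  # on the chromosome-forward oriented read
    left_score: int
    right_score: int

    @property
    def combined_score(self) -> int:
        return self.left_score + self.right_score


@dataclass
class GapStatus:
    gap_id: str
    chrom: str
    gap: Interval
    status: str  # filled | no_candidate | flank_too_short
    read_id: str | None = None
    insert_len: int | None = None
    left_score: int | None = None
    right_score: int | None = None


def anchor_query_id(gap_id: str, side: str) -> str:
    return f"{gap_id}|{side}"


def extract_anchors(
    genome: Sequence[SequenceRecord],
    flank_len: int = 5_000,
    min_gap_run: int = 1,
) -> tuple[list[GapAnchorPair], list[GapStatus]]:
    """One anchor pair per qualifying gap; short/dirty flanks reported.

    Anchors are the ``flank_len`` bases immediately adjacent to the gap and
    must contain no N; gaps whose flanks do not qualify get status
    ``flank_too_short`` instead of being silently dropped.
    """
    pairs: list[GapAnchorPair] = []
    skipped: list[GapStatus] = []
    for rec in genome:
        for gi, gap in enumerate(find_gap_runs(rec, min_gap_run), start=1):
            gap_id = f"{rec.id}_gap{gi}"
            left = rec.seq[max(0, gap.start - flank_len):gap.start]
            right = rec.seq[gap.end:gap.end + flank_len]
            if len(left) < flank_len or len(right) < flank_len \
                    or "N" in left or "N" in right:
                skipped.append(GapStatus(gap_id, rec.id, gap, "flank_too_short"))
                continue
            pairs.append(GapAnchorPair(gap_id, rec.id, gap, left, right))
    return pairs, skipped


def anchor_records(pairs: Sequence[GapAnchorPair]) -> list[SequenceRecord]:
    recs = []
    for p in pairs:
        recs.append(SequenceRecord(anchor_query_id(p.gap_id, "L"), p.left_anchor))
        recs.append(SequenceRecord(anchor_query_id(p.gap_id, "R"), p.right_anchor))
    return recs


def find_spanning(
    blocks: Sequence[AlignmentBlock],
    pairs: Sequence[GapAnchorPair],
    reads: dict[str, str],
    max_fill: int = 1_000_000,
    min_anchor_identity: float = 0.85,
    min_anchor_cov: float = 0.90,
) -> dict[str, list[FillCandidate]]:
    """Pair up left/right anchor hits on the same read, proper order.

    Works in chromosome-forward read coordinates: '-' strand hits are mapped
    onto the reverse complement of the read, so "left anchor ends at or
    before right anchor begins" holds in one frame for both orientations.
    """
    flanks = {anchor_query_id(p.gap_id, side): p for p in pairs for side in "LR"}
    # (gap_id, read, strand, side) -> best block
    hits: dict[tuple[str, str, str, str], AlignmentBlock] = {}
    for b in blocks:
        if b.query not in flanks:
            continue
        if b.identity < min_anchor_identity:
            continue
        if (b.q_end - b.q_start) < min_anchor_cov * b.q_len:
            continue
        gap_id, side = b.query.rsplit("|", 1)
        key = (gap_id, b.target, b.strand, side)
        if key not in hits or b.matches > hits[key].matches:
            hits[key] = b

    anchors = {p.gap_id: p for p in pairs}
    out: dict[str, list[FillCandidate]] = {p.gap_id: [] for p in pairs}
    for (gap_id, read_id, strand, side), left in sorted(hits.items()):
        if side != "L":
            continue
        right = hits.get((gap_id, read_id, strand, "R"))
        if right is None:
            continue
        read_seq = reads[read_id]
        fwd_read = read_seq if strand == "+" else revcomp(read_seq)
        # the seed chains locate the hits; full-anchor infix alignment on the
        # oriented read pins the exact boundaries the insert is cut at
        pair = anchors[gap_id]
        l_hit = _exact_anchor_hit(pair.left_anchor, fwd_read)
        r_hit = _exact_anchor_hit(pair.right_anchor, fwd_read)
        if l_hit is None or r_hit is None:
            continue
        (l_start, l_end, l_score) = l_hit
        (r_start, r_end, r_score) = r_hit
        if l_end > r_start:
            continue  # improper order on the read
        if r_start - l_end > max_fill:
            continue
        out[gap_id].append(FillCandidate(
            gap_id=gap_id, read_id=read_id, orientation=strand,
            insert=fwd_read[l_end:r_start], read_span=(l_end, r_start),
            left_score=l_score, right_score=r_score,
        ))
    return out


def _exact_anchor_hit(anchor: str, oriented_read: str) -> tuple[int, int, int] | None:
    """Best infix alignment of the whole anchor: (start, end, matched bases)."""
    import edlib

    res = edlib.align(anchor, oriented_read, mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end_incl = res["locations"][0]
    return start, end_incl + 1, max(0, len(anchor) - res["editDistance"])


def select_best(candidates: Sequence[FillCandidate],
                read_lengths: dict[str, int]) -> FillCandidate | None:
    """Highest combined anchor score; ties to the longer read, then read id."""
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda c: (-c.combined_score, -read_lengths[c.read_id], c.read_id),
    )


def apply_fills(
    genome: Sequence[SequenceRecord],
    selections: dict[str, FillCandidate],
    pairs: Sequence[GapAnchorPair],
    skipped: Sequence[GapStatus] = (),
) -> tuple[list[SequenceRecord], list[GapStatus]]:
    """Replace each selected gap's N run with its insert; touch nothing else.

    Returns the new genome and a per-gap report whose statuses partition the
    gap set (filled / no_candidate / flank_too_short).
    """
    by_chrom: dict[str, list[GapAnchorPair]] = {}
    for p in pairs:
        by_chrom.setdefault(p.chrom, []).append(p)
    seen_gaps = set()
    for p in pairs:
        if p.gap_id in seen_gaps:
            raise ValueError(f"duplicate gap id {p.gap_id}")
        seen_gaps.add(p.gap_id)
    for gap_id in selections:
        if gap_id not in seen_gaps:
            raise ValueError(f"selection references unknown gap {gap_id}")

    report: list[GapStatus] = list(skipped)
    new_genome: list[SequenceRecord] = []
    for rec in genome:
        gaps = sorted(by_chrom.get(rec.id, []), key=lambda p: p.gap.start)
        parts: list[str] = []
        prev = 0
        for p in gaps:
            parts.append(rec.seq[prev:p.gap.start])
            sel = selections.get(p.gap_id)
            if sel is None:
                parts.append(rec.seq[p.gap.start:p.gap.end])
                report.append(GapStatus(p.gap_id, rec.id, p.gap, "no_candidate"))
            else:
                parts.append(sel.insert)
                report.append(GapStatus(
                    p.gap_id, rec.id, p.gap, "filled", read_id=sel.read_id,
                    insert_len=len(sel.insert), left_score=sel.left_score,
                    right_score=sel.right_score,
                ))
            prev = p.gap.end
        parts.append(rec.seq[prev:])
        new_genome.append(SequenceRecord(rec.id, "".join(parts), rec.description))
    return new_genome, report


def run_gapfiller(
    genome: Sequence[SequenceRecord],
    reads: Sequence[SequenceRecord],
    aligner,
    flank_len: int = 5_000,
    min_gap_run: int = 1,
    max_fill: int = 1_000_000,
    min_anchor_identity: float = 0.85,
    min_anchor_cov: float = 0.90,
    min_block_len: int | None = None,
    threads: int = 1,
) -> dict:
    """Full gap-filling pipeline; returns filled genome + per-gap report."""
    from .parallel import run_ordered

    pairs, skipped = extract_anchors(genome, flank_len, min_gap_run)
    if not pairs:
        return {"genome": list(genome), "report": list(skipped),
                "filled": 0, "remaining_gaps": len(skipped)}
    queries = anchor_records(pairs)
    aligner.index(list(reads))
    block_lists = run_ordered(lambda r: aligner.map([r]), queries, threads)
    blocks = [b for lst in block_lists for b in lst]
    # same filtering contract as the scaffolder; anchors legitimately hit
    # several spanning reads, so no mapq cut is applied here
    if min_block_len is None:
        min_block_len = int(min_anchor_cov * flank_len)
    blocks = filter_alignments(blocks, min_block_len=min_block_len,
                               min_identity=min_anchor_identity, min_mapq=0)
    read_seqs = {r.id: r.seq for r in reads}
    read_lengths = {r.id: len(r.seq) for r in reads}
    candidates = find_spanning(blocks, pairs, read_seqs, max_fill,
                               min_anchor_identity, min_anchor_cov)
    selections = {}
    for gap_id, cands in candidates.items():
        best = select_best(cands, read_lengths)
        if best is not None:
            selections[gap_id] = best
    new_genome, report = apply_fills(genome, selections, pairs, skipped)
    n_filled = sum(1 for r in report if r.status == "filled")
    return {
        "genome": new_genome,
        "report": sorted(report, key=lambda r: (r.chrom, r.gap.start)),
        "filled": n_filled,
        "remaining_gaps": len(report) - n_filled,
    }
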
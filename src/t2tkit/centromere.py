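"""De novo centromere candidate prediction from satellite arrays.

Centromeres in most plants and animals are megabase-scale arrays of a
tandem monomer in a characteristic period range (e.g. 178 bp CEN180 in
Arabidopsis, 155-165 bp CentO in rice), interleaved with retrotransposons.
The pipeline: discover tandem arrays by self-match periodicity, keep those
in the centromeric period/copy window, cluster their consensus monomers
(rotation- and strand-aware), match representatives back along each
chromosome, merge continuous match regions into candidates, and score each
candidate by matched bases plus weighted retrotransposon content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np

from .seqio import Interval, SequenceRecord, TeAnnotation, revcomp

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


@dataclass(frozen=True)
class TandemArray:
    chrom: str
    span: Interval
    period: int
    copy_number: float
    consensus: str
    low_complexity: bool = False


@dataclass
class MonomerCluster:
    id: str
    representative: str
    members: list[TandemArray] = field(default_factory=list)

    @property
    def total_copy_number(self) -> float:
        return sum(m.copy_number for m in self.members)


@dataclass(frozen=True)
class MatchBlock:
    chrom: str
    span: Interval
    monomer_id: str
    identity: float


@dataclass
class CentromereCandidate:
    chrom: str
    span: Interval
    tandem_bp: int
    te_bp: int = 0
    score: float = 0.0
    main_monomers: list[str] = field(default_factory=list)
    rank: int = 0
    monomer_bp: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# tandem array discovery

def _consensus(codes: np.ndarray, period: int) -> str:
    n_rows = len(codes) // period
    if n_rows == 0:
        return ""
    grid = codes[:n_rows * period].reshape(n_rows, period)
    counts = np.stack([(grid == b).sum(axis=0) for b in range(4)])
    # argmax tie-break: smallest base index, i.e. alphabetical A<C<G<T
    return "".join("ACGT"[b] for b in counts.argmax(axis=0))


def _purity(codes: np.ndarray, period: int) -> float:
    if len(codes) <= period:
        return 0.0
    a, b = codes[:-period], codes[period:]
    ok = (a != 255) & (b != 255)
    if not ok.any():
        return 0.0
    return float((a[ok] == b[ok]).mean())


def _dinucleotide_entropy(consensus: str) -> float:
    """Shannon entropy (bits) of circular dinucleotide composition."""
    if len(consensus) < 2:
        return 0.0
    counts: dict[str, int] = {}
    doubled = consensus + consensus[0]
    for i in range(len(consensus)):
        d = doubled[i:i + 2]
        counts[d] = counts.get(d, 0) + 1
    total = sum(counts.values())
    return -sum((c / total) * math.log2(c / total) for c in counts.values())


def is_low_complexity(consensus: str) -> bool:
    return len(set(consensus)) < 3 or _dinucleotide_entropy(consensus) < 1.0


def _fundamental_period(codes: np.ndarray, period: int, min_purity: float) -> int:
    for d in range(1, period):
        if period % d == 0 and _purity(codes, d) >= min_purity:
            return d
    return period


def find_tandem_arrays(
    seq: str,
    chrom: str = "seq",
    period_range: tuple[int, int] = (50, 300),
    min_copies: float = 2,
    min_purity: float = 0.7,
) -> list[TandemArray]:
    """Detect tandem repeat arrays via the per-period self-match profile.

    For each period p, positions where the base equals the base p ahead form
    a self-match profile; maximal stretches where every p-wide window has
    match density >= min_purity become arrays.  Each array is collapsed to
    its fundamental (smallest self-matching divisor) period, overlapping
    same-period detections are merged, and low-complexity consensus arrays
    are flagged.
    """
    lo, hi = period_range
    if not (2 <= lo <= hi <= 5000):
        raise ValueError("period_range must sit within [2, 5000]")
    codes = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes)
    raw: list[tuple[int, int, int]] = []  # (start, end, period) sequence spans
    for p in range(lo, min(hi, n - 1) + 1):
        a, b = codes[:-p], codes[p:]
        eq = ((a == b) & (a != 255)).astype(np.int32)
        if len(eq) < p:
            continue
        csum = np.concatenate(([0], np.cumsum(eq)))
        density_ok = (csum[p:] - csum[:-p]) >= math.ceil(min_purity * p)
        if not density_ok.any():
            continue
        # maximal runs of density_ok
        d = np.diff(density_ok.astype(np.int8))
        starts = np.nonzero(d == 1)[0] + 1
        ends = np.nonzero(d == -1)[0] + 1
        if density_ok[0]:
            starts = np.concatenate(([0], starts))
        if density_ok[-1]:
            ends = np.concatenate((ends, [len(density_ok)]))
        # boundary trim: density windows straddling the flank can pass, and
        # single chance matches (25% background) cannot define the edge, so
        # the span is cut at the first/last run of w consecutive self-matches
        w = min(16, max(2, p // 4))
        run_ok = (csum[w:] - csum[:-w]) == w
        for s, e in zip(starts, ends):
            s, e = int(s), int(e)
            lo_eq, hi_eq = s, min(e + p - 1, len(run_ok))
            idx = np.nonzero(run_ok[lo_eq:hi_eq])[0]
            if len(idx) == 0:
                continue
            span_start = lo_eq + int(idx[0])
            span_end = lo_eq + int(idx[-1]) + w - 1 + p + 1
            raw.append((span_start, min(span_end, n), p))

    # collapse to fundamental periods
    collapsed: dict[int, list[tuple[int, int]]] = {}
    for s, e, p in raw:
        f = _fundamental_period(codes[s:e], p, min_purity)
        collapsed.setdefault(f, []).append((s, e))

    arrays: list[TandemArray] = []
    for period, spans in collapsed.items():
        spans.sort()
        merged: list[list[int]] = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            length = e - s
            copy_number = length / period
            if copy_number < min_copies:
                continue
            cons = _consensus(codes[s:e], period)
            arrays.append(TandemArray(
                chrom=chrom, span=Interval(chrom, s, e), period=period,
                copy_number=round(copy_number, 2), consensus=cons,
                low_complexity=is_low_complexity(cons),
            ))
    arrays.sort(key=lambda a: (a.span.start, a.period))
    return arrays


def select_centromeric_monomers(
    arrays: Sequence[TandemArray],
    min_period: int = 100,
    max_period: int = 200,
    min_total_copies: float = 10,
) -> list[TandemArray]:
    """Keep arrays whose period and copy number look centromeric."""
    return [
        a for a in arrays
        if min_period <= a.period <= max_period
        and a.copy_number >= min_total_copies
    ]


# ---------------------------------------------------------------------------
# clustering

def rotation_identity(a: str, b: str) -> float:
    """Identity of two monomers under best circular rotation, either strand.

    The shorter monomer is infix-aligned into the doubled longer one; the
    length difference is charged as edits.  Returns a fraction of the longer
    length.
    """
    if not a or not b:
        return 0.0
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = math.inf
    for pattern in (short, revcomp(short)):
        res = edlib.align(pattern, long_ + long_, mode="HW", task="distance")
        best = min(best, res["editDistance"])
    dist = best + (len(long_) - len(short))
    return 1.0 - dist / len(long_)


def cluster_monomers(
    arrays: Sequence[TandemArray],
    identity_threshold: float = 0.8,
    exclude_low_complexity: bool = True,
) -> list[MonomerCluster]:
    """Greedy incremental clustering of array consensus monomers.

    Arrays are sorted by copy_number x period descending (heaviest first);
    each consensus joins the first cluster whose representative matches at
    >= identity_threshold under best circular rotation on either strand,
    else founds a new cluster.  Deterministic given the declared sort.
    """
    pool = [a for a in arrays
            if not (exclude_low_complexity and a.low_complexity)]
    pool.sort(key=lambda a: (-a.copy_number * a.period, a.consensus,
                             a.chrom, a.span.start))
    clusters: list[MonomerCluster] = []
    for arr in pool:
        for cl in clusters:
            if rotation_identity(arr.consensus, cl.representative) \
                    >= identity_threshold:
                cl.members.append(arr)
                break
        else:
            clusters.append(MonomerCluster(
                id=f"mon{len(clusters) + 1:04d}",
                representative=arr.consensus, members=[arr],
            ))
    return clusters


# ---------------------------------------------------------------------------
# chromosome-wide matching

def map_monomers(
    representatives: Sequence[tuple[str, str]],
    chromosome: SequenceRecord,
    min_identity: float = 0.75,
    min_len_frac: float = 0.8,
) -> list[MatchBlock]:
    """Approximate occurrences of each representative along the chromosome.

    Each monomer (both strands) is infix-aligned within sliding windows of
    3x its period stepped by one period, so every occurrence lies fully
    inside at least one window; overlapping or touching hits of the same
    monomer are merged into one block with length-weighted identity.
    """
    out: list[MatchBlock] = []
    seq = chromosome.seq
    for mon_id, rep in representatives:
        p = len(rep)
        k = max(1, int(p * (1 - min_identity)))
        hits: list[tuple[int, int, float]] = []
        for pattern in (rep, revcomp(rep)):
            for w0 in range(0, max(1, len(seq) - p + 1), p):
                window = seq[w0:w0 + 3 * p]
                if len(window) < p:
                    continue
                res = edlib.align(pattern, window, mode="HW",
                                  task="locations", k=k)
                if res["editDistance"] < 0:
                    continue
                identity = 1.0 - res["editDistance"] / p
                loc = res["locations"][0]
                start, end = w0 + loc[0], w0 + loc[1] + 1
                if end - start < min_len_frac * p:
                    continue
                hits.append((start, end, identity))
        if not hits:
            continue
        hits.sort()
        cur_s, cur_e, cur_w = hits[0][0], hits[0][1], \
            hits[0][2] * (hits[0][1] - hits[0][0])
        for s, e, ident in hits[1:]:
            if s <= cur_e:
                cur_w += ident * (e - s) if e > cur_e else 0.0
                cur_e = max(cur_e, e)
            else:
                out.append(MatchBlock(
                    chromosome.id, Interval(chromosome.id, cur_s, cur_e),
                    mon_id, round(cur_w / (cur_e - cur_s), 4)))
                cur_s, cur_e, cur_w = s, e, ident * (e - s)
        out.append(MatchBlock(
            chromosome.id, Interval(chromosome.id, cur_s, cur_e),
            mon_id, round(cur_w / (cur_e - cur_s), 4)))
    out.sort(key=lambda b: (b.span.start, b.span.end, b.monomer_id))
    return out


# ---------------------------------------------------------------------------
# candidate merging and scoring

def _union_bp(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    return total + cur_e - cur_s


def merge_candidates(
    blocks: Sequence[MatchBlock],
    max_gap: int = 50_000,
    min_span: int = 10_000,
) -> list[CentromereCandidate]:
    """Single-linkage merge of match blocks (any monomer) within max_gap.

    tandem_bp is the base-level union of the member blocks, so bases matched
    by several monomers count once.  Spans shorter than min_span are dropped.
    """
    by_chrom: dict[str, list[MatchBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.chrom, []).append(b)
    out: list[CentromereCandidate] = []
    for chrom in sorted(by_chrom):
        bs = sorted(by_chrom[chrom], key=lambda b: (b.span.start, b.span.end))
        group: list[MatchBlock] = []
        group_end = -1
        for b in bs + [None]:  # type: ignore[list-item]
            if b is not None and (not group or b.span.start - group_end <= max_gap):
                group.append(b)
                group_end = max(group_end, b.span.end)
                continue
            if group:
                s = min(g.span.start for g in group)
                e = max(g.span.end for g in group)
                if e - s >= min_span:
                    per_mon: dict[str, list[tuple[int, int]]] = {}
                    for g in group:
                        per_mon.setdefault(g.monomer_id, []).append(
                            (g.span.start, g.span.end))
                    mon_bp = {m: _union_bp(iv) for m, iv in per_mon.items()}
                    out.append(CentromereCandidate(
                        chrom=chrom, span=Interval(chrom, s, e),
                        tandem_bp=_union_bp(
                            [(g.span.start, g.span.end) for g in group]),
                        monomer_bp=mon_bp,
                    ))
            if b is not None:
                group = [b]
                group_end = b.span.end
    return out


def score_and_rank(
    candidates: Sequence[CentromereCandidate],
    te_annotation: TeAnnotation | None = None,
    lambda_te: float = 1.0,
    top_monomers: int = 3,
) -> list[CentromereCandidate]:
    """score = tandem_bp + lambda_te * retrotransposon_bp within the span.

    Candidates are ranked descending per chromosome; ties go to the larger
    tandem_bp, then the leftmost span.
    """
    for c in candidates:
        te_bp = 0
        if te_annotation is not None:
            retro = [(iv.start, iv.end)
                     for iv in te_annotation.retro_intervals(c.chrom)]
            clipped = [
                (max(s, c.span.start), min(e, c.span.end))
                for s, e in retro
                if min(e, c.span.end) > max(s, c.span.start)
            ]
            te_bp = _union_bp(clipped)
        c.te_bp = te_bp
        c.score = c.tandem_bp + lambda_te * te_bp
        c.main_monomers = sorted(
            c.monomer_bp, key=lambda m: (-c.monomer_bp[m], m)
        )[:top_monomers]
    by_chrom: dict[str, list[CentromereCandidate]] = {}
    for c in candidates:
        by_chrom.setdefault(c.chrom, []).append(c)
    ranked: list[CentromereCandidate] = []
    for chrom in sorted(by_chrom):
        cs = sorted(by_chrom[chrom],
                    key=lambda c: (-c.score, -c.tandem_bp, c.span.start))
        for i, c in enumerate(cs, start=1):
            c.rank = i
        ranked.extend(cs)
    return ranked


def report_top(
    candidates: Sequence[CentromereCandidate],
    chroms: Sequence[str],
    top_n: int = 5,
) -> dict[str, list[CentromereCandidate]]:
    """Top-n ranked candidates per chromosome; empty chromosomes included."""
    report: dict[str, list[CentromereCandidate]] = {c: [] for c in chroms}
    for c in sorted(candidates, key=lambda c: (c.chrom, c.rank)):
        if c.chrom in report and len(report[c.chrom]) < top_n:
            report[c.chrom].append(c)
    return report


# ---------------------------------------------------------------------------
# orchestration

def run_centrominer(
    genome: Sequence[SequenceRecord],
    te_annotation: TeAnnotation | None = None,
    period_range: tuple[int, int] = (50, 300),
    min_period: int = 100,
    max_period: int = 200,
    min_copies: float = 10,
    min_purity: float = 0.7,
    cluster_identity: float = 0.8,
    map_identity: float = 0.75,
    max_gap: int = 50_000,
    min_span: int = 10_000,
    lambda_te: float = 1.0,
    top_n: int = 5,
    threads: int = 1,
) -> dict:
    """Per-chromosome centromere candidate pipeline."""
    from .parallel import run_ordered

    def per_chrom(rec: SequenceRecord):
        arrays = find_tandem_arrays(rec.seq, rec.id, period_range,
                                    min_purity=min_purity)
        selected = select_centromeric_monomers(arrays, min_period, max_period,
                                               min_copies)
        clusters = cluster_monomers(selected, cluster_identity)
        reps = [(f"{rec.id}.{cl.id}", cl.representative) for cl in clusters]
        blocks = map_monomers(reps, rec, map_identity)
        cands = merge_candidates(blocks, max_gap, min_span)
        return arrays, clusters, blocks, cands

    results = run_ordered(per_chrom, list(genome), threads)
    all_arrays, all_clusters, all_blocks, all_cands = [], [], [], []
    catalog: list[tuple[str, str]] = []
    for rec, (arrays, clusters, blocks, cands) in zip(genome, results):
        all_arrays.extend(arrays)
        all_clusters.extend(clusters)
        all_blocks.extend(blocks)
        all_cands.extend(cands)
        catalog.extend(
            (f"{rec.id}.{cl.id}", cl.representative) for cl in clusters
        )
    ranked = score_and_rank(all_cands, te_annotation, lambda_te)
    top = report_top(ranked, [r.id for r in genome], top_n)
    return {
        "arrays": all_arrays,
        "clusters": all_clusters,
        "blocks": all_blocks,
        "candidates": ranked,
        "top": top,
        "monomer_catalog": catalog,
    }
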
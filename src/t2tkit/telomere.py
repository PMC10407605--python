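"""Telomere identification by canonical-rotation repeat enrichment.

Telomeric repeats are short tandem monomers (7 bp TTTAGGG in most plants,
6 bp TTAGGG in most animals) arrayed at chromosome ends.  Because an array
can be read in any phase and from either strand, monomers are compared in a
canonical form: the lexicographically minimal string over all rotations of
the k-mer and of its reverse complement.  A known clade monomer can be
supplied, or the most enriched repeat at each end can be found de novo.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqio import SequenceRecord, Interval, revcomp


@dataclass(frozen=True)
class RepeatMonomer:
    """A tandem repeat unit, stored as its canonical rotation/strand form."""

    canonical: str
    period: int


@dataclass(frozen=True)
class TelomereCall:
    chrom: str
    end: str  # "left" or "right"
    monomer: RepeatMonomer | None
    copies: int
    present: bool


#: Canonical clade monomers targeted by the preset mode.
CLADE_MONOMERS = {"plant": "TTTAGGG", "animal": "TTAGGG"}


def canonical_form(kmer: str) -> str:
    """Minimal string over all rotations of kmer and of its reverse complement."""
    kmer = kmer.upper()
    if "N" in kmer:
        raise ValueError("k-mer contains N")
    if any(c not in "ACGT" for c in kmer):
        raise ValueError(f"k-mer contains non-ACGT residue: {kmer!r}")
    rc = revcomp(kmer)
    doubled, rc_doubled = kmer + kmer, rc + rc
    n = len(kmer)
    return min(
        min(doubled[i:i + n] for i in range(n)),
        min(rc_doubled[i:i + n] for i in range(n)),
    )


# ---------------------------------------------------------------------------
# vectorized canonical codes

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def _codes(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_ints(codes: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    n = len(codes) - p + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, p)
    valid = ~(win == 255).any(axis=1)
    powers = (4 ** np.arange(p - 1, -1, -1)).astype(np.int64)
    return win.astype(np.int64) @ powers, valid


def _canonical_ints(seq: str, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical integer code of the p-mer starting at every position.

    The minimum over all p rotations of the forward p-mer and all p rotations
    of its reverse complement, computed arithmetically for every position at
    once.  Returns (canonical codes, validity mask).
    """
    fwd = _codes(seq)
    vals, valid = _kmer_ints(fwd, p)
    if len(vals) == 0:
        return vals, valid
    rc_vals, _ = _kmer_ints(_codes(revcomp(seq)), p)
    # p-mer at i on the forward strand revcomps to position L - p - i of rc seq
    rc_for_pos = rc_vals[::-1]
    base = 4 ** np.arange(p, dtype=np.int64)
    best = vals.copy()
    for variant in (vals, rc_for_pos):
        rot = variant.copy()
        for _ in range(p - 1):
            rot = (rot % base[1]) * base[p - 1] + rot // base[1]
            np.minimum(best, rot, out=best)
        np.minimum(best, variant, out=best)
    return best, valid


def _int_to_kmer(code: int, p: int) -> str:
    out = []
    for _ in range(p):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def kmer_to_int(kmer: str) -> int:
    code = 0
    for c in kmer:
        code = code * 4 + "ACGT".index(c)
    return code


# ---------------------------------------------------------------------------
# enrichment

def _class_positions(seq: str, monomer: RepeatMonomer) -> np.ndarray:
    """Positions whose p-mer canonical form equals the monomer's canonical."""
    canon_ints, valid = _canonical_ints(seq, monomer.period)
    if len(canon_ints) == 0:
        return np.empty(0, np.int64)
    target = kmer_to_int(monomer.canonical)
    return np.nonzero((canon_ints == target) & valid)[0].astype(np.int64)


def _union_coverage(positions: np.ndarray, p: int) -> int:
    """Bases covered by the union of [i, i+p) over matching positions."""
    if len(positions) == 0:
        return 0
    gaps = np.diff(positions)
    return int(np.minimum(gaps, p).sum() + p)


def _tandem_supported(positions: np.ndarray, p: int) -> np.ndarray:
    """Positions with another class match exactly one period away.

    Scattered chance matches of a short class in background sequence lack
    such support; positions inside a tandem array almost always have it.
    """
    if len(positions) == 0:
        return positions
    pos_set = set(positions.tolist())
    return np.array([i for i in positions
                     if i - p in pos_set or i + p in pos_set],
                    dtype=np.int64)


def _densest_window_coverage(positions: np.ndarray, p: int,
                             seq_len: int, window: int) -> int:
    dense = 0
    for w0 in range(0, seq_len, window):
        in_w = positions[(positions >= w0) & (positions < w0 + window)]
        dense = max(dense, _union_coverage(in_w, p))
    return dense


def most_enriched_repeat(
    end_seq: str,
    period_range: tuple[int, int] = (4, 15),
    min_coverage_frac: float = 0.5,
    dense_window: int = 1_000,
) -> RepeatMonomer | None:
    """Find the most enriched short tandem repeat in a terminal window.

    For each period p in range, p-mers at every offset are pooled by
    canonical class.  A class is a telomere candidate only if it covers at
    least ``min_coverage_frac`` of its densest ``dense_window`` sub-window —
    without this guard, pure enrichment reports scattered background k-mer
    classes on ends that have no telomere at all.  Among candidates the
    winner maximizes the tandem-supported match count, then base coverage
    (union of matched spans), with remaining ties broken toward the smaller
    period (so a doubled-period class never beats its fundamental monomer).
    """
    lo, hi = period_range
    if len(end_seq) < hi:
        return None
    best: tuple[int, int, int, int] | None = None  # (n_hits, cov, -p, class)
    n_win = len(end_seq) // dense_window + 1
    for p in range(lo, hi + 1):
        canon_ints, valid = _canonical_ints(end_seq, p)
        if len(canon_ints) == 0:
            continue
        pos = np.nonzero(valid)[0]
        vals = canon_ints[pos]
        if len(vals) == 0:
            continue
        uniq, inverse = np.unique(vals, return_inverse=True)
        # cheap upper bound: per-class max hit count in any fixed sub-window
        key = inverse.astype(np.int64) * n_win + pos // dense_window
        uk, kcounts = np.unique(key, return_counts=True)
        cls_of_key = uk // n_win
        boundaries = np.nonzero(np.diff(cls_of_key))[0] + 1
        starts_idx = np.concatenate(([0], boundaries))
        max_per_class = np.maximum.reduceat(kcounts, starts_idx)
        classes = cls_of_key[starts_idx]
        floor = min_coverage_frac * dense_window
        for ci in classes[max_per_class * p >= floor]:
            cls_pos = pos[inverse == ci]
            cls_pos = _tandem_supported(cls_pos, p)
            if _densest_window_coverage(cls_pos, p, len(end_seq),
                                        dense_window) < floor:
                continue
            cov = _union_coverage(cls_pos, p)
            # coverage alone cannot separate a near-period rotation class
            # (which can tile an array using a fraction of its offsets, plus
            # chance flank hits) from the true monomer; the supported-match
            # count can, since the true period matches at every offset
            cand = (len(cls_pos), cov, -p, int(uniq[ci]))
            if best is None or cand > best:
                best = cand
    if best is None:
        return None
    _n, cov, neg_p, cls_int = best
    return RepeatMonomer(_int_to_kmer(cls_int, -neg_p), -neg_p)


def windowed_counts(seq: str, monomer: RepeatMonomer,
                    window: int = 10_000) -> list[tuple[Interval, int]]:
    """Per-window count of positions matching the monomer's canonical class."""
    positions = _class_positions(seq, monomer)
    out = []
    for w0 in range(0, len(seq), window):
        w1 = min(w0 + window, len(seq))
        count = int(((positions >= w0) & (positions < w1)).sum())
        out.append((Interval("seq", w0, w1), count))
    return out


def count_copies(seq: str, monomer: RepeatMonomer) -> int:
    """Non-overlapping tandem occurrences of the monomer class in seq.

    Only positions with another class match exactly one period away (either
    side) are counted, so scattered chance matches of a short monomer class
    in background sequence do not inflate the copy count.
    """
    positions = _class_positions(seq, monomer)
    if len(positions) == 0:
        return 0
    p = monomer.period
    pos_set = set(positions.tolist())
    count = 0
    last_end = -1
    for i in positions:
        if i >= last_end and (i - p in pos_set or i + p in pos_set):
            count += 1
            last_end = i + p
    return count


@dataclass
class TelomereSummary:
    pairs: int
    singletons: int

    @property
    def total(self) -> int:
        return telomere_total(self.pairs, self.singletons)


def telomere_total(pairs: int, singletons: int) -> int:
    """Total telomere count: two per both-end chromosome plus singletons."""
    return 2 * pairs + singletons


def call_telomeres(
    genome: Sequence[SequenceRecord],
    clade: str | None = "plant",
    min_copies: int = 100,
    terminal_window: int = 150_000,
    period_range: tuple[int, int] = (4, 15),
) -> tuple[list[TelomereCall], TelomereSummary]:
    """Call telomere presence at both ends of every chromosome.

    ``clade`` selects a preset monomer ("plant"/"animal"); None switches to
    de novo discovery with :func:`most_enriched_repeat` per end.  An end is
    present when at least ``min_copies`` non-overlapping monomer copies fall
    inside its terminal window.
    """
    preset = None
    if clade is not None:
        seq = CLADE_MONOMERS.get(clade, clade)  # allow a literal monomer
        preset = RepeatMonomer(canonical_form(seq), len(seq))
    calls: list[TelomereCall] = []
    for rec in genome:
        for end in ("left", "right"):
            win = (rec.seq[:terminal_window] if end == "left"
                   else rec.seq[-terminal_window:])
            monomer = preset or most_enriched_repeat(win, period_range)
            if monomer is None:
                calls.append(TelomereCall(rec.id, end, None, 0, False))
                continue
            copies = count_copies(win, monomer)
            calls.append(TelomereCall(rec.id, end, monomer, copies,
                                      copies >= min_copies))
    pairs = singles = 0
    for rec in genome:
        present = [c.present for c in calls if c.chrom == rec.id]
        if all(present):
            pairs += 1
        elif any(present):
            singles += 1
    return calls, TelomereSummary(pairs, singles)


def telomeric_spans(genome: Sequence[SequenceRecord],
                    calls: Sequence[TelomereCall],
                    terminal_window: int = 150_000) -> list[Interval]:
    """Genome intervals from first to last monomer match per present end."""
    spans = []
    by_id = {r.id: r for r in genome}
    for call in calls:
        if not call.present or call.monomer is None:
            continue
        rec = by_id[call.chrom]
        if call.end == "left":
            win, off = rec.seq[:terminal_window], 0
        else:
            off = max(0, len(rec.seq) - terminal_window)
            win = rec.seq[off:]
        pos = _class_positions(win, call.monomer)
        if len(pos) == 0:
            continue
        spans.append(Interval(call.chrom, off + int(pos[0]),
                              off + int(pos[-1]) + call.monomer.period))
    return spans
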
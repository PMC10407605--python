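"""Pluggable alignment backends producing PAF-style blocks.

The contract every backend satisfies is ``(queries, targets) -> list of
AlignmentBlock``.  The default builtin backend is a seed-and-extend matcher:
exact k-mer seeds over a sorted-array index, diagonal chaining, and edlib
refinement of each chain to get match counts.  It is designed for the
near-exact alignments this toolkit needs (contigs vs. a closely related
reference, gap-flank anchors vs. ultra-long reads); an external long-read
aligner can be substituted through the same contract for production use.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import edlib
import numpy as np

from .seqio import AlignmentBlock, SequenceRecord, read_paf, revcomp, write_fasta

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    """2-bit base codes; 255 marks N/invalid."""
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes for every k-mer start plus a validity mask (no N)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = ~(win == 255).any(axis=1)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    vals = win.astype(np.int64) @ powers
    return vals, valid


@dataclass
class _Chain:
    t_idx: int
    strand: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    n_seeds: int
    matches: int = 0
    block_len: int = 0
    mapq: int = 0


class BuiltinAligner:
    """Exact/near-exact seed-and-extend aligner over a k-mer index.

    Parameters
    ----------
    k : seed length; 21 is long enough to be unique in megabase genomes.
    stride : query sampling step for seeds (indexing is every position).
    max_occ : seeds occurring more often than this in the targets are skipped
        (masks satellite arrays, which would otherwise flood the chains).
    band : diagonal tolerance when grouping seeds into a chain; bounds the
        total indel drift a single chain may absorb.
    min_seeds : chains with fewer seeds are discarded as noise.
    """

    def __init__(self, k: int = 21, stride: int = 50, max_occ: int = 16,
                 band: int = 200, min_seeds: int = 3,
                 max_seed_gap: int = 100_000):
        self.k = k
        self.stride = stride
        self.max_occ = max_occ
        self.band = band
        self.min_seeds = min_seeds
        self.max_seed_gap = max_seed_gap
        self._targets: list[SequenceRecord] = []
        self._offsets = np.empty(0, dtype=np.int64)
        self._sorted_codes = np.empty(0, dtype=np.int64)
        self._sorted_pos = np.empty(0, dtype=np.int64)

    # -- index ------------------------------------------------------------
    def index(self, targets: Sequence[SequenceRecord]) -> None:
        self._targets = list(targets)
        codes_all, pos_all, offsets = [], [], [0]
        offset = 0
        for rec in self._targets:
            c = _encode(rec.seq)
            vals, valid = _kmer_codes(c, self.k)
            idx = np.nonzero(valid)[0]
            codes_all.append(vals[idx])
            pos_all.append(idx + offset)
            offset += len(rec.seq)
            offsets.append(offset)
        self._offsets = np.asarray(offsets, dtype=np.int64)
        codes = np.concatenate(codes_all) if codes_all else np.empty(0, np.int64)
        pos = np.concatenate(pos_all) if pos_all else np.empty(0, np.int64)
        order = np.argsort(codes, kind="stable")
        self._sorted_codes = codes[order]
        self._sorted_pos = pos[order]

    # -- mapping ----------------------------------------------------------
    def map(self, queries: Sequence[SequenceRecord]) -> list[AlignmentBlock]:
        if not self._targets:
            raise RuntimeError("index() must be called before map()")
        blocks: list[AlignmentBlock] = []
        for q in queries:
            blocks.extend(self._map_one(q))
        return blocks

    def align(self, queries: Sequence[SequenceRecord],
              targets: Sequence[SequenceRecord]) -> list[AlignmentBlock]:
        self.index(targets)
        return self.map(queries)

    def _map_one(self, query: SequenceRecord) -> list[AlignmentBlock]:
        chains: list[_Chain] = []
        for strand in "+-":
            seq = query.seq if strand == "+" else revcomp(query.seq)
            chains.extend(self._chain_strand(seq, strand))
        if not chains:
            return []
        for c in chains:
            self._refine(query, c)
        chains = [c for c in chains if c.block_len > 0]
        self._assign_mapq(chains)
        out = []
        qlen = len(query.seq)
        for c in chains:
            qs, qe = c.q_start, c.q_end
            if c.strand == "-":  # report on the forward query strand
                qs, qe = qlen - c.q_end, qlen - c.q_start
            out.append(AlignmentBlock(
                query=query.id, q_len=qlen, q_start=qs, q_end=qe,
                strand=c.strand,
                target=self._targets[c.t_idx].id,
                t_len=len(self._targets[c.t_idx].seq),
                t_start=c.t_start, t_end=c.t_end,
                matches=c.matches, block_len=c.block_len, mapq=c.mapq,
            ))
        out.sort(key=lambda b: (b.target, b.t_start, b.q_start, b.strand))
        return out

    def _chain_strand(self, seq: str, strand: str) -> list[_Chain]:
        codes = _encode(seq)
        vals, valid = _kmer_codes(codes, self.k)
        sample = np.arange(0, len(vals), self.stride)
        sample = sample[valid[sample]]
        if len(sample) == 0:
            return []
        qcodes = vals[sample]
        lo = np.searchsorted(self._sorted_codes, qcodes, side="left")
        hi = np.searchsorted(self._sorted_codes, qcodes, side="right")
        occ = hi - lo
        keep = (occ > 0) & (occ <= self.max_occ)
        q_hits, g_hits = [], []
        for qpos, a, b in zip(sample[keep], lo[keep], hi[keep]):
            for g in self._sorted_pos[a:b]:
                q_hits.append(qpos)
                g_hits.append(g)
        if not q_hits:
            return []
        qpos = np.asarray(q_hits, dtype=np.int64)
        gpos = np.asarray(g_hits, dtype=np.int64)
        t_idx = np.searchsorted(self._offsets, gpos, side="right") - 1
        tpos = gpos - self._offsets[t_idx]
        diag = tpos - qpos
        order = np.lexsort((qpos, diag, t_idx))
        qpos, tpos, t_idx, diag = qpos[order], tpos[order], t_idx[order], diag[order]

        chains: list[_Chain] = []
        start = 0
        for i in range(1, len(qpos) + 1):
            boundary = (
                i == len(qpos)
                or t_idx[i] != t_idx[i - 1]
                or diag[i] - diag[i - 1] > self.band
            )
            if boundary:
                sl = slice(start, i)
                if i - start >= self.min_seeds:
                    chains.extend(self._split_chain(
                        int(t_idx[start]), strand, qpos[sl], tpos[sl]))
                start = i
        return chains

    def _split_chain(self, t_idx: int, strand: str,
                     qpos: np.ndarray, tpos: np.ndarray) -> list[_Chain]:
        order = np.argsort(qpos, kind="stable")
        qpos, tpos = qpos[order], tpos[order]
        chains = []
        start = 0
        for i in range(1, len(qpos) + 1):
            if i == len(qpos) or qpos[i] - qpos[i - 1] > self.max_seed_gap:
                if i - start >= self.min_seeds:
                    chains.append(_Chain(
                        t_idx=t_idx, strand=strand,
                        q_start=int(qpos[start]), q_end=int(qpos[i - 1]) + self.k,
                        t_start=int(tpos[start:i].min()),
                        t_end=int(tpos[start:i].max()) + self.k,
                        n_seeds=i - start,
                    ))
                start = i
        return chains

    def _refine(self, query: SequenceRecord, c: _Chain) -> None:
        qseq = query.seq if c.strand == "+" else revcomp(query.seq)
        qsub = qseq[c.q_start:c.q_end]
        tsub = self._targets[c.t_idx].seq[c.t_start:c.t_end]
        res = edlib.align(qsub, tsub, mode="NW", task="distance")
        dist = res["editDistance"]
        c.block_len = max(len(qsub), len(tsub))
        c.matches = max(0, c.block_len - dist)

    def _assign_mapq(self, chains: list[_Chain]) -> None:
        for c in chains:
            rival_best = 0
            for d in chains:
                if d is c:
                    continue
                ov = min(c.q_end, d.q_end) - max(c.q_start, d.q_start)
                if ov > 0.5 * min(c.q_end - c.q_start, d.q_end - d.q_start):
                    rival_best = max(rival_best, d.matches)
            if rival_best == 0:
                c.mapq = 60
            elif rival_best >= c.matches:
                c.mapq = 0
            else:
                c.mapq = min(60, int(60 * (1 - rival_best / c.matches)))


class ExternalAligner:
    """Run a minimap2-compatible binary and parse its PAF output."""

    def __init__(self, binary: str, extra_args: Sequence[str] = ("-x", "asm5")):
        if shutil.which(binary) is None:
            raise FileNotFoundError(f"aligner binary not found: {binary}")
        self.binary = binary
        self.extra_args = list(extra_args)

    def align(self, queries: Sequence[SequenceRecord],
              targets: Sequence[SequenceRecord]) -> list[AlignmentBlock]:
        with tempfile.TemporaryDirectory() as tmp:
            qpath = Path(tmp) / "q.fa"
            tpath = Path(tmp) / "t.fa"
            opath = Path(tmp) / "out.paf"
            write_fasta(queries, qpath)
            write_fasta(targets, tpath)
            with open(opath, "w") as out:
                subprocess.run(
                    [self.binary, *self.extra_args, str(tpath), str(qpath)],
                    stdout=out, stderr=subprocess.DEVNULL, check=True,
                )
            return read_paf(opath)


def get_aligner(spec: str = "builtin", **kwargs):
    """Resolve an aligner backend from a CLI-style selector."""
    if spec == "builtin":
        return BuiltinAligner(**kwargs)
    return ExternalAligner(spec)


def semiglobal_identity(pattern: str, text: str) -> tuple[float, tuple[int, int] | None]:
    """Best infix alignment of pattern within text: (identity, location).

    Identity is 1 - dist/len(pattern); location is the half-open text span of
    the best hit, or None when text is empty.
    """
    if not text or not pattern:
        return 0.0, None
    res = edlib.align(pattern, text, mode="HW", task="locations")
    dist = res["editDistance"]
    loc = res["locations"][0]
    return 1.0 - dist / len(pattern), (loc[0], loc[1] + 1)
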
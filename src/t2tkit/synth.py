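"""Seeded synthetic genomes with planted, machine-readable ground truth.

The generator emulates the inputs of the whole pipeline: chromosomes with
terminal telomere arrays, an internal centromeric satellite array (mutated
at a configurable per-base rate), interspersed transposable-element copies,
contig fragmentation with shuffling and reverse complements, a gapped draft
with recorded true fill sequences, spanning ultra-long reads, and a
SNP/indel-diverged reference.  Everything is deterministic from (spec,
seed): each stage draws from its own generator keyed by (seed, stage), so
adding a stage never perturbs an earlier stage's stream.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .seqio import Interval, SequenceRecord, TeAnnotation, revcomp, write_fasta, \
    write_te_gff3

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# stage keys for the per-stage random streams
_STAGE_GENOME = 0
_STAGE_CONTIGS = 1
_STAGE_DRAFT = 2
_STAGE_READS = 3
_STAGE_REFERENCE = 4


@dataclass
class GenomeSpec:
    """Planted-feature layout of one synthetic genome."""

    chrom_lengths: tuple[int, ...] = (1_000_000, 1_000_000, 1_000_000)
    telomere_monomer: str = "TTTAGGG"
    telomere_copies: int = 200
    telomere_ends: str = "both"  # both | left | right | none
    centromere_period: int = 178
    centromere_copies: int = 100
    centromere_pos_frac: float = 0.5
    mutation_rate: float = 0.02  # per-base divergence of planted arrays
    te_count: int = 20           # TE copies per chromosome
    te_len_range: tuple[int, int] = (1_000, 8_000)
    retro_fraction: float = 0.7
    decoy_arrays: int = 2        # short-period tandem decoys per chromosome
    decoy_period_range: tuple[int, int] = (15, 40)
    decoy_copies: int = 60
    gc: float = 0.36
    seed: int = 42

    def validate(self) -> None:
        if not (0 <= self.mutation_rate <= 1 and 0 <= self.retro_fraction <= 1
                and 0 <= self.gc <= 1 and 0 <= self.centromere_pos_frac <= 1):
            raise ValueError("all rates must lie in [0, 1]")
        telo = self.telomere_copies * len(self.telomere_monomer)
        cen = self.centromere_copies * self.centromere_period
        for length in self.chrom_lengths:
            if 2 * telo + cen + 20_000 > length:
                raise ValueError(
                    f"planted features ({2 * telo + cen} bp) overflow a "
                    f"{length} bp chromosome"
                )


@dataclass
class TruthTable:
    """Planted ground truth, reproducible from (spec, seed) alone."""

    telomeres: dict = field(default_factory=dict)   # chrom -> {end: [s,e]}
    telomere_monomer: str = ""
    centromeres: dict = field(default_factory=dict)  # chrom -> {span, monomer}
    tes: dict = field(default_factory=dict)          # chrom -> [[s,e,class],...]
    contigs: dict = field(default_factory=dict)      # id -> [chrom,s,e,strand]
    reads: dict = field(default_factory=dict)        # id -> [chrom,s,e,strand]
    gaps: list = field(default_factory=list)         # per-gap dicts

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        with open(path) as fh:
            return cls(**json.load(fh))


def _stage_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, *key])


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    at, gcp = (1 - gc) / 2, gc / 2
    return rng.choice(_BASES, size=n, p=[at, gcp, gcp, at])


def _mutate(rng: np.random.Generator, arr: np.ndarray, rate: float) -> np.ndarray:
    """Substitute bases at the given per-base rate, never to the same base."""
    if rate <= 0:
        return arr
    out = arr.copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hit):
        idx = np.searchsorted(_BASES, out[hit])
        shift = rng.integers(1, 4, size=len(hit))
        out[hit] = _BASES[(idx + shift) % 4]
    return out


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def _tile(monomer: str, copies: int) -> np.ndarray:
    return np.frombuffer((monomer * copies).encode(), dtype=np.uint8).copy()


def make_truth_genome(spec: GenomeSpec) -> tuple[
        list[SequenceRecord], TeAnnotation, TruthTable]:
    """Generate the genome, its TE annotation and the truth table."""
    spec.validate()
    truth = TruthTable(telomere_monomer=spec.telomere_monomer)
    te_ann = TeAnnotation()
    records: list[SequenceRecord] = []

    fam_rng = _stage_rng(spec.seed, _STAGE_GENOME, 999)
    te_families = [
        ("Gypsy_LTR_retrotransposon",
         _random_seq(fam_rng, spec.te_len_range[1], 0.45)),
        ("Copia_LTR_retrotransposon",
         _random_seq(fam_rng, spec.te_len_range[1], 0.45)),
        ("DNA_transposon", _random_seq(fam_rng, spec.te_len_range[1], 0.45)),
    ]

    tlen = spec.telomere_copies * len(spec.telomere_monomer)
    for ci, length in enumerate(spec.chrom_lengths):
        rng = _stage_rng(spec.seed, _STAGE_GENOME, ci)
        chrom = f"chr{ci + 1}"
        seq = _random_seq(rng, length, spec.gc)
        occupied: list[tuple[int, int]] = []

        truth.telomeres[chrom] = {}
        want_left = spec.telomere_ends in ("both", "left")
        want_right = spec.telomere_ends in ("both", "right")
        if want_left:
            arr = _mutate(rng, _tile(spec.telomere_monomer,
                                     spec.telomere_copies), spec.mutation_rate)
            seq[:tlen] = arr
            truth.telomeres[chrom]["left"] = [0, tlen]
            occupied.append((0, tlen))
        if want_right:
            arr = _mutate(rng, _tile(revcomp(spec.telomere_monomer),
                                     spec.telomere_copies), spec.mutation_rate)
            seq[length - tlen:] = arr
            truth.telomeres[chrom]["right"] = [length - tlen, length]
            occupied.append((length - tlen, length))

        cen_monomer = _to_str(_random_seq(rng, spec.centromere_period, 0.45))
        clen = spec.centromere_copies * spec.centromere_period
        c_start = int(spec.centromere_pos_frac * length) - clen // 2
        c_start = max(tlen + 10_000, min(c_start, length - tlen - 10_000 - clen))
        arr = _mutate(rng, _tile(cen_monomer, spec.centromere_copies),
                      spec.mutation_rate)
        seq[c_start:c_start + clen] = arr
        truth.centromeres[chrom] = {
            "span": [c_start, c_start + clen],
            "monomer": cen_monomer,
            "period": spec.centromere_period,
        }
        occupied.append((c_start, c_start + clen))

        for _ in range(spec.decoy_arrays):
            p = int(rng.integers(*spec.decoy_period_range))
            mono = _to_str(_random_seq(rng, p, 0.5))
            dlen = p * spec.decoy_copies
            pos = _place(rng, length, dlen, occupied)
            if pos is None:
                continue
            seq[pos:pos + dlen] = _mutate(rng, _tile(mono, spec.decoy_copies),
                                          spec.mutation_rate)
            occupied.append((pos, pos + dlen))

        truth.tes[chrom] = []
        for _ in range(spec.te_count):
            is_retro = rng.random() < spec.retro_fraction
            fam_idx = int(rng.integers(0, 2)) if is_retro else 2
            te_class, fam_seq = te_families[fam_idx]
            te_len = int(rng.integers(*spec.te_len_range))
            pos = _place(rng, length, te_len, occupied)
            if pos is None:
                continue
            copy = _mutate(rng, fam_seq[:te_len].copy(), spec.mutation_rate)
            seq[pos:pos + te_len] = copy
            occupied.append((pos, pos + te_len))
            truth.tes[chrom].append([pos, pos + te_len, te_class])
            te_ann.intervals.append(
                (Interval(chrom, pos, pos + te_len, "+"), te_class, is_retro)
            )

        records.append(SequenceRecord(chrom, _to_str(seq)))
    return records, te_ann, truth


def _place(rng: np.random.Generator, length: int, size: int,
           occupied: list[tuple[int, int]], margin: int = 5_000,
           tries: int = 200) -> int | None:
    for _ in range(tries):
        pos = int(rng.integers(margin, length - margin - size))
        if all(pos + size + margin <= s or pos >= e + margin
               for s, e in occupied):
            return pos
    return None


def fragment_to_contigs(
    genome: list[SequenceRecord],
    truth: TruthTable,
    n_breaks: int = 3,
    shuffle: bool = True,
    rc_fraction: float = 0.5,
    seed: int | None = None,
    min_frag: int = 60_000,
) -> list[SequenceRecord]:
    """Partition each chromosome into contigs; shuffle and reverse-complement.

    Break positions are jittered even spacings, so every fragment keeps a
    workable minimum length.  Truth records each contig's source interval
    and orientation; concatenating truth-ordered, orientation-corrected
    contigs reproduces the genome.
    """
    if seed is None:
        seed = 0
    pieces: list[tuple[str, int, int, str]] = []  # chrom, start, end, strand
    for ci, rec in enumerate(genome):
        rng = _stage_rng(seed, _STAGE_CONTIGS, ci)
        L = len(rec.seq)
        if n_breaks >= L:
            raise ValueError(f"n_breaks={n_breaks} >= chromosome length {L}")
        step = L / (n_breaks + 1)
        jitter_max = max(1, int(min(step / 4, (step - min_frag) / 2)))
        breaks = sorted(
            int((i + 1) * step + rng.integers(-jitter_max, jitter_max + 1))
            for i in range(n_breaks)
        )
        bounds = [0, *breaks, L]
        for s, e in zip(bounds[:-1], bounds[1:]):
            strand = "-" if rng.random() < rc_fraction else "+"
            pieces.append((rec.id, s, e, strand))
    order_rng = _stage_rng(seed, _STAGE_CONTIGS, 10_000)
    order = (order_rng.permutation(len(pieces)) if shuffle
             else np.arange(len(pieces)))
    by_id = {r.id: r.seq for r in genome}
    contigs = []
    for rank, idx in enumerate(order, start=1):
        chrom, s, e, strand = pieces[idx]
        seq = by_id[chrom][s:e]
        if strand == "-":
            seq = revcomp(seq)
        cid = f"ctg{rank:04d}"
        contigs.append(SequenceRecord(cid, seq))
        truth.contigs[cid] = [chrom, s, e, strand]
    return contigs


def make_gapped_draft(
    genome: list[SequenceRecord],
    truth: TruthTable,
    n_gaps_per_chrom: int = 2,
    gap_run: int = 100,
    removed_len_range: tuple[int, int] = (2_000, 6_000),
    seed: int | None = None,
    margin: int = 60_000,
) -> list[SequenceRecord]:
    """Replace random spans with N runs; record the removed true fills.

    Gap sites avoid planted telomere/centromere arrays so a fill is judged
    purely on sequence identity, and sit >= margin from chromosome ends.
    """
    if seed is None:
        seed = 0
    draft = []
    for ci, rec in enumerate(genome):
        rng = _stage_rng(seed, _STAGE_DRAFT, ci)
        L = len(rec.seq)
        avoid = []
        for end_iv in truth.telomeres.get(rec.id, {}).values():
            avoid.append(tuple(end_iv))
        if rec.id in truth.centromeres:
            avoid.append(tuple(truth.centromeres[rec.id]["span"]))
        sites = []
        for _ in range(n_gaps_per_chrom):
            rem = int(rng.integers(*removed_len_range))
            pos = _place(rng, L, rem, avoid + sites, margin=margin)
            if pos is None:
                continue
            sites.append((pos, pos + rem))
        sites.sort()
        parts, prev, delta = [], 0, 0
        for s, e in sites:
            parts.append(rec.seq[prev:s])
            parts.append("N" * gap_run)
            truth.gaps.append({
                "chrom": rec.id,
                "genome_span": [s, e],
                "draft_gap_start": s - delta,
                "gap_run": gap_run,
                "true_fill": rec.seq[s:e],
            })
            delta += (e - s) - gap_run
            prev = e
        parts.append(rec.seq[prev:])
        draft.append(SequenceRecord(rec.id, "".join(parts), rec.description))
    return draft


def simulate_ultralong_reads(
    genome: list[SequenceRecord],
    truth: TruthTable,
    n_background: int = 30,
    length_range: tuple[int, int] = (60_000, 120_000),
    error_rate: float = 0.0,
    seed: int | None = None,
    spanning_per_gap: int = 2,
    flank_margin: int = 7_000,
) -> list[SequenceRecord]:
    """Ultra-long reads off the true genome, guaranteed to span each gap.

    For every recorded gap, ``spanning_per_gap`` reads cover the removed span
    with at least ``flank_margin`` on both sides; the rest are background
    reads at random positions.  Errors are substitutions only by default.
    """
    if seed is None:
        seed = 0
    rng = _stage_rng(seed, _STAGE_READS, 0)
    by_id = {r.id: r.seq for r in genome}
    reads: list[SequenceRecord] = []

    def emit(chrom: str, start: int, end: int) -> None:
        rid = f"read{len(reads) + 1:04d}"
        strand = "-" if rng.random() < 0.5 else "+"
        arr = np.frombuffer(by_id[chrom][start:end].encode(), np.uint8).copy()
        arr = _mutate(rng, arr, error_rate)
        seq = _to_str(arr)
        if strand == "-":
            seq = revcomp(seq)
        reads.append(SequenceRecord(rid, seq))
        truth.reads[rid] = [chrom, start, end, strand]

    for gap in truth.gaps:
        chrom = gap["chrom"]
        gs, ge = gap["genome_span"]
        L = len(by_id[chrom])
        need = (ge - gs) + 2 * flank_margin
        for _ in range(spanning_per_gap):
            rlen = int(rng.integers(max(need, length_range[0]),
                                    max(need + 1, length_range[1])))
            lo = max(0, ge + flank_margin - rlen)
            hi = max(lo, min(gs - flank_margin, L - rlen))
            start = int(rng.integers(lo, hi + 1))
            emit(chrom, start, min(L, start + rlen))
        if ge - gs + 2 * flank_margin > length_range[1]:
            # gap unfillable by construction with these read lengths
            import warnings
            warnings.warn(f"gap at {chrom}:{gs}-{ge} wider than reads can span")

    for _ in range(n_background):
        chrom = genome[int(rng.integers(0, len(genome)))].id
        L = len(by_id[chrom])
        rlen = int(rng.integers(*length_range))
        start = int(rng.integers(0, max(1, L - rlen)))
        emit(chrom, start, min(L, start + rlen))
    return reads


def diverge_reference(
    genome: list[SequenceRecord],
    snp_rate: float = 0.01,
    small_indel_rate: float = 0.0005,
    max_indel: int = 10,
    seed: int | None = None,
) -> list[SequenceRecord]:
    """A SNP- and small-indel-diverged copy of the genome."""
    if seed is None:
        seed = 0
    out = []
    for ci, rec in enumerate(genome):
        rng = _stage_rng(seed, _STAGE_REFERENCE, ci)
        arr = np.frombuffer(rec.seq.encode(), np.uint8).copy()
        arr = _mutate(rng, arr, snp_rate)
        if small_indel_rate > 0:
            n_events = rng.binomial(len(arr), small_indel_rate)
            positions = np.sort(rng.choice(len(arr), size=n_events,
                                           replace=False))
            parts, prev = [], 0
            for pos in positions:
                parts.append(arr[prev:pos])
                size = int(rng.integers(1, max_indel + 1))
                if rng.random() < 0.5:  # insertion
                    parts.append(_random_seq(rng, size, 0.5))
                    prev = pos
                else:  # deletion
                    prev = min(len(arr), pos + size)
            parts.append(arr[prev:])
            arr = np.concatenate(parts)
        out.append(SequenceRecord(rec.id, _to_str(arr)))
    return out


def default_spec(seed: int = 42) -> GenomeSpec:
    return GenomeSpec(seed=seed)


def generate_all(spec: GenomeSpec, outdir: str | Path) -> dict:
    """Emit the full fixture set: genome, reference, contigs, draft, reads,
    TE GFF3 and the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, te_ann, truth = make_truth_genome(spec)
    contigs = fragment_to_contigs(genome, truth, seed=spec.seed)
    draft = make_gapped_draft(genome, truth, seed=spec.seed)
    reads = simulate_ultralong_reads(genome, truth, seed=spec.seed)
    reference = diverge_reference(genome, seed=spec.seed)
    write_fasta(genome, outdir / "genome.fa")
    write_fasta(reference, outdir / "reference.fa")
    write_fasta(contigs, outdir / "contigs.fa")
    write_fasta(draft, outdir / "draft.fa")
    write_fasta(reads, outdir / "reads.fa")
    write_te_gff3(te_ann, outdir / "te.gff3")
    truth.to_json(outdir / "truth.json")
    return {"genome": genome, "reference": reference, "contigs": contigs,
            "draft": draft, "reads": reads, "te": te_ann, "truth": truth}
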
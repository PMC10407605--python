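# Methods

This note documents the models and procedures behind each stage, the
parameters that matter, the numerical choices, and what the synthetic
studies do and do not demonstrate.

## Coordinate and format conventions

Internal coordinates are 0-based half-open everywhere; AGP and GFF3 (both
1-based inclusive on disk) are converted at the I/O boundary. IUPAC
ambiguity codes other than N are normalized to N on read with a logged
warning rather than rejected, because real assemblies contain sporadic
ambiguity codes and hard failure would be unhelpful. AGP gap rows are
emitted as component type `U`, gap type `scaffold`, linkage `yes`, evidence
`align_genus`, matching the semantics of reference-alignment scaffolding in
the AGP v2.1 vocabulary.

## Built-in aligner

The default alignment backend is a seed-and-extend matcher designed for the
near-exact alignments this toolkit needs (contigs against a closely related
reference, ~1% divergence; gap-flank anchors against reads from the same
individual). Every target k-mer (k = 21) is indexed in a sorted array;
query k-mers are sampled every 50 bp on both strands; seeds sharing a
target and a diagonal within a 200 bp band are chained (chains split when
consecutive seeds are more than 100 kb apart on the query); each chain is
refined with a global edlib alignment to obtain matched bases as
`block_len − edit_distance`. Seeds occurring more than 16 times in the
targets are skipped, which masks satellite and telomere arrays — chains
simply bridge these seed deserts on the same diagonal. Mapping quality is
60 for chains without a query-overlapping rival, 0 when an equal-scoring
rival exists, and scaled in between. The backend contract is
`(queries, targets) → PAF-style blocks`, so an external long-read aligner
(e.g. minimap2) can be substituted; the built-in matcher is the tested
default so the test suite needs no binaries, and the test suite cross-checks
it against minimap2 when that binary is present.

This matcher is **not** a general-purpose aligner: sensitivity at high
divergence (>5%) or across large structural rearrangements is out of scope.

## Reference-guided scaffolding

Contigs are split at N runs (any run length by default; fragments record
their parent and offset), fragments shorter than 50 kb are dropped (flag),
and alignments are filtered by block length ≥ 5 kb, identity ≥ 0.80 and
mapq ≥ 30. The quality thresholds are exposed as flags; the defaults are
chosen so that unique placements at ~1% reference divergence pass
comfortably while repeat-induced multi-mappings (mapq 0) are excluded.

Each fragment goes to the chromosome with the largest summed aligned query
length; ties break toward the chromosome holding the single longest block,
then the lexicographically smallest id — determinism is a design goal, and
no tie is ever resolved by hash or insertion order. Orientation is the
strand with the larger aligned length on the winning chromosome; a strand
vote within 5% of 50/50 is flagged ambiguous. The ordering anchor is the
aligned-length-weighted median of target starts, which is robust to a
minority of misplaced blocks. Fragments are concatenated in anchor order
with exactly 100 N between neighbours (equal anchors order by fragment id).

Telomere-aware refinement: after ordering, any placed fragment whose
telomeric end (≥ 20 preset-monomer copies in its terminal 10 kb) faces the
chromosome interior is flagged in the log; if that fragment's strand vote
was also ambiguous, the telomere-outward orientation is used instead. The
flag-first behaviour is deliberately conservative: a confident alignment
vote is never overridden by telomere content alone.

The headline mapping rate is 100 × genome_size / contig_total rounded to
one decimal. Because spacers inflate genome size, the spacer-free placed
percentage is always reported alongside. Gap counts are reported for any N
run by default; `min_run` is exposed since the spacer length (100) and
biological gap lengths need not coincide.

## Gap filling

Anchors are the `flank_len` = 5 kb of clean (N-free) sequence immediately
adjacent to each gap; gaps without such flanks are reported as
`flank_too_short`, never silently dropped. Candidate fills require both
anchors on the same read and strand, each anchor aligned at ≥ 0.85 identity
over ≥ 90% of its length, left before right in chromosome-forward read
coordinates, and an insert no longer than `max_fill` = 1 Mb (an insert of
length zero is allowed and closes the gap to nothing). Seed chains only
locate the hits; the exact cut points come from a full-anchor infix (edlib
HW) alignment on the oriented read, which makes fills byte-exact for
error-free reads regardless of seed sampling. Among candidates, the
selection maximizes the summed matched bases of the two anchor alignments
(ties: longer read, then read id). The filled sequence is the raw read
subsequence — no polishing — consistent with the conservative contract that
deleting the inserted spans must reproduce the input byte-for-byte, which
the test suite asserts on every run. One documented divergence: no minimum
or expected distance between the anchor hits is enforced beyond `max_fill`,
i.e. the insert length is not required to resemble the gap's N-run length
(the N run is a placeholder, not a size estimate).

## Telomere identification

Monomers are compared as canonical forms: the minimal string over the 2k
rotations of the k-mer and its reverse complement, computed arithmetically
on 2-bit codes for every position of a window at once. Preset mode counts
non-overlapping canonical-class occurrences of the clade monomer in each
terminal window (default 150 kb); an end is present at ≥ `min_copies`
(default 100) copies. Only *tandem-supported* positions count — a match
must have another class match exactly one period away — because a 7-mer
class otherwise collects roughly one chance hit per kilobase of background,
enough to fake a telomere on a bare end.

De novo mode scans periods 4–15. A class is a candidate only if its
tandem-supported matches cover at least half of some 1 kb sub-window (the
density guard; without it, pure enrichment reports scattered background
classes on telomere-less ends). Among candidates the winner maximizes the
supported match count, then union base coverage, then the smaller period.
The count criterion matters: a near-period rotation class (e.g. a period-5
class on a period-6 array) can tile an array using a fraction of its
offsets and tie on coverage, but only the true period matches at every
offset; the smaller-period preference then only resolves genuine
period-doubling ties. Mutated positions are counted solely on exact
canonical match — degraded arrays are handled by the copy threshold, not by
fuzzy matching — which keeps the counting exactly testable; with the
default 2% planted divergence, a 7 bp monomer copy survives with
probability 0.98⁷ ≈ 0.87, so 200 planted copies yield ≈ 174 counted ones,
comfortably above the threshold of 100.

The terminal window size and the copy threshold are not biological
constants; both are exposed flags, and the defaults (150 kb, 100 copies)
are documented choices suitable for plant-sized chromosome ends.

## Centromere prediction

**Array discovery.** For each period p in 50–300, positions where the base
equals the base p ahead form a self-match profile; maximal stretches where
every p-wide window has density ≥ 0.7 become arrays. Boundaries are then
trimmed to the first/last run of `min(16, p/4)` consecutive self-matches,
because single chance matches (25% background rate) cannot define an edge
and density windows straddling a flank otherwise overshoot by up to
0.3 p per side. Each detection is collapsed to its fundamental period (the
smallest divisor that still self-matches at ≥ 0.7 within the span), which
removes period-doubled duplicates and reduces homopolymers to period 1;
consensus is the column-majority of the span folded at the period (ties to
the alphabetically first base). Arrays whose consensus has < 3 distinct
bases or circular dinucleotide entropy < 1 bit are flagged low-complexity
and excluded from clustering by default. A brute-force exhaustive
periodicity scan serves as the oracle for this detector on short sequences
in the test suite.

**Selection and clustering.** Arrays in the centromeric window (period
100–200 bp — bracketing the well-characterized ~178 bp and ~155–165 bp
plant satellites — with ≥ 10 copies; both configurable, since monomer
periods vary across species) are clustered greedily, heaviest
(copy_number × period) first; a consensus joins the first cluster whose
representative matches at ≥ 0.8 identity under the best circular rotation
on either strand (computed by infix-aligning the shorter monomer into the
doubled longer one and charging the length difference as edits). Clustering
is per chromosome, keeping the per-chromosome work units independent (they
parallelize and the representatives are matched back to their own
chromosome); the genome-wide monomer catalogue is the union.

**Matching, merging, scoring.** Each representative (both strands) is
infix-aligned within sliding windows of 3× its period stepped by one
period, so every occurrence lies wholly inside some window; hits at ≥ 0.75
identity over ≥ 80% of the period are kept and merged per monomer.
Candidates are single-linkage merges of blocks (any monomer) within 50 kb,
dropped below 10 kb span; `tandem_bp` is the base-level union of member
blocks, so bases matched by several monomers count once. The score is
`tandem_bp + λ · te_bp` with λ = 1 by default — the simplest monotone
combination of match length and retrotransposon content; λ = 0 recovers
length-only ranking, and adding retrotransposon bases can never lower a
score. Retrotransposon bases are those of TE features whose class contains
LTR/LINE/SINE/retrotransposon (case-insensitive, configurable). Ranking is
per chromosome, descending score, ties to larger `tandem_bp` then leftmost
span; the top 5 per chromosome are reported, and chromosomes with no
candidate are reported as empty rather than omitted. Candidates may span
assembly gaps; their N content is visible in the underlying blocks.

## Synthetic studies

The generator plants, per chromosome: telomere arrays (default TTTAGGG
× 200 per end, ~1.4 kb), one centromeric satellite array (default 178 bp
× 100 ≈ 17.8 kb at the chromosome midpoint), short-period decoy tandem
arrays, and TE copies drawn from three family consensus sequences (70%
retrotransposon-class), all mutated at a 2% per-base substitution rate, in
uniform background sequence at 36% GC. The default study is 3 chromosomes
× 1 Mb. Contigs are jittered even partitions (minimum fragment 60 kb,
above the scaffolder's 50 kb cut), half reverse-complemented, shuffled.
The draft genome removes two 2–6 kb spans per chromosome (avoiding planted
arrays, so fills are judged on unique sequence) and replaces each with a
100 N run, recording the removed sequence as the true fill. Ultra-long
reads (60–120 kb) are sampled from the ungapped genome with two reads
guaranteed to span each gap with ≥ 7 kb margins; read errors are
substitutions only by default so exact-fill checks stay byte-testable. The
reference is the genome diverged at 1% SNPs and 5 × 10⁻⁴ small indels
(≤ 10 bp). The 20-replicate centromere-recovery study uses single 400 kb
chromosomes with periods 150–180 bp and 80 copies (12–14.4 kb arrays —
scaled down from megabase real arrays but kept above the candidate minimum
span of 10 kb). All sizes are scaled-down choices that keep the full
pipeline runnable in seconds while preserving the ratios that matter
(fragment length ≫ filter cutoff, array length ≫ period, read length ≫
gap + flanks).

Every stage draws from its own generator stream keyed by (seed, stage,
chromosome), so adding a stage never perturbs earlier stages' draws, and
everything — sequences, truth table, outputs — is deterministic from the
spec and seed, including across thread counts (parallel work units are
collected in input order).

**What the synthetic studies do not show.** Background sequence is uniform
random: there are no segmental duplications, no nested/fragmented TEs, no
higher-order repeat structure in the satellite arrays, no GC or
homopolymer read-error bias, and reference divergence is small and uniform.
Passing the planted-truth studies therefore demonstrates the correctness of
the algorithms and their bookkeeping under the stated conditions, not
performance on hard real genomes — in particular, the scaffolder presumes
a collinear, closely related reference, and the centromere miner is known
to favour any sufficiently large tandem-repeat-rich region, centromeric or
not, which is why candidates are reported ranked rather than as a single
call.

## Limitations

- No Hi-C scaffolding, polishing or haplotype phasing; input contigs are
  assumed phased.
- Gap filling uses a single spanning read; reads that only jointly span a
  gap are not assembled, and no consensus/polishing is applied to inserts.
- Telomere calling does not scan for interstitial telomeric repeats.
- Centromere prediction does not integrate CENH3/ChIP evidence and does not
  decompose higher-order repeat structure.
- FASTQ qualities are discarded on read; BAM/SAM and compressed inputs are
  unsupported.
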
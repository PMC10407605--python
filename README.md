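# t2tkit

A toolkit for telomere-to-telomere (T2T) genome assembly and
characterization, for genome projects that have phased contigs and long
reads but no chromosome-scale scaffolding yet. It covers the four steps that
usually remain after contig assembly:

- **`map`** — reference-guided scaffolding: split contigs at N gaps, drop
  short fragments, align the rest to a closely related reference genome,
  assign each fragment to its best-matching chromosome, order and orient the
  fragments by reference coordinate, and join them with 100 N spacers into
  pseudo-chromosomes (FASTA + AGP v2.1 + gap BED).
- **`fill`** — conservative gap closing: the flanks of every N gap are
  extracted as anchors and aligned to ultra-long reads; when both anchors of
  a gap hit the same read, in the same orientation and in proper order, the
  read sequence between the hits fills the gap. Of several spanning reads,
  the one with the highest combined anchor homology (summed matched bases,
  each anchor also required to align at ≥ 0.85 identity over ≥ 90% of its
  length) is chosen. No base outside a gap is ever modified.
- **`telo`** — telomere identification: telomeric monomers are compared in
  canonical form — the lexicographically minimal string over all rotations
  of the k-mer and of its reverse complement — so phase and strand do not
  matter. Presets exist for the common plant (TTTAGGG) and animal (TTAGGG)
  monomers; `--clade denovo` instead finds the most enriched tandem repeat
  (periods 4–15) at each chromosome end. An end is called present when at
  least `--min-copies` tandem monomer copies sit in its terminal window.
- **`centro`** — de novo centromere candidate prediction: tandem arrays are
  discovered from per-period self-match density profiles, filtered to the
  centromeric period/copy window (default 100–200 bp, ≥ 10 copies),
  clustered rotation- and strand-aware, and the cluster representatives are
  matched back along each chromosome. Continuous match regions become
  candidates scored as `tandem_bp + λ · te_bp`, where `tandem_bp` is the
  base-level union of monomer matches in the span and `te_bp` the
  retrotransposon bases from an optional TE annotation (GFF3).

A fifth subcommand, **`synth`**, generates seeded synthetic genomes with
planted telomere arrays, centromeric satellite arrays, transposable
elements, fragmented contigs, a gapped draft, spanning ultra-long reads, a
diverged reference, and a machine-readable truth table — so every stage of
the pipeline can be verified against known ground truth without downloading
any real data.

All alignment-consuming stages accept a pluggable backend: the default is a
built-in seed-and-extend matcher (k-mer index, diagonal chaining, edlib
refinement) that needs no external binaries; `--aligner minimap2` substitutes
an external long-read aligner through the same PAF contract.

## Worked example

Generate a synthetic study (3 chromosomes × 1 Mb, telomeres at both ends,
one satellite array per chromosome) and run the whole pipeline on it:

```bash
t2tkit synth --seed 42 -o fx/
t2tkit map   -c fx/contigs.fa -r fx/reference.fa -o asm
t2tkit fill  -g asm.fasta -u fx/reads.fa -o filled
t2tkit telo  -g filled.fasta -o telo
t2tkit centro -g filled.fasta --te fx/te.gff3 -o cen
```

`asm.stats.tsv` then reports (among other fields):

```
contig_total_bp	3000000
genome_size_bp	3000900
chromosomes	3
mapping_rate_pct	100.0
gap_count	9
```

The headline mapping rate is 100 × genome_size / contig_total to one
decimal; it can exceed 100 because the inserted N spacers count toward
genome size, so the spacer-free `placed_pct` is reported alongside. The nine
gaps are the 100 N spacers between the 12 placed contigs. `telo.summary.tsv`
prints the per-genome telomere tally (`total = 2·pairs + singletons`):

```
pairs	3
singletons	0
total	6
```

and `cen.candidates.tsv` lists ranked candidate spans per chromosome, e.g.

```
chrom	start	end	rank	score	tandem_bp	te_bp	main_monomers
chr1	491042	508829	1	11912	11912	0	chr1.mon0001
```

— here the rank-1 span coincides with the planted 178 bp × 100 satellite
array at the chromosome midpoint (reciprocal overlap > 0.99).

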
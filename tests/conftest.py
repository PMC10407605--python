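"""Shared fixtures: small planted-truth genomes generated at test time."""

import pytest

from t2tkit.align import BuiltinAligner
from t2tkit.synth import (
    GenomeSpec,
    diverge_reference,
    fragment_to_contigs,
    make_gapped_draft,
    make_truth_genome,
    simulate_ultralong_reads,
)


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic study: 3 chromosomes x 1 Mb, seed 42.

    Telomeres (TTTAGGG x200) at both ends, one 178 bp x100 satellite array
    per chromosome, TEs, decoy short-period arrays, 2% planted-array
    divergence; plus contigs, a gapped draft, error-free spanning reads and
    a 1% SNP diverged reference.
    """
    spec = GenomeSpec(seed=42)
    genome, te_ann, truth = make_truth_genome(spec)
    contigs = fragment_to_contigs(genome, truth, seed=spec.seed)
    draft = make_gapped_draft(genome, truth, seed=spec.seed)
    reads = simulate_ultralong_reads(genome, truth, seed=spec.seed)
    reference = diverge_reference(genome, seed=spec.seed)
    return {
        "spec": spec, "genome": genome, "te": te_ann, "truth": truth,
        "contigs": contigs, "draft": draft, "reads": reads,
        "reference": reference,
    }


@pytest.fixture(scope="session")
def small_fixture():
    """A faster 2-chromosome x 300 kb fixture for unit-level pipeline tests."""
    spec = GenomeSpec(
        chrom_lengths=(300_000, 300_000),
        telomere_copies=150,
        centromere_copies=60,
        te_count=6,
        seed=7,
    )
    genome, te_ann, truth = make_truth_genome(spec)
    contigs = fragment_to_contigs(genome, truth, n_breaks=2, seed=spec.seed,
                                  min_frag=40_000)
    draft = make_gapped_draft(genome, truth, n_gaps_per_chrom=1,
                              seed=spec.seed, margin=40_000)
    reads = simulate_ultralong_reads(genome, truth, n_background=10,
                                     seed=spec.seed)
    reference = diverge_reference(genome, seed=spec.seed)
    return {
        "spec": spec, "genome": genome, "te": te_ann, "truth": truth,
        "contigs": contigs, "draft": draft, "reads": reads,
        "reference": reference,
    }


@pytest.fixture()
def aligner():
    return BuiltinAligner()
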
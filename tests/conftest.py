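"""Shared fixtures: synthetic cohorts and hand-built toy genes.

Everything is generated programmatically at test time from fixed seeds, so
the suite needs no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from splicerescue.pipeline import run_screen
from splicerescue.rescue_classifier import read_domain_table
from splicerescue.synthetic_data import (
    GeneBuilder,
    SimulationConfig,
    _random_seq,
    assemble_genome,
    generate_cohort,
    tsc2_like_fixture,
)
from splicerescue.transcript_io import read_genome, read_transcripts, read_variants


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """Default-mix 50-gene cohort, seed 1 (the end-to-end study condition)."""
    outdir = tmp_path_factory.mktemp("cohort50")
    return generate_cohort(SimulationConfig(n_genes=50, seed=1), str(outdir))


@pytest.fixture(scope="session")
def cohort_objects(cohort):
    genome = read_genome(cohort.genome_fa)
    transcripts = read_transcripts(cohort.gtf, genome)
    variants = read_variants(cohort.vcf, genome=genome)
    domains = read_domain_table(cohort.domains_tsv)
    return genome, transcripts, variants, domains


@pytest.fixture(scope="session")
def screened(cohort, cohort_objects):
    genome, transcripts, variants, domains = cohort_objects
    return run_screen(genome, transcripts, variants, domains=domains)


@pytest.fixture(scope="session")
def tsc2(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("tsc2like")
    return tsc2_like_fixture(str(outdir))


def make_toy_gene(
    cds_codons,
    exon_lens,
    strand="+",
    utr5=0,
    utr3=6,
    intron_len=90,
    seed=7,
):
    """Assemble a single hand-specified gene into (genome, model, builder).

    ``cds_codons`` is a list of codon strings (must start ATG, end with a
    stop); ``exon_lens`` are spliced exon lengths summing to
    utr5 + 3*len(cds_codons) + utr3.
    """
    rng = np.random.default_rng(seed)
    cds = list("".join(cds_codons))
    assert sum(exon_lens) == utr5 + len(cds) + utr3, "exon lengths do not tile the transcript"
    b = GeneBuilder(
        gene_id="toy_gene",
        transcript_id="toy_tx",
        strand=strand,
        exon_lens=list(exon_lens),
        intron_lens=[intron_len] * (len(exon_lens) - 1),
        utr5=utr5,
        utr3=utr3,
        cds=cds,
        utr5_seq=_random_seq(rng, utr5),
        utr3_seq=_random_seq(rng, utr3),
        intron_seqs=[
            "GT" + _random_seq(rng, intron_len - 4) + "AG"
            for _ in range(len(exon_lens) - 1)
        ],
    )
    config = SimulationConfig(n_genes=1, seed=seed)
    genome, assembled = assemble_genome([b], config, rng)
    return genome, assembled[0].model, b


def sense_codons(rng, n):
    from splicerescue.synthetic_data import SENSE_CODONS

    return [str(c) for c in rng.choice(SENSE_CODONS, size=n)]
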
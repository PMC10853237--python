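"""Stop-gain calling: genetic-code handling, strand, exon junctions, and
agreement with the splice-and-translate oracle."""

import numpy as np
import pytest

from splicerescue import oracle
from splicerescue.consequence import (
    apply_prefilters,
    call_stop_gain,
    classify_stop_triplet,
)
from splicerescue.transcript_io import SnvVariant, map_coordinates

from conftest import make_toy_gene, sense_codons


def _variant_at_cds(model, builder, cds_pos, alt_tx_base, genome):
    """Build an SNV editing the given CDS position to ``alt_tx_base``
    (transcript orientation)."""
    from splicerescue.transcript_io import complement

    cmap = map_coordinates(model)
    gpos = cmap.cds_to_genomic(cds_pos)
    ref = genome[model.chrom][gpos - 1]
    alt = alt_tx_base if model.strand == "+" else complement(alt_tx_base)
    return SnvVariant(chrom=model.chrom, pos=gpos, ref=ref, alt=alt)


class TestCallStopGain:
    def test_cga_to_tga_plus_strand(self):
        rng = np.random.default_rng(0)
        codons = ["ATG"] + sense_codons(rng, 3) + ["CGA"] + sense_codons(rng, 4) + ["TAA"]
        genome, model, b = make_toy_gene(codons, [15, 21])
        v = _variant_at_cds(model, b, 13, "T", genome)  # codon 5, position 1
        call = call_stop_gain(v, model, genome)
        assert call is not None
        assert (call.codon_number, call.ref_codon, call.stop_triplet) == (5, "CGA", "TGA")

    def test_tgg_to_tag_minus_strand(self):
        """Trp codon TGG, transcript-space G>A at codon position 2 (a
        genomic C>T on the reference strand) gives TAG."""
        rng = np.random.default_rng(1)
        codons = ["ATG"] + sense_codons(rng, 3) + ["TGG"] + sense_codons(rng, 4) + ["TGA"]
        genome, model, b = make_toy_gene(codons, [15, 21], strand="-")
        v = _variant_at_cds(model, b, 14, "A", genome)  # codon 5, position 2
        assert v.ref == "C" and v.alt == "T"  # reference-strand bases
        call = call_stop_gain(v, model, genome)
        assert call is not None
        assert (call.codon_number, call.ref_codon, call.stop_triplet) == (5, "TGG", "TAG")

    def test_codon_spanning_exon_junction(self):
        """A codon split across exons (bases 1-2 in exon 2, base 3 in exon
        3) still yields a valid, flagged call."""
        rng = np.random.default_rng(2)
        # 30-nt CDS over exons of 10/10/10+utr: codon 4 covers cds 10-12,
        # exon1 holds cds 1..10, so codon 4 spans the exon1/exon2 junction;
        # pick exon lengths so a codon spans exons 2 and 3 instead
        codons = ["ATG"] + sense_codons(rng, 8) + ["TAA"]
        # exons (spliced): 7 / 10 / 13+6; cds 17 = exon2 last base
        genome, model, b = make_toy_gene(codons, [7, 10, 19], utr3=6)
        # codon 6 covers cds 16..18: bases 16,17 in exon 2, base 18 in exon 3
        b.cds[15:18] = list("CAA")
        genome, model, b = make_toy_gene(
            ["".join(b.cds[i : i + 3]) for i in range(0, 30, 3)], [7, 10, 19], utr3=6
        )
        v = _variant_at_cds(model, b, 16, "T", genome)  # CAA -> TAA
        call = call_stop_gain(v, model, genome)
        assert call is not None
        assert call.stop_triplet == "TAA"
        assert call.codon_spans_junction
        assert call.exon_index == 2  # the variant base's exon
        # independent check: the oracle sees the same premature stop
        assert oracle.premature_stop(genome, model, v) == (6, "TAA")

    def test_non_stop_change_returns_none(self):
        rng = np.random.default_rng(3)
        codons = ["ATG"] + sense_codons(rng, 8) + ["TAA"]
        genome, model, b = make_toy_gene(codons, [18, 18])
        # find a substitution that is NOT a stop-gain
        cmap = map_coordinates(model)
        for cds_pos in range(4, 20):
            for alt in "ACGT":
                codon_i = (cds_pos - 1) // 3
                off = (cds_pos - 1) % 3
                ref_codon = codons[codon_i]
                if alt == ref_codon[off]:
                    continue
                new = ref_codon[:off] + alt + ref_codon[off + 1 :]
                if new not in ("TAA", "TAG", "TGA"):
                    v = _variant_at_cds(model, b, cds_pos, alt, genome)
                    assert call_stop_gain(v, model, genome) is None
                    return
        pytest.fail("no non-stop substitution found")

    def test_variant_outside_cds_returns_none(self):
        rng = np.random.default_rng(4)
        codons = ["ATG"] + sense_codons(rng, 8) + ["TAA"]
        genome, model, b = make_toy_gene(codons, [18, 18])
        intronic = SnvVariant(
            chrom=model.chrom,
            pos=model.exons[0].end + 5,
            ref=genome[model.chrom][model.exons[0].end + 4],
            alt="A" if genome[model.chrom][model.exons[0].end + 4] != "A" else "C",
        )
        assert call_stop_gain(intronic, model, genome) is None

    def test_oracle_equivalence_on_cohort(self, cohort, cohort_objects):
        """Every planted variant's call agrees with the brute-force
        splice-and-translate oracle."""
        genome, transcripts, variants, _ = cohort_objects
        by_tid = {t.transcript_id: t for t in transcripts}
        truth = {t.variant_id: t for t in cohort.truth}
        for v in variants:
            rec = truth[v.id]
            t = by_tid[rec.transcript_id]
            call = call_stop_gain(v, t, genome)
            expected = oracle.premature_stop(genome, t, v)
            assert call is not None and expected is not None
            assert (call.codon_number, call.stop_triplet) == expected
            assert call.codon_number == rec.codon_number

    def test_oracle_equivalence_random_snvs(self, cohort_objects):
        """Random (mostly non-nonsense) SNVs: the caller and the oracle
        agree on whether a premature stop is gained, and where."""
        genome, transcripts, _, _ = cohort_objects
        rng = np.random.default_rng(99)
        n_checked = 0
        for t in transcripts[:12]:
            cmap = map_coordinates(t)
            for _ in range(30):
                cds_pos = int(rng.integers(1, cmap.cds_length + 1))
                gpos = cmap.cds_to_genomic(cds_pos)
                ref = genome[t.chrom][gpos - 1]
                alt = str(rng.choice([x for x in "ACGT" if x != ref]))
                v = SnvVariant(chrom=t.chrom, pos=gpos, ref=ref, alt=alt)
                call = call_stop_gain(v, t, genome)
                expected = oracle.premature_stop(genome, t, v)
                if call is None:
                    assert expected is None
                else:
                    assert expected == (call.codon_number, call.stop_triplet)
                n_checked += 1
        assert n_checked >= 300


class TestPrefilters:
    def test_last_exon_calls_removed(self, cohort_objects):
        genome, transcripts, variants, _ = cohort_objects
        t = transcripts[0]
        rng = np.random.default_rng(5)
        cmap = map_coordinates(t)
        # craft a stop-gain in the last exon of a cohort transcript
        last = t.exons[-1]
        call = None
        for cds_pos in range(cmap.cds_length - 3, 3, -1):
            gpos = cmap.cds_to_genomic(cds_pos)
            if not last.contains(gpos):
                break
            ref = genome[t.chrom][gpos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                v = SnvVariant(chrom=t.chrom, pos=gpos, ref=ref, alt=alt)
                call = call_stop_gain(v, t, genome)
                if call is not None:
                    break
            if call is not None:
                break
        assert call is not None and call.is_last_exon
        kept, counts = apply_prefilters([call])
        assert kept == [] and counts["last_exon"] == 1

    def test_single_exon_transcript_always_removed(self):
        """In a single-exon transcript, exon 1 is the last exon."""
        rng = np.random.default_rng(6)
        codons = ["ATG"] + sense_codons(rng, 8) + ["CGA"] + sense_codons(rng, 10) + ["TAA"]
        genome, model, b = make_toy_gene(codons, [63 + 6], utr3=6)
        v = _variant_at_cds(model, b, 28, "T", genome)  # CGA codon 10 -> TGA
        call = call_stop_gain(v, model, genome)
        assert call is not None and call.is_last_exon
        kept, counts = apply_prefilters([call])
        assert kept == [] and counts["last_exon"] == 1

    def test_internal_exon_calls_retained(self, cohort_objects, cohort):
        genome, transcripts, variants, _ = cohort_objects
        by_tid = {t.transcript_id: t for t in transcripts}
        truth = {t.variant_id: t for t in cohort.truth}
        calls = [
            call_stop_gain(v, by_tid[truth[v.id].transcript_id], genome)
            for v in variants[:30]
        ]
        kept, counts = apply_prefilters(calls)
        # the generator never plants in last exons
        assert kept == calls and counts["last_exon"] == 0


@pytest.mark.parametrize(
    "triplet,label",
    [("TAA", "TAA_or_TGA"), ("TGA", "TAA_or_TGA"), ("TAG", "TAG")],
)
def test_classify_stop_triplet(triplet, label, cohort_objects, cohort):
    genome, transcripts, variants, _ = cohort_objects
    by_tid = {t.transcript_id: t for t in transcripts}
    truth = {t.variant_id: t for t in cohort.truth}
    for v in variants:
        rec = truth[v.id]
        if rec.stop_triplet == triplet:
            call = call_stop_gain(v, by_tid[rec.transcript_id], genome)
            assert classify_stop_triplet(call) == label
            return
    pytest.skip(f"no {triplet} plant in this cohort seed")
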
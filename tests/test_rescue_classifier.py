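"""Frame arithmetic, the decision tree, domain overlap, and HGVS-style
protein-consequence rendering."""

import re

import numpy as np
import pytest

from splicerescue import oracle
from splicerescue.consequence import call_stop_gain
from splicerescue.donor_gain import (
    ScreenParams,
    SpliceGainAnnotation,
    offset_to_dp,
    resolve_junction_genomic,
)
from splicerescue.rescue_classifier import (
    CANDIDATE_CATEGORIES,
    DegenerateDeletionError,
    DomainAnnotation,
    FrameComputation,
    RescueCategory,
    TruncationError,
    classify,
    compute_deletion,
    deleted_protein_range,
    overlap_domains,
    render_protein_consequence,
)
from splicerescue.transcript_io import SnvVariant, map_coordinates

from conftest import make_toy_gene, sense_codons


def _ann(ds, dp):
    return SpliceGainAnnotation(
        allele="T", symbol="g", ds_ag=None, ds_al=None, ds_dg=ds, ds_dl=None,
        dp_ag=None, dp_al=None, dp_dg=dp, dp_dl=None, strand_corrected=True,
    )


def _cohort_candidate_context(cohort, cohort_objects):
    genome, transcripts, variants, domains = cohort_objects
    by_tid = {t.transcript_id: t for t in transcripts}
    vs = {v.id: v for v in variants}
    for rec in cohort.truth:
        if rec.category in CANDIDATE_CATEGORIES:
            yield rec, vs[rec.variant_id], by_tid[rec.transcript_id], genome


class TestComputeDeletion:
    def test_planted_deletions_recovered(self, cohort, cohort_objects):
        for rec, v, t, genome in _cohort_candidate_context(cohort, cohort_objects):
            call = call_stop_gain(v, t, genome)
            frame = compute_deletion(call, _ann(rec.ds_dg, rec.dp_dg), t)
            assert frame.deleted_nt == rec.deleted_nt
            assert frame.in_frame == (rec.deleted_nt % 3 == 0)
            # the frame rule agrees with explicit sequence excision
            assert frame.in_frame == oracle.excision_in_frame(
                genome, t, v, frame.dg_last_exonic_genomic_pos
            )

    def test_junction_at_exon_end_is_degenerate(self, cohort, cohort_objects):
        rec, v, t, genome = next(_cohort_candidate_context(cohort, cohort_objects))
        call = call_stop_gain(v, t, genome)
        exon = t.exon_containing(v.pos)
        end = exon.end if t.strand == "+" else exon.start
        # dp that puts the junction exactly at the natural exon end
        offset = (end - v.pos) if t.strand == "+" else (v.pos - end)
        dp = offset_to_dp(offset)
        with pytest.raises(DegenerateDeletionError, match="exon end"):
            compute_deletion(call, _ann(0.9, dp), t)

    def test_junction_outside_exon_is_degenerate(self, cohort, cohort_objects):
        rec, v, t, genome = next(_cohort_candidate_context(cohort, cohort_objects))
        call = call_stop_gain(v, t, genome)
        with pytest.raises(DegenerateDeletionError):
            compute_deletion(call, _ann(0.9, -5000), t)

    def test_mod3_rule_simple_numbers(self, cohort, cohort_objects):
        """Junction 6 nt before the exon end is in frame, 7 nt is not."""
        for rec, v, t, genome in _cohort_candidate_context(cohort, cohort_objects):
            call = call_stop_gain(v, t, genome)
            exon = t.exon_containing(v.pos)
            end = exon.end if t.strand == "+" else exon.start
            for d, in_frame in ((6, True), (7, False)):
                offset = (end - d - v.pos) if t.strand == "+" else (v.pos - end - d)
                dp = offset_to_dp(offset)
                junction = resolve_junction_genomic(v, t.strand, dp)
                if t.exon_containing(junction) is None or not t.exon_containing(
                    junction
                ).contains(v.pos):
                    continue
                try:
                    frame = compute_deletion(call, _ann(0.9, dp), t)
                except DegenerateDeletionError:
                    continue
                assert frame.deleted_nt == d
                assert frame.in_frame is in_frame
            return


class TestDecisionTree:
    def test_forced_branches(self, cohort, cohort_objects):
        """The same call walks to different leaves as the annotation's
        score/position change."""
        genome, transcripts, variants, domains = cohort_objects
        rec, v, t, _ = next(_cohort_candidate_context(cohort, cohort_objects))
        call = call_stop_gain(v, t, genome)
        params = ScreenParams()
        below = classify(call, _ann(0.1, -2), params, domains, t, 0.2, g=genome)
        assert below.category == RescueCategory.NOT_CANDIDATE
        downstream = classify(call, _ann(0.9, 5), params, domains, t, 0.2, g=genome)
        assert downstream.category == RescueCategory.NOT_CANDIDATE
        planted = classify(call, _ann(rec.ds_dg, rec.dp_dg), params, domains, t, 0.2, g=genome)
        assert planted.category == rec.category

    def test_partition_sums_to_input(self, screened):
        """Every variant receives exactly one category at each threshold."""
        counts = screened.category_counts()
        for thr, by_cat in counts.items():
            assert sum(by_cat.values()) == screened.n_variants

    def test_frame_present_iff_candidate(self, screened):
        for r in screened.rows:
            if r.category in CANDIDATE_CATEGORIES:
                assert r.frame is not None
            elif r.category in (
                RescueCategory.NOT_NONSENSE,
                RescueCategory.NOT_CANDIDATE,
                RescueCategory.LAST_EXON_EXCLUDED,
            ):
                assert r.frame is None

    def test_domain_branch_matches_truth(self, cohort, screened):
        truth = {t.variant_id: t for t in cohort.truth}
        seen = set()
        for r in screened.rows_at(0.2):
            rec = truth[r.variant_id]
            if rec.domain_overlap is None:
                continue
            seen.add(rec.domain_overlap)
            assert bool(r.domain_hits) == rec.domain_overlap
        assert seen == {True, False}


class TestDeletedProteinRange:
    def test_phase0_exact_codons(self):
        f = FrameComputation(
            dg_last_exonic_genomic_pos=0, exon_end_genomic_pos=0,
            deleted_nt=6, in_frame=True, cds_fraction=0.01, junction_cds_pos=30,
        )
        assert deleted_protein_range(f, None, None) == (11, 12)

    def test_midcodon_includes_split_codons(self):
        f = FrameComputation(
            dg_last_exonic_genomic_pos=0, exon_end_genomic_pos=0,
            deleted_nt=6, in_frame=True, cds_fraction=0.01, junction_cds_pos=31,
        )
        assert deleted_protein_range(f, None, None) == (11, 13)

    def test_out_of_frame_rejected(self):
        f = FrameComputation(
            dg_last_exonic_genomic_pos=0, exon_end_genomic_pos=0,
            deleted_nt=7, in_frame=False, cds_fraction=0.01, junction_cds_pos=30,
        )
        with pytest.raises(ValueError):
            deleted_protein_range(f, None, None)


class TestOverlapDomains:
    D = DomainAnnotation(transcript_id="t", domain_name="d", start_residue=15, end_residue=30)

    def test_hit(self):
        assert overlap_domains((10, 20), [self.D]) == [self.D]

    def test_adjacency_is_not_overlap(self):
        d = DomainAnnotation(transcript_id="t", domain_name="d", start_residue=21, end_residue=30)
        assert overlap_domains((10, 20), [d]) == []

    def test_empty_table(self):
        assert overlap_domains((10, 20), []) == []


class TestRenderProteinConsequence:
    def _phase0_toy(self):
        """Exon 1 ends at CDS 36 (phase 0); deleting its last 6 nt removes
        codons 11-12 exactly."""
        rng = np.random.default_rng(11)
        codons = (
            ["ATG"] + sense_codons(rng, 8)  # 1-9
            + ["TGT", "AAA", "GGA", "CAT"]  # 10 Cys, 11 Lys, 12 Gly, 13 His
            + sense_codons(rng, 6)
            + ["TAA"]
        )
        assert len(codons) == 20
        genome, model, b = make_toy_gene(codons, [36, 30], utr5=0, utr3=6)
        return genome, model

    def test_phase0_pure_deletion(self):
        genome, model = self._phase0_toy()
        cmap = map_coordinates(model)
        gpos = cmap.cds_to_genomic(31)  # codon 11 base 1: AAA -> TAA
        v = SnvVariant(chrom=model.chrom, pos=gpos, ref="A", alt="T")
        call = call_stop_gain(v, model, genome)
        assert call.stop_triplet == "TAA"
        frame = compute_deletion(call, _ann(0.9, -1), model)
        assert (frame.deleted_nt, frame.in_frame) == (6, True)
        assert render_protein_consequence(frame, call, model, genome) == "p.(Lys11_Gly12del)"

    def test_rendering_oracle_on_cohort(self, cohort, cohort_objects, screened):
        """Outside the rendered residue interval the reference and rescue
        proteins are identical (proteins recomputed by sequence surgery)."""
        genome, transcripts, variants, _ = cohort_objects
        by_tid = {t.transcript_id: t for t in transcripts}
        vs = {v.id: v for v in variants}
        checked = 0
        for r in screened.rows_at(0.2):
            if r.protein_consequence is None:
                continue
            rec = next(t for t in cohort.truth if t.variant_id == r.variant_id)
            t = by_tid[rec.transcript_id]
            v = vs[r.variant_id]
            junction = resolve_junction_genomic(v, t.strand, rec.dp_dg)
            ref_prot = oracle.translate(oracle.spliced_cds(genome, t)).rstrip("*")
            alt_prot = oracle.excised_protein(genome, t, v, junction).rstrip("*")
            first, last = (int(x) for x in re.findall(r"(\d+)", r.protein_consequence)[:2]) \
                if "_" in r.protein_consequence else [int(re.search(r"(\d+)", r.protein_consequence).group(1))] * 2
            assert ref_prot[: first - 1] == alt_prot[: first - 1]
            n_tail = len(ref_prot) - last
            assert n_tail >= 0
            if n_tail:
                assert ref_prot[-n_tail:] == alt_prot[-n_tail:]
            checked += 1
        assert checked >= 2

    def test_hybrid_stop_raises_truncation(self):
        """A junction whose hybrid codon is a stop is flagged, not rendered."""
        rng = np.random.default_rng(12)
        codons = (
            ["ATG"] + sense_codons(rng, 9)  # 1-10
            + ["TAC", "CCC", "GAA", "CAT"]  # 11 Tyr .. 14
            + sense_codons(rng, 5)
            + ["TGA"]
        )
        # exon 1 ends at CDS 37 (codon 13 base 1); junction at 31 (phase 1)
        genome, model, b = make_toy_gene(codons, [37, 23], utr5=0, utr3=0)
        cmap = map_coordinates(model)
        gpos = cmap.cds_to_genomic(33)  # codon 11 base 3: TAC -> TAA
        v = SnvVariant(chrom=model.chrom, pos=gpos, ref="C", alt="A")
        call = call_stop_gain(v, model, genome)
        assert call.stop_triplet == "TAA"
        frame = compute_deletion(call, _ann(0.9, -2), model)
        assert (frame.junction_cds_pos, frame.deleted_nt, frame.in_frame) == (31, 6, True)
        # hybrid codon = "T" (codon 11 base 1) + "AA" (codon 13 bases 2-3) = TAA
        with pytest.raises(TruncationError):
            render_protein_consequence(frame, call, model, genome)

    def test_out_of_frame_rejected(self, cohort, cohort_objects):
        rec, v, t, genome = next(_cohort_candidate_context(cohort, cohort_objects))
        call = call_stop_gain(v, t, genome)
        f = FrameComputation(
            dg_last_exonic_genomic_pos=0, exon_end_genomic_pos=0,
            deleted_nt=7, in_frame=False, cds_fraction=0.01, junction_cds_pos=30,
        )
        with pytest.raises(ValueError):
            render_protein_consequence(f, call, t, genome)


class TestWorkedExample:
    def test_tsc2_like_consequence(self, tsc2):
        """The synthetic TSC2-like geometry reproduces the published
        protein consequence and rescue classification."""
        from splicerescue.pipeline import run_screen
        from splicerescue.rescue_classifier import read_domain_table
        from splicerescue.transcript_io import read_genome, read_transcripts, read_variants

        genome = read_genome(tsc2.genome_fa)
        transcripts = read_transcripts(tsc2.gtf, genome)
        variants = read_variants(tsc2.vcf, genome=genome)
        domains = read_domain_table(tsc2.domains_tsv)
        result = run_screen(genome, transcripts, variants, domains=domains)
        (row,) = result.rows_at(0.8)
        assert row.category == RescueCategory.CANDIDATE_IN_FRAME_LT10_NO_DOMAIN
        assert row.protein_consequence == "p.(Glu1360_Ser1498delinsAsp)"
        assert row.frame.in_frame
        assert row.frame.deleted_nt == 414
        assert row.frame.cds_fraction < 0.10
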
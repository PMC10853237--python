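"""End-to-end orchestration of the rescue screen.

Ties the stages together: canonical-transcript restriction, stop-gain
calling, donor-gain annotation (SpliceAI-format INFO or the PWM stand-in),
strand correction, and the decision tree at every configured threshold.
The per-variant output partitions the input: at each threshold every
variant×transcript pair receives exactly one category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .cohort_stats import (
    ClassificationRecord,
    ComparisonResult,
    ScoreBinSummary,
    compare_lp_p,
    compare_star_ratings,
    rate_summary,
    summarize_bins,
    triplet_enrichment,
)
from .consequence import call_stop_gain, classify_stop_triplet
from .donor_gain import ScreenParams, annotation_from_pwm, parse_spliceai_info, strand_correct
from .rescue_classifier import (
    CANDIDATE_CATEGORIES,
    DomainAnnotation,
    RescueCall,
    RescueCategory,
    classify,
)
from .transcript_io import (
    GenomeSequences,
    SnvVariant,
    TranscriptModel,
    map_coordinates,
    select_canonical,
)

log = logging.getLogger(__name__)


class MissingAnnotationError(ValueError):
    """No variant carries a SpliceAI INFO value and the PWM fallback is off."""


@dataclass
class ScreenResult:
    rows: List[RescueCall]
    params: ScreenParams
    n_variants: int
    n_missing_annotation: int
    bins: Optional[ScoreBinSummary] = None

    def rows_at(self, threshold: float) -> List[RescueCall]:
        return [r for r in self.rows if r.threshold == threshold]

    def category_counts(self) -> Dict[float, Dict[str, int]]:
        out: Dict[float, Dict[str, int]] = {}
        for r in self.rows:
            d = out.setdefault(r.threshold, {})
            d[r.category.value] = d.get(r.category.value, 0) + 1
        return out

    def summary(self) -> Dict[str, object]:
        return {
            "n_variants": self.n_variants,
            "n_missing_annotation": self.n_missing_annotation,
            "category_counts": {
                str(t): counts for t, counts in sorted(self.category_counts().items())
            },
            "score_bins": None
            if self.bins is None
            else {
                "per_dataset": self.bins.per_dataset,
                "overall": self.bins.overall,
                "dp_max": self.bins.dp_max,
            },
        }


def _pick_annotation(v: SnvVariant, gene_id: str):
    if v.spliceai is None:
        return None
    annotations = parse_spliceai_info(v.spliceai)
    by_gene = [a for a in annotations if a.allele == v.alt and a.symbol == gene_id]
    by_allele = [a for a in annotations if a.allele == v.alt]
    if by_gene:
        return by_gene[0]
    if by_allele:
        return by_allele[0]
    return None


def run_screen(
    genome: GenomeSequences,
    transcripts: Sequence[TranscriptModel],
    variants: Sequence[SnvVariant],
    params: Optional[ScreenParams] = None,
    domains: Sequence[DomainAnnotation] = (),
    use_pwm: bool = False,
    already_stranded: bool = False,
    dataset_labels: Optional[Dict[str, str]] = None,
) -> ScreenResult:
    """Screen ``variants`` against the canonical transcripts in
    ``transcripts`` at every threshold in ``params.dg_thresholds``."""
    params = params or ScreenParams()
    canonical = select_canonical(transcripts)
    by_chrom: Dict[str, List[TranscriptModel]] = {}
    for t in canonical:
        by_chrom.setdefault(t.chrom, []).append(t)
    cmaps = {t.transcript_id: map_coordinates(t) for t in canonical}
    cds_seqs = {t.transcript_id: t.cds_sequence(genome) for t in canonical}
    domains = list(domains)

    if not use_pwm and variants and all(v.spliceai is None for v in variants):
        raise MissingAnnotationError(
            "no variant carries a SpliceAI INFO annotation; either supply an "
            "annotated VCF or enable the PWM stand-in scorer"
        )

    rows: List[RescueCall] = []
    bin_records: List[Tuple[str, Optional[float], Optional[int]]] = []
    n_missing = 0
    for v in variants:
        hits = []
        for t in by_chrom.get(v.chrom, []):
            lo, hi = t.span
            if not lo <= v.pos <= hi:
                continue
            call = call_stop_gain(
                v, t, genome, cmap=cmaps[t.transcript_id], cds_seq=cds_seqs[t.transcript_id]
            )
            if call is not None:
                hits.append((t, call))
        if not hits:
            for thr in params.dg_thresholds:
                rows.append(
                    RescueCall(
                        call=None,
                        annotation=None,
                        category=RescueCategory.NOT_NONSENSE,
                        threshold=thr,
                        variant_id=v.id,
                    )
                )
            continue
        for t, call in hits:
            if use_pwm:
                annotation = annotation_from_pwm(
                    v, t, genome, dp_convention=params.dp_convention
                )
            else:
                annotation = _pick_annotation(v, t.gene_id)
                if annotation is None:
                    n_missing += 1
                elif already_stranded:
                    annotation = replace(annotation, strand_corrected=True)
                else:
                    annotation = strand_correct(annotation, t.strand)
            if not call.is_last_exon:
                label = (dataset_labels or {}).get(v.id, "cohort")
                bin_records.append(
                    (
                        label,
                        annotation.ds_dg if annotation else None,
                        annotation.dp_dg if annotation else None,
                    )
                )
            for thr in params.dg_thresholds:
                rows.append(
                    replace(
                        classify(
                            call,
                            annotation,
                            params,
                            domains,
                            t,
                            thr,
                            g=genome,
                            cmap=cmaps[t.transcript_id],
                            cds_seq=cds_seqs[t.transcript_id],
                        ),
                        variant_id=v.id,
                    )
                )
    bins = summarize_bins(
        bin_records, dp_max=params.dp_exclusive_max, thresholds=params.dg_thresholds
    )
    return ScreenResult(
        rows=rows,
        params=params,
        n_variants=len(variants),
        n_missing_annotation=n_missing,
        bins=bins,
    )


# ---------------------------------------------------------------------------
# Cohort statistics over a screen result
# ---------------------------------------------------------------------------


def compute_cohort_stats(
    result_rows: Sequence[RescueCall],
    classifications: Sequence[ClassificationRecord],
    threshold: float,
) -> Dict[str, object]:
    """The screen's comparison statistics at one threshold.

    Candidates are compared against the remaining nonsense variants in the
    same genes (genes containing at least one candidate).  Star-rating
    comparisons are restricted to LP/P-classified variants, mirroring how
    review-confidence differences are reported.
    """
    rows = [
        r
        for r in result_rows
        if r.threshold == threshold
        and r.call is not None
        and r.category
        not in (RescueCategory.NOT_NONSENSE, RescueCategory.LAST_EXON_EXCLUDED)
    ]
    if not rows:
        raise ValueError("no eligible stop-gain calls at this threshold")
    by_id = {c.variant_id: c for c in classifications}
    cand_rows = [r for r in rows if r.category in CANDIDATE_CATEGORIES]
    cand_genes = {r.call.gene_id for r in cand_rows}
    comp_rows = [
        r
        for r in rows
        if r.category not in CANDIDATE_CATEGORIES and r.call.gene_id in cand_genes
    ]

    triplets = [classify_stop_triplet(r.call) for r in rows]
    flags = [r.category in CANDIDATE_CATEGORIES for r in rows]
    out: Dict[str, object] = {"threshold": threshold}
    out["triplet_enrichment"] = triplet_enrichment(triplets, flags).to_dict()

    cand_cls = [by_id[r.variant_id] for r in cand_rows if r.variant_id in by_id]
    comp_cls = [by_id[r.variant_id] for r in comp_rows if r.variant_id in by_id]
    out["lp_p_comparison"] = compare_lp_p(cand_cls, comp_cls).to_dict()

    cand_stars = [c.stars for c in cand_cls if c.is_lp_p]
    comp_stars = [c.stars for c in comp_cls if c.is_lp_p]
    out["star_rating_comparison"] = compare_star_ratings(cand_stars, comp_stars).to_dict()

    inframe_lt10 = [
        r
        for r in cand_rows
        if r.category
        in (
            RescueCategory.CANDIDATE_IN_FRAME_LT10_NO_DOMAIN,
            RescueCategory.CANDIDATE_IN_FRAME_LT10_DOMAIN,
        )
    ]
    if cand_rows:
        rs = rate_summary(len(inframe_lt10), len(cand_rows))
        out["inframe_lt10_of_candidates"] = {
            "numerator": len(inframe_lt10),
            "denominator": len(cand_rows),
            "percent": rs.percent,
            "rate": rs.rate_text,
        }
    rs_all = rate_summary(len(inframe_lt10), len(rows))
    out["inframe_lt10_of_all_nonsense"] = {
        "numerator": len(inframe_lt10),
        "denominator": len(rows),
        "percent": rs_all.percent,
        "rate": rs_all.rate_text,
    }
    return out
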
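"""Decision tree for manufactured splice rescue.

Given a stop-gain call and a donor-gain annotation that passed the
candidacy rule, the classifier models the mis-splicing outcome as a
partial-exon deletion: the gained donor's junction replaces the natural
3' end of the variant's exon, the next natural acceptor is used
unchanged, and the exonic segment from the base after the junction
through the exon end is excised from the mature transcript.  The tree
then branches on

1. the reading frame of the excised segment (length mod 3),
2. for in-frame deletions, the fraction of the coding sequence removed
   (strictly below ``inframe_fraction_max`` = rescue-plausible), and
3. whether the deleted residues touch an annotated protein domain,

and renders the predicted protein consequence in HGVS style for the
in-frame cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Tuple

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .consequence import StopGainCall
from .donor_gain import (
    ScreenParams,
    SpliceGainAnnotation,
    is_candidate,
    resolve_junction_genomic,
)
from .transcript_io import (
    CoordinateMap,
    GenomeSequences,
    TranscriptModel,
    map_coordinates,
)

log = logging.getLogger(__name__)


class RescueCategory(str, Enum):
    """Mutually exclusive, exhaustive outcome labels of the screen."""

    NOT_NONSENSE = "NOT_NONSENSE"
    LAST_EXON_EXCLUDED = "LAST_EXON_EXCLUDED"
    NOT_CANDIDATE = "NOT_CANDIDATE"
    DEGENERATE = "DEGENERATE"
    CANDIDATE_OUT_OF_FRAME = "CANDIDATE_OUT_OF_FRAME"
    CANDIDATE_IN_FRAME_GE10 = "CANDIDATE_IN_FRAME_GE10"
    CANDIDATE_IN_FRAME_LT10_NO_DOMAIN = "CANDIDATE_IN_FRAME_LT10_NO_DOMAIN"
    CANDIDATE_IN_FRAME_LT10_DOMAIN = "CANDIDATE_IN_FRAME_LT10_DOMAIN"


CANDIDATE_CATEGORIES = frozenset(
    {
        RescueCategory.CANDIDATE_OUT_OF_FRAME,
        RescueCategory.CANDIDATE_IN_FRAME_GE10,
        RescueCategory.CANDIDATE_IN_FRAME_LT10_NO_DOMAIN,
        RescueCategory.CANDIDATE_IN_FRAME_LT10_DOMAIN,
    }
)


class DegenerateDeletionError(ValueError):
    """The implied junction does not yield a well-formed partial-exon
    deletion (outside the variant's exon, zero-length, or crossing a CDS
    boundary)."""


class TruncationError(ValueError):
    """The hybrid junction codon of a putative rescue is itself a stop."""


@dataclass(frozen=True)
class DomainAnnotation:
    """A protein domain interval, 1-based inclusive residue coordinates."""

    transcript_id: str
    domain_name: str
    start_residue: int
    end_residue: int

    def __post_init__(self) -> None:
        if not 1 <= self.start_residue <= self.end_residue:
            raise ValueError(
                f"invalid domain interval {self.start_residue}..{self.end_residue}"
            )


@dataclass(frozen=True)
class FrameComputation:
    """Geometry of the modelled partial-exon deletion."""

    dg_last_exonic_genomic_pos: int
    exon_end_genomic_pos: int
    deleted_nt: int
    in_frame: bool
    cds_fraction: float
    junction_cds_pos: int  # CDS coordinate of the last retained exonic base


@dataclass(frozen=True)
class RescueCall:
    """One row of the screen output: a variant × transcript × threshold."""

    call: Optional[StopGainCall]
    annotation: Optional[SpliceGainAnnotation]
    category: RescueCategory
    threshold: Optional[float]
    frame: Optional[FrameComputation] = None
    domain_hits: Tuple[DomainAnnotation, ...] = ()
    protein_consequence: Optional[str] = None
    variant_id: Optional[str] = None
    reason: Optional[str] = None

    def to_row(self) -> Dict[str, object]:
        c, a, f = self.call, self.annotation, self.frame
        v = c.variant if c is not None else None
        return {
            "variant_id": self.variant_id or (v.id if v else None),
            "chrom": v.chrom if v else None,
            "pos": v.pos if v else None,
            "ref": v.ref if v else None,
            "alt": v.alt if v else None,
            "transcript_id": c.transcript_id if c else None,
            "gene_id": c.gene_id if c else None,
            "strand": c.strand if c else None,
            "threshold": self.threshold,
            "category": self.category.value,
            "codon_number": c.codon_number if c else None,
            "ref_codon": c.ref_codon if c else None,
            "alt_codon": c.alt_codon if c else None,
            "stop_triplet": c.stop_triplet if c else None,
            "exon_index": c.exon_index if c else None,
            "n_exons": c.n_exons if c else None,
            "cds_len_nt": c.cds_len_nt if c else None,
            "codon_spans_junction": c.codon_spans_junction if c else None,
            "ds_dg": a.ds_dg if a else None,
            "dp_dg": a.dp_dg if a else None,
            "deleted_nt": f.deleted_nt if f else None,
            "in_frame": f.in_frame if f else None,
            "cds_fraction": f.cds_fraction if f else None,
            "domain_hits": ";".join(d.domain_name for d in self.domain_hits) or None,
            "protein_consequence": self.protein_consequence,
        }


# ---------------------------------------------------------------------------
# Frame arithmetic
# ---------------------------------------------------------------------------


def compute_deletion(
    call: StopGainCall,
    a: SpliceGainAnnotation,
    t: TranscriptModel,
    dp_convention: str = "last-exonic",
    cmap: Optional[CoordinateMap] = None,
) -> FrameComputation:
    """Deletion length and frame from the gained donor's delta position.

    The deleted segment runs from the base after the new junction through
    the 3' end of the variant's exon; it is in-frame iff its length is a
    multiple of 3.  Raises :class:`DegenerateDeletionError` when the
    junction falls outside the variant's exon, at/after the natural exon
    end, or the deletion would extend outside the CDS.
    """
    if a.dp_dg is None:
        raise DegenerateDeletionError("no donor-gain delta position")
    v = call.variant
    junction = resolve_junction_genomic(v, t.strand, a.dp_dg, dp_convention)
    exon = t.exon_containing(v.pos)
    if exon is None or not exon.contains(junction):
        raise DegenerateDeletionError(
            f"gained donor at {junction} lies outside the variant's exon "
            f"({exon.start}-{exon.end})" if exon else "variant not exonic"
        )
    if t.strand == "+":
        exon_end = exon.end
        deleted_nt = exon_end - junction
    else:
        exon_end = exon.start
        deleted_nt = junction - exon_end
    if deleted_nt <= 0:
        raise DegenerateDeletionError(
            f"junction at or after the natural exon end (deleted_nt={deleted_nt})"
        )
    if cmap is None:
        cmap = map_coordinates(t)
    junction_cds = cmap.genomic_to_cds(junction)
    exon_end_cds = cmap.genomic_to_cds(exon_end)
    if junction_cds is None or exon_end_cds is None:
        raise DegenerateDeletionError("deletion extends outside the CDS")
    cds_len = call.cds_len_nt
    fraction = deleted_nt / cds_len
    return FrameComputation(
        dg_last_exonic_genomic_pos=junction,
        exon_end_genomic_pos=exon_end,
        deleted_nt=deleted_nt,
        in_frame=deleted_nt % 3 == 0,
        cds_fraction=fraction,
        junction_cds_pos=junction_cds,
    )


def deleted_protein_range(
    f: FrameComputation, call: StopGainCall, t: TranscriptModel
) -> Tuple[int, int]:
    """1-based inclusive residue interval wholly or partly removed by the
    deletion, including split codons at either edge."""
    if not f.in_frame:
        raise ValueError("deleted_protein_range requires an in-frame deletion")
    first_deleted_cds = f.junction_cds_pos + 1
    last_deleted_cds = f.junction_cds_pos + f.deleted_nt
    first_res = (first_deleted_cds - 1) // 3 + 1
    last_res = (last_deleted_cds - 1) // 3 + 1
    return first_res, last_res


def overlap_domains(
    residue_range: Tuple[int, int], domains: List[DomainAnnotation]
) -> List[DomainAnnotation]:
    """Domains sharing at least one residue with the interval (closed
    intervals; adjacency is not overlap)."""
    lo, hi = residue_range
    return [d for d in domains if d.start_residue <= hi and d.end_residue >= lo]


# ---------------------------------------------------------------------------
# Protein consequence rendering
# ---------------------------------------------------------------------------


def _aa3(aa: str) -> str:
    return "Ter" if aa == "*" else seq3(aa)


def render_protein_consequence(
    f: FrameComputation,
    call: StopGainCall,
    t: TranscriptModel,
    g: GenomeSequences,
    cds_seq: Optional[str] = None,
) -> str:
    """HGVS-protein-style description of an in-frame rescue deletion.

    The alternate coding sequence is built by substituting the variant
    base and excising the deleted CDS segment, then both proteins are
    translated and diffed: ``p.(Xaa#_Yaa#del)`` when flanking residues are
    reconstituted exactly, ``p.(Xaa#_Yaa#delins...)`` when the hybrid
    junction codon encodes new residue(s).  Raises
    :class:`TruncationError` when the hybrid codon is a stop (the
    putative rescue still truncates).
    """
    if not f.in_frame:
        raise ValueError("protein consequence rendering requires an in-frame deletion")
    if cds_seq is None:
        cds_seq = t.cds_sequence(g)
    v = call.variant
    alt_base = v.alt if t.strand == "+" else str(Seq(v.alt).complement())
    i = call.cds_pos - 1
    alt_cds = cds_seq[:i] + alt_base + cds_seq[i + 1 :]
    j = f.junction_cds_pos
    alt_cds = alt_cds[:j] + alt_cds[j + f.deleted_nt :]

    ref_prot = str(Seq(cds_seq).translate())
    alt_prot = str(Seq(alt_cds).translate())
    if ref_prot.endswith("*"):
        ref_prot = ref_prot[:-1]
    if alt_prot.endswith("*"):
        alt_prot = alt_prot[:-1]
    if "*" in alt_prot:
        raise TruncationError(
            "rescue produces truncation: hybrid junction codon is a stop "
            f"(premature stop at residue {alt_prot.index('*') + 1})"
        )

    # trim common prefix, then common suffix
    a = 0
    while a < len(ref_prot) and a < len(alt_prot) and ref_prot[a] == alt_prot[a]:
        a += 1
    b = 0
    while (
        b < len(ref_prot) - a
        and b < len(alt_prot) - a
        and ref_prot[len(ref_prot) - 1 - b] == alt_prot[len(alt_prot) - 1 - b]
    ):
        b += 1
    del_first, del_last = a + 1, len(ref_prot) - b
    inserted = alt_prot[a : len(alt_prot) - b]
    if del_first > del_last:
        raise ValueError("deletion removed no residues")
    first = f"{_aa3(ref_prot[del_first - 1])}{del_first}"
    if del_last == del_first:
        span = first
    else:
        span = f"{first}_{_aa3(ref_prot[del_last - 1])}{del_last}"
    if inserted:
        return f"p.({span}delins{''.join(_aa3(aa) for aa in inserted)})"
    return f"p.({span}del)"


# ---------------------------------------------------------------------------
# The decision tree
# ---------------------------------------------------------------------------


def classify(
    call: StopGainCall,
    a: Optional[SpliceGainAnnotation],
    p: ScreenParams,
    domains: List[DomainAnnotation],
    t: TranscriptModel,
    threshold: float,
    g: Optional[GenomeSequences] = None,
    cmap: Optional[CoordinateMap] = None,
    cds_seq: Optional[str] = None,
) -> RescueCall:
    """Assign exactly one :class:`RescueCategory` to a stop-gain call at
    one donor-gain threshold, walking candidacy → frame → CDS fraction →
    domain overlap."""
    if call.is_last_exon:
        return RescueCall(
            call=call, annotation=a, category=RescueCategory.LAST_EXON_EXCLUDED,
            threshold=threshold,
        )
    if not is_candidate(call, a, p, threshold):
        return RescueCall(
            call=call, annotation=a, category=RescueCategory.NOT_CANDIDATE,
            threshold=threshold,
        )
    try:
        frame = compute_deletion(call, a, t, dp_convention=p.dp_convention, cmap=cmap)
    except DegenerateDeletionError as exc:
        log.info("variant %s: degenerate deletion: %s", call.variant.id, exc)
        return RescueCall(
            call=call, annotation=a, category=RescueCategory.DEGENERATE,
            threshold=threshold, reason=str(exc),
        )
    if not frame.in_frame:
        return RescueCall(
            call=call, annotation=a, category=RescueCategory.CANDIDATE_OUT_OF_FRAME,
            threshold=threshold, frame=frame,
        )
    if frame.cds_fraction >= p.inframe_fraction_max:
        return RescueCall(
            call=call, annotation=a, category=RescueCategory.CANDIDATE_IN_FRAME_GE10,
            threshold=threshold, frame=frame,
        )
    residue_range = deleted_protein_range(frame, call, t)
    hits = tuple(
        overlap_domains(residue_range, [d for d in domains if d.transcript_id == call.transcript_id])
    )
    consequence = None
    if g is not None:
        try:
            consequence = render_protein_consequence(frame, call, t, g, cds_seq=cds_seq)
        except TruncationError as exc:
            log.warning("variant %s: %s", call.variant.id, exc)
    category = (
        RescueCategory.CANDIDATE_IN_FRAME_LT10_DOMAIN
        if hits
        else RescueCategory.CANDIDATE_IN_FRAME_LT10_NO_DOMAIN
    )
    return RescueCall(
        call=call,
        annotation=a,
        category=category,
        threshold=threshold,
        frame=frame,
        domain_hits=hits,
        protein_consequence=consequence,
    )


# ---------------------------------------------------------------------------
# Domain table IO
# ---------------------------------------------------------------------------


def read_domain_table(path: str) -> List[DomainAnnotation]:
    """TSV with columns transcript_id, domain_name, start_residue, end_residue."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        DomainAnnotation(
            transcript_id=str(r.transcript_id),
            domain_name=str(r.domain_name),
            start_residue=int(r.start_residue),
            end_residue=int(r.end_residue),
        )
        for r in df.itertuples()
    ]


def write_domain_table(domains: List[DomainAnnotation], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tdomain_name\tstart_residue\tend_residue\n")
        for d in domains:
            fh.write(f"{d.transcript_id}\t{d.domain_name}\t{d.start_residue}\t{d.end_residue}\n")
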
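"""Stop-gain (nonsense) consequence calling on canonical transcripts.

A stop-gain call is made when an SNV converts a sense codon of the spliced
CDS into TAA, TAG or TGA.  Codons are assembled in transcript orientation,
so minus-strand variants are complemented and codons spanning exon
junctions are handled (and flagged, since their splice-rescue geometry is
ambiguous).

The structural prefilter removes calls in the last exon of their
transcript: a premature stop there is generally expected to escape
nonsense-mediated decay and is already interpreted cautiously, so it is
out of scope for the rescue screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .transcript_io import (
    STOP_TRIPLETS,
    CoordinateMap,
    GenomeMismatchError,
    GenomeSequences,
    SnvVariant,
    TranscriptModel,
    complement,
    map_coordinates,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StopGainCall:
    """A validated nonsense consequence of one SNV on one transcript."""

    variant: SnvVariant
    transcript_id: str
    gene_id: str
    strand: str
    codon_number: int
    ref_codon: str
    alt_codon: str
    stop_triplet: str
    exon_index: int
    n_exons: int
    is_last_exon: bool
    cds_len_nt: int
    cds_pos: int  # 1-based CDS coordinate of the variant base
    codon_spans_junction: bool

    def __post_init__(self) -> None:
        if self.alt_codon != self.stop_triplet or self.stop_triplet not in STOP_TRIPLETS:
            raise ValueError(f"alt codon {self.alt_codon} is not the stop triplet")
        if self.ref_codon in STOP_TRIPLETS:
            raise ValueError(f"ref codon {self.ref_codon} is already a stop")
        if not 1 <= self.exon_index <= self.n_exons:
            raise ValueError("exon index out of range")


def call_stop_gain(
    v: SnvVariant,
    t: TranscriptModel,
    g: GenomeSequences,
    cmap: Optional[CoordinateMap] = None,
    cds_seq: Optional[str] = None,
) -> Optional[StopGainCall]:
    """Return a :class:`StopGainCall` iff ``v`` converts a sense codon of
    ``t`` into a stop; ``None`` for any other location or consequence.

    ``cmap``/``cds_seq`` may be passed to amortize per-transcript work when
    screening many variants.
    """
    if v.chrom != t.chrom:
        return None
    if cmap is None:
        cmap = map_coordinates(t)
    cds_pos = cmap.genomic_to_cds(v.pos)
    if cds_pos is None:
        return None
    ref_base = g[t.chrom][v.pos - 1]
    if ref_base != v.ref:
        raise GenomeMismatchError(
            f"{v.chrom}:{v.pos} REF {v.ref} != genome {ref_base}"
        )
    if cds_seq is None:
        cds_seq = t.cds_sequence(g)
    codon_number = (cds_pos - 1) // 3 + 1
    offset = (cds_pos - 1) % 3
    codon_start = (codon_number - 1) * 3
    ref_codon = cds_seq[codon_start : codon_start + 3]
    alt_base = v.alt if t.strand == "+" else complement(v.alt)
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
    if ref_codon in STOP_TRIPLETS or alt_codon not in STOP_TRIPLETS:
        return None
    exon = t.exon_containing(v.pos)
    assert exon is not None
    codon_genomic = [cmap.cds_to_genomic(codon_start + k + 1) for k in range(3)]
    spans = len({t.exon_containing(p).rank for p in codon_genomic}) > 1
    return StopGainCall(
        variant=v,
        transcript_id=t.transcript_id,
        gene_id=t.gene_id,
        strand=t.strand,
        codon_number=codon_number,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        stop_triplet=alt_codon,
        exon_index=exon.rank,
        n_exons=t.n_exons,
        is_last_exon=exon.rank == t.n_exons,
        cds_len_nt=len(cds_seq),
        cds_pos=cds_pos,
        codon_spans_junction=spans,
    )


def apply_prefilters(
    calls: List[StopGainCall],
) -> Tuple[List[StopGainCall], Dict[str, int]]:
    """Remove calls in the last exon of their transcript.

    Returns the retained calls and per-filter removal counts.
    """
    kept = [c for c in calls if not c.is_last_exon]
    counts = {"last_exon": len(calls) - len(kept)}
    if counts["last_exon"]:
        log.info("prefilter removed %d last-exon calls", counts["last_exon"])
    return kept, counts


def classify_stop_triplet(call: StopGainCall) -> str:
    """Binary stop-triplet label used by the enrichment statistic.

    TAA and TGA can occupy positions +2..+4 of a canonical donor motif
    (GT[AG]AGT); TAG cannot, so the screen's enrichment contrast is
    TAA-or-TGA versus TAG.
    """
    return "TAA_or_TGA" if call.stop_triplet in ("TAA", "TGA") else "TAG"
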
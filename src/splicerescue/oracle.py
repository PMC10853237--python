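"""Brute-force sequence-surgery recomputation of screen consequences.

These functions rebuild the full spliced coding sequence base by base —
substituting the variant allele, excising the mis-spliced segment when a
new donor is used, re-splicing and translating — instead of doing any
coordinate arithmetic.  They exist as an independent route against which
the (much faster) coordinate-based callers are checked, and as the
construction check the synthetic-cohort generator runs on every variant it
plants.  Keep them free of any dependency on the callers they verify.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

from Bio.Seq import Seq

from .transcript_io import (
    STOP_TRIPLETS,
    GenomeSequences,
    SnvVariant,
    TranscriptModel,
    revcomp,
)


def spliced_cds(
    genome: GenomeSequences,
    t: TranscriptModel,
    substitutions: Optional[Dict[int, str]] = None,
) -> str:
    """Spliced CDS of ``t`` in transcript orientation, with optional
    genomic-position→base substitutions applied first (bases given on the
    reference strand)."""
    chrom_seq = genome[t.chrom]
    pieces = []
    for e in sorted(t.exons, key=lambda e: e.start):
        lo = max(e.start, t.cds_start)
        hi = min(e.end, t.cds_end)
        if lo > hi:
            continue
        piece = chrom_seq[lo - 1 : hi]
        if substitutions:
            chars = list(piece)
            for pos, base in substitutions.items():
                if lo <= pos <= hi:
                    chars[pos - lo] = base
            piece = "".join(chars)
        pieces.append(piece)
    seq = "".join(pieces)
    return revcomp(seq) if t.strand == "-" else seq


def translate(cds: str) -> str:
    """Translate, stopping at the first stop codon; partial tail dropped."""
    usable = cds[: len(cds) // 3 * 3]
    prot = str(Seq(usable).translate())
    star = prot.find("*")
    return prot if star < 0 else prot[: star + 1]


def premature_stop(
    genome: GenomeSequences, t: TranscriptModel, v: SnvVariant
) -> Optional[Tuple[int, str]]:
    """(codon number, stop triplet) of a premature stop gained by ``v``.

    Rebuilds the alternate spliced CDS explicitly and compares translations;
    returns ``None`` when the variant does not create exactly one new
    premature stop (including when it lies outside the CDS).
    """
    ref_cds = spliced_cds(genome, t)
    alt_cds = spliced_cds(genome, t, substitutions={v.pos: v.alt})
    if ref_cds == alt_cds:
        return None  # not in the CDS
    ref_prot = translate(ref_cds)
    alt_prot = translate(alt_cds)
    if not alt_prot.endswith("*") or len(alt_prot) >= len(ref_prot):
        return None
    stop_codon_number = len(alt_prot)
    triplet = alt_cds[(stop_codon_number - 1) * 3 : stop_codon_number * 3]
    if triplet not in STOP_TRIPLETS:
        return None
    # the ref codon at that position must have been sense
    ref_triplet = ref_cds[(stop_codon_number - 1) * 3 : stop_codon_number * 3]
    if ref_triplet in STOP_TRIPLETS:
        return None
    return stop_codon_number, triplet


def excised_cds(
    genome: GenomeSequences,
    t: TranscriptModel,
    v: SnvVariant,
    junction_genomic: int,
) -> str:
    """Alternate spliced CDS when a gained donor at ``junction_genomic``
    (genomic coordinate of the new last exonic base, inside the variant's
    exon) splices to the next natural acceptor.

    The variant's exon is truncated at the junction, every other exon is
    used unchanged, the variant allele is substituted, and the CDS is
    re-extracted from the new spliced transcript.
    """
    exon = t.exon_containing(v.pos)
    if exon is None:
        raise ValueError("variant not exonic")
    if not exon.contains(junction_genomic):
        raise ValueError("junction outside the variant's exon")
    chrom_seq = genome[t.chrom]

    def piece(lo: int, hi: int) -> str:
        s = chrom_seq[lo - 1 : hi]
        if lo <= v.pos <= hi:
            i = v.pos - lo
            s = s[:i] + v.alt + s[i + 1 :]
        return s

    pieces = []
    for e in sorted(t.exons, key=lambda e: e.start):
        start, end = e.start, e.end
        if e.rank == exon.rank:
            if t.strand == "+":
                end = junction_genomic
            else:
                start = junction_genomic
        lo = max(start, t.cds_start)
        hi = min(end, t.cds_end)
        if lo <= hi:
            pieces.append(piece(lo, hi))
    seq = "".join(pieces)
    return revcomp(seq) if t.strand == "-" else seq


def excision_in_frame(
    genome: GenomeSequences, t: TranscriptModel, v: SnvVariant, junction_genomic: int
) -> bool:
    """Frame of the rescue deletion by explicit excision: in-frame iff the
    alternate spliced CDS length is congruent to the reference mod 3."""
    ref_len = len(spliced_cds(genome, t))
    alt_len = len(excised_cds(genome, t, v, junction_genomic))
    return (ref_len - alt_len) % 3 == 0


def excised_protein(
    genome: GenomeSequences, t: TranscriptModel, v: SnvVariant, junction_genomic: int
) -> str:
    """Translation of the rescue product (stops at the first stop codon)."""
    return translate(excised_cds(genome, t, v, junction_genomic))
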
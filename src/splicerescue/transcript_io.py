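"""Readers and writers for the genomic file formats the screen touches.

All coordinates exposed by this module are 1-based and inclusive, the
convention of GTF and VCF.  Transcript models are validated on load so that
downstream coordinate arithmetic can assume a well-formed, strand-aware
exon/CDS structure.

A note on the GTF dialect: CDS features are expected to *include* the stop
codon, so that a valid coding sequence starts with ATG and ends with one of
TAA/TAG/TGA.  Ensembl-style GTFs that exclude the stop codon can be read in
lenient mode (``strict=False``), which demotes sequence-level validation
failures to warnings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from cyvcf2 import VCF

log = logging.getLogger(__name__)

#: Nucleotide triplets that terminate translation (standard nuclear code).
STOP_TRIPLETS = frozenset({"TAA", "TAG", "TGA"})

_VALID_BASES = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

GenomeSequences = Dict[str, str]


class FastaParseError(ValueError):
    """Malformed FASTA input."""


class AnnotationError(ValueError):
    """Transcript annotation violates a model invariant."""


class GenomeMismatchError(ValueError):
    """A variant's REF allele disagrees with the reference genome."""


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExonInterval:
    """One exon, genomic 1-based inclusive, with its 5'→3' transcript rank."""

    start: int
    end: int
    rank: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(f"exon start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class TranscriptModel:
    """Strand-aware exon/CDS structure of one transcript.

    ``exons`` are ordered 5'→3' with respect to the transcript strand and
    carry consecutive ranks from 1.  ``cds_start``/``cds_end`` are genomic
    (``cds_start <= cds_end`` regardless of strand); the CDS includes the
    stop codon.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple
    cds_start: int
    cds_end: int
    canonical: bool = False

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple:
        starts = [e.start for e in self.exons]
        ends = [e.end for e in self.exons]
        return min(starts), max(ends)

    def exon_containing(self, pos: int) -> Optional[ExonInterval]:
        for e in self.exons:
            if e.contains(pos):
                return e
        return None

    def cds_sequence(self, genome: GenomeSequences) -> str:
        """Spliced CDS in transcript orientation (includes the stop codon)."""
        chrom_seq = genome[self.chrom]
        pieces = []
        for e in sorted(self.exons, key=lambda e: e.start):
            lo = max(e.start, self.cds_start)
            hi = min(e.end, self.cds_end)
            if lo <= hi:
                pieces.append(chrom_seq[lo - 1 : hi])
        seq = "".join(pieces)
        return revcomp(seq) if self.strand == "-" else seq

    def cds_len(self) -> int:
        total = 0
        for e in self.exons:
            lo = max(e.start, self.cds_start)
            hi = min(e.end, self.cds_end)
            if lo <= hi:
                total += hi - lo + 1
        return total


@dataclass(frozen=True)
class SnvVariant:
    """A single-nucleotide variant; ``pos`` is 1-based genomic."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = "."
    spliceai: Optional[str] = None  # raw SpliceAI INFO value, if present

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"not an SNV: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")


class CoordinateMap:
    """Bidirectional lookup between genomic, spliced-transcript and CDS
    coordinates of one transcript (all 1-based; intronic positions have no
    spliced coordinate)."""

    def __init__(self, t: TranscriptModel):
        self.transcript = t
        self._g2t: Dict[int, int] = {}
        self._t2g: List[int] = []
        tpos = 0
        for exon in t.exons:  # already 5'→3'
            rng = (
                range(exon.start, exon.end + 1)
                if t.strand == "+"
                else range(exon.end, exon.start - 1, -1)
            )
            for g in rng:
                tpos += 1
                self._g2t[g] = tpos
                self._t2g.append(g)
        # transcript coordinate of the CDS 5' end
        cds5 = t.cds_start if t.strand == "+" else t.cds_end
        self._cds_offset = self._g2t[cds5] - 1
        self._cds_len = t.cds_len()

    @property
    def transcript_length(self) -> int:
        return len(self._t2g)

    @property
    def cds_length(self) -> int:
        return self._cds_len

    def genomic_to_transcript(self, pos: int) -> Optional[int]:
        return self._g2t.get(pos)

    def transcript_to_genomic(self, tpos: int) -> int:
        if not 1 <= tpos <= len(self._t2g):
            raise IndexError(f"transcript position {tpos} out of range")
        return self._t2g[tpos - 1]

    def genomic_to_cds(self, pos: int) -> Optional[int]:
        tpos = self._g2t.get(pos)
        if tpos is None:
            return None
        cds = tpos - self._cds_offset
        if 1 <= cds <= self._cds_len:
            return cds
        return None

    def cds_to_genomic(self, cds_pos: int) -> int:
        if not 1 <= cds_pos <= self._cds_len:
            raise IndexError(f"CDS position {cds_pos} out of range")
        return self._t2g[cds_pos + self._cds_offset - 1]


def map_coordinates(t: TranscriptModel) -> CoordinateMap:
    """Build the genomic↔transcript↔CDS coordinate lookup for ``t``."""
    return CoordinateMap(t)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_genome(path: str) -> GenomeSequences:
    """Load a FASTA file into a name→uppercase-sequence mapping.

    Raises :class:`FastaParseError` (naming the offending line) when the
    file does not start with a header or contains non-ACGTN characters.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected FASTA header, got {line.strip()!r}"
                )
            break
        else:
            log.warning("%s: empty FASTA file", path)
            return {}
    genome: GenomeSequences = {}
    for record in SeqIO.parse(path, "fasta"):
        if record.id in genome:
            raise FastaParseError(f"{path}: duplicate sequence name {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FastaParseError(
                f"{path}: sequence {record.id!r} contains non-ACGTN characters {sorted(bad)}"
            )
        genome[record.id] = seq
    return genome


def write_genome(genome: GenomeSequences, path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------


def _validate_model(t: TranscriptModel, genome: GenomeSequences, strict: bool) -> None:
    # structural checks are always fatal
    by_start = sorted(t.exons, key=lambda e: e.start)
    for a, b in zip(by_start, by_start[1:]):
        if a.end >= b.start:
            raise AnnotationError(f"{t.transcript_id}: overlapping exons {a} / {b}")
    ranks = [e.rank for e in t.exons]
    if ranks != list(range(1, len(ranks) + 1)):
        raise AnnotationError(f"{t.transcript_id}: exon ranks not consecutive: {ranks}")
    ordered = [e.start for e in t.exons]
    if t.strand == "+" and ordered != sorted(ordered):
        raise AnnotationError(f"{t.transcript_id}: + strand exons not 5'→3'")
    if t.strand == "-" and ordered != sorted(ordered, reverse=True):
        raise AnnotationError(f"{t.transcript_id}: - strand exons not 5'→3'")
    if t.exon_containing(t.cds_start) is None or t.exon_containing(t.cds_end) is None:
        raise AnnotationError(f"{t.transcript_id}: CDS boundary outside exons")

    def fail(msg: str) -> None:
        if strict:
            raise AnnotationError(msg)
        log.warning("%s", msg)

    cds = t.cds_sequence(genome)
    if len(cds) % 3 != 0:
        fail(f"{t.transcript_id}: CDS length {len(cds)} not divisible by 3")
    if not cds.startswith("ATG"):
        fail(f"{t.transcript_id}: CDS does not start with ATG ({cds[:3]})")
    if cds[-3:] not in STOP_TRIPLETS:
        fail(f"{t.transcript_id}: CDS does not end with a stop triplet ({cds[-3:]})")


def read_transcripts(
    path: str, genome: GenomeSequences, strict: bool = True
) -> List[TranscriptModel]:
    """Read exon/CDS features from a GTF file into validated models.

    The ``tag`` attribute marks canonical transcripts when it contains the
    word "canonical"; see :func:`select_canonical` for the fallback rule.
    """
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    exons: Dict[str, list] = {}
    cds: Dict[str, list] = {}
    meta: Dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            raise AnnotationError(f"{path}: {feat.featuretype} feature without transcript_id")
        info = meta.setdefault(
            tid,
            {
                "gene_id": feat.attributes.get("gene_id", [""])[0],
                "chrom": feat.seqid,
                "strand": feat.strand,
                "canonical": False,
            },
        )
        tags = feat.attributes.get("tag", [])
        if any("canonical" in tag.lower() for tag in tags):
            info["canonical"] = True
        target = exons if feat.featuretype == "exon" else cds
        target.setdefault(tid, []).append((feat.start, feat.end))

    models = []
    for tid, exon_ivs in exons.items():
        info = meta[tid]
        if tid not in cds:
            log.info("skipping non-coding transcript %s", tid)
            continue
        strand = info["strand"]
        ordered = sorted(exon_ivs, key=lambda iv: iv[0], reverse=(strand == "-"))
        exon_tuple = tuple(
            ExonInterval(start=s, end=e, rank=i + 1) for i, (s, e) in enumerate(ordered)
        )
        cds_start = min(s for s, _ in cds[tid])
        cds_end = max(e for _, e in cds[tid])
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=info["gene_id"],
            chrom=info["chrom"],
            strand=strand,
            exons=exon_tuple,
            cds_start=cds_start,
            cds_end=cds_end,
            canonical=info["canonical"],
        )
        _validate_model(t, genome, strict=strict)
        models.append(t)
    return models


def select_canonical(models: Sequence[TranscriptModel]) -> List[TranscriptModel]:
    """One canonical transcript per gene.

    A transcript tagged canonical in the annotation wins; otherwise the
    transcript with the longest spliced CDS is used, ties broken by
    lexicographically smallest transcript id (a deterministic fallback —
    annotation sources differ on what "canonical" means).
    """
    by_gene: Dict[str, List[TranscriptModel]] = {}
    for t in models:
        by_gene.setdefault(t.gene_id, []).append(t)
    chosen = []
    for gene_id in sorted(by_gene):
        ts = by_gene[gene_id]
        tagged = [t for t in ts if t.canonical]
        pool = tagged if tagged else ts
        best = sorted(pool, key=lambda t: (-t.cds_len(), t.transcript_id))[0]
        chosen.append(best)
    return chosen


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_variants(
    path: str, genome: Optional[GenomeSequences] = None
) -> List[SnvVariant]:
    """Read SNVs from a VCF; multi-allelic records are split per ALT allele.

    Indels and other non-SNV alleles are counted and skipped.  When a genome
    is supplied, each record's REF base is checked against it.
    """
    variants: List[SnvVariant] = []
    n_skipped = 0
    for rec in VCF(path):
        spliceai = rec.INFO.get("SpliceAI")
        for alt in rec.ALT:
            if len(rec.REF) != 1 or len(alt) != 1:
                n_skipped += 1
                log.info(
                    "skipping non-SNV allele %s:%d %s>%s", rec.CHROM, rec.POS, rec.REF, alt
                )
                continue
            if genome is not None:
                actual = genome[rec.CHROM][rec.POS - 1]
                if actual != rec.REF:
                    raise GenomeMismatchError(
                        f"{path}: {rec.CHROM}:{rec.POS} REF {rec.REF} != genome {actual}"
                    )
            variants.append(
                SnvVariant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    id=rec.ID or ".",
                    spliceai=spliceai,
                )
            )
    if n_skipped:
        log.info("%s: skipped %d non-SNV alleles", path, n_skipped)
    return variants


# ---------------------------------------------------------------------------
# Screen table
# ---------------------------------------------------------------------------

#: Column order of the per-variant screen table (stable; documented here).
SCREEN_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "transcript_id",
    "gene_id",
    "strand",
    "threshold",
    "category",
    "codon_number",
    "ref_codon",
    "alt_codon",
    "stop_triplet",
    "exon_index",
    "n_exons",
    "cds_len_nt",
    "codon_spans_junction",
    "ds_dg",
    "dp_dg",
    "deleted_nt",
    "in_frame",
    "cds_fraction",
    "domain_hits",
    "protein_consequence",
]


def write_screen_table(records: Iterable, path: str) -> None:
    """Write per-variant screen rows (objects exposing ``to_row()``) as TSV.

    Output is byte-identical for identical input: fixed column order, plain
    ``str`` rendering of floats (shortest round-trip representation).
    """
    rows = [r.to_row() for r in records]
    with open(path, "w") as fh:
        fh.write("\t".join(SCREEN_COLUMNS) + "\n")
        for row in rows:
            fh.write(
                "\t".join("" if row.get(c) is None else str(row.get(c)) for c in SCREEN_COLUMNS)
                + "\n"
            )


def read_screen_table(path: str) -> pd.DataFrame:
    """Read a screen table back; numeric columns recover their exact values."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    converters = {
        **{c: int for c in ("pos", "codon_number", "exon_index", "n_exons",
                            "cds_len_nt", "dp_dg", "deleted_nt")},
        **{c: float for c in ("threshold", "ds_dg", "cds_fraction")},
        **{c: {"True": True, "False": False}.get for c in ("codon_spans_junction", "in_frame")},
    }
    for col, conv in converters.items():
        df[col] = pd.Series(
            [conv(s) if s != "" else None for s in df[col]], dtype=object, index=df.index
        )
    return df
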
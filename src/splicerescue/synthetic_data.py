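"""Synthetic cohorts with planted ground truth.

Generates multi-exon protein-coding genes on both strands, plants nonsense
variants of every decision-tree category, and emits the exact file formats
the screen consumes (FASTA, GTF, VCF with SpliceAI-format INFO,
classification/domain/truth TSVs), so that every pipeline stage is testable
without external downloads.

Planted rescue candidates realize the canonical mechanism geometry: a C>T
edit at codon base 1 turns CAA→TAA or CGA→TGA while completing a consensus
donor motif whose obligate GT the variant supplies (the stop occupies donor
positions +2..+4, so the junction's last exonic base lies two pre-mRNA
positions upstream of the variant — delta position −2).  TAG stops are
planted only as non-candidates: donor position +4 must be A, which TAG
cannot satisfy.  Every plant is re-verified at generation time with the
sequence-surgery oracle, never with the coordinate-based callers the plants
are meant to test.

Identical seeds produce byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import oracle
from .donor_gain import DonorPwm, offset_to_dp, scan_donor_gain
from .rescue_classifier import RescueCategory
from .transcript_io import (
    STOP_TRIPLETS,
    ExonInterval,
    GenomeSequences,
    SnvVariant,
    TranscriptModel,
    complement,
    revcomp,
    write_genome,
)

log = logging.getLogger(__name__)

_BASE_ARRAY = np.array(list("ACGT"))
SENSE_CODONS = [
    "".join(c) for c in product("ACGT", repeat=3) if "".join(c) not in STOP_TRIPLETS
]

#: star rating → review-status text (inverse of the documented mapping)
STAR_TEXT = {
    4: "practice guideline",
    3: "reviewed by expert panel",
    2: "criteria provided, multiple submitters, no conflicts",
    1: "criteria provided, single submitter",
    0: "no assertion criteria provided",
}

CANDIDATE_PLANT_CATEGORIES = (
    RescueCategory.CANDIDATE_OUT_OF_FRAME,
    RescueCategory.CANDIDATE_IN_FRAME_GE10,
    RescueCategory.CANDIDATE_IN_FRAME_LT10_NO_DOMAIN,
    RescueCategory.CANDIDATE_IN_FRAME_LT10_DOMAIN,
)


class GenerationError(RuntimeError):
    """A planting constraint could not be satisfied."""


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a synthetic cohort.

    The default category mix plants 97% plain nonsense variants and 3%
    rescue candidates split across the frame/fraction/domain outcomes; the
    default clinical-label effect gives candidates a 0.75 probability of an
    LP/P classification versus 0.90 for the rest, with a lower mean star
    rating (≈1.10 vs ≈1.34) — the direction and rough size of the deficit
    the screen is meant to detect.
    """

    n_genes: int = 50
    variants_per_gene: int = 6
    exons_per_gene: Tuple[int, int] = (2, 8)
    exon_len: Tuple[int, int] = (60, 300)
    intron_len: Tuple[int, int] = (80, 500)
    utr_len: Tuple[int, int] = (6, 30)
    category_mix: Dict[RescueCategory, float] = field(
        default_factory=lambda: {
            RescueCategory.NOT_CANDIDATE: 0.97,
            RescueCategory.CANDIDATE_OUT_OF_FRAME: 0.012,
            RescueCategory.CANDIDATE_IN_FRAME_GE10: 0.006,
            RescueCategory.CANDIDATE_IN_FRAME_LT10_NO_DOMAIN: 0.006,
            RescueCategory.CANDIDATE_IN_FRAME_LT10_DOMAIN: 0.006,
        }
    )
    p_lpp_candidate: float = 0.75
    p_lpp_other: float = 0.90
    star_probs_candidate: Tuple[float, ...] = (0.30, 0.45, 0.13, 0.09, 0.03)
    star_probs_other: Tuple[float, ...] = (0.20, 0.45, 0.20, 0.10, 0.05)
    candidate_ds_range: Tuple[float, float] = (0.85, 0.99)
    noncandidate_ds_range: Tuple[float, float] = (0.0, 0.05)
    genes_per_chrom: int = 10
    spacer_len: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"category mix sums to {total}, expected 1")
        if any(p < 0 for p in self.category_mix.values()):
            raise ConfigError("category mix proportions must be non-negative")
        for name in ("exons_per_gene", "exon_len", "intron_len", "utr_len"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ConfigError(f"invalid range {name}={lo, hi}")
        for probs in (self.star_probs_candidate, self.star_probs_other):
            if len(probs) != 5 or abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError("star distributions must have 5 probabilities summing to 1")
        if not 0 <= self.p_lpp_candidate <= 1 or not 0 <= self.p_lpp_other <= 1:
            raise ConfigError("LP/P probabilities must lie in [0, 1]")


@dataclass
class GroundTruthRecord:
    """What was planted for one variant."""

    variant_id: str
    transcript_id: str
    gene_id: str
    category: RescueCategory
    ds_dg: float
    dp_dg: int  # strand-corrected
    stop_triplet: str
    codon_number: int
    deleted_nt: Optional[int]  # None for non-candidates
    domain_overlap: Optional[bool]  # None unless IN_FRAME_LT10


@dataclass
class CohortFiles:
    """Paths of one emitted cohort plus its in-memory ground truth."""

    genome_fa: str
    gtf: str
    vcf: str
    classifications_tsv: str
    domains_tsv: str
    truth_tsv: str
    truth: List[GroundTruthRecord]

    def paths(self) -> List[str]:
        return [
            self.genome_fa,
            self.gtf,
            self.vcf,
            self.classifications_tsv,
            self.domains_tsv,
            self.truth_tsv,
        ]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASE_ARRAY, size=n)) if n > 0 else ""


def _random_cds(rng: np.random.Generator, n_codons: int) -> List[str]:
    # ATG + random sense codons + stop; no in-frame internal stops
    body = list(rng.choice(SENSE_CODONS, size=n_codons - 2))
    stop = str(rng.choice(["TAA", "TAG", "TGA"]))
    return list("".join(["ATG"] + body + [stop]))


# ---------------------------------------------------------------------------
# Gene construction
# ---------------------------------------------------------------------------


@dataclass
class GeneBuilder:
    """Mutable scaffold of one gene while variants are being planted.

    The coding sequence lives in spliced/CDS coordinates until the genome
    is assembled, so all planting edits are simple list writes.
    """

    gene_id: str
    transcript_id: str
    strand: str
    exon_lens: List[int]
    intron_lens: List[int]
    utr5: int
    utr3: int
    cds: List[str]
    utr5_seq: str
    utr3_seq: str
    intron_seqs: List[str]
    reserved: List[Tuple[int, int]] = field(default_factory=list)
    plants: List[dict] = field(default_factory=list)
    # residue ranges that must / must not be covered by a domain
    domain_required: List[Tuple[int, int]] = field(default_factory=list)
    domain_free: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def cds_len(self) -> int:
        return len(self.cds)

    @property
    def n_exons(self) -> int:
        return len(self.exon_lens)

    def spliced(self) -> str:
        return self.utr5_seq + "".join(self.cds) + self.utr3_seq

    def exon_spliced_ranges(self) -> List[Tuple[int, int]]:
        out, pos = [], 0
        for ln in self.exon_lens:
            out.append((pos + 1, pos + ln))
            pos += ln
        return out

    def exon_cds_range(self, k: int) -> Optional[Tuple[int, int]]:
        """CDS coordinates covered by exon ``k`` (0-based), or None."""
        s, e = self.exon_spliced_ranges()[k]
        cs = max(1, s - self.utr5)
        ce = min(self.cds_len, e - self.utr5)
        return (cs, ce) if cs <= ce else None

    def exon_of_spliced(self, pos: int) -> int:
        for k, (s, e) in enumerate(self.exon_spliced_ranges()):
            if s <= pos <= e:
                return k
        raise IndexError(pos)

    def spliced_to_pre(self, pos: int) -> int:
        k = self.exon_of_spliced(pos)
        return pos + sum(self.intron_lens[:k])

    def pre_mrna(self) -> str:
        spliced = self.spliced()
        pieces = []
        for k, (s, e) in enumerate(self.exon_spliced_ranges()):
            pieces.append(spliced[s - 1 : e])
            if k < len(self.intron_seqs):
                pieces.append(self.intron_seqs[k])
        return "".join(pieces)

    def is_reserved(self, lo: int, hi: int) -> bool:
        return any(lo <= rhi and hi >= rlo for rlo, rhi in self.reserved)


def build_gene(
    rng: np.random.Generator, config: SimulationConfig, gene_id: str, strand: str
) -> GeneBuilder:
    """Sample one gene's structure and reference sequence."""
    for _ in range(50):
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = [
            int(rng.integers(config.exon_len[0], config.exon_len[1] + 1))
            for _ in range(n_ex)
        ]
        intron_lens = [
            int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
            for _ in range(n_ex - 1)
        ]
        utr5 = int(rng.integers(config.utr_len[0], config.utr_len[1] + 1))
        utr3 = int(rng.integers(config.utr_len[0], config.utr_len[1] + 1))
        cds_len = sum(exon_lens) - utr5 - utr3
        utr3 += cds_len % 3
        cds_len -= cds_len % 3
        if cds_len < 90 or utr3 >= exon_lens[-1] or utr5 >= exon_lens[0]:
            continue
        return GeneBuilder(
            gene_id=gene_id,
            transcript_id=gene_id.replace("gene", "tx"),
            strand=strand,
            exon_lens=exon_lens,
            intron_lens=intron_lens,
            utr5=utr5,
            utr3=utr3,
            cds=_random_cds(rng, cds_len // 3),
            utr5_seq=_random_seq(rng, utr5),
            utr3_seq=_random_seq(rng, utr3),
            intron_seqs=[
                "GT" + _random_seq(rng, ln - 4) + "AG" for ln in intron_lens
            ],
        )
    raise GenerationError("could not sample a feasible gene structure")


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------

_PWM = DonorPwm()
_CANDIDATE_DS_MIN = 0.8
_NONCANDIDATE_DS_MAX = 0.05


def _candidate_placements(
    b: GeneBuilder, category: RescueCategory, fraction_max: float = 0.10
) -> List[Tuple[int, int]]:
    """Feasible (exon index, deleted_nt) pairs for a candidate plant.

    The junction CDS position must have phase 2 (the stop codon starts at
    donor position +2), which fixes deleted_nt mod 3 per exon; frame and
    CDS-fraction constraints then narrow the choices.
    """
    L = b.cds_len
    placements = []
    for k in range(b.n_exons - 1):  # never the last exon
        rng_cds = b.exon_cds_range(k)
        if rng_cds is None:
            continue
        cs, ce = rng_cds
        if ce >= L - 2:  # exon reaches the stop codon; treat as terminal
            continue
        want_mod = (ce - 2) % 3
        lo_cj = max(6, cs + 2)
        d_max = ce - lo_cj
        for d in range(6, d_max + 1):
            if d % 3 != want_mod:
                continue
            in_frame = d % 3 == 0
            if category == RescueCategory.CANDIDATE_OUT_OF_FRAME:
                if in_frame:
                    continue
            else:
                if not in_frame:
                    continue
                frac_ok = d / L < fraction_max
                if category == RescueCategory.CANDIDATE_IN_FRAME_GE10 and frac_ok:
                    continue
                if category != RescueCategory.CANDIDATE_IN_FRAME_GE10 and not frac_ok:
                    continue
            cj = ce - d
            if b.is_reserved(cj - 10, cj + 10):
                continue
            if category in (
                RescueCategory.CANDIDATE_IN_FRAME_LT10_NO_DOMAIN,
                RescueCategory.CANDIDATE_IN_FRAME_LT10_DOMAIN,
            ):
                # deletions with conflicting domain requirements must not
                # share residues, or no domain table can satisfy both
                first, last = cj // 3 + 1, (cj + d - 1) // 3 + 1
                conflicting = (
                    b.domain_free
                    if category == RescueCategory.CANDIDATE_IN_FRAME_LT10_DOMAIN
                    else b.domain_required
                )
                if any(first <= hi and last >= lo for lo, hi in conflicting):
                    continue
            placements.append((k, d))
    return placements


def plant_rescue_variant(
    b: GeneBuilder, category: RescueCategory, rng: np.random.Generator
) -> dict:
    """Plant one variant of the requested category into a gene under
    construction; returns the plant record.

    Raises :class:`GenerationError` when the gene cannot host the
    category's constraints (the caller retries another gene).
    """
    if category in CANDIDATE_PLANT_CATEGORIES:
        return _plant_candidate(b, category, rng)
    if category == RescueCategory.NOT_CANDIDATE:
        return _plant_plain_nonsense(b, rng)
    raise ValueError(f"cannot plant category {category}")


def _plant_candidate(
    b: GeneBuilder, category: RescueCategory, rng: np.random.Generator
) -> dict:
    placements = _candidate_placements(b, category)
    if not placements:
        raise GenerationError(f"{b.gene_id}: no feasible placement for {category.value}")
    k, d = placements[int(rng.integers(len(placements)))]
    ce = b.exon_cds_range(k)[1]
    cj = ce - d  # junction: CDS position of the last retained exonic base

    stop = str(rng.choice(["TAA", "TGA"]))
    ref_codon = "CAA" if stop == "TAA" else "CGA"

    def put(cds_pos: int, base: str) -> None:
        b.cds[cds_pos - 1] = base

    # donor motif -3 (last base of codon k-2) must be A or C, keep it sense
    first_two = "".join(b.cds[cj - 5 : cj - 3])
    put(cj - 2, "C" if first_two in ("TG", "TA") else "A")
    for pos, base in zip(range(cj - 1, cj + 2), "AGG"):  # codon before the stop
        put(pos, base)
    for pos, base in zip(range(cj + 2, cj + 5), ref_codon):  # the edited codon
        put(pos, base)
    put(cj + 5, "G")  # donor +5
    put(cj + 6, "T")  # donor +6

    var_cds = cj + 2
    b.reserved.append((cj - 10, cj + 10))
    if category in (
        RescueCategory.CANDIDATE_IN_FRAME_LT10_NO_DOMAIN,
        RescueCategory.CANDIDATE_IN_FRAME_LT10_DOMAIN,
    ):
        rng_res = (cj // 3 + 1, (cj + d - 1) // 3 + 1)
        if category == RescueCategory.CANDIDATE_IN_FRAME_LT10_DOMAIN:
            b.domain_required.append(rng_res)
        else:
            b.domain_free.append(rng_res)

    # verify with the PWM on the pre-mRNA: the variant must score >= 0.8
    # with the junction exactly two pre-mRNA positions upstream
    pre = b.pre_mrna()
    var_pre = b.spliced_to_pre(var_cds + b.utr5)
    ds_pwm, off = scan_donor_gain(pre, var_pre - 1, "T", pwm=_PWM)
    if off is None or offset_to_dp(off) != -2 or ds_pwm < _CANDIDATE_DS_MIN:
        raise GenerationError(
            f"{b.gene_id}: planted donor context failed PWM check "
            f"(ds={ds_pwm:.3f}, offset={off})"
        )

    plant = {
        "category": category,
        "var_cds": var_cds,
        "ref_base": "C",
        "alt_base": "T",
        "stop_triplet": stop,
        "codon_number": (var_cds - 1) // 3 + 1,
        "deleted_nt": d,
        "junction_cds": cj,
        "dp_corrected": -2,
        "exon_index": k + 1,
    }
    b.plants.append(plant)
    return plant


def _plant_plain_nonsense(b: GeneBuilder, rng: np.random.Generator) -> dict:
    """A nonsense edit that creates no donor motif (PWM-checked)."""
    ranges = b.exon_spliced_ranges()
    n_codons = b.cds_len // 3
    order = rng.permutation(n_codons - 2) + 2  # codons 2 .. n-1 (skip ATG, stop)
    for codon_number in order:
        codon_number = int(codon_number)
        c_start = 3 * (codon_number - 1) + 1
        s_start = c_start + b.utr5
        # keep the codon inside one non-last exon
        k = b.exon_of_spliced(s_start)
        if k == b.n_exons - 1 or b.exon_of_spliced(s_start + 2) != k:
            continue
        if b.is_reserved(c_start - 10, c_start + 12):
            continue
        ref_codon = "".join(b.cds[c_start - 1 : c_start + 2])
        if ref_codon in STOP_TRIPLETS:
            continue
        edits = [
            (i, alt)
            for i in range(3)
            for alt in "ACGT"
            if alt != ref_codon[i]
            and ref_codon[:i] + alt + ref_codon[i + 1 :] in STOP_TRIPLETS
        ]
        if not edits:
            continue
        edits = [edits[j] for j in rng.permutation(len(edits))]
        pre = b.pre_mrna()
        for i, alt in edits:
            var_cds = c_start + i
            var_pre = b.spliced_to_pre(var_cds + b.utr5)
            ds_pwm, _ = scan_donor_gain(pre, var_pre - 1, alt, pwm=_PWM)
            if ds_pwm > _NONCANDIDATE_DS_MAX:
                continue
            b.reserved.append((var_cds - 10, var_cds + 10))
            alt_codon = ref_codon[:i] + alt + ref_codon[i + 1 :]
            plant = {
                "category": RescueCategory.NOT_CANDIDATE,
                "var_cds": var_cds,
                "ref_base": ref_codon[i],
                "alt_base": alt,
                "stop_triplet": alt_codon,
                "codon_number": codon_number,
                "deleted_nt": None,
                "junction_cds": None,
                "dp_corrected": None,
                "exon_index": k + 1,
            }
            b.plants.append(plant)
            return plant
    raise GenerationError(f"{b.gene_id}: no quiet site for a plain nonsense plant")


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------


@dataclass
class AssembledGene:
    builder: GeneBuilder
    model: TranscriptModel
    variants: List[SnvVariant]
    plant_records: List[dict]  # plant dicts + genomic fields


def assemble_genome(
    builders: List[GeneBuilder], config: SimulationConfig, rng: np.random.Generator
) -> Tuple[GenomeSequences, List[AssembledGene]]:
    """Lay the genes onto chromosomes and produce transcript models plus
    genomic-coordinate variants."""
    genome: Dict[str, List[str]] = {}
    assembled = []
    for idx, b in enumerate(builders):
        chrom = f"chr{idx // config.genes_per_chrom + 1}"
        parts = genome.setdefault(chrom, [])
        offset = sum(len(p) for p in parts) + config.spacer_len
        parts.append(_random_seq(rng, config.spacer_len))
        pre = b.pre_mrna()
        L = len(pre)
        parts.append(pre if b.strand == "+" else revcomp(pre))

        def pre_to_genomic(p: int) -> int:
            return offset + p if b.strand == "+" else offset + (L - p + 1)

        exons = []
        for rank, (s, e) in enumerate(b.exon_spliced_ranges(), start=1):
            g1 = pre_to_genomic(b.spliced_to_pre(s))
            g2 = pre_to_genomic(b.spliced_to_pre(e))
            exons.append(ExonInterval(start=min(g1, g2), end=max(g1, g2), rank=rank))
        cds5 = pre_to_genomic(b.spliced_to_pre(b.utr5 + 1))
        cds3 = pre_to_genomic(b.spliced_to_pre(b.utr5 + b.cds_len))
        model = TranscriptModel(
            transcript_id=b.transcript_id,
            gene_id=b.gene_id,
            chrom=chrom,
            strand=b.strand,
            exons=tuple(exons),
            cds_start=min(cds5, cds3),
            cds_end=max(cds5, cds3),
            canonical=True,
        )
        variants, records = [], []
        for plant in b.plants:
            gpos = pre_to_genomic(b.spliced_to_pre(plant["var_cds"] + b.utr5))
            ref = plant["ref_base"] if b.strand == "+" else complement(plant["ref_base"])
            alt = plant["alt_base"] if b.strand == "+" else complement(plant["alt_base"])
            v = SnvVariant(chrom=chrom, pos=gpos, ref=ref, alt=alt)
            variants.append(v)
            records.append({**plant, "genomic_pos": gpos, "ref": ref, "alt": alt})
        assembled.append(
            AssembledGene(builder=b, model=model, variants=variants, plant_records=records)
        )
    for chrom, parts in genome.items():
        parts.append(_random_seq(rng, config.spacer_len))
    return {c: "".join(parts) for c, parts in genome.items()}, assembled


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------


def _write_gtf(assembled: List[AssembledGene], path: str) -> None:
    with open(path, "w") as fh:
        for ag in assembled:
            t = ag.model
            span_lo, span_hi = t.span
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'tag "canonical";'
            )
            fh.write(
                f"{t.chrom}\tsynthetic\ttranscript\t{span_lo}\t{span_hi}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for e in t.exons:
                fh.write(
                    f"{t.chrom}\tsynthetic\texon\t{e.start}\t{e.end}\t.\t{t.strand}\t.\t"
                    f'{attrs} exon_number "{e.rank}";\n'
                )
                lo = max(e.start, t.cds_start)
                hi = min(e.end, t.cds_end)
                if lo <= hi:
                    fh.write(
                        f"{t.chrom}\tsynthetic\tCDS\t{lo}\t{hi}\t.\t{t.strand}\t0\t{attrs}\n"
                    )


def _spliceai_info(
    record: dict, strand: str, gene_id: str, alt: str, ds: float
) -> str:
    dp_corr = record["dp_corrected"]
    raw_dp = dp_corr if strand == "+" else -dp_corr
    return f"{alt}|{gene_id}|0.00|0.00|{ds:.2f}|0.00|0|0|{raw_dp}|0"


def _write_vcf(rows: List[dict], contigs: Dict[str, int], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in contigs:
            fh.write(f"##contig=<ID={name},length={contigs[name]}>\n")
        fh.write(
            '##INFO=<ID=SpliceAI,Number=.,Type=String,Description="SpliceAI'
            " variant annotation. Format:"
            ' ALLELE|SYMBOL|DS_AG|DS_AL|DS_DG|DS_DL|DP_AG|DP_AL|DP_DG|DP_DL">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        order = sorted(contigs)
        for row in sorted(rows, key=lambda r: (order.index(r["chrom"]), r["pos"])):
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\tSpliceAI={row['spliceai']}\n"
            )


def generate_classifications(
    variant_ids: Sequence[str],
    is_candidate: Sequence[bool],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> List[dict]:
    """Sample ClinVar-like labels with the configured group-specific LP/P
    probabilities and star distributions."""
    rows = []
    for vid, cand in zip(variant_ids, is_candidate):
        p_lpp = config.p_lpp_candidate if cand else config.p_lpp_other
        star_probs = config.star_probs_candidate if cand else config.star_probs_other
        if rng.random() < p_lpp:
            classification = "P" if rng.random() < 0.5 else "LP"
        else:
            u = rng.random()
            classification = "VUS" if u < 0.6 else ("LB" if u < 0.8 else "B")
        stars = int(rng.choice(5, p=star_probs))
        rows.append(
            {
                "variant_id": vid,
                "classification": classification,
                "review_status": STAR_TEXT[stars],
                "stars": stars,
            }
        )
    return rows


def _generate_domains(
    assembled: List[AssembledGene], rng: np.random.Generator
) -> List[dict]:
    rows = []
    counter = 0
    for ag in assembled:
        b = ag.builder
        protein_len = b.cds_len // 3 - 1
        forbidden = []  # residue ranges that must stay domain-free
        wanted = []  # residue ranges that must be hit
        for rec in ag.plant_records:
            if rec["category"] not in (
                RescueCategory.CANDIDATE_IN_FRAME_LT10_NO_DOMAIN,
                RescueCategory.CANDIDATE_IN_FRAME_LT10_DOMAIN,
            ):
                continue
            cj, d = rec["junction_cds"], rec["deleted_nt"]
            first = cj // 3 + 1
            last = (cj + d - 1) // 3 + 1
            if rec["category"] == RescueCategory.CANDIDATE_IN_FRAME_LT10_DOMAIN:
                wanted.append((first, last))
            else:
                forbidden.append((first, last))
        for first, last in wanted:
            for _ in range(100):
                start = int(rng.integers(max(1, first - 10), last + 1))
                end = min(protein_len, start + int(rng.integers(5, 31)))
                if end < first or start > last:  # must overlap the deletion
                    continue
                if any(start <= fh and end >= fl for fl, fh in forbidden):
                    continue
                counter += 1
                rows.append(
                    {
                        "transcript_id": b.transcript_id,
                        "domain_name": f"SYNDOM{counter}",
                        "start_residue": start,
                        "end_residue": end,
                    }
                )
                break
            else:
                # planting keeps wanted/forbidden ranges disjoint, so the
                # deletion interval itself is always a valid domain
                counter += 1
                rows.append(
                    {
                        "transcript_id": b.transcript_id,
                        "domain_name": f"SYNDOM{counter}",
                        "start_residue": first,
                        "end_residue": last,
                    }
                )
        # background domains, kept clear of NO_DOMAIN deletions
        for _ in range(int(rng.integers(0, 3))):
            for _ in range(20):
                start = int(rng.integers(1, max(2, protein_len - 10)))
                end = min(protein_len, start + int(rng.integers(5, 31)))
                if any(start <= fh and end >= fl for fl, fh in forbidden):
                    continue
                counter += 1
                rows.append(
                    {
                        "transcript_id": b.transcript_id,
                        "domain_name": f"SYNDOM{counter}",
                        "start_residue": start,
                        "end_residue": end,
                    }
                )
                break
    return rows


# ---------------------------------------------------------------------------
# Construction checks (sequence-surgery oracle; independent of the callers)
# ---------------------------------------------------------------------------


def _verify_plants(
    genome: GenomeSequences, assembled: List[AssembledGene]
) -> None:
    for ag in assembled:
        t = ag.model
        for v, rec in zip(ag.variants, ag.plant_records):
            got = oracle.premature_stop(genome, t, v)
            if got != (rec["codon_number"], rec["stop_triplet"]):
                raise GenerationError(
                    f"{t.transcript_id} {v.chrom}:{v.pos}: planted stop "
                    f"({rec['codon_number']}, {rec['stop_triplet']}) but oracle found {got}"
                )
            if rec["deleted_nt"] is not None:
                # junction genomic position from the planted (corrected) dp
                offset = rec["dp_corrected"]  # negative == upstream, no zero
                junction = v.pos + offset if t.strand == "+" else v.pos - offset
                ref_len = len(oracle.spliced_cds(genome, t))
                alt_len = len(oracle.excised_cds(genome, t, v, junction))
                if ref_len - alt_len != rec["deleted_nt"]:
                    raise GenerationError(
                        f"{t.transcript_id} {v.chrom}:{v.pos}: excision removes "
                        f"{ref_len - alt_len} nt, planted {rec['deleted_nt']}"
                    )


# ---------------------------------------------------------------------------
# Top-level generation
# ---------------------------------------------------------------------------


def generate_cohort(config: SimulationConfig, outdir: str) -> CohortFiles:
    """Generate a full synthetic cohort under ``outdir``.

    Emits genome FASTA, GTF, VCF (with SpliceAI-format INFO), a
    classification TSV, a protein-domain TSV, and a ground-truth TSV.
    Every plant is verified against the sequence-surgery oracle before
    anything is written; identical configs produce byte-identical files.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    builders = [
        build_gene(rng, config, f"gene{i + 1:04d}", "+" if i % 2 == 0 else "-")
        for i in range(config.n_genes)
    ]

    n_variants = config.n_genes * config.variants_per_gene
    categories = list(config.category_mix)
    probs = np.array([config.category_mix[c] for c in categories])
    drawn = [categories[i] for i in rng.choice(len(categories), size=n_variants, p=probs)]

    for category in drawn:
        gene_order = rng.permutation(len(builders))
        for gi in gene_order:
            try:
                plant_rescue_variant(builders[gi], category, rng)
                break
            except GenerationError:
                continue
        else:
            raise GenerationError(
                f"no gene in the cohort can host a {category.value} plant"
            )

    genome, assembled = assemble_genome(builders, config, rng)

    # assign ids in genomic order for a tidy VCF
    flat = []
    for ag in assembled:
        for v, rec in zip(ag.variants, ag.plant_records):
            flat.append((ag, v, rec))
    flat.sort(key=lambda item: (item[1].chrom, item[1].pos))
    vcf_rows, truth = [], []
    for i, (ag, v, rec) in enumerate(flat):
        vid = f"var{i + 1:06d}"
        object.__setattr__(v, "id", vid)  # frozen dataclass; id assigned once
        if rec["category"] in CANDIDATE_PLANT_CATEGORIES:
            ds = round(float(rng.uniform(*config.candidate_ds_range)), 2)
            dp_corr = rec["dp_corrected"]
        else:
            ds = round(float(rng.uniform(*config.noncandidate_ds_range)), 2)
            dp_corr = int(rng.choice([d for d in range(-10, 11) if d != 0]))
            rec["dp_corrected"] = dp_corr
        rec["ds"] = ds
        b = ag.builder
        vcf_rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "id": vid,
                "ref": v.ref,
                "alt": v.alt,
                "spliceai": _spliceai_info(rec, b.strand, b.gene_id, v.alt, ds),
            }
        )
        domain_overlap = None
        if rec["category"] == RescueCategory.CANDIDATE_IN_FRAME_LT10_DOMAIN:
            domain_overlap = True
        elif rec["category"] == RescueCategory.CANDIDATE_IN_FRAME_LT10_NO_DOMAIN:
            domain_overlap = False
        truth.append(
            GroundTruthRecord(
                variant_id=vid,
                transcript_id=b.transcript_id,
                gene_id=b.gene_id,
                category=rec["category"],
                ds_dg=ds,
                dp_dg=dp_corr,
                stop_triplet=rec["stop_triplet"],
                codon_number=rec["codon_number"],
                deleted_nt=rec["deleted_nt"],
                domain_overlap=domain_overlap,
            )
        )

    _verify_plants(genome, assembled)

    import os.path as op

    genome_fa = op.join(outdir, "genome.fa")
    gtf = op.join(outdir, "annotation.gtf")
    vcf = op.join(outdir, "variants.vcf")
    classifications_tsv = op.join(outdir, "classifications.tsv")
    domains_tsv = op.join(outdir, "domains.tsv")
    truth_tsv = op.join(outdir, "truth.tsv")

    write_genome(genome, genome_fa)
    _write_gtf(assembled, gtf)
    _write_vcf(vcf_rows, {c: len(s) for c, s in sorted(genome.items())}, vcf)

    is_cand = [t.category in CANDIDATE_PLANT_CATEGORIES for t in truth]
    class_rows = generate_classifications(
        [t.variant_id for t in truth], is_cand, config, rng
    )
    with open(classifications_tsv, "w") as fh:
        fh.write("variant_id\tclassification\treview_status\n")
        for row in class_rows:
            fh.write(f"{row['variant_id']}\t{row['classification']}\t{row['review_status']}\n")

    domain_rows = _generate_domains(assembled, rng)
    with open(domains_tsv, "w") as fh:
        fh.write("transcript_id\tdomain_name\tstart_residue\tend_residue\n")
        for row in domain_rows:
            fh.write(
                f"{row['transcript_id']}\t{row['domain_name']}\t"
                f"{row['start_residue']}\t{row['end_residue']}\n"
            )

    with open(truth_tsv, "w") as fh:
        fh.write(
            "variant_id\ttranscript_id\tgene_id\tcategory\tds_dg\tdp_dg\t"
            "stop_triplet\tcodon_number\tdeleted_nt\tdomain_overlap\n"
        )
        for t in truth:
            fh.write(
                f"{t.variant_id}\t{t.transcript_id}\t{t.gene_id}\t{t.category.value}\t"
                f"{t.ds_dg}\t{t.dp_dg}\t{t.stop_triplet}\t{t.codon_number}\t"
                f"{'' if t.deleted_nt is None else t.deleted_nt}\t"
                f"{'' if t.domain_overlap is None else t.domain_overlap}\n"
            )

    return CohortFiles(
        genome_fa=genome_fa,
        gtf=gtf,
        vcf=vcf,
        classifications_tsv=classifications_tsv,
        domains_tsv=domains_tsv,
        truth_tsv=truth_tsv,
        truth=truth,
    )


def read_truth(path: str) -> List[GroundTruthRecord]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for r in df.itertuples():
        out.append(
            GroundTruthRecord(
                variant_id=r.variant_id,
                transcript_id=r.transcript_id,
                gene_id=r.gene_id,
                category=RescueCategory(r.category),
                ds_dg=float(r.ds_dg),
                dp_dg=int(r.dp_dg),
                stop_triplet=r.stop_triplet,
                codon_number=int(r.codon_number),
                deleted_nt=int(r.deleted_nt) if r.deleted_nt != "" else None,
                domain_overlap={"True": True, "False": False}.get(r.domain_overlap),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Mirror transform (strand-symmetry checks)
# ---------------------------------------------------------------------------


def mirror_cohort(files: CohortFiles, outdir: str) -> CohortFiles:
    """Reverse-complement every chromosome and remap all coordinates, so a
    strand-symmetric screen must produce identical per-variant results."""
    import os

    os.makedirs(outdir, exist_ok=True)
    from .transcript_io import read_genome

    genome = read_genome(files.genome_fa)
    lengths = {c: len(s) for c, s in genome.items()}
    mirrored = {c: revcomp(s) for c, s in genome.items()}
    genome_fa = os.path.join(outdir, "genome.fa")
    write_genome(mirrored, genome_fa)

    def flip(chrom: str, pos: int) -> int:
        return lengths[chrom] - pos + 1

    gtf = os.path.join(outdir, "annotation.gtf")
    with open(files.gtf) as src, open(gtf, "w") as dst:
        for line in src:
            f = line.rstrip("\n").split("\t")
            start, end = int(f[3]), int(f[4])
            f[3], f[4] = str(flip(f[0], end)), str(flip(f[0], start))
            f[6] = "-" if f[6] == "+" else "+"
            dst.write("\t".join(f) + "\n")

    vcf = os.path.join(outdir, "variants.vcf")
    rows = []
    with open(files.vcf) as src:
        header = []
        for line in src:
            if line.startswith("#"):
                header.append(line)
                continue
            f = line.rstrip("\n").split("\t")
            chrom, pos = f[0], int(f[1])
            f[1] = str(flip(chrom, pos))
            f[3] = complement(f[3])
            f[4] = complement(f[4])
            # SpliceAI: complement the allele, negate genome-oriented DPs
            info = f[7]
            assert info.startswith("SpliceAI=")
            groups = []
            for group in info[len("SpliceAI="):].split(","):
                g = group.split("|")
                g[0] = complement(g[0])
                for i in range(6, 10):
                    if g[i] != ".":
                        g[i] = str(-int(g[i]))
                groups.append("|".join(g))
            f[7] = "SpliceAI=" + ",".join(groups)
            rows.append(f)
    rows.sort(key=lambda f: (f[0], int(f[1])))
    with open(vcf, "w") as dst:
        dst.writelines(header)
        for f in rows:
            dst.write("\t".join(f) + "\n")

    import shutil

    out = CohortFiles(
        genome_fa=genome_fa,
        gtf=gtf,
        vcf=vcf,
        classifications_tsv=os.path.join(outdir, "classifications.tsv"),
        domains_tsv=os.path.join(outdir, "domains.tsv"),
        truth_tsv=os.path.join(outdir, "truth.tsv"),
        truth=list(files.truth),
    )
    shutil.copyfile(files.classifications_tsv, out.classifications_tsv)
    shutil.copyfile(files.domains_tsv, out.domains_tsv)
    shutil.copyfile(files.truth_tsv, out.truth_tsv)
    return out


# ---------------------------------------------------------------------------
# Worked-example fixture (synthetic TSC2-like transcript)
# ---------------------------------------------------------------------------


def tsc2_like_fixture(outdir: str, seed: int = 20548) -> CohortFiles:
    """Synthetic stand-in with the CDS-level geometry of the TSC2 canonical
    transcript's worked example.

    This is NOT the real NM_000548.5 sequence: it is a constructed
    transcript with the same coding-frame geometry — CDS of 5424 nt
    (1807 residues), a C>T nonsense variant at c.4081 (codon 1361 CGA→TGA),
    a gained donor whose junction lies at c.4079 (delta position −2), and a
    variant exon ending at c.4493, so that using the new donor excises
    414 nt and the hybrid junction codon GA+T encodes Asp:
    p.(Glu1360_Ser1498delinsAsp), 7.6% of the CDS, in frame.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_codons = 1808  # 1807 residues + stop
    cds = _random_cds(rng, n_codons)

    def set_codon(number: int, triplet: str) -> None:
        cds[3 * (number - 1) : 3 * number] = list(triplet)

    set_codon(1359, "GCC")  # donor −3 is C (M)
    set_codon(1360, "GAG")  # Glu; bases 1-2 feed the hybrid codon, base 3 is donor +1
    set_codon(1361, "CGA")  # ref Arg; c.4081C>T → TGA occupying donor +2..+4
    set_codon(1362, "GTA")  # Val; bases 1-2 are donor +5..+6
    set_codon(1498, "TCT")  # Ser; base 3 completes the hybrid GAT (Asp)
    set_codon(1808, "TGA")

    utr5, utr3 = 20, 30
    exon_cds_bounds = [(1, 1200), (1201, 2600), (2601, 4493), (4494, 5300), (5301, 5424)]
    b = GeneBuilder(
        gene_id="TSC2_SYNTH",
        transcript_id="TSC2LIKE_SYNTH",
        strand="+",
        exon_lens=[utr5 + 1200, 1400, 1893, 807, 124 + utr3],
        intron_lens=[200, 200, 200, 200],
        utr5=utr5,
        utr3=utr3,
        cds=cds,
        utr5_seq=_random_seq(rng, utr5),
        utr3_seq=_random_seq(rng, utr3),
        intron_seqs=["GT" + _random_seq(rng, 196) + "AG" for _ in range(4)],
    )
    # sanity: the exon layout must reproduce the worked example's geometry
    assert [b.exon_cds_range(k) for k in range(5)] == exon_cds_bounds
    b.plants.append(
        {
            "category": RescueCategory.CANDIDATE_IN_FRAME_LT10_NO_DOMAIN,
            "var_cds": 4081,
            "ref_base": "C",
            "alt_base": "T",
            "stop_triplet": "TGA",
            "codon_number": 1361,
            "deleted_nt": 414,
            "junction_cds": 4079,
            "dp_corrected": -2,
            "exon_index": 3,
        }
    )
    config = SimulationConfig(n_genes=1, seed=seed)
    genome, assembled = assemble_genome([b], config, rng)
    _verify_plants(genome, assembled)
    ag = assembled[0]
    v = ag.variants[0]
    object.__setattr__(v, "id", "tsc2_like_c4081CtoT")

    genome_fa = os.path.join(outdir, "tsc2_like_synthetic.fa")
    gtf = os.path.join(outdir, "tsc2_like_synthetic.gtf")
    vcf = os.path.join(outdir, "tsc2_like_synthetic.vcf")
    domains_tsv = os.path.join(outdir, "tsc2_like_synthetic_domains.tsv")
    write_genome(genome, genome_fa)
    _write_gtf(assembled, gtf)
    rec = ag.plant_records[0]
    _write_vcf(
        [
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "id": v.id,
                "ref": v.ref,
                "alt": v.alt,
                # the published in-silico donor-gain score for this variant
                "spliceai": _spliceai_info(rec, "+", "TSC2_SYNTH", v.alt, 0.80),
            }
        ],
        {c: len(s) for c, s in genome.items()},
        vcf,
    )
    with open(domains_tsv, "w") as fh:
        fh.write("transcript_id\tdomain_name\tstart_residue\tend_residue\n")
        fh.write("TSC2LIKE_SYNTH\tSYNDOM_N\t100\t300\n")

    classifications_tsv = os.path.join(outdir, "tsc2_like_synthetic_classifications.tsv")
    with open(classifications_tsv, "w") as fh:
        fh.write("variant_id\tclassification\treview_status\n")
        fh.write("tsc2_like_c4081CtoT\tVUS\tcriteria provided, single submitter\n")

    truth_tsv = os.path.join(outdir, "tsc2_like_synthetic_truth.tsv")
    with open(truth_tsv, "w") as fh:
        fh.write("variant_id\tcategory\n")
        fh.write("tsc2_like_c4081CtoT\tCANDIDATE_IN_FRAME_LT10_NO_DOMAIN\n")

    return CohortFiles(
        genome_fa=genome_fa,
        gtf=gtf,
        vcf=vcf,
        classifications_tsv=classifications_tsv,
        domains_tsv=domains_tsv,
        truth_tsv=truth_tsv,
        truth=[
            GroundTruthRecord(
                variant_id="tsc2_like_c4081CtoT",
                transcript_id="TSC2LIKE_SYNTH",
                gene_id="TSC2_SYNTH",
                category=RescueCategory.CANDIDATE_IN_FRAME_LT10_NO_DOMAIN,
                ds_dg=0.80,
                dp_dg=-2,
                stop_triplet="TGA",
                codon_number=1361,
                deleted_nt=414,
                domain_overlap=False,
            )
        ],
    )
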
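"""Donor-gain annotations: SpliceAI-format parsing, strand correction, a
position-weight-matrix stand-in scorer, and the rescue-candidacy rule.

Delta positions (DP) follow a contiguous pre-mRNA numbering relative to the
variant with no position zero (…−2, −1, +1, +2…); negative always means 5'
(upstream) of the variant *after* strand correction.  The reported DP of a
gained donor refers, by default, to the LAST EXONIC base of the new
junction (``dp_convention="last-exonic"``): the excised exonic segment
begins at the next base.  The alternative ``"first-intronic"`` convention
shifts the reference base one position 3'.

A nonsense variant is a rescue candidate at a given threshold when its
donor-gain delta score meets the threshold (``>=`` by default) AND its
strand-corrected delta position is strictly below ``dp_exclusive_max``
(default 3) — i.e. the new donor lies at or upstream of the premature stop,
so that using it would splice the stop out before nonsense-mediated decay
could act.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np

from .consequence import StopGainCall
from .transcript_io import GenomeSequences, SnvVariant, TranscriptModel, revcomp

log = logging.getLogger(__name__)

_BASES = "ACGT"


class SpliceAIParseError(ValueError):
    """Malformed SpliceAI INFO value."""


class StrandCorrectionError(ValueError):
    """Attempted to strand-correct an already corrected annotation."""


# ---------------------------------------------------------------------------
# Annotation container and parsing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpliceGainAnnotation:
    """SpliceAI-format delta scores/positions for one variant allele.

    Field order mirrors the standard 10-field pipe layout
    ``ALLELE|SYMBOL|DS_AG|DS_AL|DS_DG|DS_DL|DP_AG|DP_AL|DP_DG|DP_DL``;
    missing (".") fields are ``None``.
    """

    allele: Optional[str]
    symbol: Optional[str]
    ds_ag: Optional[float]
    ds_al: Optional[float]
    ds_dg: Optional[float]
    ds_dl: Optional[float]
    dp_ag: Optional[int]
    dp_al: Optional[int]
    dp_dg: Optional[int]
    dp_dl: Optional[int]
    strand_corrected: bool = False
    raw: Optional[Tuple[str, ...]] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name in ("ds_ag", "ds_al", "ds_dg", "ds_dl"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def to_info(self) -> str:
        """Serialize back to the pipe layout.

        An unmodified parsed annotation round-trips byte-for-byte (the raw
        tokens are kept); a strand-corrected one is re-formatted.
        """
        if self.raw is not None and not self.strand_corrected:
            return "|".join(self.raw)

        def fmt(v, kind):
            if v is None:
                return "."
            return f"{v:.2f}" if kind == "f" else str(v)

        return "|".join(
            [
                self.allele or ".",
                self.symbol or ".",
                fmt(self.ds_ag, "f"),
                fmt(self.ds_al, "f"),
                fmt(self.ds_dg, "f"),
                fmt(self.ds_dl, "f"),
                fmt(self.dp_ag, "i"),
                fmt(self.dp_al, "i"),
                fmt(self.dp_dg, "i"),
                fmt(self.dp_dl, "i"),
            ]
        )


def parse_spliceai_info(info_value: str) -> List[SpliceGainAnnotation]:
    """Parse a SpliceAI INFO value (comma-separated pipe groups)."""
    annotations = []
    for group in info_value.split(","):
        fields = group.split("|")
        if len(fields) != 10:
            raise SpliceAIParseError(
                f"expected 10 pipe-separated fields, got {len(fields)} in {group!r}"
            )

        def opt(s, conv):
            return None if s == "." else conv(s)

        annotations.append(
            SpliceGainAnnotation(
                allele=opt(fields[0], str),
                symbol=opt(fields[1], str),
                ds_ag=opt(fields[2], float),
                ds_al=opt(fields[3], float),
                ds_dg=opt(fields[4], float),
                ds_dl=opt(fields[5], float),
                dp_ag=opt(fields[6], int),
                dp_al=opt(fields[7], int),
                dp_dg=opt(fields[8], int),
                dp_dl=opt(fields[9], int),
                raw=tuple(fields),
            )
        )
    return annotations


def strand_correct(a: SpliceGainAnnotation, strand: str) -> SpliceGainAnnotation:
    """Re-sign delta positions into pre-mRNA orientation.

    Raw SpliceAI delta positions are reference-genome-oriented; for a minus
    strand transcript all four are negated so that negative always means 5'
    (upstream) in pre-mRNA orientation.  Guarded against double correction.
    """
    if a.strand_corrected:
        raise StrandCorrectionError("annotation is already strand-corrected")
    if strand not in "+-":
        raise ValueError(f"invalid strand {strand!r}")

    def flip(v):
        return None if v is None else (-v if strand == "-" else v)

    return replace(
        a,
        dp_ag=flip(a.dp_ag),
        dp_al=flip(a.dp_al),
        dp_dg=flip(a.dp_dg),
        dp_dl=flip(a.dp_dl),
        strand_corrected=True,
    )


# ---------------------------------------------------------------------------
# Delta-position conventions
# ---------------------------------------------------------------------------


def offset_to_dp(offset: int) -> int:
    """Plain pre-mRNA offset → the no-zero delta-position numbering."""
    return offset if offset < 0 else offset + 1


def dp_to_offset(dp: int) -> int:
    """Inverse of :func:`offset_to_dp`."""
    if dp == 0:
        raise ValueError("delta position 0 does not exist in this numbering")
    return dp if dp < 0 else dp - 1


def resolve_junction_genomic(v: SnvVariant, strand: str, dp_dg: int, dp_convention: str = "last-exonic") -> int:
    """Genomic coordinate of the new junction's last exonic base implied by
    a strand-corrected donor-gain delta position."""
    offset = dp_to_offset(dp_dg)
    if dp_convention == "first-intronic":
        offset -= 1  # reported base is one 3' of the last exonic base
    elif dp_convention != "last-exonic":
        raise ValueError(f"unknown dp convention {dp_convention!r}")
    return v.pos + offset if strand == "+" else v.pos - offset


# ---------------------------------------------------------------------------
# Screen parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenParams:
    """Tunable thresholds of the rescue screen.

    ``dg_thresholds`` are the donor-gain delta-score cutoffs (0.2 high
    recall / 0.5 / 0.8 high precision); ``dp_exclusive_max`` is the strict
    upper bound on the delta position (candidate iff DP < 3);
    ``inframe_fraction_max`` is the strict in-frame deletion size limit as
    a fraction of the coding sequence (deletions below 10% of the CDS are
    the plausible rescues).
    """

    dg_thresholds: Tuple[float, ...] = (0.2, 0.5, 0.8)
    dp_exclusive_max: int = 3
    inframe_fraction_max: float = 0.10
    threshold_inclusive: bool = True
    dp_convention: str = "last-exonic"

    def __post_init__(self) -> None:
        ts = self.dg_thresholds
        if not ts or list(ts) != sorted(set(ts)):
            raise ValueError("dg_thresholds must be strictly increasing")
        if not all(0.0 <= t <= 1.0 for t in ts):
            raise ValueError("dg_thresholds must lie in [0, 1]")
        if self.dp_convention not in ("last-exonic", "first-intronic"):
            raise ValueError(f"unknown dp convention {self.dp_convention!r}")


def is_candidate(
    call: StopGainCall,
    a: Optional[SpliceGainAnnotation],
    p: ScreenParams,
    threshold: float,
) -> bool:
    """Apply the candidacy rule: DS_DG meets the threshold and the
    strand-corrected DP_DG is strictly below ``p.dp_exclusive_max``."""
    if a is None:
        return False
    if not a.strand_corrected:
        raise ValueError("annotation must be strand-corrected before candidacy")
    if a.ds_dg is None or a.dp_dg is None:
        log.debug(
            "variant %s: missing DS_DG/DP_DG, not a candidate", call.variant.id
        )
        return False
    meets = a.ds_dg >= threshold if p.threshold_inclusive else a.ds_dg > threshold
    return meets and a.dp_dg < p.dp_exclusive_max


# ---------------------------------------------------------------------------
# PWM stand-in scorer
# ---------------------------------------------------------------------------

#: Donor motif positions covered by the matrix: last three exonic bases
#: (−3..−1, consensus MAG) and first six intronic bases (+1..+6, GTRAGT).
PWM_POSITIONS = (-3, -2, -1, 1, 2, 3, 4, 5, 6)

_DEFAULT_FREQS = np.array(
    [
        #  A      C      G      T
        [0.33, 0.37, 0.18, 0.12],  # -3 (M)
        [0.60, 0.13, 0.14, 0.13],  # -2 (A)
        [0.08, 0.04, 0.81, 0.07],  # -1 (G)
        [0.0033, 0.0033, 0.99, 0.0034],  # +1 (G)
        [0.0033, 0.0033, 0.0034, 0.99],  # +2 (T)
        [0.60, 0.02, 0.35, 0.03],  # +3 (R)
        [0.70, 0.08, 0.12, 0.10],  # +4 (A)
        [0.07, 0.05, 0.82, 0.06],  # +5 (G)
        [0.15, 0.12, 0.13, 0.60],  # +6 (T)
    ]
)


@dataclass(frozen=True)
class DonorPwm:
    """Log-odds donor-site model over positions −3..+6 with a logistic map
    from score to a [0, 1] site probability.

    The logistic midpoint/scale are fixed so that the two contract anchors
    hold on synthetic sequence: a variant completing a full consensus donor
    scores a gain ≥ 0.8, and a variant creating no GT dinucleotide scores
    ≤ 0.05.
    """

    freqs: np.ndarray = field(default_factory=lambda: _DEFAULT_FREQS.copy())
    background: float = 0.25
    logistic_mid: float = 7.0
    logistic_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.freqs.shape != (9, 4):
            raise ValueError("frequency table must be 9 positions x ACGT")
        if not np.allclose(self.freqs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each position's frequencies must sum to 1")

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.freqs / self.background)

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.freqs.argmax(axis=1))

    def score(self, ninemer: str) -> float:
        """Sum of per-position log-odds; -inf for any non-ACGT base."""
        lo = self.log_odds
        total = 0.0
        for i, base in enumerate(ninemer):
            j = _BASES.find(base)
            if j < 0:
                return float("-inf")
            total += lo[i, j]
        return total

    def site_probability(self, score: float) -> float:
        if math.isinf(score):
            return 0.0
        return 1.0 / (1.0 + math.exp(-(score - self.logistic_mid) / self.logistic_scale))


def scan_donor_gain(
    seq: str,
    var_index: int,
    alt_base: str,
    pwm: Optional[DonorPwm] = None,
    window: int = 50,
) -> Tuple[float, Optional[int]]:
    """Best donor-gain (delta score, pre-mRNA offset of the last exonic
    base) created by substituting ``alt_base`` at 0-based ``var_index`` of
    the pre-mRNA-oriented string ``seq``.

    Only alternate 9-mers carrying the obligate GT at +1..+2 count as
    donor sites; the delta score is the logistic site probability of the
    alternate 9-mer minus that of the reference 9-mer, maximized over all
    junction placements within ``window`` nt of the variant.  Ties prefer
    the junction closest to the variant, upstream first.
    """
    if pwm is None:
        pwm = DonorPwm()
    alt_seq = seq[:var_index] + alt_base + seq[var_index + 1 :]
    best: Optional[Tuple[float, int]] = None
    lo_j = max(2, var_index - window)
    hi_j = min(len(seq) - 7, var_index + window)
    for j in range(lo_j, hi_j + 1):
        ref9 = seq[j - 2 : j + 7]
        alt9 = alt_seq[j - 2 : j + 7]
        if alt9[3:5] != "GT":
            continue
        gain = pwm.site_probability(pwm.score(alt9)) - pwm.site_probability(pwm.score(ref9))
        if gain <= 0.0:
            continue
        offset = j - var_index
        if best is None or (gain, -abs(offset), -offset) > (
            best[0],
            -abs(best[1]),
            -best[1],
        ):
            best = (gain, offset)
    if best is None:
        return 0.0, None
    return best[0], best[1]


def pwm_delta_donor(
    v: SnvVariant,
    t: TranscriptModel,
    g: GenomeSequences,
    pwm: Optional[DonorPwm] = None,
    window: int = 50,
    dp_convention: str = "last-exonic",
) -> Tuple[float, Optional[int]]:
    """Deterministic donor-gain (DS_DG, DP_DG) stand-in for one variant.

    Scans the pre-mRNA sequence around the variant (in transcript
    orientation) for the donor motif whose log-odds gain from the variant
    substitution is largest.  The returned delta position is already
    strand-corrected (pre-mRNA-oriented, no position zero).
    """
    span_lo, span_hi = t.span
    if v.chrom != t.chrom or not span_lo - window <= v.pos <= span_hi + window:
        raise ValueError(f"variant {v.chrom}:{v.pos} outside transcript ± window")
    chrom_seq = g[t.chrom]
    lo = max(1, v.pos - window - 8)
    hi = min(len(chrom_seq), v.pos + window + 8)
    region = chrom_seq[lo - 1 : hi]
    if t.strand == "+":
        var_index = v.pos - lo
        alt = v.alt
    else:
        region = revcomp(region)
        var_index = hi - v.pos
        alt = revcomp(v.alt)
    ds, offset = scan_donor_gain(region, var_index, alt, pwm=pwm, window=window)
    if offset is None:
        return ds, None
    if dp_convention == "first-intronic":
        offset += 1
    elif dp_convention != "last-exonic":
        raise ValueError(f"unknown dp convention {dp_convention!r}")
    return ds, offset_to_dp(offset)


def annotation_from_pwm(
    v: SnvVariant,
    t: TranscriptModel,
    g: GenomeSequences,
    pwm: Optional[DonorPwm] = None,
    window: int = 50,
    dp_convention: str = "last-exonic",
) -> SpliceGainAnnotation:
    """Wrap the PWM scorer's output in a (strand-corrected) annotation."""
    ds, dp = pwm_delta_donor(v, t, g, pwm=pwm, window=window, dp_convention=dp_convention)
    return SpliceGainAnnotation(
        allele=v.alt,
        symbol=t.gene_id,
        ds_ag=None,
        ds_al=None,
        ds_dg=ds,
        ds_dl=None,
        dp_ag=None,
        dp_al=None,
        dp_dg=dp,
        dp_dl=None,
        strand_corrected=True,
    )
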
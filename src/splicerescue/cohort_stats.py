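"""Cohort-level summaries and comparisons for the rescue screen.

Covers the donor-gain score bins, the TAA/TGA stop-triplet enrichment
among rescue candidates, the pathogenic/likely-pathogenic (LP/P)
classification deficit, review-confidence (star-rating) comparisons, and
headline rate formatting.

The 2×2 chi-square and the rank-sum W statistic are implemented here in
closed form (exact enumeration of the rank-sum null when both groups have
n ≤ 8); scipy's equivalents serve as independent cross-checks in the test
suite, not as the implementation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm, rankdata

log = logging.getLogger(__name__)

LP_P_CLASSES = frozenset({"P", "LP"})

#: ClinVar review-status → star-rating mapping (public ClinVar documentation,
#: fixed here for determinism; keys are lowercased).
STAR_MAP = {
    "practice guideline": 4,
    "reviewed by expert panel": 3,
    "criteria provided, multiple submitters, no conflicts": 2,
    "criteria provided, single submitter": 1,
    "criteria provided, conflicting classifications": 1,
    "criteria provided, conflicting interpretations": 1,
    "no assertion criteria provided": 0,
    "no assertion provided": 0,
    "no classification provided": 0,
    "no classification for the single variant": 0,
}


class DegenerateGroupError(ValueError):
    """A statistical comparison received an empty or zero-margin group."""


@dataclass(frozen=True)
class ClassificationRecord:
    """ClinVar-like classification of one variant."""

    variant_id: str
    classification: str  # one of P, LP, VUS, LB, B, other
    review_status: str
    stars: int

    def __post_init__(self) -> None:
        if not 0 <= self.stars <= 4:
            raise ValueError(f"stars {self.stars} outside 0..4")

    @property
    def is_lp_p(self) -> bool:
        return self.classification in LP_P_CLASSES


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a two-group comparison."""

    n_a: int
    n_b: int
    summary_a: float
    summary_b: float
    statistic_name: str
    statistic: float
    p_value: float
    two_sided: bool = True
    extras: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def to_dict(self) -> Dict[str, object]:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "summary_a": self.summary_a,
            "summary_b": self.summary_b,
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "two_sided": self.two_sided,
            **{k: v for k, v in self.extras.items()},
        }


def stars_from_review_status(review_status: str) -> int:
    """Map a ClinVar-style review status to its 0–4 star rating; unknown
    statuses map to 0 with a warning."""
    key = review_status.strip().lower()
    if key in STAR_MAP:
        return STAR_MAP[key]
    log.warning("unknown review status %r; assigning 0 stars", review_status)
    return 0


def read_classification_table(path: str) -> List[ClassificationRecord]:
    """TSV with columns variant_id, classification, review_status."""
    df = pd.read_csv(path, sep="\t")
    return [
        ClassificationRecord(
            variant_id=str(r.variant_id),
            classification=str(r.classification),
            review_status=str(r.review_status),
            stars=stars_from_review_status(str(r.review_status)),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# 2x2 chi-square
# ---------------------------------------------------------------------------


def chi_square_2x2(table: Sequence[Sequence[float]], yates: bool = False) -> ComparisonResult:
    """Pearson chi-square on a 2×2 table (df = 1, two-sided p).

    No continuity correction by default; ``yates=True`` applies it.
    Raises :class:`DegenerateGroupError` when any margin is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = t.sum()
    if (row == 0).any() or (col == 0).any():
        raise DegenerateGroupError(f"zero margin in table {t.tolist()}")
    expected = np.outer(row, col) / n
    diff = np.abs(t - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    p = float(chi2_dist.sf(stat, df=1))
    return ComparisonResult(
        n_a=int(row[0]),
        n_b=int(row[1]),
        summary_a=float(t[0, 0] / row[0]),
        summary_b=float(t[1, 0] / row[1]),
        statistic_name="chi-square",
        statistic=stat,
        p_value=p,
        extras={"df": 1, "yates": yates, "table": t.tolist()},
    )


# ---------------------------------------------------------------------------
# Rank-sum (Wilcoxon rank-sum / Mann-Whitney W)
# ---------------------------------------------------------------------------


def _rank_sum_exact_p(pooled_ranks: np.ndarray, n_a: int, u_obs: float) -> float:
    """Permutation-exact two-sided p for the rank-sum statistic, by
    enumeration of all group-A position assignments (ties handled by
    conditioning on the observed pooled values)."""
    n = len(pooled_ranks)
    us = []
    base = n_a * (n_a + 1) / 2.0
    for idx in combinations(range(n), n_a):
        us.append(pooled_ranks[list(idx)].sum() - base)
    us = np.asarray(us)
    lo = float((us <= u_obs + 1e-9).mean())
    hi = float((us >= u_obs - 1e-9).mean())
    return min(1.0, 2.0 * min(lo, hi))


def compare_star_ratings(
    group_a: Sequence[float], group_b: Sequence[float], exact_max_n: int = 8
) -> ComparisonResult:
    """Rank-sum comparison of two samples (e.g. star ratings).

    Reports W (the Mann-Whitney statistic of group A, i.e. the rank sum of
    group A minus its minimum) and a two-sided p: exact by enumeration
    when both groups have at most ``exact_max_n`` observations, otherwise
    a normal approximation with tie correction and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DegenerateGroupError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a, n_b = len(a), len(b)
    w = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
    if n_a <= exact_max_n and n_b <= exact_max_n:
        p = _rank_sum_exact_p(ranks, n_a, w)
        method = "exact"
    else:
        n = n_a + n_b
        mean_w = n_a * n_b / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float((tie_counts**3 - tie_counts).sum())
        var_w = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var_w <= 0:
            p = 1.0
        else:
            z = (w - mean_w - 0.5 * np.sign(w - mean_w)) / math.sqrt(var_w)
            p = float(min(1.0, 2.0 * norm.sf(abs(z))))
        method = "normal-approx"
    return ComparisonResult(
        n_a=n_a,
        n_b=n_b,
        summary_a=float(a.mean()),
        summary_b=float(b.mean()),
        statistic_name="W",
        statistic=w,
        p_value=p,
        extras={"method": method},
    )


# ---------------------------------------------------------------------------
# Screen-specific comparisons
# ---------------------------------------------------------------------------


def triplet_enrichment(
    triplet_labels: Sequence[str], candidate_flags: Sequence[bool]
) -> ComparisonResult:
    """TAA/TGA-vs-TAG enrichment among rescue candidates.

    ``triplet_labels`` are "TAA_or_TGA"/"TAG" per stop-gain call;
    ``candidate_flags`` mark the rescue candidates.  Builds the 2×2 of
    {TAA/TGA, TAG} × {candidate, rest} and reports the chi-square plus
    each group's TAA/TGA percentage.
    """
    if len(triplet_labels) != len(candidate_flags):
        raise ValueError("label/flag lengths differ")
    cand_aa = sum(1 for l, f in zip(triplet_labels, candidate_flags) if f and l == "TAA_or_TGA")
    cand_ag = sum(1 for l, f in zip(triplet_labels, candidate_flags) if f and l == "TAG")
    rest_aa = sum(1 for l, f in zip(triplet_labels, candidate_flags) if not f and l == "TAA_or_TGA")
    rest_ag = sum(1 for l, f in zip(triplet_labels, candidate_flags) if not f and l == "TAG")
    if cand_aa + cand_ag == 0 or rest_aa + rest_ag == 0:
        raise DegenerateGroupError("need at least one candidate and one non-candidate")
    result = chi_square_2x2([[cand_aa, cand_ag], [rest_aa, rest_ag]])
    return ComparisonResult(
        n_a=result.n_a,
        n_b=result.n_b,
        summary_a=100.0 * result.summary_a,  # % TAA/TGA among candidates
        summary_b=100.0 * result.summary_b,
        statistic_name=result.statistic_name,
        statistic=result.statistic,
        p_value=result.p_value,
        extras={**result.extras, "summary_units": "percent TAA/TGA"},
    )


def compare_lp_p(
    candidates: Sequence[ClassificationRecord],
    comparators: Sequence[ClassificationRecord],
) -> ComparisonResult:
    """LP/P proportion among rescue candidates versus the remaining
    nonsense variants (callers restrict comparators to genes containing at
    least one candidate)."""
    if not candidates or not comparators:
        raise DegenerateGroupError("both groups must be non-empty")
    c_lp = sum(r.is_lp_p for r in candidates)
    o_lp = sum(r.is_lp_p for r in comparators)
    table = [
        [c_lp, len(candidates) - c_lp],
        [o_lp, len(comparators) - o_lp],
    ]
    p_a, p_b = c_lp / len(candidates), o_lp / len(comparators)
    if p_a == p_b and p_a in (0.0, 1.0):
        # identical degenerate proportions: no departure from independence
        result = ComparisonResult(
            n_a=len(candidates), n_b=len(comparators), summary_a=p_a, summary_b=p_b,
            statistic_name="chi-square", statistic=0.0, p_value=1.0,
            extras={"df": 1, "yates": False, "table": [list(map(float, r)) for r in table]},
        )
    else:
        result = chi_square_2x2(table)
    return ComparisonResult(
        n_a=len(candidates),
        n_b=len(comparators),
        summary_a=c_lp / len(candidates),
        summary_b=o_lp / len(comparators),
        statistic_name=result.statistic_name,
        statistic=result.statistic,
        p_value=result.p_value,
        extras={**result.extras, "summary_units": "proportion LP/P"},
    )


# ---------------------------------------------------------------------------
# Score bins
# ---------------------------------------------------------------------------

#: Donor-gain delta-score bins, highest first: [0.8–1], [0.5–0.8), [0.2–0.5).
SCORE_BINS: Tuple[Tuple[float, float, str], ...] = (
    (0.8, 1.0 + 1e-12, "[0.8-1]"),
    (0.5, 0.8, "[0.5-0.8)"),
    (0.2, 0.5, "[0.2-0.5)"),
)


@dataclass(frozen=True)
class ScoreBinSummary:
    """Per-dataset counts/proportions of nonsense variants whose donor-gain
    score falls in each bin, restricted to delta positions < ``dp_max``."""

    per_dataset: Dict[str, Dict[str, object]]
    overall: Dict[str, float]  # proportion with DS >= threshold at DP < dp_max
    dp_max: int


def summarize_bins(
    records: Iterable[Tuple[str, Optional[float], Optional[int]]],
    dp_max: int = 3,
    thresholds: Sequence[float] = (0.2, 0.5, 0.8),
) -> ScoreBinSummary:
    """Bin nonsense variants by donor-gain delta score.

    ``records`` are (dataset_label, ds_dg, strand-corrected dp_dg) per
    nonsense variant; variants with missing scores contribute to the
    denominators only.  Proportions are invariant under record order and
    dataset relabelling.
    """
    per: Dict[str, Dict[str, object]] = {}
    all_rows = list(records)
    for label, ds, dp in all_rows:
        entry = per.setdefault(
            label,
            {"n_total": 0, "bin_counts": {name: 0 for *_, name in SCORE_BINS}},
        )
        entry["n_total"] += 1
        if ds is None or dp is None or dp >= dp_max:
            continue
        for lo, hi, name in SCORE_BINS:
            if lo <= ds < hi:
                entry["bin_counts"][name] += 1
                break
    for entry in per.values():
        n = entry["n_total"]
        entry["bin_proportions"] = {
            name: (count / n if n else 0.0) for name, count in entry["bin_counts"].items()
        }
    n_all = len(all_rows)
    overall = {}
    for thr in thresholds:
        hits = sum(
            1
            for _, ds, dp in all_rows
            if ds is not None and dp is not None and ds >= thr and dp < dp_max
        )
        overall[f">={thr}"] = hits / n_all if n_all else 0.0
    return ScoreBinSummary(per_dataset=per, overall=overall, dp_max=dp_max)


# ---------------------------------------------------------------------------
# Headline rates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateSummary:
    percent: float  # rounded to 1 decimal place
    rate_text: str  # "1 in N"


def rate_summary(numerator: int, denominator: int) -> RateSummary:
    """Percent (1 d.p.) and reciprocal "1 in N" rate text."""
    if denominator <= 0 or numerator > denominator or numerator < 0:
        raise ValueError(f"invalid rate {numerator}/{denominator}")
    if numerator == 0:
        return RateSummary(percent=0.0, rate_text="0")
    percent = round(100.0 * numerator / denominator, 1)
    return RateSummary(percent=percent, rate_text=f"1 in {round(denominator / numerator)}")
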
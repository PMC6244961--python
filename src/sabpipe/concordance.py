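"""Intraindividual concordance of one serum across 2x2 assay conditions.

Each serum is measured under four conditions: two vendor bead panels
(LS = LABScreen, LC = LIFECODES) crossed with two secondary detection
antibodies (FcMonoIgG, a 1:1 Fc-specific monoclonal; IgHPolyFab, a
polyclonal F(ab')2 capable of signal amplification).  Comparisons are
restricted to antigens common to both panels.  This module provides the
per-locus reactive counts, LS-vs-LC tallies, exact paired nonparametric
tests (sign test and Wilcoxon signed-rank), per-condition median MFIs,
and the reactivity-group classification (1A-1C / 2A-2C).

The exact Wilcoxon signed-rank null distribution is computed by a
generating-function convolution over the (doubled, hence integer)
mid-ranks, which handles tied absolute differences; zero differences are
dropped.  For n > 25 a normal approximation with continuity and tie
correction is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import SerumProfile
from .panels import Antigen, Locus

__all__ = [
    "ConditionQuartet",
    "GroupLabel",
    "SignTestResult",
    "WilcoxonResult",
    "count_reactive",
    "tally_beadsets",
    "sign_test_exact",
    "wilcoxon_signed_rank_exact",
    "classify_serum_group",
    "median_positive_mfi",
    "per_serum_summary",
    "cohort_summary",
    "DEFAULT_HIGH_CUTOFF",
    "GROUP1_MIN_ANTIGENS",
]

VENDORS = ("LS", "LC")
SECONDARIES = ("FcMonoIgG", "IgHPolyFab")

DEFAULT_HIGH_CUTOFF = 1000.0
#: minimum positive antigens (in the maximal condition) for Group 1
GROUP1_MIN_ANTIGENS = 5
#: minimum high-MFI antigens for a vendor to count as consistently reactive
_HIGH_MIN = 2


class GroupLabel(str, Enum):
    NONREACTIVE = "nonreactive"
    G1A = "1A"
    G1B = "1B"
    G1C = "1C"
    G2A = "2A"
    G2B = "2B"
    G2C = "2C"


@dataclass
class ConditionQuartet:
    """The four (vendor x secondary) profiles of one serum, on one antigen
    universe (the common set)."""

    serum_id: str
    profiles: Dict[Tuple[str, str], SerumProfile] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [k for k in self._keys() if k not in self.profiles]
        if missing:
            raise ValueError(f"quartet {self.serum_id}: missing conditions {missing}")
        cutoffs = {p.cutoff for p in self.profiles.values()}
        dilutions = {p.dilution for p in self.profiles.values()}
        if len(cutoffs) > 1 or len(dilutions) > 1:
            raise ValueError(
                f"quartet {self.serum_id}: profiles disagree on cutoff/dilution"
            )
        universes = {
            frozenset(r.antigen for r in p.records.values())
            for p in self.profiles.values()
        }
        if len(universes) > 1:
            raise ValueError(
                f"quartet {self.serum_id}: profiles cover different antigen sets; "
                "restrict all four to the common-antigen universe first"
            )

    @staticmethod
    def _keys() -> List[Tuple[str, str]]:
        return [(v, s) for v in VENDORS for s in SECONDARIES]

    def profile(self, vendor: str, secondary: str) -> SerumProfile:
        return self.profiles[(vendor, secondary)]

    def restricted_to(self, antigens: Iterable[Antigen]) -> "ConditionQuartet":
        keep = frozenset(antigens)
        return ConditionQuartet(
            serum_id=self.serum_id,
            profiles={k: p.restrict(keep) for k, p in self.profiles.items()},
        )


def count_reactive(profile: SerumProfile, locus: Optional[Locus] = None) -> int:
    """Number of positive antigens in the profile (optionally at one locus)."""
    n = 0
    for rec in profile.records.values():
        if not rec.positive:
            continue
        antigen = rec.antigen
        rec_locus = antigen.locus if hasattr(antigen, "locus") else antigen[0].locus
        if locus is None or rec_locus is locus:
            n += 1
    return n


def tally_beadsets(quartets: Sequence[ConditionQuartet],
                   locus: Optional[Locus], secondary: str) -> Tuple[int, int, int]:
    """Per-serum LS-vs-LC reactive-count comparison: (n_gt, n_eq, n_lt).

    Only sera with a nonzero count on at least one vendor are tallied.
    """
    n_gt = n_eq = n_lt = 0
    for q in quartets:
        ls = count_reactive(q.profile("LS", secondary), locus)
        lc = count_reactive(q.profile("LC", secondary), locus)
        if ls == 0 and lc == 0:
            continue
        if ls > lc:
            n_gt += 1
        elif ls < lc:
            n_lt += 1
        else:
            n_eq += 1
    return n_gt, n_eq, n_lt


class SignTestResult(NamedTuple):
    n_pos: int
    n_neg: int
    n_ties: int
    p_greater: float  # H1: x tends to exceed y
    p_less: float
    p_two_sided: float


def sign_test_exact(pairs: Sequence[Tuple[float, float]]) -> SignTestResult:
    """Exact binomial sign test on paired observations; ties dropped."""
    diffs = [x - y for x, y in pairs]
    n_pos = sum(d > 0 for d in diffs)
    n_neg = sum(d < 0 for d in diffs)
    n = n_pos + n_neg
    if n == 0:
        raise ValueError("sign test needs at least one non-tied pair")
    p_greater = stats.binomtest(n_pos, n, 0.5, alternative="greater").pvalue
    p_less = stats.binomtest(n_pos, n, 0.5, alternative="less").pvalue
    p_two = stats.binomtest(n_pos, n, 0.5, alternative="two-sided").pvalue
    return SignTestResult(n_pos, n_neg, len(diffs) - n, p_greater, p_less, p_two)


class WilcoxonResult(NamedTuple):
    w_plus: float
    n_used: int
    p_greater: float
    p_less: float
    p_two_sided: float
    method: str  # "exact" or "normal"


_EXACT_N_MAX = 25


def _exact_wplus_distribution(doubled_ranks: Sequence[int]) -> np.ndarray:
    """Counts of each achievable doubled W+ value over all 2^n sign patterns."""
    total = int(sum(doubled_ranks))
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    upper = 0
    for r in doubled_ranks:
        upper += int(r)
        counts[int(r):upper + 1] += counts[0:upper + 1 - int(r)]
    return counts


def wilcoxon_signed_rank_exact(pairs: Sequence[Tuple[float, float]]) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped; tied absolute differences get mid-ranks.
    Exact enumeration of the null for n <= 25, else a normal approximation
    with continuity correction and the usual tie correction of the variance.
    """
    diffs = np.asarray([x - y for x, y in pairs], dtype=float)
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        raise ValueError("Wilcoxon signed-rank test needs a non-zero difference")
    ranks = stats.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())

    if n <= _EXACT_N_MAX:
        doubled = np.rint(2 * ranks).astype(int)
        counts = _exact_wplus_distribution(doubled)
        total = counts.sum()  # == 2**n
        s_obs = int(round(2 * w_plus))
        p_greater = counts[s_obs:].sum() / total
        p_less = counts[:s_obs + 1].sum() / total
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
        sd = math.sqrt(var)
        p_greater = stats.norm.sf((w_plus - 0.5 - mean) / sd)
        p_less = stats.norm.cdf((w_plus + 0.5 - mean) / sd)
        method = "normal"
    p_two = min(1.0, 2.0 * min(p_greater, p_less))
    return WilcoxonResult(w_plus, n, float(p_greater), float(p_less),
                          float(p_two), method)


def median_positive_mfi(profile: SerumProfile) -> Optional[float]:
    """Median normalized MFI over positive records; None when none positive."""
    values = [r.normalized_mfi for r in profile.records.values() if r.positive]
    if not values:
        return None
    return float(np.median(values))


def _high_count(quartet: ConditionQuartet, vendor: str, high_cutoff: float) -> int:
    """Antigens at or above the high-MFI cutoff on a vendor, max over secondaries."""
    best = 0
    for secondary in SECONDARIES:
        profile = quartet.profile(vendor, secondary)
        n = sum(r.normalized_mfi >= high_cutoff for r in profile.records.values())
        best = max(best, n)
    return best


def classify_serum_group(quartet: ConditionQuartet,
                         high_cutoff: float = DEFAULT_HIGH_CUTOFF,
                         group1_min: int = GROUP1_MIN_ANTIGENS,
                         high_min: int = _HIGH_MIN) -> GroupLabel:
    """Reactivity-group label for one serum.

    Size: Group 1 when the condition with the most positive antigens reaches
    ``group1_min`` (default 5), Group 2 otherwise; nonreactive if no condition
    has a positive antigen.  Pattern letter, from the count of antigens at or
    above ``high_cutoff`` per vendor (max over secondaries), H(v):

    * C - both vendors consistently high: H(LS) >= 2 and H(LC) >= 2
    * B - exactly one vendor high: one H >= 2
    * A - positives exist but reactivity stays sub-high (or is confined to
      one vendor at sub-high MFI): neither H >= 2
    """
    max_pos = max(
        count_reactive(quartet.profile(v, s)) for v in VENDORS for s in SECONDARIES
    )
    if max_pos == 0:
        return GroupLabel.NONREACTIVE
    size = "1" if max_pos >= group1_min else "2"
    high = {v: _high_count(quartet, v, high_cutoff) for v in VENDORS}
    n_high_vendors = sum(h >= high_min for h in high.values())
    letter = {2: "C", 1: "B", 0: "A"}[n_high_vendors]
    return GroupLabel(size + letter)


def per_serum_summary(quartets: Sequence[ConditionQuartet],
                      loci: Sequence[Locus]) -> pd.DataFrame:
    """Per-serum reactive counts per condition and locus, plus group label."""
    rows = []
    for q in quartets:
        row: Dict[str, object] = {"serum_id": q.serum_id}
        for locus in loci:
            for vendor in VENDORS:
                for secondary in SECONDARIES:
                    key = f"{locus.value}_{vendor}_{secondary}"
                    row[key] = count_reactive(q.profile(vendor, secondary), locus)
        for vendor in VENDORS:
            for secondary in SECONDARIES:
                med = median_positive_mfi(q.profile(vendor, secondary))
                row[f"median_mfi_{vendor}_{secondary}"] = (
                    np.nan if med is None else med
                )
        row["group"] = classify_serum_group(q).value
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_summary(quartets: Sequence[ConditionQuartet],
                   loci: Sequence[Locus]) -> pd.DataFrame:
    """Cohort-level LS-vs-LC comparison per locus and secondary antibody.

    Tallies per-serum reactive-count comparisons and reports both paired
    nonparametric tests (one-sided, H1: LS > LC) on the counts.
    """
    rows = []
    for locus in loci:
        for secondary in SECONDARIES:
            n_gt, n_eq, n_lt = tally_beadsets(quartets, locus, secondary)
            pairs = []
            for q in quartets:
                ls = count_reactive(q.profile("LS", secondary), locus)
                lc = count_reactive(q.profile("LC", secondary), locus)
                if ls or lc:
                    pairs.append((ls, lc))
            row = {
                "locus": locus.value,
                "secondary": secondary,
                "n_sera": len(pairs),
                "ls_gt_lc": n_gt,
                "ls_eq_lc": n_eq,
                "ls_lt_lc": n_lt,
            }
            nonzero_diff = [p for p in pairs if p[0] != p[1]]
            if nonzero_diff:
                sign = sign_test_exact(pairs)
                wil = wilcoxon_signed_rank_exact(pairs)
                row.update(
                    sign_p_one_sided=sign.p_greater,
                    sign_p_two_sided=sign.p_two_sided,
                    wilcoxon_p_one_sided=wil.p_greater,
                    wilcoxon_p_two_sided=wil.p_two_sided,
                )
            else:
                row.update(
                    sign_p_one_sided=np.nan, sign_p_two_sided=np.nan,
                    wilcoxon_p_one_sided=np.nan, wilcoxon_p_two_sided=np.nan,
                )
            rows.append(row)
    return pd.DataFrame(rows)
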
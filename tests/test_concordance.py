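"""Quartet comparisons, exact paired tests, and reactivity grouping."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from sabpipe.concordance import (
    ConditionQuartet,
    GroupLabel,
    classify_serum_group,
    count_reactive,
    median_positive_mfi,
    sign_test_exact,
    tally_beadsets,
    wilcoxon_signed_rank_exact,
)
from sabpipe.normalize import ProfileRecord, SerumProfile
from sabpipe.panels import Locus, parse_allele


def make_profile(mfis, vendor="LS", secondary="FcMonoIgG", serum="S1", cutoff=500.0):
    """Profile from {allele label: normalized MFI}."""
    records = {}
    for i, (label, mfi) in enumerate(mfis.items()):
        allele = parse_allele(label)
        records[f"{vendor}-{i:03d}"] = ProfileRecord(allele, mfi, mfi >= cutoff)
    return SerumProfile(serum_id=serum, vendor=vendor, secondary=secondary,
                        records=records, cutoff=cutoff)


def make_quartet(by_condition, serum="S1"):
    """Quartet from {(vendor, secondary): {allele: mfi}}; conditions not
    given default to all-zero over the same allele universe."""
    universe = sorted({a for m in by_condition.values() for a in m})
    profiles = {}
    for vendor in ("LS", "LC"):
        for sec in ("FcMonoIgG", "IgHPolyFab"):
            mfis = by_condition.get((vendor, sec), {})
            full = {a: mfis.get(a, 0.0) for a in universe}
            profiles[(vendor, sec)] = make_profile(
                full, vendor=vendor, secondary=sec, serum=serum)
    return ConditionQuartet(serum_id=serum, profiles=profiles)


# ---------------------------------------------------------------------------


class TestCountReactive:
    def test_all_negative_is_zero(self):
        p = make_profile({"A*01:01": 0.0, "B*07:02": 200.0})
        assert count_reactive(p) == 0

    def test_seven_supercutoff_b_alleles(self):
        mfis = {f"B*{i:02d}:01": 800.0 for i in range(7, 14)}
        mfis.update({"A*01:01": 9000.0, "Cw*01:02": 100.0})
        p = make_profile(mfis)
        assert count_reactive(p, Locus.B) == 7
        assert count_reactive(p) == 8

    def test_boundary_allele_counted(self):
        p = make_profile({"A*01:01": 500.0})
        assert count_reactive(p) == 1


class TestTallyBeadsets:
    def test_identical_vendors_all_equal(self):
        quartets = [
            make_quartet({
                ("LS", "FcMonoIgG"): {"A*01:01": 900.0},
                ("LC", "FcMonoIgG"): {"A*01:01": 900.0},
            }, serum=f"S{i}")
            for i in range(4)
        ]
        assert tally_beadsets(quartets, Locus.A, "FcMonoIgG") == (0, 4, 0)

    def test_empty_cohort(self):
        assert tally_beadsets([], Locus.A, "FcMonoIgG") == (0, 0, 0)

    def test_fully_nonreactive_sera_excluded(self):
        quartets = [make_quartet({("LS", "FcMonoIgG"): {"A*01:01": 0.0}})]
        assert tally_beadsets(quartets, Locus.A, "FcMonoIgG") == (0, 0, 0)

    def test_components_sum_to_reactive_sera(self):
        quartets = [
            make_quartet({("LS", "FcMonoIgG"): {"A*01:01": 900.0}}, serum="S1"),
            make_quartet({("LC", "FcMonoIgG"): {"A*01:01": 900.0}}, serum="S2"),
            make_quartet({
                ("LS", "FcMonoIgG"): {"A*01:01": 900.0},
                ("LC", "FcMonoIgG"): {"A*01:01": 900.0},
            }, serum="S3"),
        ]
        gt, eq, lt = tally_beadsets(quartets, Locus.A, "FcMonoIgG")
        assert (gt, eq, lt) == (1, 1, 1)
        assert gt + eq + lt == 3


# ---------------------------------------------------------------------------
# exact tests vs brute-force enumeration


def brute_force_sign(pairs):
    diffs = [x - y for x, y in pairs if x != y]
    n, k = len(diffs), sum(d > 0 for d in diffs)
    patterns = list(itertools.product([0, 1], repeat=n))
    p_ge = sum(sum(p) >= k for p in patterns) / 2 ** n
    p_le = sum(sum(p) <= k for p in patterns) / 2 ** n
    return p_ge, p_le, min(1.0, 2 * min(p_ge, p_le))


def brute_force_wilcoxon(pairs):
    diffs = np.array([x - y for x, y in pairs], dtype=float)
    diffs = diffs[diffs != 0]
    ranks = stats.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    n = len(diffs)
    stats_all = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    p_ge = sum(w >= w_obs - 1e-12 for w in stats_all) / 2 ** n
    p_le = sum(w <= w_obs + 1e-12 for w in stats_all) / 2 ** n
    return p_ge, p_le


class TestSignTest:
    def test_five_concordant_pairs(self):
        res = sign_test_exact([(2, 1)] * 5)
        assert res.p_greater == pytest.approx(0.03125)

    def test_single_pair(self):
        assert sign_test_exact([(2, 1)]).p_greater == pytest.approx(0.5)

    def test_balanced_signs_two_sided_one(self):
        pairs = [(1, 0), (0, 1)] * 3
        assert sign_test_exact(pairs).p_two_sided == pytest.approx(1.0)

    def test_all_ties_rejected(self):
        with pytest.raises(ValueError):
            sign_test_exact([(1, 1), (2, 2)])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        pairs = [tuple(rng.integers(0, 5, size=2)) for _ in range(n)]
        if all(x == y for x, y in pairs):
            pairs[0] = (1, 0)
        res = sign_test_exact(pairs)
        p_ge, p_le, p_two = brute_force_sign(pairs)
        assert res.p_greater == pytest.approx(p_ge)
        assert res.p_less == pytest.approx(p_le)


class TestWilcoxon:
    def test_n5_one_sided_minimum(self):
        res = wilcoxon_signed_rank_exact([(i + 2.0, i + 1.0) for i in range(5)])
        assert res.p_greater == pytest.approx(0.03125)
        assert res.method == "exact"

    def test_mirror_symmetry(self):
        pairs = [(3.0, 1.0), (2.0, 5.0), (7.0, 4.0), (1.0, 0.5)]
        a = wilcoxon_signed_rank_exact(pairs)
        b = wilcoxon_signed_rank_exact([(y, x) for x, y in pairs])
        assert a.p_two_sided == pytest.approx(b.p_two_sided)
        assert a.p_greater == pytest.approx(b.p_less)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank_exact([(1.0, 1.0)] * 3)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_with_ties(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(3, 13))
        # integer pairs produce tied |differences| and zero differences
        pairs = [tuple(map(float, rng.integers(0, 6, size=2))) for _ in range(n)]
        if all(x == y for x, y in pairs):
            pairs[0] = (2.0, 0.0)
        res = wilcoxon_signed_rank_exact(pairs)
        p_ge, p_le = brute_force_wilcoxon(pairs)
        assert res.p_greater == pytest.approx(p_ge)
        assert res.p_less == pytest.approx(p_le)

    def test_matches_scipy_exact_when_tie_free(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        res = wilcoxon_signed_rank_exact(list(zip(x, y)))
        ref = stats.wilcoxon(x, y, alternative="greater", method="exact")
        assert res.p_greater == pytest.approx(ref.pvalue)

    def test_normal_approximation_close_to_exact_at_boundary(self):
        rng = np.random.default_rng(11)
        pairs = [tuple(rng.normal(size=2)) for _ in range(26)]  # n > exact cap
        res = wilcoxon_signed_rank_exact(pairs)
        assert res.method == "normal"
        ref = stats.wilcoxon([x for x, _ in pairs], [y for _, y in pairs],
                             alternative="greater", method="approx",
                             correction=True)
        assert res.p_greater == pytest.approx(ref.pvalue, rel=1e-6)


# ---------------------------------------------------------------------------


class TestGroupClassification:
    def test_all_negative_is_nonreactive(self):
        q = make_quartet({("LS", "FcMonoIgG"): {"A*01:01": 0.0}})
        assert classify_serum_group(q) is GroupLabel.NONREACTIVE

    def test_ls_only_low_mfi_broad_is_1a(self):
        mfis = {f"B*{i:02d}:01": 700.0 for i in range(7, 14)}
        q = make_quartet({("LS", "IgHPolyFab"): mfis})
        assert classify_serum_group(q) is GroupLabel.G1A

    def test_ls_only_low_mfi_narrow_is_2a(self):
        q = make_quartet({("LS", "IgHPolyFab"): {"B*07:02": 700.0}})
        assert classify_serum_group(q) is GroupLabel.G2A

    def test_one_vendor_high_is_b(self):
        mfis = {f"B*{i:02d}:01": 2500.0 for i in range(7, 14)}
        q = make_quartet({("LS", "IgHPolyFab"): mfis})
        assert classify_serum_group(q) is GroupLabel.G1B

    def test_both_vendors_high_is_c(self):
        mfis = {f"B*{i:02d}:01": 2500.0 for i in range(7, 14)}
        q = make_quartet({
            ("LS", "IgHPolyFab"): mfis,
            ("LC", "FcMonoIgG"): mfis,
        })
        assert classify_serum_group(q) is GroupLabel.G1C

    def test_five_antigen_boundary_is_group1(self):
        mfis = {f"B*{i:02d}:01": 700.0 for i in range(7, 12)}  # exactly 5
        q = make_quartet({("LS", "IgHPolyFab"): mfis})
        assert classify_serum_group(q).value.startswith("1")

    def test_invariant_to_adding_negative_beads(self):
        mfis = {f"B*{i:02d}:01": 700.0 for i in range(7, 14)}
        q1 = make_quartet({("LS", "IgHPolyFab"): mfis})
        padded = dict(mfis, **{f"A*{i:02d}:01": 0.0 for i in range(1, 10)})
        q2 = make_quartet({("LS", "IgHPolyFab"): padded})
        assert classify_serum_group(q1) is classify_serum_group(q2)

    def test_quartet_requires_shared_universe(self):
        with pytest.raises(ValueError, match="antigen set"):
            ConditionQuartet(serum_id="S1", profiles={
                (v, s): make_profile(
                    {"A*01:01": 0.0} if v == "LS" else {"A*02:01": 0.0},
                    vendor=v, secondary=s)
                for v in ("LS", "LC") for s in ("FcMonoIgG", "IgHPolyFab")
            })


class TestMedianPositiveMfi:
    def test_median_over_positives_only(self):
        p = make_profile({"A*01:01": 600.0, "A*02:01": 800.0,
                          "A*03:01": 1000.0, "B*07:02": 100.0})
        assert median_positive_mfi(p) == pytest.approx(800.0)

    def test_single_positive(self):
        p = make_profile({"A*01:01": 5000.0})
        assert median_positive_mfi(p) == pytest.approx(5000.0)

    def test_no_positive_is_none_not_zero(self):
        p = make_profile({"A*01:01": 100.0})
        assert median_positive_mfi(p) is None
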
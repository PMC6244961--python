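"""Unacceptable-antigen expansion and the cPRA probability engines."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sabpipe.cpra import (
    FrequencyTable,
    Population,
    UnacceptableSet,
    cpra_haplotype,
    cpra_per_locus,
    expand_unacceptable,
    simulate_donors_oracle,
)
from sabpipe.panels import UnmappedAlleleError
from .test_concordance import make_profile


def single_locus_table(freqs, name="pop"):
    haps = [(frozenset([ag]), f) for ag, f in freqs.items()]
    return FrequencyTable(mode="haplotype",
                          populations=[Population(name, 1.0, haplotypes=haps)])


def random_table(rng, n_pops=2, n_loci=3, n_antigens=4):
    """Random multi-locus haplotype table with matching per-locus marginals."""
    pops = []
    weights = rng.dirichlet(np.ones(n_pops))
    for i in range(n_pops):
        n_haps = int(rng.integers(5, 12))
        freqs = rng.dirichlet(np.ones(n_haps))
        haps = []
        for f in freqs:
            antigens = frozenset(
                f"L{l}-ag{rng.integers(n_antigens)}" for l in range(n_loci)
            )
            haps.append((antigens, float(f)))
        # merge duplicate antigen sets to keep frequencies well-defined
        merged = {}
        for ags, f in haps:
            merged[ags] = merged.get(ags, 0.0) + f
        pops.append(Population(f"pop{i}", float(weights[i]),
                               haplotypes=list(merged.items())))
    return FrequencyTable(mode="haplotype", populations=pops)


class TestExpandUnacceptable:
    def test_positive_allele_adds_base_and_allele_level(self, antigen_map):
        profile = make_profile({"A*02:03": 900.0, "A*01:01": 100.0})
        ua = expand_unacceptable(profile, antigen_map)
        assert ua.antigens == frozenset({"A2", "A0203"})

    def test_drb4_positive_adds_dr53(self, antigen_map):
        profile = make_profile({"DRB4*01:03": 600.0})
        ua = expand_unacceptable(profile, antigen_map)
        assert "DR53" in ua.antigens

    def test_dp_pair_goes_to_excluded(self, antigen_map):
        from sabpipe.normalize import ProfileRecord, SerumProfile
        from sabpipe.panels import parse_bead

        bead = parse_bead("DPB1*23:01\\DPA1*02:01")
        profile = SerumProfile(
            serum_id="S1", vendor="LS", secondary="FcMonoIgG",
            records={"b1": ProfileRecord(bead.antigen, 2000.0, True)})
        ua = expand_unacceptable(profile, antigen_map)
        assert ua.antigens == frozenset()
        assert set(ua.excluded) == {"DPB1*23:01", "DPA1*02:01"}

    def test_sub_cutoff_beads_ignored(self, antigen_map):
        profile = make_profile({"A*02:03": 499.0})
        ua = expand_unacceptable(profile, antigen_map)
        assert ua.antigens == frozenset()

    def test_unmapped_listable_allele_is_an_error(self, antigen_map):
        profile = make_profile({"A*98:01": 900.0})
        with pytest.raises(UnmappedAlleleError):
            expand_unacceptable(profile, antigen_map)

    def test_base_group_always_accompanies_allele_level(self, ls_panel, antigen_map):
        mfis = {b.alleles[0].name: 1500.0 for b in ls_panel.antigen_beads()[:20]}
        ua = expand_unacceptable(make_profile(mfis), antigen_map)
        bases = {a for a in ua.antigens if ":" not in a and "*" not in a}
        # every allele-level label coexists with its base group
        assert len(bases) >= 1
        assert len(ua.antigens) >= 2 * 1


class TestEngines:
    def test_empty_set_gives_zero(self, demo_freqs):
        assert cpra_haplotype(UnacceptableSet(), demo_freqs).cpra == 0.0

    def test_single_locus_closed_form(self):
        table = single_locus_table({"A1": 0.3, "A2": 0.7})
        res = cpra_haplotype(UnacceptableSet(frozenset({"A1"})), table)
        assert res.cpra == pytest.approx(1 - (1 - 0.3) ** 2)

    def test_per_locus_engine_matches_haplotype_on_one_locus(self):
        hap = single_locus_table({"A1": 0.3, "A2": 0.7})
        loc = FrequencyTable(
            mode="per_locus_antigen",
            populations=[Population("pop", 1.0,
                                    locus_freqs={"A": {"A1": 0.3, "A2": 0.7}})])
        ua = UnacceptableSet(frozenset({"A1"}))
        assert cpra_per_locus(ua, loc).cpra == pytest.approx(
            cpra_haplotype(ua, hap).cpra)

    def test_saturated_locus_gives_one(self):
        loc = FrequencyTable(
            mode="per_locus_antigen",
            populations=[Population("pop", 1.0,
                                    locus_freqs={"A": {"A1": 0.4, "A2": 0.6}})])
        ua = UnacceptableSet(frozenset({"A1", "A2"}))
        assert cpra_per_locus(ua, loc).cpra == pytest.approx(1.0)

    def test_identical_populations_match_single_population(self):
        haps = [(frozenset({"A1"}), 0.3), (frozenset({"A2"}), 0.7)]
        two = FrequencyTable(mode="haplotype", populations=[
            Population("p1", 0.5, haplotypes=haps),
            Population("p2", 0.5, haplotypes=haps)])
        one = FrequencyTable(mode="haplotype",
                             populations=[Population("p", 1.0, haplotypes=haps)])
        ua = UnacceptableSet(frozenset({"A1"}))
        assert cpra_haplotype(ua, two).cpra == pytest.approx(
            cpra_haplotype(ua, one).cpra)

    def test_bad_frequency_sum_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            single_locus_table({"A1": 0.3, "A2": 0.6})

    @given(seed=st.integers(0, 10_000))
    def test_monotone_under_antigen_addition(self, seed):
        rng = np.random.default_rng(seed)
        table = random_table(rng)
        all_antigens = sorted(
            {a for p in table.populations for ags, _ in p.haplotypes for a in ags}
        )
        chosen = [a for a in all_antigens if rng.uniform() < 0.3]
        ua = UnacceptableSet(frozenset(chosen))
        base = cpra_haplotype(ua, table).cpra
        extra = rng.choice([a for a in all_antigens] or ["none"])
        grown = cpra_haplotype(
            UnacceptableSet(ua.antigens | {extra}), table).cpra
        assert grown >= base - 1e-12
        assert 0.0 <= base <= 1.0


class TestOracle:
    def test_empty_set_estimates_exactly_zero(self, demo_freqs):
        res = simulate_donors_oracle(UnacceptableSet(), demo_freqs, 1000, seed=0)
        assert res.cpra == 0.0

    def test_closed_form_within_three_se(self):
        table = single_locus_table({"A1": 0.3, "A2": 0.7})
        ua = UnacceptableSet(frozenset({"A1"}))
        res = simulate_donors_oracle(ua, table, 100_000, seed=42)
        assert abs(res.cpra - 0.51) <= 3 * res.standard_error

    def test_fixed_seed_is_bit_identical(self, demo_freqs):
        ua = UnacceptableSet(frozenset({"A2", "B7"}))
        a = simulate_donors_oracle(ua, demo_freqs, 10_000, seed=7)
        b = simulate_donors_oracle(ua, demo_freqs, 10_000, seed=7)
        assert a.cpra == b.cpra

    def test_per_locus_mode_oracle(self):
        loc = FrequencyTable(
            mode="per_locus_antigen",
            populations=[Population("pop", 1.0, locus_freqs={
                "A": {"A1": 0.3, "A2": 0.7},
                "B": {"B7": 0.2, "B8": 0.8}})])
        ua = UnacceptableSet(frozenset({"A1", "B7"}))
        expected = cpra_per_locus(ua, loc).cpra
        res = simulate_donors_oracle(ua, loc, 100_000, seed=3)
        assert abs(res.cpra - expected) <= 3 * res.standard_error
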
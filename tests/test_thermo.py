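"""Duplex MFE and partition function against brute-force enumeration."""

import math

import pytest

from _oracles import (
    brute_force_duplex_mfe,
    brute_force_log_partition,
    duplex_structure_energy,
)
from conftest import random_rna
from mirlearn.thermo import (
    ALL_PAIRS,
    EnergyModel,
    duplex_energy,
    ensemble_free_energy,
    open_energy_window,
    pair_type,
    partition_function,
)


class TestEnergyModel:
    def test_default_loads_from_package_data(self, model):
        assert model.init_penalty == pytest.approx(4.09)
        assert model.RT == pytest.approx(0.61633)

    def test_stack_table_is_symmetric(self, model):
        """Reading a stack 5'->3' on either strand gives the same energy."""
        for key, e in model.stacks.items():
            outer, inner = key.split(":")
            flipped = f"{inner[1]}{inner[0]}:{outer[1]}{outer[0]}"
            assert model.stacks[flipped] == pytest.approx(e), key

    def test_stack_table_covers_all_pair_combinations(self, model):
        import math

        for p1 in ALL_PAIRS:
            for p2 in ALL_PAIRS:
                assert math.isfinite(model.stack_energy(p1, p2))

    def test_gc_stack_is_most_stable_category(self, model):
        gc = model.stack_energy(("G", "C"), ("C", "G"))
        au = model.stack_energy(("A", "U"), ("U", "A"))
        gu = model.stack_energy(("G", "U"), ("U", "G"))
        assert gc < au < 0 and gc < gu

    def test_loop_extrapolation_increases_with_size(self, model):
        assert model.hairpin_energy(30) > model.hairpin_energy(9)
        assert model.loop_energy(0, 12) > model.loop_energy(0, 6)

    def test_loop_energy_dispatch(self, model):
        # one-sided gap = bulge table; two-sided = internal table
        assert model.loop_energy(2, 0) == model.bulge_loop[2]
        assert model.loop_energy(1, 1) == model.internal_loop[2]
        with pytest.raises(ValueError):
            model.loop_energy(0, 0)

    def test_end_penalty(self, model):
        assert model.end_penalty(("G", "C")) == 0.0
        assert model.end_penalty(("A", "U")) == pytest.approx(model.au_end_penalty)
        assert model.end_penalty(("G", "U")) == pytest.approx(model.au_end_penalty)

    def test_hairpin_below_minimum_raises(self, model):
        with pytest.raises(ValueError):
            model.hairpin_energy(2)


class TestPairType:
    @pytest.mark.parametrize(
        "a,b,t",
        [("G", "C", "WC"), ("A", "U", "WC"), ("G", "U", "GU"), ("U", "G", "GU"),
         ("A", "G", "none"), ("A", "A", "none")],
    )
    def test_pair_types(self, a, b, t):
        assert pair_type(a, b) == t


class TestDuplexEnergy:
    def test_perfect_gc_helix(self, model):
        # GGGG/CCCC: init + 3 stacks of GC:GC, no AU ends
        res = duplex_energy("GGGG", "CCCC", model)
        expect = model.init_penalty + 3 * model.stack_energy(("G", "C"), ("G", "C"))
        assert res.energy == pytest.approx(expect)
        assert res.pairs == [(0, 3), (1, 2), (2, 1), (3, 0)]

    def test_no_possible_pair_returns_zero(self, model):
        res = duplex_energy("AAAA", "CCCC", model)
        assert res.energy == 0.0 and res.pairs == []

    def test_positive_mfe_rejected_in_favor_of_open_state(self, model):
        # a single weak AU pair cannot beat the 4.09 initiation penalty
        res = duplex_energy("AA", "UU", model)
        assert res.energy == 0.0 and res.pairs == []

    def test_antiparallel_pair_geometry(self, model):
        res = duplex_energy("GGCC", "GGCC", model)
        for (i1, j1), (i2, j2) in zip(res.pairs, res.pairs[1:]):
            assert i2 > i1 and j2 < j1

    def test_trace_energy_matches_reported_energy(self, model, rng):
        for _ in range(60):
            s1 = random_rna(rng, int(rng.integers(4, 12)))
            s2 = random_rna(rng, int(rng.integers(4, 12)))
            res = duplex_energy(s1, s2, model)
            if not res.pairs:
                assert res.energy == 0.0
                continue
            assert duplex_structure_energy(res.pairs, s1, s2, model) == pytest.approx(
                res.energy, abs=1e-9
            )

    def test_matches_brute_force_enumeration(self, model, rng):
        for _ in range(50):
            s1 = random_rna(rng, int(rng.integers(2, 9)))
            s2 = random_rna(rng, int(rng.integers(2, 9)))
            got = duplex_energy(s1, s2, model).energy
            want = brute_force_duplex_mfe(s1, s2, model)
            assert got == pytest.approx(want, abs=1e-9), (s1, s2)

    def test_dna_input_accepted(self, model):
        a = duplex_energy("GGGG", "CCCC", model).energy
        b = duplex_energy("GGGG", "CCCC".replace("C", "C"), model).energy
        assert a == b
        assert duplex_energy("GGTT", "AACC", model).energy == duplex_energy(
            "GGUU", "AACC", model
        ).energy

    def test_short_strand_rejected(self, model):
        with pytest.raises(ValueError):
            duplex_energy("G", "CCC", model)

    def test_bulge_bridged_helix_beats_split_helices(self, model):
        # GGG-A-GGG vs CCCCCC: the bulge lets both GC helices share one init
        res = duplex_energy("GGGAGGG", "CCCCCC", model)
        bulged = (
            model.init_penalty
            + 4 * model.stack_energy(("G", "C"), ("G", "C"))
            + model.bulge_loop[1]
        )
        assert res.energy <= bulged + 1e-9
        assert len(res.pairs) >= 6


class TestPartitionFunction:
    def test_unpairable_sequence_gives_log_one(self, model):
        assert partition_function("AAAAAAA", model) == 0.0

    def test_min_hairpin_enforced(self, model):
        # GAAAC can close a 3-nt loop; GAAC (2-nt loop) cannot pair at all
        assert partition_function("GAAAC", model) != 0.0
        assert partition_function("GAAC", model) == 0.0

    def test_matches_brute_force(self, model, rng):
        for _ in range(30):
            s = random_rna(rng, int(rng.integers(5, 15)))
            got = partition_function(s, model)
            want = brute_force_log_partition(s, model)
            assert got == pytest.approx(want, rel=1e-10, abs=1e-10), s

    def test_constrained_matches_brute_force(self, model, rng):
        for _ in range(15):
            n = int(rng.integers(8, 14))
            s = random_rna(rng, n)
            k = int(rng.integers(0, n - 3))
            forbidden = frozenset(range(k, k + 3))
            got = partition_function(s, model, forbidden)
            want = brute_force_log_partition(s, model, forbidden)
            assert got == pytest.approx(want, rel=1e-10, abs=1e-10), (s, sorted(forbidden))

    def test_constraint_never_increases_partition(self, model, rng):
        for _ in range(20):
            s = random_rna(rng, 20)
            free = partition_function(s, model)
            con = partition_function(s, model, range(5, 10))
            assert con <= free + 1e-12

    def test_multiloop_sequence_matches_brute_force(self, model):
        # two stems separated enough to allow a multiloop inside a closing pair
        s = "GGGAAACCCAAGGGAAACCC"
        got = partition_function(s, model)
        want = brute_force_log_partition(s, model)
        assert got == pytest.approx(want, rel=1e-10)


class TestOpenEnergy:
    def test_open_energy_non_negative(self, model, rng):
        for _ in range(10):
            w = random_rna(rng, 40)
            assert open_energy_window(w, 15, 25, model) >= 0.0

    def test_unstructured_window_costs_nothing(self, model):
        assert open_energy_window("A" * 30, 10, 20, model) == 0.0

    def test_hairpin_site_costs_energy(self, model):
        # strong hairpin right on the site
        w = "AAAAA" + "GGGGGCAAAAGCCCCC" + "AAAAA"
        cost = open_energy_window(w, 5, 21, model)
        assert cost > 1.0

    def test_site_bounds_validated(self, model):
        with pytest.raises(ValueError):
            open_energy_window("ACGU" * 5, 10, 30, model)

    def test_equals_free_energy_difference(self, model, rng):
        w = random_rna(rng, 30)
        g_free = ensemble_free_energy(w, model)
        g_con = ensemble_free_energy(w, model, range(10, 20))
        assert open_energy_window(w, 10, 20, model) == pytest.approx(
            max(0.0, g_con - g_free)
        )
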
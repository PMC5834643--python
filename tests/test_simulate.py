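"""Synthetic-data generator: determinism, ground truth and planted structure."""

import numpy as np
import pytest

from mirlearn._seq import to_dna
from mirlearn.quantify import map_reads
from mirlearn.reads import classify_length, process_library
from mirlearn.simulate import (
    DEFAULT_ADAPTER3P,
    MIR137_MATURE,
    MIR137_NAME,
    SimulationConfig,
    default_config,
    expected_count,
    generate_hairpin_set,
    generate_library,
    generate_qpcr_table,
    generate_target_utr,
    relative_abundances,
)


class TestConfig:
    def test_default_config_plants_fourteen_effects(self):
        cfg = default_config(1)
        assert len(cfg.planted_effects) == 14
        assert cfg.planted_effects[MIR137_NAME] == ("1h", 1.5)
        libs = [lib for lib, _ in cfg.planted_effects.values()]
        assert libs.count("1h") == 10 and libs.count("6h") == 4

    def test_all_default_qualities_above_q20(self):
        cfg = default_config(1)
        assert min(cfg.base_quality) > 20

    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(rng_seed=1, n_mirnas=0)
        with pytest.raises(ValueError):
            SimulationConfig(rng_seed=1, mapped_fraction=0.9)  # > mature class prop
        with pytest.raises(ValueError):
            SimulationConfig(rng_seed=1, planted_effects={"m": ("nope", 1.5)})
        with pytest.raises(ValueError):
            SimulationConfig(rng_seed=1, planted_effects={"m": ("1h", 0.0)})
        with pytest.raises(ValueError):
            SimulationConfig(
                rng_seed=1, size_class_mixture={"mature_miRNA": 0.5, "other": 0.4}
            )


class TestHairpins:
    def test_first_record_is_mir137(self, hairpins):
        assert hairpins[0].name == MIR137_NAME
        assert hairpins[0].mature_seq == to_dna(MIR137_MATURE)

    def test_names_unique_and_matures_distinct(self, hairpins):
        names = [h.name for h in hairpins]
        assert len(set(names)) == len(names)
        matures = [h.mature_seq for h in hairpins]
        assert len(set(matures)) == len(matures)

    def test_mature_lengths_in_class(self, hairpins):
        for h in hairpins:
            assert classify_length(len(h.mature_seq)) == "mature_miRNA"

    def test_deterministic(self, small_config, hairpins):
        again = generate_hairpin_set(small_config)
        assert again == hairpins


class TestAbundances:
    def test_sum_to_one_and_span_orders(self, small_config, hairpins):
        ab = relative_abundances(small_config, hairpins)
        vals = np.array(list(ab.values()))
        assert vals.sum() == pytest.approx(1.0)
        assert (vals > 0).all()

    def test_expected_count_applies_planted_fold(self, hairpins):
        cfg = SimulationConfig(
            rng_seed=42,
            n_mirnas=20,
            library_depths={"naive": 5000, "1h": 5000},
            planted_effects={MIR137_NAME: ("1h", 1.5)},
        )
        ab = relative_abundances(cfg, hairpins)
        base = expected_count(cfg, ab, MIR137_NAME, "naive")
        up = expected_count(cfg, ab, MIR137_NAME, "1h")
        assert up == pytest.approx(1.5 * base)
        other = hairpins[1].name
        assert expected_count(cfg, ab, other, "1h") == pytest.approx(
            expected_count(cfg, ab, other, "naive")
        )


@pytest.fixture(scope="module")
def lib(small_config, hairpins):
    return generate_library(small_config, hairpins, "naive")


class TestLibrary:
    def test_reads_are_deterministic(self, small_config, hairpins, lib):
        again = generate_library(small_config, hairpins, "naive")
        assert again.reads == lib.reads and again.true_counts == lib.true_counts

    def test_depth_near_nominal(self, small_config, lib):
        depth = small_config.library_depths["naive"]
        assert abs(len(lib.reads) - depth) < 5 * np.sqrt(depth)

    def test_reads_are_adapter_ligated_and_truncated(self, small_config, lib):
        assert all(len(r) <= small_config.read_length for r in lib.reads)
        adapter = DEFAULT_ADAPTER3P
        with_adapter = sum(adapter[:5] in r.sequence for r in lib.reads)
        assert with_adapter > 0.95 * len(lib.reads)

    def test_true_counts_recovered_exactly_by_pipeline(
        self, small_config, hairpins, lib
    ):
        """Noiseless round trip: trim + filter + map returns the emitted counts."""
        kept, tally = process_library(lib.reads, small_config.adapter3p)
        res = map_reads(kept, hairpins, max_mismatches=0)
        counts = {}
        for name in res.assignments.values():
            counts[name] = counts.get(name, 0) + 1
        truth = {k: v for k, v in lib.true_counts.items() if v > 0}
        assert counts == truth

    def test_mapped_fraction_near_target(self, small_config, hairpins, lib):
        kept, _ = process_library(lib.reads, small_config.adapter3p)
        res = map_reads(kept, hairpins, max_mismatches=0)
        frac = len(res.assignments) / len(lib.reads)
        assert frac == pytest.approx(small_config.mapped_fraction, abs=0.03)

    def test_size_class_mixture_respected(self, small_config, lib):
        total = sum(lib.class_counts.values())
        mix = small_config.size_class_mixture
        mature = lib.class_counts["mature_miRNA"] + lib.class_counts["mature_miRNA_decoy"]
        assert mature / total == pytest.approx(mix["mature_miRNA"], abs=0.02)
        assert lib.class_counts["piRNA"] / total == pytest.approx(mix["piRNA"], abs=0.02)

    def test_different_libraries_differ(self, small_config, hairpins, lib):
        other = generate_library(small_config, hairpins, "1h")
        assert other.reads != lib.reads

    def test_unknown_library_id(self, small_config, hairpins):
        with pytest.raises(KeyError):
            generate_library(small_config, hairpins, "48h")

    def test_overdispersion_inflates_variance(self):
        """NB counts vary far more than Poisson across replicate libraries.

        All libraries share one abundance vector (same config seed), so the
        between-library variance isolates the counting noise.
        """
        depths = {f"rep{i:02d}": 5000 for i in range(20)}
        base = dict(rng_seed=5, n_mirnas=20, library_depths=depths, planted_effects={})
        c_po = SimulationConfig(**base)
        c_nb = SimulationConfig(overdispersion=0.5, **base)
        hp = generate_hairpin_set(c_po)
        po = [generate_library(c_po, hp, lib).true_counts[MIR137_NAME] for lib in depths]
        nb = [generate_library(c_nb, hp, lib).true_counts[MIR137_NAME] for lib in depths]
        lam = expected_count(c_po, relative_abundances(c_po, hp), MIR137_NAME, "rep00")
        assert abs(np.mean(po) - lam) < 5 * np.sqrt(np.var(po, ddof=1) / len(po))
        assert abs(np.mean(nb) - lam) < 5 * np.sqrt(np.var(nb, ddof=1) / len(nb))
        assert np.var(nb, ddof=1) > 3 * np.var(po, ddof=1)


class TestQpcrTable:
    def test_planted_folds_recovered_noiselessly(self):
        df = generate_qpcr_table({"1h": 1.5, "6h": 1.0}, ct_noise_sd=0.0, rng_seed=3)
        from mirlearn.qpcr import CTMeasurement, summarize_groups

        ms = [
            CTMeasurement(r.sample_id, r.group, r.ct_target, r.ct_reference, r.is_calibrator)
            for r in df.itertuples()
        ]
        by_group = {g.group: g.mean for g in summarize_groups(ms)}
        assert by_group["control"] == pytest.approx(1.0)
        assert by_group["1h"] == pytest.approx(1.5)
        assert by_group["6h"] == pytest.approx(1.0)

    def test_calibrator_group_flagged(self):
        df = generate_qpcr_table({"1h": 1.5}, 0.1, rng_seed=3)
        assert set(df.loc[df.is_calibrator, "group"]) == {"control"}
        assert (~df.loc[df.group != "control", "is_calibrator"]).all()

    def test_noise_is_deterministic(self):
        a = generate_qpcr_table({"1h": 1.5}, 0.2, rng_seed=11)
        b = generate_qpcr_table({"1h": 1.5}, 0.2, rng_seed=11)
        assert a.equals(b)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_qpcr_table({"1h": 1.5}, -0.1, rng_seed=1)
        with pytest.raises(ValueError):
            generate_qpcr_table({"1h": 0.0}, 0.1, rng_seed=1)


class TestTargetUtr:
    def test_site_coordinates_and_uniqueness(self):
        p = generate_target_utr(MIR137_MATURE, flank_len=80, rng_seed=5)
        L = len(MIR137_MATURE)
        assert p.site_start == 80 and p.site_end == 80 + L
        assert p.seed_start == 80 + (L - 8) and p.seed_end == 80 + (L - 1)
        from mirlearn.targets import scan_utr

        hits = scan_utr(p.utr, MIR137_MATURE)
        assert [h.utr_start for h in hits] == [p.seed_start]

    def test_deterministic(self):
        a = generate_target_utr(MIR137_MATURE, 60, rng_seed=9)
        b = generate_target_utr(MIR137_MATURE, 60, rng_seed=9)
        assert a == b

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_target_utr(MIR137_MATURE, -1, rng_seed=1)
        with pytest.raises(ValueError):
            generate_target_utr("ACGUACG", 10, rng_seed=1)
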
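"""Synthetic-data generators: construction, determinism, planted truth."""

import numpy as np
import pandas as pd
import pytest

import oacgh as og
from oacgh.genome import GenomeModel
from oacgh.simulate import FISH_CATEGORIES, component_rng


class TestGenGenome:
    def test_default_is_38_autosomes_plus_x(self):
        genome = og.gen_genome(38)
        assert len(genome.names) == 39
        assert genome.names[-1] == "X"
        assert genome.names[0] == "1"

    def test_same_seed_identical(self):
        assert og.gen_genome(5, seed=3) == og.gen_genome(5, seed=3)

    def test_autosomal_total_recorded(self):
        genome = og.gen_genome(2, length_scale=1.0)
        total = genome.total_length(exclude={"X"})
        assert total == genome.lengths["1"] + genome.lengths["2"]

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            og.gen_genome(0)
        with pytest.raises(ValueError):
            og.gen_genome(3, length_scale=-1)
        with pytest.raises(ValueError):
            GenomeModel(names=("1",), lengths={"1": 0})

    def test_full_genome_scale(self):
        genome = og.canfam2_genome()
        assert 2.0e9 < genome.total_length(exclude={"X"}) < 2.5e9


class TestGenProbes:
    def test_probe_count_is_floor_of_length_over_spacing(self):
        genome = GenomeModel(names=("1",), lengths={"1": 130_000})
        probes = og.gen_probes(genome, spacing=13_000)
        assert len(probes) == 10

    def test_full_array_scale_matches_180k_features(self):
        probes = og.gen_probes(og.canfam2_genome(), spacing=13_000)
        assert 160_000 < len(probes) < 200_000

    def test_short_chromosome_still_gets_one_probe(self):
        genome = GenomeModel(names=("1",), lengths={"1": 5_000})
        assert len(og.gen_probes(genome, spacing=13_000)) == 1

    def test_deterministic_and_sorted(self, toy_genome):
        a = og.gen_probes(toy_genome)
        b = og.gen_probes(toy_genome)
        pd.testing.assert_frame_equal(a, b)
        for _, grp in a.groupby("chrom"):
            assert grp["start"].is_monotonic_increasing


class TestGenSignalProfile:
    def test_null_case_zero_noise_zero_ratio(self, toy_probes):
        table = og.gen_signal_profile(toy_probes, [], noise_sd=0.0, seed=0)
        ratio = np.log2(table["r_signal"] / table["g_signal"])
        np.testing.assert_allclose(ratio, 0.0, atol=1e-12)

    def test_planted_gain_exact_at_zero_noise(self, toy_probes):
        cna = og.PlantedCNA("1", 650_000, 1_950_000, "gain", 1.0)
        table = og.gen_signal_profile(toy_probes, [cna], noise_sd=0.0, seed=0)
        ratio = np.log2(table["r_signal"] / table["g_signal"])
        inside = (table["chrom"] == "1") & (table["start"] >= 650_000) & (
            table["start"] < 1_950_000
        )
        np.testing.assert_allclose(ratio[inside], 1.0, atol=1e-12)
        np.testing.assert_allclose(ratio[~inside], 0.0, atol=1e-12)

    def test_noisy_mean_within_clt_bound(self):
        # 500 probes inside a +0.58 interval at noise 0.1: the sample mean
        # should land within 3 sigma/sqrt(n) of the planted shift
        genome = GenomeModel(names=("1",), lengths={"1": 500 * 13_000})
        probes = og.gen_probes(genome, spacing=13_000)
        cna = og.PlantedCNA("1", 0, genome.lengths["1"], "gain", 0.58)
        table = og.gen_signal_profile(probes, [cna], noise_sd=0.1, seed=5)
        ratio = np.log2(table["r_signal"] / table["g_signal"])
        assert abs(ratio.mean() - 0.58) < 3 * 0.1 / np.sqrt(500)

    def test_signals_strictly_positive(self, toy_probes, toy_genome):
        table = og.gen_signal_profile(
            toy_probes, og.toy_cnas(toy_genome), noise_sd=0.2, seed=2
        )
        assert (table["r_signal"] > 0).all()
        assert (table["g_signal"] > 0).all()

    def test_overlapping_cnas_rejected(self, toy_probes):
        cnas = [
            og.PlantedCNA("1", 0, 1_000_000, "gain", 0.58),
            og.PlantedCNA("1", 500_000, 1_500_000, "loss", -1.0),
        ]
        with pytest.raises(ValueError, match="overlap"):
            og.gen_signal_profile(toy_probes, cnas, seed=0)

    def test_invalid_cna_construction(self):
        with pytest.raises(ValueError):
            og.PlantedCNA("1", 10, 10, "gain", 0.5)
        with pytest.raises(ValueError):
            og.PlantedCNA("1", 0, 10, "gain", -0.5)
        with pytest.raises(ValueError):
            og.PlantedCNA("1", 0, 10, "loss", 0.5)

    def test_same_seed_bit_identical(self, toy_probes, toy_genome):
        a = og.gen_signal_profile(toy_probes, og.toy_cnas(toy_genome), seed=9)
        b = og.gen_signal_profile(toy_probes, og.toy_cnas(toy_genome), seed=9)
        pd.testing.assert_frame_equal(a, b)


@pytest.fixture(scope="module")
def tiny_grid():
    return pd.DataFrame(
        {
            "chrom": ["1", "1", "2", "2"],
            "start": [0, 1_000_000, 0, 1_000_000],
            "end": [1_000_000, 2_000_000, 1_000_000, 2_000_000],
        }
    )


@pytest.fixture(scope="module")
def two_signatures():
    return [
        og.SubtypeSignature(
            "B-LSA", ((og.PlantedCNA("1", 0, 2_000_000, "gain", 0.58), 1.0),)
        ),
        og.SubtypeSignature(
            "T-LSA", ((og.PlantedCNA("2", 0, 2_000_000, "loss", -1.0), 1.0),)
        ),
    ]


class TestGenCohort:
    def test_degenerate_draw_identical_profiles(self, two_signatures, tiny_grid):
        matrix, labels, carriers = og.gen_cohort(
            two_signatures, 5, tiny_grid, noise_sd=0.0, seed=1
        )
        b_rows = matrix.loc[labels == "B-LSA"]
        assert (b_rows.nunique(axis=0) == 1).all()
        np.testing.assert_allclose(b_rows.iloc[0], [0.58, 0.58, 0.0, 0.0])
        assert carriers.loc[labels == "B-LSA", "B-LSA:0"].all()

    def test_carrier_fraction_within_binomial_bound(self, tiny_grid):
        sigs = [
            og.SubtypeSignature(
                "B-LSA", ((og.PlantedCNA("1", 0, 2_000_000, "gain", 0.58), 0.5),)
            ),
            og.SubtypeSignature(
                "T-LSA", ((og.PlantedCNA("2", 0, 2_000_000, "loss", -1.0), 0.5),)
            ),
        ]
        _, labels, carriers = og.gen_cohort(sigs, 200, tiny_grid, seed=7)
        frac = carriers.loc[labels == "B-LSA", "B-LSA:0"].mean()
        assert abs(frac - 0.5) < 0.11  # 3 sigma of Binomial(200, .5)/200

    def test_seven_by_twenty_gives_140_labeled_rows(self):
        genome = og.canfam2_genome()
        grid = og.make_marker_grid(genome, bin_size=10_000_000)
        matrix, labels, _ = og.gen_cohort(
            og.default_signatures(genome), 20, grid, seed=0
        )
        assert matrix.shape[0] == 140
        assert labels.value_counts().eq(20).all()

    def test_preconditions(self, two_signatures, tiny_grid):
        with pytest.raises(ValueError):
            og.gen_cohort(two_signatures[:1], 5, tiny_grid)
        with pytest.raises(ValueError):
            og.gen_cohort(two_signatures, 1, tiny_grid)


class TestGenFishCounts:
    def test_degenerate_concordance_one(self):
        counts = og.gen_fish_counts(og.FISHTruth("MYC", 2, 1.0), n_cells=50, seed=0)
        assert counts[2] == 50
        assert sum(counts.values()) == 50

    @pytest.mark.parametrize("seed", range(5))
    def test_counts_sum_to_n_cells(self, seed):
        truth = og.FISHTruth("KIT", 3, 0.8)
        counts = og.gen_fish_counts(truth, n_cells=57, seed=seed)
        assert sum(counts.values()) == 57
        assert set(counts) == set(FISH_CATEGORIES)

    def test_edge_category_spills_to_single_neighbor(self):
        counts = og.gen_fish_counts(og.FISHTruth("CDKN2A", 0, 0.9), n_cells=200, seed=1)
        assert counts[0] > 0 and counts[1] >= 0
        assert all(counts[c] == 0 for c in (2, 3, 4, 5))

    def test_truth_validation(self):
        with pytest.raises(ValueError):
            og.FISHTruth("X", 7, 0.9)
        with pytest.raises(ValueError):
            og.FISHTruth("X", 2, 0.0)
        with pytest.raises(ValueError):
            og.gen_fish_counts(og.FISHTruth("X", 2, 0.9), n_cells=0)


class TestGenExpression:
    def test_no_effect_rows_all_filtered(self):
        matrix, _, _ = og.gen_expression(
            100, {"control": 3, "case": 3}, effect_log2=0.0, within_sd=0.1,
            n_diff=0, seed=0,
        )
        assert og.sd_filter(matrix, threshold=0.5).empty

    def test_planted_row_survives_sd_filter(self):
        # a row split 5 vs 5 by effect 5 has SD ~ 2.5 > 2
        matrix, _, mask = og.gen_expression(
            50, {"control": 5, "case": 5}, effect_log2=5.0, within_sd=0.05,
            n_diff=1, seed=0,
        )
        kept = og.sd_filter(matrix, threshold=2.0)
        assert list(kept.index) == list(matrix.index[mask])

    def test_same_seed_identical(self):
        a, _, _ = og.gen_expression(30, {"c": 2, "t": 2}, n_diff=5, seed=4)
        b, _, _ = og.gen_expression(30, {"c": 2, "t": 2}, n_diff=5, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            og.gen_expression(10, {"only": 3})
        with pytest.raises(ValueError):
            og.gen_expression(10, {"a": 1, "b": 0})


def test_component_substreams_are_independent():
    a = component_rng(1, "profile").normal(size=5)
    b = component_rng(1, "cohort").normal(size=5)
    assert not np.allclose(a, b)
    np.testing.assert_array_equal(a, component_rng(1, "profile").normal(size=5))


def test_truth_sidecar_round_trips_planted_cnas(toy_genome):
    cnas = og.toy_cnas(toy_genome)
    sidecar = og.truth_sidecar(cnas)
    assert len(sidecar) == len(cnas)
    rebuilt = [
        og.PlantedCNA(r.chrom, r.start, r.end, r.state, r.shift)
        for r in sidecar.itertuples()
    ]
    assert set(rebuilt) == set(cnas)
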
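"""Sweep consistency, paired design, and display-smoothing contracts."""

import numpy as np
import pytest

from popdecode.classifiers import DecoderSpec, train_decoder
from popdecode.evaluate import paired_permutation_test
from popdecode.experiments import (
    _subset_ids,
    compare_decoders,
    memory_analysis,
    pairwise_tests,
    per_seed_table,
    restrict_dataset,
    smooth_matrix,
    sweep_imbalance,
    sweep_joint,
    sweep_population_size,
    sweep_trial_number,
)
from popdecode.rng import substream


@pytest.fixture(scope="module")
def spec():
    return DecoderSpec("r_ole")


@pytest.fixture(scope="module")
def baseline(endo_dataset, spec):
    return compare_decoders(
        endo_dataset, [spec], "endogenous", master_seed=7, n_seeds=3, n_perm=2
    )


class TestCompareDecoders:
    def test_strong_population_is_significant(self, baseline):
        row = baseline.iloc[0]
        assert row["decoder"] == "r_ole"
        assert row["significant"]
        assert row["relative_pct"] == pytest.approx(
            row["mean_pct"] - row["upper95_pct"]
        )

    def test_noise_population_is_not_significant(self, noise_dataset, spec):
        table = compare_decoders(
            noise_dataset, [spec], "endogenous", master_seed=3, n_seeds=3,
            n_perm=4,
        )
        assert not table["significant"].iloc[0]
        assert 30 < table["mean_pct"].iloc[0] < 70

    def test_selective_subset_uses_flagged_attention_cells(self, endo_dataset):
        ids = _subset_ids(endo_dataset, "selective", substream(0, "x"))
        expected = [
            c.cell_id for c in endo_dataset.cells
            if c.selectivity_class in ("attention", "mixed")
        ]
        assert list(ids) == expected


class TestSweepConsistency:
    def test_full_population_size_reproduces_baseline(self, endo_dataset, spec, baseline):
        table = sweep_population_size(
            endo_dataset, spec, sizes=(40,), master_seed=7, n_draws=1,
            n_seeds=3, n_perm=2,
        )
        assert table["mean_pct"].iloc[0] == pytest.approx(
            baseline["mean_pct"].iloc[0]
        )

    def test_full_train_set_reproduces_baseline(self, endo_dataset, spec, baseline):
        table = sweep_trial_number(
            endo_dataset, spec, train_sizes=(84,), master_seed=7, n_seeds=3
        )
        assert table["mean_pct"].iloc[0] == pytest.approx(
            baseline["mean_pct"].iloc[0]
        )

    def test_joint_corner_reproduces_baseline(self, endo_dataset, spec, baseline):
        joint = sweep_joint(
            endo_dataset, spec, size_grid=(10, 40), trial_grid=(20, 84),
            master_seed=7, n_seeds=3, with_nulls=False,
        )
        assert joint["performance"].shape == (2, 2)
        assert joint["performance"][1, 1] == pytest.approx(
            baseline["mean_pct"].iloc[0]
        )

    def test_tiny_training_set_runs_on_noise(self, noise_dataset, spec):
        table = sweep_trial_number(
            noise_dataset, spec, train_sizes=(2,), master_seed=1, n_seeds=2,
            variable="exogenous",
        )
        assert 0 <= table["mean_pct"].iloc[0] <= 100


class TestSmoothMatrix:
    def test_display_smoothing_preserves_global_mean(self, rng):
        mat = 60 + 10 * rng.random((8, 6))
        sm = smooth_matrix(mat, sigma=7)
        assert sm.shape == mat.shape
        assert sm.mean() == pytest.approx(mat.mean(), rel=0.01)


class TestSweepImbalance:
    def test_zero_imbalance_drop_is_exactly_zero(self, endo_dataset, spec):
        table = sweep_imbalance(
            endo_dataset, [spec], imbalance_grid=(0.0,), master_seed=7, n_seeds=2
        )
        assert table["drop_pct"].iloc[0] == 0.0

    def test_paired_rows_per_decoder_and_level(self, endo_dataset):
        specs = [DecoderSpec("r_ole"), DecoderSpec("bayes")]
        table = sweep_imbalance(
            endo_dataset, specs, imbalance_grid=(0.0, 0.5), master_seed=7,
            n_seeds=2,
        )
        assert len(table) == 4
        assert set(table["decoder"]) == {"r_ole", "bayes"}


class TestPairedInference:
    def test_decoder_against_itself_is_null(self, endo_dataset, rng):
        table = per_seed_table(
            endo_dataset, [DecoderSpec("r_ole"), DecoderSpec("bayes")],
            "endogenous", master_seed=7, n_seeds=6,
        )
        assert len(table) == 12
        p_same = paired_permutation_test(
            table[table["decoder"] == "r_ole"]["performance_pct"],
            table[table["decoder"] == "r_ole"]["performance_pct"],
            rng,
        )
        assert p_same == pytest.approx(1.0)

    def test_informative_beats_label_free_decoder(self, endo_dataset, rng):
        # r_ole on real cells vs on a single unselective cell: clearly paired
        specs = [DecoderSpec("r_ole"), DecoderSpec("bayes")]
        table = per_seed_table(endo_dataset, specs, "endogenous",
                               master_seed=7, n_seeds=6)
        tests = pairwise_tests(table, rng)
        assert set(tests.columns) == {
            "decoder_a", "decoder_b", "mean_diff_pct", "p_value"
        }
        assert ((tests["p_value"] > 0) & (tests["p_value"] <= 1)).all()


class TestReservoirVariantConsistency:
    def test_unleaked_memory_variant_matches_static_reservoir(self, endo_seeds):
        # with tau = 1, the static window and a tiny input scale, the memory
        # variant differs from the static one only through tanh, which is
        # linear to ~1e-9 at that scale
        seed = endo_seeds[0]
        window = (245 - 37, 245 + 38)
        scale = 1e-4
        static = train_decoder(
            DecoderSpec("reservoir",
                        params=dict(n_nodes=40, input_scale=scale)),
            seed, 245, rng=np.random.default_rng(5),
        )
        memory = train_decoder(
            DecoderSpec("reservoir_memory",
                        params=dict(n_nodes=40, input_scale=scale, tau=1.0,
                                    train_window=window)),
            seed, 245, rng=np.random.default_rng(5),
        )
        traces = seed.X_window(0, seed.duration, seed.test_idx)
        times = np.arange(195, 295)
        a = static.decision_over_time(traces, times)
        b = memory.decision_over_time(traces, times)
        assert np.array_equal(static.W_in, memory.W_in)
        assert a == pytest.approx(b, abs=1e-4)


class TestMemoryAnalysis:
    def test_transient_only_signal_decays_for_both_variants(self):
        from popdecode.synth import GeneratorConfig, generate_dataset

        cfg = GeneratorConfig(
            n_cells=16, fraction_visual=0, fraction_attention=1.0,
            attention_gain=8.0, attention_sustain=0.0,
            n_trials_mean=60, n_trials_sd=0, rng_seed=13,
        )
        ds = generate_dataset(cfg)
        table = memory_analysis(ds, master_seed=5, n_seeds=3, n_perm=2)
        late = table[table["time_ms"] >= 420]
        ref = table[(table["time_ms"] - 245).abs() <= 5]
        for variant in ("narrow", "wide"):
            peak = ref[ref["variant"] == variant]["mean_pct"].mean()
            tail = late[late["variant"] == variant]["mean_pct"].mean()
            assert tail < peak - 10  # transient gone, decode decays to chance
            assert tail < 65
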
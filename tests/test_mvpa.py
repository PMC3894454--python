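import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from stimpat.mvpa import (
    PatternDataset,
    SimulationSpec,
    correlational_analysis,
    normalize_correlation,
    normalize_svm,
    pairwise_svm_decode,
    read_dataset_csv,
    simulate_patterns,
    split_half,
    train_test_split,
    write_dataset_csv,
)


@pytest.fixture
def dataset():
    spec = SimulationSpec(n_conditions=3, n_runs=2,
                          samples_per_condition_per_run=4, n_voxels=30,
                          signal_sd=2.0, run_noise_sd=0.5,
                          sample_noise_sd=1.0, seed=11)
    return simulate_patterns(spec)


def shuffle_labels_within_runs(ds, rng):
    cond = ds.condition.copy()
    for r in np.unique(ds.run):
        idx = np.flatnonzero(ds.run == r)
        cond[idx] = cond[rng.permutation(idx)]
    return PatternDataset(ds.data, cond, ds.run, ds.subject, ds.roi)


class TestSimulate:
    def test_bookkeeping(self):
        spec = SimulationSpec(n_conditions=2, n_runs=2,
                              samples_per_condition_per_run=4, n_voxels=50,
                              seed=0)
        ds = simulate_patterns(spec)
        assert ds.data.shape == (16, 50)
        assert len(ds.condition) == 16
        counts = pd.Series(ds.condition).value_counts()
        assert set(counts) == {8}
        ds.check_runs()

    def test_zero_noise_reproduces_templates(self):
        spec = SimulationSpec(n_conditions=2, n_runs=2,
                              samples_per_condition_per_run=2, n_voxels=20,
                              signal_sd=1.0, run_noise_sd=0.0,
                              sample_noise_sd=0.0, seed=3)
        ds = simulate_patterns(spec)
        for c in ds.conditions:
            block = ds.data[ds.condition == c]
            assert np.all(block == block[0])

    def test_seed_determinism(self):
        spec = SimulationSpec(seed=9)
        a = simulate_patterns(spec)
        b = simulate_patterns(spec)
        assert np.array_equal(a.data, b.data)
        c = simulate_patterns(SimulationSpec(seed=10))
        assert not np.array_equal(a.data, c.data)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            SimulationSpec(n_conditions=0)
        with pytest.raises(ValueError):
            SimulationSpec(signal_sd=-1.0)


class TestNormalizers:
    def test_correlation_centering_per_run_per_voxel(self, dataset):
        out = normalize_correlation(dataset)
        for r in np.unique(out.run):
            means = out.data[out.run == r].mean(axis=0)
            assert np.abs(means).max() <= 1e-12

    def test_svm_centering_per_run_condition(self, dataset):
        out = normalize_svm(dataset)
        for r in np.unique(out.run):
            for c in np.unique(out.condition):
                m = (out.run == r) & (out.condition == c)
                assert abs(out.data[m].mean()) <= 1e-12

    @pytest.mark.parametrize("norm", [normalize_correlation, normalize_svm])
    def test_idempotent(self, dataset, norm):
        once = norm(dataset)
        twice = norm(once)
        assert np.abs(once.data - twice.data).max() <= 1e-12

    def test_correlation_equals_per_run_oracle(self, dataset):
        out = normalize_correlation(dataset)
        for r in np.unique(dataset.run):
            m = dataset.run == r
            sub = PatternDataset(dataset.data[m], dataset.condition[m],
                                 dataset.run[m])
            np.testing.assert_allclose(out.data[m],
                                       normalize_correlation(sub).data,
                                       atol=1e-12)

    def test_svm_matches_group_loop_oracle(self, dataset):
        out = normalize_svm(dataset)
        expected = dataset.data.copy()
        for i in range(dataset.n_samples):
            m = ((dataset.run == dataset.run[i])
                 & (dataset.condition == dataset.condition[i]))
            expected[i] = dataset.data[i] - dataset.data[m].mean()
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_single_sample_runs_become_zero(self):
        # one sample per run; conditions spread over runs
        ds = PatternDataset(np.arange(8.0).reshape(4, 2),
                            np.array(["a", "b", "a", "b"]),
                            np.array([0, 1, 2, 3]))
        out = normalize_correlation(ds)
        assert np.all(out.data == 0)


class TestSplitHalf:
    def test_even_counts_split_evenly(self, dataset):
        rng = np.random.default_rng(0)
        a, b = split_half(dataset, rng)
        for c in dataset.conditions:
            assert (a.condition == c).sum() == 4
            assert (b.condition == c).sum() == 4

    def test_halves_partition_samples(self, dataset):
        rng = np.random.default_rng(1)
        a, b = split_half(dataset, rng)
        assert a.n_samples + b.n_samples == dataset.n_samples
        stacked = np.vstack([a.data, b.data])
        assert (np.sort(stacked, axis=0) == np.sort(dataset.data, axis=0)).all()

    def test_odd_leftover_assignment_is_balanced(self):
        ds = PatternDataset(np.random.default_rng(5).random((6, 3)),
                            np.array(["a"] * 3 + ["b"] * 3),
                            np.zeros(6, dtype=int))
        rng = np.random.default_rng(77)
        bigger_a = sum(
            (split_half(ds, rng)[0].condition == "a").sum() == 2
            for _ in range(1000))
        assert binomtest(bigger_a, 1000, 0.5).pvalue > 0.001

    def test_small_condition_rejected(self):
        ds = PatternDataset(np.random.default_rng(0).random((3, 3)),
                            np.array(["a", "a", "b"]),
                            np.zeros(3, dtype=int))
        with pytest.raises(ValueError, match="'b'"):
            split_half(ds, np.random.default_rng(0))


class TestTrainTestSplit:
    def test_rounding_at_three_quarters(self, dataset):
        # 8 samples per condition -> 6 train, 2 test
        train, test = train_test_split(dataset, 0.75,
                                       np.random.default_rng(0))
        for c in dataset.conditions:
            assert (train.condition == c).sum() == 6
            assert (test.condition == c).sum() == 2

    def test_two_samples_split_one_one(self):
        ds = PatternDataset(np.random.default_rng(1).random((4, 3)),
                            np.array(["a", "a", "b", "b"]),
                            np.zeros(4, dtype=int))
        train, test = train_test_split(ds, 0.75, np.random.default_rng(2))
        assert train.n_samples == test.n_samples == 2

    def test_partition_is_exhaustive(self, dataset):
        train, test = train_test_split(dataset, 0.75,
                                       np.random.default_rng(3))
        stacked = np.vstack([train.data, test.data])
        assert (np.sort(stacked, axis=0) == np.sort(dataset.data, axis=0)).all()

    def test_run_unit_assigns_whole_runs(self):
        spec = SimulationSpec(n_conditions=2, n_runs=4,
                              samples_per_condition_per_run=2, n_voxels=10,
                              seed=5)
        ds = simulate_patterns(spec)
        train, test = train_test_split(ds, 0.75, np.random.default_rng(1),
                                       unit="run")
        train_runs = set(np.unique(train.run))
        test_runs = set(np.unique(test.run))
        assert train_runs.isdisjoint(test_runs)
        assert len(train_runs) == 3 and len(test_runs) == 1
        assert train.n_samples + test.n_samples == ds.n_samples


class TestCorrelationalAnalysis:
    def test_noise_free_within_condition_is_one(self):
        spec = SimulationSpec(n_conditions=3, n_runs=2,
                              samples_per_condition_per_run=2, n_voxels=40,
                              signal_sd=1.0, run_noise_sd=0.0,
                              sample_noise_sd=0.0, seed=21)
        tab = correlational_analysis(simulate_patterns(spec), n_iter=10,
                                     seed=0)
        within = tab[tab.condition_a == tab.condition_b]["value"]
        np.testing.assert_allclose(within, 1.0, atol=1e-9)

    def test_record_count_is_all_unordered_pairs(self, dataset):
        tab = correlational_analysis(dataset, n_iter=5, seed=0)
        k = len(dataset.conditions)
        assert len(tab) == k * (k + 1) // 2
        assert (tab["value"].abs() <= 1.0).all()

    def test_metadata_records_defaults(self, dataset):
        tab = correlational_analysis(dataset, seed=0)
        assert tab.attrs["metadata"]["n_iter"] == 100

    def test_high_snr_within_exceeds_between(self):
        wins = 0
        for rep in range(100):
            spec = SimulationSpec(n_conditions=3, n_runs=2,
                                  samples_per_condition_per_run=2,
                                  n_voxels=40, signal_sd=5.0,
                                  run_noise_sd=0.2, sample_noise_sd=0.5,
                                  seed=1000 + rep)
            tab = correlational_analysis(simulate_patterns(spec), n_iter=10,
                                         seed=rep)
            within = tab[tab.condition_a == tab.condition_b]["value"].mean()
            between = tab[tab.condition_a != tab.condition_b]["value"].mean()
            wins += within > between
        assert wins >= 99

    def test_deterministic_given_seed(self, dataset):
        a = correlational_analysis(dataset, n_iter=20, seed=4)
        b = correlational_analysis(dataset, n_iter=20, seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert (a["value"] == b["value"]).all()


class TestPairwiseSVM:
    def test_separated_templates_decode_perfectly(self):
        spec = SimulationSpec(n_conditions=3, n_runs=2,
                              samples_per_condition_per_run=4, n_voxels=50,
                              signal_sd=5.0, run_noise_sd=0.1,
                              sample_noise_sd=0.1, seed=3)
        tab = pairwise_svm_decode(simulate_patterns(spec), n_iter=20, seed=0)
        assert (tab["value"] == 1.0).all()

    def test_record_count_excludes_diagonal(self, dataset):
        tab = pairwise_svm_decode(dataset, n_iter=5, seed=0)
        k = len(dataset.conditions)
        assert len(tab) == k * (k - 1) // 2
        assert ((tab["value"] >= 0) & (tab["value"] <= 1)).all()

    def test_metadata_records_defaults(self, dataset):
        tab = pairwise_svm_decode(dataset, n_iter=2, seed=0)
        md = tab.attrs["metadata"]
        assert md["train_frac"] == 0.75
        assert md["nu"] == 0.5

    def test_deterministic_given_seed(self, dataset):
        a = pairwise_svm_decode(dataset, n_iter=10, seed=8)
        b = pairwise_svm_decode(dataset, n_iter=10, seed=8)
        assert (a["value"] == b["value"]).all()

    def test_shuffled_labels_are_at_chance(self):
        # Monte Carlo with a fresh dataset, shuffle and splits per
        # replication, so the replication means are i.i.d. and their
        # empirical SE covers dataset-level variance.  The calibration data
        # are exchangeable (no condition signal, no run noise): sample-level
        # splits only guarantee chance under exchangeability.
        rng = np.random.default_rng(55)
        means = []
        for rep in range(12):
            ds = simulate_patterns(SimulationSpec(
                n_conditions=3, n_runs=2, samples_per_condition_per_run=4,
                n_voxels=30, signal_sd=0.0, run_noise_sd=0.0,
                sample_noise_sd=1.0, seed=int(rng.integers(2**31))))
            shuf = shuffle_labels_within_runs(ds, rng)
            tab = pairwise_svm_decode(shuf, n_iter=25, seed=rep)
            means.append(tab["value"].mean())
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - 0.5) <= 3 * se + 1e-12

    def test_run_level_splits_stay_at_chance_despite_run_noise(self):
        # whole-run splits keep both run offsets and the run-consistent
        # shuffled label structure out of the train/test leak path, so
        # chance holds even with condition signal and strong run noise
        rng = np.random.default_rng(66)
        means = []
        for rep in range(12):
            ds = simulate_patterns(SimulationSpec(
                n_conditions=3, n_runs=4, samples_per_condition_per_run=2,
                n_voxels=30, signal_sd=1.0, run_noise_sd=1.0,
                sample_noise_sd=1.0, seed=int(rng.integers(2**31))))
            shuf = shuffle_labels_within_runs(ds, rng)
            tab = pairwise_svm_decode(shuf, n_iter=25, seed=rep,
                                      split_unit="run")
            means.append(tab["value"].mean())
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - 0.5) <= 3 * se + 1e-12


class TestSnrLadder:
    def test_correlation_contrast_monotone_in_snr(self):
        contrasts = []
        for noise in (2.0, 1.0, 0.5):  # rising SNR
            spec = SimulationSpec(n_conditions=3, n_runs=2,
                                  samples_per_condition_per_run=4,
                                  n_voxels=60, signal_sd=1.0,
                                  run_noise_sd=0.3, sample_noise_sd=noise,
                                  seed=42)
            tab = correlational_analysis(simulate_patterns(spec), n_iter=30,
                                         seed=7)
            within = tab[tab.condition_a == tab.condition_b]["value"].mean()
            between = tab[tab.condition_a != tab.condition_b]["value"].mean()
            contrasts.append(within - between)
        assert contrasts[0] < contrasts[1] < contrasts[2]


class TestDatasetIO:
    def test_csv_roundtrip(self, dataset, tmp_path):
        dpath, lpath = tmp_path / "data.csv", tmp_path / "labels.csv"
        write_dataset_csv(dataset, dpath, lpath)
        back = read_dataset_csv(dpath, lpath)
        np.testing.assert_allclose(back.data, dataset.data, atol=1e-9)
        assert (back.condition == dataset.condition).all()
        assert (back.run == dataset.run).all()
        assert back.subject == dataset.subject
        assert back.roi == dataset.roi

    def test_missing_label_column_rejected(self, dataset, tmp_path):
        dpath, lpath = tmp_path / "d.csv", tmp_path / "l.csv"
        write_dataset_csv(dataset, dpath, lpath)
        labels = pd.read_csv(lpath).drop(columns=["run"])
        labels.to_csv(lpath, index=False)
        with pytest.raises(ValueError, match="run"):
            read_dataset_csv(dpath, lpath)


class TestDatasetValidation:
    def test_run_coverage_checked_at_analysis_entry(self):
        ds = PatternDataset(np.random.default_rng(0).random((6, 4)),
                            np.array(["a", "a", "b", "b", "a", "a"]),
                            np.array([0, 0, 0, 0, 1, 1]))
        with pytest.raises(ValueError, match="missing condition"):
            correlational_analysis(ds, n_iter=2, seed=0)

    def test_needs_two_conditions_and_voxels(self):
        with pytest.raises(ValueError):
            PatternDataset(np.zeros((4, 4)), np.array(["a"] * 4),
                           np.zeros(4, dtype=int))
        with pytest.raises(ValueError):
            PatternDataset(np.zeros((4, 1)), np.array(["a", "a", "b", "b"]),
                           np.zeros(4, dtype=int))
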
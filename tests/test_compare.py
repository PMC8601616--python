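"""ICA comparison stage: filtering, stability scan, optimal N, knee selection.

The expensive pieces (bootstrapped stability scans, repeated fastICA) run
once per session on the planted-source fixture and are shared across
tests.
"""

import numpy as np
import pytest

from commet.compare import (CombinedLoadings, StabilityScan, choose_optimal_n,
                            concat_and_filter, final_ica, knee_select,
                            stability_scan)
from commet.decompose import LoadingMatrix
from commet.fixtures import make_planted_loadings

SEED = 7


@pytest.fixture(scope="module")
def planted():
    return make_planted_loadings(n_reactions=1000, sources=3,
                                 noise_sd=0.02, seed=0)


@pytest.fixture(scope="module")
def combined(planted):
    return concat_and_filter(planted.condition1, planted.condition2)


@pytest.fixture(scope="module")
def scan(combined):
    return stability_scan(combined, n_range=range(2, 11), runs=20, seed=SEED)


@pytest.fixture(scope="module")
def features(combined, scan):
    n_opt = choose_optimal_n(scan)
    return knee_select(final_ica(combined, n_opt, runs=200, seed=SEED))


class TestConcatAndFilter:
    def test_cutoff_formula_worked_example(self):
        # per-reaction maxima (1.0, 0.9, 0.1, 0.05):
        # median 0.5, mean 0.5125, mean abs dev 0.4375 -> cutoff 0.9375
        ids = ["r1", "r2", "r3", "r4"]
        lm1 = LoadingMatrix(ids, np.array([[1.0], [0.9], [0.1], [0.05]]),
                            np.array([1.0]), rotated=True,
                            condition_label="c1")
        lm2 = LoadingMatrix(ids, np.zeros((4, 1)), np.array([1.0]),
                            rotated=True, condition_label="c2")
        cl = concat_and_filter(lm1, lm2)
        assert cl.cutoff == pytest.approx(0.9375)
        assert cl.reaction_ids == ["r1"]
        assert cl.n_removed_reactions == 3

    def test_disjoint_reaction_sets_zero_filled(self):
        lm1 = LoadingMatrix(["a"], np.array([[2.0]]), np.array([1.0]),
                            rotated=True, condition_label="c1")
        lm2 = LoadingMatrix(["b"], np.array([[2.0]]), np.array([1.0]),
                            rotated=True, condition_label="c2")
        cl = concat_and_filter(lm1, lm2)
        assert cl.reaction_ids == ["a", "b"]
        np.testing.assert_array_equal(cl.matrix, [[2.0, 0.0], [0.0, 2.0]])

    def test_column_provenance(self, planted, combined):
        k1 = planted.condition1.n_components
        assert combined.provenance[0] == ("condition1", 0)
        assert combined.provenance[k1] == ("condition2", 0)
        assert combined.n_columns == k1 + planted.condition2.n_components

    def test_requires_rotated_inputs(self):
        lm = LoadingMatrix(["a"], np.array([[1.0]]), np.array([1.0]),
                           rotated=False)
        with pytest.raises(ValueError, match="rotated"):
            concat_and_filter(lm, lm)


class TestStabilityScan:
    def test_two_laplace_sources_highly_stable_at_n2(self):
        rng = np.random.default_rng(3)
        Z = rng.laplace(size=(600, 2))
        W = rng.uniform(-1, 1, size=(6, 2))
        X = Z @ W.T + 0.01 * rng.standard_normal((600, 6))
        cl = CombinedLoadings([f"r{i}" for i in range(600)], X,
                              [("c1", j) for j in range(6)], 0.0, 0)
        scan = stability_scan(cl, n_range=range(2, 5), runs=15, seed=1)
        assert (scan.profiles[2] > 0.9).all()

    def test_deterministic_for_fixed_seed(self, combined):
        a = stability_scan(combined, n_range=range(2, 5), runs=5, seed=3)
        b = stability_scan(combined, n_range=range(2, 5), runs=5, seed=3)
        assert a.n_values == b.n_values
        for n in a.n_values:
            np.testing.assert_array_equal(a.profiles[n], b.profiles[n])

    def test_profile_lengths_and_range(self, scan):
        for n, prof in scan.profiles.items():
            assert len(prof) == n
            assert (prof >= -1).all() and (prof <= 1).all()
            assert (np.diff(prof) <= 1e-12).all()  # sorted descending

    def test_average_stability_decreases_beyond_true_sources(self, scan):
        mean_by_n = {n: scan.profiles[n].mean() for n in scan.n_values}
        assert mean_by_n[3] > mean_by_n[10]

    def test_n_range_validation(self, combined):
        with pytest.raises(ValueError, match="below the column count"):
            stability_scan(combined, n_range=range(2, combined.n_columns + 1),
                           runs=5, seed=0)
        with pytest.raises(ValueError, match="at least 2"):
            stability_scan(combined, n_range=range(2, 4), runs=1, seed=0)


class TestChooseOptimalN:
    def test_constructed_profiles_cross_at_five(self):
        profiles = {n: np.array([0.95] * min(n, 5) + [0.2] * max(0, n - 5))
                    for n in range(2, 11)}
        scan = StabilityScan(profiles, runs=10, nonlinearity="pow3", seed=0)
        assert choose_optimal_n(scan) == 5

    def test_planted_three_sources_found(self, scan):
        assert choose_optimal_n(scan) == 3

    def test_needs_three_n_values(self):
        scan = StabilityScan({2: np.array([0.9, 0.9])}, 10, "pow3", 0)
        with pytest.raises(ValueError, match="at least 3"):
            choose_optimal_n(scan)

    def test_degenerate_uniform_values_error(self):
        profiles = {n: np.full(n, 0.5) for n in (2, 3, 4)}
        scan = StabilityScan(profiles, 10, "pow3", 0)
        with pytest.raises(ValueError, match="degenerate|dominates"):
            choose_optimal_n(scan)


class TestFinalIca:
    def test_gaussian_columns_rarely_retained(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((500, 6))
        cl = CombinedLoadings([f"r{i}" for i in range(500)], X,
                              [("c1", j) for j in range(6)], 0.0, 0)
        feats = final_ica(cl, 3, runs=30, seed=2)
        # Gaussian excess kurtosis is 0: retention should be rare
        assert feats.kurtosis_retained <= 0.25 * 3 * 30

    def test_planted_laplace_components_retained(self, features):
        assert features.kurtosis_retained > 0.8 * features.runs * 3

    def test_deterministic_frequencies(self, combined):
        a = final_ica(combined, 3, runs=10, seed=4)
        b = final_ica(combined, 3, runs=10, seed=4)
        np.testing.assert_array_equal(a.frequencies, b.frequencies)

    def test_frequency_bounded_by_retained(self, features):
        assert features.frequencies.sum() == features.kurtosis_retained
        assert (features.frequencies >= 0).all()


class TestKneeSelect:
    def make(self, freq):
        from commet.compare import DistinctFeatures
        freq = np.asarray(freq)
        return DistinctFeatures(
            optimal_n=3, frequencies=freq, kurtosis_retained=int(freq.sum()),
            runs=100, kurtosis_bound=1.0,
            provenance=[("c1", j) for j in range(freq.size)], seed=0)

    def test_plateau_cliff_curve(self):
        feats = knee_select(self.make([100, 98, 96, 10, 9, 8]))
        assert feats.knee_index == 2
        assert len(feats.selected_columns) == 3

    def test_convex_curve_stops_before_drop(self):
        feats = knee_select(self.make([200, 180, 5, 0, 0, 0]))
        assert len(feats.selected_columns) == 2

    def test_linear_curve_fallback_empty(self):
        with pytest.warns(RuntimeWarning, match="flat/linear"):
            feats = knee_select(self.make([50, 40, 30, 20, 10, 0]))
        assert feats.selected_columns == []
        assert feats.knee_index is None

    def test_selection_subset_and_provenance(self, features, combined):
        sel = features.selected_columns
        assert sel and set(sel) <= set(range(combined.n_columns))
        per_cond = features.selected_per_condition()
        assert sum(per_cond.values()) == len(sel)


class TestSourceRecovery:
    def test_condition_specific_columns_recovered(self, planted, combined,
                                                  features):
        sel = set(features.selected_columns)
        k1 = planted.condition1.n_components
        expected = {col for col, _ in planted.specific_columns["condition1"]}
        expected |= {col + k1 for col, _ in planted.specific_columns["condition2"]}
        assert expected <= sel

    def test_selected_columns_match_ground_truth_sources(self, planted,
                                                         combined, features):
        rows = [planted.condition1.reaction_ids.index(r)
                for r in combined.reaction_ids]
        for col in features.selected_columns:
            best = max(
                abs(np.corrcoef(combined.matrix[:, col],
                                planted.sources[rows, s])[0, 1])
                for s in range(planted.sources.shape[1]))
            assert best >= 0.95
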
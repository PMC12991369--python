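"""Subsampling, the instability criterion phi, and tuning-value selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import BaseEstimator

from connis.genome import GeneSet, InsertionSiteSet
from connis.instability import (
    InstabilityTuner,
    instability_phi,
    label_matrix,
    select_tuning,
    subsample_insertions,
)
from connis.callers import ConnisCaller
from connis.metrics import confusion, mcc, sweep
from connis.simulate import SimulationConfig, simulate_library


class TestSubsample:
    def test_size_and_membership(self, rng):
        iss = InsertionSiteSet(100, np.arange(1, 21), np.arange(1, 21))
        sub = subsample_insertions(iss, 0.5, rng)
        assert sub.h == 10
        assert set(sub.positions) <= set(iss.positions)
        # read counts travel with their positions
        assert all(sub.sites[p] == iss.sites[p] for p in sub.positions)

    def test_same_seed_same_subsample(self):
        iss = InsertionSiteSet(1000, np.arange(1, 101))
        a = subsample_insertions(iss, 0.5, np.random.default_rng(7))
        b = subsample_insertions(iss, 0.5, np.random.default_rng(7))
        assert np.array_equal(a.positions, b.positions)

    def test_floor_of_fraction(self):
        iss = InsertionSiteSet(10_000, np.arange(1, 1001))
        assert subsample_insertions(iss, 0.999, np.random.default_rng(0)).h == 999

    def test_empty_subsample_rejected(self):
        iss = InsertionSiteSet(100, [5])
        with pytest.raises(ValueError):
            subsample_insertions(iss, 0.5, np.random.default_rng(0))


class TestPhi:
    def test_hand_worked_example(self):
        m = np.array([[1, 1, 1, 1], [1, 0, 0, 0], [0, 0, 0, 0]], dtype=bool)
        phi, q, pi = instability_phi(m)
        assert pi.tolist() == [1.0, 0.25, 0.0]
        assert q == 2
        assert phi == pytest.approx(0.09375, abs=1e-15)

    def test_constant_labels_are_perfectly_stable(self):
        assert instability_phi(np.ones((5, 8), dtype=bool))[0] == 0.0
        assert instability_phi(np.zeros((5, 8), dtype=bool))[0] == 0.0

    def test_half_half_matrix_attains_maximum(self):
        # every counted gene essential in exactly half the subsamples: coin-flip
        m = np.tile([True, False], (7, 5))
        assert instability_phi(m)[0] == 0.25

    @settings(max_examples=200, deadline=None)
    @given(st.integers(1, 30), st.integers(2, 16), st.integers(0, 2**31 - 1))
    def test_bounds_on_random_matrices(self, p, m, seed):
        labels = np.random.default_rng(seed).random((p, m)) < 0.4
        phi, q, pi = instability_phi(labels)
        assert 0.0 <= phi <= 0.25
        assert (phi == 0.0) == bool(np.all((pi == 0) | (pi == 1)))

    def test_invariant_under_row_and_column_permutation(self, rng):
        labels = rng.random((20, 10)) < 0.3
        phi = instability_phi(labels)[0]
        assert instability_phi(labels[rng.permutation(20)])[0] == pytest.approx(phi)
        assert instability_phi(labels[:, rng.permutation(10)])[0] == pytest.approx(phi)

    def test_fair_coin_rows_approach_maximum(self, rng):
        labels = rng.random((200, 4000)) < 0.5
        assert instability_phi(labels)[0] == pytest.approx(0.25, abs=3 / np.sqrt(4000))


class TestSelectTuning:
    def test_hand_trace_discards_uninformative_prefix(self):
        ws, w_max = select_tuning([0.1, 0.2, 0.3, 0.4, 0.5], [0, 0.10, 0.20, 0.15, 0.18])
        assert (ws, w_max) == (0.4, 0.3)

    def test_decreasing_phi_keeps_whole_grid(self):
        ws, w_max = select_tuning([1, 2, 3], [0.2, 0.1, 0.05])
        assert (ws, w_max) == (3, 1)

    def test_constant_phi_breaks_ties_small(self):
        ws, w_max = select_tuning([0.1, 0.2, 0.3], [0.1, 0.1, 0.1])
        assert (ws, w_max) == (0.1, 0.1)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            select_tuning([], [])


class _FixedLabeler(BaseEstimator):
    """Labels are a deterministic function of the tuning value only."""

    tuning_param = "level"
    default_grid = (0.0, 1.0)

    def __init__(self, level=1.0):
        self.level = level

    def _prepare(self, genes, insertions):
        return {"n": len(genes)}

    def _labels_from_state(self, state):
        return np.full(state["n"], self.level > 0.5), {}


class TestLabelMatrix:
    GENES = GeneSet(["a", "b", "c"], [1, 30, 60], [20, 50, 80], genome_length=100)
    ISS = InsertionSiteSet(100, np.arange(1, 101, 3))

    def test_always_reject_gives_all_ones(self):
        m = label_matrix(_FixedLabeler(level=1.0), self.GENES, self.ISS, m=4, seed=0)
        assert m.shape == (3, 4) and m.all()

    def test_never_reject_gives_all_zeros(self):
        m = label_matrix(_FixedLabeler(level=0.0), self.GENES, self.ISS, m=4, seed=0)
        assert not m.any()

    def test_connis_matrix_reproducible(self):
        caller = ConnisCaller(weight=1.0, alpha=0.5, correction="none", trunc_frac=0.0)
        a = label_matrix(caller, self.GENES, self.ISS, m=3, seed=42)
        b = label_matrix(caller, self.GENES, self.ISS, m=3, seed=42)
        assert np.array_equal(a, b)


class TestTuner:
    @pytest.fixture(scope="class")
    def easy_library(self):
        # sinusoidal density with light noise: the regime the criterion is
        # built for (an interior weight is both stable and informative)
        cfg = SimulationConfig(genome_length=400_000, n_genes=350, n_essential=30,
                               free_fraction=0.8, n_is=35_000, n_noise=700,
                               profile="sinusoidal", seed=5)
        return simulate_library(cfg)

    def test_selected_weight_is_near_grid_optimal(self, easy_library):
        lib = easy_library
        caller = ConnisCaller(alpha=0.05, correction="holm", trunc_frac=0.05)
        tuner = InstabilityTuner(caller, m=30, seed=9).fit(lib.genes, lib.insertions)
        table = sweep(caller, lib.genes, lib.insertions, lib.truth)
        selected_mcc = mcc(confusion(lib.truth.to_numpy(), tuner.labels_))
        assert selected_mcc >= table.mcc.max() - 0.05
        # and never worse than the unweighted (w = 1) caller
        unweighted = table.set_index("value").loc[1.0, "mcc"]
        assert selected_mcc >= unweighted - 1e-12

    def test_profile_shape_and_flags(self, easy_library):
        lib = easy_library
        tuner = InstabilityTuner(ConnisCaller(), grid=[0.4, 0.7, 1.0], m=5, seed=3)
        tuner.fit(lib.genes, lib.insertions)
        assert list(tuner.profile_["value"]) == [0.4, 0.7, 1.0]
        assert tuner.profile_["selected"].sum() == 1
        assert np.all((tuner.profile_["phi"] >= 0) & (tuner.profile_["phi"] <= 0.25))
        assert tuner.pi_hat_.shape == (len(lib.genes), 3)
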
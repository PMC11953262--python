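"""Binary firefly-algorithm wavelength selection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spectracal as sc
from spectracal import firefly
from spectracal.exceptions import DomainError, ShapeError


@pytest.fixture(scope="module")
def toy6():
    """12 samples x 6 channels of near-linear mixture data."""
    rng = np.random.default_rng(0)
    C = rng.uniform(1, 10, size=(12, 3))
    E = rng.uniform(0.02, 0.1, size=(3, 6))
    X = C @ E + rng.normal(0, 0.002, size=(12, 6))
    return X, C[:, 0]


@pytest.fixture(scope="module")
def split_fixture():
    """8 samples x 31 channels; signal only at 200-280 nm, strong pure
    noise elsewhere — the informative region is known by construction."""
    g = sc.WavelengthGrid(200, 350, 5)
    wl = g.wavelengths()
    informative = wl <= 280
    profs = sc.default_ternary_library(g)
    rng = np.random.default_rng(1)
    C = rng.uniform(1, 10, size=(8, 3))
    E = np.zeros((3, g.n_points))
    for k, p in enumerate(profs):
        E[k] = np.where(informative, p.epsilon(wl), 0.0)
    X = C @ E + rng.normal(0, 0.002, size=(8, g.n_points))
    X[:, ~informative] = rng.normal(0, 0.2, size=(8, int((~informative).sum())))
    return X, C[:, 0], informative


class TestAttraction:
    @pytest.mark.parametrize("beta0,gamma,r,expected", [
        (1.0, 1.0, 0.0, 1.0),
        (2.0, 1.0, 1.0, 2.0 * np.exp(-1)),
    ])
    def test_kernel_values(self, beta0, gamma, r, expected):
        assert sc.attraction(beta0, gamma, r) == pytest.approx(expected, rel=1e-12)

    @settings(deadline=None, max_examples=60)
    @given(beta0=st.floats(0.1, 5), gamma=st.floats(0.01, 10),
           r1=st.floats(0, 10), r2=st.floats(0, 10))
    def test_monotone_decreasing_in_distance(self, beta0, gamma, r1, r2):
        lo, hi = sorted((r1, r2))
        assert sc.attraction(beta0, gamma, hi) <= sc.attraction(beta0, gamma, lo)

    def test_negative_distance_rejected(self):
        with pytest.raises(DomainError):
            sc.attraction(1, 1, -0.1)


class TestFaSelect:
    def test_within_ten_percent_of_exhaustive_optimum(self, toy6):
        """On a 6-channel instance the FA mask scores within 10% of the
        brute-force optimum over all feasible masks."""
        X, y = toy6
        cfg = sc.AnnConfig(n_hidden=1, n_restarts=1, max_epochs=150, seed=2)
        best = np.inf
        for bits in itertools.product([0, 1], repeat=6):
            mask = np.array(bits, dtype=bool)
            if mask.sum() < 3:  # min_selected = n_hidden + 2
                continue
            best = min(best, sc.loo_rrmsecv(X, y, cfg, wavelength_mask=mask))
        params = sc.FaParams(n_fireflies=10, max_generations=25, stagnation_window=10, seed=3)
        res = sc.fa_select(X, y, params, cfg)
        assert res.best_rrmsecv <= 1.1 * best + 1e-8

    def test_full_mask_fitness_is_full_spectrum_rrmsecv(self, toy6):
        X, y = toy6
        cfg = sc.AnnConfig(n_hidden=1, n_restarts=1, max_epochs=150, seed=2)
        full = sc.loo_rrmsecv(X, y, cfg)
        masked = sc.loo_rrmsecv(X, y, cfg, wavelength_mask=np.ones(6, dtype=bool))
        assert masked == full

    def test_best_never_worse_than_full_spectrum(self, toy6):
        X, y = toy6
        cfg = sc.AnnConfig(n_hidden=1, n_restarts=1, max_epochs=150, seed=2)
        params = sc.FaParams(n_fireflies=6, max_generations=5, stagnation_window=3, seed=0)
        res = sc.fa_select(X, y, params, cfg)
        assert res.best_rrmsecv <= sc.loo_rrmsecv(X, y, cfg) + 1e-12

    def test_history_is_nonincreasing(self, toy6):
        X, y = toy6
        cfg = sc.AnnConfig(n_hidden=1, n_restarts=1, max_epochs=150, seed=2)
        params = sc.FaParams(n_fireflies=8, max_generations=10, stagnation_window=5, seed=4)
        res = sc.fa_select(X, y, params, cfg)
        assert all(a >= b for a, b in zip(res.history, res.history[1:]))
        assert res.generations_run <= params.max_generations
        assert res.best_rrmsecv == res.history[-1]

    def test_reproducibility(self, toy6):
        X, y = toy6
        cfg = sc.AnnConfig(n_hidden=1, n_restarts=1, max_epochs=150, seed=2)
        params = sc.FaParams(n_fireflies=6, max_generations=6, stagnation_window=3, seed=5)
        a = sc.fa_select(X, y, params, cfg)
        b = sc.fa_select(X, y, params, cfg)
        np.testing.assert_array_equal(a.mask, b.mask)
        assert a.best_rrmsecv == b.best_rrmsecv and a.history == b.history

    def test_selection_concentrates_on_informative_region(self, split_fixture):
        """At least 70% of the selected channels fall in the region that
        carries signal by construction."""
        X, y, informative = split_fixture
        cfg = sc.AnnConfig(n_hidden=1, n_restarts=1, max_epochs=150, seed=2)
        params = sc.FaParams(n_fireflies=12, max_generations=40, stagnation_window=15,
                             alpha=0.3, seed=1)
        res = sc.fa_select(X, y, params, cfg)
        assert res.mask[informative].sum() / res.mask.sum() >= 0.7
        assert res.n_selected < X.shape[1]  # dimensionality reduced

    def test_min_selected_enforced(self, toy6):
        X, y = toy6
        cfg = sc.AnnConfig(n_hidden=1, n_restarts=1, max_epochs=150, seed=2)
        params = sc.FaParams(n_fireflies=4, max_generations=3, stagnation_window=2,
                             min_selected=6, seed=0)
        res = sc.fa_select(X, y, params, cfg)
        assert res.n_selected == 6  # only the all-ones mask is feasible

    def test_too_narrow_matrix_rejected(self, toy6):
        X, y = toy6
        cfg = sc.AnnConfig(n_hidden=1, n_restarts=1, max_epochs=150, seed=2)
        with pytest.raises(ShapeError):
            sc.fa_select(X[:, :2], y, sc.FaParams(min_selected=3), cfg)

    def test_sigmoid_binarization_runs(self, toy6):
        X, y = toy6
        cfg = sc.AnnConfig(n_hidden=1, n_restarts=1, max_epochs=150, seed=2)
        params = sc.FaParams(n_fireflies=6, max_generations=4, stagnation_window=2,
                             seed=6, binarization="sigmoid")
        res = sc.fa_select(X, y, params, cfg)
        assert res.n_selected >= 3


class TestGridSearch:
    def test_single_cell_equals_plain_run(self, toy6):
        X, y = toy6
        cfg = sc.AnnConfig(n_hidden=1, n_restarts=1, max_epochs=150, seed=2)
        base = sc.FaParams(n_fireflies=6, max_generations=4, stagnation_window=2, seed=9)
        best_params, table = sc.grid_search_fa(X, y, {"gamma": [1.0]}, cfg, base)
        assert len(table) == 1
        # the cell runs with the derived seed recorded in best_params
        res = sc.fa_select(X, y, best_params, cfg)
        assert res.best_rrmsecv == table["best_rrmsecv"].iloc[0]

    def test_product_table_shape(self, toy6):
        X, y = toy6
        cfg = sc.AnnConfig(n_hidden=1, n_restarts=1, max_epochs=100, seed=2)
        base = sc.FaParams(n_fireflies=4, max_generations=2, stagnation_window=2, seed=9)
        _, table = sc.grid_search_fa(X, y, {"gamma": [0.5, 2.0], "alpha": [0.1, 0.3]},
                                     cfg, base)
        assert len(table) == 4
        assert set(table.columns) == {"gamma", "alpha", "best_rrmsecv", "n_selected"}

    def test_ties_break_toward_smaller_mask(self, toy6, monkeypatch):
        X, y = toy6
        cfg = sc.AnnConfig(n_hidden=1, n_restarts=1, max_epochs=100, seed=2)
        canned = {0.5: (1.0, 5), 2.0: (1.0, 3)}  # same fitness, smaller mask for gamma=2

        def fake_select(X_, y_, params, ann_config, include_full_mask=True):
            fit, npick = canned[params.gamma]
            mask = np.zeros(6, dtype=bool)
            mask[:npick] = True
            return firefly.SelectionResult(mask, fit, [fit], 1, params)

        monkeypatch.setattr(firefly, "fa_select", fake_select)
        best_params, _ = firefly.grid_search_fa(X, y, {"gamma": [0.5, 2.0]}, cfg)
        assert best_params.gamma == 2.0

    def test_empty_grid_rejected(self, toy6):
        X, y = toy6
        cfg = sc.AnnConfig(n_hidden=1, n_restarts=1, seed=2)
        with pytest.raises(DomainError):
            sc.grid_search_fa(X, y, {}, cfg)
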
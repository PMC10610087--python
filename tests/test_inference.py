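"""Composite likelihood, bounded optimization, grids and gridsearch."""

import logging

import numpy as np
import pytest

from imscan.demography import DemographyParams, KmaxSpec, Model
from imscan.engine import compute_bsfs_pmf, sample_block_tally
from imscan.inference import (
    GridSpec,
    default_grid,
    gridsearch,
    ln_composite_likelihood,
    makegrid,
    optimize,
)
from imscan.tally import BsfsTally

KMAX = KmaxSpec(2, 2, 2, 2)


def _tally_from_cells(cells: dict):
    counts = np.zeros(KMAX.shape, dtype=np.int64)
    for idx, n in cells.items():
        counts[idx] = n
    return BsfsTally.from_array(counts, KMAX)


def test_ln_cl_direct_arithmetic():
    # two configurations: counts {c1: 2, c2: 1}, p(c1)=0.5, p(c2)=0.25
    tally = _tally_from_cells({(0, 0, 0, 0): 2, (1, 0, 0, 0): 1})
    logp = np.full(KMAX.shape, -np.inf)
    logp[0, 0, 0, 0] = np.log(0.5)
    logp[1, 0, 0, 0] = np.log(0.25)
    val = ln_composite_likelihood(tally, logp)
    assert val == pytest.approx(2 * np.log(0.5) + np.log(0.25))
    assert val == pytest.approx(-2.772588722239781)


def test_ln_cl_linear_in_counts():
    tally = _tally_from_cells({(0, 0, 0, 0): 3, (0, 1, 0, 0): 4})
    double = _tally_from_cells({(0, 0, 0, 0): 6, (0, 1, 0, 0): 8})
    logp = np.log(np.full(KMAX.shape, 1.0 / 256))
    assert ln_composite_likelihood(double, logp) == \
        pytest.approx(2 * ln_composite_likelihood(tally, logp))


def test_ln_cl_empty_tally_is_zero():
    assert ln_composite_likelihood(_tally_from_cells({}), np.zeros(KMAX.shape)) == 0.0


def test_ln_cl_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="shape"):
        ln_composite_likelihood(_tally_from_cells({}), np.zeros((3, 3, 3, 3)))


def test_observed_zero_probability_cell_reported(caplog):
    tally = _tally_from_cells({(1, 1, 1, 1): 1})
    logp = np.full(KMAX.shape, -np.inf)
    with caplog.at_level(logging.WARNING):
        val = ln_composite_likelihood(tally, logp)
    assert val == -np.inf
    assert "zero model probability" in caplog.text


def test_ln_cl_invariant_to_block_order(global_model_params):
    """Pooling blocks from several pairs in any order gives the same
    composite likelihood (the sum runs over pairs and blocks)."""
    logp = compute_bsfs_pmf(global_model_params, KMAX).log()
    a = sample_block_tally(global_model_params, KMAX, 5000, seed=1)
    b = sample_block_tally(global_model_params, KMAX, 5000, seed=2)
    pooled = BsfsTally.from_array(a + b, KMAX)
    split_sum = (ln_composite_likelihood(BsfsTally.from_array(a, KMAX), logp)
                 + ln_composite_likelihood(BsfsTally.from_array(b, KMAX), logp))
    assert ln_composite_likelihood(pooled, logp) == pytest.approx(split_sum, rel=1e-12)


# ---------------------------------------------------------------------------
# optimize
# ---------------------------------------------------------------------------


def test_collapsed_bounds_return_that_point(global_model_params):
    tally = BsfsTally.from_array(
        sample_block_tally(global_model_params, KMAX, 2000, seed=9), KMAX)
    p = global_model_params
    bounds = {k: (getattr(p, k), getattr(p, k))
              for k in ("N_A", "N_B", "N_anc", "T", "m_e")}
    res = optimize(tally, p.model, bounds, mu=p.mu, block_length=p.block_length)
    assert res.params.N_A == p.N_A and res.params.m_e == p.m_e
    expected = ln_composite_likelihood(tally, compute_bsfs_pmf(p, KMAX).log())
    assert res.ln_cl == pytest.approx(expected)


def test_midpoint_start_is_default_and_random_start_is_seeded(global_model_params):
    tally = BsfsTally.from_array(
        sample_block_tally(global_model_params, KMAX, 2000, seed=9), KMAX)
    bounds = {"N_A": (1e5, 1e6), "N_B": (1e5, 1e6), "N_anc": (1e5, 1e6),
              "T": (1e6, 1e7), "m_e": (1e-8, 1e-5)}
    res = optimize(tally, Model.IM_AtoB, bounds, max_evaluations=3)
    assert res.start["N_A"] == pytest.approx(np.sqrt(1e5 * 1e6))
    r1 = optimize(tally, Model.IM_AtoB, bounds, start="random", seed=5,
                  max_evaluations=3)
    r2 = optimize(tally, Model.IM_AtoB, bounds, start="random", seed=5,
                  max_evaluations=3)
    assert r1.start == r2.start


def test_optimize_recovers_three_parameter_migration_model():
    """Scaled-down parameter recovery under the MIG model (the full
    five-parameter run lives in the acceptance suite)."""
    truth = DemographyParams(Model.MIG_AtoB, N_A=5e5, N_B=1.2e6, m_e=8e-7,
                             mu=2.9e-9, block_length=64)
    tally = BsfsTally.from_array(sample_block_tally(truth, KMAX, 200_000, seed=31), KMAX)
    bounds = {"N_A": (5e4, 5e6), "N_B": (5e4, 5e6), "m_e": (1e-8, 1e-5)}
    res = optimize(tally, truth.model, bounds, mu=truth.mu)
    for k in ("N_A", "N_B", "m_e"):
        assert abs(getattr(res.params, k) - getattr(truth, k)) / getattr(truth, k) < 0.1


# ---------------------------------------------------------------------------
# makegrid / gridsearch
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def toy_grid():
    spec = GridSpec(
        model=Model.IM_AtoB,
        axes={"N_A": np.array([3e5, 6e5]), "N_B": np.array([8e5, 1.6e6]),
              "N_anc": np.array([5e5, 1e6]), "m_e": np.array([0.0, 7.41e-7])},
        fixed={"T": 4.216e6}, mu=2.9e-9, block_length=64, kmax=KMAX,
    )
    return makegrid(spec)


def test_toy_grid_stores_normalised_pmfs(toy_grid):
    assert toy_grid.n_points == 16
    assert not toy_grid.errors
    probs = np.exp(toy_grid.flat())
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-8)


def test_gridsearch_equals_brute_force_loop(toy_grid, global_model_params):
    tallies = [BsfsTally.from_array(
        sample_block_tally(global_model_params, KMAX, 500, seed=s), KMAX)
        for s in range(4)]
    res = gridsearch(tallies, toy_grid)
    flat = toy_grid.flat()
    for t, tally in enumerate(tallies):
        c = tally.counts.ravel()
        sel = c > 0
        brute = np.array([float((flat[h, sel] * c[sel]).sum())
                          for h in range(toy_grid.n_points)])
        assert np.allclose(res.ln_cl[t], brute, rtol=1e-12, atol=0)
        assert res.best_index[t] == int(np.argmax(brute))


def test_one_point_grid_is_trivially_argmax(global_model_params):
    spec = GridSpec(model=Model.IM_AtoB,
                    axes={"N_A": np.array([5e5]), "N_B": np.array([1.4e6]),
                          "N_anc": np.array([9e5]), "m_e": np.array([7e-7])},
                    fixed={"T": 4.216e6}, mu=2.9e-9, kmax=KMAX)
    grid = makegrid(spec)
    tally = BsfsTally.from_array(
        sample_block_tally(global_model_params, KMAX, 100, seed=1), KMAX)
    res = gridsearch(tally, grid)
    assert res.best_index[0] == 0


def test_ties_broken_to_lowest_index_and_reported(toy_grid):
    empty = BsfsTally.from_array(np.zeros(KMAX.shape, dtype=np.int64), KMAX)
    res = gridsearch(empty, toy_grid)
    assert res.best_index[0] == 0
    assert res.ties[0] == list(range(16))


def test_gridsearch_on_combined_tally_bounds_per_window_average(
        toy_grid, global_model_params):
    """ln CL of the pooled tally at any shared grid point equals the sum
    over windows, so the pooled maximum is at least the sum of any single
    shared point's per-window values."""
    tallies = [BsfsTally.from_array(
        sample_block_tally(global_model_params, KMAX, 1000, seed=40 + s), KMAX)
        for s in range(3)]
    pooled = BsfsTally.from_array(sum(t.counts for t in tallies), KMAX)
    res_w = gridsearch(tallies, toy_grid)
    res_p = gridsearch(pooled, toy_grid)
    best_pooled = res_p.ln_cl[0, res_p.best_index[0]]
    for h in range(toy_grid.n_points):
        assert best_pooled >= res_w.ln_cl[:, h].sum() - 1e-9


def test_grid_containing_truth_is_selected_on_large_tally(global_model_params):
    """Self-consistency: with the generating parameters on the grid, a
    large simulated tally picks them."""
    p = global_model_params
    spec = GridSpec(
        model=p.model,
        axes={"N_A": p.N_A * np.array([0.5, 1.0, 2.0]),
              "N_B": p.N_B * np.array([0.5, 1.0, 2.0]),
              "N_anc": p.N_anc * np.array([0.5, 1.0, 2.0]),
              "m_e": p.m_e * np.array([0.0, 0.5, 1.0, 2.0])},
        fixed={"T": p.T}, mu=p.mu, kmax=KMAX)
    grid = makegrid(spec)
    tally = BsfsTally.from_array(sample_block_tally(p, KMAX, 300_000, seed=77), KMAX)
    res = gridsearch(tally, grid)
    best = res.best_point[0]
    assert best["N_A"] == p.N_A and best["N_B"] == p.N_B
    assert best["N_anc"] == p.N_anc and best["m_e"] == p.m_e


def test_makegrid_records_failures_and_continues():
    spec = GridSpec(model=Model.MIG_AtoB,
                    axes={"N_A": np.array([1e5]), "N_B": np.array([1e5]),
                          "m_e": np.array([0.0, 1e-7])},
                    fixed={}, mu=1e-9, kmax=KMAX)
    grid = makegrid(spec)
    assert 0 in grid.errors            # m_e = 0 under MIG cannot coalesce
    assert len(grid.errors) == 1
    # the surviving point stores a proper distribution (four-gamete-
    # impossible cells legitimately carry -inf log-probability)
    assert np.exp(grid.flat()[1]).sum() == pytest.approx(1.0, abs=1e-8)


def test_default_grid_contains_centre_and_zero_migration():
    g = default_grid(Model.IM_AtoB,
                     center=dict(N_A=5e5, N_B=1e6, N_anc=9e5, m_e=7.41e-7),
                     fixed={"T": 4.2e6}, n_sizes=4, n_m=6)
    assert g.axes["m_e"][0] == 0.0
    assert 7.41e-7 in g.axes["m_e"]
    assert g.shape == (4, 4, 4, 6)


def test_grid_spec_validates_parameter_coverage():
    with pytest.raises(ValueError, match="neither"):
        GridSpec(model=Model.IM_AtoB, axes={"N_A": np.array([1e5])}, fixed={})
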
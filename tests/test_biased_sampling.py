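import numpy as np
import pytest

from tcrmsm.biased_sampling import (
    KB_KCAL_PER_MOL_K,
    AnalyticPotential,
    BiasState,
    reconstruct_free_energy,
    run_wt_metadynamics,
)
from tcrmsm.synthetic import double_well


def flat_potential(extent=50.0):
    return AnalyticPotential(lambda s: 0.0 * np.asarray(s),
                             lambda s: 0.0 * np.asarray(s),
                             (-extent, extent))


def _crossings(traj, threshold=0.5):
    side = np.where(traj < -threshold, -1, np.where(traj > threshold, 1, 0))
    side = side[side != 0]
    return int(np.sum(np.diff(side) != 0))


def test_free_diffusion_variance_grows_linearly():
    """Unbiased dynamics on a flat potential: Var[s(t)] ≈ 2·D·t with D = kB·T,
    checked at three time points within 3 standard errors over 200 repeats."""
    pot = flat_potential()
    dt = 0.01
    d = KB_KCAL_PER_MOL_K * 300.0
    checkpoints = [100, 300, 500]
    finals = {c: [] for c in checkpoints}
    for rep in range(200):
        bias = BiasState(hill_width=0.3, deposition_stride=10 ** 9)
        traj, _ = run_wt_metadynamics(pot, bias, steps=500, step_size=dt,
                                      seed=rep, s0=0.0)
        for c in checkpoints:
            finals[c].append(traj[c])
    for c in checkpoints:
        samples = np.asarray(finals[c])
        expected = 2.0 * d * c * dt
        var = samples.var(ddof=1)
        # SE of a variance estimate from n normal samples: var·sqrt(2/(n−1))
        se = var * np.sqrt(2.0 / (len(samples) - 1))
        assert abs(var - expected) < 3 * se


def test_huge_bias_factor_recovers_standard_metadynamics():
    bias = BiasState(hill_width=0.3, initial_height=1.5, bias_factor=1e9,
                     deposition_stride=1)
    bias.deposit(0.0)
    h = bias.deposit(0.0)      # second hill on top of the first
    assert h == pytest.approx(1.5, abs=1e-6 * 1.5)


def test_hill_heights_follow_tempering_law_exactly():
    """Oracle: replay the deposition history and recompute every height from
    the well-tempered law; stored heights must match to 1e-10."""
    pot = double_well(barrier=3.0)
    bias = BiasState(hill_width=0.25, initial_height=0.5, deposition_stride=200)
    _, bias = run_wt_metadynamics(pot, bias, steps=20000, step_size=0.004,
                                  seed=0, s0=-1.0)
    damp = (bias.bias_factor - 1.0) * KB_KCAL_PER_MOL_K * bias.temperature
    replay_heights = []
    for k, c in enumerate(bias.hill_centers):
        v = sum(replay_heights[j] * np.exp(
            -0.5 * ((c - bias.hill_centers[j]) / bias.hill_width) ** 2)
            for j in range(k))
        replay_heights.append(bias.initial_height * np.exp(-v / damp))
    np.testing.assert_allclose(bias.hill_heights, replay_heights, atol=1e-10)


def test_bias_potential_equals_brute_force_hill_sum():
    rng = np.random.default_rng(1)
    bias = BiasState(hill_width=0.4)
    bias.hill_centers = rng.uniform(-2, 2, 30)
    bias.hill_heights = rng.uniform(0.1, 1.0, 30)
    for s in rng.uniform(-2, 2, 10):
        expected = sum(h * np.exp(-0.5 * ((s - c) / 0.4) ** 2)
                       for c, h in zip(bias.hill_centers, bias.hill_heights))
        assert bias.bias_potential(s) == pytest.approx(expected, abs=1e-12)


def test_bias_accelerates_barrier_crossing():
    """The point of the method: the biased walker escapes deep minima."""
    pot = double_well(barrier=6.0)
    unbiased = BiasState(hill_width=0.25, initial_height=0.5,
                         deposition_stride=10 ** 9)
    traj0, _ = run_wt_metadynamics(pot, unbiased, steps=200_000,
                                   step_size=0.004, seed=11, s0=-1.0)
    biased = BiasState(hill_width=0.25, initial_height=0.5,
                       deposition_stride=500)
    traj1, _ = run_wt_metadynamics(pot, biased, steps=200_000,
                                   step_size=0.004, seed=11, s0=-1.0)
    assert _crossings(traj0) == 0
    assert _crossings(traj1) >= 5


def test_single_hill_reconstruction_closed_form():
    bias = BiasState(hill_width=0.3, initial_height=2.0, bias_factor=10.0)
    bias.deposit(0.5)
    grid = np.linspace(-1, 2, 61)
    f = reconstruct_free_energy(bias, grid)
    gauss = 2.0 * np.exp(-0.5 * ((grid - 0.5) / 0.3) ** 2)
    expected = -(10.0 / 9.0) * gauss
    expected -= expected.min()
    np.testing.assert_allclose(f, expected, atol=1e-10)


@pytest.fixture(scope="module")
def converged_double_well_run():
    pot = double_well(barrier=6.0)
    bias = BiasState(hill_width=0.25, initial_height=0.5, deposition_stride=500)
    traj, bias = run_wt_metadynamics(pot, bias, steps=600_000, step_size=0.004,
                                     seed=12, s0=-1.0)
    return pot, bias


def _barrier_and_asymmetry(bias):
    grid = np.linspace(-1.4, 1.4, 281)
    f = reconstruct_free_energy(bias, grid)
    left = f[grid < -0.5].min()
    right = f[grid > 0.5].min()
    barrier = f[np.abs(grid) < 0.15].min() - 0.5 * (left + right)
    return barrier, abs(left - right)


def test_double_well_barrier_reconstruction(converged_double_well_run):
    _, bias = converged_double_well_run
    barrier, asym = _barrier_and_asymmetry(bias)
    assert abs(barrier - 6.0) / 6.0 < 0.15
    assert asym < 0.10 * 6.0     # symmetric well: equal minima


def test_hill_heights_damped_in_revisited_regions(converged_double_well_run):
    _, bias = converged_double_well_run
    c, h = bias.hill_centers, bias.hill_heights
    close = np.abs(c[:, None] - c[None, :]) < 0.05 * bias.hill_width
    ii, jj = np.nonzero(np.triu(close, k=1))
    assert ii.size > 50            # the wells are revisited many times
    assert np.all(h[jj] <= h[ii] * 1.10)


def test_reconstruction_error_decreases_with_simulation_length():
    pot = double_well(barrier=6.0)
    errors = []
    for steps in (100_000, 300_000, 600_000):
        bias = BiasState(hill_width=0.25, initial_height=0.5,
                         deposition_stride=500)
        _, bias = run_wt_metadynamics(pot, bias, steps=steps, step_size=0.004,
                                      seed=20, s0=-1.0)
        barrier, _ = _barrier_and_asymmetry(bias)
        errors.append(abs(barrier - 6.0))
    assert errors[-1] < errors[0]


def test_validation_errors():
    with pytest.raises(ValueError, match="gamma"):
        BiasState(hill_width=0.3, bias_factor=1.0)
    with pytest.raises(ValueError, match="steps"):
        run_wt_metadynamics(flat_potential(), BiasState(hill_width=0.3),
                            steps=0, step_size=0.01, seed=0)
    bias = BiasState(hill_width=0.3)
    with pytest.raises(ValueError, match="grid"):
        reconstruct_free_energy(bias, np.array([]))
    with pytest.raises(ValueError, match="hills"):
        reconstruct_free_energy(bias, np.linspace(-1, 1, 5))


def test_divergence_detected_for_unstable_step():
    stiff = AnalyticPotential(lambda s: 50.0 * np.asarray(s) ** 2,
                              lambda s: 100.0 * np.asarray(s), (-1.0, 1.0))
    with pytest.raises(RuntimeError, match="step_size"):
        run_wt_metadynamics(stiff, BiasState(hill_width=0.3,
                                             deposition_stride=10 ** 9),
                            steps=5000, step_size=0.5, seed=0, s0=0.5)
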
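"""Toy well-tempered metadynamics on analytic 1-D potentials.

The production simulations behind this kind of analysis bias an all-atom
system along a collective variable (CV); here the bias mathematics is
isolated on overdamped Langevin dynamics directly in CV space, which is what
the acceptance of the method actually depends on: hill deposition with
geometric tempering, escape from deep minima, and free-energy reconstruction.

Well-tempered deposition: every ``deposition_stride`` steps a Gaussian of
height h = h0 · exp(−V_bias(s) / ((γ−1) kB T)) is added at the current CV
value s. At convergence the bias tends to −(1 − 1/γ)·F(s), so the free
energy is recovered as F(s) = −γ/(γ−1) · V_bias(s) (minimum shifted to 0).

Defaults follow the production-scale settings where stated: deposition every
1,000 steps, bias factor γ = 10, 300 K. The hill height there is 10.0
kcal/mol on an all-atom CV; on the desk-scale analytic potentials used here
the height is a config parameter (the examples use 0.5 kcal/mol).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KB_KCAL_PER_MOL_K",
    "BiasState",
    "AnalyticPotential",
    "run_wt_metadynamics",
    "reconstruct_free_energy",
]

KB_KCAL_PER_MOL_K = 0.0019872041


@dataclass
class AnalyticPotential:
    """1-D potential with analytic gradient, kcal/mol over a bounded domain."""

    evaluate: callable        # s -> energy
    gradient: callable        # s -> dV/ds
    domain: tuple[float, float]


@dataclass
class BiasState:
    """Accumulated metadynamics bias: hills in deposition order."""

    hill_width: float                 # σ, CV units
    initial_height: float = 10.0      # kcal/mol
    bias_factor: float = 10.0         # γ
    temperature: float = 300.0        # K
    deposition_stride: int = 1000     # steps
    period: float | None = None       # CV period for periodic CVs
    hill_centers: np.ndarray = field(default_factory=lambda: np.empty(0))
    hill_heights: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if not self.bias_factor > 1:
            raise ValueError("bias factor gamma must be > 1")
        if not self.initial_height > 0:
            raise ValueError("initial hill height must be > 0")
        if not self.hill_width > 0:
            raise ValueError("hill width sigma must be > 0")
        self.hill_centers = np.asarray(self.hill_centers, dtype=float)
        self.hill_heights = np.asarray(self.hill_heights, dtype=float)

    @property
    def n_hills(self) -> int:
        return self.hill_centers.size

    def _delta(self, s) -> np.ndarray:
        d = np.subtract.outer(np.atleast_1d(np.asarray(s, float)), self.hill_centers)
        if self.period is not None:
            d -= self.period * np.round(d / self.period)  # minimum image
        return d

    def bias_potential(self, s) -> np.ndarray | float:
        """Total bias at s — the sum over all deposited hills."""
        if self.n_hills == 0:
            out = np.zeros(np.shape(np.atleast_1d(s)))
        else:
            d = self._delta(s)
            out = (self.hill_heights * np.exp(-0.5 * (d / self.hill_width) ** 2)).sum(axis=-1)
        return out if np.ndim(s) else float(out[0])

    def bias_gradient(self, s) -> float:
        if self.n_hills == 0:
            return 0.0
        d = self._delta(s)[0]
        w = self.hill_heights * np.exp(-0.5 * (d / self.hill_width) ** 2)
        return float((w * (-d / self.hill_width ** 2)).sum())

    def deposit(self, s: float) -> float:
        """Add a well-tempered hill at s; returns the deposited height."""
        damp = (self.bias_factor - 1.0) * KB_KCAL_PER_MOL_K * self.temperature
        h = self.initial_height * np.exp(-self.bias_potential(s) / damp)
        self.hill_centers = np.append(self.hill_centers, s)
        self.hill_heights = np.append(self.hill_heights, h)
        return float(h)

    def hills_dataframe(self):
        """HILLS-style log: time index, center, width, height."""
        import pandas as pd
        return pd.DataFrame({
            "hill": np.arange(self.n_hills),
            "center": self.hill_centers,
            "sigma": np.full(self.n_hills, self.hill_width),
            "height": self.hill_heights,
        })


def run_wt_metadynamics(potential: AnalyticPotential, bias: BiasState,
                        steps: int, step_size: float, seed: int,
                        s0: float | None = None):
    """Overdamped Langevin dynamics in CV space under a growing bias.

    ds = −(V' + V_bias') dt + sqrt(2 kB T dt) η, mobility 1, so the free
    diffusion coefficient is D = kB T. Deterministic for a fixed seed.
    Returns (cv_trajectory, bias).
    """
    if steps <= 0:
        raise ValueError("steps must be > 0")
    rng = np.random.default_rng(seed)
    lo, hi = potential.domain
    extent = hi - lo
    kt = KB_KCAL_PER_MOL_K * bias.temperature
    noise_scale = np.sqrt(2.0 * kt * step_size)
    s = 0.5 * (lo + hi) if s0 is None else float(s0)
    traj = np.empty(steps + 1)
    traj[0] = s
    noise = rng.standard_normal(steps)
    for t in range(steps):
        force = -(potential.gradient(s) + bias.bias_gradient(s))
        s = s + force * step_size + noise_scale * noise[t]
        if bias.period is not None:
            s = lo + (s - lo) % bias.period
        if s < lo - 10 * extent or s > hi + 10 * extent:
            raise RuntimeError(
                f"CV diverged to {s:.3g} at step {t}; reduce step_size"
            )
        if (t + 1) % bias.deposition_stride == 0:
            bias.deposit(s)
        traj[t + 1] = s
    return traj, bias


def reconstruct_free_energy(bias: BiasState, grid: np.ndarray) -> np.ndarray:
    """Well-tempered estimator F(s) = −γ/(γ−1) · V_bias(s), min-shifted to 0."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    if bias.n_hills == 0:
        raise ValueError("no hills deposited; nothing to reconstruct")
    f = -(bias.bias_factor / (bias.bias_factor - 1.0)) * bias.bias_potential(grid)
    return f - f.min()
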
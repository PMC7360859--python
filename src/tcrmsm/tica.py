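"""Time-lagged independent component analysis and free-energy surfaces.

tICA finds the linear combinations of features with maximal autocorrelation
at a lag time τ (10 ns at production scale): solve the generalized
eigenproblem C(τ) v = λ C(0) v, with both covariances estimated over all
(t, t+τ) pairs — pairs never span trajectory boundaries — and C(τ)
symmetrized, which assumes reversible dynamics and guarantees a real
spectrum with eigenvalues in (−1, 1]. Leading components approximate the
slowest collective motions; two are retained by default (the landscapes in
this analysis are 2-D).

Free-energy surfaces are Boltzmann inversions of the projected histogram,
F = −kB·T ln ρ, minimum shifted to zero; unsampled bins carry NaN, not a
number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .biased_sampling import KB_KCAL_PER_MOL_K
from .featurize import FeatureMatrix

__all__ = [
    "TICAModel",
    "FreeEnergySurface",
    "fit_tica",
    "project",
    "project_structure",
    "free_energy_surface",
]


@dataclass
class TICAModel:
    mean: np.ndarray              # per-feature mean over pair-weighted data
    eigenvalues: np.ndarray       # retained, sorted descending, clipped to (-1, 1]
    components: np.ndarray        # (n_features, n_components), C0-orthonormal
    lag: float                    # ns
    regularization: float
    labels: list[str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "mean": self.mean.tolist(),
                "eigenvalues": self.eigenvalues.tolist(),
                "components": self.components.tolist(),
                "lag_ns": self.lag,
                "regularization": self.regularization,
                "labels": self.labels,
            }, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TICAModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["mean"]), np.array(d["eigenvalues"]),
                   np.array(d["components"]), d["lag_ns"],
                   d["regularization"], list(d["labels"]))


@dataclass
class FreeEnergySurface:
    edges: list[np.ndarray]       # per-axis bin edges
    values: np.ndarray            # kcal/mol; NaN where unsampled
    counts: np.ndarray
    temperature: float            # K


def _as_feature_list(features) -> list[FeatureMatrix]:
    if isinstance(features, FeatureMatrix):
        return [features]
    return list(features)


def fit_tica(features, lag: float, n_components: int = 2,
             reg: float = 1e-6) -> TICAModel:
    """Fit tICA at lag time ``lag`` (ns) over one or several trajectories."""
    fms = _as_feature_list(features)
    dt = fms[0].frame_interval
    labels = fms[0].labels
    for fm in fms[1:]:
        if fm.labels != labels:
            raise ValueError("feature labels differ between trajectories")
        if fm.frame_interval != dt:
            raise ValueError("frame intervals differ between trajectories")
    tau = lag / dt
    tau_frames = int(round(tau))
    if tau_frames < 1 or abs(tau - tau_frames) > 1e-6:
        raise ValueError(f"lag {lag} ns is not a positive multiple of the "
                         f"{dt} ns frame interval")
    shortest = min(fm.n_frames for fm in fms)
    if tau_frames >= shortest:
        raise ValueError(f"lag of {tau_frames} frames >= shortest trajectory "
                         f"({shortest} frames)")
    d = len(labels)
    sum_x = np.zeros(d)
    c0 = np.zeros((d, d))
    ct = np.zeros((d, d))
    n_pairs = 0
    for fm in fms:
        x0 = fm.values[:-tau_frames]
        xt = fm.values[tau_frames:]
        sum_x += x0.sum(axis=0) + xt.sum(axis=0)
        c0 += x0.T @ x0 + xt.T @ xt
        ct += x0.T @ xt
        n_pairs += x0.shape[0]
    mean = sum_x / (2.0 * n_pairs)
    c0 = c0 / (2.0 * n_pairs) - np.outer(mean, mean)
    ct = ct / n_pairs - np.outer(mean, mean)
    ct = 0.5 * (ct + ct.T)                        # reversibility symmetrization
    c0r = c0 + reg * np.eye(d)
    try:
        eigvals, eigvecs = scipy.linalg.eigh(ct, c0r)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError("singular instantaneous covariance; increase reg") from exc
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order][:n_components]
    eigvecs = eigvecs[:, order][:, :n_components]
    eigvals = np.clip(eigvals, -1.0, 1.0)         # reporting range
    return TICAModel(mean, eigvals, eigvecs, lag, reg, list(labels))


def project(model: TICAModel, features) -> np.ndarray:
    """Mean-centered projection onto the retained components."""
    if isinstance(features, FeatureMatrix):
        if features.labels != model.labels:
            raise ValueError("feature labels do not match the tICA model")
        x = features.values
    else:
        x = np.atleast_2d(np.asarray(features, float))
        if x.shape[1] != model.mean.size:
            raise ValueError("feature dimension does not match the tICA model")
    return (x - model.mean) @ model.components


def project_structure(model: TICAModel, structure, selections,
                      angles=("psi", "phi")) -> np.ndarray:
    """Project a single conformation (e.g. a crystal structure) into tICA space.

    The structure is featurized with the identical dihedral definition used
    for the trajectories, so the point is directly comparable with the
    landscape. Returns a 1-D point of length n_components.
    """
    from .featurize import psi_phi_features
    from .structure_io import Trajectory
    traj = Trajectory(structure, structure.coordinates[None], 1.0)
    fm = psi_phi_features(traj, selections, angles)
    if fm.labels != model.labels:
        raise ValueError(
            "structure features do not match the model (different loop "
            "length or selection?)"
        )
    return project(model, fm)[0]


def free_energy_surface(projections: np.ndarray, temperature: float = 300.0,
                        bins: int | tuple = 40) -> FreeEnergySurface:
    """Boltzmann inversion of the histogram of projected points."""
    pts = np.atleast_2d(np.asarray(projections, float))
    if pts.shape[0] < 1:
        raise ValueError("need at least one projected point")
    for axis in range(pts.shape[1]):
        if pts.shape[0] > 1 and np.ptp(pts[:, axis]) == 0.0:
            raise ValueError(f"projection axis {axis} has zero extent")
    counts, edges = np.histogramdd(pts, bins=bins)
    kt = KB_KCAL_PER_MOL_K * temperature
    with np.errstate(divide="ignore"):
        f = -kt * np.log(counts / counts.sum())
    f[counts == 0] = np.nan
    f -= np.nanmin(f)
    return FreeEnergySurface([np.asarray(e) for e in edges], f, counts.astype(int),
                             temperature)
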
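"""Synthetic inputs with known ground truth.

Three generators stand in for the production simulation data while keeping
every downstream contract exercised end to end:

* hidden-Markov dihedral trajectories — a discrete-state Markov chain with a
  known transition matrix emits backbone φ/ψ angles (state-specific means +
  Gaussian noise) that are realised as toy polyalanine-like backbones via
  NeRF-style chain extension with idealised geometry;
* two-domain assemblies — rigid pseudo-Vα/Vβ domains plus pseudo-CDR3
  loops, placed per frame so the four-COM interdomain torsion equals a
  macrostate-specific target exactly (plus optional angle-level and
  coordinate-level noise);
* analytic double-well potentials for the metadynamics test bed.

Hidden-state dwell times are geometric (discrete-time chain), so the
Markov-state-model assumptions are exactly satisfiable — which is the point
of a ground truth. All generators are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .featurize import _wrap_deg
from .msm import sample_markov_chain
from .structure_io import RegionSelection, Structure, Trajectory

__all__ = [
    "HMMDihedralSpec",
    "TwoDomainSpec",
    "generate_hmm_trajectory",
    "generate_two_domain_trajectory",
    "double_well",
    "build_backbone",
]

# Idealised backbone geometry (Å, degrees); side chains omitted — downstream
# features are dihedral-based, so this suffices.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA = 180.0

MASS = {"N": 14.007, "CA": 12.011, "C": 12.011}


def _place(a, b, c, bond: float, angle_deg: float, torsion_deg) -> np.ndarray:
    """NeRF placement of atom d given three predecessors (vectorised over frames)."""
    angle = np.radians(angle_deg)
    torsion = np.radians(np.asarray(torsion_deg, float))
    bc = c - b
    bc /= np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    d2 = np.stack([
        -bond * np.cos(angle) * np.ones_like(torsion),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ], axis=-1)
    return c + (d2[..., 0:1] * bc + d2[..., 1:2] * m + d2[..., 2:3] * n)


def build_backbone(phi_deg: np.ndarray, psi_deg: np.ndarray) -> np.ndarray:
    """Backbone coordinates from torsions, atoms N/CA/C per residue.

    ``phi_deg``/``psi_deg`` are (n_frames, n_res) arrays; φ of the first
    residue and ψ of the last are ignored (undefined without a flanking
    residue). Returns (n_frames, 3·n_res, 3) in Å.
    """
    phi = np.atleast_2d(np.asarray(phi_deg, float))
    psi = np.atleast_2d(np.asarray(psi_deg, float))
    n_frames, n_res = phi.shape
    coords = np.empty((n_frames, 3 * n_res, 3))
    ang = np.radians(ANGLE_N_CA_C)
    coords[:, 0] = [0.0, 0.0, 0.0]                     # N1
    coords[:, 1] = [BOND_N_CA, 0.0, 0.0]               # CA1
    coords[:, 2] = coords[:, 1] + [BOND_CA_C * -np.cos(ang),
                                   BOND_CA_C * np.sin(ang), 0.0]  # C1
    for i in range(1, n_res):
        nn, ca, cc = 3 * (i - 1), 3 * (i - 1) + 1, 3 * (i - 1) + 2
        coords[:, 3 * i] = _place(coords[:, nn], coords[:, ca], coords[:, cc],
                                  BOND_C_N, ANGLE_CA_C_N, psi[:, i - 1])
        coords[:, 3 * i + 1] = _place(coords[:, ca], coords[:, cc], coords[:, 3 * i],
                                      BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        coords[:, 3 * i + 2] = _place(coords[:, cc], coords[:, 3 * i],
                                      coords[:, 3 * i + 1],
                                      BOND_CA_C, ANGLE_N_CA_C, phi[:, i])
    return coords


def _backbone_topology(chains: dict[str, int], start_resnum: int = 1,
                       coords: np.ndarray | None = None) -> Structure:
    names, resnums, chain_ids, elements, masses = [], [], [], [], []
    for chain, n_res in chains.items():
        for r in range(n_res):
            for atom in ("N", "CA", "C"):
                names.append(atom)
                resnums.append(start_resnum + r)
                chain_ids.append(chain)
                elements.append(atom[0])
                masses.append(MASS[atom])
    n = len(names)
    if coords is None:
        coords = np.zeros((n, 3))
    return Structure(names, np.array(resnums), chain_ids, elements,
                     np.array(masses), coords)


# ---------------------------------------------------------------------------
# Hidden-Markov dihedral trajectories

@dataclass
class HMMDihedralSpec:
    """Metastable dihedral dynamics with a known hidden chain.

    ``psi_means`` maps chain id → (n_states, n_res−1) state-specific ψ means
    (degrees); φ is held near ``phi_mean`` for every state (the slow motions
    of interest here live in ψ). Emission noise is i.i.d. Gaussian with
    ``emission_sigma`` degrees on every sampled angle.
    """

    transition_matrix: np.ndarray
    psi_means: dict[str, np.ndarray]
    emission_sigma: float = 15.0
    phi_mean: float = -60.0
    n_frames: int = 10000
    frame_interval: float = 1.0     # ns
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, float)
        t = self.transition_matrix
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ValueError("transition matrix must be square")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must sum to 1")
        if not self.emission_sigma > 0:
            raise ValueError("emission sigma must be > 0")
        n_states = t.shape[0]
        self.psi_means = {k: np.atleast_2d(np.asarray(v, float))
                          for k, v in self.psi_means.items()}
        for chain, means in self.psi_means.items():
            if means.shape[0] != n_states:
                raise ValueError(
                    f"chain {chain}: psi_means has {means.shape[0]} state rows, "
                    f"expected {n_states}"
                )

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def selections(self) -> list[RegionSelection]:
        names = {"A": "CDR3_alpha", "B": "CDR3_beta"}
        out = []
        for chain, means in self.psi_means.items():
            n_res = means.shape[1] + 1
            out.append(RegionSelection(names.get(chain, "custom"), chain,
                                       (1, n_res)))
        return out


def generate_hmm_trajectory(spec: HMMDihedralSpec):
    """Sample the hidden chain and realise per-frame backbones.

    Returns (Trajectory, hidden_states). Chains are laid out side by side
    (100 Å apart) so they never interleave spatially.
    """
    rng = np.random.default_rng(spec.seed)
    hidden = sample_markov_chain(
        spec.transition_matrix, spec.n_frames,
        seed=int(rng.integers(2 ** 31)),
    )
    blocks = []
    offset = 0.0
    chain_sizes = {}
    for chain, means in spec.psi_means.items():
        n_res = means.shape[1] + 1
        chain_sizes[chain] = n_res
        psi = means[hidden] + rng.normal(0.0, spec.emission_sigma,
                                         (spec.n_frames, n_res - 1))
        psi = _wrap_deg(psi)
        # pad the (undefined) last-residue psi; build_backbone ignores it
        psi_full = np.concatenate([psi, np.zeros((spec.n_frames, 1))], axis=1)
        phi = _wrap_deg(rng.normal(spec.phi_mean, spec.emission_sigma,
                                   (spec.n_frames, n_res)))
        xyz = build_backbone(phi, psi_full)
        xyz[..., 0] += offset
        offset += 100.0
        blocks.append(xyz)
    frames = np.concatenate(blocks, axis=1)
    topology = _backbone_topology(chain_sizes, coords=frames[0])
    return Trajectory(topology, frames, spec.frame_interval), hidden


# ---------------------------------------------------------------------------
# Two-domain assemblies with prescribed interdomain torsion

@dataclass
class TwoDomainSpec:
    """Rigid pseudo-Vα/Vβ assembly with macrostate-conditioned torsions.

    Each macrostate prescribes a target interdomain torsion (degrees); the
    per-frame macrostate label is drawn i.i.d. from ``occupancies`` or, when
    given, from ``label_transition_matrix`` (a Markov chain, which makes the
    labels themselves MSM-estimable). ``angle_sigma_deg`` adds Gaussian
    spread on the realised torsion; ``jitter_sigma`` adds Å-level noise on
    every atom. ``loop_psi_means`` optionally couples pseudo-CDR3 loop
    conformations to the macrostate (one (n_states, loop_n_res−1) array per
    loop), which is what makes the headline coupling between loop state and
    interface angle reproducible — and removable — on synthetic data.
    """

    targets_deg: np.ndarray
    occupancies: np.ndarray | None = None
    label_transition_matrix: np.ndarray | None = None
    jitter_sigma: float = 0.0          # Å
    angle_sigma_deg: float = 0.0
    n_frames: int = 1000
    frame_interval: float = 1.0        # ns
    seed: int = 0
    loop_n_res: int = 6
    loop_psi_means: np.ndarray | None = None   # (n_states, loop_n_res-1)
    loop_sigma_deg: float = 8.0
    domain_separation: float = 40.0    # Å between Vα and Vβ COMs
    cdr_offset: float = 15.0           # Å from domain axis to each CDR COM

    def __post_init__(self) -> None:
        self.targets_deg = np.atleast_1d(np.asarray(self.targets_deg, float))
        if np.any((self.targets_deg <= -180) | (self.targets_deg > 180)):
            raise ValueError("targets must lie in (-180, 180]")
        n = self.targets_deg.size
        if self.label_transition_matrix is not None:
            t = np.asarray(self.label_transition_matrix, float)
            if t.shape != (n, n) or not np.allclose(t.sum(axis=1), 1.0):
                raise ValueError("label transition matrix must be row-stochastic n×n")
            self.label_transition_matrix = t
        else:
            occ = np.atleast_1d(np.asarray(
                self.occupancies if self.occupancies is not None
                else np.full(n, 1.0 / n), float))
            if occ.size != n or not np.isclose(occ.sum(), 1.0):
                raise ValueError("occupancies must sum to 1, one per macrostate")
            self.occupancies = occ
        if self.loop_psi_means is not None:
            m = np.atleast_2d(np.asarray(self.loop_psi_means, float))
            if m.shape != (n, self.loop_n_res - 1):
                raise ValueError("loop_psi_means must be (n_states, loop_n_res-1)")
            self.loop_psi_means = m

    @property
    def n_states(self) -> int:
        return self.targets_deg.size

    # region definitions matching the generated topology
    def region_selections(self):
        fw = (1, 6)
        loop = (101, 100 + self.loop_n_res)
        return {
            "cdr_alpha": RegionSelection("CDR_loops_alpha", "A", loop),
            "v_alpha": RegionSelection("V_alpha", "A", fw),
            "v_beta": RegionSelection("V_beta", "B", fw),
            "cdr_beta": RegionSelection("CDR_loops_beta", "B", loop),
        }

    def loop_selections(self):
        loop = (101, 100 + self.loop_n_res)
        return [RegionSelection("CDR3_alpha", "A", loop),
                RegionSelection("CDR3_beta", "B", loop)]


def _octahedron(radius: float = 3.0) -> np.ndarray:
    return radius * np.array([
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
    ], float)


def _two_domain_topology(spec: TwoDomainSpec, coords: np.ndarray) -> Structure:
    names, resnums, chain_ids, elements, masses = [], [], [], [], []
    for chain in ("A", "B"):
        for r in range(6):                      # framework pseudo-atoms
            names.append("CA")
            resnums.append(1 + r)
            chain_ids.append(chain)
            elements.append("C")
            masses.append(MASS["CA"])
        for r in range(spec.loop_n_res):        # loop backbone
            for atom in ("N", "CA", "C"):
                names.append(atom)
                resnums.append(101 + r)
                chain_ids.append(chain)
                elements.append(atom[0])
                masses.append(MASS[atom])
    return Structure(names, np.array(resnums), chain_ids, elements,
                     np.array(masses), coords)


def generate_two_domain_trajectory(spec: TwoDomainSpec):
    """Build the assembly frame by frame; returns (Trajectory, labels).

    Geometry: Vα framework COM at the origin, Vβ framework COM at
    (0, 0, d); the α-loop COM at (r, 0, 0) and the β-loop COM at
    (r·cos θ, r·sin θ, d), which realises the four-COM torsion θ exactly
    (equivalently: the β side rotated about the Vα–Vβ COM axis).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    if spec.label_transition_matrix is not None:
        labels = sample_markov_chain(spec.label_transition_matrix, n,
                                     seed=int(rng.integers(2 ** 31)))
    else:
        labels = rng.choice(spec.n_states, size=n, p=spec.occupancies)
    theta = spec.targets_deg[labels]
    if spec.angle_sigma_deg > 0:
        theta = theta + rng.normal(0.0, spec.angle_sigma_deg, n)
    theta_rad = np.radians(theta)
    d = spec.domain_separation
    r = spec.cdr_offset
    p1 = np.stack([np.full(n, r), np.zeros(n), np.zeros(n)], axis=1)
    p4 = np.stack([r * np.cos(theta_rad), r * np.sin(theta_rad),
                   np.full(n, d)], axis=1)

    def loop_coords(loop_idx: int) -> np.ndarray:
        if spec.loop_psi_means is not None:
            psi = spec.loop_psi_means[labels]
        else:
            psi = np.full((n, spec.loop_n_res - 1), -45.0)
        if spec.loop_sigma_deg > 0:
            psi = psi + rng.normal(0.0, spec.loop_sigma_deg, psi.shape)
        psi_full = np.concatenate([_wrap_deg(psi), np.zeros((n, 1))], axis=1)
        phi = np.full((n, spec.loop_n_res), -60.0)
        xyz = build_backbone(phi, psi_full)
        # translate so the loop's mass-weighted COM sits at the target point
        m = np.tile([MASS["N"], MASS["CA"], MASS["C"]], spec.loop_n_res)
        com = np.einsum("fij,i->fj", xyz, m) / m.sum()
        return xyz - com[:, None, :]

    oct_a = _octahedron()
    oct_b = _octahedron() + np.array([0.0, 0.0, d])
    loops_a = loop_coords(0) + p1[:, None, :]
    loops_b = loop_coords(1) + p4[:, None, :]
    frames = np.concatenate([
        np.broadcast_to(oct_a, (n, 6, 3)),
        loops_a,
        np.broadcast_to(oct_b, (n, 6, 3)),
        loops_b,
    ], axis=1).copy()
    if spec.jitter_sigma > 0:
        frames += rng.normal(0.0, spec.jitter_sigma, frames.shape)
    topology = _two_domain_topology(spec, frames[0])
    return Trajectory(topology, frames, spec.frame_interval), labels


# ---------------------------------------------------------------------------
# Analytic double well

def double_well(barrier: float, min_separation: float = 2.0):
    """Quartic double well V(s) = B·((s/m)² − 1)² with minima at ±m.

    The barrier V(0) − V(±m) equals ``barrier`` exactly by construction;
    m = min_separation / 2. Gradient is analytic.
    """
    from .biased_sampling import AnalyticPotential
    if not barrier > 0:
        raise ValueError("barrier must be > 0")
    m = min_separation / 2.0

    def evaluate(s):
        u = (np.asarray(s, float) / m) ** 2 - 1.0
        return barrier * u ** 2

    def gradient(s):
        s = np.asarray(s, float)
        return 4.0 * barrier * s * ((s / m) ** 2 - 1.0) / m ** 2

    return AnalyticPotential(evaluate, gradient, (-2.0 * m, 2.0 * m))
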
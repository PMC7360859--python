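"""Backbone dihedrals, periodic feature embedding, the metadynamics collective
variable, centers of mass, and the relative Vα-Vβ interdomain torsion.

Angles are degrees in (−180, 180] at every public boundary (figures in this
field report degrees); radians are used internally. The dihedral follows the
IUPAC sign convention: right-handed, cis = 0°.

The interdomain orientation is the torsion angle over four centers of mass —
COM(CDR loops, α chain), COM(Vα), COM(Vβ), COM(CDR loops, β chain) — the
standard four-point proxy for the relative variable-domain (VH/VL-like)
packing angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import RegionSelection, Structure, Trajectory, resolve_selection

__all__ = [
    "FeatureMatrix",
    "CollectiveVariable",
    "AngleSeries",
    "dihedral",
    "psi_phi_features",
    "collective_variable",
    "center_of_mass",
    "interdomain_torsion",
]


@dataclass
class FeatureMatrix:
    """Frames × features, sin/cos-embedded dihedrals in [−1, 1]."""

    values: np.ndarray            # (n_frames, n_features)
    labels: list[str]             # "chain:resnum:psi:sin" etc.
    frame_interval: float         # ns

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (frames x features)")
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("label count must equal feature count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.values, columns=self.labels)


@dataclass
class CollectiveVariable:
    """Linear combination of sine and cosine of selected ψ angles:
    s = Σ a_i sin ψ_i + Σ b_i cos ψ_i.

    The published CV is of this form but its coefficients are not printed;
    the default is uniform weights a_i = b_i = 1, overridable in config.
    """

    weights_sin: np.ndarray
    weights_cos: np.ndarray

    def __post_init__(self) -> None:
        self.weights_sin = np.asarray(self.weights_sin, dtype=float)
        self.weights_cos = np.asarray(self.weights_cos, dtype=float)
        if self.weights_sin.shape != self.weights_cos.shape:
            raise ValueError("sin and cos weight vectors must have equal length")

    @classmethod
    def uniform(cls, n_angles: int) -> "CollectiveVariable":
        return cls(np.ones(n_angles), np.ones(n_angles))


@dataclass
class AngleSeries:
    """Per-frame interdomain torsion, degrees in (−180, 180]."""

    values: np.ndarray
    definition: tuple = field(default=())

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any((self.values <= -180.0) | (self.values > 180.0)):
            raise ValueError("angles must lie in (-180, 180]")


def _wrap_deg(a: np.ndarray) -> np.ndarray:
    """Map to (−180, 180]."""
    a = np.asarray(a, dtype=float)
    wrapped = ((-a + 180.0) % 360.0)
    return 180.0 - wrapped


def dihedral(p1, p2, p3, p4) -> np.ndarray | float:
    """Torsion angle of four points (broadcasts over leading axes), degrees.

    IUPAC convention: looking from p2 to p3, the angle from the p1 side to the
    p4 side, positive clockwise; cis (p1, p4 eclipsed) = 0°.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    eps = 1e-12
    if np.any(b2n < eps) or np.any(np.linalg.norm(n1, axis=-1) < eps) \
            or np.any(np.linalg.norm(n2, axis=-1) < eps):
        raise ValueError("degenerate dihedral geometry (coincident or collinear points)")
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * (b2 / b2n[..., None]), axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    return _wrap_deg(ang)


def _residue_backbone_index(topology: Structure):
    """Map (chain, resnum, icode) -> {atom_name: atom_index} for backbone atoms."""
    table: dict = {}
    for i, name in enumerate(topology.atom_names):
        if name in ("N", "CA", "C", "O"):
            key = (topology.chain_ids[i], int(topology.residue_numbers[i]),
                   topology.insertion_codes[i])
            table.setdefault(key, {})[name] = i
    return table


def _selection_residues(selection: RegionSelection, topology: Structure):
    """Ordered residue keys of a selection (file order within the chain)."""
    idx = resolve_selection(selection, topology)
    keys: list = []
    for i in idx:
        key = (topology.chain_ids[i], int(topology.residue_numbers[i]),
               topology.insertion_codes[i])
        if key not in keys:
            keys.append(key)
    return keys


def _chain_residues(topology: Structure, chain_id: str):
    keys: list = []
    for i in range(topology.n_atoms):
        if topology.chain_ids[i] != chain_id:
            continue
        key = (chain_id, int(topology.residue_numbers[i]), topology.insertion_codes[i])
        if key not in keys:
            keys.append(key)
    return keys


def dihedral_quadruples(topology: Structure, selections, angles=("psi",)):
    """Atom-index quadruples and labels for the requested backbone dihedrals.

    ψ(i) = N(i), CA(i), C(i), N(i+1); φ(i) = C(i−1), N(i), CA(i), C(i).
    Flanking residues are taken from the full chain even when outside the
    selection; a terminal residue without the needed flank contributes no angle.
    """
    bb = _residue_backbone_index(topology)
    quads: list[tuple[int, int, int, int]] = []
    labels: list[str] = []
    for sel in selections:
        sel_keys = _selection_residues(sel, topology)
        chain_keys = _chain_residues(topology, sel.chain_id)
        pos = {k: j for j, k in enumerate(chain_keys)}
        for key in sel_keys:
            res = bb.get(key, {})
            for want in ("N", "CA", "C"):
                if want not in res:
                    raise ValueError(f"residue {key} lacks backbone atom {want}")
            j = pos[key]
            if "phi" in angles and j > 0:
                prev = bb.get(chain_keys[j - 1], {})
                if "C" in prev:
                    quads.append((prev["C"], res["N"], res["CA"], res["C"]))
                    labels.append(f"{key[0]}:{key[1]}{key[2]}:phi")
            if "psi" in angles and j + 1 < len(chain_keys):
                nxt = bb.get(chain_keys[j + 1], {})
                if "N" in nxt:
                    quads.append((res["N"], res["CA"], res["C"], nxt["N"]))
                    labels.append(f"{key[0]}:{key[1]}{key[2]}:psi")
    return quads, labels


def backbone_dihedrals(traj: Trajectory, selections, angles=("psi",)):
    """Raw dihedral series (degrees), one column per angle, plus labels."""
    quads, labels = dihedral_quadruples(traj.topology, selections, angles)
    if not quads:
        raise ValueError("no dihedrals resolvable for the given selections")
    q = np.array(quads)
    vals = dihedral(
        traj.frames[:, q[:, 0]], traj.frames[:, q[:, 1]],
        traj.frames[:, q[:, 2]], traj.frames[:, q[:, 3]],
    )
    return vals, labels


def psi_phi_features(traj: Trajectory, selections, angles=("psi", "phi")) -> FeatureMatrix:
    """Sin/cos-embedded backbone dihedral features for the selected loops."""
    vals_deg, base_labels = backbone_dihedrals(traj, selections, angles)
    rad = np.radians(vals_deg)
    n_frames, n_ang = rad.shape
    out = np.empty((n_frames, 2 * n_ang))
    out[:, 0::2] = np.sin(rad)
    out[:, 1::2] = np.cos(rad)
    labels = []
    for lab in base_labels:
        labels.extend([f"{lab}:sin", f"{lab}:cos"])
    return FeatureMatrix(out, labels, traj.frame_interval)


def collective_variable(features: FeatureMatrix, cv: CollectiveVariable) -> np.ndarray:
    """Evaluate s = Σ a_i sin ψ_i + Σ b_i cos ψ_i per frame."""
    sin_cols = [j for j, lab in enumerate(features.labels)
                if lab.endswith(":psi:sin")]
    cos_cols = [j for j, lab in enumerate(features.labels)
                if lab.endswith(":psi:cos")]
    if len(sin_cols) != cv.weights_sin.size:
        raise ValueError(
            f"CV has {cv.weights_sin.size} weights but features carry "
            f"{len(sin_cols)} psi angles"
        )
    return (features.values[:, sin_cols] @ cv.weights_sin
            + features.values[:, cos_cols] @ cv.weights_cos)


def center_of_mass(coordinates: np.ndarray, topology: Structure,
                   selection: RegionSelection | np.ndarray,
                   mass_weighted: bool = True) -> np.ndarray:
    """COM of a selection; ``coordinates`` may be (n_atoms, 3) or (frames, n_atoms, 3)."""
    if isinstance(selection, RegionSelection):
        idx = resolve_selection(selection, topology)
    else:
        idx = np.asarray(selection, dtype=int)
        if idx.size == 0:
            raise ValueError("empty selection")
    coords = np.asarray(coordinates, dtype=float)[..., idx, :]
    if mass_weighted:
        m = topology.masses[idx]
        total = m.sum()
        if not total > 0:
            raise ValueError("zero total mass in selection")
        return np.einsum("...ij,i->...j", coords, m) / total
    return coords.mean(axis=-2)


def interdomain_torsion(traj: Trajectory,
                        cdr_alpha_loops: RegionSelection,
                        v_alpha: RegionSelection,
                        v_beta: RegionSelection,
                        cdr_beta_loops: RegionSelection,
                        mass_weighted: bool = True) -> AngleSeries:
    """Per-frame four-COM interdomain torsion θ, degrees.

    COM order: CDR loops (α chain) → Vα → Vβ → CDR loops (β chain). The four
    selections must be mutually disjoint.
    """
    sels = (cdr_alpha_loops, v_alpha, v_beta, cdr_beta_loops)
    idx_sets = [resolve_selection(s, traj.topology) for s in sels]
    for a in range(4):
        for b in range(a + 1, 4):
            if np.intersect1d(idx_sets[a], idx_sets[b]).size:
                raise ValueError(
                    f"selections {sels[a].name} and {sels[b].name} overlap"
                )
    coms = [center_of_mass(traj.frames, traj.topology, idx, mass_weighted)
            for idx in idx_sets]
    try:
        vals = dihedral(*coms)
    except ValueError as exc:
        # locate the offending frame for the error message
        for t in range(traj.n_frames):
            try:
                dihedral(coms[0][t], coms[1][t], coms[2][t], coms[3][t])
            except ValueError:
                raise ValueError(f"degenerate COM geometry at frame {t}") from exc
        raise
    return AngleSeries(np.atleast_1d(vals), definition=sels)
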
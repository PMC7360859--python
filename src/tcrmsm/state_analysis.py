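"""Macrostate-conditioned interdomain-angle distributions, their pairwise
statistical comparison, and per-residue RMSF.

Angle summaries use circular statistics by default (mean direction and a
circular variance reported in degrees²); a linear mode is available for
comparability with analyses that ignore wraparound — the two agree far from
±180°, where interface-angle distributions typically live.

Frames are treated as independent by the two-sample Kolmogorov-Smirnov
test although simulation frames are autocorrelated; an optional stride thins
the samples before testing. Raw p-values are reported alongside a
Bonferroni-adjusted column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .clustering import superpose
from .featurize import AngleSeries
from .structure_io import Trajectory

__all__ = [
    "AngleDistribution",
    "KSResult",
    "macrostate_angle_distributions",
    "ks_two_sample",
    "pairwise_ks_table",
    "rmsf",
]


@dataclass
class AngleDistribution:
    """Interdomain-angle sample of one macrostate, degrees."""

    macro: int
    values: np.ndarray
    mean: float                  # circular (or linear) mean, (−180, 180]
    variance: float              # degrees²
    n: int
    empty: bool = False


@dataclass
class KSResult:
    statistic: float             # D in [0, 1]
    p_value: float
    n1: int
    n2: int


def _circular_mean_var(deg: np.ndarray) -> tuple[float, float]:
    rad = np.radians(deg)
    s, c = np.sin(rad).mean(), np.cos(rad).mean()
    mean = math.degrees(math.atan2(s, c))
    if mean <= -180.0:
        mean += 360.0
    r = math.hypot(s, c)
    # circular standard deviation sqrt(-2 ln R), expressed in degrees
    sd = math.degrees(math.sqrt(max(0.0, -2.0 * math.log(max(r, 1e-300)))))
    return mean, sd ** 2


def macrostate_angle_distributions(angles: AngleSeries | np.ndarray,
                                   assignment: np.ndarray,
                                   n_macro: int | None = None,
                                   mode: str = "circular"
                                   ) -> list[AngleDistribution]:
    """One angle distribution per macrostate.

    ``assignment`` holds a macrostate id per frame; negative ids (or None)
    mark unassignable frames, which are excluded. A macrostate with zero
    frames is returned flagged (``empty=True``), never silently dropped.
    """
    vals = angles.values if isinstance(angles, AngleSeries) else np.asarray(angles, float)
    assign = np.array([-1 if a is None else int(a) for a in assignment])
    if assign.size != vals.size:
        raise ValueError("assignment must cover every frame")
    if n_macro is None:
        n_macro = int(assign.max()) + 1
    out = []
    for macro in range(n_macro):
        sample = vals[assign == macro]
        if sample.size == 0:
            out.append(AngleDistribution(macro, sample, float("nan"),
                                         float("nan"), 0, empty=True))
            continue
        if mode == "circular":
            mean, var = _circular_mean_var(sample)
        elif mode == "linear":
            mean, var = float(sample.mean()), float(sample.var(ddof=0))
        else:
            raise ValueError("mode must be 'circular' or 'linear'")
        out.append(AngleDistribution(macro, sample, mean, var, sample.size))
    return out


def ks_two_sample(a, b, stride: int = 1) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test: D = sup |ECDF_a − ECDF_b|.

    The p-value uses the asymptotic Kolmogorov distribution with the
    standard effective-n correction. ``stride`` thins both samples first
    (autocorrelated frames violate the independence assumption; thinning is
    the caller's mitigation).
    """
    a = np.asarray(a, float)[::stride]
    b = np.asarray(b, float)[::stride]
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test requires non-empty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return KSResult(float(res.statistic), float(res.pvalue), a.size, b.size)


def pairwise_ks_table(distributions: list[AngleDistribution],
                      stride: int = 1):
    """Symmetric all-vs-all KS comparison of macrostate angle distributions.

    Returns a DataFrame with one row per unordered pair: D, raw p-value, a
    Bonferroni-adjusted p-value, and the sample sizes. Empty macrostates
    raise, naming the offending ids.
    """
    import pandas as pd
    if len(distributions) < 2:
        raise ValueError("need >= 2 distributions to compare")
    empty = [d.macro for d in distributions if d.empty]
    if empty:
        raise ValueError(f"macrostates {empty} have no frames; cannot compare")
    rows = []
    n_pairs = len(distributions) * (len(distributions) - 1) // 2
    for i, da in enumerate(distributions):
        for db in distributions[i + 1:]:
            r = ks_two_sample(da.values, db.values, stride=stride)
            rows.append((da.macro, db.macro, r.statistic, r.p_value,
                         min(1.0, r.p_value * n_pairs), r.n1, r.n2))
    return pd.DataFrame(rows, columns=["macro_a", "macro_b", "D", "p_value",
                                       "p_bonferroni", "n_a", "n_b"])


def ks_matrix(distributions: list[AngleDistribution], stride: int = 1) -> np.ndarray:
    """Square matrix of D statistics (diagonal 0), matching the pair table."""
    k = len(distributions)
    mat = np.zeros((k, k))
    table = pairwise_ks_table(distributions, stride=stride)
    index = {d.macro: i for i, d in enumerate(distributions)}
    for _, row in table.iterrows():
        i, j = index[row["macro_a"]], index[row["macro_b"]]
        mat[i, j] = mat[j, i] = row["D"]
    return mat


def rmsf(traj: Trajectory, selection: np.ndarray,
         frame_subset: np.ndarray | None = None) -> np.ndarray:
    """Per-residue backbone RMSF (Å) over a frame subset.

    Two-pass superposition: every frame is superposed onto the first, the
    mean structure is formed, frames are re-superposed onto that mean, and
    RMSF_r is the root-mean-square deviation of residue r's backbone
    centroid from its mean position.
    """
    sel = np.asarray(selection, int)
    frames = np.arange(traj.n_frames) if frame_subset is None \
        else np.asarray(frame_subset, int)
    if frames.size < 2:
        raise ValueError("RMSF needs >= 2 frames")
    coords = traj.frames[frames][:, sel]

    def _align_to(ref: np.ndarray, stack: np.ndarray) -> np.ndarray:
        out = np.empty_like(stack)
        for i, frame in enumerate(stack):
            rot, trans, _ = superpose(frame, ref)
            out[i] = frame @ rot.T + trans
        return out

    aligned = _align_to(coords[0], coords)
    mean = aligned.mean(axis=0)
    aligned = _align_to(mean, aligned)
    mean = aligned.mean(axis=0)

    resnums = traj.topology.residue_numbers[sel]
    chains = np.array(traj.topology.chain_ids)[sel]
    keys = list(dict.fromkeys(zip(chains, resnums)))
    out = np.empty(len(keys))
    for r, key in enumerate(keys):
        mask = (chains == key[0]) & (resnums == key[1])
        centroid = aligned[:, mask].mean(axis=1)
        mean_centroid = mean[mask].mean(axis=0)
        out[r] = np.sqrt(np.mean(np.sum((centroid - mean_centroid) ** 2, axis=1)))
    return out
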
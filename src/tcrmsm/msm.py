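"""Markov-state models: counting, reversible estimation, validation,
PCCA+ coarse-graining, kinetics, and assignment of external structures.

A Markov-state model is estimated from sliding-window transition counts of a
discretised trajectory at a lag time τ. Only the largest strongly connected
set of states is retained — transition probabilities and relative
equilibrium probabilities are only meaningful on a fully connected network.
The maximum-likelihood transition matrix satisfying detailed balance is
obtained with the classic self-consistent iteration; its spectrum is real,
giving implied timescales t_i = −τ / ln λ_i. PCCA+ aggregates microstates
into metastable macrostates from the leading eigenvectors, and the
Chapman-Kolmogorov test compares model-propagated transition probabilities
[T(τ)]^k against models re-estimated at lag kτ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse
import scipy.sparse.csgraph

from .clustering import DiscreteTrajectory

__all__ = [
    "TransitionModel",
    "MacrostateModel",
    "CKReport",
    "sample_markov_chain",
    "stationary_distribution",
    "count_transitions",
    "largest_connected_set",
    "estimate_reversible",
    "estimate_msm",
    "implied_timescales",
    "pcca_plus",
    "chapman_kolmogorov",
    "mfpt",
    "assign_to_macrostate",
]


def _as_state_arrays(dtrajs) -> list[np.ndarray]:
    if isinstance(dtrajs, (DiscreteTrajectory, np.ndarray, list)) and not (
        isinstance(dtrajs, list) and dtrajs
        and isinstance(dtrajs[0], (DiscreteTrajectory, np.ndarray, list))
    ):
        dtrajs = [dtrajs]
    out = []
    for d in dtrajs:
        arr = d.states if isinstance(d, DiscreteTrajectory) else np.asarray(d, int)
        out.append(np.asarray(arr, int))
    return out


def sample_markov_chain(transition_matrix: np.ndarray, n_steps: int, seed: int,
                        start: int | None = None) -> np.ndarray:
    """Sample a discrete-time chain; the start state is drawn from the
    stationary distribution when not given. Deterministic per seed."""
    t = np.asarray(transition_matrix, float)
    rng = np.random.default_rng(seed)
    cum = np.cumsum(t, axis=1)
    states = np.empty(n_steps, int)
    if start is None:
        pi = stationary_distribution(t)
        start = int(rng.choice(t.shape[0], p=pi))
    states[0] = start
    u = rng.random(n_steps - 1)
    for k in range(1, n_steps):
        states[k] = np.searchsorted(cum[states[k - 1]], u[k - 1])
    return states


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Left Perron eigenvector of a row-stochastic matrix, normalised to 1."""
    t = np.asarray(transition_matrix, float)
    vals, vecs = np.linalg.eig(t.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


@dataclass
class TransitionModel:
    """Reversible MSM over the largest connected set of microstates."""

    count_matrix: np.ndarray          # restricted to active_set
    transition_matrix: np.ndarray     # row-stochastic
    stationary: np.ndarray
    lag: float                        # ns
    active_set: np.ndarray            # original state ids retained

    def __post_init__(self) -> None:
        t = self.transition_matrix
        pi = self.stationary
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.allclose(pi @ t, pi, atol=1e-8):
            raise ValueError("stationary vector is not stationary under T")
        flux = pi[:, None] * t
        if not np.allclose(flux, flux.T, atol=1e-8):
            raise ValueError("detailed balance violated beyond tolerance")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def eigenvalues(self, k: int | None = None) -> np.ndarray:
        """Real spectrum (descending) via the detailed-balance symmetrization."""
        vals, _ = _reversible_spectrum(self.transition_matrix, self.stationary)
        return vals if k is None else vals[:k]

    def timescales(self, k: int | None = None) -> np.ndarray:
        """Implied timescales −τ/ln λ (ns); inf for λ≥1, NaN for λ≤0."""
        vals = self.eigenvalues()[1:]
        if k is not None:
            vals = vals[:k]
        out = np.full(vals.shape, np.nan)
        out[vals >= 1.0] = np.inf
        good = (vals > 0.0) & (vals < 1.0)
        out[good] = -self.lag / np.log(vals[good])
        return out


def _reversible_spectrum(t: np.ndarray, pi: np.ndarray):
    """Eigenvalues (descending, real) and right eigenvectors of reversible T."""
    sq = np.sqrt(pi)
    sym = (sq[:, None] * t) / sq[None, :]
    sym = 0.5 * (sym + sym.T)
    vals, vecs = np.linalg.eigh(sym)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    psi = vecs[:, order] / sq[:, None]          # right eigenvectors of T
    # normalise so the Perron eigenvector is the constant 1
    psi /= psi[0:1, 0:1] if abs(psi[0, 0]) > 0 else 1.0
    psi[:, 0] = 1.0
    return vals, psi


def count_transitions(dtrajs, lag: int) -> np.ndarray:
    """Sliding-window transition counts C_ij at an integer lag (frames)."""
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    trajs = _as_state_arrays(dtrajs)
    n = max(int(t.max()) for t in trajs) + 1
    c = np.zeros((n, n))
    counted = False
    for t in trajs:
        if t.size <= lag:
            continue
        np.add.at(c, (t[:-lag], t[lag:]), 1)
        counted = True
    if not counted:
        raise ValueError(f"lag {lag} >= every trajectory length")
    return c


def largest_connected_set(count_matrix: np.ndarray) -> np.ndarray:
    """Largest strongly connected component of the directed count graph.

    Ties on size are broken toward the component with more total counts,
    then toward lower state indices.
    """
    c = np.asarray(count_matrix, float)
    n = c.shape[0]
    graph = scipy.sparse.csr_matrix(c > 0)
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        graph, directed=True, connection="strong")
    best, best_key = None, None
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        key = (members.size, c[np.ix_(members, members)].sum(), -members[0])
        if best_key is None or key > best_key:
            best, best_key = members, key
    return np.sort(best)


def estimate_reversible(count_matrix: np.ndarray, lag_ns: float = 1.0,
                        active_set: np.ndarray | None = None,
                        tol: float = 1e-10, max_iter: int = 1_000_000
                        ) -> TransitionModel:
    """Maximum-likelihood reversible transition matrix from counts.

    Self-consistent iteration on the unnormalised edge weights x_ij:
    x_ij ← (c_ij + c_ji) / (c_i/x_i + c_j/x_j), which converges to the MLE
    under detailed balance; π_i = x_i / Σ x and T_ij = x_ij / x_i.
    """
    c_full = np.asarray(count_matrix, float)
    if active_set is None:
        active_set = largest_connected_set(c_full)
    c = c_full[np.ix_(active_set, active_set)]
    csym = c + c.T
    x = csym / csym.sum()
    ci = c.sum(axis=1)
    mask = csym > 0
    for _ in range(max_iter):
        xi = x.sum(axis=1)
        denom = ci[:, None] / xi[:, None] + ci[None, :] / xi[None, :]
        x_new = np.where(mask, csym / np.where(denom > 0, denom, 1.0), 0.0)
        x_new /= x_new.sum()
        delta = np.max(np.abs(x_new - x) / np.maximum(np.abs(x), 1e-300))
        x = x_new
        if delta < tol:
            break
    else:
        raise RuntimeError(f"reversible MLE did not converge; residual {delta:.2e}")
    xi = x.sum(axis=1)
    t = x / xi[:, None]
    pi = xi / xi.sum()
    return TransitionModel(c, t, pi, lag_ns, np.asarray(active_set, int))


def estimate_msm(dtrajs, lag_frames: int, frame_interval: float = 1.0
                 ) -> TransitionModel:
    """Count → largest connected set → reversible MLE, lag reported in ns."""
    c = count_transitions(dtrajs, lag_frames)
    return estimate_reversible(c, lag_ns=lag_frames * frame_interval)


def implied_timescales(models: list[TransitionModel], k: int = 5):
    """Timescale table over models at multiple lags (rows: lag ns)."""
    import pandas as pd
    if len(models) < 2:
        raise ValueError("need models at >= 2 lags")
    rows = {}
    for m in models:
        ts = m.timescales()[:k]
        rows[m.lag] = np.pad(ts, (0, max(0, k - ts.size)), constant_values=np.nan)
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[f"t{i + 2}" for i in range(k)])
    df.index.name = "lag_ns"
    return df.sort_index()


# ---------------------------------------------------------------------------
# PCCA+

def _index_search(x: np.ndarray) -> np.ndarray:
    """Deuflhard's vertex search: rows of x spanning the simplex."""
    n, m = x.shape
    d = x.copy()
    idx = np.empty(m, int)
    idx[0] = int(np.argmax((d ** 2).sum(axis=1)))
    d = d - d[idx[0]]
    for j in range(1, m):
        norms = (d ** 2).sum(axis=1)
        idx[j] = int(np.argmax(norms))
        v = d[idx[j]] / np.sqrt(norms[idx[j]])
        d = d - np.outer(d @ v, v)
    return idx


@dataclass
class MacrostateModel:
    """PCCA+ fuzzy memberships and coarse kinetics over a TransitionModel."""

    memberships: np.ndarray       # (n_micro, n_macro), rows sum to 1
    crisp_assignment: np.ndarray  # macro id per microstate (active-set order)
    macro_stationary: np.ndarray
    mfpt_matrix: np.ndarray       # ns, between crisp macrostates
    parent: TransitionModel = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        chi = self.memberships
        if np.any(chi < -1e-12) or np.any(chi > 1 + 1e-12):
            raise ValueError("memberships must lie in [0, 1]")
        if not np.allclose(chi.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("membership rows must sum to 1")

    @property
    def n_macrostates(self) -> int:
        return self.memberships.shape[1]


def pcca_plus(model: TransitionModel, n_macro: int) -> MacrostateModel:
    """Coarse-grain microstates into metastable macrostates.

    Fuzzy memberships come from the simplex (inner-simplex / vertex)
    transformation of the leading n_macro eigenvectors; crisp assignment is
    the argmax membership, ties toward the lower macrostate id.
    """
    n = model.n_states
    if not 2 <= n_macro <= n:
        raise ValueError(f"n_macro must be in [2, {n}]")
    vals, psi = _reversible_spectrum(model.transition_matrix, model.stationary)
    if n_macro < n and vals[n_macro - 1] <= 1e-12:
        raise ValueError(
            f"no spectral structure for {n_macro} macrostates: eigenvalue "
            f"{n_macro} is {vals[n_macro - 1]:.3g} (gap to next: "
            f"{vals[n_macro - 1] - vals[n_macro]:.3g})"
        )
    x = psi[:, :n_macro]
    idx = _index_search(x)
    a = np.linalg.inv(x[idx])
    chi = x @ a
    chi = np.clip(chi, 0.0, None)
    chi /= chi.sum(axis=1, keepdims=True)
    crisp = np.argmax(chi, axis=1)
    pi = model.stationary
    macro_pi = chi.T @ pi
    macro_pi /= macro_pi.sum()
    m = np.full((n_macro, n_macro), np.nan)
    for a_id in range(n_macro):
        for b_id in range(n_macro):
            if a_id == b_id:
                m[a_id, b_id] = 0.0
                continue
            src = np.flatnonzero(crisp == a_id)
            tgt = np.flatnonzero(crisp == b_id)
            if src.size and tgt.size:
                m[a_id, b_id] = mfpt(model, src, tgt)
    return MacrostateModel(chi, crisp, macro_pi, m, parent=model)


# ---------------------------------------------------------------------------
# Chapman-Kolmogorov

@dataclass
class CKReport:
    """Predicted vs re-estimated macrostate self-transition probabilities."""

    records: object               # DataFrame: set, multiple, predicted,
                                  # estimated, lower, upper, flagged
    lag: float                    # base lag, ns

    def pass_fraction(self, slack: float = 0.0) -> float:
        """Fraction of un-flagged points whose prediction lies in the band."""
        df = self.records[~self.records["flagged"]]
        ok = ((df["predicted"] >= df["lower"] - slack)
              & (df["predicted"] <= df["upper"] + slack))
        return float(ok.mean()) if len(df) else float("nan")

    def passed(self, threshold: float = 0.9) -> bool:
        return self.pass_fraction() >= threshold


def _macro_stay_probability(t: np.ndarray, pi: np.ndarray, members: np.ndarray,
                            power: int) -> float:
    """π-weighted probability of remaining in the member set after ``power`` steps."""
    w = pi[members] / pi[members].sum()
    tk = np.linalg.matrix_power(t, power)
    return float(w @ tk[np.ix_(members, members)].sum(axis=1))


def _bootstrap_pool(trajs: list[np.ndarray], n_segments: int = 10) -> list[np.ndarray]:
    if len(trajs) >= 2:
        return trajs
    # single trajectory: bootstrap contiguous segments instead
    t = trajs[0]
    edges = np.linspace(0, t.size, n_segments + 1).astype(int)
    return [t[a:b] for a, b in zip(edges[:-1], edges[1:]) if b - a > 1]


def chapman_kolmogorov(dtrajs, model: TransitionModel, n_macro: int,
                       multiples=(1, 2, 3, 4, 5), n_boot: int = 100,
                       seed: int = 0, frame_interval: float | None = None
                       ) -> CKReport:
    """Compare [T(τ)]^k at the macrostate level with MSMs re-estimated at kτ.

    Uncertainty bands are 2.5/97.5 percentiles from a bootstrap over
    trajectories (contiguous segments when only one trajectory is given),
    100 resamples by default. Multiples with insufficient data are flagged,
    never silently dropped.
    """
    import pandas as pd
    trajs = _as_state_arrays(dtrajs)
    dt = frame_interval or 1.0
    lag_frames = int(round(model.lag / dt))
    if lag_frames < 1:
        raise ValueError("model lag is below one frame")
    macro = pcca_plus(model, n_macro)
    sets = [model.active_set[np.flatnonzero(macro.crisp_assignment == a)]
            for a in range(n_macro)]
    pos = {s: i for i, s in enumerate(model.active_set)}
    rng = np.random.default_rng(seed)
    pool = _bootstrap_pool(trajs)
    rows = []
    for k in multiples:
        klag = k * lag_frames
        try:
            est = estimate_msm(trajs, klag, dt)
        except (ValueError, RuntimeError):
            for a in range(n_macro):
                rows.append((a, k, np.nan, np.nan, np.nan, np.nan, True))
            continue
        boots = []
        for _ in range(n_boot):
            pick = [pool[i] for i in rng.integers(len(pool), size=len(pool))]
            try:
                boots.append(estimate_msm(pick, klag, dt))
            except (ValueError, RuntimeError):
                continue
        for a, members in enumerate(sets):
            local = np.array([pos[s] for s in members], int)
            pred = _macro_stay_probability(
                model.transition_matrix, model.stationary, local, k)
            est_val, flagged = np.nan, True
            epos = {s: i for i, s in enumerate(est.active_set)}
            emem = np.array([epos[s] for s in members if s in epos], int)
            if emem.size:
                est_val = _macro_stay_probability(
                    est.transition_matrix, est.stationary, emem, 1)
                flagged = False
            bvals = []
            for b in boots:
                bpos = {s: i for i, s in enumerate(b.active_set)}
                bmem = np.array([bpos[s] for s in members if s in bpos], int)
                if bmem.size:
                    bvals.append(_macro_stay_probability(
                        b.transition_matrix, b.stationary, bmem, 1))
            if len(bvals) >= 10:
                lo, hi = np.percentile(bvals, [2.5, 97.5])
            else:
                lo, hi, flagged = np.nan, np.nan, True
            rows.append((a, k, pred, est_val, lo, hi, flagged))
    df = pd.DataFrame(rows, columns=["set", "multiple", "predicted",
                                     "estimated", "lower", "upper", "flagged"])
    return CKReport(df, model.lag)


# ---------------------------------------------------------------------------
# Kinetics and assignment

def mfpt(model: TransitionModel, source, target) -> float:
    """Mean first-passage time from a source set to a target set, ns.

    Solves (I − T_QQ) m_Q = τ·1 over non-target states Q; the reported value
    is the stationary-weighted mean over the source states. Returns inf when
    the target is unreachable, 0 when the source lies inside the target.
    """
    source = np.atleast_1d(np.asarray(source, int))
    target = np.atleast_1d(np.asarray(target, int))
    if source.size == 0 or target.size == 0:
        raise ValueError("source and target must be non-empty")
    if np.intersect1d(source, target).size and \
            not np.all(np.isin(source, target)):
        raise ValueError("source and target sets must be disjoint")
    n = model.n_states
    m_full = np.zeros(n)
    q = np.setdiff1d(np.arange(n), target)
    if q.size:
        t_qq = model.transition_matrix[np.ix_(q, q)]
        a = np.eye(q.size) - t_qq
        try:
            m_q = np.linalg.solve(a, np.full(q.size, model.lag))
        except np.linalg.LinAlgError:
            return float("inf")
        if np.any(m_q < -1e-6) or not np.all(np.isfinite(m_q)):
            return float("inf")
        m_full[q] = m_q
    w = model.stationary[source]
    return float(w @ m_full[source] / w.sum())


def assign_to_macrostate(item, tica_model, centers: np.ndarray,
                         model: TransitionModel, macro: MacrostateModel,
                         selections=None, angles=("psi", "phi")):
    """Assign a structure (or a pre-projected point) to a macrostate.

    Route: featurize → tICA-project → nearest k-means center → crisp
    macrostate of that microstate. Returns None when the microstate fell
    outside the model's connected set ("unassignable").
    """
    from .structure_io import Structure
    from .tica import project, project_structure
    if isinstance(item, Structure):
        if selections is None:
            raise ValueError("selections are required to featurize a Structure")
        point = project_structure(tica_model, item, selections, angles)
    else:
        point = np.asarray(item, float).ravel()
        if point.size != centers.shape[1]:
            point = project(tica_model, point[None])[0]
    micro = int(np.argmin(((centers - point) ** 2).sum(axis=1)))
    where = np.flatnonzero(model.active_set == micro)
    if where.size == 0:
        return None
    return int(macro.crisp_assignment[where[0]])
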
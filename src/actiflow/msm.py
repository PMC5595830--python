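"""Markov state model estimation, validation, lumping and error bars.

The workflow mirrors standard MSM practice: k-means microstates in the tICA
space, sliding-window transition counts at a lag time, restriction to the
largest strongly connected state set, reversible maximum-likelihood
estimation of the transition matrix (fixed-point iteration under detailed
balance), implied timescales ``t_i = -tau / ln|lambda_i|`` for lag-time
selection, a Chapman-Kolmogorov self-consistency test, PCCA+ lumping of
microstates into metastable macrostates, stationary-weighted macrostate
statistics and activation-region classification, kinetic evolution of an
initial distribution, and a trajectory-bootstrap protocol (95% subsets,
first/third quartiles) for error bars.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse
import scipy.sparse.csgraph

from .tica import Projection

__all__ = [
    "MicrostateAssignment",
    "MarkovModel",
    "ImpliedTimescaleCurve",
    "MacrostateModel",
    "BootstrapResult",
    "REGION_LABELS",
    "cluster_microstates",
    "count_transitions",
    "estimate_msm",
    "implied_timescales",
    "ck_test",
    "pcca_lump",
    "macrostate_statistics",
    "classify_region",
    "kinetic_evolution",
    "bootstrap",
]

REGION_LABELS = ("inactive", "active", "intermediate_I", "intermediate_II")


# ---------------------------------------------------------------------------
# microstates
# ---------------------------------------------------------------------------

@dataclass
class MicrostateAssignment:
    """Per-trajectory integer microstate labels."""

    labels: list[np.ndarray]
    n_states: int
    frame_interval_ns: float = 1.0

    def __post_init__(self) -> None:
        self.labels = [np.asarray(l, dtype=np.int64) for l in self.labels]
        for l in self.labels:
            if l.size and (l.min() < 0 or l.max() >= self.n_states):
                raise ValueError("labels out of range [0, n_states)")

    @property
    def n_frames_total(self) -> int:
        return int(sum(l.size for l in self.labels))


def cluster_microstates(
    projections: Projection | Sequence[np.ndarray],
    k: int = 1000,
    seed: int = 0,
    frame_interval_ns: float = 1.0,
) -> MicrostateAssignment:
    """k-means microstates over the pooled projected frames (k-means++ init)."""
    from sklearn.cluster import KMeans

    blocks = projections.blocks if isinstance(projections, Projection) else [
        np.asarray(b, dtype=float) for b in projections
    ]
    pooled = np.vstack([np.atleast_2d(b.T).T if b.ndim == 1 else b for b in blocks])
    if pooled.ndim == 1:
        pooled = pooled[:, None]
    if pooled.shape[0] < k:
        raise ValueError(f"{pooled.shape[0]} frames < k={k} clusters")
    km = KMeans(n_clusters=k, random_state=seed, n_init=1, init="k-means++")
    flat = km.fit_predict(pooled)
    out, start = [], 0
    for b in blocks:
        n = b.shape[0]
        out.append(flat[start : start + n])
        start += n
    return MicrostateAssignment(labels=out, n_states=k, frame_interval_ns=frame_interval_ns)


def count_transitions(assignment: MicrostateAssignment, lag: int) -> np.ndarray:
    """Sliding-window transition counts at the given lag (frames)."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    K = assignment.n_states
    C = np.zeros((K, K))
    for l in assignment.labels:
        if l.size > lag:
            np.add.at(C, (l[:-lag], l[lag:]), 1.0)
    return C


# ---------------------------------------------------------------------------
# reversible maximum-likelihood estimation
# ---------------------------------------------------------------------------

@dataclass
class MarkovModel:
    lag: int  # frames
    frame_interval_ns: float
    counts: np.ndarray  # full count matrix (all microstates)
    active_set: np.ndarray  # microstate indices of the ergodic set
    transition_matrix: np.ndarray  # (n_active, n_active), row-stochastic
    stationary_distribution: np.ndarray
    eigenvalues: np.ndarray  # descending, from the reversible estimate

    def __post_init__(self) -> None:
        T = self.transition_matrix
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must sum to 1 within 1e-10")
        pi = self.stationary_distribution
        if np.any(pi <= 0) or not np.isclose(pi.sum(), 1.0, atol=1e-10):
            raise ValueError("stationary distribution must be positive and normalized")
        flux = pi[:, None] * T
        scale = np.maximum(np.abs(flux), np.abs(flux.T))
        bad = np.abs(flux - flux.T) > 1e-8 * np.maximum(scale, 1e-300)
        if np.any(bad & (scale > 1e-12)):
            raise ValueError("detailed balance violated beyond tolerance")

    @property
    def lag_ns(self) -> float:
        return self.lag * self.frame_interval_ns

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]


def _largest_strong_component(counts: np.ndarray) -> np.ndarray:
    adj = scipy.sparse.csr_matrix((counts > 0).astype(np.int8))
    n_comp, labels = scipy.sparse.csgraph.connected_components(adj, connection="strong")
    visited = counts.sum(axis=1) + counts.sum(axis=0) > 0
    best, best_weight = None, -1.0
    for c in range(n_comp):
        members = np.flatnonzero((labels == c) & visited)
        if members.size == 0:
            continue
        weight = counts[np.ix_(members, members)].sum()
        if weight > best_weight or (weight == best_weight and best is not None and members.size > best.size):
            best, best_weight = members, weight
    if best is None or best.size == 0:
        raise ValueError("no ergodic microstate set: count matrix is empty")
    return best


def _reversible_mle(
    counts: np.ndarray, tol: float = 1e-10, max_iter: int = 1_000_000
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-point reversible MLE: returns (T, pi) on the given count matrix."""
    C = np.asarray(counts, dtype=float)
    c_i = C.sum(axis=1)
    if np.any(c_i <= 0):
        raise ValueError("every state needs outgoing counts (trim to the ergodic set first)")
    Csym = C + C.T
    x = Csym.copy()
    x /= x.sum()
    mask = Csym > 0
    for iteration in range(max_iter):
        x_i = x.sum(axis=1)
        denom = (c_i / x_i)[:, None] + (c_i / x_i)[None, :]
        x_new = np.where(mask, Csym / np.where(denom > 0, denom, 1.0), 0.0)
        x_new /= x_new.sum()
        delta = np.max(np.abs(x_new - x) / np.maximum(np.abs(x), 1e-300) * mask)
        x = x_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"reversible MLE did not converge in {max_iter} iterations (last delta={delta:.3e})"
        )
    pi = x.sum(axis=1)
    T = x / pi[:, None]
    T /= T.sum(axis=1, keepdims=True)
    pi = pi / pi.sum()
    return T, pi


def _reversible_spectrum(T: np.ndarray, pi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and right eigenvectors of a reversible T."""
    sqrt_pi = np.sqrt(pi)
    S = (sqrt_pi[:, None] * T) / sqrt_pi[None, :]
    S = 0.5 * (S + S.T)
    vals, vecs = scipy.linalg.eigh(S)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    right = vecs[:, order] / sqrt_pi[:, None]
    # normalize the stationary eigenvector to 1 and fix signs deterministically
    for j in range(right.shape[1]):
        k = int(np.argmax(np.abs(right[:, j])))
        if right[k, j] < 0:
            right[:, j] *= -1.0
    return vals, right


def estimate_msm(
    assignment: MicrostateAssignment, lag: int, tol: float = 1e-10, max_iter: int = 1_000_000
) -> MarkovModel:
    """Reversible MLE Markov model at the given lag, on the largest ergodic set."""
    counts = count_transitions(assignment, lag)
    if counts.sum() == 0:
        raise ValueError("no transitions observed at this lag")
    active = _largest_strong_component(counts)
    total_visited = int((counts.sum(axis=1) + counts.sum(axis=0) > 0).sum())
    if active.size < total_visited:
        warnings.warn(
            f"trimmed to largest strongly connected set: {active.size}/{total_visited} microstates"
        )
    T, pi = _reversible_mle(counts[np.ix_(active, active)], tol=tol, max_iter=max_iter)
    vals, _ = _reversible_spectrum(T, pi)
    return MarkovModel(
        lag=lag,
        frame_interval_ns=assignment.frame_interval_ns,
        counts=counts,
        active_set=active,
        transition_matrix=T,
        stationary_distribution=pi,
        eigenvalues=vals,
    )


# ---------------------------------------------------------------------------
# implied timescales and the Chapman-Kolmogorov test
# ---------------------------------------------------------------------------

@dataclass
class ImpliedTimescaleCurve:
    lags: np.ndarray  # frames
    timescales: np.ndarray  # (n_lags, n_timescales), ns; inf where flagged
    frame_interval_ns: float
    q1: np.ndarray | None = None
    q3: np.ndarray | None = None

    @property
    def lags_ns(self) -> np.ndarray:
        return self.lags * self.frame_interval_ns

    def to_frame(self) -> pd.DataFrame:
        cols = {f"t{i+2}_ns": self.timescales[:, i] for i in range(self.timescales.shape[1])}
        return pd.DataFrame({"lag_ns": self.lags_ns, **cols})


def _timescales_from_eigenvalues(
    eigenvalues: np.ndarray, lag: int, n_timescales: int, frame_interval_ns: float
) -> np.ndarray:
    """t_i = -tau / ln|lambda_i| for the non-stationary eigenvalues, in ns."""
    lam = eigenvalues[1 : n_timescales + 1]
    out = np.full(n_timescales, np.nan)
    for i, l in enumerate(lam):
        mag = abs(l)
        if mag >= 1.0 - 1e-12:
            out[i] = np.inf  # flagged: relaxation slower than resolvable
        elif mag <= 0.0:
            out[i] = 0.0
        else:
            out[i] = -lag / np.log(mag) * frame_interval_ns
    return out


def implied_timescales(
    assignment: MicrostateAssignment,
    lags: Sequence[int],
    n_timescales: int = 5,
    n_bootstrap: int = 0,
    bootstrap_fraction: float = 0.95,
    seed: int = 0,
) -> ImpliedTimescaleCurve:
    """Implied relaxation timescales across lags, optionally with bootstrap quartiles."""
    lags = np.asarray(sorted(int(l) for l in lags))
    shortest = min(l.size for l in assignment.labels)
    if lags.max() >= shortest:
        raise ValueError("largest lag must be smaller than the shortest trajectory")

    def curve(a: MicrostateAssignment) -> np.ndarray:
        rows = []
        for lag in lags:
            m = estimate_msm(a, int(lag))
            rows.append(
                _timescales_from_eigenvalues(m.eigenvalues, int(lag), n_timescales, a.frame_interval_ns)
            )
        return np.asarray(rows)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        point = curve(assignment)
    q1 = q3 = None
    if n_bootstrap > 0:
        def estimator(subset: Sequence[np.ndarray]) -> np.ndarray:
            sub = MicrostateAssignment(
                labels=list(subset), n_states=assignment.n_states,
                frame_interval_ns=assignment.frame_interval_ns,
            )
            return curve(sub)

        result = bootstrap(estimator, list(assignment.labels), n_samples=n_bootstrap,
                           fraction=bootstrap_fraction, seed=seed)
        q1, q3 = result.q1, result.q3
    return ImpliedTimescaleCurve(
        lags=lags, timescales=point, frame_interval_ns=assignment.frame_interval_ns, q1=q1, q3=q3
    )


def _set_self_probability(T: np.ndarray, pi: np.ndarray, members: np.ndarray) -> float:
    """Probability of being in the set after one step, started from restricted pi."""
    w = pi[members]
    if w.sum() <= 0:
        raise ValueError("macrostate has zero stationary weight")
    w = w / w.sum()
    return float(w @ T[np.ix_(members, members)].sum(axis=1))


def ck_test(
    model: MarkovModel,
    assignment: MicrostateAssignment,
    sets: Sequence[Sequence[int]],
    multiples: Sequence[int] = (1, 2, 4, 8),
    n_bootstrap: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Chapman-Kolmogorov test on macrostate self-transition probabilities.

    ``predicted`` propagates the lag-tau model ``m`` times; ``observed``
    re-estimates a model directly at lag ``m * tau``.  Both are reported per
    (set, multiple); optional bootstrap quartiles for the observed branch.
    """
    flat = [s for group in sets for s in group]
    if len(set(flat)) != len(flat):
        raise ValueError("macrostate sets must be disjoint")
    index_of = {int(s): i for i, s in enumerate(model.active_set)}
    rows = []
    for m in multiples:
        Tm = np.linalg.matrix_power(model.transition_matrix, int(m))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            obs_model = estimate_msm(assignment, model.lag * int(m))
        obs_index = {int(s): i for i, s in enumerate(obs_model.active_set)}
        for si, group in enumerate(sets):
            members = np.array([index_of[int(s)] for s in group if int(s) in index_of])
            if members.size == 0:
                raise ValueError(f"set {si} has no members in the active set")
            pred = _set_self_probability(Tm, model.stationary_distribution, members)
            obs_members = np.array([obs_index[int(s)] for s in group if int(s) in obs_index])
            obs = _set_self_probability(
                obs_model.transition_matrix, obs_model.stationary_distribution, obs_members
            )
            row = {"set": si, "multiple": int(m), "lag_ns": model.lag_ns * int(m),
                   "predicted": pred, "observed": obs}
            rows.append(row)
    table = pd.DataFrame(rows)
    if n_bootstrap > 0:
        def estimator(subset: Sequence[np.ndarray]) -> np.ndarray:
            sub = MicrostateAssignment(list(subset), assignment.n_states,
                                       assignment.frame_interval_ns)
            vals = []
            for m in multiples:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    om = estimate_msm(sub, model.lag * int(m))
                oi = {int(s): i for i, s in enumerate(om.active_set)}
                for group in sets:
                    mem = np.array([oi[int(s)] for s in group if int(s) in oi])
                    vals.append(
                        _set_self_probability(om.transition_matrix, om.stationary_distribution, mem)
                    )
            return np.asarray(vals)

        res = bootstrap(estimator, list(assignment.labels), n_samples=n_bootstrap,
                        fraction=0.95, seed=seed)
        # estimator emits rows in (multiple-major, set-minor) order, matching `rows`
        table["observed_q1"] = res.q1
        table["observed_q3"] = res.q3
    return table


# ---------------------------------------------------------------------------
# PCCA+ lumping and macrostate analysis
# ---------------------------------------------------------------------------

@dataclass
class MacrostateModel:
    microstate_to_macrostate: np.ndarray  # (n_active,) crisp labels in [0, M)
    memberships: np.ndarray  # (n_active, M) fuzzy memberships
    probabilities: np.ndarray  # (M,) equilibrium macrostate probabilities
    n_macrostates: int
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if not np.isclose(self.probabilities.sum(), 1.0, atol=1e-10):
            raise ValueError("macrostate probabilities must sum to 1 within 1e-10")

    def members(self, macro: int) -> np.ndarray:
        return np.flatnonzero(self.microstate_to_macrostate == macro)


def _inner_simplex_vertices(X: np.ndarray, m: int) -> np.ndarray:
    """Indices of m rows of X spanning the simplex (ISA vertex search)."""
    ortho = X.copy()
    vertices = np.empty(m, dtype=int)
    idx = int(np.argmax(np.linalg.norm(ortho, axis=1)))
    vertices[0] = idx
    ortho -= ortho[idx]  # translate first vertex to the origin
    for j in range(1, m):
        norms = np.linalg.norm(ortho, axis=1)
        idx = int(np.argmax(norms))
        vertices[j] = idx
        v = ortho[idx] / norms[idx]
        ortho -= np.outer(ortho @ v, v)
    return vertices


def pcca_lump(model: MarkovModel, n_macrostates: int) -> MacrostateModel:
    """PCCA+ lumping of microstates into metastable macrostates.

    Fuzzy memberships are obtained from the top right eigenvectors of the
    reversible transition matrix via the inner-simplex vertex construction;
    crisp assignment is by maximal membership, and macrostate probabilities
    sum the stationary weights of their member microstates.
    """
    M = int(n_macrostates)
    K = model.n_states
    if not 1 <= M <= K:
        raise ValueError("n_macrostates must be in [1, n_microstates]")
    if M == K:
        return MacrostateModel(
            microstate_to_macrostate=np.arange(K),
            memberships=np.eye(K),
            probabilities=model.stationary_distribution.copy(),
            n_macrostates=K,
        )
    vals, right = _reversible_spectrum(model.transition_matrix, model.stationary_distribution)
    if M < K and abs(vals[M - 1] - vals[M]) < 1e-10:
        raise ValueError(
            "degenerate eigenvalues at the spectral cut; choose a different number of macrostates"
        )
    X = right[:, :M]
    X[:, 0] = 1.0  # stationary eigenvector is constant
    vertices = _inner_simplex_vertices(X, M)
    A = np.linalg.inv(X[vertices])
    chi = X @ A
    chi = np.clip(chi, 0.0, None)
    rowsum = chi.sum(axis=1, keepdims=True)
    chi = np.where(rowsum > 0, chi / np.maximum(rowsum, 1e-300), 1.0 / M)
    crisp = np.argmax(chi, axis=1)
    pi = model.stationary_distribution
    probs = np.array([pi[crisp == j].sum() for j in range(M)])
    probs = probs / probs.sum()
    return MacrostateModel(
        microstate_to_macrostate=crisp, memberships=chi, probabilities=probs, n_macrostates=M
    )


def _weighted_quartiles(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cw = np.cumsum(w) / w.sum()
    q1 = float(v[np.searchsorted(cw, 0.25)])
    q3 = float(v[np.searchsorted(cw, 0.75)])
    return q1, q3


def macrostate_statistics(
    macromodel: MacrostateModel,
    model: MarkovModel,
    traces: dict[str, np.ndarray],
    assignment: MicrostateAssignment,
) -> pd.DataFrame:
    """Stationary-weighted macrostate averages and quartiles of order parameters.

    Each trace is a pooled per-frame array aligned with the pooled
    assignment labels.  Microstate trace means are combined with stationary
    weights; quartiles come from the stationary-reweighted frame
    distribution (each frame weighted by pi of its microstate divided by the
    microstate's frame count).
    """
    labels = np.concatenate(assignment.labels)
    active = model.active_set
    pi = model.stationary_distribution
    pi_of_micro = {int(s): pi[i] for i, s in enumerate(active)}
    rows = []
    for macro in range(macromodel.n_macrostates):
        micro_local = macromodel.members(macro)
        micros = active[micro_local]
        frame_mask = np.isin(labels, micros)
        if not frame_mask.any():
            raise ValueError(f"macrostate {macro} has no frames")
        counts = {int(s): int((labels == s).sum()) for s in micros}
        frame_weights = np.array(
            [pi_of_micro[int(s)] / counts[int(s)] for s in labels[frame_mask]]
        )
        row: dict[str, float] = {"macrostate": macro, "probability": macromodel.probabilities[macro]}
        for name, trace in traces.items():
            trace = np.asarray(trace, dtype=float)
            if trace.shape[0] != labels.shape[0]:
                raise ValueError(f"trace {name!r} is not frame-aligned with the assignment")
            micro_means = np.array([trace[labels == s].mean() for s in micros])
            w = pi[micro_local] / pi[micro_local].sum()
            row[f"{name}_mean"] = float(w @ micro_means)
            q1, q3 = _weighted_quartiles(trace[frame_mask], frame_weights)
            row[f"{name}_q1"] = q1
            row[f"{name}_q3"] = q3
        rows.append(row)
    return pd.DataFrame(rows)


def classify_region(
    distance_mean: float,
    rmsd_mean: float,
    distance_inactive: float = 10.0,
    rmsd_threshold: float = 2.5,
    distance_active: float = 13.0,
) -> str:
    """Activation-region label from the two order-parameter averages.

    The inactive rule (TM3-TM6 Calpha distance within 10 A and NPxxYA Calpha
    RMSD within 2.5 A, boundary inclusive) follows the published criterion;
    the remaining grid uses a configurable outer distance threshold
    (default 13 A): beyond it the macrostate is intermediate_I when the
    NPxxYA segment is still inactive-like and active when it is not, while
    states with distorted NPxxYA but intermediate TM6 opening fall in
    intermediate_II.
    """
    if not (np.isfinite(distance_mean) and np.isfinite(rmsd_mean)):
        raise ValueError("both order-parameter statistics are required")
    if distance_mean <= distance_inactive and rmsd_mean <= rmsd_threshold:
        return "inactive"
    if rmsd_mean <= rmsd_threshold:
        # TM6 at least partially open, NPxxYA inactive-like
        return "intermediate_I"
    if distance_mean > distance_active:
        return "active"
    return "intermediate_II"


def kinetic_evolution(
    model: MarkovModel,
    macromodel: MacrostateModel,
    source: int | str,
    horizon: int,
) -> pd.DataFrame:
    """Macrostate occupancies under repeated application of the transition matrix.

    The initial distribution is proportional to the stationary weights of
    the microstates in the source macrostate (or region label) and zero
    elsewhere.  Returns a table of shape (horizon + 1, n_macrostates).
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if isinstance(source, str):
        if macromodel.region_labels is None:
            raise ValueError("region labels unavailable; pass a macrostate index")
        members = [m for m, lab in enumerate(macromodel.region_labels) if lab == source]
        if not members:
            raise ValueError(f"no macrostate labelled {source!r}")
        micro_local = np.concatenate([macromodel.members(m) for m in members])
    else:
        micro_local = macromodel.members(int(source))
    if micro_local.size == 0:
        raise ValueError("source macrostate is empty")
    pi = model.stationary_distribution
    p = np.zeros(model.n_states)
    p[micro_local] = pi[micro_local]
    p /= p.sum()
    T = model.transition_matrix
    M = macromodel.n_macrostates
    occ = np.empty((horizon + 1, M))
    for t in range(horizon + 1):
        for j in range(M):
            occ[t, j] = p[macromodel.members(j)].sum()
        if t < horizon:
            p = p @ T
    table = pd.DataFrame(occ, columns=[f"macrostate_{j}" for j in range(M)])
    table.insert(0, "step", np.arange(horizon + 1))
    table.insert(1, "time_ns", np.arange(horizon + 1) * model.lag_ns)
    return table


# ---------------------------------------------------------------------------
# bootstrap protocol
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    point: np.ndarray
    q1: np.ndarray
    q3: np.ndarray
    estimates: np.ndarray  # (n_ok, ...) successful re-estimates
    n_failed: int


def bootstrap(
    estimator: Callable[[Sequence], np.ndarray],
    trajectories: Sequence,
    n_samples: int = 500,
    fraction: float = 0.95,
    seed: int = 0,
) -> BootstrapResult:
    """Trajectory-subset bootstrap: Q1/Q3 of repeated re-estimates.

    Each of the ``n_samples`` replicates calls ``estimator`` on a random
    subset of ``fraction`` of the trajectories drawn without replacement
    (all frames of the selected trajectories included).  Replicates on which
    the estimator raises are recorded and excluded.
    """
    n = len(trajectories)
    if n < 2:
        raise ValueError("bootstrap requires at least 2 trajectories")
    size = max(1, int(round(fraction * n)))
    rng = np.random.default_rng(seed)
    point = np.asarray(estimator(list(trajectories)), dtype=float)
    estimates, n_failed = [], 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_samples):
            pick = rng.choice(n, size=size, replace=False)
            try:
                estimates.append(np.asarray(estimator([trajectories[i] for i in pick]), dtype=float))
            except Exception:
                n_failed += 1
    if not estimates:
        raise RuntimeError("all bootstrap replicates failed")
    stacked = np.stack(estimates)
    q1 = np.percentile(stacked, 25, axis=0)
    q3 = np.percentile(stacked, 75, axis=0)
    return BootstrapResult(point=point, q1=q1, q3=q3, estimates=stacked, n_failed=n_failed)
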
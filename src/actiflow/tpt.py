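"""Transition path theory between two microstate sets.

Given a reversible Markov model and disjoint source (A) and target (B)
sets, this module computes the forward committor (probability of reaching B
before A), the reactive gross/net flux, a coarse-grained flux network over
macrostates, a deterministic pathway decomposition by repeated removal of
the bottleneck (widest) path, and mean first-passage times from first-step
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .msm import MacrostateModel, MarkovModel

__all__ = [
    "CommittorField",
    "FluxNetwork",
    "PathwayDecomposition",
    "committor",
    "reactive_flux",
    "decompose_pathways",
    "mfpt",
    "mfpt_matrix",
    "flux_to_dot",
]


def flux_to_dot(net: np.ndarray, labels: Sequence[str] | None = None) -> str:
    """Render a net-flux graph as Graphviz DOT (edge width ~ flux share)."""
    net = np.asarray(net, dtype=float)
    n = net.shape[0]
    labels = list(labels) if labels is not None else [str(i) for i in range(n)]
    top = net.max() if net.max() > 0 else 1.0
    lines = ["digraph flux {"]
    for i in range(n):
        lines.append(f'  "{labels[i]}";')
    for i in range(n):
        for j in range(n):
            if net[i, j] > 0:
                w = 0.5 + 4.5 * net[i, j] / top
                lines.append(
                    f'  "{labels[i]}" -> "{labels[j]}" '
                    f'[penwidth={w:.2f}, label="{net[i, j]:.3g}"];'
                )
    lines.append("}")
    return "\n".join(lines)


@dataclass
class CommittorField:
    q: np.ndarray  # forward committor per active microstate
    source: np.ndarray  # microstate indices (local, within active set)
    target: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.q < -1e-12) or np.any(self.q > 1 + 1e-12):
            raise ValueError("committor values must lie in [0, 1]")
        self.q = np.clip(self.q, 0.0, 1.0)


@dataclass
class FluxNetwork:
    gross: np.ndarray  # microstate-level gross flux
    net: np.ndarray  # microstate-level net flux, antisymmetric part clipped at 0
    total: float  # total A->B reactive flux per lag step
    macrostate_net: np.ndarray | None = None  # coarse-grained net flux


@dataclass
class PathwayDecomposition:
    pathways: list[tuple[tuple[int, ...], float]]  # (macrostate sequence, flux)
    total_flux: float

    @property
    def fractions(self) -> np.ndarray:
        return np.array([f for _, f in self.pathways]) / self.total_flux

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pathway": ["->".join(map(str, p)) for p, _ in self.pathways],
                "flux": [f for _, f in self.pathways],
                "fraction": self.fractions,
            }
        )


def _validate_sets(model: MarkovModel, A: Sequence[int], B: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    A = np.asarray(sorted(set(int(a) for a in A)))
    B = np.asarray(sorted(set(int(b) for b in B)))
    if A.size == 0 or B.size == 0:
        raise ValueError("source and target sets must be non-empty")
    if np.intersect1d(A, B).size:
        raise ValueError("source and target sets must be disjoint")
    n = model.n_states
    if A.max() >= n or B.max() >= n:
        raise ValueError("set members must be local indices within the active set")
    return A, B


def committor(model: MarkovModel, A: Sequence[int], B: Sequence[int]) -> CommittorField:
    """Forward committor: q=0 on A, q=1 on B, harmonic in between."""
    A, B = _validate_sets(model, A, B)
    T = model.transition_matrix
    n = model.n_states
    q = np.zeros(n)
    q[B] = 1.0
    interior = np.setdiff1d(np.arange(n), np.concatenate([A, B]))
    if interior.size:
        M = np.eye(interior.size) - T[np.ix_(interior, interior)]
        rhs = T[np.ix_(interior, B)].sum(axis=1)
        try:
            q[interior] = np.linalg.solve(M, rhs)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "committor system is singular: intermediate states disconnected from A and B"
            ) from exc
    return CommittorField(q=q, source=A, target=B)


def reactive_flux(
    model: MarkovModel,
    committor_field: CommittorField,
    macromodel: MacrostateModel | None = None,
) -> FluxNetwork:
    """Reactive gross and net flux; optionally coarse-grained over macrostates.

    Gross flux ``f_ij = pi_i (1 - q_i) T_ij q_j`` for ``i != j``; the net
    flux keeps the positive part of ``f_ij - f_ji``.  The total A->B flux is
    the net flux out of the source set.
    """
    q = committor_field.q
    pi = model.stationary_distribution
    T = model.transition_matrix
    gross = pi[:, None] * (1.0 - q)[:, None] * T * q[None, :]
    np.fill_diagonal(gross, 0.0)
    net = np.clip(gross - gross.T, 0.0, None)
    total = float(net[committor_field.source, :].sum())
    macro_net = None
    if macromodel is not None:
        crisp = macromodel.microstate_to_macrostate
        M = macromodel.n_macrostates
        Z = np.zeros((len(crisp), M))
        Z[np.arange(len(crisp)), crisp] = 1.0
        macro_net = Z.T @ net @ Z
        np.fill_diagonal(macro_net, 0.0)
        macro_net = np.clip(macro_net - macro_net.T, 0.0, None)
    return FluxNetwork(gross=gross, net=net, total=total, macrostate_net=macro_net)


def _widest_path(net: np.ndarray, source: Sequence[int], target: Sequence[int]) -> tuple[list[int], float]:
    """Bottleneck (maximum-capacity) path from any source to any target node."""
    n = net.shape[0]
    width = np.full(n, -np.inf)
    prev = np.full(n, -1, dtype=int)
    width[list(source)] = np.inf
    visited = np.zeros(n, dtype=bool)
    while True:
        candidates = np.where(~visited, width, -np.inf)
        u = int(np.argmax(candidates))
        if candidates[u] <= 0:
            return [], 0.0
        if u in set(int(t) for t in target):
            if np.isinf(width[u]):  # source and target overlap
                return [], 0.0
            path = [u]
            while prev[path[-1]] >= 0:
                path.append(int(prev[path[-1]]))
            return path[::-1], float(width[u])
        visited[u] = True
        for v in range(n):
            if visited[v] or net[u, v] <= 0:
                continue
            w = min(width[u], net[u, v])
            if w > width[v]:
                width[v] = w
                prev[v] = u


def decompose_pathways(
    net: np.ndarray,
    source: Sequence[int],
    target: Sequence[int],
    min_fraction: float = 0.01,
    max_paths: int = 1000,
) -> PathwayDecomposition:
    """Flux decomposition by repeated bottleneck-path removal.

    At each step the widest (maximum bottleneck capacity) path from source
    to target is found, its bottleneck flux subtracted along the path, and
    the path recorded.  Pathways carrying at least ``min_fraction`` of the
    total flux are returned, sorted by flux descending.
    """
    net = np.array(net, dtype=float)
    source = [int(s) for s in source]
    target = [int(t) for t in target]
    total = float(net[source, :].sum() - net[:, source].sum())
    if total <= 0:
        raise ValueError("total source->target flux must be positive")
    pathways = []
    removed = 0.0
    for _ in range(max_paths):
        path, width = _widest_path(net, source, target)
        if not path or width <= total * 1e-12:
            break
        for a, b in zip(path[:-1], path[1:]):
            net[a, b] -= width
        pathways.append((tuple(path), width))
        removed += width
        if total - removed <= total * 1e-9:
            break
    pathways.sort(key=lambda pf: pf[1], reverse=True)
    kept = [(p, f) for p, f in pathways if f / total >= min_fraction]
    return PathwayDecomposition(pathways=kept, total_flux=total)


def mfpt(model: MarkovModel, source: Sequence[int], target: Sequence[int]) -> float:
    """Mean first-passage time (in lag steps) from source to target.

    First-step analysis gives the expected hitting time of the target set
    from every state; the reported value averages over the source states
    with weights proportional to their stationary probabilities.  Returns
    ``inf`` when the target is unreachable.
    """
    target_arr = np.asarray(sorted(set(int(t) for t in target)))
    source_arr = np.asarray(sorted(set(int(s) for s in source)))
    if np.intersect1d(source_arr, target_arr).size:
        return 0.0 if np.all(np.isin(source_arr, target_arr)) else _mfpt_general(model, source_arr, target_arr)
    return _mfpt_general(model, source_arr, target_arr)


def _mfpt_general(model: MarkovModel, source: np.ndarray, target: np.ndarray) -> float:
    T = model.transition_matrix
    n = model.n_states
    others = np.setdiff1d(np.arange(n), target)
    h = np.zeros(n)
    if others.size:
        M = np.eye(others.size) - T[np.ix_(others, others)]
        try:
            h[others] = np.linalg.solve(M, np.ones(others.size))
        except np.linalg.LinAlgError:
            return np.inf
        if np.any(h[others] < -1e-9):
            return np.inf
    pi = model.stationary_distribution
    w = pi[source]
    w = w / w.sum()
    return float(w @ h[source])


def mfpt_matrix(
    model: MarkovModel, macromodel: MacrostateModel, physical: bool = True
) -> pd.DataFrame:
    """Macrostate-to-macrostate mean first-passage times.

    Entry (i, j) is the stationary-weighted MFPT from macrostate i's
    microstates to macrostate j's microstate set, in ns when ``physical``
    (lag steps otherwise).  The diagonal is zero.
    """
    M = macromodel.n_macrostates
    out = np.zeros((M, M))
    for i in range(M):
        for j in range(M):
            if i == j:
                continue
            steps = mfpt(model, macromodel.members(i), macromodel.members(j))
            out[i, j] = steps * model.lag_ns if physical else steps
    labels = [f"macrostate_{i}" for i in range(M)]
    return pd.DataFrame(out, index=labels, columns=labels)
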
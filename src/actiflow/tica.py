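"""Time-lagged independent component analysis.

tICA finds the slowest linearly-decorrelating coordinates of a feature time
series by solving the generalized eigenproblem

    C_tl(tau) u = lambda C u

where ``C`` is the instantaneous covariance of the mean-centred data and
``C_tl(tau)`` the time-lagged covariance at lag ``tau`` (averaged over
trajectories, never across trajectory boundaries).  ``C_tl`` is symmetrized
before the solve, which guarantees a real spectrum and corresponds to a
reversible estimate; a small ridge on the diagonal of ``C`` keeps the
problem well-posed when binary contact columns make ``C`` rank-deficient.

Eigenvalues are sorted descending; eigenvectors are C-orthonormal
(``U^T C U = I``) and sign-fixed so the largest-magnitude loading of each
component is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .descriptors import FeatureMatrix

__all__ = ["TicaModel", "Projection", "estimate_tica", "project", "rank_descriptor_correlations"]


@dataclass
class TicaModel:
    mean: np.ndarray
    covariance: np.ndarray
    lagged_covariance: np.ndarray  # symmetrized
    eigenvectors: np.ndarray  # (n_features, n_components), C-orthonormal
    eigenvalues: np.ndarray  # descending
    lag: int
    n_components: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")
        if np.max(np.abs(self.eigenvalues)) > 1.0 + 1e-6:
            raise ValueError("tICA eigenvalue magnitude exceeds 1 beyond tolerance")


@dataclass
class Projection:
    """Per-trajectory projections onto the retained components."""

    blocks: list[np.ndarray]
    n_components: int

    @property
    def stacked(self) -> np.ndarray:
        return np.vstack(self.blocks)


def _as_blocks(features: FeatureMatrix | Sequence[np.ndarray]) -> list[np.ndarray]:
    if isinstance(features, FeatureMatrix):
        return features.blocks
    return [np.asarray(b, dtype=float) for b in features]


def estimate_tica(
    features: FeatureMatrix | Sequence[np.ndarray],
    lag: int,
    n_components: int = 10,
    ridge: float | None = None,
) -> TicaModel:
    """Estimate a tICA model from one or more feature trajectories.

    ``ridge`` defaults to ``1e-8 * trace(C) / n_features`` added to the
    diagonal of ``C``.  Every trajectory must be longer than ``lag``.
    """
    blocks = _as_blocks(features)
    if lag < 1:
        raise ValueError("lag must be >= 1")
    for b in blocks:
        if b.shape[0] <= lag:
            raise ValueError("every trajectory must be longer than the lag")
    dim = blocks[0].shape[1]
    n_total = sum(b.shape[0] for b in blocks)
    mean = sum(b.sum(axis=0) for b in blocks) / n_total

    C = np.zeros((dim, dim))
    Ctl = np.zeros((dim, dim))
    n_pairs = 0
    for b in blocks:
        x = b - mean
        C += x.T @ x
        Ctl += x[:-lag].T @ x[lag:]
        n_pairs += x.shape[0] - lag
    C /= n_total
    Ctl /= n_pairs
    Ctl = 0.5 * (Ctl + Ctl.T)

    if ridge is None:
        ridge = 1e-8 * np.trace(C) / dim
    C_reg = C + ridge * np.eye(dim)

    if n_components > dim:
        raise ValueError("n_components exceeds the feature dimension")
    eigvals, eigvecs = scipy.linalg.eigh(Ctl, C_reg)
    order = np.argsort(eigvals)[::-1][:n_components]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-|loading| entry positive
    for j in range(eigvecs.shape[1]):
        k = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] *= -1.0
    return TicaModel(
        mean=mean,
        covariance=C,
        lagged_covariance=Ctl,
        eigenvectors=eigvecs,
        eigenvalues=eigvals,
        lag=lag,
        n_components=n_components,
    )


def project(model: TicaModel, features: FeatureMatrix | Sequence[np.ndarray]) -> Projection:
    """Mean-centre the data and project onto the retained eigenvectors."""
    blocks = _as_blocks(features)
    dim = model.mean.shape[0]
    out = []
    for b in blocks:
        if b.shape[1] != dim:
            raise ValueError(f"feature dimension {b.shape[1]} does not match model ({dim})")
        out.append((b - model.mean) @ model.eigenvectors)
    return Projection(blocks=out, n_components=model.n_components)


def rank_descriptor_correlations(
    projection: Projection,
    features: FeatureMatrix | Sequence[np.ndarray],
    component: int = 0,
    top_n: int = 75,
    names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Rank descriptors by |Pearson correlation| with one projected component.

    Constant descriptor columns get correlation 0 and a ``constant`` flag.
    Returns the ``top_n`` rows sorted by absolute correlation, descending.
    """
    blocks = _as_blocks(features)
    X = np.vstack(blocks)
    y = projection.stacked[:, component]
    if X.shape[0] != y.shape[0]:
        raise ValueError("feature and projection frame counts differ")
    if names is None:
        names = features.names if isinstance(features, FeatureMatrix) else [
            f"descriptor_{i}" for i in range(X.shape[1])
        ]
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    # relative constancy test: rounding residue of a constant column scales
    # with its magnitude
    scale = np.maximum(np.abs(X).max(axis=0), 1.0)
    constant = sx <= 1e-10 * np.sqrt(X.shape[0]) * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (xc.T @ yc) / (sx * sy)
    corr = np.where(constant | ~np.isfinite(corr), 0.0, corr)
    table = pd.DataFrame(
        {"descriptor": list(names), "correlation": corr, "constant": constant}
    )
    table = table.reindex(table["correlation"].abs().sort_values(ascending=False).index)
    return table.head(top_n).reset_index(drop=True)
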
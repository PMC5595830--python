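"""Shared test constructions."""

import numpy as np

# A-I-B birth-death chain with P(I->A)=0.2, P(I->B)=0.1: q(I) = 1/3
CHAIN_AIB = np.array([[0.8, 0.2, 0.0], [0.2, 0.7, 0.1], [0.0, 0.1, 0.9]])


def exact_model(T):
    """Wrap an exact reversible transition matrix in a MarkovModel."""
    from actiflow.msm import MarkovModel

    T = np.asarray(T, dtype=float)
    vals, vecs = np.linalg.eig(T.T)
    pi = np.abs(vecs[:, np.argmax(vals.real)].real)
    pi /= pi.sum()
    vals_sorted = np.sort(np.linalg.eigvals(T).real)[::-1]
    return MarkovModel(
        lag=1,
        frame_interval_ns=1.0,
        counts=pi[:, None] * T * 1e6,
        active_set=np.arange(len(T)),
        transition_matrix=T,
        stationary_distribution=pi,
        eigenvalues=vals_sorted,
    )
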
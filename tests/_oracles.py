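"""Independent oracles used by the test suite.

Deliberately implemented apart from the package: quaternion-eigenvalue RMSD,
brute-force medoids and nearest-neighbour scans, hand likelihoods.  They share
no code path with the implementations they check.
"""

from __future__ import annotations

import numpy as np


def quaternion_rmsd(X: np.ndarray, Y: np.ndarray) -> float:
    """Minimum RMSD after optimal rotation, by the quaternion eigenvalue method.

    Builds the 4x4 key matrix from the centered covariance; the largest
    eigenvalue lambda_max gives rmsd^2 = (Gx + Gy - 2 lambda_max) / N.
    """
    X = np.asarray(X, float) - np.mean(X, axis=0)
    Y = np.asarray(Y, float) - np.mean(Y, axis=0)
    n = X.shape[0]
    R = X.T @ Y
    Gx = float(np.sum(X * X))
    Gy = float(np.sum(Y * Y))
    Sxx, Sxy, Sxz = R[0]
    Syx, Syy, Syz = R[1]
    Szx, Szy, Szz = R[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    return float(np.sqrt(max(Gx + Gy - 2.0 * lam, 0.0) / n))


def brute_force_min_distance(A: np.ndarray, B: np.ndarray) -> float:
    best = np.inf
    for a in A:
        for b in B:
            best = min(best, float(np.linalg.norm(a - b)))
    return best


def brute_force_medoid(frames: np.ndarray, rmsd_fn) -> int:
    """Index of the frame minimising summed RMSD to all others."""
    n = frames.shape[0]
    totals = [sum(rmsd_fn(frames[i], frames[j]) for j in range(n)) for i in range(n)]
    return int(np.argmin(totals))


def brute_force_nearest_center(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape[0], dtype=int)
    for i, x in enumerate(X):
        d = [float(np.linalg.norm(x - c)) for c in centers]
        out[i] = int(np.argmin(d))
    return out


def hand_count_transitions(labels: np.ndarray, lag: int, n_states: int) -> np.ndarray:
    C = np.zeros((n_states, n_states))
    for t in range(len(labels) - lag):
        C[labels[t], labels[t + lag]] += 1
    return C


def markov_log_likelihood(C: np.ndarray, T: np.ndarray) -> float:
    mask = C > 0
    return float(np.sum(C[mask] * np.log(T[mask])))


def empirical_transition_matrix(labels: np.ndarray, n_states: int) -> np.ndarray:
    C = hand_count_transitions(np.asarray(labels, int), 1, n_states)
    return C / C.sum(axis=1, keepdims=True)


def covariance_pca(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """PCA by explicit covariance eigendecomposition (loadings, projections)."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:k]
    W = vecs[:, order].T
    return W, Xc @ W.T


def lumped_two_state_chain(T_hidden: np.ndarray, lump: np.ndarray, power: int) -> np.ndarray:
    """Exact marginalised 2-observed-state transition matrix of a hidden chain.

    ``lump[i]`` maps hidden state i to observed state 0/1; the hidden chain is
    propagated ``power`` steps and projected with stationary weighting.
    """
    vals, vecs = np.linalg.eig(T_hidden.T)
    pi = np.real(vecs[:, np.argmin(np.abs(vals - 1))])
    pi = np.abs(pi) / np.abs(pi).sum()
    P = np.linalg.matrix_power(T_hidden, power)
    out = np.zeros((2, 2))
    for a in range(2):
        w = pi * (lump == a)
        flux = w @ P
        for b in range(2):
            out[a, b] = flux[lump == b].sum()
        out[a] /= w.sum()
    return out
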
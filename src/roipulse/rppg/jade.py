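"""JADE blind source separation by joint diagonalization of cumulant matrices.

Compact port of Cardoso's classic algorithm for small sensor counts (here 3
color channels).  Deterministic: whitening via eigendecomposition and Jacobi
sweeps need no random initialization.
"""

from __future__ import annotations

import numpy as np

__all__ = ["jade", "DecompositionError"]


class DecompositionError(ValueError):
    """Input is rank-deficient or otherwise unseparable."""


def jade(X: np.ndarray, n_sources: int | None = None,
         rank_tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Separate ``X`` (n_sensors x T) into independent components.

    Returns ``(S, B)`` with sources ``S = B @ X`` (n_sources x T).  Sources
    are recovered up to sign, scale and permutation; they are ordered by
    descending variance explained in the whitened space.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DecompositionError(f"need a (n>=2, T) sensor matrix, got {X.shape}")
    n, T = X.shape
    m = n_sources or n
    X = X - X.mean(axis=1, keepdims=True)

    # --- whitening
    C = (X @ X.T) / T
    d, U = np.linalg.eigh(C)
    order = np.argsort(d)[::-1][:m]
    d, U = d[order], U[:, order]
    if d[0] <= 0 or d[-1] <= rank_tol * d[0]:
        raise DecompositionError(
            f"rank-deficient input: covariance eigenvalues {np.sort(d)[::-1]}")
    W = (U / np.sqrt(d)).T  # (m, n)
    Z = W @ X

    # --- fourth-order cumulant matrices (m(m+1)/2 of them, stacked columns)
    R = np.eye(m)
    nbcm = m * (m + 1) // 2
    CM = np.zeros((m, m * nbcm))
    pos = 0
    for im in range(m):
        Zim = Z[im]
        Q = ((Zim * Zim) * Z) @ Z.T / T - R - 2.0 * np.outer(R[:, im], R[:, im])
        CM[:, pos:pos + m] = Q
        pos += m
        for jm in range(im):
            Zijm = Zim * Z[jm]
            Q = np.sqrt(2.0) * (
                (Zijm * Z) @ Z.T / T
                - np.outer(R[:, im], R[:, jm])
                - np.outer(R[:, jm], R[:, im])
            )
            CM[:, pos:pos + m] = Q
            pos += m

    # --- joint diagonalization by Jacobi rotations
    V = np.eye(m)
    threshold = 1e-6 / np.sqrt(T)
    active = True
    sweeps = 0
    while active and sweeps < 100:
        active = False
        sweeps += 1
        for p in range(m - 1):
            for q in range(p + 1, m):
                Ip = np.arange(p, m * nbcm, m)
                Iq = np.arange(q, m * nbcm, m)
                g = np.vstack([CM[p, Ip] - CM[q, Iq], CM[p, Iq] + CM[q, Ip]])
                gg = g @ g.T
                ton = gg[0, 0] - gg[1, 1]
                toff = gg[0, 1] + gg[1, 0]
                theta = 0.5 * np.arctan2(toff, ton + np.sqrt(ton * ton + toff * toff))
                if abs(theta) > threshold:
                    active = True
                    c, s = np.cos(theta), np.sin(theta)
                    G = np.array([[c, -s], [s, c]])
                    V[:, [p, q]] = V[:, [p, q]] @ G
                    CM[[p, q], :] = G.T @ CM[[p, q], :]
                    CM[:, np.concatenate([Ip, Iq])] = np.hstack([
                        c * CM[:, Ip] + s * CM[:, Iq],
                        -s * CM[:, Ip] + c * CM[:, Iq],
                    ])

    B = V.T @ W
    S = B @ X
    # deterministic ordering/sign: by source variance, positive skew-of-peak
    var = S.var(axis=1)
    order = np.argsort(var)[::-1]
    S, B = S[order], B[order]
    signs = np.sign(np.sum(S ** 3, axis=1))
    signs[signs == 0] = 1.0
    return S * signs[:, None], B * signs[:, None]
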
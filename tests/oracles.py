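"""Independent reference implementations used as test oracles.

These are deliberately written in the most literal textbook form (matrix
inversion, dense numerical integration) and share no code with the
package's decoder.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import multivariate_normal


def kalman_filter(ys, A, b, Q, H, p, V, m0, P0):
    """Plain textbook Kalman filter (predict + update via matrix inverse).

    Returns per-bin posterior means, covariances and log innovation
    likelihoods.
    """
    ys = np.atleast_2d(ys)
    x, P = np.asarray(m0, float).copy(), np.asarray(P0, float).copy()
    means, covs, logliks = [], [], []
    for y in ys:
        x = A @ x + b
        P = A @ P @ A.T + Q
        S = H @ P @ H.T + V
        Sinv = np.linalg.inv(S)
        innov = y - (H @ x + p)
        sign, logdet = np.linalg.slogdet(S)
        logliks.append(
            -0.5 * (len(y) * np.log(2 * np.pi) + logdet + innov @ Sinv @ innov)
        )
        K = P @ H.T @ Sinv
        x = x + K @ innov
        P = (np.eye(len(x)) - K @ H) @ P
        means.append(x.copy())
        covs.append(P.copy())
    return np.array(means), np.array(covs), np.array(logliks)


def grid_mixture_decode(ys, models, prior, m0, P0, axes):
    """Dense numerical integration of the mixture filtering recursion.

    ``models`` is a list of (A, b, Q, H, p, V) tuples; ``axes`` a list of
    1D grids, one per state dimension.  Maintains, for each regime, the
    unnormalised density P(x_t, y_1..t | m) P(m) on the grid; returns the
    collapsed posterior means and the regime weights per bin.
    """
    ys = np.atleast_2d(ys)
    mesh = np.meshgrid(*axes, indexing="ij")
    X = np.stack([m.ravel() for m in mesh], axis=1)  # (G, d)
    dx = np.prod([ax[1] - ax[0] for ax in axes])
    G = X.shape[0]

    f = []
    trans = []
    for (A, b, Q, H, p, V), pm in zip(models, prior):
        f.append(pm * multivariate_normal.pdf(X, mean=m0, cov=P0))
        # T[i, j] = N(X[i]; A X[j] + b, Q)
        propagated = X @ np.asarray(A).T + np.asarray(b)
        T = np.empty((G, G))
        for j in range(G):
            T[:, j] = multivariate_normal.pdf(X, mean=propagated[j], cov=Q)
        trans.append(T)

    means, weights = [], []
    for y in ys:
        masses = np.empty(len(models))
        mixture_mean = 0.0
        new_f = []
        for k, (A, b, Q, H, p, V) in enumerate(models):
            pred = trans[k] @ f[k] * dx
            obs_mean = X @ np.asarray(H).T + np.asarray(p)
            resid = obs_mean - y
            Vinv = np.linalg.inv(V)
            _, logdetV = np.linalg.slogdet(V)
            log_lik = -0.5 * (
                len(y) * np.log(2 * np.pi)
                + logdetV
                + np.einsum("ij,jk,ik->i", resid, Vinv, resid)
            )
            fk = pred * np.exp(log_lik)
            new_f.append(fk)
            masses[k] = fk.sum() * dx
        f = new_f
        total = masses.sum()
        weights.append(masses / total)
        num = sum(fk[:, None] * X for fk in f).sum(axis=0) * dx
        means.append(num / total)
    return np.array(means), np.array(weights)
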
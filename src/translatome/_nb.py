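"""Negative-binomial fitting primitives shared by the differential tests.

Counts y_gj are modelled as NB2 with mean mu_gj and dispersion phi_g
(Var = mu + phi * mu^2).  Library sizes enter as multiplicative offsets, so
every fit estimates a per-million-style rate r with mu_gj = r_g * N_j.
All solvers are vectorised across genes; no per-gene Python loops.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

# dispersion below this is treated as effectively Poisson-sized
_PHI_FLOOR = 1e-6
_MAX_ITER = 60
_TOL = 1e-10


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row sums of the NB2 log-likelihood. y, mu: (G, S); phi: (G,)."""
    phi = np.maximum(np.asarray(phi, dtype=float), _PHI_FLOOR)
    k = (1.0 / phi)[:, None]
    mu = np.maximum(mu, 1e-300)
    ll = (
        gammaln(y + k)
        - gammaln(k)
        - gammaln(y + 1.0)
        + k * np.log(k / (k + mu))
        + y * np.log(mu / (k + mu))
    )
    # mu == 0 contributes 0 when y == 0 (point mass at zero)
    ll = np.where((y == 0) & (mu <= 1e-299), 0.0, ll)
    return ll.sum(axis=1)


def nb_mean_mle(
    y: np.ndarray, libsize: np.ndarray, phi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """MLE of the common rate r (mu_j = r * N_j) per gene, plus the log-lik.

    Fisher scoring on theta = log r; the log-likelihood is concave in theta,
    and the Poisson MLE sum(y)/sum(N) is the starting value.
    """
    y = np.asarray(y, dtype=float)
    libsize = np.asarray(libsize, dtype=float)
    phi = np.maximum(np.asarray(phi, dtype=float), _PHI_FLOOR)
    k = 1.0 / phi

    total = y.sum(axis=1)
    positive = total > 0
    r = np.where(positive, total / libsize.sum(), 0.0)

    theta = np.log(np.where(positive, r, 1.0))
    kcol = k[:, None]
    for _ in range(_MAX_ITER):
        mu = np.exp(theta)[:, None] * libsize[None, :]
        score = (y - mu * (y + kcol) / (kcol + mu)).sum(axis=1)
        info = (mu * kcol / (kcol + mu)).sum(axis=1)
        step = np.where(positive & (info > 0), score / np.maximum(info, 1e-12), 0.0)
        step = np.clip(step, -4.0, 4.0)
        theta = theta + step
        if np.max(np.abs(step)) < _TOL:
            break
    r = np.where(positive, np.exp(theta), 0.0)
    mu = r[:, None] * libsize[None, :]
    return r, nb_loglik(y, mu, phi)


def nb_glm_irls(
    y: np.ndarray,
    X: np.ndarray,
    libsize: np.ndarray,
    phi: np.ndarray,
    n_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit log-link NB regressions (shared design X, per-gene counts).

    eta = X beta + log(libsize).  Returns beta (G, P) and log-likelihoods.
    Fisher scoring with expected weights w = mu / (1 + phi mu).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    libsize = np.asarray(libsize, dtype=float)
    phi = np.maximum(np.asarray(phi, dtype=float), _PHI_FLOOR)

    G, S = y.shape
    P = X.shape[1]
    offset = np.log(libsize)[None, :]

    # start from a flat rate per gene (intercept-only), small floor for zeros
    r0 = np.maximum(y.sum(axis=1) / libsize.sum(), 1e-8)
    beta = np.zeros((G, P))
    beta[:, 0] = np.log(r0)

    eye = np.eye(P) * 1e-8
    for _ in range(n_iter):
        eta = beta @ X.T + offset
        mu = np.exp(np.clip(eta, -500, 500))
        w = mu / (1.0 + phi[:, None] * mu)
        z = (eta - offset) + (y - mu) / np.maximum(mu, 1e-12)
        A = np.einsum("jp,gj,jq->gpq", X, w, X) + eye
        b = np.einsum("jp,gj->gp", X, w * z)
        new_beta = np.linalg.solve(A, b[..., None])[..., 0]
        delta = np.max(np.abs(new_beta - beta))
        beta = new_beta
        if delta < 1e-9:
            break
    eta = beta @ X.T + offset
    mu = np.exp(np.clip(eta, -500, 500))
    return beta, nb_loglik(y, mu, phi)
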
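"""Small MCMC building blocks shared by the inference modules.

Contains a robust adaptive random-walk Metropolis sampler (covariance
adapted during burn-in, frozen afterwards so the chain is Markovian when
draws are kept) and the split potential-scale-reduction diagnostic.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from pyrethro.errors import DomainError


def adaptive_metropolis(
    log_post: Callable[[np.ndarray], float],
    x0: np.ndarray,
    n_iter: int,
    rng: np.random.Generator,
    initial_scale: float = 0.1,
    adapt_until: float = 0.5,
    target_accept: float = 0.3,
) -> tuple[np.ndarray, float]:
    """Random-walk Metropolis with diagonal-to-full covariance adaptation.

    Returns the full chain (n_iter, dim) and the post-adaptation acceptance
    rate.  Scale adapts by Robbins-Monro toward ``target_accept`` and the
    proposal covariance is re-estimated from the history every 200 steps,
    both only during the first ``adapt_until`` fraction of iterations.
    """
    x = np.asarray(x0, dtype=float).copy()
    dim = x.size
    lp = log_post(x)
    if not np.isfinite(lp):
        raise DomainError("initial point has zero posterior density")
    chain = np.empty((n_iter, dim))
    scale = initial_scale
    chol = np.eye(dim)
    n_adapt = int(adapt_until * n_iter)
    accepted_post = 0
    for i in range(n_iter):
        prop = x + scale * chol @ rng.standard_normal(dim)
        lp_prop = log_post(prop)
        if np.log(rng.random()) < lp_prop - lp:
            x, lp = prop, lp_prop
            accept = 1.0
        else:
            accept = 0.0
        chain[i] = x
        if i < n_adapt:
            scale *= np.exp((accept - target_accept) / (1 + i) ** 0.6 * 2.0)
            if i > 50 and (i + 1) % 200 == 0:
                cov = np.cov(chain[max(0, i - 1000) : i + 1].T).reshape(dim, dim)
                cov += 1e-10 * np.eye(dim)
                try:
                    chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    pass
        else:
            accepted_post += int(accept)
    rate = accepted_post / max(1, n_iter - n_adapt)
    return chain, rate


def split_rhat(chains: np.ndarray) -> float:
    """Split potential scale reduction factor for one scalar parameter.

    ``chains`` has shape (n_chains, n_iterations).  Each chain is split in
    half before the between/within variance comparison.  Chains that are
    exactly constant and identical have, by convention, R-hat = 1.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise DomainError("need >= 2 chains of equal length")
    n = chains.shape[1]
    if n < 10:
        raise DomainError("chains too short for a split diagnostic (need >= 10)")
    half = n // 2
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n2 = split.shape
    means = split.mean(axis=1)
    variances = split.var(axis=1, ddof=1)
    w = variances.mean()
    b = n2 * means.var(ddof=1)
    if w == 0.0:
        return 1.0  # zero-variance guard: identical constant chains
    var_hat = (n2 - 1) / n2 * w + b / n2
    return float(np.sqrt(var_hat / w))
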
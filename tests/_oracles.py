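"""Independent reference computations used by the tests.

These deliberately avoid the package's own code paths: the intercept
posterior comes from deterministic numerical quadrature of the exact
unnormalized density, and AUC from brute-force enumeration of
positive-negative pairs.
"""

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import expit


def quadrature_intercept_posterior(
    y, prior_mean, prior_var, sigma2=1.0, grid=None, n_nodes=80
):
    """Exact posterior of the intercept in the over-dispersed intercept-only model.

    The per-observation likelihood marginalizes the latent Gaussian
    over-dispersion by Gauss-Hermite quadrature:
    ``pbar(b0) = E[expit(b0 + eps)], eps ~ N(0, sigma2)``; the posterior on a
    dense grid is then normalized by the trapezoid rule.

    Returns (grid, pdf, cdf, mean).
    """
    y = np.asarray(y, float)
    if grid is None:
        grid = np.linspace(-15.0, 15.0, 6001)
    nodes, weights = hermegauss(n_nodes)
    weights = weights / np.sqrt(2.0 * np.pi)
    pbar = expit(grid[:, None] + np.sqrt(sigma2) * nodes[None, :]) @ weights
    n1 = float(y.sum())
    n0 = float(len(y) - n1)
    log_post = (
        n1 * np.log(pbar)
        + n0 * np.log1p(-pbar)
        - 0.5 * (grid - prior_mean) ** 2 / prior_var
    )
    log_post -= log_post.max()
    pdf = np.exp(log_post)
    pdf /= np.trapezoid(pdf, grid)
    mean = float(np.trapezoid(grid * pdf, grid))
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(grid))])
    cdf /= cdf[-1]
    return grid, pdf, cdf, mean


def ks_distance(draws, grid, cdf):
    """Kolmogorov-Smirnov distance between an empirical sample and a gridded CDF."""
    draws = np.sort(np.asarray(draws, float))
    theoretical = np.interp(draws, grid, cdf)
    n = len(draws)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(
        max(np.abs(theoretical - ecdf_hi).max(), np.abs(theoretical - ecdf_lo).max())
    )


def pairwise_auc(scores, labels):
    """Mann-Whitney AUC by enumerating every positive-negative pair, ties counted half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))
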
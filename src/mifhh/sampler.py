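"""Metropolis-within-Gibbs sampler for the hierarchical logistic model.

Model
-----
For dyad row ``ij`` (informant i reporting on family member j):

    y_ij ~ Bernoulli(theta_ij),   logit(theta_ij) = eta_ij
    eta_ij = X_ij beta + W_i b_{g(ij)} + eps_ij
    eps_ij ~ N(0, sigma^2)                    (per-observation over-dispersion)
    b_c    ~ N_q(0, D)                        (informant- or family-level)
    beta   ~ N_p(b, B^-1)
    sigma^2 ~ InvGamma(nu, delta)
    D      ~ InvWishart(psi, rho)

Update scheme
-------------
The per-observation latent logits ``eta`` are updated by random-walk
Metropolis with one proposal scale per observation, adapted during burn-in
by Robbins–Monro toward the target acceptance rate (default 45%) and frozen
afterwards.  Conditional on ``eta`` the remaining block is an ordinary
linear-Gaussian hierarchy with ``eta`` as the response, so ``beta``, the
``b_c``, ``D`` and ``sigma^2`` are drawn from their exact conjugate full
conditionals.  A fixed seed gives bitwise-identical draws.

The default run configuration keeps every other draw of a 20,000-iteration
sampling phase after a 5,000-iteration burn-in, for a retained sample of
S = 10,000.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

from mifhh.data import DesignMatrices
from mifhh.exceptions import ConfigurationError, DegenerateInputError
from mifhh.priors import HyperParameters

#: clamp bound applied to theta before taking logs in the deviance
THETA_CLAMP = 1.0e-12

#: Robbins-Monro step-size decay exponent for proposal-scale adaptation
_RM_DECAY = 0.55


@dataclass
class SamplerConfig:
    """Chain-length and adaptation settings.

    ``n_iterations`` is the number of post-burn-in sampling iterations;
    every ``thin``-th of them is retained, so the retained sample size is
    ``S = n_iterations // thin`` (defaults: 20,000 / 2 = 10,000 after a
    5,000-iteration burn-in).
    """

    n_iterations: int = 20_000
    burn_in: int = 5_000
    thin: int = 2
    target_acceptance: float = 0.45
    seed: int = 0
    adapt: bool = True
    initial_step: float = 1.0

    def __post_init__(self) -> None:
        if self.burn_in < 0:
            raise ConfigurationError("burn_in must be >= 0")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")
        if not 0.0 < self.target_acceptance < 1.0:
            raise ConfigurationError("target_acceptance must lie in (0, 1)")
        if self.n_iterations < self.thin:
            raise ConfigurationError("n_iterations must be >= thin")
        if self.initial_step <= 0:
            raise ConfigurationError("initial_step must be positive")

    @property
    def n_retained(self) -> int:
        return self.n_iterations // self.thin


@dataclass
class PosteriorDraws:
    """Retained MCMC output.

    Arrays are indexed by retained draw ``s``: ``beta[s]`` is the p-vector of
    fixed effects (intercept first), ``b[s]`` the C x q matrix of cluster
    coefficients, ``D[s]`` the level-2 covariance, ``sigma2[s]`` the
    over-dispersion variance (constant 1 when fixed), ``theta[s]`` the
    N-vector of dyad Bernoulli probabilities (inverse-logit of the latent
    linear predictor including eps), and ``deviance[s]`` the Bernoulli
    deviance of the data at ``theta[s]``.  ``acceptance_rate`` is the
    realized mean Metropolis acceptance over the sampling phase.
    """

    beta: np.ndarray
    b: Optional[np.ndarray]
    D: Optional[np.ndarray]
    sigma2: np.ndarray
    theta: np.ndarray
    deviance: np.ndarray
    acceptance_rate: float

    @property
    def S(self) -> int:
        return self.beta.shape[0]

    def save_npz(self, path) -> None:
        """Compact binary columnar export (NumPy ``.npz``)."""
        arrays = {
            "beta": self.beta,
            "sigma2": self.sigma2,
            "theta": self.theta,
            "deviance": self.deviance,
            "acceptance_rate": np.array(self.acceptance_rate),
        }
        if self.b is not None:
            arrays["b"] = self.b
            arrays["D"] = self.D
        np.savez_compressed(path, **arrays)

    @classmethod
    def load_npz(cls, path) -> "PosteriorDraws":
        with np.load(path) as data:
            return cls(
                beta=data["beta"],
                b=data["b"] if "b" in data else None,
                D=data["D"] if "D" in data else None,
                sigma2=data["sigma2"],
                theta=data["theta"],
                deviance=data["deviance"],
                acceptance_rate=float(data["acceptance_rate"]),
            )

    def save_csv(self, directory, include_theta: bool = False) -> None:
        """Delimited-text export, one file per parameter block with a draw column.

        ``theta`` is S x N and is only written when requested.
        """
        import pandas as pd
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        draw = np.arange(self.S)

        beta_cols = {f"beta{k}": self.beta[:, k] for k in range(self.beta.shape[1])}
        pd.DataFrame({"draw": draw, **beta_cols}).to_csv(directory / "beta.csv", index=False)
        pd.DataFrame({"draw": draw, "sigma2": self.sigma2}).to_csv(
            directory / "sigma2.csv", index=False
        )
        pd.DataFrame({"draw": draw, "deviance": self.deviance}).to_csv(
            directory / "deviance.csv", index=False
        )
        if self.b is not None:
            S, C, q = self.b.shape
            cols = {
                f"b_c{c}_q{k}": self.b[:, c, k] for c in range(C) for k in range(q)
            }
            pd.DataFrame({"draw": draw, **cols}).to_csv(directory / "b.csv", index=False)
            dcols = {
                f"D_{r}{c}": self.D[:, r, c] for r in range(q) for c in range(q)
            }
            pd.DataFrame({"draw": draw, **dcols}).to_csv(directory / "D.csv", index=False)
        if include_theta:
            pd.DataFrame(
                self.theta, columns=[f"dyad{i}" for i in range(self.theta.shape[1])]
            ).assign(draw=draw).to_csv(directory / "theta.csv", index=False)


def bernoulli_deviance(y: np.ndarray, theta: np.ndarray) -> float:
    """``-2 * sum(y ln theta + (1-y) ln(1-theta))`` with theta clamped away from {0,1}."""
    y = np.asarray(y, float)
    theta = np.asarray(theta, float)
    if y.shape != theta.shape:
        raise ValueError("y and theta must have equal length")
    if np.any(theta <= 0.0) or np.any(theta >= 1.0):
        warnings.warn(
            f"theta values at or outside (0,1) clamped to [{THETA_CLAMP}, 1-{THETA_CLAMP}]",
            stacklevel=2,
        )
    theta = np.clip(theta, THETA_CLAMP, 1.0 - THETA_CLAMP)
    return float(-2.0 * np.sum(y * np.log(theta) + (1.0 - y) * np.log(1.0 - theta)))


def _deviance_from_theta(y: np.ndarray, theta: np.ndarray) -> float:
    # internal hot-path variant: theta already strictly inside (0,1)
    theta = np.clip(theta, THETA_CLAMP, 1.0 - THETA_CLAMP)
    return float(-2.0 * np.sum(y * np.log(theta) + (1.0 - y) * np.log(1.0 - theta)))


def _invwishart_rvs(scale: np.ndarray, df: float, rng: np.random.Generator) -> np.ndarray:
    """Bartlett-decomposition inverse-Wishart draw: D = (L A A' L')^-1 with L = chol(scale^-1)."""
    q = scale.shape[0]
    chol_inv = np.linalg.cholesky(np.linalg.inv(scale))
    A = np.zeros((q, q))
    for i in range(q):
        A[i, i] = np.sqrt(rng.chisquare(df - i))
    if q > 1:
        idx = np.tril_indices(q, k=-1)
        A[idx] = rng.standard_normal(len(idx[0]))
    factor = chol_inv @ A
    wishart = factor @ factor.T
    return np.linalg.inv(wishart)


def _check_consistency(design: DesignMatrices, hyper: HyperParameters) -> None:
    if design.N == 0:
        raise DegenerateInputError("design has no observations")
    if hyper.p != design.p:
        raise ConfigurationError(
            f"hyperparameter dimension p={hyper.p} does not match design p={design.p}"
        )
    if hyper.q != design.q:
        raise ConfigurationError(
            f"hyperparameter dimension q={hyper.q} does not match design q={design.q}"
        )
    if design.q >= 1 and design.C < 2:
        warnings.warn(
            "level-2 covariance is weakly identified with fewer than 2 clusters",
            stacklevel=3,
        )


def fit(
    design: DesignMatrices,
    hyper: HyperParameters,
    config: SamplerConfig,
    estimate_sigma2: Optional[bool] = None,
) -> PosteriorDraws:
    """Sample the joint posterior of (beta, {b_c}, D, sigma^2, {eps_ij}).

    ``estimate_sigma2=None`` defers to ``design.spec.estimate_sigma2``; when
    false, sigma^2 is held at 1 (the over-dispersion fixed to 1).  With
    ``q = 0`` (no clustering) the random-effect block is skipped and the
    model is an over-dispersed logistic regression.
    """
    _check_consistency(design, hyper)
    if estimate_sigma2 is None:
        estimate_sigma2 = design.spec.estimate_sigma2

    y = design.y
    X = design.X
    W = design.W
    N, p = X.shape
    q = design.q
    C = design.C
    rng = np.random.default_rng(config.seed)

    if q:
        # recode clusters by first appearance so that relabelling cluster
        # identifiers leaves fixed-seed draws unchanged up to the matching
        # permutation of b
        code_of: dict[int, int] = {}
        g = np.empty(N, dtype=np.intp)
        for i, c in enumerate(design.g):
            g[i] = code_of.setdefault(int(c), len(code_of))
        back = np.empty(C, dtype=np.intp)  # canonical code -> caller code
        for caller, canon in code_of.items():
            back[canon] = caller
    else:
        g = None

    XtX = X.T @ X
    Bb = hyper.B @ hyper.b
    if q:
        # per-cluster W'W, fixed across iterations
        WtW = np.zeros((C, q, q))
        np.add.at(WtW, g, W[:, :, None] * W[:, None, :])

    # deterministic, prior-consistent initial state
    beta = hyper.b.copy()
    b = np.zeros((C, q)) if q else None
    D = (hyper.psi / hyper.rho) if q else None
    sigma2 = 1.0
    eta = X @ beta  # eps initialized at 0, b at 0

    log_step = np.full(N, np.log(config.initial_step))
    target = config.target_acceptance

    S = config.n_retained
    beta_draws = np.empty((S, p))
    b_draws = np.empty((S, C, q)) if q else None
    D_draws = np.empty((S, q, q)) if q else None
    sigma2_draws = np.empty(S)
    theta_draws = np.empty((S, N))
    deviance_draws = np.empty(S)

    total = config.burn_in + config.n_iterations
    accept_sum = 0.0
    accept_iters = 0
    stored = 0
    eye_flat = np.eye(q).ravel() if q else None

    for t in range(1, total + 1):
        mu = X @ beta
        if q:
            mu = mu + np.einsum("nk,nk->n", W, b[g])

        # --- Metropolis update of the latent logits eta ---
        prop = eta + np.exp(log_step) * rng.standard_normal(N)
        log_ratio = (
            y * (prop - eta)
            - np.logaddexp(0.0, prop)
            + np.logaddexp(0.0, eta)
            - ((prop - mu) ** 2 - (eta - mu) ** 2) / (2.0 * sigma2)
        )
        accepted = np.log(rng.random(N)) < log_ratio
        eta = np.where(accepted, prop, eta)

        if config.adapt and t <= config.burn_in:
            gamma = t ** -_RM_DECAY
            log_step += gamma * (accepted - target)
            np.clip(log_step, -10.0, 5.0, out=log_step)
        if t > config.burn_in:
            accept_sum += accepted.mean()
            accept_iters += 1

        # --- conjugate Gaussian block given eta ---
        if q:
            resid = eta - np.einsum("nk,nk->n", W, b[g])
        else:
            resid = eta
        prec = hyper.B + XtX / sigma2
        cf = cho_factor(prec, lower=True)
        mean = cho_solve(cf, Bb + X.T @ resid / sigma2)
        beta = mean + np.linalg.solve(
            np.linalg.cholesky(prec).T, rng.standard_normal(p)
        )

        if q:
            r = eta - X @ beta
            Wtr = np.empty((C, q))
            for k in range(q):
                Wtr[:, k] = np.bincount(g, weights=W[:, k] * r, minlength=C)
            Dinv = np.linalg.inv(D)
            prec_c = Dinv[None, :, :] + WtW / sigma2
            L_c = np.linalg.cholesky(prec_c)
            mean_c = np.linalg.solve(prec_c, Wtr[:, :, None] / sigma2)[:, :, 0]
            noise = np.linalg.solve(
                np.transpose(L_c, (0, 2, 1)), rng.standard_normal((C, q, 1))
            )[:, :, 0]
            b = mean_c + noise

            Sb = b.T @ b
            D = _invwishart_rvs(hyper.psi + Sb, hyper.rho + C, rng)

        if estimate_sigma2:
            if q:
                eps_now = eta - X @ beta - np.einsum("nk,nk->n", W, b[g])
            else:
                eps_now = eta - X @ beta
            shape = hyper.nu + 0.5 * N
            scale = hyper.delta + 0.5 * float(eps_now @ eps_now)
            sigma2 = scale / rng.gamma(shape)

        # --- retention ---
        if t > config.burn_in and (t - config.burn_in) % config.thin == 0:
            theta = expit(eta)
            beta_draws[stored] = beta
            if q:
                b_draws[stored] = b
                D_draws[stored] = D
            sigma2_draws[stored] = sigma2
            theta_draws[stored] = theta
            deviance_draws[stored] = _deviance_from_theta(y, theta)
            stored += 1

    if q:
        # return b in the caller's cluster coding
        b_out = np.empty_like(b_draws[:stored])
        b_out[:, back, :] = b_draws[:stored]
    return PosteriorDraws(
        beta=beta_draws[:stored],
        b=b_out if q else None,
        D=D_draws[:stored] if q else None,
        sigma2=sigma2_draws[:stored],
        theta=theta_draws[:stored],
        deviance=deviance_draws[:stored],
        acceptance_rate=accept_sum / max(accept_iters, 1),
    )


def fit_null(
    design: DesignMatrices, hyper: HyperParameters, config: SamplerConfig
) -> PosteriorDraws:
    """Non-hierarchical intercept-only baseline.

    An ordinary Bayesian logistic regression on the stacked reports with no
    random effects and no over-dispersion term: logit(theta) = beta0 for
    every dyad, so theta is constant across dyads within a draw.  beta0 is
    updated by adaptive random-walk Metropolis.
    """
    if design.N == 0:
        raise DegenerateInputError("design has no observations")
    if hyper.p != 1:
        raise ConfigurationError("the null model uses hyper with p=1 (intercept only)")

    y = design.y
    N = y.shape[0]
    n_ones = float(y.sum())
    rng = np.random.default_rng(config.seed)

    prior_mean = float(hyper.b[0])
    prior_prec = float(hyper.B[0, 0])

    def log_post(beta0: float) -> float:
        return (
            n_ones * beta0
            - N * np.logaddexp(0.0, beta0)
            - 0.5 * prior_prec * (beta0 - prior_mean) ** 2
        )

    beta0 = prior_mean
    lp = log_post(beta0)
    log_step = np.log(config.initial_step)
    target = config.target_acceptance

    S = config.n_retained
    beta_draws = np.empty((S, 1))
    theta_draws = np.empty((S, N))
    deviance_draws = np.empty(S)
    total = config.burn_in + config.n_iterations
    accept_sum = 0.0
    accept_iters = 0
    stored = 0

    for t in range(1, total + 1):
        prop = beta0 + np.exp(log_step) * rng.standard_normal()
        lp_prop = log_post(prop)
        accepted = np.log(rng.random()) < lp_prop - lp
        if accepted:
            beta0, lp = prop, lp_prop
        if config.adapt and t <= config.burn_in:
            log_step += (t ** -_RM_DECAY) * (float(accepted) - target)
            log_step = float(np.clip(log_step, -10.0, 5.0))
        if t > config.burn_in:
            accept_sum += float(accepted)
            accept_iters += 1
        if t > config.burn_in and (t - config.burn_in) % config.thin == 0:
            theta = expit(beta0)
            beta_draws[stored, 0] = beta0
            theta_draws[stored] = theta
            deviance_draws[stored] = _deviance_from_theta(y, np.full(N, theta))
            stored += 1

    return PosteriorDraws(
        beta=beta_draws[:stored],
        b=None,
        D=None,
        sigma2=np.ones(stored),
        theta=theta_draws[:stored],
        deviance=deviance_draws[:stored],
        acceptance_rate=accept_sum / max(accept_iters, 1),
    )
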
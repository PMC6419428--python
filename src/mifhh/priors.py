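"""Prior construction for the hierarchical logistic model.

The priors are the conjugate family for the linear-Gaussian hierarchy that
sits behind the latent logits: a normal prior on the fixed effects
``beta ~ N_p(b, B^-1)``, an inverse-gamma prior on the over-dispersion
variance ``sigma^2``, and an inverse-Wishart prior on the level-2 covariance
``D ~ IW(psi, rho)`` with ``rho >= q``.

Background disease prevalence enters through the intercept component of
``b``: a population prevalence ``pi`` maps to a prior intercept mean of
``logit(pi)``, with a wide but finite variance (default 100).  For type 2
diabetes, a US background prevalence of roughly 12% gives the prior mean
``logit(0.12) = -1.99``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from mifhh.exceptions import ConfigurationError

#: default prior variance for non-intercept fixed effects: effectively flat on
#: the logit scale while keeping the conjugate normal update proper
DEFAULT_SLOPE_VARIANCE = 1.0e6

#: default diffuse inverse-gamma hyperparameters for sigma^2
DEFAULT_NU = 0.001
DEFAULT_DELTA = 0.001


def prevalence_to_intercept_mean(prevalence: float) -> float:
    """Map a background disease prevalence to the prior intercept mean, ``logit(p)``.

    >>> round(prevalence_to_intercept_mean(0.12), 2)
    -1.99
    """
    if not 0.0 < prevalence < 1.0:
        raise ConfigurationError(f"prevalence must lie strictly in (0, 1); got {prevalence}")
    return math.log(prevalence / (1.0 - prevalence))


def _check_spd(mat: np.ndarray, name: str) -> None:
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ConfigurationError(f"{name} must be a square matrix; got shape {mat.shape}")
    if not np.allclose(mat, mat.T):
        raise ConfigurationError(f"{name} must be symmetric")
    try:
        np.linalg.cholesky(mat)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError(f"{name} must be positive definite") from exc


@dataclass
class HyperParameters:
    """All prior constants of the model.

    ``b``/``B`` are the mean and *precision* of the fixed-effect prior
    (``B^-1`` is the prior variance).  ``nu``/``delta`` are the shape and
    scale of the inverse-gamma prior on sigma^2 (density proportional to
    ``(s2)^-(nu+1) * exp(-delta/s2)``).  ``psi``/``rho`` are the
    inverse-Wishart scale matrix and degrees of freedom for the level-2
    covariance; both are ``None`` for the non-hierarchical null model.
    """

    b: np.ndarray
    B: np.ndarray
    nu: float = DEFAULT_NU
    delta: float = DEFAULT_DELTA
    psi: Optional[np.ndarray] = None
    rho: Optional[float] = None

    def __post_init__(self) -> None:
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        if self.psi is not None:
            self.psi = np.atleast_2d(np.asarray(self.psi, dtype=float))
        self.validate()

    @property
    def p(self) -> int:
        return self.b.shape[0]

    @property
    def q(self) -> int:
        return 0 if self.psi is None else self.psi.shape[0]

    def validate(self) -> None:
        if self.B.shape != (self.p, self.p):
            raise ConfigurationError(
                f"B must be {self.p}x{self.p} to match b; got shape {self.B.shape}"
            )
        _check_spd(self.B, "B")
        if self.nu <= 0 or self.delta <= 0:
            raise ConfigurationError("nu and delta must be positive")
        if (self.psi is None) != (self.rho is None):
            raise ConfigurationError("psi and rho must be provided together")
        if self.psi is not None:
            _check_spd(self.psi, "psi")
            if self.rho < self.psi.shape[0]:
                raise ConfigurationError(
                    f"rho must be >= q = {self.psi.shape[0]}; got {self.rho}"
                )

    def to_dict(self) -> dict:
        out = {
            "b": self.b.tolist(),
            "B": self.B.tolist(),
            "nu": self.nu,
            "delta": self.delta,
        }
        if self.psi is not None:
            out["psi"] = self.psi.tolist()
            out["rho"] = self.rho
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "HyperParameters":
        return cls(
            b=np.asarray(data["b"], float),
            B=np.asarray(data["B"], float),
            nu=float(data.get("nu", DEFAULT_NU)),
            delta=float(data.get("delta", DEFAULT_DELTA)),
            psi=None if data.get("psi") is None else np.asarray(data["psi"], float),
            rho=None if data.get("rho") is None else float(data["rho"]),
        )


def default_hyperparameters(
    p: int,
    q: int,
    prevalence: float = 0.12,
    intercept_variance: float = 100.0,
    slope_variance: float = DEFAULT_SLOPE_VARIANCE,
    nu: float = DEFAULT_NU,
    delta: float = DEFAULT_DELTA,
) -> HyperParameters:
    """Default priors: prevalence-informed intercept, vague everything else.

    The fixed-effect prior mean is ``(logit(prevalence), 0, ..., 0)`` with
    independent prior variances ``intercept_variance`` (default 100) for the
    intercept and ``slope_variance`` for the remaining components.  The
    level-2 covariance prior uses ``rho = q`` and ``psi = q * I_q``; with
    ``q = 0`` (null model) no level-2 prior is constructed.
    """
    if p < 1:
        raise ConfigurationError(f"p must be >= 1; got {p}")
    if q < 0:
        raise ConfigurationError(f"q must be >= 0; got {q}")
    if intercept_variance <= 0 or slope_variance <= 0:
        raise ConfigurationError("prior variances must be positive")
    b = np.zeros(p)
    b[0] = prevalence_to_intercept_mean(prevalence)
    precisions = np.full(p, 1.0 / slope_variance)
    precisions[0] = 1.0 / intercept_variance
    B = np.diag(precisions)
    if q == 0:
        return HyperParameters(b=b, B=B, nu=nu, delta=delta)
    return HyperParameters(
        b=b, B=B, nu=nu, delta=delta, psi=float(q) * np.eye(q), rho=float(q)
    )
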
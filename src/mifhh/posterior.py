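"""Posterior-predictive probabilities, individual risk aggregation, and DIC.

The sampler works at the dyad level; risk for a family member is obtained by
averaging the posterior-predictive dyad probabilities over the informants
who reported on that member, with equal weight per report.  Credible bounds
for the aggregate come from averaging the theta draws across the member's
dyads *within* each retained draw and taking equal-tailed quantiles of that
per-draw average.

Model comparison uses the deviance information criterion in the
"mean deviance plus half its variance" form: the variance term is
proportional to the effective number of parameters.  Lower DIC is preferred.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from mifhh.data import DesignMatrices
from mifhh.exceptions import DegenerateInputError
from mifhh.sampler import PosteriorDraws

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RiskEstimate:
    """Aggregated posterior disease probability for one family member."""

    member_id: str
    family_id: str
    n_reports: int
    risk: float
    ci_low: float
    ci_high: float


@dataclass
class ModelFitSummary:
    """Machine-readable fit/accuracy record for one fitted model (Table-1 analogue)."""

    model: str
    cluster_level: str
    n_parameters: int
    dic: float
    mean_deviance: float
    half_var_deviance: float
    auc_dyadic: Optional[float] = None
    auc_individual: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)


def compute_dic(deviance_draws: np.ndarray) -> tuple[float, float, float]:
    """DIC = mean posterior deviance + half its sample variance (ddof=1).

    Returns ``(dic, mean_deviance, half_var_deviance)``.
    """
    dev = np.asarray(deviance_draws, float)
    if dev.ndim != 1 or dev.size < 2:
        raise DegenerateInputError("DIC needs at least 2 deviance draws")
    mean_dev = float(dev.mean())
    half_var = 0.5 * float(dev.var(ddof=1))
    return mean_dev + half_var, mean_dev, half_var


def dyad_theta_means(draws: PosteriorDraws) -> np.ndarray:
    """Posterior-mean dyad probability: element-wise average of theta over draws."""
    if draws.theta.size == 0:
        raise DegenerateInputError("no theta draws")
    return draws.theta.mean(axis=0)


def dyad_marginal_scores(draws: PosteriorDraws, design: DesignMatrices) -> np.ndarray:
    """Posterior-mean dyad probability from the cluster-level predictor only.

    Averages ``invlogit(X beta + W b)`` over draws, *excluding* the
    per-observation over-dispersion term.  ``theta`` conditions on each
    row's own eps draw, which partially memorizes the observed report and
    inflates within-sample classification; this marginal score is the honest
    dyadic classifier and is what model-comparison AUCs use.
    """
    from scipy.special import expit

    S = draws.S
    total = np.zeros(design.N)
    # chunk over draws to keep the (chunk, N) intermediates small
    for start in range(0, S, 1000):
        beta = draws.beta[start : start + 1000]
        eta = beta @ design.X.T  # (chunk, N)
        if draws.b is not None:
            b_rows = draws.b[start : start + 1000][:, design.g, :]  # (chunk, N, q)
            eta = eta + np.einsum("nk,snk->sn", design.W, b_rows)
        total += expit(eta).sum(axis=0)
    return total / S


def aggregate_individual(
    draws: PosteriorDraws,
    dyad_index: pd.DataFrame,
    ci_level: float = 0.95,
) -> list[RiskEstimate]:
    """Average dyad posterior probabilities to per-member risk estimates.

    Each report carries equal weight.  Because finite sums commute, the
    member's risk equals both the mean over its rows of the per-row posterior
    means and the posterior mean of the per-draw row average; the credible
    bounds use the latter ordering (average across rows within a draw, then
    quantiles over draws).
    """
    theta = draws.theta
    if theta.shape[1] != len(dyad_index):
        raise ValueError(
            f"theta has {theta.shape[1]} columns but dyad_index has {len(dyad_index)} rows"
        )
    alpha = (1.0 - ci_level) / 2.0
    estimates: list[RiskEstimate] = []
    grouped = dyad_index.reset_index(drop=True).groupby("member_id", sort=True)
    for member_id, rows in grouped:
        idx = rows.index.to_numpy()
        if idx.size == 0:  # pragma: no cover - groupby never yields empty groups
            logger.info("member %s has no reports; excluded", member_id)
            continue
        per_draw = theta[:, idx].mean(axis=1)
        lo, hi = np.quantile(per_draw, [alpha, 1.0 - alpha])
        estimates.append(
            RiskEstimate(
                member_id=str(member_id),
                family_id=str(rows["family_id"].iloc[0]),
                n_reports=int(idx.size),
                risk=float(per_draw.mean()),
                ci_low=float(lo),
                ci_high=float(hi),
            )
        )
    return estimates


def risk_table(estimates: Sequence[RiskEstimate]) -> pd.DataFrame:
    """Risk estimates as a DataFrame ready for delimited-text export."""
    return pd.DataFrame(
        [
            {
                "member_id": e.member_id,
                "family_id": e.family_id,
                "n_reports": e.n_reports,
                "risk": e.risk,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
            }
            for e in estimates
        ]
    )


def count_parameters(design: DesignMatrices, estimate_sigma2: Optional[bool] = None) -> int:
    """Explicit parameter count: p + C*q + q(q+1)/2 distinct D entries + sigma^2 flag.

    This is the package's own counting convention for reporting model size;
    other conventions (e.g. effective parameter counts) will differ.
    """
    if estimate_sigma2 is None:
        estimate_sigma2 = design.spec.estimate_sigma2
    q = design.q
    return design.p + design.C * q + q * (q + 1) // 2 + (1 if estimate_sigma2 else 0)


def summarize_fit(
    draws: PosteriorDraws,
    design: DesignMatrices,
    auc_dyadic: Optional[float] = None,
    auc_individual: Optional[float] = None,
) -> ModelFitSummary:
    """Bundle DIC, parameter count and optional AUCs for one fitted model."""
    dic, mean_dev, half_var = compute_dic(draws.deviance)
    return ModelFitSummary(
        model=design.spec.name,
        cluster_level=design.spec.cluster_level,
        n_parameters=count_parameters(design),
        dic=dic,
        mean_deviance=mean_dev,
        half_var_deviance=half_var,
        auc_dyadic=auc_dyadic,
        auc_individual=auc_individual,
    )
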
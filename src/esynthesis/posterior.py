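"""Posterior probability of dose-responsiveness and the trend test.

Bayes' theorem over the binary hypothesis space {DR, not-DR}:

    P(DR | data) = P(data | DR) P(DR) / P(data)
    P(data) = P(data | DR) P(DR) + P(data | not-DR) (1 - P(DR))

where P(data | DR) is the grouped binomial likelihood under the selected
dose-response model and P(data | not-DR) the flat-model likelihood.  All
arithmetic runs in log space via log-sum-exp; likelihood ratios of order
exp(7) (as in the worked example) would otherwise be harmless, but flat
tables with cohort-sized groups produce likelihoods near 1e-300.

The "MCP" signal-detection step is a Cochran-Armitage trend test on the
grouped binomial table, using the actual dose values as scores, with a
two-sided p-value from the standard-normal reference distribution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .data import DoseResponseTable
from .errors import DomainError, InsufficientDataError, ValidationError
from .likelihood import LikelihoodResult, log_likelihood, null_likelihood
from .models import FittedModel, SelectionResult, fit, select_model

__all__ = [
    "PosteriorResult",
    "TrendTestResult",
    "posterior_dr",
    "assess_dose_responsiveness",
    "prior_sweep",
    "trend_test",
]

#: minimum number of dose groups before dose-responsiveness can be
#: assessed: a dose-response pattern requires >= 3 data points
MIN_GROUPS_FOR_DR = 3


@dataclass(frozen=True)
class PosteriorResult:
    """Posterior P(DR | data) with the evidence that produced it."""

    prior: float
    loglik_dr: float
    loglik_null: float
    log_marginal: float
    posterior: float
    dr_model_tag: str = "DR"
    # reserved for study-quality modulator adjustment (not yet implemented)
    modulators: None = None

    @property
    def posterior_display(self) -> float:
        """Posterior rounded to 2 decimals (the report's display convention)."""
        return round(self.posterior, 2)

    @property
    def log_bayes_factor(self) -> float:
        return self.loglik_dr - self.loglik_null

    def to_dict(self) -> dict:
        return {
            "prior": self.prior,
            "loglik_dr": self.loglik_dr,
            "loglik_null": self.loglik_null,
            "log_marginal": self.log_marginal,
            "log_bayes_factor": self.log_bayes_factor,
            "posterior": self.posterior,
            "posterior_display": self.posterior_display,
            "dr_model": self.dr_model_tag,
        }


def posterior_dr(
    loglik_dr: float, loglik_null: float, prior: float, dr_model_tag: str = "DR"
) -> PosteriorResult:
    """Posterior probability of dose-responsiveness from two log-likelihoods.

    Computed in log space:  posterior = exp(ln prior + loglik_dr - ln marginal)
    with ln marginal = logsumexp(ln prior + loglik_dr, ln(1-prior) + loglik_null).
    Degenerate priors short-circuit: prior 0 gives posterior 0, prior 1 gives 1.
    """
    if not 0.0 <= prior <= 1.0:
        raise DomainError(f"prior must lie in [0, 1], got {prior}")
    if math.isinf(loglik_dr) and math.isinf(loglik_null):
        raise DomainError("both hypotheses assign zero probability to the data")
    if prior == 0.0:
        return PosteriorResult(prior, loglik_dr, loglik_null, loglik_null, 0.0, dr_model_tag)
    if prior == 1.0:
        return PosteriorResult(prior, loglik_dr, loglik_null, loglik_dr, 1.0, dr_model_tag)
    log_terms = np.array([math.log(prior) + loglik_dr, math.log1p(-prior) + loglik_null])
    log_marginal = float(logsumexp(log_terms))
    posterior = float(math.exp(log_terms[0] - log_marginal))
    return PosteriorResult(
        prior=prior,
        loglik_dr=loglik_dr,
        loglik_null=loglik_null,
        log_marginal=log_marginal,
        posterior=min(posterior, 1.0),
        dr_model_tag=dr_model_tag,
    )


@dataclass(frozen=True)
class TrendTestResult:
    """Cochran-Armitage trend statistic and two-sided normal p-value."""

    statistic: float
    p_value: float
    direction: str  # "increasing" or "decreasing"

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "direction": self.direction,
        }


def trend_test(table: DoseResponseTable) -> TrendTestResult:
    """Cochran-Armitage test for trend in grouped binomial proportions.

    Scores are the table's actual dose values.  The statistic is

        Z = sum_i (y_i - n_i p) d_i / sqrt( p (1-p) S_dd )

    with pooled rate p = sum(y)/sum(n) and the score sum of squares
    S_dd = sum n_i d_i^2 - (sum n_i d_i)^2 / N.  Degenerate tables
    (no events, all events, or constant rates) return Z = 0, p = 1.
    """
    if len(table) < 2:
        raise InsufficientDataError("trend test needs at least two dose groups")
    d, n, y = table.doses, table.sizes.astype(float), table.events.astype(float)
    total_n, total_y = n.sum(), y.sum()
    p_pool = total_y / total_n
    s_dd = float(np.sum(n * d**2) - np.sum(n * d) ** 2 / total_n)
    numerator = float(np.sum((y - n * p_pool) * d))
    denom_sq = p_pool * (1.0 - p_pool) * s_dd
    # degenerate tables: no events, all events, or perfectly flat rates
    if denom_sq <= 0 or numerator == 0.0:
        return TrendTestResult(0.0, 1.0, "increasing")
    z = numerator / math.sqrt(denom_sq)
    p_value = float(2.0 * stats.norm.sf(abs(z)))
    return TrendTestResult(z, min(p_value, 1.0), "increasing" if z >= 0 else "decreasing")


@dataclass(frozen=True)
class DoseResponseAssessment:
    """Full evidence report for one table: fits, selection, trend, posterior."""

    posterior_result: PosteriorResult
    selection: SelectionResult
    null_k: float
    null_result: LikelihoodResult
    dr_result: LikelihoodResult
    trend: TrendTestResult

    def to_dict(self) -> dict:
        return {
            "posterior": self.posterior_result.to_dict(),
            "dr_model": self.dr_result.to_dict(),
            "null_model": {"k": self.null_k, **self.null_result.to_dict()},
            "trend_test": self.trend.to_dict(),
            "selection_criterion": self.selection.criterion,
            "ranking": self.selection.ranking_records(),
        }

    def to_json(self, path: str | Path | None = None, **kwargs) -> str:
        payload = json.dumps(self.to_dict(), **kwargs)
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload


DEFAULT_FAMILIES = ("constant", "linear", "quadratic", "cubic", "exponential")


def assess_dose_responsiveness(
    table: DoseResponseTable,
    families: Sequence[str] = DEFAULT_FAMILIES,
    prior: float = 0.5,
    criterion: str = "aic",
    dr_model: str | FittedModel | None = None,
    null_estimator: str = "least_squares",
) -> DoseResponseAssessment:
    """End-to-end assessment of dose-responsiveness for one table.

    Fits the requested candidate families (the flat/constant family is
    never a DR candidate; it defines the null), selects the DR model by
    the given criterion, computes the flat-model null likelihood, and
    combines both with the prior via Bayes' theorem.

    ``dr_model`` can force the DR model: a family name (use its fit) or
    an already-fitted :class:`FittedModel` (use its exact parameters,
    e.g. externally published ones).
    """
    if len(table) < MIN_GROUPS_FOR_DR:
        raise InsufficientDataError(
            f"dose-responsiveness assessment requires at least {MIN_GROUPS_FOR_DR} "
            f"dose groups (a dose-response pattern needs >= 3 points); got {len(table)}"
        )
    candidate_names = [f for f in families if f != "constant"]
    if not candidate_names and not isinstance(dr_model, FittedModel):
        raise ValidationError("no non-constant candidate families requested")
    fits = [fit(name, table) for name in candidate_names]
    if isinstance(dr_model, FittedModel):
        ranked = select_model(fits + [dr_model], criterion=criterion) if fits else select_model(
            [dr_model], criterion=criterion
        )
        chosen = dr_model
    else:
        ranked = select_model(fits, criterion=criterion)
        if dr_model is None:
            chosen = ranked.best
        else:
            by_name = {m.family.name: m for m in fits}
            if dr_model not in by_name:
                raise ValidationError(f"dr_model {dr_model!r} not among fitted families")
            chosen = by_name[dr_model]

    dr_result = log_likelihood(
        table, chosen.predictor(), model_tag=chosen.family.name, theta=chosen.theta
    )
    k, null_result = null_likelihood(table, estimator=null_estimator)
    post = posterior_dr(
        dr_result.loglik, null_result.loglik, prior, dr_model_tag=chosen.family.name
    )
    return DoseResponseAssessment(
        posterior_result=post,
        selection=ranked,
        null_k=k,
        null_result=null_result,
        dr_result=dr_result,
        trend=trend_test(table),
    )


def prior_sweep(
    loglik_dr_by_model: Mapping[str, float],
    loglik_null: float,
    grid: Sequence[float],
) -> dict[str, np.ndarray]:
    """Posterior-versus-prior sensitivity curves, one per DR model.

    Each curve passes through (0, 0) and (1, 1) and is monotone
    non-decreasing in the prior.
    """
    grid_arr = np.asarray(grid, dtype=float)
    if grid_arr.size == 0:
        raise ValidationError("prior grid is empty")
    if np.any(grid_arr < 0) or np.any(grid_arr > 1):
        raise DomainError("prior grid values must lie in [0, 1]")
    curves: dict[str, np.ndarray] = {}
    for tag, loglik_dr in loglik_dr_by_model.items():
        curves[tag] = np.array(
            [posterior_dr(loglik_dr, loglik_null, float(p), tag).posterior for p in grid_arr]
        )
    return curves
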
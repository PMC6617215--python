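"""Grouped binomial log-likelihood and the flat-model null.

The log-likelihood of a grouped dose-response table under a per-dose
event probability f is

    ln P(data | f) = sum_i [ ln C(n_i, y_i) + y_i ln f(d_i)
                             + (n_i - y_i) ln(1 - f(d_i)) ]

with the 0 * ln 0 = 0 convention for degenerate groups.  All arithmetic
stays in natural-log space; the raw probability (typically ~1e-12 for
cohort-sized tables) is only exponentiated for display.

The flat ("no dose-response") null sets f identically to the constant
k~ that minimises the least-squares distance to the observed rates,
which is their arithmetic mean <r>.  Note that k~ generally differs from
the pooled binomial MLE sum(y)/sum(n); the least-squares value defines
the null here, and the pooled MLE is available via
:func:`null_likelihood`'s ``estimator`` switch (or :func:`pooled_mle`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .data import DoseResponseTable
from .errors import DomainError, ValidationError

__all__ = [
    "LikelihoodResult",
    "log_binomial_coefficient",
    "log_likelihood",
    "null_likelihood",
    "pooled_mle",
]


def log_binomial_coefficient(n: int, y: int) -> float:
    """ln C(n, y) via log-gamma, stable for n up to 1e9 and beyond."""
    if not 0 <= y <= n:
        raise DomainError(f"need 0 <= y <= n, got y={y}, n={n}")
    return float(gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1))


@dataclass(frozen=True)
class LikelihoodResult:
    """Log-likelihood of a table under a model, with per-group terms.

    ``loglik`` is the sum of ``per_group``; each per-group value is the
    log of a binomial probability mass and hence <= 0.  ``impossible``
    marks a flagged -inf result (an f of 0 or 1 contradicted by the
    observed counts); it is carried rather than raised so that model
    comparison can proceed.
    """

    loglik: float
    per_group: tuple[float, ...]
    model_tag: str
    theta_used: tuple[float, ...] = ()

    @property
    def impossible(self) -> bool:
        return math.isinf(self.loglik) and self.loglik < 0

    @property
    def likelihood(self) -> float:
        """P(data | model) = exp(loglik); display-scale only."""
        return math.exp(self.loglik) if not self.impossible else 0.0

    def to_dict(self) -> dict:
        return {
            "model": self.model_tag,
            "theta": list(self.theta_used),
            "loglik": self.loglik,
            "likelihood": self.likelihood,
            "per_group": list(self.per_group),
            "impossible": self.impossible,
        }

    def to_json(self, path: str | Path | None = None, **kwargs) -> str:
        payload = json.dumps(self.to_dict(), **kwargs)
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload


def _group_loglik(n: int, y: int, f: float) -> float:
    if not 0.0 <= f <= 1.0:
        raise DomainError(f"event probability {f} outside [0, 1]")
    # impossible-data cases: probability mass is exactly zero
    if (f == 0.0 and y > 0) or (f == 1.0 and y < n):
        return -math.inf
    term = log_binomial_coefficient(n, y)
    if y > 0:  # 0 * ln 0 convention handled by skipping the term
        term += y * math.log(f)
    if y < n:
        term += (n - y) * math.log1p(-f)
    return term


def log_likelihood(
    table: DoseResponseTable,
    prob_at_dose: Callable[[float], float] | Mapping[float, float] | Sequence[float],
    model_tag: str = "model",
    theta: Sequence[float] = (),
) -> LikelihoodResult:
    """Grouped binomial log-likelihood of a table under a dose->probability map.

    ``prob_at_dose`` may be a callable d -> f(d), a mapping keyed by dose,
    or a sequence aligned with the table's groups.
    """
    if callable(prob_at_dose):
        probs = [float(prob_at_dose(g.dose)) for g in table.groups]
    elif isinstance(prob_at_dose, Mapping):
        try:
            probs = [float(prob_at_dose[g.dose]) for g in table.groups]
        except KeyError as exc:
            raise ValidationError(f"no probability supplied for dose {exc}") from exc
    else:
        probs = [float(p) for p in prob_at_dose]
        if len(probs) != len(table):
            raise ValidationError(
                f"got {len(probs)} probabilities for {len(table)} dose groups"
            )
    per_group = tuple(
        _group_loglik(int(g.n), int(g.events), f) for g, f in zip(table.groups, probs)
    )
    return LikelihoodResult(
        loglik=float(sum(per_group)),
        per_group=per_group,
        model_tag=model_tag,
        theta_used=tuple(float(t) for t in theta),
    )


def pooled_mle(table: DoseResponseTable) -> float:
    """Pooled binomial MLE sum(y_i) / sum(n_i) for a constant rate."""
    return float(table.events.sum() / table.sizes.sum())


def null_likelihood(
    table: DoseResponseTable, estimator: str = "least_squares"
) -> tuple[float, LikelihoodResult]:
    """Likelihood of the data under the flat (no dose-response) model.

    Returns ``(k, result)`` where ``k`` is the constant event probability:
    the arithmetic mean of observed rates under the default
    ``least_squares`` estimator, or sum(y)/sum(n) under ``pooled_mle``.
    """
    if estimator == "least_squares":
        k = float(np.mean(table.rates))
    elif estimator == "pooled_mle":
        k = pooled_mle(table)
    else:
        raise ValidationError(
            f"unknown null estimator {estimator!r}; use 'least_squares' or 'pooled_mle'"
        )
    result = log_likelihood(
        table, lambda _d: k, model_tag="flat-null", theta=(k,)
    )
    return k, result
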
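"""Candidate dose-response model families and least-squares fitting.

Each family gives a functional form f(d | theta) for the event probability
as a function of dose:

========== =================================== ==========================
family      f(d | theta)                        theta
========== =================================== ==========================
constant    k                                   (k,)
linear      beta*d + alpha                      (alpha, beta)
quadratic   gamma*d^2 + beta*d + alpha          (alpha, beta, gamma)
cubic       delta*d^3 + ... + alpha             (alpha, beta, gamma, delta)
exponential alpha*exp(beta*d)                   (alpha, beta)
emax        E0 + Emax*d / (ED50 + d)            (E0, Emax, ED50)
sigmoid_emax E0 + Emax*d^h / (ED50^h + d^h)     (E0, Emax, ED50, h)
========== =================================== ==========================

Fitting minimises the unweighted sum of squared residuals on the observed
group rates r_i (size-weighted least squares is available as an option).
Because f is interpreted downstream as a binomial success probability, a
fitted curve that leaves [0, 1] anywhere on the data's dose range is
rejected with :class:`~esynthesis.errors.DomainError` rather than clamped.

Fit criteria (AIC, BIC, R^2, adjusted R^2) use the full Gaussian
log-likelihood convention with the residual variance counted as a free
parameter, so the effective parameter count is k = p + 1.  Under this
convention BIC - AIC = k (ln n - 2) identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .data import DoseResponseTable
from .errors import DomainError, FitError, InsufficientDataError, ValidationError

__all__ = [
    "ModelFamily",
    "FittedModel",
    "SelectionResult",
    "FAMILIES",
    "fit",
    "predict",
    "fit_criteria",
    "select_model",
]

# rss below this is treated as an exact interpolation ("perfect fit"):
# Gaussian information criteria are undefined there and reported as NaN
# with the perfect_fit flag set instead of -inf.
_PERFECT_FIT_RSS = 1e-300


@dataclass(frozen=True)
class ModelFamily:
    """A named dose-response functional form f(d | theta)."""

    name: str
    parameter_names: tuple[str, ...]
    predictor: Callable[[np.ndarray, np.ndarray], np.ndarray]

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    def __call__(self, dose, theta):
        return self.predictor(np.asarray(dose, dtype=float), np.asarray(theta, dtype=float))


def _poly_predictor(degree: int):
    # theta ordered low-to-high: (alpha, beta, gamma, delta)
    def f(d, theta):
        return sum(theta[j] * d**j for j in range(degree + 1))

    return f


def _exponential(d, theta):
    return theta[0] * np.exp(theta[1] * d)


def _emax(d, theta):
    e0, emax, ed50 = theta
    return e0 + emax * d / (ed50 + d)


def _sigmoid_emax(d, theta):
    e0, emax, ed50, h = theta
    d = np.asarray(d, dtype=float)
    # d = 0 maps to 0 regardless of the Hill exponent (avoids 0**h warnings)
    dh = np.where(d > 0, np.power(np.maximum(d, 1e-300), h), 0.0)
    return e0 + emax * dh / (ed50**h + dh)


FAMILIES: dict[str, ModelFamily] = {
    "constant": ModelFamily("constant", ("k",), _poly_predictor(0)),
    "linear": ModelFamily("linear", ("alpha", "beta"), _poly_predictor(1)),
    "quadratic": ModelFamily("quadratic", ("alpha", "beta", "gamma"), _poly_predictor(2)),
    "cubic": ModelFamily("cubic", ("alpha", "beta", "gamma", "delta"), _poly_predictor(3)),
    "exponential": ModelFamily("exponential", ("alpha", "beta"), _exponential),
    "emax": ModelFamily("emax", ("E0", "Emax", "ED50"), _emax),
    "sigmoid_emax": ModelFamily("sigmoid_emax", ("E0", "Emax", "ED50", "h"), _sigmoid_emax),
}

_POLY_DEGREE = {"constant": 0, "linear": 1, "quadratic": 2, "cubic": 3}


def resolve_family(family: str | ModelFamily) -> ModelFamily:
    if isinstance(family, ModelFamily):
        return family
    try:
        return FAMILIES[family]
    except KeyError:
        raise ValidationError(
            f"unknown model family {family!r}; available: {sorted(FAMILIES)}"
        ) from None


@dataclass(frozen=True)
class FittedModel:
    """A family with fitted parameters, residuals and fit criteria."""

    family: ModelFamily
    theta: tuple[float, ...]
    rss: float
    n_fit: int
    criteria: dict[str, float]
    doses: tuple[float, ...] = ()
    rates: tuple[float, ...] = ()

    @property
    def perfect_fit(self) -> bool:
        return self.rss < _PERFECT_FIT_RSS

    def predict(self, dose) -> np.ndarray | float:
        return predict(self, dose)

    def predictor(self) -> Callable[[float], float]:
        """The fitted curve d -> f(d | theta) as a plain callable."""
        theta = np.asarray(self.theta)
        return lambda d: float(self.family(d, theta))

    def to_dict(self) -> dict:
        return {
            "family": self.family.name,
            "parameter_names": list(self.family.parameter_names),
            "theta": list(self.theta),
            "rss": self.rss,
            "n_fit": self.n_fit,
            "criteria": dict(self.criteria),
            "perfect_fit": self.perfect_fit,
        }

    def to_json(self, path: str | Path | None = None, **kwargs) -> str:
        payload = json.dumps(self.to_dict(), **kwargs)
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload


def predict(model: FittedModel, dose) -> np.ndarray | float:
    """Evaluate the fitted curve at one or more doses.

    Raises :class:`DomainError` if any predicted value leaves [0, 1],
    because predictions feed the grouped binomial likelihood as success
    probabilities and must never be silently clamped.
    """
    dose_arr = np.asarray(dose, dtype=float)
    if np.any(dose_arr < 0):
        raise DomainError("doses must be non-negative")
    values = model.family(dose_arr, np.asarray(model.theta))
    values_arr = np.atleast_1d(np.asarray(values, dtype=float))
    if np.any(values_arr < 0) or np.any(values_arr > 1):
        bad = values_arr[(values_arr < 0) | (values_arr > 1)]
        raise DomainError(
            f"{model.family.name} prediction {bad[0]:.6g} outside [0, 1]: "
            "not a valid event probability"
        )
    return values if np.ndim(dose) else float(values_arr[0])


def fit_criteria(rss: float, n: int, p: int, tss: float) -> dict[str, float]:
    """Gaussian-ML information criteria and coefficients of determination.

    Uses k = p + 1 effective parameters (the residual variance counts):
    AIC = 2k + n ln(2 pi rss / n) + n, BIC likewise with k ln n.
    An rss of exactly zero (interpolating fit) yields NaN criteria with
    r2 = 1 rather than -inf sentinels.
    """
    k = p + 1
    if rss < _PERFECT_FIT_RSS:
        return {"aic": math.nan, "bic": math.nan, "r2": 1.0, "adj_r2": 1.0}
    gauss = n * math.log(2 * math.pi * rss / n) + n
    r2 = 1.0 - rss / tss if tss > 0 else math.nan
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p) if (tss > 0 and n > p) else math.nan
    return {"aic": 2 * k + gauss, "bic": k * math.log(n) + gauss, "r2": r2, "adj_r2": adj_r2}


def _exponential_start(d: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Log-linear regression on the positive rates: ln r ~ ln alpha + beta d."""
    mask = r > 0
    if mask.sum() >= 2:
        slope, intercept = np.polyfit(d[mask], np.log(r[mask]), 1)
        return np.array([math.exp(intercept), slope])
    return np.array([max(r.mean(), 1e-6), 0.0])


def _emax_start(d: np.ndarray, r: np.ndarray) -> np.ndarray:
    span = r.max() - r.min()
    ed50 = np.median(d[d > 0]) if np.any(d > 0) else 1.0
    return np.array([r[np.argmin(d)], span if span > 0 else 1e-6, ed50])


def _sigmoid_emax_start(d: np.ndarray, r: np.ndarray) -> np.ndarray:
    return np.append(_emax_start(d, r), 1.0)


_NONLINEAR_START = {
    "exponential": _exponential_start,
    "emax": _emax_start,
    "sigmoid_emax": _sigmoid_emax_start,
}


def _check_probability_range(family: ModelFamily, theta: np.ndarray, d: np.ndarray) -> None:
    # evaluate on a dense grid over the data's dose range, not just the
    # design points: a quadratic can dip below zero between doses
    grid = np.linspace(d.min(), d.max(), 201)
    values = family(grid, theta)
    if np.any(values < -1e-12) or np.any(values > 1 + 1e-12):
        raise DomainError(
            f"fitted {family.name} curve leaves [0, 1] on the dose range "
            f"[{d.min():g}, {d.max():g}]; it cannot serve as an event probability"
        )


def fit(
    family: str | ModelFamily,
    table: DoseResponseTable,
    subset: Sequence[int] | None = None,
    weighted: bool = False,
) -> FittedModel:
    """Least-squares fit of a family to a table's observed rates.

    Parameters
    ----------
    family
        Family name or :class:`ModelFamily`.
    table
        Grouped dose-response data.
    subset
        Optional 0-based group indices restricting the fit.
    weighted
        Weight squared residuals by group size n_i (off by default; the
        flat-model derivation uses unweighted least squares on rates).
    """
    family = resolve_family(family)
    if subset is not None:
        table = table.subset(subset)
    d, r = table.doses, table.rates
    n_pts, p = len(d), family.n_parameters
    if n_pts < p:
        raise InsufficientDataError(
            f"{family.name} has {p} parameters but only {n_pts} dose groups are available"
        )
    w = table.sizes.astype(float) if weighted else np.ones(n_pts)

    if family.name in _POLY_DEGREE:
        degree = _POLY_DEGREE[family.name]
        design = np.vander(d, degree + 1, increasing=True)
        sw = np.sqrt(w)
        theta, *_ = np.linalg.lstsq(design * sw[:, None], r * sw, rcond=None)
    else:
        start = _NONLINEAR_START[family.name](d, r)
        sw = np.sqrt(w)

        def residuals(theta):
            return (family(d, theta) - r) * sw

        # ED50 and the Hill exponent must stay positive for the predictor
        # to be defined; the exponential family is unconstrained
        bounds = {
            "emax": ([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            "sigmoid_emax": ([-np.inf, -np.inf, 1e-9, 1e-3], [np.inf, np.inf, np.inf, 100.0]),
        }.get(family.name, (-np.inf, np.inf))
        method = "lm" if family.name == "exponential" else "trf"
        result = optimize.least_squares(
            residuals,
            start,
            method=method,
            bounds=bounds,
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=10_000,
        )
        if not result.success:
            raise FitError(
                f"{family.name} fit did not converge: {result.message}",
                diagnostics={"status": result.status, "nfev": result.nfev, "start": list(start)},
            )
        theta = result.x

    _check_probability_range(family, theta, d)
    resid = family(d, theta) - r
    rss = float(np.sum(w * resid**2))
    mean_r = float(np.average(r, weights=w))
    tss = float(np.sum(w * (r - mean_r) ** 2))
    return FittedModel(
        family=family,
        theta=tuple(float(t) for t in theta),
        rss=rss,
        n_fit=n_pts,
        criteria=fit_criteria(rss, n_pts, p, tss),
        doses=tuple(d),
        rates=tuple(r),
    )


@dataclass(frozen=True)
class SelectionResult:
    """Best fit under a criterion plus the full ranked table."""

    best: FittedModel
    criterion: str
    ranking: tuple[FittedModel, ...]

    def ranking_records(self) -> list[dict]:
        return [
            {
                "rank": i + 1,
                "family": m.family.name,
                "theta": list(m.theta),
                "rss": m.rss,
                **m.criteria,
            }
            for i, m in enumerate(self.ranking)
        ]


#: criteria where larger values indicate better fit
_HIGHER_IS_BETTER = {"r2", "adj_r2"}


def select_model(
    fits: Sequence[FittedModel], criterion: str = "aic"
) -> SelectionResult:
    """Rank fitted models under a criterion and return the best.

    Default criterion is AIC (lower is better); ``r2``/``adj_r2`` rank
    higher-is-better.  Ties break toward fewer parameters, then family
    name order.  Perfect fits (NaN information criteria) sort last under
    AIC/BIC since they carry no comparable penalised likelihood.
    """
    fits = list(fits)
    if not fits:
        raise ValidationError("select_model needs at least one fitted model")
    if criterion not in {"aic", "bic", "r2", "adj_r2", "rss"}:
        raise ValidationError(f"unknown selection criterion {criterion!r}")
    sign = -1.0 if criterion in _HIGHER_IS_BETTER else 1.0

    def key(m: FittedModel):
        value = m.rss if criterion == "rss" else m.criteria[criterion]
        primary = math.inf if math.isnan(value) else sign * value
        return (primary, m.family.n_parameters, m.family.name)

    ranked = tuple(sorted(fits, key=key))
    return SelectionResult(best=ranked[0], criterion=criterion, ranking=ranked)
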
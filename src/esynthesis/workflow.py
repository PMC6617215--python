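"""Pipeline orchestration and the turnkey paracetamol-asthma reproduction.

:func:`reproduce_paracetamol_example` reruns the published worked example
on the built-in cohort table: the flat-model likelihood with the constant
rate set to the mean observed rate, the exponential-model likelihood at
the published parameters theta = (alpha, beta) = (1.01266e-3, 4.17805e-3),
the predicted per-dose rates, the posterior probability of
dose-responsiveness at the equipoise prior 0.5, and posterior-versus-prior
sensitivity curves for the exponential against the cubic and linear
alternatives.  The emitted comparison table lists each computed quantity
next to its published reference value with the absolute deviation.

One documented discrepancy is flagged rather than forced to agree: the
published predicted rate at the top dose is 1.46e-3, while direct
evaluation of alpha*exp(beta*86.67) with the published parameters gives
1.4545e-3, which rounds to 1.45e-3.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .data import DoseResponseTable, paracetamol_asthma_table
from .errors import ValidationError
from .likelihood import log_likelihood, null_likelihood
from .models import FAMILIES, FittedModel, fit, fit_criteria
from .posterior import assess_dose_responsiveness, posterior_dr, prior_sweep, trend_test

__all__ = ["ExampleReport", "PUBLISHED_EXPONENTIAL_THETA", "reproduce_paracetamol_example", "run_pipeline"]

#: published exponential parameters (alpha, beta) for the worked example
PUBLISHED_EXPONENTIAL_THETA: tuple[float, float] = (1.01266e-3, 4.17805e-3)

#: published reference values the reproduction is compared against
_REFERENCE = {
    "k_tilde": 1.195e-3,
    "loglik_null": -25.903,
    "lik_null": 5.63e-12,
    "loglik_exp": -18.6327,
    "lik_exp": 8.09e-9,
    "posterior_at_half_rounded": 1.00,
    "predicted_rates": (1.01e-3, 1.06e-3, 1.16e-3, 1.30e-3, 1.46e-3),
}

_TOP_DOSE_NOTE = (
    "published value 1.46e-3 differs from direct evaluation "
    "alpha*exp(beta*86.67) = 1.4545e-3 (rounds to 1.45e-3); documented "
    "discrepancy, reported rather than matched"
)


@dataclass(frozen=True)
class ExampleReport:
    """Computed quantities of the worked example plus the comparison table."""

    k_tilde: float
    loglik_null: float
    lik_null: float
    loglik_exp: float
    lik_exp: float
    predicted_rates: tuple[float, ...]
    posterior_at_half: float
    sweep_curves: dict[str, np.ndarray]
    sweep_grid: tuple[float, ...]
    comparison: tuple[dict, ...]
    theta: tuple[float, float]
    theta_source: str

    @property
    def posterior_at_half_rounded(self) -> float:
        return round(self.posterior_at_half, 2)

    def to_dict(self) -> dict:
        return {
            "theta_source": self.theta_source,
            "theta": list(self.theta),
            "k_tilde": self.k_tilde,
            "loglik_null": self.loglik_null,
            "lik_null": self.lik_null,
            "loglik_exp": self.loglik_exp,
            "lik_exp": self.lik_exp,
            "predicted_rates": list(self.predicted_rates),
            "posterior_at_half": self.posterior_at_half,
            "posterior_at_half_rounded": self.posterior_at_half_rounded,
            "sweep_grid": list(self.sweep_grid),
            "sweep_curves": {k: v.tolist() for k, v in self.sweep_curves.items()},
            "comparison": list(self.comparison),
        }

    def to_json(self, path: str | Path | None = None, **kwargs) -> str:
        payload = json.dumps(self.to_dict(), **kwargs)
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload


def reproduce_paracetamol_example(
    theta_source: str = "printed",
    prior_grid: Sequence[float] | None = None,
) -> ExampleReport:
    """Recompute the paracetamol-asthma worked example from the fixture.

    ``theta_source`` selects the exponential parameters: ``"printed"``
    (default) uses the published values and reproduces the published
    likelihoods; ``"refit"`` re-estimates them from the five observed
    rates by least squares.  The refit path does not reproduce the
    published model-evaluation table, whose estimation subset was never
    stated, and is labelled accordingly.
    """
    if theta_source not in {"printed", "refit"}:
        raise ValidationError("theta_source must be 'printed' or 'refit'")
    table = paracetamol_asthma_table()
    grid = tuple(prior_grid) if prior_grid is not None else tuple(np.linspace(0, 1, 101))

    if theta_source == "printed":
        theta = PUBLISHED_EXPONENTIAL_THETA
    else:
        theta = fit("exponential", table).theta  # does not reproduce published values

    k_tilde, null_result = null_likelihood(table)
    exp_family = FAMILIES["exponential"]
    predicted = tuple(float(exp_family(d, np.asarray(theta))) for d in table.doses)
    exp_result = log_likelihood(table, list(predicted), model_tag="exponential", theta=theta)
    posterior = posterior_dr(exp_result.loglik, null_result.loglik, prior=0.5,
                             dr_model_tag="exponential")

    # sensitivity curves: exponential against the refitted cubic and linear
    cubic = fit("cubic", table)
    linear = fit("linear", table)
    logliks = {
        "exponential": exp_result.loglik,
        "cubic": log_likelihood(table, cubic.predictor(), "cubic", cubic.theta).loglik,
        "linear": log_likelihood(table, linear.predictor(), "linear", linear.theta).loglik,
    }
    curves = prior_sweep(logliks, null_result.loglik, grid)

    comparison = []

    def compare(name: str, computed: float, reference: float, note: str = ""):
        entry = {
            "quantity": name,
            "computed": computed,
            "reference": reference,
            "abs_deviation": abs(computed - reference),
        }
        if note:
            entry["note"] = note
        comparison.append(entry)

    compare("k_tilde", k_tilde, _REFERENCE["k_tilde"])
    compare("loglik_null", null_result.loglik, _REFERENCE["loglik_null"])
    compare("lik_null", null_result.likelihood, _REFERENCE["lik_null"])
    compare("loglik_exp", exp_result.loglik, _REFERENCE["loglik_exp"])
    compare("lik_exp", exp_result.likelihood, _REFERENCE["lik_exp"])
    compare(
        "posterior_at_half_rounded",
        round(posterior.posterior, 2),
        _REFERENCE["posterior_at_half_rounded"],
    )
    for i, (computed, reference) in enumerate(
        zip(predicted, _REFERENCE["predicted_rates"])
    ):
        compare(
            f"predicted_rate_{i + 1}",
            computed,
            reference,
            note=_TOP_DOSE_NOTE if i == len(predicted) - 1 else "",
        )

    return ExampleReport(
        k_tilde=k_tilde,
        loglik_null=null_result.loglik,
        lik_null=null_result.likelihood,
        loglik_exp=exp_result.loglik,
        lik_exp=exp_result.likelihood,
        predicted_rates=predicted,
        posterior_at_half=posterior.posterior,
        sweep_curves=curves,
        sweep_grid=grid,
        comparison=tuple(comparison),
        theta=tuple(theta),
        theta_source=theta_source,
    )


DEFAULT_PIPELINE_CONFIG: dict = {
    "prior": 0.5,
    "families": ("constant", "linear", "quadratic", "cubic", "exponential"),
    "criterion": "aic",
    "dr_model": None,
    "null_estimator": "least_squares",
    "sweep_grid": tuple(np.linspace(0, 1, 101)),
}


def run_pipeline(table: DoseResponseTable, config: Mapping | None = None) -> dict:
    """Full analysis of one table: trend test, fits, selection, posterior.

    Returns a JSON-serialisable report bundle with a structured log of
    every stage and decision (families fitted, criterion, prior, the
    selected model's parameters).  Errors propagate annotated with the
    stage in which they occurred.
    """
    cfg = dict(DEFAULT_PIPELINE_CONFIG)
    cfg.update(config or {})
    log: list[dict] = []
    bundle: dict = {
        "label": table.label,
        "table": table.to_dict(),
        "config": {
            key: (list(value) if isinstance(value, tuple) else value)
            for key, value in cfg.items()
        },
        "log": log,
    }
    stage = "trend_test"
    try:
        result_trend = trend_test(table)
        bundle["trend_test"] = result_trend.to_dict()
        log.append({"stage": stage, "statistic": result_trend.statistic})

        stage = "assessment"
        assessment = assess_dose_responsiveness(
            table,
            families=cfg["families"],
            prior=cfg["prior"],
            criterion=cfg["criterion"],
            dr_model=cfg["dr_model"],
            null_estimator=cfg["null_estimator"],
        )
        bundle["assessment"] = assessment.to_dict()
        log.append(
            {
                "stage": stage,
                "selected_model": assessment.posterior_result.dr_model_tag,
                "criterion": cfg["criterion"],
                "prior": cfg["prior"],
                "posterior": assessment.posterior_result.posterior,
            }
        )

        stage = "prior_sweep"
        logliks = {
            record["family"]: log_likelihood(
                table,
                FittedModel(
                    family=FAMILIES[record["family"]],
                    theta=tuple(record["theta"]),
                    rss=record["rss"],
                    n_fit=len(table),
                    criteria={},
                ).predictor(),
                record["family"],
            ).loglik
            for record in assessment.selection.ranking_records()
        }
        curves = prior_sweep(logliks, assessment.null_result.loglik, cfg["sweep_grid"])
        bundle["prior_sweep"] = {
            "grid": list(cfg["sweep_grid"]),
            "curves": {tag: curve.tolist() for tag, curve in curves.items()},
        }
        log.append({"stage": stage, "models": sorted(curves)})
    except Exception as exc:
        exc.args = (f"[stage: {stage}] {exc}",) + exc.args[1:]
        raise
    return bundle
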
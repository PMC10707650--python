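"""Closed-form new-stand prediction and sample-size planning.

With the common-SD model adopted, everything needed to plan how many shoots
to measure in a previously unsampled stand is conjugate normal algebra.
Before any measurement the stand mean ``mu_s`` is
``Normal(mu_bar, sigma_M^2)``; after ``n`` log measurements ``y_1..y_n`` the
posterior of the stand mean is normal with

    mu_n      = (mu_bar/sigma_M^2 + sum_i y_i / sigma_bar^2) / (1/sigma_M^2 + n/sigma_bar^2)
    1/sigma_n^2 = 1/sigma_M^2 + n/sigma_bar^2

and the next individual's log concentration is
``Normal(mu_n, sigma_bar^2 + sigma_n^2)``.  Replacing the sample mean by the
stand's true mean gives the *expected* posterior mean as a function of n —
the shrinkage curve behind the recommendation to measure five shoots per
stand.  Scale helpers convert log-scale quantities to the multiplicative
(Bq kg^-1) scale: geometric SD, fold changes, and the model-implied
probability that an individual falls below a regulatory threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .inference import PosteriorDraws
from .models import HyperParams

__all__ = [
    "NewStandPosterior",
    "PredictiveDistribution",
    "update_stand_posterior",
    "expected_stand_mean",
    "predictive_sd",
    "prediction_interval",
    "geometric_sd",
    "fold_change",
    "prob_below_threshold",
    "sample_size_curve",
]


@dataclass(frozen=True)
class NewStandPosterior:
    """Posterior of a new stand's mean log concentration after n observations."""

    mu_n: float
    sigma_n: float
    n: int
    hyper: HyperParams


@dataclass(frozen=True)
class PredictiveDistribution:
    """Normal predictive distribution of the next individual's log concentration."""

    mean: float
    sd: float
    level: float
    lower_log: float
    upper_log: float

    @property
    def lower_bq(self) -> float:
        return float(np.exp(self.lower_log))

    @property
    def upper_bq(self) -> float:
        return float(np.exp(self.upper_log))


def _check_hyper(hyper: HyperParams) -> None:
    if not (hyper.sigma_bar > 0 and hyper.sigma_M > 0):
        raise ValueError("prediction requires sigma_bar > 0 and sigma_M > 0")


def update_stand_posterior(y: Sequence[float] | Iterable[float], hyper: HyperParams) -> NewStandPosterior:
    """Conjugate update of a new stand's mean from log measurements ``y``.

    An empty ``y`` returns the prior ``(mu_bar, sigma_M)``.
    """
    _check_hyper(hyper)
    y = np.asarray(list(y), dtype=float)
    n = y.size
    prec = 1.0 / hyper.sigma_M**2 + n / hyper.sigma_bar**2
    mu_n = (hyper.mu_bar / hyper.sigma_M**2 + y.sum() / hyper.sigma_bar**2) / prec
    return NewStandPosterior(mu_n=float(mu_n), sigma_n=float(prec**-0.5), n=int(n), hyper=hyper)


def expected_stand_mean(n: int, true_mu_s: float, hyper: HyperParams) -> float:
    """Expected posterior stand mean after n measurements from a stand whose
    true mean is ``true_mu_s``: the precision-weighted compromise
    ``(mu_bar/sigma_M^2 + n*true_mu_s/sigma_bar^2) / (1/sigma_M^2 + n/sigma_bar^2)``.
    """
    _check_hyper(hyper)
    if n < 0:
        raise ValueError("n must be non-negative")
    w0 = 1.0 / hyper.sigma_M**2
    w1 = n / hyper.sigma_bar**2
    return float((w0 * hyper.mu_bar + w1 * true_mu_s) / (w0 + w1))


def predictive_sd(n: int, hyper: HyperParams) -> float:
    """Predictive SD of the next individual's log concentration after n
    measurements: ``sqrt(sigma_bar^2 + 1/(1/sigma_M^2 + n/sigma_bar^2))``.

    Decreases with n and is floored at the within-stand SD ``sigma_bar``.
    """
    _check_hyper(hyper)
    if n < 0:
        raise ValueError("n must be non-negative")
    sigma_n_sq = 1.0 / (1.0 / hyper.sigma_M**2 + n / hyper.sigma_bar**2)
    return float(np.sqrt(hyper.sigma_bar**2 + sigma_n_sq))


def prediction_interval(point: NewStandPosterior, level: float = 0.95) -> PredictiveDistribution:
    """Central normal prediction interval for the next individual.

    Bounds are ``mu_n ± z * sqrt(sigma_bar^2 + sigma_n^2)`` on the log scale;
    linear-scale (Bq kg^-1) bounds are their exponentials.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly between 0 and 1")
    sd = float(np.sqrt(point.hyper.sigma_bar**2 + point.sigma_n**2))
    z = float(norm.ppf(0.5 + level / 2.0))
    return PredictiveDistribution(
        mean=point.mu_n,
        sd=sd,
        level=level,
        lower_log=point.mu_n - z * sd,
        upper_log=point.mu_n + z * sd,
    )


def geometric_sd(sigma_log: float) -> float:
    """Geometric SD of a log-normal: ``exp`` of the log-scale SD."""
    if sigma_log < 0:
        raise ValueError("sigma_log must be non-negative")
    return float(np.exp(sigma_log))


def fold_change(delta_log: float) -> float:
    """Multiplicative factor corresponding to a log-scale difference."""
    return float(np.exp(delta_log))


def prob_below_threshold(mu_s: float, sigma_s: float, threshold_bq: float) -> float:
    """Model-implied fraction of individuals below an activity threshold.

    ``Phi((ln threshold - mu_s) / sigma_s)`` under the stand's log-normal.
    """
    if threshold_bq <= 0:
        raise ValueError("threshold must be positive (Bq kg^-1)")
    if sigma_s <= 0:
        raise ValueError("sigma_s must be positive")
    return float(norm.cdf((np.log(threshold_bq) - mu_s) / sigma_s))


def sample_size_curve(
    n_range: Sequence[int],
    true_mu_s: float,
    hyper: HyperParams | PosteriorDraws,
    level: float = 0.95,
) -> pd.DataFrame:
    """Expected stand mean and predictive SD as functions of the sample size.

    With point hyperparameters the band columns are the normal predictive
    interval around the expected mean.  With posterior draws the expected
    mean is pushed through the shrinkage formula draw by draw and the band is
    its 2.5%/97.5% posterior quantiles — the uncertainty of the expected
    value itself.
    """
    n_range = list(n_range)
    if not n_range:
        raise ValueError("n_range must be non-empty")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly between 0 and 1")

    if isinstance(hyper, PosteriorDraws):
        draws = hyper
        mu_bar = draws.stacked("mu_bar")
        sigma_bar = draws.stacked("sigma_bar")
        sigma_M = draws.stacked("sigma_M")
        point = HyperParams(
            mu_bar=float(mu_bar.mean()),
            sigma_bar=float(sigma_bar.mean()),
            sigma_M=float(sigma_M.mean()),
        )
        rows = []
        alpha = (1.0 - level) / 2.0
        for n in n_range:
            w0 = 1.0 / sigma_M**2
            w1 = n / sigma_bar**2
            per_draw = (w0 * mu_bar + w1 * true_mu_s) / (w0 + w1)
            rows.append(
                {
                    "n": int(n),
                    "expected_mean_log": expected_stand_mean(n, true_mu_s, point),
                    "predictive_sd_log": predictive_sd(n, point),
                    "lower": float(np.quantile(per_draw, alpha)),
                    "upper": float(np.quantile(per_draw, 1.0 - alpha)),
                    "expected_mean_bq": float(np.exp(expected_stand_mean(n, true_mu_s, point))),
                }
            )
        return pd.DataFrame(rows)

    z = float(norm.ppf(0.5 + level / 2.0))
    rows = []
    for n in n_range:
        m = expected_stand_mean(n, true_mu_s, hyper)
        s = predictive_sd(n, hyper)
        rows.append(
            {
                "n": int(n),
                "expected_mean_log": m,
                "predictive_sd_log": s,
                "lower": m - z * s,
                "upper": m + z * s,
                "expected_mean_bq": float(np.exp(m)),
            }
        )
    return pd.DataFrame(rows)
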
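"""WAIC model comparison targeting prediction in a *new* stand.

Because the predictive task is a stand never seen before, the pointwise
predictive density must not condition on the fitted stand effects: the
random stand effects (on the mean and, for the varying-SD model, on the
log-SD) are integrated out of the likelihood before WAIC is computed.  For
the common-SD model this marginal is closed form — integrating
``eps_M ~ Normal(0, sigma_M^2)`` out of a normal likelihood gives
``y_i ~ Normal(mu_i, sigma_bar^2 + sigma_M^2)``.  For the varying-SD model
the double integral over ``(eps_M, eps_V)`` has no closed form and is done
by Monte Carlo with fresh standard-normal nodes, averaged with
log-sum-exp.  Species effects and the origin coefficient, when present, are
conditioned on: the prediction target is a new stand, not a new species.

WAIC is on the deviance scale: ``-2 * (lppd - p_waic)`` with
``p_waid = sum_i var_t(log p(y_i | draw t))``; smaller predicts better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .inference import PosteriorDraws
from .models import ModelData, ModelSpec

__all__ = [
    "PointwiseLogLik",
    "WaicResult",
    "marginal_pointwise_loglik",
    "waic",
    "select_model",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
DEFAULT_MC_SAMPLES = 1000
# |ΔWAIC| at or below this is treated as sampling noise and the structurally
# simpler model wins; 2 deviance units is the conventional noise scale.
DEFAULT_TOLERANCE = 2.0


@dataclass
class PointwiseLogLik:
    """Matrix of log predictive densities, (posterior draw, observation)."""

    matrix: np.ndarray
    mc_samples: int
    seed: int

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("pointwise log-likelihood must be a (draws, obs) matrix")


@dataclass(frozen=True)
class WaicResult:
    """lppd, effective-parameter penalty, and WAIC on the deviance scale."""

    lppd: float
    p_waic: float
    waic: float

    @classmethod
    def from_parts(cls, lppd: float, p_waic: float) -> "WaicResult":
        return cls(lppd=lppd, p_waic=p_waic, waic=-2.0 * (lppd - p_waic))


def _conditional_mean_offset(draws: PosteriorDraws, spec: ModelSpec, data: ModelData) -> np.ndarray:
    """Per-draw, per-observation mean contributions that are conditioned on
    (origin shift and species effects), shape (draws, n_obs)."""
    n = draws.n_chains * draws.n_draws
    offset = np.zeros((n, data.n_obs))
    if spec.has_origin:
        offset += draws.stacked("beta")[:, None] * data.origin[None, :]
    if spec.has_species:
        eps_S = draws.effect_matrix("eps_S")  # (n, n_species)
        offset += eps_S[:, data.species_index]
    return offset


def marginal_pointwise_loglik(
    draws: PosteriorDraws,
    spec: ModelSpec,
    table,
    mc_samples: int = DEFAULT_MC_SAMPLES,
    seed: int = 0,
    force_mc: bool = False,
    draw_chunk: int = 16,
) -> PointwiseLogLik:
    """New-stand pointwise log predictive density, stand effects integrated out.

    Parameters
    ----------
    draws : posterior draws from :func:`shootcs.inference.fit` of ``spec``.
    spec, table : the fitted model and its (censoring-filtered) data.
    mc_samples : Monte Carlo nodes per posterior draw for models without a
        closed-form marginal (ignored on the closed-form path).
    force_mc : evaluate the common-SD model by Monte Carlo too (used to
        validate the integrator against the closed form).
    """
    data = table if isinstance(table, ModelData) else ModelData.from_table(table)
    n = draws.n_chains * draws.n_draws
    mu_bar = draws.stacked("mu_bar")
    sigma_bar = draws.stacked("sigma_bar")
    sigma_M = draws.stacked("sigma_M")
    offset = _conditional_mean_offset(draws, spec, data)
    y = data.log_activity

    use_mc = spec.has_varying_sd or force_mc
    if not use_mc:
        # closed form: y_i ~ Normal(mu_bar + offset_i, sigma_bar^2 + sigma_M^2)
        var = (sigma_bar**2 + sigma_M**2)[:, None]
        resid = y[None, :] - (mu_bar[:, None] + offset)
        ll = -0.5 * np.log(var) - _LOG_SQRT_2PI - 0.5 * resid**2 / var
        return PointwiseLogLik(ll, mc_samples=0, seed=seed)

    if mc_samples < 2:
        raise ValueError("Monte Carlo marginalization needs mc_samples >= 2")
    rng = np.random.default_rng(seed)
    sigma_V = draws.stacked("sigma_V") if spec.has_varying_sd else np.zeros(n)
    ll = np.empty((n, data.n_obs))
    for start in range(0, n, draw_chunk):
        stop = min(start + draw_chunk, n)
        m = stop - start
        z_M = rng.standard_normal((m, mc_samples))
        eps_M = sigma_M[start:stop, None] * z_M
        if spec.has_varying_sd:
            z_V = rng.standard_normal((m, mc_samples))
            log_sd = np.log(sigma_bar[start:stop])[:, None] + sigma_V[start:stop, None] * z_V
        else:
            log_sd = np.broadcast_to(np.log(sigma_bar[start:stop])[:, None], (m, mc_samples))
        # (m, mc, obs): normal log density of each observation at each node
        mean = (mu_bar[start:stop, None, None] + eps_M[:, :, None]) + offset[start:stop, None, :]
        r = (y[None, None, :] - mean) * np.exp(-log_sd)[:, :, None]
        node_ll = -log_sd[:, :, None] - _LOG_SQRT_2PI - 0.5 * r**2
        ll[start:stop] = logsumexp(node_ll, axis=1) - math.log(mc_samples)
    return PointwiseLogLik(ll, mc_samples=mc_samples, seed=seed)


def waic(pll: PointwiseLogLik) -> WaicResult:
    """Watanabe's widely applicable information criterion from pointwise densities."""
    ll = pll.matrix
    if ll.shape[0] < 2:
        raise ValueError("WAIC needs at least 2 posterior draws")
    if not np.all(np.isfinite(ll)):
        t, i = np.argwhere(~np.isfinite(ll))[0]
        raise ValueError(f"non-finite pointwise log likelihood at draw {t}, observation {i}")
    n_draws = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - math.log(n_draws)))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return WaicResult.from_parts(lppd, p_waic)


def select_model(
    result_simple: WaicResult,
    result_complex: WaicResult,
    tolerance: float = DEFAULT_TOLERANCE,
    names: tuple[str, str] = ("model1", "model2"),
) -> str:
    """Choose between a simpler and a more complex model by WAIC.

    ``names[0]`` must be the structurally simpler model (fewer variance
    components).  If the WAIC difference is within ``tolerance`` the simpler
    model is preferred; otherwise the smaller WAIC wins.  Ties go to
    simplicity.
    """
    delta = result_simple.waic - result_complex.waic
    if abs(delta) <= tolerance or delta <= 0:
        return names[0]
    return names[1]
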
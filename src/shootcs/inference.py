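"""MCMC fitting, convergence checking and posterior summaries.

The sampler is an affine-invariant ensemble (emcee).  Each of the
``chains`` requested in :class:`McmcConfig` is an independent ensemble run
from its own seed, so the split-R̂ diagnostic compares genuinely independent
chains.  Sampling happens on an unconstrained parameterization — SDs on the
log scale with the half-normal prior's Jacobian, remaining random effects as
standardized draws ``z`` with ``eps = sigma*z`` — and the stand-mean effects
``eps_M`` are marginalized out of the sampled density analytically
(normal–normal conjugacy gives the per-stand integral in closed form).
Collapsing ``eps_M`` removes one dimension per stand from the ensemble's
walk, which is what makes the high-dimensional hierarchical posteriors mix
within a practical warmup; it changes nothing statistically, because after
sampling the collapsed posterior each retained draw is completed with an
exact draw of ``eps_M`` from its conjugate normal conditional — the
composition is a draw from the full joint posterior.  The models module
remains the single source of density truth: the collapsed density is pinned
to :func:`shootcs.models.log_posterior` through an exact identity asserted
in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import emcee
import numpy as np
import pandas as pd

from .models import HyperParams, LatentEffects, ModelData, ModelSpec, log_posterior

__all__ = [
    "McmcConfig",
    "PosteriorDraws",
    "DiagnosticError",
    "fit",
    "fit_stand_mean",
    "rhat",
    "converged",
    "summarize",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
RHAT_THRESHOLD = 1.1


class DiagnosticError(RuntimeError):
    """The sampling engine failed; the message carries its diagnostics."""


@dataclass(frozen=True)
class McmcConfig:
    """Sampling protocol.

    ``warmup`` counts discarded ensemble sweeps; ``sampling`` counts retained
    posterior draws per chain (collected by flattening the walkers of the
    post-warmup sweeps in sweep-major order).  The defaults mirror the
    4-chain, 8000-warmup / 8000-draw protocol of the survey analysis;
    ``test_scale`` divides both for quick runs without touching the contract
    of the defaults.
    """

    chains: int = 4
    warmup: int = 8000
    sampling: int = 8000
    walkers: int | None = None
    seed: int = 0
    test_scale: float | None = None

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("at least 2 chains are required (split-R̂ needs them)")
        if self.warmup < 1 or self.sampling < 1:
            raise ValueError("warmup and sampling must be positive")

    @property
    def effective_warmup(self) -> int:
        if self.test_scale:
            return max(2, int(round(self.warmup / self.test_scale)))
        return self.warmup

    @property
    def effective_sampling(self) -> int:
        if self.test_scale:
            return max(4, int(round(self.sampling / self.test_scale)))
        return self.sampling


@dataclass
class PosteriorDraws:
    """Named posterior samples indexed by (chain, draw).

    Parameter names follow the model's field notation: ``mu_bar``, ``beta``,
    ``sigma_bar``, ``sigma_M``, ``sigma_V``, ``sigma_S`` and per-group
    effects ``eps_M[<stand>]``, ``eps_V[<stand>]``, ``eps_S[<species>]``.
    """

    params: dict[str, np.ndarray]
    spec: ModelSpec
    config: McmcConfig
    stand_ids: list[str] = field(default_factory=list)
    species_names: list[str] = field(default_factory=list)
    data_fingerprint: str = ""

    def __post_init__(self):
        shapes = {v.shape for v in self.params.values()}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent (chain, draw) shapes: {shapes}")

    @property
    def names(self) -> list[str]:
        return list(self.params)

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """All chains pooled into one flat array (chain-major)."""
        return self.params[name].reshape(-1)

    def hyper_names(self) -> list[str]:
        return [n for n in self.params if not n.startswith("eps_")]

    def effect_matrix(self, prefix: str) -> np.ndarray:
        """Pooled draws of a random-effect family, shape (total draws, groups)."""
        cols = [n for n in self.params if n.startswith(prefix + "[")]
        return np.column_stack([self.stacked(n) for n in cols]) if cols else np.empty((self.n_chains * self.n_draws, 0))

    def thin(self, step: int) -> "PosteriorDraws":
        """Keep every ``step``-th draw of every chain (cuts WAIC integration cost)."""
        if step < 1:
            raise ValueError("thinning step must be >= 1")
        return PosteriorDraws(
            params={k: v[:, ::step].copy() for k, v in self.params.items()},
            spec=self.spec,
            config=self.config,
            stand_ids=self.stand_ids,
            species_names=self.species_names,
            data_fingerprint=self.data_fingerprint,
        )

    def to_frame(self) -> pd.DataFrame:
        n_c, n_d = self.n_chains, self.n_draws
        data = {
            "chain": np.repeat(np.arange(n_c), n_d),
            "draw": np.tile(np.arange(n_d), n_c),
        }
        for name, arr in self.params.items():
            data[name] = arr.reshape(-1)
        return pd.DataFrame(data)

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path: str | Path, spec: ModelSpec, config: McmcConfig | None = None) -> "PosteriorDraws":
        df = pd.read_csv(path)
        chains = int(df["chain"].max()) + 1
        draws = int(df["draw"].max()) + 1
        params = {}
        for name in df.columns:
            if name in ("chain", "draw"):
                continue
            params[name] = df[name].to_numpy(dtype=float).reshape(chains, draws)
        cfg = config or McmcConfig(chains=max(chains, 2), warmup=1, sampling=draws)
        stands = [n[len("eps_M["):-1] for n in params if n.startswith("eps_M[")]
        species = [n[len("eps_S["):-1] for n in params if n.startswith("eps_S[")]
        return cls(params, spec, cfg, stands, species)


# ---------------------------------------------------------------------------
# parameter packing on the unconstrained, eps_M-collapsed space


class _Packing:
    def __init__(self, spec: ModelSpec, data: ModelData):
        self.spec = spec
        self.data = data
        idx = 0
        self.slices: dict[str, slice] = {}

        def grab(name: str, size: int):
            nonlocal idx
            self.slices[name] = slice(idx, idx + size)
            idx += size

        grab("mu_bar", 1)
        if spec.has_origin:
            grab("beta", 1)
        grab("log_sigma_bar", 1)
        grab("log_sigma_M", 1)
        if spec.has_varying_sd:
            grab("log_sigma_V", 1)
        if spec.has_species:
            grab("log_sigma_S", 1)
        # eps_M is not sampled: it is integrated out of the density in closed
        # form and re-drawn exactly from its conditional after sampling
        if spec.has_varying_sd:
            grab("z_V", data.n_stands)
        if spec.has_species:
            grab("z_S", data.n_species)
        self.ndim = idx
        # per-stand observation bookkeeping for the collapsed likelihood:
        # indicator matrix (n_obs, n_stands) and per-stand counts
        self.group = np.zeros((data.n_obs, data.n_stands))
        self.group[np.arange(data.n_obs), data.stand_index] = 1.0
        self.counts = self.group.sum(axis=0)

    def __getitem__(self, name: str) -> slice:
        return self.slices[name]


def _halfnormal_plus_jacobian(log_sigma: np.ndarray, scale: float) -> np.ndarray:
    # log p(sigma) * |d sigma / d log sigma|, sigma = exp(log_sigma)
    sigma = np.exp(log_sigma)
    return (
        math.log(2.0) - math.log(scale) - _LOG_SQRT_2PI - 0.5 * (sigma / scale) ** 2 + log_sigma
    )


def _resid_and_stand_logsd(theta: np.ndarray, pack: _Packing) -> tuple[np.ndarray, np.ndarray]:
    """Residuals after the conditioned-on mean terms (no ``eps_M``) and the
    per-stand log within-stand SD; shapes (m, n_obs) and (m, n_stands)."""
    spec, data = pack.spec, pack.data
    mu = np.broadcast_to(theta[:, pack["mu_bar"]], (theta.shape[0], data.n_obs)).copy()
    if spec.has_origin:
        mu += theta[:, pack["beta"]] * data.origin[None, :]
    if spec.has_species:
        sigma_S = np.exp(theta[:, pack["log_sigma_S"]][:, 0])
        mu += sigma_S[:, None] * theta[:, pack["z_S"]][:, data.species_index]
    log_sb = theta[:, pack["log_sigma_bar"]][:, 0]
    if spec.has_varying_sd:
        sigma_V = np.exp(theta[:, pack["log_sigma_V"]][:, 0])
        log_sd_stand = log_sb[:, None] + sigma_V[:, None] * theta[:, pack["z_V"]]
    else:
        log_sd_stand = np.broadcast_to(log_sb[:, None], (theta.shape[0], data.n_stands))
    return data.log_activity[None, :] - mu, log_sd_stand


def _stand_conditional_moments(
    resid: np.ndarray, log_sd_stand: np.ndarray, sigma_M: np.ndarray, pack: _Packing
) -> tuple[np.ndarray, np.ndarray]:
    """Conjugate conditional of ``eps_M`` given everything else.

    With residuals ``r_i = y_i - (mean terms without eps_M)`` and within-stand
    variance ``v_s``, ``eps_M[s] | rest ~ Normal(m_s, w_s)`` with
    ``1/w_s = 1/sigma_M^2 + n_s/v_s`` and ``m_s = w_s * sum_i r_i / v_s``.
    Returns (means, variances), each (m, n_stands).
    """
    var_s = np.exp(2.0 * log_sd_stand)
    sum_r = resid @ pack.group
    prec = 1.0 / sigma_M[:, None] ** 2 + pack.counts[None, :] / var_s
    w = 1.0 / prec
    return w * sum_r / var_s, w


def _collapsed_loglik(
    resid: np.ndarray, log_sd_stand: np.ndarray, sigma_M: np.ndarray, pack: _Packing
) -> np.ndarray:
    """Log likelihood with ``eps_M`` integrated out analytically, summed over
    stands; each stand's integral is the closed-form normal–normal marginal

    ``log L_s = -((n_s-1)/2) log(2 pi v_s) - SS_s/(2 v_s) - (1/2) log n_s
                + log Normal(rbar_s; 0, v_s/n_s + sigma_M^2)``

    where ``rbar_s`` and ``SS_s`` are the stand residual mean and centered sum
    of squares and ``v_s`` the within-stand variance.
    """
    n_s = pack.counts[None, :]
    var_s = np.exp(2.0 * log_sd_stand)
    sum_r = resid @ pack.group
    sumsq = (resid**2) @ pack.group
    rbar = sum_r / n_s
    ss = sumsq - n_s * rbar**2
    var_mean = var_s / n_s + sigma_M[:, None] ** 2
    per_stand = (
        -0.5 * (n_s - 1) * (2.0 * _LOG_SQRT_2PI + np.log(var_s))
        - 0.5 * ss / var_s
        - 0.5 * np.log(n_s)
        - 0.5 * (2.0 * _LOG_SQRT_2PI + np.log(var_mean))
        - 0.5 * rbar**2 / var_mean
    )
    return per_stand.sum(axis=1)


def _unconstrained_log_prob(theta: np.ndarray, pack: _Packing) -> np.ndarray:
    """Vectorized log density on the collapsed sampling space; theta is (m, ndim)."""
    theta = np.atleast_2d(theta)
    spec = pack.spec
    mu_bar = theta[:, pack["mu_bar"]][:, 0]
    log_sb = theta[:, pack["log_sigma_bar"]][:, 0]
    log_sm = theta[:, pack["log_sigma_M"]][:, 0]
    sigma_M = np.exp(log_sm)

    lp = (
        -math.log(spec.prior_mu_sd) - _LOG_SQRT_2PI - 0.5 * (mu_bar / spec.prior_mu_sd) ** 2
        + _halfnormal_plus_jacobian(log_sb, spec.prior_sigma_scale)
        + _halfnormal_plus_jacobian(log_sm, spec.prior_sigma_scale)
    )
    if spec.has_origin:
        beta = theta[:, pack["beta"]][:, 0]
        lp += -math.log(spec.prior_mu_sd) - _LOG_SQRT_2PI - 0.5 * (beta / spec.prior_mu_sd) ** 2
    if spec.has_species:
        log_ss = theta[:, pack["log_sigma_S"]][:, 0]
        z_S = theta[:, pack["z_S"]]
        lp += _halfnormal_plus_jacobian(log_ss, spec.prior_sigma_scale)
        lp += np.sum(-_LOG_SQRT_2PI - 0.5 * z_S**2, axis=1)
    if spec.has_varying_sd:
        log_sv = theta[:, pack["log_sigma_V"]][:, 0]
        z_V = theta[:, pack["z_V"]]
        lp += _halfnormal_plus_jacobian(log_sv, spec.prior_sigma_scale)
        lp += np.sum(-_LOG_SQRT_2PI - 0.5 * z_V**2, axis=1)

    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        resid, log_sd_stand = _resid_and_stand_logsd(theta, pack)
        lp = lp + _collapsed_loglik(resid, log_sd_stand, sigma_M, pack)
    return np.where(np.isfinite(lp), lp, -np.inf)


def unconstrained_log_prob_reference(
    theta_row: np.ndarray, spec: ModelSpec, data: ModelData, eps_M: np.ndarray | None = None
) -> float:
    """Scalar reference for the collapsed sampling density via the centered contract.

    Uses the exact identity ``p(theta) = p(theta, eps_M) / p(eps_M | theta)``,
    valid for *any* value of ``eps_M``: evaluates ``models.log_posterior`` at
    the transformed parameters with the supplied (or zero) ``eps_M``, adds the
    change-of-variables terms for the sampled coordinates, and subtracts the
    conjugate conditional density of ``eps_M``, computed here scalar-by-scalar
    and independently of the vectorized sampler path.  Used by tests to pin
    the sampler's density to the models module.
    """
    pack = _Packing(spec, data)
    hyper, latent_rest = _decode(theta_row, pack)
    if eps_M is None:
        eps_M = np.zeros(data.n_stands)
    latent = LatentEffects(eps_M=np.asarray(eps_M, dtype=float),
                           eps_V=latent_rest.eps_V, eps_S=latent_rest.eps_S)
    lp = log_posterior(spec, hyper, latent, data)
    # Jacobians: d sigma / d log sigma = sigma for each sampled SD, and the
    # non-centered z -> eps map contributes |d eps/d z| = sigma per sampled
    # effect, while the z prior replaces the centered effect prior.
    jac = math.log(hyper.sigma_bar) + math.log(hyper.sigma_M)
    if spec.has_varying_sd:
        jac += math.log(hyper.sigma_V) + data.n_stands * math.log(hyper.sigma_V)
    if spec.has_species:
        jac += math.log(hyper.sigma_S) + data.n_species * math.log(hyper.sigma_S)
    # conditional eps_M[s] | rest ~ Normal(m_s, w_s), derived per stand
    cond = 0.0
    for s in range(data.n_stands):
        mask = data.stand_index == s
        mu_i = hyper.mu_bar + hyper.beta * data.origin[mask]
        if spec.has_species and latent.eps_S is not None:
            mu_i = mu_i + latent.eps_S[data.species_index[mask]]
        r = data.log_activity[mask] - mu_i
        sd_s = hyper.sigma_bar
        if spec.has_varying_sd and latent.eps_V is not None:
            sd_s = hyper.sigma_bar * math.exp(latent.eps_V[s])
        prec = 1.0 / hyper.sigma_M**2 + r.size / sd_s**2
        w_s = 1.0 / prec
        m_s = w_s * float(np.sum(r)) / sd_s**2
        cond += -0.5 * math.log(2.0 * math.pi * w_s) - 0.5 * (latent.eps_M[s] - m_s) ** 2 / w_s
    return lp + jac - cond


def _decode(theta_row: np.ndarray, pack: _Packing) -> tuple[HyperParams, LatentEffects]:
    spec = pack.spec
    sigma_bar = float(np.exp(theta_row[pack["log_sigma_bar"]][0]))
    sigma_M = float(np.exp(theta_row[pack["log_sigma_M"]][0]))
    sigma_V = float(np.exp(theta_row[pack["log_sigma_V"]][0])) if spec.has_varying_sd else 0.0
    sigma_S = float(np.exp(theta_row[pack["log_sigma_S"]][0])) if spec.has_species else 0.0
    hyper = HyperParams(
        mu_bar=float(theta_row[pack["mu_bar"]][0]),
        sigma_bar=sigma_bar,
        sigma_M=sigma_M,
        sigma_V=sigma_V,
        sigma_S=sigma_S,
        beta=float(theta_row[pack["beta"]][0]) if spec.has_origin else 0.0,
    )
    latent = LatentEffects(
        eps_M=np.zeros(pack.data.n_stands),
        eps_V=sigma_V * theta_row[pack["z_V"]] if spec.has_varying_sd else None,
        eps_S=sigma_S * theta_row[pack["z_S"]] if spec.has_species else None,
    )
    return hyper, latent


def _initial_center(spec: ModelSpec, data: ModelData, pack: _Packing) -> np.ndarray:
    """Moment-based starting point: stand-mean spread seeds sigma_M, pooled
    within-stand residual SD seeds sigma_bar."""
    y = data.log_activity
    center = np.zeros(pack.ndim)
    center[pack["mu_bar"]] = np.mean(y)
    stand_means = np.array([y[data.stand_index == s].mean() for s in range(data.n_stands)])
    resid = y - stand_means[data.stand_index]
    sigma_bar0 = max(float(np.std(resid)), 0.1)
    sigma_M0 = max(float(np.std(stand_means)), 0.1)
    center[pack["log_sigma_bar"]] = math.log(sigma_bar0)
    center[pack["log_sigma_M"]] = math.log(sigma_M0)
    if spec.has_varying_sd:
        center[pack["log_sigma_V"]] = math.log(0.2)
    if spec.has_species:
        sp_means = np.array(
            [y[data.species_index == k].mean() if np.any(data.species_index == k) else np.mean(y)
             for k in range(data.n_species)]
        )
        sigma_S0 = max(float(np.std(sp_means)), 0.1)
        center[pack["log_sigma_S"]] = math.log(sigma_S0)
    return center


def fit(spec: ModelSpec, table, config: McmcConfig) -> PosteriorDraws:
    """Sample the posterior of a model on a censoring-filtered table.

    Runs ``config.chains`` independent ensembles, discards warmup sweeps and
    retains ``config.effective_sampling`` draws per chain.  Deterministic
    given ``config.seed`` and the emcee version.
    """
    data = table if isinstance(table, ModelData) else ModelData.from_table(table)
    if data.n_obs == 0:
        raise ValueError("empty table")
    pack = _Packing(spec, data)
    ndim = pack.ndim
    nwalkers = config.walkers or max(2 * ndim + 2, 48)
    nwalkers += nwalkers % 2

    warmup_steps = config.effective_warmup
    keep_draws = config.effective_sampling
    keep_steps = max(1, math.ceil(keep_draws / nwalkers))

    center = _initial_center(spec, data, pack)
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    per_chain: list[np.ndarray] = []
    per_chain_eps_M: list[np.ndarray] = []
    for c in range(config.chains):
        rng = np.random.default_rng(seeds[c])
        coords = center[None, :] + 0.1 * rng.standard_normal((nwalkers, ndim))
        lp0 = _unconstrained_log_prob(coords, pack)
        if not np.any(np.isfinite(lp0)):
            raise DiagnosticError("no finite log posterior at initialization")
        coords[~np.isfinite(lp0)] = center + 0.01 * rng.standard_normal(ndim)

        sampler = emcee.EnsembleSampler(
            nwalkers, ndim, _unconstrained_log_prob, args=(pack,), vectorize=True
        )
        mt_seed = int(rng.integers(0, 2**31 - 1))
        state = emcee.State(coords, random_state=np.random.RandomState(mt_seed).get_state())
        try:
            state = sampler.run_mcmc(state, warmup_steps, progress=False)
            sampler.reset()
            sampler.run_mcmc(state, keep_steps, progress=False)
        except Exception as exc:  # pragma: no cover - engine failure path
            raise DiagnosticError(f"sampling engine failed: {exc!r}") from exc
        chain = sampler.get_chain()  # (steps, walkers, ndim), sweep-major
        flat = chain.reshape(-1, ndim)[:keep_draws]
        per_chain.append(flat)
        # complete each retained draw with an exact conjugate draw of eps_M;
        # (collapsed draw, conditional eps_M draw) is a joint posterior draw
        resid, log_sd_stand = _resid_and_stand_logsd(flat, pack)
        m, w = _stand_conditional_moments(resid, log_sd_stand, np.exp(flat[:, pack["log_sigma_M"]][:, 0]), pack)
        per_chain_eps_M.append(m + np.sqrt(w) * rng.standard_normal(m.shape))

    draws = np.stack(per_chain)  # (chains, keep, ndim)
    eps_M_draws = np.stack(per_chain_eps_M)  # (chains, keep, n_stands)
    params = _named_params(draws, spec, pack, data, eps_M_draws)
    return PosteriorDraws(
        params=params,
        spec=spec,
        config=config,
        stand_ids=data.stand_ids,
        species_names=data.species_names,
        data_fingerprint=data.fingerprint(),
    )


def _named_params(
    draws: np.ndarray, spec: ModelSpec, pack: _Packing, data: ModelData, eps_M_draws: np.ndarray
) -> dict[str, np.ndarray]:
    params: dict[str, np.ndarray] = {}
    params["mu_bar"] = draws[:, :, pack["mu_bar"]][:, :, 0]
    if spec.has_origin:
        params["beta"] = draws[:, :, pack["beta"]][:, :, 0]
    params["sigma_bar"] = np.exp(draws[:, :, pack["log_sigma_bar"]][:, :, 0])
    params["sigma_M"] = np.exp(draws[:, :, pack["log_sigma_M"]][:, :, 0])
    if spec.has_varying_sd:
        params["sigma_V"] = np.exp(draws[:, :, pack["log_sigma_V"]][:, :, 0])
    if spec.has_species:
        params["sigma_S"] = np.exp(draws[:, :, pack["log_sigma_S"]][:, :, 0])
    for j, sid in enumerate(data.stand_ids):
        params[f"eps_M[{sid}]"] = eps_M_draws[:, :, j]
    if spec.has_varying_sd:
        z_V = draws[:, :, pack["z_V"]]
        for j, sid in enumerate(data.stand_ids):
            params[f"eps_V[{sid}]"] = params["sigma_V"] * z_V[:, :, j]
    if spec.has_species:
        z_S = draws[:, :, pack["z_S"]]
        for j, sp in enumerate(data.species_names):
            params[f"eps_S[{sp}]"] = params["sigma_S"] * z_S[:, :, j]
    return params


def fit_stand_mean(y_log, hyper: HyperParams, config: McmcConfig) -> np.ndarray:
    """MCMC posterior of a single stand mean with hyperparameters held fixed.

    The target is proportional to
    ``Normal(mu_s; mu_bar, sigma_M^2) * prod_i Normal(y_i; mu_s, sigma_bar^2)``,
    whose exact posterior is the conjugate normal of
    :func:`shootcs.prediction.update_stand_posterior`; this sampler is the
    MCMC side of that cross-check.  Returns pooled draws of ``mu_s``.
    """
    y = np.asarray(y_log, dtype=float)

    def logp(theta):
        mu = np.atleast_2d(theta)[:, 0]
        lp = -0.5 * ((mu - hyper.mu_bar) / hyper.sigma_M) ** 2
        if y.size:
            lp = lp - 0.5 * np.sum((y[None, :] - mu[:, None]) ** 2, axis=1) / hyper.sigma_bar**2
        return lp

    nwalkers = config.walkers or 16
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    chains = []
    for c in range(config.chains):
        rng = np.random.default_rng(seeds[c])
        coords = hyper.mu_bar + rng.standard_normal((nwalkers, 1))
        sampler = emcee.EnsembleSampler(nwalkers, 1, logp, vectorize=True)
        mt_seed = int(rng.integers(0, 2**31 - 1))
        state = emcee.State(coords, random_state=np.random.RandomState(mt_seed).get_state())
        state = sampler.run_mcmc(state, config.effective_warmup, progress=False)
        sampler.reset()
        keep_steps = max(1, math.ceil(config.effective_sampling / nwalkers))
        sampler.run_mcmc(state, keep_steps, progress=False)
        chains.append(sampler.get_chain().reshape(-1)[: config.effective_sampling])
    return np.concatenate(chains)


# ---------------------------------------------------------------------------
# diagnostics and summaries


def _split_rhat_1d(x: np.ndarray) -> float:
    """Classic split-R̂: each chain halved, between/within variance ratio."""
    m, n = x.shape
    half = n // 2
    if half < 2:
        raise ValueError("need at least 4 draws per chain for split-R̂")
    chains = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)  # (2m, half)
    within = chains.var(axis=1, ddof=1).mean()
    means = chains.mean(axis=1)
    between = half * means.var(ddof=1)
    if within == 0:
        return 1.0 if between == 0 else np.inf
    var_hat = (half - 1) / half * within + between / half
    return float(np.sqrt(var_hat / within))


def rhat(draws: PosteriorDraws | Mapping[str, np.ndarray]) -> dict[str, float]:
    """Split-R̂ (Gelman–Rubin) per parameter; values near 1 indicate mixing."""
    params = draws.params if isinstance(draws, PosteriorDraws) else dict(draws)
    first = next(iter(params.values()))
    if first.shape[0] < 2:
        raise ValueError("split-R̂ requires at least 2 chains; rerun with chains >= 2")
    return {name: _split_rhat_1d(np.asarray(arr, dtype=float)) for name, arr in params.items()}


def converged(draws: PosteriorDraws, threshold: float = RHAT_THRESHOLD) -> bool:
    """All-parameter convergence verdict at the survey's R̂ < 1.1 rule."""
    return all(v < threshold for v in rhat(draws).values())


def summarize(draws: PosteriorDraws, include_effects: bool = True) -> pd.DataFrame:
    """Posterior mean, SD, 2.5%/97.5% quantiles and R̂ per parameter.

    Chains are pooled for the moments and quantiles; R̂ uses the chain
    structure.  The layout mirrors the survey's posterior summary table.
    """
    rh = rhat(draws)
    rows = []
    for name in draws.names:
        if not include_effects and name.startswith("eps_"):
            continue
        x = draws.stacked(name)
        rows.append(
            {
                "parameter": name,
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
                "q2.5": float(np.quantile(x, 0.025)),
                "q97.5": float(np.quantile(x, 0.975)),
                "rhat": rh[name],
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
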
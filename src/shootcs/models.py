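"""Hierarchical log-normal models for radiocesium in growing shoots.

The observable is the natural log of the radiocesium activity concentration
(Bq kg^-1) of an individual growing shoot.  Each individual belongs to a
stand (a small forest plot); log concentrations within stand *s* are normal
with mean ``mu_s`` and SD ``sigma_s``.  Three model variants are supported:

* ``model1`` — stand means vary (``mu_s = mu_bar + eps_M[s]``) but the
  within-stand SD is common to all stands (``sigma_s = sigma_bar``).
* ``model2`` — additionally the within-stand SD varies by stand on the log
  scale, ``sigma_s = sigma_bar * exp(eps_V[s])``.
* ``full`` — model1's variance structure plus a binary stem-origin covariate
  (0 = coppice sprout, 1 = plantation) with coefficient ``beta`` and a
  random species effect ``eps_S``.

Priors: ``mu_bar ~ Normal(0, 100^2)`` and ``beta ~ Normal(0, 100^2)`` (vague);
every SD hyperparameter has a half-normal prior with scale 10 (weakly
informative).  Random effects are centered normals with their respective SDs.
All densities here are written in the centered parameterization; samplers may
reparameterize as long as the density is equivalent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .data_io import SampleTable

__all__ = [
    "HyperParams",
    "LatentEffects",
    "ModelSpec",
    "ModelData",
    "MODEL1",
    "MODEL2",
    "FULL",
    "model_spec",
    "log_likelihood",
    "log_prior",
    "log_posterior",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class HyperParams:
    """Population-level parameters of the hierarchical model.

    Parameters
    ----------
    mu_bar : overall mean of log activity (log_e Bq kg^-1).
    sigma_bar : overall within-stand SD of log activity.
    sigma_M : SD of random stand effects on the mean.
    sigma_V : SD of random stand effects on the log of the within-stand SD
        (0 for models with a common SD).
    sigma_S : SD of random species effects (0 when species are absent).
    beta : coefficient of stem origin (0 when origin is absent).  Negative
        values mean plantation stems are less contaminated than sprouts.
    """

    mu_bar: float
    sigma_bar: float
    sigma_M: float
    sigma_V: float = 0.0
    sigma_S: float = 0.0
    beta: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "mu_bar": self.mu_bar,
            "sigma_bar": self.sigma_bar,
            "sigma_M": self.sigma_M,
            "sigma_V": self.sigma_V,
            "sigma_S": self.sigma_S,
            "beta": self.beta,
        }


@dataclass
class LatentEffects:
    """Centered random effects bound to a particular dataset.

    ``eps_M``/``eps_V`` are indexed like the stands of the bound dataset,
    ``eps_S`` like its species.
    """

    eps_M: np.ndarray
    eps_V: np.ndarray | None = None
    eps_S: np.ndarray | None = None

    @staticmethod
    def zeros(n_stands: int, n_species: int = 0, varying_sd: bool = False) -> "LatentEffects":
        return LatentEffects(
            eps_M=np.zeros(n_stands),
            eps_V=np.zeros(n_stands) if varying_sd else None,
            eps_S=np.zeros(n_species) if n_species else None,
        )


@dataclass(frozen=True)
class ModelSpec:
    """Which structural components a model variant includes, plus prior scales."""

    name: str
    has_varying_sd: bool
    has_species: bool
    has_origin: bool
    prior_mu_sd: float = 100.0
    prior_sigma_scale: float = 10.0

    def with_prior_scales(self, mu_sd: float | None = None, sigma_scale: float | None = None) -> "ModelSpec":
        return replace(
            self,
            prior_mu_sd=self.prior_mu_sd if mu_sd is None else mu_sd,
            prior_sigma_scale=self.prior_sigma_scale if sigma_scale is None else sigma_scale,
        )


MODEL1 = ModelSpec("model1", has_varying_sd=False, has_species=False, has_origin=False)
MODEL2 = ModelSpec("model2", has_varying_sd=True, has_species=False, has_origin=False)
FULL = ModelSpec("full", has_varying_sd=False, has_species=True, has_origin=True)

_SPECS = {s.name: s for s in (MODEL1, MODEL2, FULL)}


def model_spec(name: str) -> ModelSpec:
    """Look up a model variant by name (``model1``, ``model2`` or ``full``)."""
    try:
        return _SPECS[name]
    except KeyError:
        raise ValueError(f"unknown model {name!r}; expected one of {sorted(_SPECS)}") from None


class ModelData:
    """Index-coded view of a censoring-filtered sample table.

    Holds the log activities plus integer stand/species codes so likelihood
    evaluations are plain vectorized array operations.
    """

    def __init__(
        self,
        log_activity: np.ndarray,
        stand_index: np.ndarray,
        stand_ids: list[str],
        species_index: np.ndarray | None = None,
        species_names: list[str] | None = None,
        origin: np.ndarray | None = None,
    ):
        self.log_activity = np.asarray(log_activity, dtype=float)
        self.stand_index = np.asarray(stand_index, dtype=np.intp)
        self.stand_ids = list(stand_ids)
        self.species_index = None if species_index is None else np.asarray(species_index, dtype=np.intp)
        self.species_names = list(species_names) if species_names is not None else []
        self.origin = None if origin is None else np.asarray(origin, dtype=float)

    @property
    def n_obs(self) -> int:
        return self.log_activity.size

    @property
    def n_stands(self) -> int:
        return len(self.stand_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    def fingerprint(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(self.log_activity.tobytes())
        h.update(self.stand_index.tobytes())
        if self.species_index is not None:
            h.update(self.species_index.tobytes())
        if self.origin is not None:
            h.update(self.origin.tobytes())
        return h.hexdigest()[:16]

    @classmethod
    def from_table(cls, table: SampleTable) -> "ModelData":
        df = table.to_frame()
        if bool(df["censored"].any()):
            raise ValueError(
                "table contains censored records; apply exclude_censored() before model fitting"
            )
        activity = df["activity"].to_numpy(dtype=float)
        if np.any(~(activity > 0)):
            bad = int(np.flatnonzero(~(activity > 0))[0])
            raise ValueError(
                f"non-positive activity at row {bad}: such records should have been censored"
            )
        stand_codes, stand_ids = pd_factorize_stable(df["stand"])
        species_codes, species_names = pd_factorize_stable(df["species"])
        return cls(
            log_activity=np.log(activity),
            stand_index=stand_codes,
            stand_ids=stand_ids,
            species_index=species_codes,
            species_names=species_names,
            origin=df["origin"].to_numpy(dtype=float),
        )


def pd_factorize_stable(series) -> tuple[np.ndarray, list[str]]:
    """Factorize a label column keeping first-appearance order (stable grouping)."""
    import pandas as pd

    codes, uniques = pd.factorize(series, sort=False)
    return codes.astype(np.intp), [str(u) for u in uniques]


def _coerce_data(table) -> ModelData:
    if isinstance(table, ModelData):
        return table
    return ModelData.from_table(table)


def _check_latent(spec: ModelSpec, latent: LatentEffects, data: ModelData) -> None:
    if len(latent.eps_M) != data.n_stands:
        raise ValueError(
            f"eps_M has length {len(latent.eps_M)} but the data have {data.n_stands} stands"
        )
    if spec.has_varying_sd:
        if latent.eps_V is None or len(latent.eps_V) != data.n_stands:
            raise ValueError("model with varying SD requires eps_V of length n_stands")
    if spec.has_species:
        if latent.eps_S is None or len(latent.eps_S) != data.n_species:
            raise ValueError("model with species effects requires eps_S of length n_species")


def log_likelihood(spec: ModelSpec, hyper: HyperParams, latent: LatentEffects, table) -> float:
    """Sum of normal log densities of the log activities.

    The mean of observation *i* is ``mu_bar + beta*O_i + eps_M[s(i)]
    (+ eps_S[sp(i)])`` and its SD is ``sigma_bar * exp(eps_V[s(i)])`` (the
    exponential factor only in models with varying SD).
    """
    data = _coerce_data(table)
    _check_latent(spec, latent, data)
    if not (hyper.sigma_bar > 0):
        return -np.inf

    mu = hyper.mu_bar + np.asarray(latent.eps_M, dtype=float)[data.stand_index]
    if spec.has_origin:
        if data.origin is None:
            raise ValueError("model includes origin but the data carry no origin column")
        mu = mu + hyper.beta * data.origin
    if spec.has_species:
        mu = mu + np.asarray(latent.eps_S, dtype=float)[data.species_index]

    if spec.has_varying_sd:
        sd = hyper.sigma_bar * np.exp(np.asarray(latent.eps_V, dtype=float)[data.stand_index])
    else:
        sd = np.full(data.n_obs, hyper.sigma_bar)

    z = (data.log_activity - mu) / sd
    return float(np.sum(-np.log(sd) - _LOG_SQRT_2PI - 0.5 * z * z))


def _halfnormal_logpdf(x: float, scale: float) -> float:
    # density 2/(scale*sqrt(2*pi)) * exp(-x^2/(2 scale^2)) on x >= 0
    if x < 0:
        return -np.inf
    return math.log(2.0) - math.log(scale) - _LOG_SQRT_2PI - 0.5 * (x / scale) ** 2


def _normal_logpdf_sum(x: np.ndarray, sd: float) -> float:
    x = np.asarray(x, dtype=float)
    if sd == 0:
        return 0.0 if np.all(x == 0) else -np.inf
    return float(np.sum(-math.log(sd) - _LOG_SQRT_2PI - 0.5 * (x / sd) ** 2))


def log_prior(spec: ModelSpec, hyper: HyperParams, latent: LatentEffects) -> float:
    """Joint log prior of hyperparameters and centered random effects.

    Out-of-support SDs return ``-inf`` rather than raising, so samplers can
    probe freely.
    """
    if not (hyper.sigma_bar > 0) or hyper.sigma_M < 0 or hyper.sigma_V < 0 or hyper.sigma_S < 0:
        return -np.inf

    lp = 0.0
    # vague normal prior on the overall mean
    lp += -math.log(spec.prior_mu_sd) - _LOG_SQRT_2PI - 0.5 * (hyper.mu_bar / spec.prior_mu_sd) ** 2
    lp += _halfnormal_logpdf(hyper.sigma_bar, spec.prior_sigma_scale)
    lp += _halfnormal_logpdf(hyper.sigma_M, spec.prior_sigma_scale)
    if spec.has_varying_sd:
        lp += _halfnormal_logpdf(hyper.sigma_V, spec.prior_sigma_scale)
    if spec.has_species:
        lp += _halfnormal_logpdf(hyper.sigma_S, spec.prior_sigma_scale)
    if spec.has_origin:
        lp += -math.log(spec.prior_mu_sd) - _LOG_SQRT_2PI - 0.5 * (hyper.beta / spec.prior_mu_sd) ** 2

    lp += _normal_logpdf_sum(latent.eps_M, hyper.sigma_M)
    if spec.has_varying_sd:
        lp += _normal_logpdf_sum(latent.eps_V, hyper.sigma_V)
    if spec.has_species:
        lp += _normal_logpdf_sum(latent.eps_S, hyper.sigma_S)
    return lp


def log_posterior(spec: ModelSpec, hyper: HyperParams, latent: LatentEffects, table) -> float:
    """Unnormalized log posterior: ``log_likelihood + log_prior``; -inf propagates."""
    lp = log_prior(spec, hyper, latent)
    if not np.isfinite(lp):
        return -np.inf
    return lp + log_likelihood(spec, hyper, latent, table)
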
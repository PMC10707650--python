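"""Synthetic sample tables with the hierarchical structure the models assume.

Each generated individual carries a stand, a species, a stem origin and a
log-normal activity concentration whose log-scale mean decomposes into an
overall mean, an origin shift, a random stand effect and a random species
effect; the log-scale SD is common to all stands unless a varying-SD truth
(``sigma_V > 0``) is requested, in which case per-stand SD multipliers
``exp(eps_V)`` are drawn.  Setting ``sigma_V = 0`` reproduces the
common-SD data-generating process exactly.

:func:`default_survey_config` mirrors the structure of the Fukushima coppice
survey the models were designed for: 40 stands, five hardwood species with
strongly unequal frequencies (weights 184:111:86:30:7), hyperparameters at
the posterior point estimates of the all-species fit (overall mean 4.92,
within-stand SD 0.74, between-stand SD 1.33, species SD 0.62, origin
coefficient -0.39), and a detection limit placed so that about 7.7% of
records fall below it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .data_io import SampleTable
from .models import HyperParams

__all__ = [
    "GeneratorConfig",
    "TruthRecord",
    "generate",
    "default_survey_config",
    "SURVEY_SPECIES_WEIGHTS",
    "SURVEY_HYPERPARAMS",
]

# Species frequencies observed in the survey the default configuration emulates.
SURVEY_SPECIES_WEIGHTS: dict[str, int] = {
    "Quercus serrata": 184,
    "Cerasus jamasakura": 111,
    "Castanea crenata": 86,
    "Quercus acutissima": 30,
    "Zelkova serrata": 7,
}

# All-species posterior point estimates used as the default truth.  sigma_M
# uses the value 1.33 quoted in the survey's running text (the table prints
# 1.32; the difference is rounding).
SURVEY_HYPERPARAMS = HyperParams(
    mu_bar=4.92, sigma_bar=0.74, sigma_M=1.33, sigma_V=0.0, sigma_S=0.62, beta=-0.39
)


@dataclass
class GeneratorConfig:
    """Everything needed to draw one synthetic survey.

    Parameters
    ----------
    n_stands : number of stands.
    per_stand_n : individuals per stand — a single count or one count per stand.
    species_pool : species label -> sampling weight (weights are normalized).
    origin_prob : probability an individual is a plantation stem (origin 1).
    truth : hyperparameters of the data-generating process.
    detection_limit : activity (Bq kg^-1) below which a record is censored,
        or ``None`` for no censoring.
    seed : RNG seed; two runs with the same config are bit-identical.
    """

    n_stands: int = 40
    per_stand_n: int | Sequence[int] = 11
    species_pool: Mapping[str, float] = field(default_factory=lambda: dict(SURVEY_SPECIES_WEIGHTS))
    origin_prob: float = 0.25
    truth: HyperParams = field(default_factory=lambda: SURVEY_HYPERPARAMS)
    detection_limit: float | None = None
    seed: int = 0

    def counts(self) -> np.ndarray:
        if np.isscalar(self.per_stand_n):
            return np.full(self.n_stands, int(self.per_stand_n))
        c = np.asarray(self.per_stand_n, dtype=int)
        if c.size != self.n_stands:
            raise ValueError("per_stand_n vector length must equal n_stands")
        return c

    def normalized_weights(self) -> tuple[list[str], np.ndarray]:
        names = list(self.species_pool)
        w = np.asarray([self.species_pool[k] for k in names], dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("species weights must be non-negative and sum to a positive value")
        return names, w / w.sum()

    def validate(self) -> None:
        if self.n_stands <= 0 or int(np.sum(self.counts())) <= 0:
            raise ValueError("configuration must produce at least one stand and one individual")
        t = self.truth
        if not (t.sigma_bar > 0) or min(t.sigma_M, t.sigma_V, t.sigma_S) < 0:
            raise ValueError("truth SDs must be non-negative (sigma_bar strictly positive)")
        if not 0.0 <= self.origin_prob <= 1.0:
            raise ValueError("origin_prob must lie in [0, 1]")
        self.normalized_weights()


@dataclass
class TruthRecord:
    """The latent effects and hyperparameters behind one generated table."""

    hyper: HyperParams
    eps_M: dict[str, float]
    eps_V: dict[str, float]
    eps_S: dict[str, float]
    rng: str = "numpy.random.default_rng(PCG64)"
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "hyper": self.hyper.as_dict(),
            "eps_M": self.eps_M,
            "eps_V": self.eps_V,
            "eps_S": self.eps_S,
            "rng": self.rng,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        d = json.loads(Path(path).read_text())
        return cls(
            hyper=HyperParams(**d["hyper"]),
            eps_M=d["eps_M"],
            eps_V=d["eps_V"],
            eps_S=d["eps_S"],
            rng=d.get("rng", ""),
            seed=d.get("seed", 0),
        )


def generate(config: GeneratorConfig) -> tuple[SampleTable, TruthRecord]:
    """Draw one synthetic sample table and the truth behind it.

    Log activity of each individual is drawn from
    ``Normal(mu_bar + beta*O + eps_M[stand] + eps_S[species],
    (sigma_bar * exp(eps_V[stand]))^2)``; stand effects are drawn once per
    stand, species effects once per species (species are crossed with
    stands, not nested).  Records whose activity falls below the detection
    limit are marked censored and their activity withheld, as in real
    below-detection data.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    t = config.truth
    counts = config.counts()
    stand_ids = [f"S{k + 1:02d}" for k in range(config.n_stands)]
    species_names, weights = config.normalized_weights()

    eps_M = rng.normal(0.0, t.sigma_M, size=config.n_stands) if t.sigma_M > 0 else np.zeros(config.n_stands)
    eps_V = rng.normal(0.0, t.sigma_V, size=config.n_stands) if t.sigma_V > 0 else np.zeros(config.n_stands)
    eps_S = rng.normal(0.0, t.sigma_S, size=len(species_names)) if t.sigma_S > 0 else np.zeros(len(species_names))

    stand_idx = np.repeat(np.arange(config.n_stands), counts)
    n_total = stand_idx.size
    sp_idx = rng.choice(len(species_names), size=n_total, p=weights)
    origin = (rng.random(n_total) < config.origin_prob).astype(int)

    mu = t.mu_bar + t.beta * origin + eps_M[stand_idx] + eps_S[sp_idx]
    sd = t.sigma_bar * np.exp(eps_V[stand_idx])
    log_y = rng.normal(mu, sd)
    activity = np.exp(log_y)

    censored = (
        activity < config.detection_limit
        if config.detection_limit is not None
        else np.zeros(n_total, dtype=bool)
    )

    import pandas as pd

    df = pd.DataFrame(
        {
            "stand": [stand_ids[k] for k in stand_idx],
            "species": [species_names[k] for k in sp_idx],
            "origin": origin,
            "activity": np.where(censored, np.nan, activity),
            "censored": censored,
        }
    )
    table = SampleTable(df, provenance=f"synthetic(seed={config.seed})")
    truth = TruthRecord(
        hyper=t,
        eps_M=dict(zip(stand_ids, map(float, eps_M))),
        eps_V=dict(zip(stand_ids, map(float, eps_V))),
        eps_S=dict(zip(species_names, map(float, eps_S))),
        seed=config.seed,
    )
    return table, truth


def marginal_activity_quantile(config: GeneratorConfig, q: float) -> float:
    """Quantile of the marginal activity distribution implied by a config.

    Marginally over stand and species effects, log activity is a two-component
    normal mixture over origin (weights ``1 - p`` and ``p``) with common SD
    ``sqrt(sigma_bar^2 + sigma_M^2 + sigma_S^2)``; the quantile is found by
    root-finding on the mixture CDF and exponentiated.  Exact only for
    common-SD truths (``sigma_V = 0``).
    """
    t = config.truth
    if t.sigma_V != 0:
        raise ValueError("marginal quantile is closed-form only for sigma_V = 0 truths")
    p = config.origin_prob
    s = float(np.sqrt(t.sigma_bar**2 + t.sigma_M**2 + t.sigma_S**2))
    m0, m1 = t.mu_bar, t.mu_bar + t.beta

    def cdf(x: float) -> float:
        return (1 - p) * norm.cdf(x, m0, s) + p * norm.cdf(x, m1, s)

    lo = min(m0, m1) - 10 * s
    hi = max(m0, m1) + 10 * s
    x = brentq(lambda v: cdf(v) - q, lo, hi)
    return float(np.exp(x))


def default_survey_config(seed: int = 0, censored_fraction: float = 0.077) -> GeneratorConfig:
    """Configuration emulating the 40-stand, five-species hardwood survey.

    The detection limit is placed at the ``censored_fraction`` quantile of the
    marginal activity distribution so the expected share of below-detection
    records matches the survey's 7.7%.
    """
    config = GeneratorConfig(seed=seed)
    if censored_fraction > 0:
        config.detection_limit = marginal_activity_quantile(config, censored_fraction)
    return config
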
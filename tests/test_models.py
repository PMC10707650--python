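import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import halfnorm, norm

import shootcs as sc
from shootcs.models import FULL, MODEL1, MODEL2, LatentEffects, ModelData, model_spec
from shootcs.inference import _Packing, _unconstrained_log_prob, unconstrained_log_prob_reference


def _table(stands, activities, species=None, origin=None):
    n = len(stands)
    return sc.SampleTable.from_frame(
        pd.DataFrame(
            {
                "stand": stands,
                "species": species or ["oak"] * n,
                "origin": origin or [0] * n,
                "activity": activities,
                "censored": [False] * n,
            }
        )
    )


class TestLogLikelihood:
    def test_standard_normal_mode(self):
        table = _table(["A"], [math.e**1.0])  # log activity exactly 1.0
        hyper = sc.HyperParams(mu_bar=1.0, sigma_bar=1.0, sigma_M=1.0)
        latent = LatentEffects(eps_M=np.zeros(1))
        ll = sc.log_likelihood(MODEL1, hyper, latent, table)
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_matches_hand_summed_densities(self):
        table = _table(["A", "B"], [10.0, 5.0])
        hyper = sc.HyperParams(mu_bar=2.0, sigma_bar=0.7, sigma_M=1.0)
        latent = LatentEffects(eps_M=np.array([0.3, -0.4]))
        expected = norm.logpdf(math.log(10.0), 2.3, 0.7) + norm.logpdf(math.log(5.0), 1.6, 0.7)
        assert sc.log_likelihood(MODEL1, hyper, latent, table) == pytest.approx(expected)

    def test_varying_sd_reduces_to_common_sd(self, single_species_table):
        hyper1 = sc.HyperParams(mu_bar=5.0, sigma_bar=0.8, sigma_M=1.2)
        hyper2 = sc.HyperParams(mu_bar=5.0, sigma_bar=0.8, sigma_M=1.2, sigma_V=0.5)
        n_stands = len(single_species_table.stand_ids)
        eps_M = np.linspace(-1, 1, n_stands)
        l1 = sc.log_likelihood(MODEL1, hyper1, LatentEffects(eps_M=eps_M), single_species_table)
        l2 = sc.log_likelihood(
            MODEL2, hyper2, LatentEffects(eps_M=eps_M, eps_V=np.zeros(n_stands)), single_species_table
        )
        assert l2 == pytest.approx(l1)

    def test_full_model_offsets(self):
        table = _table(["A", "A"], [10.0, 10.0], species=["oak", "cherry"], origin=[0, 1])
        hyper = sc.HyperParams(mu_bar=2.0, sigma_bar=1.0, sigma_M=1.0, sigma_S=0.5, beta=-0.4)
        latent = LatentEffects(eps_M=np.zeros(1), eps_S=np.array([0.2, -0.1]))
        y = math.log(10.0)
        expected = norm.logpdf(y, 2.0 + 0.2, 1.0) + norm.logpdf(y, 2.0 - 0.4 - 0.1, 1.0)
        assert sc.log_likelihood(FULL, hyper, latent, table) == pytest.approx(expected)

    def test_censored_record_rejected(self):
        df = _table(["A"], [10.0]).to_frame()
        df.loc[0, "censored"] = True
        df.loc[0, "activity"] = np.nan
        with pytest.raises(ValueError, match="censored"):
            ModelData.from_table(sc.SampleTable(df))

    def test_record_order_invariance(self, single_species_table):
        hyper = sc.HyperParams(mu_bar=5.0, sigma_bar=0.8, sigma_M=1.2)
        n = len(single_species_table.stand_ids)
        latent = LatentEffects(eps_M=np.linspace(-1, 1, n))
        df = single_species_table.to_frame()
        shuffled = sc.SampleTable.from_frame(
            df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        )
        a = sc.log_posterior(MODEL1, hyper, latent, single_species_table)
        # stand first-appearance order changes, so map effects by stand id
        order = [single_species_table.stand_ids.index(s) for s in shuffled.stand_ids]
        b = sc.log_posterior(MODEL1, hyper, LatentEffects(eps_M=latent.eps_M[order]), shuffled)
        assert b == pytest.approx(a)

    def test_location_equivariance(self, single_species_table):
        shift = 2.5
        n = len(single_species_table.stand_ids)
        latent = LatentEffects(eps_M=np.linspace(-0.5, 0.5, n))
        df = single_species_table.to_frame()
        df["activity"] = df["activity"] * math.exp(shift)
        shifted = sc.SampleTable.from_frame(df)
        h0 = sc.HyperParams(mu_bar=5.0, sigma_bar=0.8, sigma_M=1.2)
        h1 = sc.HyperParams(mu_bar=5.0 + shift, sigma_bar=0.8, sigma_M=1.2)
        assert sc.log_likelihood(MODEL1, h1, latent, shifted) == pytest.approx(
            sc.log_likelihood(MODEL1, h0, latent, single_species_table)
        )


class TestLogPrior:
    def test_closed_form_density_sum(self):
        hyper = sc.HyperParams(mu_bar=0.0, sigma_bar=0.5, sigma_M=0.3)
        latent = LatentEffects(eps_M=np.zeros(4))
        expected = (
            norm.logpdf(0.0, 0, 100)
            + halfnorm.logpdf(0.5, scale=10)
            + halfnorm.logpdf(0.3, scale=10)
            + 4 * norm.logpdf(0.0, 0, 0.3)
        )
        assert sc.log_prior(MODEL1, hyper, latent) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "hyper",
        [
            sc.HyperParams(0, -0.1, 1.0),
            sc.HyperParams(0, 0.0, 1.0),
            sc.HyperParams(0, 1.0, -0.5),
        ],
    )
    def test_out_of_support_is_minus_inf(self, hyper):
        assert sc.log_prior(MODEL1, hyper, LatentEffects(eps_M=np.zeros(2))) == -np.inf

    def test_stand_count_additivity_at_zero(self):
        hyper = sc.HyperParams(mu_bar=0.0, sigma_bar=0.5, sigma_M=0.3)
        lp4 = sc.log_prior(MODEL1, hyper, LatentEffects(eps_M=np.zeros(4)))
        lp8 = sc.log_prior(MODEL1, hyper, LatentEffects(eps_M=np.zeros(8)))
        assert lp8 - lp4 == pytest.approx(4 * norm.logpdf(0.0, 0, 0.3))

    def test_full_model_includes_beta_and_species(self):
        hyper = sc.HyperParams(1.0, 0.5, 0.3, sigma_S=0.4, beta=-0.2)
        latent = LatentEffects(eps_M=np.zeros(2), eps_S=np.array([0.1, -0.1]))
        expected = (
            norm.logpdf(1.0, 0, 100)
            + halfnorm.logpdf(0.5, scale=10)
            + halfnorm.logpdf(0.3, scale=10)
            + halfnorm.logpdf(0.4, scale=10)
            + norm.logpdf(-0.2, 0, 100)
            + 2 * norm.logpdf(0.0, 0, 0.3)
            + norm.logpdf(0.1, 0, 0.4)
            + norm.logpdf(-0.1, 0, 0.4)
        )
        assert sc.log_prior(FULL, hyper, latent) == pytest.approx(expected)


class TestLogPosterior:
    def test_is_sum_of_parts(self, single_species_table):
        hyper = sc.HyperParams(5.0, 0.8, 1.2)
        latent = LatentEffects(eps_M=np.zeros(len(single_species_table.stand_ids)))
        assert sc.log_posterior(MODEL1, hyper, latent, single_species_table) == pytest.approx(
            sc.log_prior(MODEL1, hyper, latent)
            + sc.log_likelihood(MODEL1, hyper, latent, single_species_table)
        )

    def test_minus_inf_propagates(self, single_species_table):
        bad = sc.HyperParams(5.0, -1.0, 1.2)
        latent = LatentEffects(eps_M=np.zeros(len(single_species_table.stand_ids)))
        assert sc.log_posterior(MODEL1, bad, latent, single_species_table) == -np.inf

    def test_finite_at_generator_truth(self):
        cfg = sc.default_survey_config(seed=8)
        table, truth = sc.generate(cfg)
        kept, _ = sc.exclude_censored(table)
        data = ModelData.from_table(kept)
        latent = LatentEffects(
            eps_M=np.array([truth.eps_M[s] for s in data.stand_ids]),
            eps_S=np.array([truth.eps_S[s] for s in data.species_names]),
        )
        lp = sc.log_posterior(FULL, truth.hyper, latent, data)
        assert np.isfinite(lp)

    def test_sigma_v_limit_matches_model1(self, single_species_table):
        n = len(single_species_table.stand_ids)
        latent1 = LatentEffects(eps_M=np.linspace(-1, 1, n))
        latent2 = LatentEffects(eps_M=latent1.eps_M, eps_V=np.full(n, 1e-12))
        h1 = sc.HyperParams(5.0, 0.8, 1.2)
        h2 = sc.HyperParams(5.0, 0.8, 1.2, sigma_V=1e-12)
        l1 = sc.log_likelihood(MODEL1, h1, latent1, single_species_table)
        l2 = sc.log_likelihood(MODEL2, h2, latent2, single_species_table)
        assert l2 == pytest.approx(l1, abs=1e-8)


class TestModelSpecLookup:
    def test_known_names(self):
        assert model_spec("model1") is MODEL1
        assert model_spec("model2").has_varying_sd
        assert model_spec("full").has_species and model_spec("full").has_origin

    def test_unknown_name(self):
        with pytest.raises(ValueError, match="unknown model"):
            model_spec("model3")


class TestSamplerDensityEquivalence:
    """The sampler's collapsed density must equal the centered contract via
    the exact identity p(theta) = p(theta, eps_M) / p(eps_M | theta), for
    every model variant and for arbitrary eps_M values."""

    @pytest.mark.parametrize("name", ["model1", "model2", "full"])
    def test_vectorized_matches_reference(self, name):
        spec = model_spec(name)
        cfg = sc.GeneratorConfig(
            n_stands=6,
            per_stand_n=4,
            species_pool={"oak": 2.0, "cherry": 1.0},
            origin_prob=0.5,
            truth=sc.HyperParams(5.0, 0.7, 1.2, sigma_V=0.3, sigma_S=0.5, beta=-0.4),
            seed=21,
        )
        table, _ = sc.generate(cfg)
        data = ModelData.from_table(table)
        pack = _Packing(spec, data)
        rng = np.random.default_rng(3)
        theta = rng.normal(0, 0.7, size=(5, pack.ndim))
        vec = _unconstrained_log_prob(theta, pack)
        ref_zero = np.array([unconstrained_log_prob_reference(row, spec, data) for row in theta])
        np.testing.assert_allclose(vec, ref_zero, rtol=1e-10)
        # the identity holds for any eps_M: a random eps_M must give the
        # same collapsed density as eps_M = 0
        ref_rand = np.array(
            [
                unconstrained_log_prob_reference(
                    row, spec, data, eps_M=rng.normal(0, 2.0, data.n_stands)
                )
                for row in theta
            ]
        )
        np.testing.assert_allclose(vec, ref_rand, rtol=1e-10)
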
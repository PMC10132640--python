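import numpy as np
import pytest

from paleoiso.diet_model import (
    ConsumerObservation,
    DietPosterior,
    FitConfig,
    OffsetSpec,
    RoutingSpec,
    fit_diet,
    marine_fraction_for_calibration,
    predict_signals,
    summarize_posterior,
)
from paleoiso.foodweb import FoodGroup

FAST = FitConfig(n_iter=4000, burn_steps=500, n_walkers=40, seed=0)


def make_group(name, d13c_p, d13c_e, d15n, protein=50.0, sds=0.0):
    bulk = (protein * d13c_p + (100 - protein) * d13c_e) / 100
    return FoodGroup(
        name=name,
        n_items=1,
        protein_pct=protein,
        protein_pct_sd=sds,
        energy_pct=100 - protein,
        energy_pct_sd=sds,
        d13C_bulk=bulk,
        d13C_bulk_sd=sds,
        d13C_protein=d13c_p,
        d13C_protein_sd=sds,
        d13C_energy=d13c_e,
        d13C_energy_sd=sds,
        d15N_protein=d15n,
        d15N_protein_sd=sds,
    )


class TestPredictSignals:
    def test_pure_c3_diet_single_source_limits(self, groups):
        co, n15, ap = predict_signals([1, 0, 0, 0, 0], groups)
        assert n15 == pytest.approx(3.3 + 3.6)
        assert ap == pytest.approx(-25.5 + 10.1)
        # routed collagen: 74% protein, 26% energy plus configured offset
        assert co == pytest.approx(0.74 * -26.5 + 0.26 * -25.3 + 4.8, abs=1e-6)

    def test_diet_must_lie_on_simplex(self, groups):
        with pytest.raises(ValueError):
            predict_signals([0.5, 0.5, 0.5, 0, 0], groups)

    def test_zero_protein_diet_rejected(self):
        g = [
            make_group("A", -20, -25, 5, protein=0.0),
            make_group("B", -10, -15, 8, protein=0.0),
        ]
        with pytest.raises(ValueError, match="protein"):
            predict_signals([0.5, 0.5], g)


class TestFitDiet:
    def test_draws_close_on_simplex_and_means_sum_to_100(self, groups):
        c = ConsumerObservation("B1", d13C_co=-14.9, d15N_co=9.5, d13C_ap=-6.3)
        post = fit_diet(c, groups, config=FAST)
        sums = post.draws.sum(axis=1)
        assert np.all(np.abs(sums - 1.0) < 1e-9)
        assert np.all(post.draws >= 0)
        assert post.means.sum() * 100 == pytest.approx(100.0, abs=0.1)

    @pytest.mark.parametrize(
        "prior,prior_sd", [("normalized_uniform", 0.113), ("dirichlet", 0.163)]
    )
    def test_prior_predictive_means_are_twenty_percent(self, groups, prior, prior_sd):
        """With every proxy missing the posterior is the prior: exchangeable
        group means of 20% each, and the marginal spread of the respective
        prior (Dirichlet(1): sqrt(0.2*0.8/6); normalized uniforms: ~0.113)."""
        c = ConsumerObservation("blank")
        cfg = FitConfig(n_iter=20000, burn_steps=1500, n_walkers=40, seed=3, prior=prior)
        post = fit_diet(c, groups, config=cfg)
        assert post.dropped_proxies == ("d13C_co", "d15N_co", "d13C_ap")
        assert np.allclose(post.means, 0.2, atol=0.04)
        assert np.allclose(post.sds, prior_sd, atol=0.02)

    def test_identical_sources_get_equal_shares(self):
        g = [
            make_group("A", -18, -24, 6, sds=1.0),
            make_group("B", -18, -24, 6, sds=1.0),
        ]
        co, n15, ap = predict_signals([0.5, 0.5], g)
        c = ConsumerObservation("sym", d13C_co=co, d15N_co=n15, d13C_ap=ap)
        post = fit_diet(c, g, config=FAST)
        assert post.means[0] == pytest.approx(post.means[1], abs=0.03)

    def test_two_source_one_proxy_matches_linear_unmixing(self):
        """Zero source uncertainty, one proxy: the posterior concentrates on
        the closed-form unmixing solution alpha_A*4 + alpha_B*8 = 5."""
        g = [
            make_group("A", -20, -20, 4.0, protein=100.0),
            make_group("B", -20, -20, 8.0, protein=100.0),
        ]
        offs = OffsetSpec(
            d13C_ap_offset_sd=0.0, d15N_offset=0.0, d15N_offset_sd=0.0,
            d13C_co_offset_sd=0.0,
        )
        routing = RoutingSpec(collagenC_protein_frac_sd=0.0)
        c = ConsumerObservation("toy", d15N_co=5.0, sd_d15N_co=0.02)
        post = fit_diet(c, g, routing=routing, offsets=offs, config=FAST)
        hist, edges = np.histogram(post.draws[:, 0], bins=60, range=(0, 1))
        mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        assert mode == pytest.approx(0.75, abs=0.01)

    def test_missing_proxy_dropped_and_recorded(self, groups):
        c = ConsumerObservation("m", d13C_co=-18.3, d15N_co=8.9, d13C_ap=None)
        post = fit_diet(c, groups, config=FAST)
        assert post.dropped_proxies == ("d13C_ap",)

    def test_reproducible_under_fixed_seed(self, groups):
        c = ConsumerObservation("B4", d13C_co=-15.1, d15N_co=9.3, d13C_ap=-5.7)
        a = fit_diet(c, groups, config=FAST)
        b = fit_diet(c, groups, config=FAST)
        assert np.array_equal(a.draws, b.draws)

    def test_forward_inverse_consistency(self, groups):
        """A consumer generated noise-free at the source means yields a
        posterior whose mean-diet prediction brackets the input signals."""
        truth = np.array([0.3, 0.1, 0.3, 0.1, 0.2])
        co, n15, ap = predict_signals(truth, groups)
        c = ConsumerObservation("fw", d13C_co=co, d15N_co=n15, d13C_ap=ap)
        post = fit_diet(c, groups, config=FAST)
        pred = predict_signals(post.means / post.means.sum(), groups)
        for have, got in zip((co, n15, ap), pred):
            assert got == pytest.approx(have, abs=1.5)


class TestSummaries:
    def make_posterior(self, means):
        draws = np.tile(np.asarray(means, dtype=float), (2000, 1))
        return DietPosterior(
            burial_id="t",
            group_names=("C3", "C4CAM", "FWTERR", "M1", "M2"),
            draws=draws,
        )

    def test_ratios_match_published_convention(self):
        # terrestrial:marine 30.9/(11.8+13.7) -> 1.2; C3:C4 37.5/14.3 -> 2.6
        row = summarize_posterior(self.make_posterior([.264, .172, .309, .118, .137]))
        assert row["terr_marine_ratio"] == 1.2
        row2 = summarize_posterior(self.make_posterior([.375, .143, .268, .121, .094]))
        assert row2["c3_c4_ratio"] == 2.6

    def test_degenerate_posterior_has_zero_sd(self):
        row = summarize_posterior(self.make_posterior([.2, .2, .2, .2, .2]))
        assert row["C3_sd"] == pytest.approx(0.0, abs=1e-9)

    def test_zero_denominator_reported_as_undefined(self):
        row = summarize_posterior(self.make_posterior([.5, 0.0, .5, 0.0, 0.0]))
        assert row["c3_c4_ratio"] is None
        assert row["terr_marine_ratio"] is None

    def test_requires_enough_draws(self):
        small = DietPosterior(
            burial_id="t",
            group_names=("C3", "C4CAM", "FWTERR", "M1", "M2"),
            draws=np.full((10, 5), 0.2),
        )
        with pytest.raises(ValueError):
            summarize_posterior(small)

    def test_marine_fraction_additivity(self):
        post = self.make_posterior([.3, .3, .2, .1, .1])
        m, sd = marine_fraction_for_calibration(post)
        assert m == pytest.approx(0.2)
        assert sd == pytest.approx(0.0)
        assert np.allclose(post.marine_draws, post.draws[:, 3] + post.draws[:, 4])

    def test_all_terrestrial_posterior_has_zero_marine(self):
        post = self.make_posterior([.4, .3, .3, 0.0, 0.0])
        assert marine_fraction_for_calibration(post) == (0.0, 0.0)
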
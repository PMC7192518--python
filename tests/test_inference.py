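import numpy as np
import pandas as pd
import pytest

from valueddm import ddm_core as dc
from valueddm import inference as inf
from valueddm.synthetic_cohort import CohortConfig, GroupHyper, generate_cohort
from valueddm.value_models import sv_risky, sv_temporal


class TestBuildModel:
    @pytest.mark.parametrize("task,variant,n", [
        ("TD", "ddms", 7), ("PD", "ddms", 6), ("TD", "ddm0", 4),
        ("PD", "ddm0", 4), ("TD", "ddmlin", 6), ("PD", "ddmlin", 5),
        ("TD", "softmax", 3), ("PD", "softmax", 2),
        ("TD", "mixture", 12), ("PD", "mixture", 11),
    ])
    def test_subject_parameter_counts(self, task, variant, n):
        assert len(inf.build_model(task, variant).params) == n

    def test_mixture_contains_both_component_sets_plus_lambda(self):
        p = inf.build_model("TD", "mixture").params
        assert {"alpha", "tau", "z", "v_coeff", "v_max",
                "alpha_0", "tau_0", "z_0", "v_0", "lambda_z"} <= set(p)

    def test_prior_table_covers_exactly_the_variant_parameters(self):
        spec = inf.build_model("PD", "ddms")
        assert list(spec.prior_table["parameter"]) == list(spec.params)
        row = spec.prior_table.set_index("parameter").loc["alpha"]
        assert row["group_mean_prior"] == "Uniform(0.01, 5.0)"
        assert row["group_precision_prior"] == "Gamma(0.001, 0.001)"

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            inf.build_model("TD", "bogus")


def _toy_data(task="TD"):
    rows = []
    srt = [1.4, -2.1, 3.0]
    for i, s in enumerate(srt):
        if task == "TD":
            rows.append({"subject_id": "s1", "group": "controls",
                         "trial_index": i, "signed_rt": s, "rt": abs(s),
                         "boundary": "upper" if s > 0 else "lower",
                         "amount_ll": [20.0, 50.0, 11.0][i], "amount_ss": 10.0,
                         "iri": [5.0, 30.0, 1.0][i], "condition_I": [0, 1, 0][i]})
    return pd.DataFrame(rows)


class TestLogLikelihood:
    PARAMS = dict(alpha=2.5, tau=0.6, z=0.5, v_coeff=0.4, v_max=1.8,
                  log_k_now=-3.0, shift_logk=0.8)

    def _params_df(self, **over):
        row = {"subject_id": "s1", **self.PARAMS, **over}
        return pd.DataFrame([row])

    def test_toy_dataset_matches_wiener_density_oracle(self):
        data = _toy_data()
        spec = inf.build_model("TD", "ddms")
        ll = inf.log_likelihood(data, self._params_df(), spec)
        sv = sv_temporal(data, self.PARAMS["log_k_now"], self.PARAMS["shift_logk"])
        drift = dc.drift_sigmoid(sv - 10.0, self.PARAMS["v_coeff"], self.PARAMS["v_max"])
        p = dc.DDMParams(self.PARAMS["alpha"], self.PARAMS["tau"], self.PARAMS["z"])
        expected = dc.wfpt_logdensity(data["signed_rt"].to_numpy(), p, drift)
        assert np.allclose(ll, expected, rtol=1e-12)
        assert np.isfinite(ll.sum())

    def test_mixture_collapses_to_sigmoid_component_at_lambda_one(self):
        data = _toy_data()
        mix = self._params_df(alpha_0=2.0, tau_0=0.5, z_0=0.5, v_0=0.3,
                              lambda_z=40.0)
        ll_mix = inf.log_likelihood(data, mix, inf.build_model("TD", "mixture"))
        ll_s = inf.log_likelihood(data, self._params_df(),
                                  inf.build_model("TD", "ddms"))
        assert np.array_equal(ll_mix, ll_s)

    def test_mixture_collapses_to_null_component_at_lambda_zero(self):
        data = _toy_data()
        mix = self._params_df(alpha_0=2.0, tau_0=0.5, z_0=0.45, v_0=0.3,
                              lambda_z=-40.0)
        null = pd.DataFrame([{"subject_id": "s1", "alpha": 2.0, "tau": 0.5,
                              "z": 0.45, "v": 0.3}])
        ll_mix = inf.log_likelihood(data, mix, inf.build_model("TD", "mixture"))
        ll_0 = inf.log_likelihood(data, null, inf.build_model("TD", "ddm0"))
        assert np.array_equal(ll_mix, ll_0)

    def test_fast_rt_contributes_minus_infinity_not_an_exception(self):
        data = _toy_data()
        ll = inf.log_likelihood(data, self._params_df(tau=1.5),
                                inf.build_model("TD", "ddms"))
        assert ll[0] == -np.inf and np.isfinite(ll[2])


class TestRhat:
    def test_identical_chains_give_exactly_one(self):
        assert inf.rhat(np.ones((2, 100))) == 1.0
        # identical stationary chains: no between-chain disagreement
        noise = np.random.default_rng(3).standard_normal(400)
        assert inf.rhat(np.tile(noise, (2, 1))) == pytest.approx(1.0, abs=0.01)

    def test_offset_chain_detected(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 500))
        x[1] += 50.0
        assert inf.rhat(x) > 5.0

    def test_matches_reference_implementation(self):
        import arviz as az
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 1000)) + np.array([[0.0], [0.3]])
        ours = inf.rhat(x)
        theirs = float(az.rhat(az.convert_to_dataset(x), method="split")["x"].values)
        assert ours == pytest.approx(theirs, rel=1e-10)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            inf.rhat(np.zeros((1, 100)))


class TestFitHierarchical:
    def test_identical_seed_and_config_give_identical_draws(self):
        b = generate_cohort(CohortConfig(task="PD", design_size="reduced",
                                         n_patients=2, n_controls=3), seed=4)
        mc = inf.MCMCConfig(chains=2, warmup=150, draws=150)
        spec = inf.build_model("PD", "ddms")
        p1 = inf.fit_hierarchical(b.merged(), spec, mc, seed=5)
        p2 = inf.fit_hierarchical(b.merged(), spec, mc, seed=5)
        assert np.array_equal(p1.subject, p2.subject)
        assert np.array_equal(p1.mu, p2.mu)
        assert np.array_equal(p1.log_sd, p2.log_sd)

    def test_posterior_mass_respects_prior_supports(self, pd_ddms_fit):
        post = pd_ddms_fit
        from valueddm._params import PARAM_TABLE
        for j, name in enumerate(post.param_names):
            lo, hi, _ = PARAM_TABLE[name]
            assert post.subject[:, :, :, j].min() >= lo
            assert post.subject[:, :, :, j].max() <= hi
            assert post.mu[:, :, :, j].min() >= lo
            assert post.mu[:, :, :, j].max() <= hi

    def test_retained_draw_count_matches_config(self, pd_ddms_fit):
        assert pd_ddms_fit.mu.shape[:2] == (2, 600)
        assert pd_ddms_fit.meta["chains"] == 2

    def test_group_mean_posteriors_concentrate_near_truth(self, pd_cohort, pd_ddms_fit):
        # high-information check on the best-identified parameters
        for name in ("tau", "z", "v_max"):
            for group in ("patients", "controls"):
                draws = pd_ddms_fit.group_mean(name, group).ravel()
                true = pd_cohort.config.hyper[group].means[name]
                assert abs(draws.mean() - true) < 4 * draws.std() + 0.1

    def test_split_rhat_within_acceptable_range_on_desk_cohort(self, pd_cohort):
        post = inf.fit_hierarchical(
            pd_cohort.merged(), inf.build_model("PD", "ddms"),
            inf.MCMCConfig(chains=2, warmup=2000, draws=6000), seed=0)
        worst = post.rhat()["rhat"].max()
        assert 1.0 <= worst <= 1.01

    def test_softmax_inverse_temperature_recovers_monotonically(self):
        est = []
        for beta in (0.05, 0.3, 1.5):
            hyper = {"patients": GroupHyper.default_patients(),
                     "controls": GroupHyper.default_controls()}
            for g in hyper:
                hyper[g].means["beta"] = beta
            cfg = CohortConfig(task="PD", variant="softmax", design_size="reduced",
                               n_patients=4, n_controls=6, hyper=hyper)
            b = generate_cohort(cfg, seed=2)
            post = inf.fit_hierarchical(b.merged(), inf.build_model("PD", "softmax"),
                                        inf.MCMCConfig(chains=2, warmup=400, draws=400),
                                        seed=2)
            est.append(np.mean([post.group_mean("beta", g).mean()
                                for g in ("patients", "controls")]))
        assert est[0] < est[1] < est[2]

    def test_too_few_subjects_per_group_rejected(self):
        b = generate_cohort(CohortConfig(task="PD", design_size="reduced",
                                         n_patients=1, n_controls=3), seed=0)
        with pytest.raises(ValueError, match="fewer than 2"):
            inf.fit_hierarchical(b.merged(), inf.build_model("PD", "ddms"),
                                 inf.MCMCConfig(chains=2, warmup=10, draws=10), seed=0)

    def test_unknown_group_label_rejected(self):
        data = _toy_data().assign(group="cases")
        with pytest.raises(ValueError, match="unknown group"):
            inf.fit_hierarchical(data, inf.build_model("TD", "ddms"),
                                 inf.MCMCConfig(chains=2, warmup=10, draws=10), seed=0)


class TestPosteriorSerialization:
    def test_round_trip(self, pd_ddms_fit, tmp_path):
        pd_ddms_fit.save(tmp_path / "post")
        loaded = inf.PosteriorSamples.load(tmp_path / "post")
        assert np.array_equal(loaded.mu, pd_ddms_fit.mu)
        assert loaded.param_names == pd_ddms_fit.param_names
        assert loaded.subject_ids == pd_ddms_fit.subject_ids
        ll_a = loaded.pointwise_loglik(max_draws=10)
        ll_b = pd_ddms_fit.pointwise_loglik(max_draws=10)
        assert np.allclose(ll_a, ll_b)
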
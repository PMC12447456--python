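"""Sampler correctness against closed-form and grid oracles; imputation."""

import numpy as np
import pytest

from idiodbn.cohort import DEFAULT_PARAMS, GroundTruth, simulate_cohort, simulate_participant
from idiodbn.daily_data import DailySeries, standardize
from idiodbn.dbn import PriorConfig, default_structure
from idiodbn.inference import (
    InferenceError,
    McmcConfig,
    _node_design,
    conjugate_posterior_oracle,
    fit_participant,
    grid_posterior_oracle,
    grid_tv_distance,
)

from conftest import make_series


class TestConjugateOracle:
    def test_no_data_returns_prior(self):
        mean, cov = conjugate_posterior_oracle(
            np.empty((0, 2)), np.empty(0), noise_sd=1.0, prior_mean=[0.5, -1.0], prior_sd=2.0
        )
        np.testing.assert_allclose(mean, [0.5, -1.0])
        np.testing.assert_allclose(cov, np.diag([4.0, 4.0]))

    def test_single_observation_halves(self):
        # x=1, y=1, sigma=1, prior N(0,1): precision 2, mean 1/2
        mean, cov = conjugate_posterior_oracle(np.array([[1.0]]), np.array([1.0]), 1.0)
        assert mean[0] == pytest.approx(0.5)
        assert cov[0, 0] == pytest.approx(0.5)

    def test_zero_response_symmetric(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        mean, _ = conjugate_posterior_oracle(X, np.zeros(20), 1.0)
        np.testing.assert_allclose(mean, 0.0, atol=1e-12)

    def test_invalid_noise_sd(self):
        with pytest.raises(InferenceError):
            conjugate_posterior_oracle(np.array([[1.0]]), np.array([1.0]), 0.0)


class TestGridOracle:
    def _fixture(self, n_days=16, missing=None, seed=21):
        truth = GroundTruth(params=dict(DEFAULT_PARAMS))
        s = simulate_participant(truth, n_days=n_days, seed=seed)
        if missing:
            vals = {k: v.copy() for k, v in s.values.items()}
            for var, k in missing:
                vals[var][k] = np.nan
            s = DailySeries(s.participant_id, s.group, s.dates, vals)
        return s

    def _fixed_except(self, *free):
        structure = default_structure()
        return {
            nm: DEFAULT_PARAMS.get(nm, 0.0)
            for nm in structure.parameter_names()
            if nm not in free
        }

    def test_normalizes(self):
        s = self._fixture()
        gp = grid_posterior_oracle(
            s, default_structure(), PriorConfig(),
            {"wB": np.linspace(-1, 1.5, 61)}, self._fixed_except("wB"),
        )
        assert gp.probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_conjugate_closed_form(self):
        """Two independent oracles agree on the fully observed case."""
        s = self._fixture()
        structure = default_structure()
        fixed = self._fixed_except("wB")
        grid = np.linspace(-1.0, 1.8, 201)
        gp = grid_posterior_oracle(s, structure, PriorConfig(), {"wB": grid}, fixed)
        std = standardize(s)
        filled = {k: v.copy() for k, v in std.values.items()}
        X, y = _node_design(structure.node("B"), filled)
        # conditional on the fixed bias: regress y - bB on the lagged column
        y_adj = y - fixed["bB"]
        mean, cov = conjugate_posterior_oracle(
            X[:, :1], y_adj, noise_sd=fixed["sigma_B"]
        )
        from scipy.stats import norm

        dens = norm.pdf(grid, mean[0], np.sqrt(cov[0, 0]))
        dens /= dens.sum()
        assert 0.5 * np.abs(dens - gp.probs).sum() < 0.01

    def test_too_many_free_parameters(self):
        s = self._fixture()
        with pytest.raises(InferenceError):
            grid_posterior_oracle(
                s, default_structure(), PriorConfig(),
                {"wB": np.r_[0.0], "wR": np.r_[0.0], "wPV": np.r_[0.0]},
                self._fixed_except("wB", "wR", "wPV"),
            )


class TestFitParticipant:
    def test_same_seed_identical_draws(self):
        truth = GroundTruth(params=dict(DEFAULT_PARAMS))
        s = simulate_participant(truth, n_days=80, seed=13)
        cfg = McmcConfig(n_draws=60, n_warmup=40, seed=99)
        a = fit_participant(s, cfg=cfg)
        b = fit_participant(s, cfg=cfg)
        np.testing.assert_array_equal(a.draws, b.draws)
        assert a.columns == b.columns

    def test_fully_observed_has_no_imputation_columns(self):
        truth = GroundTruth(params=dict(DEFAULT_PARAMS))
        s = simulate_participant(truth, n_days=60, seed=14)
        post = fit_participant(s, cfg=McmcConfig(n_draws=50, n_warmup=20, seed=1))
        assert post.missing_index == {}
        assert not any(c.startswith("imp_") for c in post.columns)

    def test_imputation_columns_match_missing_entries(self):
        s = make_series(40)
        s.values["B"][[3, 17, 30]] = np.nan
        post = fit_participant(s, cfg=McmcConfig(n_draws=50, n_warmup=20, seed=2))
        assert list(post.missing_index["B"]) == [3, 17, 30]
        assert [c for c in post.columns if c.startswith("imp_")] == [
            "imp_B_3", "imp_B_17", "imp_B_30",
        ]

    def test_noise_sd_draws_positive(self):
        truth = GroundTruth(params=dict(DEFAULT_PARAMS))
        s = simulate_participant(truth, n_days=60, seed=15)
        post = fit_participant(s, cfg=McmcConfig(n_draws=100, n_warmup=50, seed=3))
        for nm in default_structure().noise_sd_names():
            assert (post.col(nm) > 0).all()

    def test_ineligible_series_rejected(self):
        s = make_series(20)
        s.values["B"][:10] = np.nan  # 50% missing
        with pytest.raises(InferenceError, match="ineligible"):
            fit_participant(s, cfg=McmcConfig(n_draws=10, n_warmup=0, seed=0))

    def test_conjugate_posterior_recovered(self):
        """Fixed noise SDs: coefficient posteriors match the closed form."""
        truth = GroundTruth(params=dict(DEFAULT_PARAMS))
        s = simulate_participant(truth, n_days=60, seed=16)
        structure = default_structure()
        fixed = {nm: 0.8 for nm in structure.noise_sd_names()}
        post = fit_participant(
            s, cfg=McmcConfig(n_draws=1500, n_warmup=100, seed=4), fixed_params=fixed
        )
        std = standardize(s)
        filled = {k: v.copy() for k, v in std.values.items()}
        for name, spec in structure.nodes.items():
            X, y = _node_design(spec, filled)
            mean, cov = conjugate_posterior_oracle(X, y, 0.8)
            names = list(spec.weight_names) + [spec.bias_name]
            for i, nm in enumerate(names):
                assert abs(post.mean(nm) - mean[i]) < 3 * post.mcse(nm)
                sd_se = post.sd(nm) / np.sqrt(2 * post.ess(nm))
                assert abs(post.sd(nm) - np.sqrt(cov[i, i])) < 3 * sd_se

    def test_sampler_matches_grid_with_missing_value(self):
        """One free weight + one missing value: marginal agrees with the grid."""
        truth = GroundTruth(params=dict(DEFAULT_PARAMS))
        s = simulate_participant(truth, n_days=20, seed=17)
        vals = {k: v.copy() for k, v in s.values.items()}
        vals["B"][7] = np.nan
        s = DailySeries(s.participant_id, s.group, s.dates, vals)
        structure = default_structure()
        fixed = {
            nm: DEFAULT_PARAMS.get(nm, 0.0)
            for nm in structure.parameter_names()
            if nm != "wB"
        }
        grid = np.linspace(-1.2, 1.6, 141)
        gp = grid_posterior_oracle(s, structure, PriorConfig(), {"wB": grid}, fixed)
        post = fit_participant(
            s, cfg=McmcConfig(n_draws=6000, n_warmup=300, seed=5), fixed_params=fixed
        )
        assert grid_tv_distance(gp, "wB", post.col("wB")) < 0.08

    def test_imputations_track_held_out_truth(self):
        """Posterior-mean imputations correlate with the hidden values.

        Busyness carries enough dynamic signal (self-lag 0.4 plus observed
        children) for r > 0.5; restedness's weaker dynamics cap its ceiling
        lower, so the per-variable floor is 0.2 and the pooled floor 0.4.
        """
        cohort = simulate_cohort(seed=2)[:6]
        pooled_m, pooled_t = [], []
        by_var = {v: ([], []) for v in ("B", "R", "FS")}
        for i, (s, _) in enumerate(cohort):
            post = fit_participant(s, cfg=McmcConfig(n_draws=400, n_warmup=400, seed=50 + i))
            for var, idx in post.missing_index.items():
                mu, sd = post.scales[var]
                for k in idx:
                    t = (s.masked_truth[var][k] - mu) / sd
                    m = float(post.col(f"imp_{var}_{k}").mean())
                    pooled_m.append(m)
                    pooled_t.append(t)
                    by_var[var][0].append(m)
                    by_var[var][1].append(t)
        assert np.corrcoef(pooled_m, pooled_t)[0, 1] > 0.4
        assert np.corrcoef(*by_var["B"])[0, 1] > 0.5
        for var, (m, t) in by_var.items():
            assert np.corrcoef(m, t)[0, 1] > 0.2
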
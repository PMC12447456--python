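"""Structure, linear conditional means, priors, and the joint log density."""

import math

import numpy as np
import pytest
from scipy import stats

from idiodbn.daily_data import standardize
from idiodbn.dbn import (
    DBNStructure,
    ModelError,
    NodeSpec,
    PriorConfig,
    conditional_mean,
    default_structure,
    log_joint,
    validate_structure,
    zero_params,
)

from conftest import make_series


class TestDefaultStructure:
    def test_full_hypothesis_set(self):
        s = default_structure()
        assert len(s.node("FS").parents) == 7
        assert s.node("B").parents == (("B", 1),)
        assert s.node("R").parents == (("R", 1),)
        assert ("PV", 1) in s.node("FS").parents
        assert "t_pvfs" in s.alias_map

    def test_printed_equation_form(self):
        s = default_structure(include_temp_on_pv=False, include_lagged_pv_on_fs=False)
        assert len(s.node("FS").parents) == 6
        assert len(s.node("PV").parents) == 5
        assert ("T", 0) not in s.node("PV").parents
        assert ("PV", 1) not in s.node("FS").parents
        assert "t_pvfs" not in s.alias_map

    def test_default_is_valid(self):
        assert validate_structure(default_structure()) == []

    def test_every_node_has_own_lag(self):
        s = default_structure()
        for name, spec in s.nodes.items():
            assert (name, 1) in spec.parents

    def test_aliases_point_at_existing_edges(self):
        s = default_structure()
        for alias, (node, (parent, lag)) in s.alias_map.items():
            assert s.weight_for_edge(node, parent, lag)

    def test_yaml_round_trip(self, tmp_path):
        s = default_structure()
        path = tmp_path / "structure.yaml"
        s.to_yaml(path)
        back = DBNStructure.from_yaml(path)
        assert back.to_dict() == s.to_dict()

    def test_prior_config_round_trip(self):
        pc = PriorConfig(weight_sd=0.5, normal_overrides={"wB": (0.2, 0.3)}, rate_overrides={"sigma_B": 2.0})
        back = PriorConfig.from_dict(pc.to_dict())
        assert back.normal("wB") == (0.2, 0.3)
        assert back.normal("wR") == (0.0, 0.5)
        assert back.rate("sigma_B") == 2.0


class TestValidateStructure:
    def test_lag0_two_cycle(self):
        s = default_structure()
        pv = s.node("PV")
        s.nodes["PV"] = NodeSpec(
            "PV", pv.parents + (("FS", 0),), pv.weight_names + ("wPVFS",),
            pv.bias_name, pv.noise_sd_name,
        )
        assert any("cycle" in v for v in validate_structure(s))

    def test_unknown_parent(self):
        s = default_structure()
        b = s.node("B")
        s.nodes["B"] = NodeSpec("B", (("steps", 1),), ("wB",), "bB", "sigma_B")
        assert any("unknown parent" in v for v in validate_structure(s))

    def test_duplicate_weight_names(self):
        s = default_structure()
        r = s.node("R")
        s.nodes["R"] = NodeSpec("R", r.parents, ("wB",), "bR", "sigma_R")
        assert any("duplicate weight" in v for v in validate_structure(s))

    def test_self_lag0_parent_rejected(self):
        with pytest.raises(ModelError):
            NodeSpec("B", (("B", 0),), ("wB",), "bB", "sigma_B")


class TestConditionalMean:
    def _data(self, n=4):
        return {k: np.linspace(0, 1, n) for k in ("B", "R", "PV", "FS", "MS", "T", "W")}

    def test_single_parent(self):
        s = default_structure()
        params = zero_params(s)
        params["wB"] = 0.5
        data = self._data()
        data["B"] = np.array([1.0, 0.0, 0.0, 0.0])
        assert conditional_mean(s.node("B"), params, data, 1) == pytest.approx(0.5)

    def test_intercept_only(self):
        s = default_structure()
        params = zero_params(s)
        params["bPV"] = 0.1
        for k in (1, 2, 3):
            assert conditional_mean(s.node("PV"), params, self._data(), k) == pytest.approx(0.1)

    def test_hand_summed_combination(self):
        s = default_structure()
        params = zero_params(s)
        params.update({"wPV": 0.3, "wPVBU": -0.2, "bPV": 0.1})
        data = {k: np.zeros(3) for k in ("B", "R", "PV", "FS", "MS", "T", "W")}
        data["PV"][0] = 1.0
        data["B"][1] = 0.5
        # 0.3*1 - 0.2*0.5 + 0.1 = 0.3
        assert conditional_mean(s.node("PV"), params, data, 1) == pytest.approx(0.3)

    def test_day_zero_is_not_modeled(self):
        s = default_structure()
        with pytest.raises(ModelError):
            conditional_mean(s.node("B"), zero_params(s), self._data(), 0)

    @pytest.mark.parametrize("alpha,beta", [(2.0, 0.0), (0.5, 0.5), (-1.0, 3.0)])
    def test_linear_in_parameters(self, alpha, beta):
        s = default_structure()
        rng = np.random.default_rng(4)
        data = {k: rng.normal(size=5) for k in ("B", "R", "PV", "FS", "MS", "T", "W")}
        spec = s.node("FS")
        names = list(spec.weight_names) + [spec.bias_name]
        p1 = zero_params(s)
        p2 = zero_params(s)
        for nm in names:
            p1[nm] = rng.normal()
            p2[nm] = rng.normal()
        combo = dict(p1)
        for nm in names:
            combo[nm] = alpha * p1[nm] + beta * p2[nm]
        expected = alpha * conditional_mean(spec, p1, data, 2) + beta * conditional_mean(
            spec, p2, data, 2
        )
        assert conditional_mean(spec, combo, data, 2) == pytest.approx(expected)


def _prior_log_density(structure, priors, params):
    """Independent term-by-term prior summation (oracle)."""
    total = 0.0
    for nm in structure.weight_names() + structure.bias_names():
        mu, sd = priors.normal(nm)
        total += stats.norm.logpdf(params[nm], mu, sd)
    for nm in structure.noise_sd_names():
        total += stats.expon.logpdf(params[nm], scale=1.0 / priors.rate(nm))
    return total


class TestLogJoint:
    def test_single_day_is_prior_only(self):
        s = default_structure()
        priors = PriorConfig()
        params = zero_params(s)
        data = {k: np.array([0.3]) for k in ("B", "R", "PV", "FS", "MS", "T", "W")}
        assert log_joint(s, priors, data, params) == pytest.approx(
            _prior_log_density(s, priors, params)
        )

    def test_zero_residual_term_is_half_log_2pi(self):
        s = default_structure()
        priors = PriorConfig()
        params = zero_params(s)
        params["bB"] = 0.1
        data = {k: np.zeros(2) for k in ("B", "R", "PV", "FS", "MS", "T", "W")}
        data["B"] = np.array([0.0, 0.1])  # residual exactly 0 for node B
        lj = log_joint(s, priors, data, params)
        prior = _prior_log_density(s, priors, params)
        # four transitions: B has residual 0, the others residual -bias=0 too,
        # except B's bias shifts only B. All sigmas 1, so each zero-residual
        # term contributes -log(2*pi)/2.
        resids = [0.0, 0.0, 0.0, 0.0]
        expected = prior + sum(stats.norm.logpdf(r) for r in resids)
        assert lj == pytest.approx(expected)

    def test_hand_summed_fixture(self):
        """N=4 default structure vs an independent term-by-term oracle."""
        s = default_structure()
        priors = PriorConfig(weight_sd=0.7, noise_rate=1.3)
        rng = np.random.default_rng(11)
        params = zero_params(s)
        for nm in s.weight_names() + s.bias_names():
            params[nm] = rng.normal(scale=0.4)
        for nm in s.noise_sd_names():
            params[nm] = rng.uniform(0.5, 1.5)
        data = {k: rng.normal(size=4) for k in ("B", "R", "PV", "FS", "MS", "T", "W")}
        expected = _prior_log_density(s, priors, params)
        for name, spec in s.nodes.items():
            for k in (1, 2, 3):
                mean = params[spec.bias_name]
                for (p, lag), wn in zip(spec.parents, spec.weight_names):
                    mean += params[wn] * data[p][k - lag]
                expected += stats.norm.logpdf(data[name][k], mean, params[spec.noise_sd_name])
        assert log_joint(s, priors, data, params) == pytest.approx(expected, rel=1e-12)

    def test_likelihood_additivity_over_independent_series(self):
        s = default_structure()
        priors = PriorConfig()
        rng = np.random.default_rng(5)
        params = zero_params(s)
        data_a = {k: rng.normal(size=5) for k in ("B", "R", "PV", "FS", "MS", "T", "W")}
        data_b = {k: rng.normal(size=7) for k in ("B", "R", "PV", "FS", "MS", "T", "W")}
        prior = _prior_log_density(s, priors, params)
        lik_a = log_joint(s, priors, data_a, params) - prior
        lik_b = log_joint(s, priors, data_b, params) - prior
        # doubling participant A's data doubles its likelihood contribution
        assert lik_a == pytest.approx(
            (log_joint(s, priors, data_a, params) - prior), rel=1e-12
        )
        combined = lik_a + lik_b + prior
        assert combined == pytest.approx(
            log_joint(s, priors, data_a, params) + log_joint(s, priors, data_b, params) - prior
        )

    def test_imputed_values_fill_missing(self):
        s = default_structure()
        priors = PriorConfig()
        params = zero_params(s)
        data = {k: np.zeros(3) for k in ("B", "R", "PV", "FS", "MS", "T", "W")}
        data["B"][1] = np.nan
        with pytest.raises(ModelError, match="unimputed"):
            log_joint(s, priors, data, params)
        filled = dict(data)
        filled["B"] = np.zeros(3)
        assert log_joint(s, priors, data, params, imputed={("B", 1): 0.0}) == pytest.approx(
            log_joint(s, priors, filled, params)
        )

    def test_day0_imputation_carries_standard_normal_prior(self):
        s = default_structure()
        priors = PriorConfig()
        params = zero_params(s)
        data = {k: np.zeros(3) for k in ("B", "R", "PV", "FS", "MS", "T", "W")}
        data["B"][0] = np.nan
        lj0 = log_joint(s, priors, data, params, imputed={("B", 0): 0.0})
        lj1 = log_joint(s, priors, data, params, imputed={("B", 0): 1.0})
        # difference includes both the N(0,1) prior and B(1)'s likelihood term
        d_prior = stats.norm.logpdf(0.0) - stats.norm.logpdf(1.0)
        assert lj0 - lj1 == pytest.approx(d_prior + (stats.norm.logpdf(0.0) - stats.norm.logpdf(0.0)))

    def test_non_positive_noise_sd_rejected(self):
        s = default_structure()
        params = zero_params(s)
        params["sigma_B"] = 0.0
        data = {k: np.zeros(2) for k in ("B", "R", "PV", "FS", "MS", "T", "W")}
        with pytest.raises(ModelError, match="non-positive"):
            log_joint(s, PriorConfig(), data, params)
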
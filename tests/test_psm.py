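"""Tests for propensity modelling, matching, balance and differential testing."""

import numpy as np
import pandas as pd
import pytest

import ferroscore as fs
from ferroscore.psm import encode_covariates


def _series(vals, prefix="s"):
    return pd.Series(vals, index=[f"{prefix}{i}" for i in range(len(vals))])


class TestFitPropensity:
    def test_intercept_only_gives_prevalence(self):
        cov = pd.DataFrame({"x": [1.0] * 10}, index=[f"s{i}" for i in range(10)])
        group = _series([1, 1, 1, 0, 0, 0, 0, 0, 0, 0]).astype(bool)
        fit = fs.fit_propensity(cov, group)
        assert fit.dropped == ["x"]
        assert np.allclose(fit.propensity, 0.3)

    def test_grid_search_likelihood_oracle(self):
        # brute-force maximizer of the Bernoulli likelihood over a 2-d grid
        rng = np.random.default_rng(0)
        x = rng.normal(size=25)
        y = (rng.random(25) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        cov = pd.DataFrame({"x": x}, index=[f"s{i}" for i in range(25)])
        fit = fs.fit_propensity(cov, pd.Series(y.astype(bool), index=cov.index))

        def nll(a, b):
            eta = a + b * x
            return -(y * eta - np.log1p(np.exp(eta))).sum()

        grid = np.linspace(-3, 3, 601)
        best = min(((nll(a, b), a, b) for a in grid for b in grid))
        assert fit.beta[0] == pytest.approx(best[1], abs=1.1e-2)
        assert fit.beta[1] == pytest.approx(best[2], abs=1.1e-2)

    def test_separation_flagged_and_clipped(self):
        cov = pd.DataFrame({"x": np.arange(10.0)}, index=[f"s{i}" for i in range(10)])
        group = _series([0] * 5 + [1] * 5).astype(bool)
        fit = fs.fit_propensity(cov, group)
        assert fit.separated
        assert fit.propensity.between(1e-6, 1 - 1e-6).all()

    def test_categorical_covariates_encoded(self):
        cov = pd.DataFrame(
            {"stage": ["I", "II", "III", "I", "II", "III"] * 3,
             "age": np.linspace(40, 70, 18)},
            index=[f"s{i}" for i in range(18)],
        )
        group = _series([0, 1] * 9).astype(bool)
        fit = fs.fit_propensity(cov, group)
        assert any(name.startswith("stage_") for name in fit.feature_names)

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        x = rng.normal(size=(80, 2))
        eta = 0.5 * x[:, 0] - 0.7 * x[:, 1]
        y = rng.random(80) < 1 / (1 + np.exp(-eta))
        cov = pd.DataFrame(x, columns=["a", "b"], index=[f"s{i}" for i in range(80)])
        fit = fs.fit_propensity(cov, pd.Series(y, index=cov.index))
        ref = sm.GLM(y.astype(float), sm.add_constant(x),
                     family=sm.families.Binomial()).fit()
        assert np.allclose(fit.beta, ref.params, atol=1e-6)


class TestMatchNearest:
    def test_identical_multisets_fully_matched(self):
        ps = _series([0.3, 0.5, 0.7, 0.3, 0.5, 0.7])
        group = _series([1, 1, 1, 0, 0, 0]).astype(bool)
        match = fs.match_nearest(ps, group)
        assert match.n_pairs == 3
        assert not [u for u in match.unmatched]

    def test_greedy_order_hand_enumeration(self):
        ps = pd.Series(
            [0.9, 0.5, 0.85, 0.55, 0.1], index=["h1", "h2", "l1", "l2", "l3"]
        )
        group = pd.Series([1, 1, 0, 0, 0], index=ps.index).astype(bool)
        match = fs.match_nearest(ps, group, caliper_sd=100.0)
        assert ("h1", "l1") in match.pairs and ("h2", "l2") in match.pairs

    def test_zero_caliper_only_exact_ties(self):
        ps = pd.Series([0.4, 0.6, 0.4, 0.61], index=["h1", "h2", "l1", "l2"])
        group = pd.Series([1, 1, 0, 0], index=ps.index).astype(bool)
        match = fs.match_nearest(ps, group, caliper_sd=0.0)
        assert match.pairs == [("h1", "l1")]

    def test_no_pairs_raises_with_advice(self):
        ps = pd.Series([0.9, 0.1], index=["h1", "l1"])
        group = pd.Series([1, 0], index=ps.index).astype(bool)
        with pytest.raises(ValueError, match="caliper"):
            fs.match_nearest(ps, group, caliper_sd=0.0)

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        ps = _series(rng.uniform(0.1, 0.9, 40))
        group = _series(rng.integers(0, 2, 40)).astype(bool)
        a = fs.match_nearest(ps, group, seed=1)
        b = fs.match_nearest(ps, group, seed=1)
        assert a.pairs == b.pairs

    def test_without_replacement(self):
        rng = np.random.default_rng(2)
        ps = _series(rng.uniform(0.2, 0.8, 30))
        group = _series([1] * 20 + [0] * 10).astype(bool)
        match = fs.match_nearest(ps, group, caliper_sd=50.0)
        controls = [l for _, l in match.pairs]
        assert len(controls) == len(set(controls))


class TestBalanceSMD:
    def test_identical_groups_zero(self):
        cov = pd.DataFrame({"x": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]},
                           index=[f"s{i}" for i in range(6)])
        group = _series([1, 1, 1, 0, 0, 0]).astype(bool)
        pairs = [("s0", "s3"), ("s1", "s4"), ("s2", "s5")]
        bal = fs.balance_smd(cov, group, pairs)
        assert bal.loc["x", "smd_before"] == pytest.approx(0.0)
        assert bal.loc["x", "smd_after"] == pytest.approx(0.0)

    def test_matching_shrinks_planted_confounding(self):
        cfg = fs.SimulationConfig(
            seed=5, n_samples=150, n_features={"mrna": 120}, confounder_strength=0.7
        )
        groups, cohort = fs.generate_confounded_pair(cfg)
        cov = cohort.clinical.data[["tumor_purity"]]
        fit = fs.fit_propensity(cov, groups == "high")
        match = fs.match_nearest(fit.propensity, groups == "high")
        bal = fs.balance_smd(cov, groups == "high", match.pairs)
        assert abs(bal.loc["tumor_purity", "smd_after"]) < abs(
            bal.loc["tumor_purity", "smd_before"]
        )

    def test_binary_covariate_proportion_convention(self):
        cov = pd.DataFrame({"flag": [1, 1, 1, 0, 1, 0, 0, 0]},
                           index=[f"s{i}" for i in range(8)])
        group = _series([1, 1, 1, 1, 0, 0, 0, 0]).astype(bool)
        bal = fs.balance_smd(cov, group)
        p1, p0 = 0.75, 0.25
        pooled = np.sqrt(0.5 * (p1 * (1 - p1) + p0 * (1 - p0)) * 4 / 3)
        assert bal.loc["flag", "smd_before"] == pytest.approx((p1 - p0) / pooled)

    def test_constant_covariate_zero_by_convention(self):
        cov = pd.DataFrame({"x": [2.0] * 6}, index=[f"s{i}" for i in range(6)])
        group = _series([1, 1, 1, 0, 0, 0]).astype(bool)
        bal = fs.balance_smd(cov, group)
        assert bal.loc["x", "smd_before"] == 0.0


class TestDifferentialFeatures:
    def _pairs(self, n):
        return [(f"h{i}", f"l{i}") for i in range(n)]

    def _layer(self, values, layer="mrna"):
        n = values.shape[1] // 2
        cols = [f"h{i}" for i in range(n)] + [f"l{i}" for i in range(n)]
        return fs.OmicsMatrix(
            pd.DataFrame(values, index=[f"f{i}" for i in range(values.shape[0])],
                         columns=cols),
            layer,
        )

    def test_identical_values_nothing_significant(self):
        # matched high and low samples carry the same values per feature
        rng = np.random.default_rng(0)
        half = rng.normal(size=(5, 4))
        vals = np.hstack([half, half])
        diff = fs.differential_features(self._layer(vals), self._pairs(4))
        assert diff["significant"].sum() == 0

    def test_planted_signal_sensitivity_and_fdr(self):
        cfg = fs.SimulationConfig(
            seed=8,
            n_samples=80,
            n_features={"mrna": 1000},
            n_pro=0,
            n_anti=0,
            n_planted_up={"mrna": 50},
            n_planted_down={"mrna": 50},
            planted_effect=1.5,
            confounder_strength=0.0,
        )
        cohort = fs.generate_cohort(cfg)
        f = cohort.latent
        groups = pd.Series(np.where(f > f.median(), "high", "low"), index=f.index)
        hi = sorted(groups.index[groups == "high"])
        lo = sorted(groups.index[groups == "low"])
        pairs = list(zip(hi, lo))
        diff = fs.differential_features(cohort.layers["mrna"], pairs)
        truth = set(cohort.planted_features("mrna"))
        called = set(diff.loc[diff["significant"], "feature"])
        sensitivity = len(called & truth) / len(truth)
        fdr = len(called - truth) / max(len(called), 1)
        assert sensitivity >= 0.9
        assert fdr <= 0.1

    def test_planted_direction_labels(self):
        cfg = fs.SimulationConfig(
            seed=9, n_samples=60, n_features={"mrna": 100}, n_pro=0, n_anti=0,
            n_planted_up={"mrna": 3}, confounder_strength=0.0, planted_effect=2.5,
        )
        cohort = fs.generate_cohort(cfg)
        f = cohort.latent
        hi = sorted(f.index[f > f.median()])
        lo = sorted(f.index[f <= f.median()])
        diff = fs.differential_features(cohort.layers["mrna"], list(zip(hi, lo)))
        planted = diff.set_index("feature").loc[cohort.planted_features("mrna")]
        assert (planted["direction"] == "up_in_high").all()

    def test_infinite_effect_threshold_vacuous(self):
        rng = np.random.default_rng(0)
        layer = self._layer(rng.normal(size=(20, 10)))
        diff = fs.differential_features(
            layer, self._pairs(5), effect_threshold=np.inf
        )
        assert diff["significant"].sum() == 0

    def test_methylation_effect_is_delta_beta(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 1, size=(10, 8))
        diff = fs.differential_features(
            self._layer(vals, "methylation"), self._pairs(4)
        )
        assert diff.attrs["effect_measure"] == "delta_beta"
        assert (diff["effect"].abs() <= 1).all()

    def test_too_few_pairs_rejected(self):
        rng = np.random.default_rng(2)
        layer = self._layer(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError):
            fs.differential_features(layer, self._pairs(2))

    def test_q_dominates_p(self):
        rng = np.random.default_rng(3)
        layer = self._layer(rng.normal(size=(50, 12)))
        diff = fs.differential_features(layer, self._pairs(6))
        assert (diff["q"] >= diff["p"] - 1e-15).all()


class TestExtractGenePanel:
    def _results(self):
        return pd.DataFrame(
            {
                "feature": ["A", "B"],
                "layer": "mrna",
                "effect": [1.2, -0.3],
                "p": [0.001, 0.4],
                "q": [0.01, 0.6],
                "direction": ["up_in_high", "up_in_low"],
                "significant": [True, False],
            }
        )

    def test_present_gene_row(self):
        out = fs.extract_gene_panel(self._results(), ["A"])
        assert len(out) == 1 and bool(out.loc[0, "tested"])
        assert out.loc[0, "direction"] == "up_in_high"

    def test_untested_gene_flagged(self):
        out = fs.extract_gene_panel(self._results(), ["A", "ZZ"])
        assert not out.set_index("feature").loc["ZZ", "tested"]

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            fs.extract_gene_panel(self._results(), [])

    def test_pipeline_planted_panel_gene(self):
        cfg = fs.SimulationConfig(
            seed=12, n_samples=60, n_features={"mrna": 80}, n_pro=0, n_anti=0,
            n_planted_up={"mrna": 2}, planted_effect=2.5, confounder_strength=0.0,
        )
        cohort = fs.generate_cohort(cfg)
        f = cohort.latent
        hi = sorted(f.index[f > f.median()])
        lo = sorted(f.index[f <= f.median()])
        diff = fs.differential_features(cohort.layers["mrna"], list(zip(hi, lo)))
        panel = cohort.planted_features("mrna")[:1]
        out = fs.extract_gene_panel(diff, panel)
        assert out.loc[0, "direction"] == "up_in_high"
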
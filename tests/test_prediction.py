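"""High-cost threshold models, ROC/PR, lognormal cost regression, stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from casemix.config import GeneratorConfig
from casemix.errors import DataError
from casemix.groupers import GrouperAssignment, drg_severity
from casemix.prediction import (
    fit_lognormal_model,
    fit_numeric_threshold_model,
    fit_threshold_model,
    high_cost_labels,
    observed_vs_expected,
    percentile_cutoffs,
    roc_pr_curves,
    stratified_run,
)
from casemix.synthetic import generate_population

from conftest import FLAT_PROFILE, make_episodes


def pairwise_auroc(scores, labels):
    """O(n²) concordant-pair oracle: P(score⁺ > score⁻) + ½ P(tie)."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestPercentileCutoffs:
    def test_linear_interpolation_convention(self):
        cuts = percentile_cutoffs(np.arange(1, 101), (80,))
        assert cuts[80.0] == pytest.approx(80.2)

    def test_all_equal_gives_zero_positives(self):
        costs = np.full(50, 7.0)
        cuts = percentile_cutoffs(costs, (90,))
        assert cuts[90.0] == 7.0
        assert high_cost_labels(costs, cuts[90.0]).sum() == 0

    def test_positive_fraction_tracks_percentile(self, rng):
        costs = np.exp(rng.normal(8, 1, 100_000))
        cuts = percentile_cutoffs(costs, (80, 90, 95))
        for p, expected in ((80.0, 0.20), (90.0, 0.10), (95.0, 0.05)):
            frac = high_cost_labels(costs, cuts[p]).mean()
            assert frac == pytest.approx(expected, abs=0.005)

    def test_empty_errors(self):
        with pytest.raises(DataError):
            percentile_cutoffs([])


class TestThresholdModel:
    def test_saturated_probability_is_empirical_rate(self):
        costs = np.r_[np.full(8, 10.0), np.full(2, 100.0), np.full(5, 10.0), np.full(5, 100.0)]
        groups = ["a"] * 10 + ["b"] * 10
        table = make_episodes(costs, base_group=groups)
        model = fit_threshold_model(table, GrouperAssignment("base", table["base_group"]), cutoff=50.0)
        assert model.per_group_probability["a"] == pytest.approx(0.2)
        assert model.per_group_probability["b"] == pytest.approx(0.5)

    def test_single_group_is_uninformative(self):
        costs = np.r_[np.full(9, 10.0), [100.0]]
        table = make_episodes(costs)
        model = fit_threshold_model(table, GrouperAssignment("base", table["base_group"]), 50.0)
        assert model.per_group_probability.iloc[0] == pytest.approx(model.prevalence)
        assert model.auroc == pytest.approx(0.5)
        assert model.auprc == pytest.approx(model.prevalence)

    def test_probabilities_match_groupby_oracle(self, random_small_table):
        cut = percentile_cutoffs(random_small_table["total_cost"], (80,))[80.0]
        model = fit_threshold_model(
            random_small_table, GrouperAssignment("base", random_small_table["base_group"]), cut
        )
        y = random_small_table["total_cost"] > cut
        oracle = y.groupby(random_small_table["base_group"]).mean()
        pd.testing.assert_series_equal(
            model.per_group_probability,
            oracle.rename("probability"),
            atol=1e-12,
            check_names=False,
        )

    def test_matches_statsmodels_logistic(self, random_small_table):
        """The closed-form saturated fit equals an actual categorical GLM fit."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        cut = float(random_small_table["total_cost"].median())
        model = fit_threshold_model(
            random_small_table, GrouperAssignment("base", random_small_table["base_group"]), cut
        )
        df = random_small_table.assign(high=(random_small_table["total_cost"] > cut).astype(int))
        glm = smf.glm("high ~ C(base_group)", data=df, family=sm.families.Binomial()).fit()
        fitted = pd.Series(glm.fittedvalues, index=df.index).groupby(df["base_group"]).first()
        # separated groups keep the empirical 0/1 rate; compare the rest
        free = [g for g in fitted.index if g not in model.separated_groups]
        np.testing.assert_allclose(
            model.per_group_probability[free], fitted[free], atol=1e-6
        )

    def test_separation_flagged(self):
        costs = np.r_[np.full(5, 1.0), np.full(5, 100.0)]
        table = make_episodes(costs, base_group=["lo"] * 5 + ["hi"] * 5)
        model = fit_threshold_model(table, GrouperAssignment("b", table["base_group"]), 50.0)
        assert set(model.separated_groups) == {"lo", "hi"}
        smoothed = fit_threshold_model(
            table, GrouperAssignment("b", table["base_group"]), 50.0, smoothing="add_half"
        )
        assert 0 < smoothed.per_group_probability["lo"] < smoothed.per_group_probability["hi"] < 1

    def test_constant_outcome_errors(self):
        table = make_episodes([1.0, 2.0, 3.0])
        with pytest.raises(DataError, match="constant"):
            fit_threshold_model(table, GrouperAssignment("b", table["base_group"]), 100.0)

    def test_numeric_predictor_ranks_like_the_index(self, rng):
        qip = rng.gamma(2, 5, 2000)
        costs = np.exp(7 + 0.3 * (qip - qip.mean()) / qip.std() + rng.normal(0, 0.3, 2000))
        table = make_episodes(costs, qip=qip)
        cut = percentile_cutoffs(costs, (80,))[80.0]
        model = fit_numeric_threshold_model(
            table, GrouperAssignment("QIP", table["qipp"]), cut
        )
        # a monotone logistic in the index scores like the index itself
        assert model.auroc == pytest.approx(pairwise_auroc(qip, costs > cut), abs=1e-9)


class TestRocPr:
    def test_perfect_separation(self):
        scores = [0.1, 0.2, 0.9, 0.95]
        labels = [0, 0, 1, 1]
        _, _, auroc, auprc = roc_pr_curves(scores, labels)
        assert auroc == 1.0 and auprc == 1.0

    def test_constant_score(self):
        _, _, auroc, auprc = roc_pr_curves(np.full(10, 0.3), [1, 0, 0, 0, 1, 0, 0, 0, 0, 0])
        assert auroc == pytest.approx(0.5)
        assert auprc == pytest.approx(0.2)  # prevalence

    def test_roc_endpoints(self, rng):
        roc, _, _, _ = roc_pr_curves(rng.random(50), rng.integers(0, 2, 50))
        assert (roc.iloc[0]["fpr"], roc.iloc[0]["tpr"]) == (0.0, 0.0)
        assert (roc.iloc[-1]["fpr"], roc.iloc[-1]["tpr"]) == (1.0, 1.0)

    @pytest.mark.parametrize("n", [8, 12])
    def test_auroc_equals_pair_count_oracle(self, rng, n):
        for _ in range(5):
            scores = rng.choice([0.1, 0.4, 0.4, 0.8], size=n)  # ties on purpose
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            _, _, auroc, _ = roc_pr_curves(scores, labels)
            assert auroc == pytest.approx(pairwise_auroc(scores, labels), abs=1e-12)

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_auroc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(30)
        labels = np.r_[np.ones(5, int), np.zeros(25, int)]
        _, _, a1, _ = roc_pr_curves(scores, labels)
        _, _, a2, _ = roc_pr_curves(np.exp(3 * scores) + 1, labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_one_class_errors(self):
        with pytest.raises(DataError, match="both classes"):
            roc_pr_curves([0.1, 0.2], [1, 1])


class TestLognormalModel:
    def test_two_point_hand_computation(self):
        """Costs {e¹, e³}: μ=2, residual σ=√2 (one dof), so the corrected
        expectation is exp(2 + 1) = e³ while the naive one is e²."""
        table = make_episodes([np.e, np.e**3])
        assignment = GrouperAssignment("b", table["base_group"])
        corrected = fit_lognormal_model(table, assignment)
        assert corrected.per_group_location.iloc[0] == pytest.approx(2.0)
        assert corrected.residual_log_sd == pytest.approx(np.sqrt(2))
        assert corrected.expected_cost.iloc[0] == pytest.approx(np.exp(3.0))
        naive = fit_lognormal_model(table, assignment, back_transform="naive")
        assert naive.expected_cost.iloc[0] == pytest.approx(np.exp(2.0))

    def test_zero_residual_variance_reproduces_costs(self):
        table = make_episodes([10.0, 10.0, 40.0, 40.0], base_group=["a", "a", "b", "b"])
        model = fit_lognormal_model(table, GrouperAssignment("b", table["base_group"]))
        np.testing.assert_allclose(model.expected_cost, table["total_cost"])

    def test_nonpositive_cost_errors(self):
        table = make_episodes([1.0, 2.0])
        table.loc[0, "total_cost"] = -1.0
        with pytest.raises(DataError, match="non-positive"):
            fit_lognormal_model(table, GrouperAssignment("b", table["base_group"]))

    def test_parameter_recovery_on_simulation(self):
        """Fitted per-group log-means land within 3 SE of the generator truth."""
        cfg = GeneratorConfig(
            n_episodes=120_000,
            n_base_groups=4,
            zipf_exponent=0.0,
            procedure_effect=0.0,
            noise_sd=0.4,
            seed=31,
            **FLAT_PROFILE,
        )
        table, params = generate_population(cfg, return_params=True)
        labels = drg_severity(table["base_group"], table["severity"])
        model = fit_lognormal_model(table, GrouperAssignment("DRG_Severity", labels))
        sizes = labels.value_counts()
        for label, mu_hat in model.per_group_location.items():
            g = int(label.split("-")[0][1:]) - 1
            sev = int(label.split("-")[1])
            truth = (
                params["global_log_mean"]
                + params["base_effects"][g]
                + cfg.severity_effect * (sev - 1)
            )
            se = cfg.noise_sd / np.sqrt(sizes[label])
            assert abs(mu_hat - truth) < 3 * se
        assert model.residual_log_sd == pytest.approx(cfg.noise_sd, rel=0.02)


class TestObservedVsExpected:
    def test_zero_noise_gives_ks_zero(self):
        table = make_episodes([10.0, 10.0, 40.0, 40.0], base_group=["a", "a", "b", "b"])
        model = fit_lognormal_model(table, GrouperAssignment("b", table["base_group"]))
        _, ks = observed_vs_expected(table, model)
        assert ks == pytest.approx(0.0, abs=1e-12)

    def test_quantile_table_matches_sorting_oracle(self, rng):
        costs = np.exp(rng.normal(7, 1, 500))
        groups = rng.choice(list("abc"), 500)
        table = make_episodes(costs, base_group=groups)
        model = fit_lognormal_model(table, GrouperAssignment("b", table["base_group"]))
        qtable, _ = observed_vs_expected(table, model)
        np.testing.assert_allclose(
            qtable["observed"], np.quantile(np.sort(costs), qtable["quantile"])
        )

    def test_refinement_fits_distribution_at_least_as_well(self, rng):
        coarse = rng.choice(list("ab"), 4000)
        fine = np.char.add(coarse, rng.choice(list("uvwx"), 4000))
        effects = {lab: rng.normal(0, 0.5) for lab in np.unique(fine)}
        costs = np.exp(7 + np.array([effects[f] for f in fine]) + rng.normal(0, 0.3, 4000))
        table = make_episodes(costs, base_group=coarse)
        ks_coarse = observed_vs_expected(
            table, fit_lognormal_model(table, GrouperAssignment("c", pd.Series(coarse)))
        )[1]
        ks_fine = observed_vs_expected(
            table, fit_lognormal_model(table, GrouperAssignment("f", pd.Series(fine)))
        )[1]
        assert ks_fine <= ks_coarse + 1e-9


class TestStratifiedRun:
    def _table(self, rng, sizes={"A": 60, "B": 40}):
        rows = []
        for base, n in sizes.items():
            sev = rng.integers(1, 5, n)
            costs = np.exp(7 + 0.3 * sev + rng.normal(0, 0.3, n))
            rows.append(make_episodes(costs, base_group=[base] * n, severity=sev))
        out = pd.concat(rows, ignore_index=True)
        out["episode_id"] = [f"E{i:05d}" for i in range(len(out))]
        return out

    def test_small_base_groups_dropped(self, rng):
        table = self._table(rng, sizes={"big": 30, "small": 24})
        res = stratified_run(
            table, GrouperAssignment("severity", table["severity"]), table["base_group"]
        )
        assert res.per_base["base_group"].tolist() == ["big"]
        assert res.exclusion_report["removed_groups"] == {"small": 24}

    def test_single_base_group_equals_unstratified(self, rng):
        from casemix.evaluation import reduction_in_variance

        table = self._table(rng, sizes={"only": 80})
        inner = GrouperAssignment("severity", table["severity"])
        res = stratified_run(table, inner, table["base_group"])
        assert res.pooled["rv"] == pytest.approx(reduction_in_variance(table, inner))

    def test_pooled_rv_equals_pair_grouping_oracle(self, rng):
        from casemix.evaluation import reduction_in_variance

        table = self._table(rng)
        inner = GrouperAssignment("severity", table["severity"])
        res = stratified_run(table, inner, table["base_group"])
        pair = GrouperAssignment(
            "pair",
            table["base_group"].astype(str) + "|" + table["severity"].astype(str),
        )
        assert res.pooled["rv"] == pytest.approx(reduction_in_variance(table, pair), abs=1e-12)

    def test_no_surviving_base_group_errors(self, rng):
        table = self._table(rng, sizes={"tiny": 10})
        with pytest.raises(DataError, match="no base group"):
            stratified_run(
                table, GrouperAssignment("severity", table["severity"]), table["base_group"]
            )
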
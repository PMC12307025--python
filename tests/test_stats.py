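"""Group tests, outlier detection, OLS families and leverage filtering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from eegconn.stats import (FAMILY_METRICS, detect_score_outliers, fit_model,
                           hat_diagonal, leverage_filter_refit,
                           metrics_to_analysis_table, run_all_models,
                           wilcoxon_ranksum)


class TestWilcoxon:
    def test_identical_samples(self, rng):
        x = rng.normal(size=30)
        w, p, r = wilcoxon_ranksum(x, x, exact=False)
        assert p > 0.9
        assert r == pytest.approx(0.0, abs=0.05)

    def test_complete_separation_exact_p(self):
        w, p, r = wilcoxon_ranksum([1, 2, 3], [10, 11, 12], exact=True)
        # all 3 ranks lowest: 2 / C(6,3) = 0.1 two-sided
        assert p == pytest.approx(0.1)

    def test_rank_invariance_under_scaling(self, rng):
        x, y = rng.normal(size=20), rng.normal(1.0, size=25)
        a = wilcoxon_ranksum(x, y)
        b = wilcoxon_ranksum(2 * x, 2 * y)
        assert a == b

    def test_monotone_transform_invariance(self, rng):
        x = rng.random(15) + 0.1
        y = rng.random(12) + 0.5
        a = wilcoxon_ranksum(x, y)
        b = wilcoxon_ranksum(np.log(x), np.log(y))
        assert a == b

    def test_exact_matches_enumeration(self, rng):
        x, y = rng.normal(size=4), rng.normal(size=5)
        w, p, _ = wilcoxon_ranksum(x, y, exact=True)
        ranks = {v: k for k, v in
                 enumerate(sorted(np.concatenate([x, y])), start=1)}
        obs = sum(ranks[v] for v in x) - 4 * 5 / 2
        us = [sum(c) - 4 * 5 / 2
              for c in itertools.combinations(range(1, 10), 4)]
        us = np.array(us)
        expected = min(1.0, 2 * min((us <= obs).mean(), (us >= obs).mean()))
        assert p == pytest.approx(expected)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="observation"):
            wilcoxon_ranksum([], [1.0])


class TestOutliers:
    def test_gross_outlier_flagged(self):
        # enough regular scores that the outlier cannot mask itself by
        # inflating the SD (in tiny samples |z| is bounded by (n-1)/sqrt(n))
        scores = [10, 11, 12, 13] * 10 + [100]
        idx = detect_score_outliers(scores)
        assert list(idx) == [40]

    def test_all_equal_none(self):
        assert detect_score_outliers([5, 5, 5, 5]).size == 0

    def test_infinite_k_none(self, rng):
        assert detect_score_outliers(rng.normal(size=50),
                                     k=np.inf).size == 0


def planted_table(rng, n_per_group, betas, residual_sd, bands=("delta",),
                  metric="dwpli_mean"):
    """Analysis table with scores planted on one z-scaled metric."""
    n = 2 * n_per_group
    rows = {
        "subject_id": [f"s{i}" for i in range(n)],
        "age_group": ["younger"] * n_per_group + ["older"] * n_per_group,
        "sex": ["female", "male"] * n_per_group,
    }
    table = pd.DataFrame(rows)
    older = (table["age_group"] == "older").to_numpy(float)
    male = (table["sex"] == "male").to_numpy(float)
    for band in bands:
        for m in ("dwpli_mean", "clustering", "modularity", "path_length",
                  "small_world"):
            table[f"{band}_{m}"] = rng.normal(size=n)
    x = table[f"{bands[0]}_{metric}"].to_numpy()
    z = (x - x.mean()) / x.std(ddof=1)
    score = (betas.get("intercept", 0) + betas.get("metric", 0) * z
             + betas.get("age", 0) * older + betas.get("sex", 0) * male
             + betas.get("interaction", 0) * z * older
             + rng.normal(0, residual_sd, size=n))
    table["semantic_fluency"] = score
    table["letter_fluency"] = 15 + rng.normal(0, residual_sd, size=n)
    return table


class TestFitModel:
    def test_noiseless_recovery_machine_precision(self, rng):
        betas = {"intercept": 25.0, "metric": 2.0, "age": -3.0, "sex": 0.0,
                 "interaction": 0.0}
        table = planted_table(rng, 40, betas, residual_sd=0.0)
        fit = fit_model(table, "dwpli", "delta", "semantic_fluency")
        assert fit.coefficients["Intercept"][0] == pytest.approx(25.0)
        assert fit.coefficients["dwpli_mean"][0] == pytest.approx(2.0)
        assert fit.coefficients["age"][0] == pytest.approx(-3.0)

    def test_interaction_recovery_large_n(self, rng):
        betas = {"intercept": 25.0, "metric": 1.5, "age": -2.5,
                 "sex": 0.0, "interaction": -3.85}
        estimates = []
        for _ in range(20):
            table = planted_table(rng, 200, betas, residual_sd=2.0)
            fit = fit_model(table, "dwpli", "delta", "semantic_fluency")
            estimates.append(fit.coefficients["dwpli_mean:age"][0])
        assert np.mean(estimates) == pytest.approx(-3.85, abs=0.5)

    def test_null_model_adjusted_r2_and_f(self, rng):
        rejections = 0
        neg_adj = 0
        n_sims = 100
        for _ in range(n_sims):
            table = planted_table(rng, 30, {"intercept": 20.0},
                                  residual_sd=3.0)
            fit = fit_model(table, "dwpli", "delta", "semantic_fluency")
            rejections += fit.f_pvalue < 0.05
            neg_adj += fit.adjusted_r2 <= 0
        assert rejections <= 0.15 * n_sims
        assert neg_adj >= 0.5 * n_sims

    def test_reference_level_swap_flips_sign(self, rng):
        betas = {"intercept": 24.0, "metric": 1.0, "age": -2.0,
                 "sex": 0.5, "interaction": 0.0}
        table = planted_table(rng, 30, betas, residual_sd=0.0)
        fit = fit_model(table, "dwpli", "delta", "semantic_fluency")
        swapped = table.copy()
        swapped["age_group"] = swapped["age_group"].map(
            {"younger": "older", "older": "younger"})
        fit2 = fit_model(swapped, "dwpli", "delta", "semantic_fluency")
        # main effect sign flips (up to the interaction redefinition);
        # fitted values identical, so residual df and R^2 agree
        assert fit2.coefficients["age"][0] == pytest.approx(
            -fit.coefficients["age"][0])
        assert fit2.adjusted_r2 == pytest.approx(fit.adjusted_r2)

    def test_scaling_contract_affine_invariance(self, rng):
        betas = {"intercept": 24.0, "metric": 1.3, "age": -2.0,
                 "sex": 0.0, "interaction": -1.0}
        table = planted_table(rng, 50, betas, residual_sd=1.0)
        fit = fit_model(table, "dwpli", "delta", "semantic_fluency")
        table2 = table.copy()
        table2["delta_dwpli_mean"] = 100 * table2["delta_dwpli_mean"] - 7
        fit2 = fit_model(table2, "dwpli", "delta", "semantic_fluency")
        for name in fit.coefficients:
            assert fit2.coefficients[name] == pytest.approx(
                fit.coefficients[name])

    def test_rank_deficient_design_names_columns(self, rng):
        table = planted_table(rng, 20, {"intercept": 20.0}, 1.0)
        table["delta_clustering"] = table["delta_modularity"]
        with pytest.raises(ValueError, match="collinear"):
            fit_model(table, "segregation", "delta", "semantic_fluency")

    def test_missing_rows_dropped_listwise(self, rng):
        table = planted_table(rng, 20, {"intercept": 20.0}, 1.0)
        table.loc[3, "delta_dwpli_mean"] = np.nan
        fit = fit_model(table, "dwpli", "delta", "semantic_fluency")
        assert fit.n_used == len(table) - 1


class TestLeverage:
    def test_extreme_x_removed(self, rng):
        table = planted_table(rng, 30, {"intercept": 20.0, "metric": 1.0},
                              residual_sd=0.5)
        table.loc[0, "delta_dwpli_mean"] = 100.0
        fit = fit_model(table, "dwpli", "delta", "semantic_fluency")
        refit = leverage_filter_refit(fit)
        assert refit.n_leverage_removed >= 1
        assert refit.n_used < fit.n_used

    def test_balanced_design_no_removals(self):
        # two-level factor only: every row has hat value (p+1)/n exactly
        n = 40
        table = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "age_group": ["younger", "older"] * (n // 2),
            "sex": ["female"] * n,
            "semantic_fluency": np.tile([20.0, 24.0], n // 2),
            "letter_fluency": 15.0,
            "delta_dwpli_mean": np.tile([-1.0, 1.0], n // 2),
        })
        design = pd.DataFrame({
            "Intercept": 1.0,
            "age": (table["age_group"] == "older").astype(float),
        })
        hat = hat_diagonal(design)
        assert np.allclose(hat, 2 / n)

    def test_filter_idempotent_on_balanced_design(self):
        # full 2x2x(+-1) factorial: every row shares the same hat value,
        # so no removals happen and a second pass changes nothing
        combos = [(a, s, m) for a in ("younger", "older")
                  for s in ("female", "male") for m in (-1.0, 1.0)]
        rows = combos * 5
        table = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(len(rows))],
            "age_group": [r[0] for r in rows],
            "sex": [r[1] for r in rows],
            "delta_dwpli_mean": [r[2] for r in rows],
            "letter_fluency": 15.0,
        })
        table["semantic_fluency"] = (
            20.0 + table["delta_dwpli_mean"]
            - 2.0 * (table["age_group"] == "older"))
        fit = fit_model(table, "dwpli", "delta", "semantic_fluency")
        once = leverage_filter_refit(fit)
        twice = leverage_filter_refit(once)
        assert once.n_leverage_removed == 0
        assert twice.n_used == once.n_used == len(rows)


class TestRunAll:
    def test_full_table_yields_32_models(self, rng):
        table = planted_table(rng, 30, {"intercept": 20.0, "metric": 1.0},
                              residual_sd=1.0,
                              bands=("delta", "theta", "alpha", "beta"))
        models = run_all_models(table)
        assert len(models) == 32
        ids = {m.model_id for m in models}
        assert len(ids) == 32

    def test_missing_band_skipped_with_warning(self, rng):
        table = planted_table(rng, 30, {"intercept": 20.0}, 1.0,
                              bands=("delta", "theta", "alpha", "beta"))
        table = table.drop(columns=[c for c in table.columns
                                    if c.startswith("theta_")])
        with pytest.warns(UserWarning, match="theta"):
            models = run_all_models(table)
        assert len(models) == 24

    def test_planted_delta_interaction_has_smallest_p(self, rng):
        betas = {"intercept": 24.0, "metric": 1.0, "age": -2.0,
                 "sex": 0.0, "interaction": -3.85}
        hits, seeds = 0, 10
        for _ in range(seeds):
            table = planted_table(rng, 100, betas, residual_sd=2.0,
                                  bands=("delta", "theta", "alpha", "beta"))
            models = run_all_models(table, leverage_filter=False)
            inter_ps = {}
            for m in models:
                if m.outcome != "semantic_fluency":
                    continue
                for name, (est, se, t, p) in m.coefficients.items():
                    if name.endswith(":age"):
                        inter_ps[(m.model_id, name)] = p
            best = min(inter_ps, key=inter_ps.get)
            hits += best == ("dwpli:delta:semantic_fluency",
                             "dwpli_mean:age")
        assert hits >= 8

    def test_metrics_join(self):
        metrics = pd.DataFrame({
            "subject_id": ["a", "a", "b", "b"],
            "band": ["delta", "alpha"] * 2,
            "dwpli_mean": [0.1, 0.2, 0.3, 0.4],
            "clustering": [0.5, 0.6, 0.7, 0.8],
            "modularity": [0.1] * 4,
            "path_length": [2.0] * 4,
            "small_world": [1.0] * 4,
        })
        behaviour = pd.DataFrame({
            "subject_id": ["a", "b"],
            "age_group": ["younger", "older"],
            "sex": ["female", "male"],
            "semantic_fluency": [25, 22],
            "letter_fluency": [15, 13],
        })
        table = metrics_to_analysis_table(metrics, behaviour)
        assert len(table) == 2
        assert table.loc[table.subject_id == "a",
                         "delta_dwpli_mean"].item() == 0.1
        assert table.loc[table.subject_id == "b",
                         "alpha_clustering"].item() == 0.8
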
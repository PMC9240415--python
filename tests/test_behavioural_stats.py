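"""Mixed ANOVA and staged regressions, checked against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from cohmap.behavioural_stats import (COMPONENTS, executive_only_regression,
                                      mixed_anova, staged_regressions)
from cohmap.synthetic_data import GeneratorConfig, make_component_scores


def _toy_scores():
    """4 participants (2 per group) x 3 tasks, hand-chosen integers."""
    data = {
        "s1": ("control", [8, 6, 7]),
        "s2": ("control", [9, 7, 8]),
        "s3": ("patient", [5, 3, 4]),
        "s4": ("patient", [4, 4, 2]),
    }
    rows = []
    for pid, (grp, vals) in data.items():
        for task, v in zip(("picture_description", "storytelling", "procedural"), vals):
            rows.append({"participant_id": pid, "group": grp, "task": task,
                         "global_coherence": float(v)})
    return pd.DataFrame(rows)


def _split_plot_oracle(df):
    """Brute-force sums-of-squares mixed (split-plot) ANOVA, balanced design."""
    wide = df.pivot_table(index=["participant_id", "group"], columns="task",
                          values="global_coherence")
    y = wide.to_numpy()
    groups = wide.index.get_level_values("group").to_numpy()
    n, k = y.shape
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    subj_means = y.mean(axis=1)
    ss_between_subj = k * ((subj_means - grand) ** 2).sum()
    ss_group = sum(k * (y[groups == g].mean() - grand) ** 2 * (groups == g).sum()
                   for g in np.unique(groups))
    ss_subj_within = ss_between_subj - ss_group
    task_means = y.mean(axis=0)
    ss_task = n * ((task_means - grand) ** 2).sum()
    cell_means = np.stack([y[groups == g].mean(axis=0) for g in np.unique(groups)])
    group_means = np.array([y[groups == g].mean() for g in np.unique(groups)])
    counts = np.array([(groups == g).sum() for g in np.unique(groups)])
    ss_cells = sum(counts[i] * ((cell_means[i] - grand) ** 2).sum()
                   for i in range(len(counts)))
    ss_int = ss_cells - ss_group - ss_task
    ss_err = ss_total - ss_between_subj - ss_task - ss_int
    g = len(np.unique(groups))
    df_group, df_sw = g - 1, n - g
    df_task, df_int, df_err = k - 1, (g - 1) * (k - 1), (n - g) * (k - 1)
    F_group = (ss_group / df_group) / (ss_subj_within / df_sw)
    F_task = (ss_task / df_task) / (ss_err / df_err)
    F_int = (ss_int / df_int) / (ss_err / df_err)
    return {"group": (F_group, df_group, df_sw),
            "task": (F_task, df_task, df_err),
            "group x task": (F_int, df_int, df_err)}


class TestMixedAnova:
    def test_matches_sums_of_squares_oracle(self):
        df = _toy_scores()
        effects, _ = mixed_anova(df, posthoc=False)
        oracle = _split_plot_oracle(df)
        for e in effects:
            F, df1, df2 = oracle[e.effect]
            assert e.F == pytest.approx(F, abs=1e-8), e.effect
            assert e.df == (df1, df2)
            # partial eta^2 identity
            assert e.partial_eta_sq == pytest.approx(
                e.F * e.df[0] / (e.F * e.df[0] + e.df[1]), abs=1e-8)

    def test_identical_groups_give_zero_group_effect(self):
        df = _toy_scores()
        # overwrite patients with the controls' values
        wide = df.pivot_table(index=["participant_id", "group"], columns="task",
                              values="global_coherence")
        vals = wide.to_numpy()
        vals[2:] = vals[:2]
        rows = []
        for (pid, grp), row in zip(wide.index, vals):
            for task, v in zip(wide.columns, row):
                rows.append({"participant_id": pid, "group": grp, "task": task,
                             "global_coherence": v})
        effects, _ = mixed_anova(pd.DataFrame(rows), posthoc=False)
        group = next(e for e in effects if e.effect == "group")
        assert group.F == pytest.approx(0.0, abs=1e-10)

    def test_published_partial_eta_sq_identity(self):
        # F(1,64) = 18.44 corresponds to partial eta^2 ~ 0.23
        assert 18.44 / (18.44 + 64) == pytest.approx(0.23, abs=0.007)

    def test_incomplete_participants_excluded(self):
        df = _toy_scores()
        extra = pd.DataFrame([{"participant_id": "s5", "group": "patient",
                               "task": "procedural", "global_coherence": 1.0}])
        effects, _ = mixed_anova(pd.concat([df, extra]), posthoc=False)
        oracle = _split_plot_oracle(df)
        group = next(e for e in effects if e.effect == "group")
        assert group.F == pytest.approx(oracle["group"][0], abs=1e-8)

    def test_posthoc_contrasts_are_bonferroni_scaled(self):
        effects, contrasts = mixed_anova(_toy_scores())
        assert len(contrasts) == 3
        np.testing.assert_allclose(
            contrasts["p_bonf"], np.minimum(1.0, contrasts["p_unc"] * 3))


def _forward_cohort(seed=0, noise_sd=0.05, n=46):
    cfg = GeneratorConfig(seed=seed, n_patients=n, noise_sd=noise_sd)
    comps, y, truth = make_component_scores(cfg, mode="forward")
    return comps, y, truth


class TestStagedRegressions:
    def test_ols_matches_normal_equations_oracle(self):
        comps, y, _ = _forward_cohort(seed=2)
        results = staged_regressions(y, comps)
        m3 = results[2]
        X = np.column_stack([np.ones(len(y))] +
                            [comps[c].to_numpy() for c in m3.predictors])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        got = [m3.coefficients["const"]] + [m3.coefficients[p] for p in m3.predictors]
        np.testing.assert_allclose(got, beta, atol=1e-8)

    def test_noiseless_generator_recovers_planted_coefficients(self):
        comps, y, truth = _forward_cohort(seed=3, noise_sd=0.0)
        results = staged_regressions(y, comps)
        m3 = results[2]
        for name in COMPONENTS:
            expected = truth.coefficients.get(name, 0.0)
            assert m3.coefficients[name] == pytest.approx(expected, abs=1e-6)
        assert results[1].r_squared == pytest.approx(1.0, abs=1e-10)

    def test_nested_r_squared_monotone(self):
        for seed in range(5):
            comps, y, _ = _forward_cohort(seed=seed, noise_sd=0.15)
            r2 = [r.r_squared for r in staged_regressions(y, comps)]
            assert r2 == sorted(r2)

    def test_null_generator_keeps_r_squared_small(self):
        cfg = GeneratorConfig(seed=11)
        comps, y, _ = make_component_scores(cfg, mode="null")
        results = staged_regressions(y, comps)
        assert results[2].r_squared < 0.5   # 7 predictors, n=46, pure noise

    def test_duplicated_predictor_rejected(self):
        comps, y, _ = _forward_cohort(seed=4)
        comps = comps.copy()
        comps["verbal_quality"] = comps["verbal_fluency"]
        with pytest.raises(ValueError, match="collinear"):
            staged_regressions(y, comps)

    def test_interaction_terms_built_from_significant_predictors(self):
        comps, y, _ = _forward_cohort(seed=5, noise_sd=0.01)
        m4 = staged_regressions(y, comps)[3]
        inter = [p for p in m4.predictors if ":" in p]
        assert inter, "expected at least one interaction term"
        for p in inter:
            assert p.startswith("executive_functions:")


class TestExecutiveOnly:
    def test_null_effect_gives_near_zero_r_squared(self):
        comps, y, _ = _forward_cohort(seed=6, noise_sd=0.05)
        res = executive_only_regression(y, comps)
        assert res.r_squared < 0.15   # executive not planted

    def test_planted_effect_recovered(self):
        cfg = GeneratorConfig(seed=7, coefficients={"executive_functions": 0.2},
                              noise_sd=0.001)
        comps, y, _ = make_component_scores(cfg, mode="forward")
        res = executive_only_regression(y, comps)
        assert res.r_squared > 0.99
        assert res.coefficients["executive_functions"] == pytest.approx(0.2, abs=1e-2)

    def test_constant_predictor_rejected(self):
        comps, y, _ = _forward_cohort(seed=8)
        comps = comps.copy()
        comps["executive_functions"] = 1.0
        with pytest.raises(ValueError, match="zero-variance"):
            executive_only_regression(y, comps)
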
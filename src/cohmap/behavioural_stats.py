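"""Group-level statistics on coherence scores.

Two analyses: a 2 (group) x 3 (task) mixed ANOVA on per-task global
coherence, and a staged ledger of simultaneous multiple regressions relating
each patient's composite coherence to seven orthogonal language/cognitive
component scores — core language components first (Model 1), then connected
speech (Model 2), then executive functions (Model 3), then interactions of
executive functions with previously significant predictors (Model 4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "COMPONENTS",
    "MODEL1",
    "MODEL2",
    "MODEL3",
    "AnovaResult",
    "RegressionResult",
    "mixed_anova",
    "staged_regressions",
    "executive_only_regression",
]

logger = logging.getLogger(__name__)

COMPONENTS = (
    "phonological_production",
    "semantic_processing",
    "phonological_recognition",
    "verbal_fluency",
    "verbal_quality",
    "motor_speech",
    "executive_functions",
)

MODEL1 = ("phonological_production", "phonological_recognition", "semantic_processing")
MODEL2 = MODEL1 + ("verbal_fluency", "verbal_quality", "motor_speech")
MODEL3 = MODEL2 + ("executive_functions",)


@dataclass
class AnovaResult:
    effect: str
    F: float
    df: tuple[float, float]
    p: float
    partial_eta_sq: float
    p_gg: float | None = None  # Greenhouse-Geisser corrected, within effects only


@dataclass
class RegressionResult:
    label: str
    predictors: list[str]
    coefficients: dict[str, float]         # unstandardized B, incl. intercept
    p_values: dict[str, float]
    r_squared: float
    F: float
    df: tuple[int, int]
    model_p: float
    delta_r_squared: float | None = None   # vs the previous nested model


def _split_plot_fallback(df: pd.DataFrame) -> pd.DataFrame:
    """Split-plot sums-of-squares decomposition for a balanced complete
    design; used only when the library path fails on degenerate data."""
    wide = df.pivot_table(index=["participant_id", "group"], columns="task",
                          values="global_coherence")
    y = wide.to_numpy()
    groups = wide.index.get_level_values("group").to_numpy()
    uniq = np.unique(groups)
    n, k = y.shape
    g = len(uniq)
    grand = y.mean()
    subj_means = y.mean(axis=1)
    ss_between_subj = k * ((subj_means - grand) ** 2).sum()
    ss_group = sum(k * (groups == gr).sum() * (y[groups == gr].mean() - grand) ** 2
                   for gr in uniq)
    ss_subj_within = ss_between_subj - ss_group
    ss_task = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_cells = sum((groups == gr).sum() *
                   ((y[groups == gr].mean(axis=0) - grand) ** 2).sum()
                   for gr in uniq)
    ss_int = ss_cells - ss_group - ss_task
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_between_subj - ss_task - ss_int
    dfs = {"group": (g - 1, n - g), "task": (k - 1, (n - g) * (k - 1)),
           "Interaction": ((g - 1) * (k - 1), (n - g) * (k - 1))}
    sss = {"group": (ss_group, ss_subj_within),
           "task": (ss_task, ss_err), "Interaction": (ss_int, ss_err)}

    def _safe_f(ss_eff, df1, ss_res, df2):
        ms_eff, ms_res = ss_eff / df1, ss_res / df2
        return float(ms_eff / ms_res) if ms_res > 0 else (
            0.0 if ms_eff == 0 else np.inf)

    rows = []
    for src, (df1, df2) in dfs.items():
        ss_eff, ss_res = sss[src]
        F = _safe_f(ss_eff, df1, ss_res, df2)
        p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        np2 = ss_eff / (ss_eff + ss_res) if (ss_eff + ss_res) > 0 else 0.0
        rows.append({"Source": src, "F": F, "DF1": df1, "DF2": df2,
                     "p_unc": p, "np2": np2, "p_GG_corr": None})
    return pd.DataFrame(rows)


def mixed_anova(scores: pd.DataFrame, posthoc: bool = True):
    """2 x 3 mixed ANOVA on global coherence.

    ``scores`` is the tidy table from :func:`cohmap.coherence.score_cohort`
    (columns participant_id, group, task, global_coherence). Participants
    missing any task score are excluded (complete cases), with the count
    logged. Returns (effects, posthocs): three :class:`AnovaResult` — group
    (between), task (within, with Greenhouse-Geisser corrected p), and the
    group x task interaction — and Bonferroni-corrected paired t-test
    contrasts between tasks (pooled across groups).
    """
    df = scores.dropna(subset=["global_coherence"]).copy()
    df.attrs = {}   # a DataFrame-valued attr breaks pandas concat downstream
    counts = df.groupby("participant_id")["task"].nunique()
    n_tasks = df["task"].nunique()
    complete = counts[counts == n_tasks].index
    n_excluded = counts.size - complete.size
    if n_excluded:
        logger.info("mixed_anova: excluding %d incomplete participant(s)", n_excluded)
    df = df[df["participant_id"].isin(complete)]
    for g in ("control", "patient"):
        if df.loc[df["group"] == g, "participant_id"].nunique() < 2:
            raise ValueError(f"fewer than 2 complete participants in group {g!r}")

    try:
        aov = pg.mixed_anova(
            data=df, dv="global_coherence", within="task",
            subject="participant_id", between="group", correction=True,
        )
    except (KeyError, ZeroDivisionError):
        # pingouin chokes on degenerate (zero-variance) data where the
        # sphericity machinery is undefined; fall back to a direct
        # sums-of-squares decomposition without the GG correction
        aov = _split_plot_fallback(df)
    effects = []
    for _, row in aov.iterrows():
        name = {"group": "group", "task": "task", "Interaction": "group x task"}.get(
            row["Source"], row["Source"]
        )
        p_gg = row.get("p_GG_corr", row.get("p-GG-corr"))
        effects.append(
            AnovaResult(
                effect=name,
                F=float(row["F"]),
                df=(float(row["DF1"]), float(row["DF2"])),
                p=float(row.get("p_unc", row.get("p-unc"))),
                partial_eta_sq=float(row["np2"]),
                p_gg=float(p_gg) if p_gg is not None and np.isfinite(p_gg) else None,
            )
        )

    contrasts = None
    if posthoc:
        wide = df.pivot_table(
            index="participant_id", columns="task", values="global_coherence"
        )
        tasks = list(wide.columns)
        rows = []
        pairs = [(a, b) for i, a in enumerate(tasks) for b in tasks[i + 1:]]
        for a, b in pairs:
            t, p = stats.ttest_rel(wide[a], wide[b])
            rows.append({"task_a": a, "task_b": b, "t": float(t), "p_unc": float(p),
                         "p_bonf": float(min(1.0, p * len(pairs)))})
        contrasts = pd.DataFrame(rows)
    return effects, contrasts


def _fit_ols(y: np.ndarray, X: pd.DataFrame, label: str) -> RegressionResult:
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.values])) < X.shape[1] + 1:
        # name the offending columns for the error message
        bad = []
        base = np.ones((len(X), 1))
        for c in X.columns:
            cand = np.column_stack([base, X[c].values])
            if np.linalg.matrix_rank(cand) < cand.shape[1]:
                bad.append(c)
            else:
                base = cand
        raise ValueError(f"rank-deficient design; collinear columns: {bad or list(X.columns)}")
    model = sm.OLS(y, sm.add_constant(X)).fit()
    coefs = {k: float(v) for k, v in model.params.items()}
    pvals = {k: float(v) for k, v in model.pvalues.items()}
    return RegressionResult(
        label=label,
        predictors=list(X.columns),
        coefficients=coefs,
        p_values=pvals,
        r_squared=float(model.rsquared),
        F=float(model.fvalue),
        df=(int(model.df_model), int(model.df_resid)),
        model_p=float(model.f_pvalue),
    )


def staged_regressions(
    composite: pd.Series | np.ndarray,
    components: pd.DataFrame,
    alpha_significant: float = 0.001,
) -> list[RegressionResult]:
    """Fit the four-stage regression ledger predicting composite coherence.

    Model 1: phonological production, phonological recognition, semantic
    processing. Model 2: + verbal fluency, verbal quality, motor speech.
    Model 3: + executive functions. Model 4: + interactions between executive
    functions and every predictor significant (p < ``alpha_significant``) in
    Models 1-3, built from mean-centred factors. Returns results with
    delta R^2 between successive models.
    """
    X_all = components[list(COMPONENTS)].astype(float)
    y = np.asarray(composite, dtype=float)
    if len(y) != len(X_all):
        raise ValueError("composite and components length mismatch")
    if len(y) <= len(MODEL3) + 1:
        raise ValueError("need more patients than predictors in the largest model")

    results = [
        _fit_ols(y, X_all[list(MODEL1)], "M1"),
        _fit_ols(y, X_all[list(MODEL2)], "M2"),
        _fit_ols(y, X_all[list(MODEL3)], "M3"),
    ]
    significant = []
    for res in results:
        for pred in res.predictors:
            if res.p_values.get(pred, 1.0) < alpha_significant and pred not in significant:
                significant.append(pred)
    X4 = X_all[list(MODEL3)].copy()
    exec_c = X_all["executive_functions"] - X_all["executive_functions"].mean()
    for pred in significant:
        if pred == "executive_functions":
            continue
        pred_c = X_all[pred] - X_all[pred].mean()
        X4[f"executive_functions:{pred}"] = exec_c * pred_c
    results.append(_fit_ols(y, X4, "M4"))

    for prev, cur in zip(results, results[1:]):
        cur.delta_r_squared = cur.r_squared - prev.r_squared
    return results


def executive_only_regression(
    composite: pd.Series | np.ndarray, components: pd.DataFrame
) -> RegressionResult:
    """Single-predictor model: composite coherence on executive functions."""
    x = components["executive_functions"].astype(float)
    if float(np.var(x)) == 0.0:
        raise ValueError("zero-variance predictor: executive_functions")
    return _fit_ols(np.asarray(composite, dtype=float), x.to_frame(), "executive-only")


def regression_report(results: list[RegressionResult]) -> pd.DataFrame:
    """Tidy summary: one row per model with R^2, delta R^2, F, dfs, p."""
    rows = []
    for r in results:
        rows.append({
            "model": r.label,
            "n_predictors": len(r.predictors),
            "r_squared": r.r_squared,
            "delta_r_squared": r.delta_r_squared,
            "F": r.F, "df1": r.df[0], "df2": r.df[1], "p": r.model_p,
            "significant_predictors": ", ".join(
                p for p in r.predictors if r.p_values.get(p, 1) < 0.001
            ),
        })
    return pd.DataFrame(rows)
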
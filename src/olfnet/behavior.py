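"""Behavioral indices and factorial effect-size statistics.

Scalar indices for odor-guided behavior (preference ratio, recognition
index RI = No/(No+Fo), dishabituation index DI = (No-Fo)/(No+Fo),
anhedonia fraction, trapezoidal AUC over the concentration series) and the
factorial machinery reported alongside them: Type III ANOVA with
sum-to-zero contrasts, partial eta-squared and Cohen's f, bootstrap
effect-size intervals, estimated marginal means, and Tukey/Sidak post hoc
contrasts.

Repeated measures are aggregated to one value per subject before fitting
(a fixed-effects approximation of a subject random intercept; see the
methods note), so every model here is an ordinary least-squares fit.
"""

from __future__ import annotations

import re
from itertools import combinations, product

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from statsmodels.stats.anova import anova_lm

from .exceptions import ConfigurationError, DataIntegrityError, UndefinedResultError

# ---------------------------------------------------------------------------
# Scalar indices
# ---------------------------------------------------------------------------


def recognition_index(novel_s: float, familiar_s: float) -> float:
    """RI = No / (No + Fo), the novel-odor share of investigation time.

    Values above 0.5 indicate memory of the familiar odor.  Undefined when
    neither object was investigated."""
    _check_pair(novel_s, familiar_s)
    total = novel_s + familiar_s
    if total == 0:
        raise UndefinedResultError("recognition index undefined: No + Fo = 0")
    return novel_s / total


def dishabituation_index(novel_s: float, familiar_s: float) -> float:
    """DI = (No - Fo) / (No + Fo), in [-1, 1]; computed from the trial-5
    novel-odor time against the trial-4 familiar-odor time."""
    _check_pair(novel_s, familiar_s)
    total = novel_s + familiar_s
    if total == 0:
        raise UndefinedResultError("dishabituation index undefined: No + Fo = 0")
    return (novel_s - familiar_s) / total


def _check_pair(novel_s, familiar_s):
    for v in (novel_s, familiar_s):
        if not np.isfinite(v) or v < 0:
            raise DataIntegrityError(f"investigation times must be finite and >= 0, got {v}")


def preference_ratio(times_per_object) -> np.ndarray:
    """Each object's share of total investigation time; shares sum to 1."""
    t = np.asarray(times_per_object, dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise DataIntegrityError("object times must be finite and nonnegative")
    total = t.sum()
    if total == 0:
        raise UndefinedResultError("preference ratio undefined: all object times are 0")
    return t / total


def anhedonia_index(tracked_s: float, total_odor_s: float) -> float:
    """Fraction of tracked time not spent engaging odorized objects.

    Immobility is retained (it may reflect diminished hedonic drive), so
    the index is simply (tracked - odor time) / tracked."""
    if tracked_s <= 0:
        raise DataIntegrityError("tracked time must be positive")
    if total_odor_s > tracked_s:
        raise DataIntegrityError(
            f"odor exploration ({total_odor_s}) exceeds tracked time ({tracked_s})"
        )
    if total_odor_s < 0:
        raise DataIntegrityError("odor exploration time must be nonnegative")
    return (tracked_s - total_odor_s) / tracked_s


def exploration_auc(concentrations, responses, normalize: bool = False,
                    abscissa: str = "rank") -> float:
    """Trapezoidal area under the response-vs-concentration curve.

    The concentration series includes 0 (vehicle), so the default abscissa
    is the equally spaced concentration rank 1..k; ``abscissa='value'``
    integrates over the raw concentrations instead.  ``normalize`` divides
    responses by their sum first."""
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.shape != y.shape:
        raise ConfigurationError("concentrations and responses must have equal length")
    if len(c) < 2:
        raise ConfigurationError("need at least 2 concentration points")
    if np.any(np.diff(c) <= 0):
        raise ConfigurationError("concentrations must be strictly ascending")
    if normalize:
        total = y.sum()
        if total == 0:
            return 0.0
        y = y / total
    if abscissa == "rank":
        x = np.arange(1, len(c) + 1, dtype=float)
    elif abscissa == "value":
        x = c
    else:
        raise ConfigurationError(f"unknown abscissa {abscissa!r}")
    return float(np.trapezoid(y, x))


def habituation_curve(trial_table: pd.DataFrame, switched_object: str = "obj1") -> pd.DataFrame:
    """Per-subject trial-wise mean investigation over all four objects and
    over the odor-switched object alone.

    Missing trials appear as explicit NaN gaps rather than being dropped."""
    hab = trial_table[trial_table["task"] == "habituation"]
    trials = range(1, 6)
    rows = []
    for sid, sub in hab.groupby("subject_id", sort=True):
        for t in trials:
            at_t = sub[sub["trial"] == t]
            if len(at_t) == 0:
                rows.append((sid, t, np.nan, np.nan))
                continue
            mean_all = at_t["investigation_s"].mean()
            sw = at_t[at_t["object"] == switched_object]["investigation_s"]
            rows.append((sid, t, mean_all, sw.mean() if len(sw) else np.nan))
    return pd.DataFrame(rows, columns=["subject_id", "trial", "mean_all_objects",
                                       "switched_object"])


# ---------------------------------------------------------------------------
# Per-subject summaries
# ---------------------------------------------------------------------------


def summarize_behavior(trials: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-subject summary: AUCs over the concentration series,
    anhedonia, DI (trial 5 vs trial 4 of the switched object), and RI per
    memory probe."""
    out = []
    for sid, sub in trials.groupby("subject_id", sort=True):
        row = {"subject_id": sid}

        pref = sub[sub["task"] == "preference"]
        if len(pref):
            per_conc = pref.groupby("concentration")["investigation_s"].mean().sort_index()
            row["auc_raw"] = exploration_auc(per_conc.index, per_conc.values)
            row["auc_norm"] = exploration_auc(per_conc.index, per_conc.values, normalize=True)
            per_trial = pref.groupby("trial").agg(
                odor=("investigation_s", "sum"), tracked=("tracked_s", "first")
            )
            row["anhedonia"] = float(
                np.mean([anhedonia_index(t, o) for o, t in
                         zip(per_trial["odor"], per_trial["tracked"])])
            )

        hab = sub[sub["task"] == "habituation"]
        if len(hab):
            sw = hab[hab["object"] == "obj1"].set_index("trial")["investigation_s"]
            if 4 in sw.index and 5 in sw.index:
                row["di"] = dishabituation_index(sw.loc[5], sw.loc[4])

        for probe in ("1h", "24h", "48h"):
            mem = sub[sub["task"] == f"memory_{probe}"].set_index("object")["investigation_s"]
            if {"novel", "familiar"} <= set(mem.index):
                row[f"ri_{probe}"] = recognition_index(mem.loc["novel"], mem.loc["familiar"])
        out.append(row)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Effect sizes / factorial ANOVA
# ---------------------------------------------------------------------------


def cohens_f(eta_sq: float) -> float:
    """f = sqrt(eta2 / (1 - eta2))."""
    if not 0 <= eta_sq < 1:
        raise ConfigurationError(f"partial eta-squared must be in [0, 1), got {eta_sq}")
    return float(np.sqrt(eta_sq / (1.0 - eta_sq)))


def _sum_formula(outcome: str, factors) -> str:
    terms = "*".join(f"C({f}, Sum)" for f in factors)
    return f"Q('{outcome}') ~ {terms}"


_TERM_RE = re.compile(r"C\(([^,)]+), Sum\)")


def _clean_term(term: str) -> str:
    return _TERM_RE.sub(r"\1", term)


def factorial_anova(
    outcome_table: pd.DataFrame,
    design: pd.DataFrame,
    outcome: str,
    factors,
    aggregate: bool = True,
):
    """Type III factorial ANOVA with sum-to-zero contrasts.

    Repeated measures are first averaged to one value per subject
    (``aggregate=True``); the model is then an OLS fit of
    ``outcome ~ f1 * f2 * ...``.  Returns a tidy frame with one
    EffectSizeEntry per fixed term: SS, df, F, p, partial eta-squared and
    Cohen's f.  A rank-deficient design raises an error naming the aliased
    columns."""
    data = outcome_table[["subject_id", outcome]].dropna()
    if aggregate:
        data = data.groupby("subject_id", as_index=False)[outcome].mean()
    data = data.merge(design[["subject_id", *factors]], on="subject_id", how="inner")
    if data[outcome].nunique() == 0:
        raise DataIntegrityError("no overlapping subjects between outcome and design")

    fit = smf.ols(_sum_formula(outcome, factors), data=data).fit()
    _check_full_rank(fit)
    if fit.df_resid < 1:
        raise DataIntegrityError("no residual degrees of freedom")

    ss_error = float(fit.ssr)
    if ss_error <= 1e-12 * max(1.0, float(np.abs(data[outcome]).max()) ** 2 * len(data)):
        # degenerate all-equal outcome: every effect SS is 0 by convention
        table = anova_lm(fit, typ=3)
        rows = []
        for term in table.index:
            if term in ("Intercept", "Residual"):
                continue
            rows.append(dict(term=_clean_term(term), ss_effect=0.0, ss_error=0.0,
                             df1=int(table.loc[term, "df"]), df2=int(fit.df_resid),
                             F=0.0, p=1.0, partial_eta_sq=0.0, cohens_f=0.0))
        return pd.DataFrame(rows)

    table = anova_lm(fit, typ=3)
    rows = []
    for term in table.index:
        if term in ("Intercept", "Residual"):
            continue
        ss = float(table.loc[term, "sum_sq"])
        df1 = int(table.loc[term, "df"])
        df2 = int(fit.df_resid)
        F = float(table.loc[term, "F"])
        p = float(table.loc[term, "PR(>F)"])
        eta = ss / (ss + ss_error)
        rows.append(dict(term=_clean_term(term), ss_effect=ss, ss_error=ss_error,
                         df1=df1, df2=df2, F=F, p=p, partial_eta_sq=eta,
                         cohens_f=cohens_f(eta)))
    return pd.DataFrame(rows)


def _check_full_rank(fit):
    exog = fit.model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # identify aliased columns via pivoted QR on the design
        names = fit.model.exog_names
        _, r = np.linalg.qr(exog)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(exog.shape) * np.finfo(float).eps
        aliased = [names[i] for i in range(len(diag)) if diag[i] < tol]
        raise DataIntegrityError(
            f"rank-deficient design (rank {rank} of {exog.shape[1]}); "
            f"aliased terms: {aliased or 'empty design cells'}"
        )


def bootstrap_effect_sizes(
    outcome_table: pd.DataFrame,
    design: pd.DataFrame,
    outcome: str,
    factors,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Nonparametric bootstrap (resampling subjects) percentile CIs for
    partial eta-squared and Cohen's f per term."""
    rng = np.random.default_rng(seed)
    base = factorial_anova(outcome_table, design, outcome, factors)
    draws = {term: [] for term in base["term"]}
    subjects = design["subject_id"].to_numpy()
    for _ in range(n_boot):
        pick = rng.choice(subjects, size=len(subjects), replace=True)
        boot_design = design.set_index("subject_id").loc[pick].reset_index()
        boot_design["subject_id"] = [f"B{i}" for i in range(len(pick))]
        lookup = outcome_table.groupby("subject_id")[outcome].mean()
        boot_out = pd.DataFrame(
            {"subject_id": boot_design["subject_id"], outcome: lookup.loc[pick].to_numpy()}
        )
        try:
            res = factorial_anova(boot_out, boot_design, outcome, factors)
        except DataIntegrityError:
            continue  # resample lost a design cell
        for term, eta in zip(res["term"], res["partial_eta_sq"]):
            if term in draws:
                draws[term].append(eta)
    lo, hi = (1 - level) / 2 * 100, (1 + level) / 2 * 100
    records = []
    for _, row in base.iterrows():
        d = np.asarray(draws[row["term"]])
        records.append(dict(
            term=row["term"], partial_eta_sq=row["partial_eta_sq"],
            cohens_f=row["cohens_f"],
            eta_ci_lo=float(np.percentile(d, lo)) if len(d) else np.nan,
            eta_ci_hi=float(np.percentile(d, hi)) if len(d) else np.nan,
            f_ci_lo=cohens_f(float(np.percentile(d, lo))) if len(d) else np.nan,
            f_ci_hi=cohens_f(min(float(np.percentile(d, hi)), 1 - 1e-12)) if len(d) else np.nan,
            n_boot_used=len(d),
        ))
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Estimated marginal means and post hoc contrasts
# ---------------------------------------------------------------------------


def estimated_marginal_means(fit, data: pd.DataFrame, focal_factors, averaged_factors=()):
    """Equal-weight average of model-predicted cell means over the averaged
    factors, with normal-approximation CIs.

    On balanced designs these equal raw group means.  Raises naming the
    first focal x averaged cell with no observed data."""
    focal_levels = [sorted(data[f].unique().tolist()) for f in focal_factors]
    avg_levels = [sorted(data[f].unique().tolist()) for f in averaged_factors]
    design_info = fit.model.data.design_info
    cov = fit.cov_params().to_numpy() if hasattr(fit.cov_params(), "to_numpy") else fit.cov_params()
    params = np.asarray(fit.params)

    rows = []
    for focal_combo in product(*focal_levels):
        grid = []
        for avg_combo in product(*avg_levels) if avg_levels else [()]:
            cell = dict(zip(focal_factors, focal_combo))
            cell.update(zip(averaged_factors, avg_combo))
            mask = np.ones(len(data), dtype=bool)
            for col, lev in cell.items():
                mask &= (data[col] == lev).to_numpy()
            if not mask.any():
                raise DataIntegrityError(f"empty design cell: {cell}")
            grid.append(cell)
        grid_df = pd.DataFrame(grid)
        (X,) = build_design_matrices([design_info], grid_df)
        L = np.asarray(X).mean(axis=0)
        emm = float(L @ params)
        se = float(np.sqrt(L @ cov @ L))
        row = dict(zip(focal_factors, focal_combo))
        row.update(emm=emm, se=se, ci_lo=emm - 1.959963984540054 * se,
                   ci_hi=emm + 1.959963984540054 * se)
        rows.append(row)
    return pd.DataFrame(rows)


def posthoc_contrasts(data: pd.DataFrame, outcome: str, factor: str,
                      method: str = "tukey", pairs=None) -> pd.DataFrame:
    """All-pairwise Tukey HSD, or Sidak-adjusted planned pairs."""
    groups = {lev: sub[outcome].to_numpy() for lev, sub in data.groupby(factor)}
    levels = sorted(groups)
    if method == "tukey":
        res = scipy.stats.tukey_hsd(*[groups[lev] for lev in levels])
        rows = []
        for i, j in combinations(range(len(levels)), 2):
            rows.append(dict(a=levels[i], b=levels[j],
                             diff=float(np.mean(groups[levels[i]]) - np.mean(groups[levels[j]])),
                             p_adj=float(res.pvalue[i, j])))
        return pd.DataFrame(rows)
    if method == "sidak":
        if pairs is None:
            pairs = list(combinations(levels, 2))
        m = len(pairs)
        rows = []
        for a, b in pairs:
            t = scipy.stats.ttest_ind(groups[a], groups[b])
            p_adj = 1.0 - (1.0 - t.pvalue) ** m
            rows.append(dict(a=a, b=b, diff=float(np.mean(groups[a]) - np.mean(groups[b])),
                             p_adj=float(min(1.0, p_adj))))
        return pd.DataFrame(rows)
    raise ConfigurationError(f"unknown post hoc method {method!r}")
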
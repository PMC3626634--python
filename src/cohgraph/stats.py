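"""Two-way group modelling with an age covariate, plus auxiliary tests.

Every derived measure y is fit with the additive Gaussian linear model

    y = y0 + b_ASD * ASD + b_TSC * TSC + b_age * age

(ordinary least squares; two binary group factors, one continuous
covariate, no interaction — a two-way ANCOVA).  Coefficient t-tests with
n - 4 residual degrees of freedom ask whether the ASD and/or TSC effects
differ from zero.  Interaction effects are deliberately not modelled; an
effect confined to a single subgroup is probed separately by post-hoc
t-tests between the subgroups carrying a condition.

No multiple-testing correction is applied across measures or bands — the
measures are strongly correlated and the joint correction is unknown — so
all reported p-values are raw and labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "AncovaResult",
    "TestResult",
    "fit_ancova",
    "acc_validation_test",
    "subgroup_posthoc",
    "demographic_tests",
    "simulate_measure_table",
    "results_grid",
    "fit_linear_model",
]

_TERMS = ("intercept", "ASD", "TSC", "age")


@dataclass
class AncovaResult:
    measure: str
    band: str | None
    params: dict[str, float]
    bse: dict[str, float]
    tvalues: dict[str, float]
    pvalues: dict[str, float]  # raw (uncorrected), two-sided
    df_resid: int
    n_obs: int
    n_excluded: int  # rows dropped for undefined measure values


@dataclass
class TestResult:
    name: str
    statistic: float
    pvalue: float
    n1: int
    n2: int
    note: str = ""


def fit_linear_model(table: pd.DataFrame, measure: str,
                     terms: tuple[str, ...]) -> "sm.regression.linear_model.RegressionResultsWrapper":
    """OLS of ``measure`` on an intercept plus the named columns.

    Lower-level entry point: no design checks beyond a rank test.  The
    reduced model ``terms=('ASD',)`` coincides exactly with a pooled
    two-sample t-test on the ASD contrast.
    """
    cols = table[list(terms) + [measure]].astype(float)
    cols = cols[np.isfinite(cols[measure])]
    X = sm.add_constant(cols[list(terms)].to_numpy())
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design matrix with terms {terms} is rank-deficient")
    return sm.OLS(cols[measure].to_numpy(), X).fit()


def fit_ancova(table: pd.DataFrame, measure: str,
               band: str | None = None) -> AncovaResult:
    """OLS fit of measure ~ ASD + TSC + age on a cohort table.

    ``measure`` is a column name (band-specific columns are conventionally
    ``<measure>__<band>``; pass ``band`` for labelling only).  Rows with
    undefined (NaN) measure values are excluded listwise.
    """
    cols = table[["ASD", "TSC", "age", measure]].astype(float)
    mask = np.isfinite(cols[measure])
    dropped = int((~mask).sum())
    cols = cols[mask]
    n = len(cols)
    if n < 8:
        raise ValueError(f"need at least 8 usable subjects, got {n}")
    for flag in ("ASD", "TSC"):
        if cols[flag].nunique() < 2:
            raise ValueError(
                f"design is rank-deficient: {flag} does not vary "
                "(a subgroup is empty)")
    fit = fit_linear_model(cols, measure, ("ASD", "TSC", "age"))
    return AncovaResult(
        measure=measure, band=band,
        params=dict(zip(_TERMS, fit.params)),
        bse=dict(zip(_TERMS, fit.bse)),
        tvalues=dict(zip(_TERMS, fit.tvalues)),
        pvalues=dict(zip(_TERMS, fit.pvalues)),
        df_resid=int(fit.df_resid), n_obs=n, n_excluded=dropped)


def acc_validation_test(acc_ratios, control_ratios) -> TestResult:
    """One-tailed two-sample t-test: ACC inter/intra ratio < control."""
    a = np.asarray(acc_ratios, dtype=float)
    c = np.asarray(control_ratios, dtype=float)
    if len(a) < 2 or len(c) < 2:
        raise ValueError("need at least two subjects per group")
    note = ""
    if a.std(ddof=1) == 0 and c.std(ddof=1) == 0:
        note = "degenerate: zero variance in both groups"
    res = sps.ttest_ind(a, c, equal_var=True, alternative="less")
    return TestResult("acc_inter_intra_less", float(res.statistic),
                      float(res.pvalue), len(a), len(c), note)


def subgroup_posthoc(table: pd.DataFrame, measure: str,
                     condition: str) -> TestResult:
    """Two-sided t-test of the ``condition`` contribution between its two
    subgroups (for "ASD": ASD with TSC vs ASD without TSC; symmetrically
    for "TSC").

    The measure is first adjusted for the *other* condition and age
    (residuals of an OLS fit on the full table), so that under a purely
    additive model the two subgroups carry the same expected contribution
    and the test stays calm; a subgroup-specific (interaction) effect
    shows up as a difference.
    """
    if condition not in ("ASD", "TSC"):
        raise ValueError("condition must be 'ASD' or 'TSC'")
    other = "TSC" if condition == "ASD" else "ASD"
    cols = table[[condition, other, "age", measure]].astype(float).dropna()
    adj = cols.copy()
    terms = tuple(t for t in (other, "age") if cols[t].nunique() > 1)
    if terms:
        fit = fit_linear_model(cols, measure, terms)
        X = sm.add_constant(cols[list(terms)].to_numpy())
        adj[measure] = cols[measure].to_numpy() - X @ fit.params
    sel = adj[adj[condition] == 1]
    g1 = sel.loc[sel[other] == 1, measure].to_numpy(dtype=float)
    g2 = sel.loc[sel[other] == 0, measure].to_numpy(dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        return TestResult(f"posthoc_{condition}_{measure}", np.nan, np.nan,
                          len(g1), len(g2), "skipped: empty subgroup")
    res = sps.ttest_ind(g1, g2, equal_var=True)
    return TestResult(f"posthoc_{condition}_{measure}",
                      float(res.statistic), float(res.pvalue),
                      len(g1), len(g2))


def demographic_tests(table: pd.DataFrame, group: str,
                      binary: list[str] = (),
                      continuous: list[str] = ("age",)) -> pd.DataFrame:
    """Fisher's exact test for binary contrasts, two-sample t for
    continuous ones, against the binary ``group`` column."""
    rows = []
    g = table[group].astype(int)
    for col in binary:
        v = table[col].astype(int)
        ct = pd.crosstab(g, v).reindex(index=[0, 1], columns=[0, 1],
                                       fill_value=0).to_numpy()
        _, p = sps.fisher_exact(ct)
        rows.append((col, "fisher_exact", np.nan, float(p)))
    for col in continuous:
        a = table.loc[g == 1, col].dropna()
        b = table.loc[g == 0, col].dropna()
        res = sps.ttest_ind(a, b, equal_var=True)
        rows.append((col, "t_test", float(res.statistic), float(res.pvalue)))
    return pd.DataFrame(rows, columns=["variable", "test", "statistic",
                                       "pvalue"])


def simulate_measure_table(n_per_subgroup: tuple[int, int, int, int],
                           rng: np.random.Generator, *,
                           baseline: float = 0.5, beta_asd: float = 0.0,
                           beta_tsc: float = 0.0, beta_age: float = 0.0,
                           interaction: float = 0.0, noise_sd: float = 0.1,
                           age_range: tuple[float, float] = (0.7, 20.0),
                           ) -> pd.DataFrame:
    """Direct measure-level cohort draw from the additive model plus noise.

    Used for model calibration (type-I error, power, post-hoc behaviour)
    without simulating signals.  Subgroup order: control, TSC-only,
    ASD-only, TSC+ASD.  ``interaction`` adds a non-additive ASD*TSC term.
    """
    rows = []
    for (asd, tsc), n in zip(((0, 0), (0, 1), (1, 0), (1, 1)),
                             n_per_subgroup):
        age = rng.uniform(*age_range, size=n)
        y = (baseline + beta_asd * asd + beta_tsc * tsc + beta_age * age
             + interaction * asd * tsc
             + noise_sd * rng.standard_normal(n))
        for a, v in zip(age, y):
            rows.append((asd, tsc, float(a), float(v)))
    return pd.DataFrame(rows, columns=["ASD", "TSC", "age", "y"])


def results_grid(table: pd.DataFrame, measures: list[str],
                 bands: list[str]) -> pd.DataFrame:
    """Table-1-style grid: raw ANCOVA p-values per measure x condition x band.

    Expects band-specific measure columns named ``<measure>__<band>``.
    """
    rows = []
    for measure in measures:
        row: dict[str, object] = {"measure": measure}
        for cond in ("ASD", "TSC"):
            for band in bands:
                col = f"{measure}__{band}"
                res = fit_ancova(table, col, band=band)
                row[f"{cond}_{band}"] = res.pvalues[cond]
        rows.append(row)
    return pd.DataFrame(rows)
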
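"""Per-mediator screening statistics.

Covers the univariate layer of the pipeline: pooled two-sample t differences
between the two treated arms (per time point and pooled over time), variance
homogeneity (Levene) with Games-Howell post-hoc comparisons, two-way ANOVA on
the balanced treated design, an orthogonal-polynomial time-trend regression,
the across-sample correlation matrix, and the baseline-alteration gate that
feeds the dynamic network stage.

All p-values are raw (no multiple-testing correction gates anything); a
Bonferroni column is provided on tables for transparency only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .panel import MediatorPanel, TREATED_TIMES

WINDOWS = ((0, 1), (1, 2), (2, 3), (3, 4))


@dataclass(frozen=True)
class TTestResult:
    """Classical pooled-variance two-sample t; ``mean_diff`` is meanB - meanA."""

    t: float
    df: float
    p: float
    mean_diff: float


def pooled_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Student's two-sample t with pooled variance, df = nA + nB - 2.

    The sign convention is B minus A.  Degenerate inputs: equal groups with
    zero pooled variance give t = 0, p = 1; unequal means with zero pooled
    variance give signed infinity and p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise AnalysisError("each group needs at least 2 values")
    na, nb = a.size, b.size
    df = na + nb - 2
    diff = b.mean() - a.mean()
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, df, 1.0, 0.0)
        return TTestResult(float(np.sign(diff)) * np.inf, df, 0.0, diff)
    t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p), float(diff))


def t_from_summary(
    mean_a: float, sem_a: float, n_a: int, mean_b: float, sem_b: float, n_b: int
) -> TTestResult:
    """Pooled t from group summaries (mean, SEM, n), as printed in reports.

    Equivalent to :func:`pooled_t_test` on the raw samples, since the pooled
    statistic depends on the data only through these summaries.
    """
    sa2 = (sem_a * np.sqrt(n_a)) ** 2
    sb2 = (sem_b * np.sqrt(n_b)) ** 2
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * sa2 + (n_b - 1) * sb2) / df
    diff = mean_b - mean_a
    if sp2 == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, df, 1.0, 0.0)
        return TTestResult(float(np.sign(diff)) * np.inf, df, 0.0, diff)
    t = diff / np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    return TTestResult(float(t), float(df), float(2.0 * stats.t.sf(abs(t), df)), float(diff))


@dataclass
class TDifferenceTable:
    """Per-time and pooled ST_HS - ST t statistics, one row per mediator."""

    t: pd.DataFrame  # columns "1 h".."4 h", "overall"
    p: pd.DataFrame
    df: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        out = self.t.copy()
        out.columns = [f"t_{c}" for c in out.columns]
        pb = self.p.copy()
        pb.columns = [f"p_{c}" for c in pb.columns]
        bonf = (self.p * self.p.size).clip(upper=1.0)
        bonf.columns = [f"p_bonferroni_{c}" for c in bonf.columns]
        return pd.concat([out, pb, bonf], axis=1)


def t_difference_table(
    panel: MediatorPanel, mediators: Iterable[str] | None = None
) -> TDifferenceTable:
    """ST_HS minus ST pooled t per time point plus an all-times pooled column."""
    meds = list(mediators) if mediators is not None else list(panel.mediators)
    cols = [f"{t} h" for t in TREATED_TIMES] + ["overall"]
    t_tab = pd.DataFrame(index=meds, columns=cols, dtype=float)
    p_tab = t_tab.copy()
    df_tab = t_tab.copy()
    for m in meds:
        overall_a, overall_b = [], []
        for t in TREATED_TIMES:
            a = panel.cell_values("ST", t, m)
            b = panel.cell_values("ST_HS", t, m)
            if a.size == 0 or b.size == 0:
                raise AnalysisError(f"missing cell for {m!r} at {t} h")
            res = pooled_t_test(a, b)
            t_tab.loc[m, f"{t} h"] = res.t
            p_tab.loc[m, f"{t} h"] = res.p
            df_tab.loc[m, f"{t} h"] = res.df
            overall_a.append(a)
            overall_b.append(b)
        res = pooled_t_test(np.concatenate(overall_a), np.concatenate(overall_b))
        t_tab.loc[m, "overall"] = res.t
        p_tab.loc[m, "overall"] = res.p
        df_tab.loc[m, "overall"] = res.df
    return TDifferenceTable(t_tab, p_tab, df_tab)


def levene_test(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Levene's W on absolute deviations from group means."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise AnalysisError("need >= 2 groups with >= 2 values each")
    if all(np.ptp(a) == 0 for a in arrs):
        return 0.0, 1.0
    w, p = stats.levene(*arrs, center="mean")
    return float(w), float(p)


def games_howell(groups: Sequence[Sequence[float]]) -> pd.DataFrame:
    """Games-Howell pairwise comparisons for unequal variances.

    For each pair: SE = sqrt(si^2/ni + sj^2/nj), Welch-Satterthwaite df, and
    p from the studentized-range distribution with k = number of groups.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise AnalysisError("need >= 2 groups with >= 2 values each")
    k = len(arrs)
    rows = []
    for i, j in combinations(range(k), 2):
        a, b = arrs[i], arrs[j]
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        diff = b.mean() - a.mean()
        se = np.sqrt(va + vb)
        if se == 0.0:
            rows.append((i, j, diff, 0.0, np.inf, np.inf if diff else 0.0,
                         0.0 if diff else 1.0))
            continue
        df = (va + vb) ** 2 / (
            va**2 / (a.size - 1) + vb**2 / (b.size - 1)
        )
        q = abs(diff) / (se / np.sqrt(2.0))
        p = float(stats.studentized_range.sf(q, k, df))
        rows.append((i, j, diff, se, df, q, p))
    return pd.DataFrame(
        rows, columns=["group_i", "group_j", "mean_diff", "se", "df", "q", "p"]
    )


@dataclass
class AnovaTable:
    """Two-way ANOVA terms for one mediator on the balanced treated design."""

    table: pd.DataFrame  # index Procedure/Time/Procedure:Time/Residual

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]


def anova_two_way(panel: MediatorPanel, mediator: str) -> AnovaTable:
    """Procedure x Time ANOVA (both categorical), UNTREATED excluded.

    Requires a balanced treated design; with n animals per cell the residual
    df is 2*4*n - 8 (40 at n = 6).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = panel.treated().data
    df = df[df["mediator"] == mediator]
    if df.empty:
        raise AnalysisError(f"mediator {mediator!r} not in panel")
    counts = df.groupby(["procedure", "time_h"], observed=True)["value"].count()
    if counts.nunique() != 1 or len(counts) != 2 * len(TREATED_TIMES):
        raise AnalysisError(
            "two-way ANOVA requires a balanced treated design; "
            f"cell counts: {counts.to_dict()}"
        )
    fit = smf.ols("value ~ C(procedure) * C(time_h)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    tab = tab.rename(
        index={
            "C(procedure)": "Procedure",
            "C(time_h)": "Time",
            "C(procedure):C(time_h)": "Procedure:Time",
        }
    )
    tab = tab.rename(columns={"PR(>F)": "p"})
    return AnovaTable(tab)


# orthogonal polynomial contrasts for 4 equally spaced levels (unit norm)
_TIME_L = {t: c for t, c in zip(TREATED_TIMES, np.array([-3.0, -1.0, 1.0, 3.0]) / np.sqrt(20.0))}
_TIME_Q = {t: c for t, c in zip(TREATED_TIMES, np.array([1.0, -1.0, -1.0, 1.0]) / 2.0)}


@dataclass
class TrendFit:
    """Linear/quadratic time-trend regression for one mediator.

    Coefficients are for intercept, Procedure (ST = 0, ST_HS = 1), the
    orthogonal linear and quadratic time contrasts, and their interactions
    with Procedure.  ``reduced`` indicates the quadratic terms were dropped
    because both were nonsignificant at ``alpha``.
    """

    params: pd.DataFrame  # coef, se, t, p per term
    resid_scale: float
    reduced: bool


def trend_model_fit(
    panel: MediatorPanel, mediator: str, alpha: float = 0.05, reduce: bool = True
) -> TrendFit:
    """Fit mediator ~ Procedure + Time.L + Time.Q + interactions on treated data.

    When both quadratic terms (Time.Q and Procedure:Time.Q) have p > alpha the
    model is refit without them and flagged as reduced.
    """
    import statsmodels.api as sm

    df = panel.treated().data
    df = df[df["mediator"] == mediator]
    if df.empty:
        raise AnalysisError(f"mediator {mediator!r} not in panel")
    proc = (df["procedure"] == "ST_HS").astype(float).to_numpy()
    tl = df["time_h"].map(_TIME_L).to_numpy()
    tq = df["time_h"].map(_TIME_Q).to_numpy()
    y = df["value"].to_numpy()

    def _fit(names: list[str], cols: list[np.ndarray]):
        X = sm.add_constant(np.column_stack(cols))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise AnalysisError("rank-deficient trend design")
        res = sm.OLS(y, X).fit()
        params = pd.DataFrame(
            {
                "coef": res.params,
                "se": res.bse,
                "t": res.tvalues,
                "p": res.pvalues,
            }
        )
        params.index = ["Intercept"] + names
        return res, params

    full_names = ["Procedure", "Time.L", "Time.Q", "Procedure:Time.L", "Procedure:Time.Q"]
    res, params = _fit(full_names, [proc, tl, tq, proc * tl, proc * tq])
    reduced = False
    if (
        reduce
        and params.loc["Time.Q", "p"] > alpha
        and params.loc["Procedure:Time.Q", "p"] > alpha
    ):
        res, params = _fit(
            ["Procedure", "Time.L", "Procedure:Time.L"], [proc, tl, proc * tl]
        )
        reduced = True
    return TrendFit(params, float(np.sqrt(res.scale)), reduced)


def correlation_matrix(
    panel: MediatorPanel, mediators: Iterable[str] | None = None
) -> pd.DataFrame:
    """Pearson correlations across all treated samples; NaN where undefined."""
    meds = list(mediators) if mediators is not None else list(panel.mediators)
    wide = panel.treated().values_matrix()[meds]
    if wide.shape[0] < 3:
        raise AnalysisError("need at least 3 samples for a correlation matrix")
    sd = wide.std(ddof=1)
    degenerate = sd.index[sd <= 1e-10 * wide.abs().max().clip(lower=1.0)].tolist()
    if degenerate:
        warnings.warn(
            f"zero-variance mediators {degenerate}: correlations undefined (NaN)",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = wide.corr(method="pearson")
    for m in degenerate:
        corr.loc[m, :] = np.nan
        corr.loc[:, m] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass(frozen=True)
class AlteredSet:
    """Mediators significantly different from baseline in one window."""

    procedure: str
    window: tuple[int, int]
    mediators: frozenset[str]


def baseline_altered_set(
    panel: MediatorPanel,
    procedure: str,
    window: tuple[int, int],
    alpha: float = 0.05,
) -> AlteredSet:
    """Mediators whose window samples differ from the untreated baseline.

    Student's pooled t, two-sided, p < alpha.  For the 0-1 h window only the
    1-h cell is tested (the baseline group itself is the other bound); later
    windows pool both bounding cells.
    """
    if window not in WINDOWS:
        raise AnalysisError(f"window must be one of {WINDOWS}, got {window}")
    try:
        base = panel.values_matrix(procedure="UNTREATED", times=[0])
    except Exception as exc:
        raise AnalysisError("no UNTREATED baseline group present") from exc
    times = [t for t in window if t > 0]
    test = pd.concat(
        [panel.values_matrix(procedure=procedure, times=[t]) for t in times]
    )
    missing = [m for m in panel.mediators if m not in test.columns or m not in base.columns]
    if missing:
        raise AnalysisError(f"missing values for {missing} in window {window}")
    meds = list(panel.mediators)
    a = base[meds].to_numpy()
    b = test[meds].to_numpy()
    na, nb = a.shape[0], b.shape[0]
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / df
    diff = b.mean(axis=0) - a.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        p = np.where(sp2 > 0, 2.0 * stats.t.sf(np.abs(t), df), (diff == 0).astype(float))
    hits = {m for m, pv in zip(meds, p) if pv < alpha}
    return AlteredSet(procedure, window, frozenset(hits))


def percent_modulated(panel: MediatorPanel, alpha: float = 0.05) -> pd.DataFrame:
    """Percent of panel mediators baseline-altered, per procedure and window."""
    rows = []
    for proc in ("ST", "ST_HS"):
        for w in WINDOWS:
            alt = baseline_altered_set(panel, proc, w, alpha)
            rows.append(
                {
                    "procedure": proc,
                    "window": f"{w[0]}-{w[1]} h",
                    "n_altered": len(alt.mediators),
                    "percent": 100.0 * len(alt.mediators) / len(panel.mediators),
                }
            )
    return pd.DataFrame(rows)
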
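"""Logistic discrimination of procedure from mediators, and its calibration.

The discrimination layer models the log-odds that an animal underwent
hemorrhagic shock (ST_HS) rather than trauma alone (ST) as a linear function
of selected mediator concentrations, fit by maximum likelihood (IRLS).
Classification success is judged against an exact random-assignment null:
when n labels of each class are allocated at random among 2n animals, the
number of correct assignments is 2k with k hypergeometric, giving an exact
reference distribution for any observed success count.

A two-way MANOVA with Wilks' lambda (Rao's F approximation) tests whether a
small multivariate response separates the procedure/time design cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .panel import MediatorPanel, TREATED_TIMES


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic model on the original predictor scale."""

    names: list[str]
    coef: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    loglik: float
    converged: bool
    separated: bool
    n_iter: int
    _standardizer: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        eta = self.coef.iloc[0] + X @ self.coef.iloc[1:].to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))


def fit_logistic_mle(
    X,
    y,
    names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> LogisticFit:
    """Fit a binary logistic model by iteratively reweighted least squares.

    Predictors are standardized internally for numerical stability and the
    coefficients (and their covariance) are mapped back to the original
    concentration scale.  Perfect separation is detected (fitted
    probabilities at the class labels) and returned as a flagged fit with the
    last finite coefficients and no Wald p-values, rather than an exception.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if names is None:
        names = [f"x{j + 1}" for j in range(k)]
    if len(set(y)) != 2 or not set(np.unique(y)) <= {0.0, 1.0}:
        raise AnalysisError("y must contain both classes, coded 0/1")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    flat = np.nonzero(sd == 0)[0]
    if flat.size:
        raise AnalysisError(
            f"constant predictor(s) {[names[j] for j in flat]}: slope inestimable"
        )
    Z = np.column_stack([np.ones(n), (X - mu) / sd])

    beta = np.zeros(k + 1)
    beta[0] = np.log(y.mean() / (1 - y.mean()))
    ll_old = -np.inf
    separated = converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(Z @ beta, -30, 30)
        p_hat = 1.0 / (1.0 + np.exp(-eta))
        w = p_hat * (1.0 - p_hat)
        grad = Z.T @ (y - p_hat)
        H = (Z * w[:, None]).T @ Z
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            separated = True
            break
        beta = beta + step
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        if np.max(np.abs(y - p_hat)) < 1e-7 or np.max(np.abs(beta)) > 1e3:
            separated = True
            break
        if abs(ll - ll_old) < tol and np.max(np.abs(grad)) < 1e-6:
            converged = True
            break
        ll_old = ll

    eta = np.clip(Z @ beta, -30, 30)
    p_hat = 1.0 / (1.0 + np.exp(-eta))
    loglik = float(np.sum(y * eta - np.log1p(np.exp(eta))))

    # back-transform: beta_orig = T @ beta_std, cov_orig = T cov_std T'
    T = np.eye(k + 1)
    T[0, 1:] = -mu / sd
    T[1:, 1:] = np.diag(1.0 / sd)
    coef = T @ beta
    idx = ["Intercept"] + list(names)
    if separated:
        se = np.full(k + 1, np.nan)
        zval = np.full(k + 1, np.nan)
        pval = np.full(k + 1, np.nan)
    else:
        w = p_hat * (1.0 - p_hat)
        cov_std = np.linalg.inv((Z * w[:, None]).T @ Z)
        cov = T @ cov_std @ T.T
        se = np.sqrt(np.diag(cov))
        zval = coef / se
        pval = 2.0 * stats.norm.sf(np.abs(zval))
    return LogisticFit(
        names=list(names),
        coef=pd.Series(coef, index=idx),
        se=pd.Series(se, index=idx),
        z=pd.Series(zval, index=idx),
        p=pd.Series(pval, index=idx),
        loglik=loglik,
        converged=converged,
        separated=separated,
        n_iter=it,
        _standardizer=(mu, sd),
    )


def _treated_xy(panel: MediatorPanel):
    wide = panel.treated().wide()
    y = (wide["procedure"] == "ST_HS").astype(float).to_numpy()
    if len(set(y)) != 2:
        raise AnalysisError("both ST and ST_HS must be present")
    return wide, y


def rank_single_mediators(
    panel: MediatorPanel, tiers: tuple[float, ...] = (0.01, 0.05, 0.10)
) -> pd.DataFrame:
    """Rank mediators by single-predictor logistic p-value, tiered.

    One logistic fit per mediator on all treated samples; rows sorted by
    ascending slope p-value.  ``sign`` exposes the direction of the
    association (positive: higher in ST_HS).
    """
    wide, y = _treated_xy(panel)
    pbar = y.mean()
    ll_null = len(y) * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar))
    rows = []
    for m in panel.mediators:
        fit = fit_logistic_mle(wide[[m]].to_numpy(), y, names=[m])
        slope = fit.coef.iloc[1]
        # likelihood-ratio p drives the ranking: the Wald statistic loses
        # power for strong effects (Hauck-Donner) and is undefined under
        # perfect separation, where the LRT still orders fits sensibly
        lrt = max(2.0 * (fit.loglik - ll_null), 0.0)
        rows.append(
            {
                "mediator": m,
                "coef": slope,
                "sign": "+" if slope >= 0 else "-",
                "p": stats.chi2.sf(lrt, 1),
                "p_wald": fit.p.iloc[1],
                "separated": fit.separated,
            }
        )
    out = pd.DataFrame(rows).sort_values("p").reset_index(drop=True)
    bounds = sorted(tiers)

    def tier(p: float) -> str:
        if np.isnan(p):
            return "separated"
        for b in bounds:
            if p < b:
                return f"p < {b:g}"
        return f"p >= {bounds[-1]:g}"

    out["tier"] = out["p"].map(tier)
    return out


@dataclass
class ClassificationResult:
    """Per-sample probabilities and the resulting success count."""

    frame: pd.DataFrame  # index subject_id; prob_st_hs, predicted, true
    n_correct: int
    n_samples: int

    @property
    def success_ratio(self) -> float:
        return self.n_correct / self.n_samples


def fit_pair_model(
    panel: MediatorPanel,
    m1: str,
    m2: str,
    split: str = "all_data",
    seed: int = 0,
    cutoff: float = 0.5,
) -> tuple[LogisticFit, ClassificationResult]:
    """Two-mediator logistic model with in-sample or held-out scoring.

    ``split='all_data'`` fits on all treated samples and classifies them
    in-sample; ``split='train80_test20'`` holds out one animal per
    (procedure, time) cell (a stratified ~20% at the study's n = 6),
    selected by ``seed``, and scores only the held-out animals.
    """
    wide, y = _treated_xy(panel)
    X = wide[[m1, m2]].to_numpy()
    if split == "all_data":
        train = np.ones(len(y), dtype=bool)
        test = train
    elif split == "train80_test20":
        rng = np.random.default_rng(seed)
        test = np.zeros(len(y), dtype=bool)
        cells = wide.groupby(["procedure", "time_h"], observed=True).indices
        for _, idx in sorted(cells.items()):
            n_hold = max(1, int(round(0.2 * len(idx))))
            test[rng.choice(idx, size=n_hold, replace=False)] = True
        train = ~test
    else:
        raise AnalysisError(f"unknown split {split!r}")
    fit = fit_logistic_mle(X[train], y[train], names=[m1, m2])
    prob = fit.predict_proba(X[test])
    pred = (prob >= cutoff).astype(int)
    true = y[test].astype(int)
    frame = pd.DataFrame(
        {
            "prob_st_hs": prob,
            "predicted": np.where(pred == 1, "ST_HS", "ST"),
            "true": np.where(true == 1, "ST_HS", "ST"),
        },
        index=wide.index[test],
    )
    n_correct = int((pred == true).sum())
    return fit, ClassificationResult(frame, n_correct, int(test.sum()))


@dataclass
class HypergeomNull:
    """Exact distribution of correct assignments under random labelling.

    With n animals per class and 2n animals total, randomly assigning n
    labels of each class makes the correct count 2k, k ~ Hypergeometric;
    only even counts are achievable and the expectation is n.
    """

    n_per_group: int
    support: np.ndarray  # achievable correct counts 0, 2, ..., 2n
    pmf: np.ndarray

    @property
    def expected_correct(self) -> float:
        return float(np.sum(self.support * self.pmf))

    def tail(self, c: int) -> float:
        """P(correct >= c)."""
        return float(self.pmf[self.support >= c].sum())


def hypergeometric_null(n_per_group: int) -> HypergeomNull:
    """Build the exact random-assignment null for equal groups of size n."""
    if n_per_group < 1:
        raise AnalysisError("n_per_group must be >= 1")
    n = n_per_group
    k = np.arange(n + 1)
    pmf = stats.hypergeom.pmf(k, 2 * n, n, n)
    return HypergeomNull(n, 2 * k, pmf / pmf.sum())


def manova_wilks(
    panel: MediatorPanel, responses: tuple[str, ...] | list[str]
) -> pd.DataFrame:
    """Two-way MANOVA (Procedure x Time, all interactions) with Wilks' lambda.

    Uses sum-to-zero factor coding on the balanced treated design; each
    term's hypothesis cross-products come from the fit with that term
    removed (equivalent to sequential sums here by balance).  Returns a
    table with Wilks' lambda, Rao's F approximation, the df pair, and p per
    term.
    """
    wide = panel.treated().wide()
    Y = wide[list(responses)].to_numpy(dtype=float)
    n = Y.shape[0]
    counts = wide.groupby(["procedure", "time_h"], observed=True).size()
    if counts.nunique() != 1 or len(counts) != 2 * len(TREATED_TIMES):
        raise AnalysisError("MANOVA requires a balanced treated design")

    proc = np.where(wide["procedure"] == "ST_HS", 1.0, -1.0)
    tcols = []
    for t in TREATED_TIMES[:-1]:
        col = np.where(wide["time_h"] == t, 1.0, 0.0) - np.where(
            wide["time_h"] == TREATED_TIMES[-1], 1.0, 0.0
        )
        tcols.append(col)
    time_block = np.column_stack(tcols)
    inter_block = time_block * proc[:, None]
    blocks = {
        "Procedure": proc[:, None],
        "Time": time_block,
        "Procedure:Time": inter_block,
    }
    X_full = np.column_stack([np.ones(n)] + list(blocks.values()))

    def sse(X: np.ndarray) -> np.ndarray:
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        R = Y - X @ coef
        return R.T @ R

    E = sse(X_full)
    if np.linalg.det(E) <= 0:
        raise AnalysisError("singular error cross-product matrix")
    v = n - np.linalg.matrix_rank(X_full)
    p_resp = Y.shape[1]
    rows = []
    for term, block in blocks.items():
        others = [b for t, b in blocks.items() if t != term]
        X_red = np.column_stack([np.ones(n)] + others)
        E_red = sse(X_red)
        lam = float(np.linalg.det(E) / np.linalg.det(E_red))
        q = block.shape[1]
        denom = p_resp**2 + q**2 - 5
        s = np.sqrt((p_resp**2 * q**2 - 4) / denom) if denom > 0 else 1.0
        m = v - (p_resp - q + 1) / 2.0
        df1 = p_resp * q
        df2 = m * s - df1 / 2.0 + 1.0
        lam_s = lam ** (1.0 / s)
        F = (1.0 - lam_s) / lam_s * df2 / df1
        pval = float(stats.f.sf(F, df1, df2))
        rows.append(
            {"term": term, "wilks_lambda": lam, "F": F, "df1": df1, "df2": df2, "p": pval}
        )
    return pd.DataFrame(rows).set_index("term")
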
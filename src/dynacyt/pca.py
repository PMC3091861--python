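"""Variance-weighted PCA driver scoring.

Each procedure's treated samples, max-normalized per mediator to [0, 1], are
decomposed into principal components of the covariance matrix.  A mediator's
overall driver score sums, over the selected leading components, the
absolute loading times the component's fraction of total variance:

    S_j = sum_i |W_ij| * e_i

Mediators with the largest S are the "principal drivers" of that
procedure's response.  The variance fractions e_i are taken over all
components, so scores are comparable across selection rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .panel import MediatorPanel, max_normalize


@dataclass
class PcaResult:
    """Loadings (unit-norm rows, one per component), variance fractions and
    sample coordinates of a covariance PCA."""

    loadings: pd.DataFrame  # components x mediators
    var_frac: np.ndarray  # descending, sums to 1
    scores: pd.DataFrame  # samples x components

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def run_pca(normalized: pd.DataFrame) -> PcaResult:
    """PCA of column-centered data via SVD; deterministic sign convention
    (each component's largest-magnitude weight is positive)."""
    M = normalized.to_numpy(dtype=float)
    n, p = M.shape
    if n < 2 or p < 2:
        raise AnalysisError("need >= 2 samples and >= 2 mediators")
    C = M - M.mean(axis=0)
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    keep = s > s[0] * 1e-12 if s[0] > 0 else slice(0, 1)
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    # sign convention
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    var = s**2
    var_frac = var / var.sum() if var.sum() > 0 else np.full(len(var), 1.0 / len(var))
    comp_names = [f"PC{i + 1}" for i in range(Vt.shape[0])]
    loadings = pd.DataFrame(Vt, index=comp_names, columns=normalized.columns)
    scores = pd.DataFrame(U * s, index=normalized.index, columns=comp_names)
    return PcaResult(loadings, var_frac, scores)


def select_components(
    result: PcaResult, *, k: int | None = None, tau: float | None = None
) -> list[int]:
    """Component indices (0-based): the first ``k``, or the minimal prefix
    whose cumulative variance fraction reaches ``tau``."""
    if (k is None) == (tau is None):
        raise AnalysisError("give exactly one of k or tau")
    if k is not None:
        if not 1 <= k <= result.n_components:
            raise AnalysisError(f"k must be in 1..{result.n_components}")
        return list(range(k))
    if not 0 < tau <= 1:
        raise AnalysisError("tau must be in (0, 1]")
    cum = np.cumsum(result.var_frac)
    stop = int(np.searchsorted(cum, tau - 1e-12) + 1)
    return list(range(min(stop, result.n_components)))


@dataclass
class DriverScores:
    """Ranked per-mediator overall scores S_j = sum |W_ij| e_i."""

    scores: pd.Series  # descending
    selection: list[int]

    def top(self, n: int = 3) -> list[str]:
        return self.scores.index[:n].tolist()


def overall_pca_scores(result: PcaResult, selection: list[int]) -> DriverScores:
    """Variance-weighted absolute-loading score over the selected components.

    The absolute loading makes the score invariant to the arbitrary sign of
    each component.
    """
    if not selection:
        raise AnalysisError("component selection is empty")
    W = np.abs(result.loadings.to_numpy()[selection])
    e = result.var_frac[selection]
    s = pd.Series(W.T @ e, index=result.loadings.columns)
    return DriverScores(s.sort_values(ascending=False), list(selection))


def pca_driver_scores(
    panel: MediatorPanel,
    procedure: str,
    *,
    k: int | None = 3,
    tau: float | None = None,
    scope: str = "per_procedure",
) -> tuple[PcaResult, DriverScores]:
    """Full stage for one procedure: normalize within the procedure's treated
    samples, run PCA, select components, and score drivers."""
    source = panel if scope == "per_procedure" else max_normalize(panel, "whole_panel")
    sub = MediatorPanel(
        source.data[source.data["procedure"] == procedure].copy(), panel.mediators
    )
    if sub.data.empty:
        raise AnalysisError(f"no samples for procedure {procedure!r}")
    if scope == "per_procedure":
        sub = max_normalize(sub, "whole_panel")
    result = run_pca(sub.values_matrix())
    sel = select_components(result, k=k, tau=tau)
    return result, overall_pca_scores(result, sel)
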
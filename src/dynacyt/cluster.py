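"""Hierarchical clustering of samples on correlation distance.

Samples (animals) are compared by the Pearson correlation of their
21-mediator profiles, clustered agglomeratively, cut into two groups at the
root, and the group x procedure composition is tested with a Pearson
chi-square.  The conventional input is the log-transformed treated panel
(baseline animals omitted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import AnalysisError
from .panel import MediatorPanel, log_transform

LINKAGES = ("average", "complete", "single")


def correlation_distance(samples: pd.DataFrame) -> pd.DataFrame:
    """Pairwise d(i, j) = 1 - r(profile_i, profile_j) between sample rows."""
    M = samples.to_numpy(dtype=float)
    if M.shape[1] < 2:
        raise AnalysisError("need >= 2 mediators per profile")
    sd = M.std(axis=1)
    flat = np.nonzero(sd <= 1e-10 * np.maximum(np.abs(M).max(axis=1), 1.0))[0]
    if flat.size:
        raise AnalysisError(
            f"constant profile(s) {list(samples.index[flat])}: correlation undefined"
        )
    corr = np.corrcoef(M)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return pd.DataFrame(d, index=samples.index, columns=samples.index)


@dataclass
class LinkageTree:
    """Agglomerative merge sequence over labelled leaves."""

    Z: np.ndarray  # scipy linkage matrix, (n-1) x 4
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.Z)]

    def to_newick(self) -> str:
        """Nested serialization with branch heights."""
        tree = hierarchy.to_tree(self.Z)

        def rec(node, parent_h: float) -> str:
            length = parent_h - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_h:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{max(length, 0.0):.6g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"

    def merges(self) -> pd.DataFrame:
        return pd.DataFrame(self.Z, columns=["child_a", "child_b", "height", "n_members"])


def hcluster(dist: pd.DataFrame, linkage: str = "average") -> LinkageTree:
    """Agglomerative clustering of a symmetric distance matrix.

    Ties are resolved deterministically by the nearest-neighbor chain order
    of the underlying algorithm, which depends only on input order.
    """
    if linkage not in LINKAGES:
        raise AnalysisError(f"linkage must be one of {LINKAGES}")
    D = dist.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-12):
        raise AnalysisError("distance matrix must be square and symmetric")
    Z = hierarchy.linkage(squareform(D, checks=False), method=linkage)
    return LinkageTree(Z, [str(x) for x in dist.index])


@dataclass
class GroupAssignment:
    """Two-group partition of samples from the root split of the tree."""

    labels: pd.Series  # sample id -> 1 or 2

    def sizes(self) -> dict[int, int]:
        return self.labels.value_counts().to_dict()


def cut_two_groups(tree: LinkageTree) -> GroupAssignment:
    """Cut at the last merge; group 1 is the larger side (ties: the side
    containing the lowest-index sample)."""
    if tree.n_leaves < 2:
        raise AnalysisError("need >= 2 leaves to cut")
    raw = hierarchy.fcluster(tree.Z, t=2, criterion="maxclust")
    s = pd.Series(raw, index=tree.labels)
    counts = s.value_counts()
    if len(counts) == 1:  # all distances zero: arbitrary but deterministic
        return GroupAssignment(pd.Series(1, index=tree.labels))
    a, b = counts.index[:2]
    if counts[a] == counts[b]:
        first = s.iloc[0]
        order = [first, a if first != a else b]
    else:
        order = [a, b]
    remap = {order[0]: 1, order[1]: 2}
    return GroupAssignment(s.map(remap))


def composition_chi2(
    assignment: GroupAssignment, procedures: pd.Series
) -> tuple[float, int, float, pd.DataFrame]:
    """Pearson chi-square (no continuity correction) of group x procedure.

    ``procedures`` maps sample id -> procedure label.  Returns (statistic,
    df, p, contingency table).
    """
    aligned = procedures.reindex(assignment.labels.index)
    if aligned.isna().any():
        raise AnalysisError("procedure labels missing for some samples")
    table = pd.crosstab(assignment.labels, aligned)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise AnalysisError(
            "contingency table has a zero margin (a group or procedure is absent)"
        )
    chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(chi2), int(dof), float(p), table


def cluster_panel(
    panel: MediatorPanel, linkage: str = "average", log_offset: float = 1.0
) -> tuple[LinkageTree, GroupAssignment, tuple[float, int, float, pd.DataFrame]]:
    """Full clustering stage: log-transform, treated samples only, correlate,
    cluster, cut in two, and test procedure composition."""
    treated = log_transform(panel, log_offset).treated()
    wide = treated.wide()
    profiles = wide.drop(columns=["procedure", "time_h"])
    tree = hcluster(correlation_distance(profiles), linkage)
    groups = cut_two_groups(tree)
    test = composition_chi2(groups, wide["procedure"])
    return tree, groups, test
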
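"""Dynamic Network Analysis (DyNA).

Per-procedure correlation networks are built in the four adjacent 1-h
windows (0-1, 1-2, 2-3, 3-4 h).  A mediator enters a window's network only
if its concentrations there differ significantly from the untreated
baseline (Student's t, p < alpha); among those "significantly altered"
nodes, an undirected signed edge connects every pair whose Pearson
correlation across the window's animals satisfies |r| >= r_threshold
(0.7 by default, about the p < 0.05 point at the study's 12 samples).

The density of a window's network is size-corrected by the number of
altered nodes:

    D = 2 E / (N_sig (N_sig - 1)),   D = 0 when N_sig < 2

so a window with many altered but unconnected mediators scores low even
though its node count is high.  Central nodes are the mediators of maximal
degree.

Because the design has no per-procedure time-0 animals, the 0-1 h window
borrows the shared untreated group as its time-0 cell for both procedures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import AnalysisError
from .panel import MediatorPanel
from .univariate import WINDOWS, baseline_altered_set


def window_label(window: tuple[int, int]) -> str:
    return f"{window[0]}-{window[1]} h"


def window_samples(
    panel: MediatorPanel, procedure: str, window: tuple[int, int]
) -> pd.DataFrame:
    """Sample x mediator matrix of the window's two bounding cells.

    Rows are ordered by (time, subject id); at the study's n = 6 this is a
    12-row matrix.  The time-0 cell is the untreated group.
    """
    if window not in WINDOWS:
        raise AnalysisError(f"window must be one of {WINDOWS}, got {window}")
    start, end = window
    parts = []
    for t in (start, end):
        proc = "UNTREATED" if t == 0 else procedure
        try:
            parts.append(panel.values_matrix(procedure=proc, times=[t]))
        except Exception as exc:
            raise AnalysisError(
                f"missing cell ({proc}, {t} h) for window {window_label(window)}"
            ) from exc
    return pd.concat(parts, axis=0)


@dataclass
class DynaWindowNetwork:
    """Gated correlation network for one (procedure, window)."""

    procedure: str
    window: tuple[int, int]
    nodes: list[str]  # significantly altered mediators, N_sig of them
    corr: pd.DataFrame  # node x node correlations (NaN where undefined)
    edges: list[tuple[str, str, float, str]]  # (a, b, r, "+"/"-"), a < b
    flagged: list[str] = field(default_factory=list)  # zero-variance nodes

    @property
    def n_sig(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> dict[str, int]:
        deg = {m: 0 for m in self.nodes}
        for a, b, _, _ in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg


def build_window_network(
    panel: MediatorPanel,
    procedure: str,
    window: tuple[int, int],
    r_threshold: float = 0.7,
    alpha: float = 0.05,
    log_scale: bool = False,
) -> DynaWindowNetwork:
    """Gate mediators on baseline alteration, then connect by |r| >= threshold.

    ``log_scale`` correlates log10(1 + value) instead of raw concentrations.
    A gated node with zero variance within the window stays a node but is
    flagged and contributes no edges.
    """
    gate = baseline_altered_set(panel, procedure, window, alpha)
    nodes = sorted(gate.mediators, key=list(panel.mediators).index)
    samples = window_samples(panel, procedure, window)
    if not nodes:
        empty = pd.DataFrame(dtype=float)
        return DynaWindowNetwork(procedure, window, [], empty, [])
    M = samples[nodes]
    if log_scale:
        M = np.log10(1.0 + M)
    sd = M.std(ddof=1)
    # relative floor: pivot/aggregation arithmetic leaves ~1e-13 residuals
    floor = 1e-10 * M.abs().max().clip(lower=1.0)
    flagged = sd.index[sd <= floor].tolist()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = M.corr(method="pearson")
    edges = []
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            if a in flagged or b in flagged:
                continue
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) >= r_threshold:
                edges.append((a, b, float(r), "+" if r >= 0 else "-"))
    return DynaWindowNetwork(procedure, window, nodes, corr, edges, flagged)


def network_density(network: DynaWindowNetwork) -> float:
    """Size-corrected density D = 2E / (N_sig (N_sig - 1)); 0 below 2 nodes."""
    n = network.n_sig
    if n < 2:
        return 0.0
    return 2.0 * network.n_edges / (n * (n - 1))


def central_nodes(network: DynaWindowNetwork) -> set[str]:
    """All nodes attaining the maximum degree; empty when there are no edges."""
    if not network.edges:
        return set()
    deg = network.degrees()
    top = max(deg.values())
    return {m for m, d in deg.items() if d == top}


def dyna_series(
    panel: MediatorPanel,
    procedure: str,
    r_threshold: float = 0.7,
    alpha: float = 0.05,
    log_scale: bool = False,
) -> tuple[list[DynaWindowNetwork], pd.DataFrame]:
    """Networks for all four windows plus the density trajectory table."""
    nets = [
        build_window_network(panel, procedure, w, r_threshold, alpha, log_scale)
        for w in WINDOWS
    ]
    traj = pd.DataFrame(
        {
            "procedure": procedure,
            "window": [window_label(n.window) for n in nets],
            "n_sig": [n.n_sig for n in nets],
            "n_edges": [n.n_edges for n in nets],
            "density": [network_density(n) for n in nets],
            "central_nodes": [";".join(sorted(central_nodes(n))) for n in nets],
        }
    )
    return nets, traj


def to_graph(network: DynaWindowNetwork) -> nx.Graph:
    """networkx view with node attribute 'significant' and edge attrs r/sign."""
    G = nx.Graph()
    for m in network.nodes:
        G.add_node(m, significant=True)
    for a, b, r, sign in network.edges:
        G.add_edge(a, b, r=r, sign=sign)
    return G


def export_network(
    network: DynaWindowNetwork, path: str | Path, format: str = "edge_list_tsv"
) -> None:
    """Write the network as a TSV edge list or GraphML."""
    path = Path(path)
    if format == "edge_list_tsv":
        rows = [
            {"node_a": a, "node_b": b, "r": r, "sign": s}
            for a, b, r, s in network.edges
        ]
        pd.DataFrame(rows, columns=["node_a", "node_b", "r", "sign"]).to_csv(
            path, sep="\t", index=False
        )
    elif format == "graphml":
        nx.write_graphml(to_graph(network), path)
    else:
        raise AnalysisError(f"unknown export format {format!r}")


def load_edge_list(path: str | Path) -> set[tuple[str, str]]:
    """Edge set from a TSV edge list (order-normalized pairs)."""
    df = pd.read_csv(path, sep="\t")
    return {tuple(sorted((a, b))) for a, b in zip(df["node_a"], df["node_b"])}
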
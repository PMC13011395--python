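"""Cross-kingdom correlation networks.

All-pairs Spearman correlation (midranks, t-approximation p) across
typed feature blocks, BH-thresholded signed graph construction,
topology metrics, hub ranking, and side-by-side comparison of two
group-wise networks.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from virome_ap.differential import bh_adjust

logger = logging.getLogger(__name__)

NODE_CLASSES = ("virus", "bacterium", "clinical")


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho on average ranks with a t-distribution p-value.

    Returns ``(nan, nan)`` when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        return float("nan"), float("nan")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    rho = float(np.clip((rx * ry).mean(), -1.0, 1.0))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, p


def spearman_all_pairs(
    blocks: dict[str, pd.DataFrame],
    min_pairs: int = 5,
    include_within: bool = True,
) -> pd.DataFrame:
    """Spearman rho/p for every feature pair across (and within) blocks.

    ``blocks`` maps a node class (virus / bacterium / clinical) to a
    samples x features table; all tables must share the sample index.
    Constant features and pairs with fewer than ``min_pairs`` complete
    observations are skipped (counts logged).
    """
    classes = list(blocks)
    index = None
    for cls, df in blocks.items():
        if cls not in NODE_CLASSES:
            raise ValueError(f"unknown node class {cls!r}")
        index = df.index if index is None else index
        if not df.index.equals(index):
            raise ValueError("blocks are not sample-aligned")
    wide = pd.concat(
        [blocks[cls].add_prefix(f"{cls}:") for cls in classes], axis=1
    )
    node_class = {f"{cls}:{c}": cls for cls in classes for c in blocks[cls].columns}
    cols = wide.columns.tolist()
    x = wide.to_numpy(dtype=float)
    n, m = x.shape

    skipped = 0
    complete = not np.isnan(x).any()
    if complete:
        const = np.array([np.all(x[:, j] == x[0, j]) for j in range(m)])
        ranks = np.empty_like(x)
        for j in range(m):
            ranks[:, j] = stats.rankdata(x[:, j])
        std = ranks.std(axis=0)
        std[std == 0] = 1.0
        z = (ranks - ranks.mean(axis=0)) / std
        rho_mat = (z.T @ z) / n
    rows = []
    for i in range(m):
        for j in range(i + 1, m):
            ci, cj = node_class[cols[i]], node_class[cols[j]]
            if not include_within and ci == cj:
                continue
            if complete:
                if const[i] or const[j] or n < min_pairs:
                    skipped += 1
                    continue
                rho = float(np.clip(rho_mat[i, j], -1.0, 1.0))
                if abs(rho) == 1.0:
                    p = 0.0
                else:
                    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
                    p = float(2.0 * stats.t.sf(abs(t), n - 2))
            else:
                mask = ~(np.isnan(x[:, i]) | np.isnan(x[:, j]))
                if mask.sum() < min_pairs:
                    skipped += 1
                    continue
                rho, p = spearman(x[mask, i], x[mask, j])
                if np.isnan(rho):
                    skipped += 1
                    continue
            rows.append((cols[i], cols[j], ci, cj, rho, p))
    if skipped:
        logger.info("skipped %d constant/under-observed pairs", skipped)
    return pd.DataFrame(rows, columns=["node_a", "node_b", "class_a", "class_b", "rho", "p"])


def build_graph(
    correlations: pd.DataFrame,
    rho_min: float = 0.4,
    q_max: float = 0.05,
    annotations: dict[str, str] | None = None,
) -> nx.Graph:
    """Signed correlation graph: edge iff |rho| > rho_min and BH-q < q_max.

    BH is applied jointly over every tested pair in the input.
    """
    corr = correlations.copy()
    corr["q"] = bh_adjust(corr["p"].to_numpy()) if len(corr) else []
    keep = corr[(corr["rho"].abs() > rho_min) & (corr["q"] < q_max)]
    g = nx.Graph(rho_min=rho_min, q_max=q_max)
    for _, row in correlations.iterrows():
        for node, cls in ((row["node_a"], row["class_a"]), (row["node_b"], row["class_b"])):
            if node not in g:
                ann = (annotations or {}).get(node, "")
                g.add_node(node, node_class=cls, annotation=ann)
    for _, row in keep.iterrows():
        if row["node_a"] == row["node_b"]:
            continue
        g.add_edge(
            row["node_a"],
            row["node_b"],
            rho=float(row["rho"]),
            q=float(row["q"]),
            sign=1 if row["rho"] > 0 else -1,
        )
    return g


def _bfs_lengths(adj: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def average_path_length(g: nx.Graph) -> float:
    """Mean unweighted shortest-path length over connected ordered pairs."""
    adj = {u: list(g.neighbors(u)) for u in g.nodes}
    total = 0
    pairs = 0
    for u in g.nodes:
        dist = _bfs_lengths(adj, u)
        total += sum(d for v, d in dist.items() if v != u)
        pairs += len(dist) - 1
    return total / pairs if pairs else 0.0


def topology(g: nx.Graph) -> dict:
    """Topology report over non-isolated nodes.

    average_degree = 2E/N; path length averaged over connected ordered
    pairs only; isolated nodes are excluded from every metric.
    """
    core_nodes = [u for u in g.nodes if g.degree(u) > 0]
    if not core_nodes:
        logger.warning("graph has no edges; topology report is all zero")
        return {
            "n_nodes": 0, "n_edges": 0, "average_degree": 0.0,
            "average_path_length": 0.0, "n_components": 0,
            "positive_edges": 0, "negative_edges": 0,
        }
    core = g.subgraph(core_nodes)
    n_edges = core.number_of_edges()
    signs = [d.get("sign", 1) for _, _, d in core.edges(data=True)]
    return {
        "n_nodes": core.number_of_nodes(),
        "n_edges": n_edges,
        "average_degree": 2.0 * n_edges / core.number_of_nodes(),
        "average_path_length": average_path_length(core),
        "n_components": nx.number_connected_components(core),
        "positive_edges": int(sum(1 for s in signs if s > 0)),
        "negative_edges": int(sum(1 for s in signs if s < 0)),
    }


def hub_ranking(g: nx.Graph, top_k: int = 20) -> list[tuple[str, int]]:
    """Nodes by descending degree; ties broken by node id."""
    ranked = sorted(g.degree, key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_k]


def clinical_edge_signs(g: nx.Graph) -> dict[str, int]:
    """Counts of positive/negative edges incident to clinical nodes."""
    pos = neg = 0
    for u, v, d in g.edges(data=True):
        if g.nodes[u].get("node_class") == "clinical" or g.nodes[v].get("node_class") == "clinical":
            if d.get("sign", 1) > 0:
                pos += 1
            else:
                neg += 1
    return {"positive": pos, "negative": neg}


def compare_networks(g_a: nx.Graph, g_b: nx.Graph) -> dict:
    """Side-by-side topology plus clinical-edge sign tabulation.

    Raises when the graphs were built with different thresholds.
    """
    for key in ("rho_min", "q_max"):
        if g_a.graph.get(key) != g_b.graph.get(key):
            raise ValueError(f"graphs built with different {key}")
    top_a, top_b = topology(g_a), topology(g_b)
    diff = {k: top_a[k] - top_b[k] for k in top_a}
    return {
        "a": top_a,
        "b": top_b,
        "diff": diff,
        "clinical_edge_signs": {"a": clinical_edge_signs(g_a), "b": clinical_edge_signs(g_b)},
    }


def write_edge_list(g: nx.Graph, path) -> None:
    rows = [
        (u, v, d["rho"], d["q"], d["sign"],
         g.nodes[u].get("node_class"), g.nodes[v].get("node_class"))
        for u, v, d in g.edges(data=True)
    ]
    pd.DataFrame(
        rows, columns=["node_a", "node_b", "rho", "q", "sign", "class_a", "class_b"]
    ).to_csv(path, sep="\t", index=False)
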
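"""Group-specific lncRNA-mRNA coexpression networks and core-node screening.

For each group (responder / nonresponder) a bipartite network is built over
the dysregulated lncRNAs and mRNAs, with an edge wherever the Pearson
correlation across that group's samples satisfies |r| >= cutoff (default
0.99; the sign is kept on the edge).  A node's *relative degree* is its
degree divided by the largest degree in its network; "core" lncRNAs and
mRNAs are those with the largest absolute difference in relative degree
between the two group networks (top k per class, default 5).
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

LNC = "lncRNA"
MRNA = "mRNA"


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation and its two-sided p-value (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Pearson correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _corr_p(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, np.finfo(float).tiny))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def build_network(
    lnc_ids,
    mrna_ids,
    lnc_matrix: ExpressionMatrix,
    mrna_matrix: ExpressionMatrix,
    samples,
    cutoff: float = 0.99,
    group: str | None = None,
) -> nx.Graph:
    """Bipartite coexpression graph for one group's samples.

    All candidate nodes are present in the graph (typed by ``rna_class``);
    an edge (lnc, mrna) exists iff |r| >= cutoff over ``samples``, with the
    signed r and its p-value stored as edge attributes.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in (0, 1], got {cutoff}")
    samples = list(samples)
    if len(samples) < 3:
        raise ValueError("need at least 3 samples to correlate")
    lnc_ids = list(lnc_ids)
    mrna_ids = list(mrna_ids)
    G = nx.Graph(group=group or "", cutoff=cutoff)
    G.add_nodes_from(lnc_ids, rna_class=LNC)
    G.add_nodes_from(mrna_ids, rna_class=MRNA)
    if not lnc_ids or not mrna_ids:
        return G

    X = lnc_matrix.values.loc[lnc_ids, samples].to_numpy(dtype=float)
    Y = mrna_matrix.values.loc[mrna_ids, samples].to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xs = np.sqrt((Xc**2).sum(axis=1))
    ys = np.sqrt((Yc**2).sum(axis=1))
    if (xs == 0).any() or (ys == 0).any():
        raise ValueError("constant feature vector within group")
    R = (Xc @ Yc.T) / np.outer(xs, ys)
    P = _corr_p(R, len(samples))
    ii, jj = np.nonzero(np.abs(R) >= cutoff)
    for i, j in zip(ii, jj):
        G.add_edge(lnc_ids[i], mrna_ids[j], r=float(R[i, j]), p=float(P[i, j]))
    return G


def relative_degree(network: nx.Graph) -> dict[str, float]:
    """Degree of each node divided by the largest degree in the network."""
    degrees = dict(network.degree())
    max_deg = max(degrees.values(), default=0)
    if max_deg == 0:
        raise ValueError("network has no edges: relative degree undefined")
    return {v: d / max_deg for v, d in degrees.items()}


def differential_centrality(net_resp: nx.Graph, net_nonresp: nx.Graph) -> pd.DataFrame:
    """Cross-group relative-degree table over the union of both node sets.

    A node absent from one network (or in a network with no edges) has
    relative degree 0 there.  Rows are ranked per RNA class by descending
    |rd_resp - rd_nonresp|, ties broken by larger max degree then id.
    """

    def safe_rd(net: nx.Graph) -> dict[str, float]:
        try:
            return relative_degree(net)
        except ValueError:
            return {}

    rd_r, rd_n = safe_rd(net_resp), safe_rd(net_nonresp)
    nodes = sorted(set(net_resp.nodes) | set(net_nonresp.nodes))
    classes = {}
    for net in (net_resp, net_nonresp):
        for v, data in net.nodes(data=True):
            classes.setdefault(v, data.get("rna_class", ""))
    rows = []
    for v in nodes:
        dr = net_resp.degree(v) if v in net_resp else 0
        dn = net_nonresp.degree(v) if v in net_nonresp else 0
        rr = rd_r.get(v, 0.0)
        rn = rd_n.get(v, 0.0)
        rows.append(
            {
                "node": v,
                "rna_class": classes[v],
                "degree_resp": dr,
                "degree_nonresp": dn,
                "rd_resp": rr,
                "rd_nonresp": rn,
                "delta_rd": abs(rr - rn),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "node",
            "rna_class",
            "degree_resp",
            "degree_nonresp",
            "rd_resp",
            "rd_nonresp",
            "delta_rd",
        ],
    )
    if table.empty:
        table["max_degree"] = pd.Series(dtype=int)
        table["rank"] = pd.Series(dtype=int)
        return table
    table["max_degree"] = table[["degree_resp", "degree_nonresp"]].max(axis=1)
    table = table.sort_values(
        by=["rna_class", "delta_rd", "max_degree", "node"],
        ascending=[True, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table["rank"] = table.groupby("rna_class").cumcount() + 1
    return table


def core_nodes(table: pd.DataFrame, k: int = 5) -> tuple[list[str], list[str]]:
    """Top-k lncRNAs and mRNAs by relative-degree difference (deterministic)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    out = []
    for cls in (LNC, MRNA):
        sub = table[table["rna_class"] == cls]
        if k > len(sub):
            warnings.warn(
                f"k={k} exceeds {len(sub)} {cls} nodes; returning all", stacklevel=2
            )
        out.append(sub.nsmallest(min(k, len(sub)), "rank")["node"].tolist())
    return out[0], out[1]
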
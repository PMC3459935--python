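"""Two-group sparse Gaussian graphical model networks.

Group-specific partial-correlation networks over genes (plus optional
clinical nodes) are inferred jointly: each group's empirical covariance is
*intertwined* with the pooled covariance over both groups
(alpha * S_group + (1 - alpha) * S_pooled), which biases the two estimates
toward a common structure, and an l1-penalized sparse estimate is computed
on the mixed covariance.  The default solver is neighborhood selection
(per-node lasso regressions, solved by coordinate descent directly on the
covariance) with the conservative "AND" edge policy; a penalized-likelihood
graphical-lasso backend is available behind the same contract.  The penalty
is calibrated by bisection so the network hits a target edge density
(default 15% of node pairs).
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import GgmNetwork

DEFAULT_DENSITY = 0.15
DEFAULT_ALPHA_MIX = 0.5


# --------------------------------------------------------------------------- #
# covariances                                                                 #
# --------------------------------------------------------------------------- #

def standardize_within_group(data: pd.DataFrame, groups: pd.Series,
                             ) -> pd.DataFrame:
    """Zero-mean unit-variance columns within each group (ddof=1)."""
    out = data.copy().astype(float)
    for g in groups.unique():
        idx = groups.index[groups == g]
        sub = out.loc[idx]
        sd = sub.std(ddof=1)
        if (sd == 0).any():
            bad = sd.index[sd == 0].tolist()
            raise ValueError(f"constant columns within group {g!r}: {bad}")
        out.loc[idx] = (sub - sub.mean()) / sd
    return out


def group_covariances(data: pd.DataFrame, groups: pd.Series,
                      standardize: bool = True,
                      ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-group and pooled empirical covariance of observation-rows.

    ``groups`` assigns each row of ``data`` to a group.  With
    ``standardize`` (default) columns are scaled to zero mean / unit
    variance within group first, so the covariances are correlation-like
    and share a unit diagonal.
    """
    if not data.index.equals(groups.index):
        groups = groups.reindex(data.index)
    counts = groups.value_counts()
    if (counts < 2).any():
        raise ValueError("need at least 2 observations per group")
    sd0 = data.std(ddof=1)
    if (sd0 == 0).any():
        raise ValueError(f"constant columns: {sd0.index[sd0 == 0].tolist()}")
    X = standardize_within_group(data, groups) if standardize else data

    per_group = {}
    for g in sorted(groups.unique(), key=str):
        sub = X.loc[groups == g].to_numpy(float)
        per_group[g] = np.cov(sub, rowvar=False, ddof=1)
    pooled = np.cov(X.to_numpy(float), rowvar=False, ddof=1)
    return per_group, pooled


def intertwine(s_group: np.ndarray, s_pooled: np.ndarray,
               alpha_mix: float = DEFAULT_ALPHA_MIX) -> np.ndarray:
    """Convex mix of a group covariance with the pooled covariance."""
    if not 0.0 <= alpha_mix <= 1.0:
        raise ValueError("alpha_mix must lie in [0, 1]")
    if s_group.shape != s_pooled.shape:
        raise ValueError("covariance shapes differ")
    return alpha_mix * s_group + (1.0 - alpha_mix) * s_pooled


# --------------------------------------------------------------------------- #
# sparse inference                                                            #
# --------------------------------------------------------------------------- #

def _lasso_cd(S: np.ndarray, j: int, lam: float, tol: float = 1e-8,
              max_iter: int = 5000) -> np.ndarray:
    """Lasso regression of node j on the others, from the covariance alone.

    Minimizes 0.5 b' S_11 b - s' b + lam * |b|_1 by cyclic coordinate
    descent, where S_11 drops row/column j and s = S[-j, j].
    """
    idx = np.delete(np.arange(S.shape[0]), j)
    S11 = S[np.ix_(idx, idx)]
    s = S[idx, j]
    p = len(idx)
    beta = np.zeros(p)
    diag = np.clip(np.diag(S11), 1e-12, None)
    for _ in range(max_iter):
        delta = 0.0
        for k in range(p):
            r = s[k] - S11[k] @ beta + diag[k] * beta[k]
            new = np.sign(r) * max(abs(r) - lam, 0.0) / diag[k]
            d = new - beta[k]
            if d != 0.0:
                beta[k] = new
                delta = max(delta, abs(d))
        if delta < tol:
            break
    else:  # pragma: no cover - cap reached
        raise RuntimeError(f"lasso coordinate descent for node {j} did not "
                           f"converge within {max_iter} iterations")
    return beta


def _neighborhood_selection(S: np.ndarray, lam: float, policy: str,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Meinshausen-Buhlmann neighborhood selection on a covariance.

    Returns (adjacency, precision estimate).  The precision is assembled
    from the node-wise regressions: theta_jj = 1 / residual variance of
    node j; theta_ij = average of the two directed estimates on edges kept
    by the policy.
    """
    p = S.shape[0]
    betas = np.zeros((p, p))       # betas[j, k]: coefficient of k in node-j fit
    for j in range(p):
        idx = np.delete(np.arange(p), j)
        betas[j, idx] = _lasso_cd(S, j, lam)

    sel = betas != 0
    if policy == "AND":
        adj = sel & sel.T
    elif policy == "OR":
        adj = sel | sel.T
    else:
        raise ValueError(f"unknown edge policy {policy!r}")
    np.fill_diagonal(adj, False)

    theta = np.zeros((p, p))
    resvar = np.empty(p)
    for j in range(p):
        idx = np.delete(np.arange(p), j)
        resvar[j] = max(S[j, j] - S[idx, j] @ betas[j, idx], 1e-12)
        theta[j, j] = 1.0 / resvar[j]
    for i in range(p):
        for j in range(i + 1, p):
            if adj[i, j]:
                theta[i, j] = theta[j, i] = -0.5 * (
                    betas[i, j] / resvar[i] + betas[j, i] / resvar[j])
    return adj.astype(bool), theta


def _graphical_lasso(S: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    from sklearn.covariance import graphical_lasso

    if lam <= 0:
        theta = np.linalg.inv(S + 1e-10 * np.eye(S.shape[0]))
    else:
        _, theta = graphical_lasso(S, alpha=lam, max_iter=500)
    adj = np.abs(theta) > 1e-10
    np.fill_diagonal(adj, False)
    return adj, theta


def sparse_ggm_infer(S_mixed: np.ndarray, lam: float, policy: str = "AND",
                     solver: str = "neighborhood",
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Sparse inverse-covariance support at penalty ``lam``.

    Returns (precision estimate, boolean adjacency).  ``solver`` is
    ``"neighborhood"`` (per-node lasso, AND/OR symmetrization) or
    ``"glasso"`` (penalized likelihood; the policy argument is ignored
    because the estimate is symmetric by construction).
    """
    S_mixed = np.asarray(S_mixed, float)
    if S_mixed.shape[0] != S_mixed.shape[1] or \
            not np.allclose(S_mixed, S_mixed.T, atol=1e-8):
        raise ValueError("S_mixed must be a symmetric square matrix")
    if lam < 0:
        raise ValueError("penalty must be non-negative")
    if solver == "neighborhood":
        adj, theta = _neighborhood_selection(S_mixed, lam, policy)
    elif solver == "glasso":
        adj, theta = _graphical_lasso(S_mixed, lam)
    else:
        raise ValueError(f"unknown solver {solver!r}")
    return theta, adj


def partial_correlation(theta: np.ndarray) -> np.ndarray:
    """Partial correlations from a precision matrix:
    rho_ij = -theta_ij / sqrt(theta_ii * theta_jj); unit diagonal."""
    theta = np.asarray(theta, float)
    d = np.diag(theta)
    if np.any(d <= 0):
        raise ValueError("precision diagonal must be positive")
    denom = np.sqrt(np.outer(d, d))
    rho = -theta / denom
    np.fill_diagonal(rho, 1.0)
    return rho


# --------------------------------------------------------------------------- #
# density calibration                                                         #
# --------------------------------------------------------------------------- #

def _edge_count(adj: np.ndarray) -> int:
    return int(np.triu(adj, 1).sum())


def calibrate_density(S_mixed: np.ndarray, target: float = DEFAULT_DENSITY,
                      nodes: list[str] | None = None, policy: str = "AND",
                      solver: str = "neighborhood", group: str = "",
                      max_iter: int = 60) -> GgmNetwork:
    """Bisect the penalty until the inferred density matches the target.

    Edge count is non-increasing in the penalty along the solution path;
    bisection narrows in on the penalty whose achieved edge count is the
    closest attainable to ``target`` x (number of node pairs).  Ties are
    broken toward the smaller penalty (the denser network).
    """
    if not 0.0 <= target < 1.0:
        raise ValueError("target density must lie in [0, 1)")
    p = S_mixed.shape[0]
    pairs = p * (p - 1) // 2
    target_edges = int(round(target * pairs))
    nodes = nodes or [f"n{i}" for i in range(p)]

    def infer(lam):
        """Solve at lam; a non-converged solve at a small penalty (ill-posed
        when observations < nodes) is treated as denser than any target."""
        try:
            theta, adj = sparse_ggm_infer(S_mixed, lam, policy=policy,
                                          solver=solver)
        except RuntimeError:
            return None, None, pairs + 1
        return theta, adj, _edge_count(adj)

    lam_hi = float(np.abs(S_mixed - np.diag(np.diag(S_mixed))).max()) + 1e-6
    # an exactly-zero penalty is ill-posed when observations < nodes; the
    # bisection starts just above it
    lam_lo = 1e-3 * lam_hi if target > 0 else lam_hi
    best = None      # (|count - target|, lam, theta, adj)

    def consider(lam, theta, adj, count):
        nonlocal best
        if adj is None:
            return
        key = (abs(count - target_edges), lam)
        if best is None or key < (best[0], best[1]):
            best = (abs(count - target_edges), lam, theta, adj)

    theta, adj, c_lo = infer(lam_lo)
    consider(lam_lo, theta, adj, c_lo)
    if target_edges > c_lo:
        raise ValueError(
            f"target of {target_edges} edges not attainable: the unpenalized "
            f"fit has only {c_lo}")
    theta, adj, c_hi = infer(lam_hi)
    consider(lam_hi, theta, adj, c_hi)

    lo, hi = lam_lo, lam_hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        theta, adj, c = infer(mid)
        consider(mid, theta, adj, c)
        if c == target_edges:
            break
        if c > target_edges:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-10:
            break

    if best is None:
        raise ValueError("no penalty in the bracket produced a usable fit")
    _, lam_star, theta, adj = best
    rho = partial_correlation(theta)
    weights = np.where(adj, rho, 0.0)
    return GgmNetwork(nodes=list(nodes), adjacency=adj.astype(bool),
                      weights=weights, penalty=float(lam_star), group=group,
                      precision=theta)


def infer_group_networks(data: pd.DataFrame, groups: pd.Series,
                         alpha_mix: float = DEFAULT_ALPHA_MIX,
                         target_density: float = DEFAULT_DENSITY,
                         policy: str = "AND", solver: str = "neighborhood",
                         ) -> dict[str, GgmNetwork]:
    """Full two-group workflow: standardize, intertwine, calibrate."""
    per_group, pooled = group_covariances(data, groups)
    nets = {}
    for g, S_g in per_group.items():
        S_mix = intertwine(S_g, pooled, alpha_mix)
        nets[g] = calibrate_density(S_mix, target=target_density,
                                    nodes=list(data.columns), policy=policy,
                                    solver=solver, group=str(g))
    return nets


# --------------------------------------------------------------------------- #
# metrics and comparison                                                      #
# --------------------------------------------------------------------------- #

def to_networkx(net: GgmNetwork) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(net.nodes)
    idx = np.argwhere(np.triu(net.adjacency, 1))
    for i, j in idx:
        G.add_edge(net.nodes[i], net.nodes[j],
                   weight=float(net.weights[i, j]))
    return G


def network_metrics(net: GgmNetwork) -> pd.DataFrame:
    """Per-node degree and (unnormalized) betweenness centrality."""
    G = to_networkx(net)
    betweenness = nx.betweenness_centrality(G, normalized=False)
    return pd.DataFrame({
        "degree": pd.Series(dict(G.degree()), dtype=float),
        "betweenness": pd.Series(betweenness, dtype=float),
    }).loc[net.nodes]


def shared_edge_fraction(net_a: GgmNetwork, net_b: GgmNetwork,
                         ) -> dict[str, float]:
    """Edge overlap between two networks on the same node set.

    Reports the Jaccard fraction |A & B| / |A | B| together with the
    per-network fractions |A & B| / |A| and |A & B| / |B| (all as
    percentages) and the raw intersection size.
    """
    if net_a.nodes != net_b.nodes:
        raise ValueError("networks must share the same node set")
    ea, eb = net_a.edge_set(), net_b.edge_set()
    inter = len(ea & eb)
    union = len(ea | eb)
    return {
        "n_intersection": float(inter),
        "jaccard_pct": 100.0 * inter / union if union else 100.0,
        "of_a_pct": 100.0 * inter / len(ea) if ea else 100.0,
        "of_b_pct": 100.0 * inter / len(eb) if eb else 100.0,
    }


def edge_f1(net: GgmNetwork, true_edges: set[tuple[int, int]]) -> float:
    """F1 score of the inferred edge set against a true (i<j) index support."""
    inferred = {(int(i), int(j))
                for i, j in np.argwhere(np.triu(net.adjacency, 1))}
    if not inferred and not true_edges:
        return 1.0
    tp = len(inferred & true_edges)
    prec = tp / len(inferred) if inferred else 0.0
    rec = tp / len(true_edges) if true_edges else 0.0
    return 2 * prec * rec / (prec + rec) if prec + rec else 0.0


# --------------------------------------------------------------------------- #
# export                                                                      #
# --------------------------------------------------------------------------- #

def export_network(net: GgmNetwork, path: str, fmt: str = "graphml") -> None:
    """Write the network as GraphML or an edge-list TSV.

    Nodes carry degree and betweenness attributes; edges carry the signed
    partial-correlation weight.  GraphML round-trips through
    :func:`import_network`.
    """
    metrics = network_metrics(net)
    if fmt == "graphml":
        G = to_networkx(net)
        for node in G.nodes:
            G.nodes[node]["degree"] = float(metrics.loc[node, "degree"])
            G.nodes[node]["betweenness"] = float(
                metrics.loc[node, "betweenness"])
        G.graph["group"] = net.group
        G.graph["penalty"] = net.penalty
        nx.write_graphml(G, path)
    elif fmt == "tsv":
        idx = np.argwhere(np.triu(net.adjacency, 1))
        rows = [{"source": net.nodes[i], "target": net.nodes[j],
                 "partial_correlation": float(net.weights[i, j]),
                 "sign": "+" if net.weights[i, j] >= 0 else "-"}
                for i, j in idx]
        pd.DataFrame(rows, columns=["source", "target",
                                    "partial_correlation", "sign"]
                     ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_network(path: str) -> GgmNetwork:
    """Re-import a GraphML file written by :func:`export_network`."""
    G = nx.read_graphml(path)
    nodes = list(G.nodes)
    p = len(nodes)
    pos = {n: i for i, n in enumerate(nodes)}
    adj = np.zeros((p, p), dtype=bool)
    weights = np.zeros((p, p))
    for u, v, d in G.edges(data=True):
        i, j = pos[u], pos[v]
        adj[i, j] = adj[j, i] = True
        w = float(d.get("weight", 0.0))
        weights[i, j] = weights[j, i] = w
    return GgmNetwork(nodes=nodes, adjacency=adj, weights=weights,
                      penalty=float(G.graph.get("penalty", np.nan)),
                      group=str(G.graph.get("group", "")))
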
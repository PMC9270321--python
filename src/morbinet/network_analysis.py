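"""Quantities computed on an estimated network.

Community structure comes from the walktrap algorithm (short random-walk
distances, Ward-style agglomerative merging, dendrogram cut at maximum
modularity).  Node predictability reports how well each node is predicted
by its selected neighbours.  Nonparametric bootstrap and case-dropping
subsampling quantify edge accuracy and stability (correlation-stability
coefficient).  The flow layout places a target node leftmost and layers the
remaining nodes by their connection distance to it.

Community detection and the flow layout operate on absolute edge weights
(a random walk needs non-negative weights); signs are preserved in exports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .network_estimation import IsingNetwork, MGMNetwork

DROP_FRACTIONS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7)


@dataclass
class CommunityPartition:
    """node → community assignment with the merge dendrogram behind it."""

    labels: list[str]
    assignment: np.ndarray          # community id per node, contiguous from 0
    dendrogram: list[tuple]         # ordered merges (members_a, members_b)
    modularity_profile: np.ndarray  # modularity after 0, 1, ... merges
    chosen_level: int

    @property
    def n_communities(self) -> int:
        return int(self.assignment.max()) + 1

    def members(self) -> list[list[str]]:
        return [
            [self.labels[i] for i in np.flatnonzero(self.assignment == c)]
            for c in range(self.n_communities)
        ]


@dataclass
class PredictabilityReport:
    """Per-node in-sample predictability against an intercept-only baseline."""

    labels: list[str]
    measure: list[str]   # variance_explained | correct_classification
    value: np.ndarray
    baseline: np.ndarray
    isolated: list[bool]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": self.labels,
                "measure": self.measure,
                "value": self.value,
                "baseline": self.baseline,
                "isolated": self.isolated,
            }
        )


@dataclass
class BootstrapSummary:
    """Edge-weight resampling quantiles and case-dropping stability."""

    B: int
    edge_index: list[tuple[str, str]]
    q025: np.ndarray
    q50: np.ndarray
    q975: np.ndarray
    inclusion: np.ndarray
    n_failed: int
    case_drop_fractions: tuple | None = None
    case_drop_curve: np.ndarray | None = None
    cs_coefficient: float | None = None

    def to_json(self) -> str:
        payload = {
            "B": self.B,
            "edges": [list(e) for e in self.edge_index],
            "q025": self.q025.tolist(),
            "q50": self.q50.tolist(),
            "q975": self.q975.tolist(),
            "inclusion": self.inclusion.tolist(),
            "n_failed": self.n_failed,
        }
        if self.case_drop_curve is not None:
            payload["case_drop_fractions"] = list(self.case_drop_fractions)
            payload["case_drop_curve"] = self.case_drop_curve.tolist()
            payload["cs_coefficient"] = self.cs_coefficient
        return json.dumps(payload)


@dataclass
class FlowLayout:
    """Layered placement of nodes by distance to a target node."""

    target: str
    labels: list[str]
    layer: np.ndarray            # 0 for target; sentinel last layer if unreachable
    order: list[list[str]]       # vertical order per layer
    sentinel_layer: int


# ---------------------------------------------------------------------------
# walktrap


def modularity(weights: np.ndarray, assignment: np.ndarray) -> float:
    """Newman weighted modularity
    ``Q = (1/2m) Σ_ij [w_ij − k_i k_j / 2m] δ(c_i, c_j)``; 0 for an all-zero
    matrix by convention."""
    W = np.asarray(weights, dtype=float)
    two_m = W.sum()
    if two_m == 0:
        return 0.0
    k = W.sum(axis=1)
    same = assignment[:, None] == assignment[None, :]
    return float(((W - np.outer(k, k) / two_m) * same).sum() / two_m)


def walktrap(
    weights: np.ndarray, t: int = 4, labels: list[str] | None = None
) -> CommunityPartition:
    """Random-walk community detection (Pons–Latapy) with a modularity cut.

    ``weights`` must be symmetric and non-negative with a zero diagonal
    (pass absolute edge weights).  Communities are merged agglomeratively,
    always the adjacent pair whose merge least increases the mean squared
    random-walk distance; disconnected components are processed
    independently and never merged across.  The returned partition is the
    dendrogram level with maximum modularity.
    """
    W = np.asarray(weights, dtype=float)
    p = W.shape[0]
    if W.shape != (p, p) or not np.allclose(W, W.T):
        raise ValueError("weights must be a symmetric matrix")
    if (W < 0).any():
        raise ValueError("weights must be non-negative; pass absolute weights")
    if np.abs(np.diag(W)).max(initial=0.0) > 0:
        raise ValueError("self-loops are not allowed")
    if labels is None:
        labels = [f"v{i}" for i in range(p)]
    elif len(labels) != p:
        raise ValueError("labels length must match the matrix")

    deg = W.sum(axis=1)
    # transition probabilities; isolated nodes stay put (their rows are unused:
    # they are singleton components)
    P = np.zeros_like(W)
    nz = deg > 0
    P[nz] = W[nz] / deg[nz, None]
    Pt = np.linalg.matrix_power(P, t)
    inv_d = np.zeros(p)
    inv_d[nz] = 1.0 / deg[nz]

    # connected components over nonzero edges
    comp = np.full(p, -1)
    n_comp = 0
    for s in range(p):
        if comp[s] >= 0:
            continue
        stack = [s]
        comp[s] = n_comp
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(W[u] > 0):
                if comp[v] < 0:
                    comp[v] = n_comp
                    stack.append(v)
        n_comp += 1

    # community state
    members: dict[int, list[int]] = {i: [i] for i in range(p)}
    profile_vec = {i: Pt[i].copy() for i in range(p)}
    community_of = np.arange(p)
    adjacency: dict[int, set[int]] = {
        i: set(np.flatnonzero(W[i] > 0)) - {i} for i in range(p)
    }

    def dist2(a: int, b: int) -> float:
        diff = profile_vec[a] - profile_vec[b]
        return float((diff * diff * inv_d).sum())

    def delta_sigma(a: int, b: int) -> float:
        na, nb = len(members[a]), len(members[b])
        return na * nb / (na + nb) / p * dist2(a, b)

    merges: list[tuple] = []
    assignments = [community_of.copy()]
    active = set(range(p))
    while True:
        best = None
        best_cost = np.inf
        for a in active:
            for b in adjacency[a]:
                if b <= a:
                    continue
                cost = delta_sigma(a, b)
                if cost < best_cost - 1e-15:
                    best_cost = cost
                    best = (a, b)
        if best is None:
            break
        a, b = best
        merges.append((
            [labels[i] for i in members[a]],
            [labels[i] for i in members[b]],
        ))
        na, nb = len(members[a]), len(members[b])
        profile_vec[a] = (na * profile_vec[a] + nb * profile_vec[b]) / (na + nb)
        members[a] = members[a] + members[b]
        adjacency[a] = (adjacency[a] | adjacency[b]) - {a, b}
        for c in adjacency[b]:
            adjacency[c].discard(b)
            if c != a:
                adjacency[c].add(a)
        del profile_vec[b], members[b]
        adjacency.pop(b)
        active.discard(b)
        community_of = community_of.copy()
        community_of[np.isin(community_of, [b])] = a
        assignments.append(community_of.copy())

    profile = np.array([modularity(W, a) for a in assignments])
    chosen = int(np.argmax(profile))
    raw = assignments[chosen]
    # contiguous ids ordered by first occurrence
    _, contiguous = np.unique(raw, return_inverse=True)
    order_map = {}
    out = np.empty(p, dtype=int)
    nxt = 0
    for i in range(p):
        key = contiguous[i]
        if key not in order_map:
            order_map[key] = nxt
            nxt += 1
        out[i] = order_map[key]
    return CommunityPartition(labels, out, merges, profile, chosen)


# ---------------------------------------------------------------------------
# predictability


def node_predictability(table, network) -> PredictabilityReport:
    """Refit each node on its selected neighbours without penalty.

    Binary nodes report the in-sample proportion correctly classified at a
    0.5 threshold (baseline: the larger marginal class share); count and
    continuous nodes report the in-sample proportion of variance explained
    (baseline 0).  Isolated nodes score exactly their baseline.
    """
    if isinstance(table, pd.DataFrame):
        X = table[network.labels].astype(float).to_numpy()
    else:
        X = np.asarray(table, dtype=float)
    labels = network.labels
    types = (
        network.node_types
        if isinstance(network, MGMNetwork)
        else ["binary"] * len(labels)
    )
    p = len(labels)
    values = np.zeros(p)
    baselines = np.zeros(p)
    measures = []
    isolated = []
    for j in range(p):
        y = X[:, j]
        t = types[j]
        if t == "binary":
            measures.append("correct_classification")
            base = float(max(y.mean(), 1 - y.mean()))
        else:
            measures.append("variance_explained")
            base = 0.0
        baselines[j] = base
        neigh = np.flatnonzero(network.weights[j] != 0)
        if len(neigh) == 0:
            values[j] = base
            isolated.append(True)
            continue
        isolated.append(False)
        D = sm.add_constant(X[:, neigh])
        if t == "binary":
            fam = sm.families.Binomial()
        elif t == "count":
            fam = sm.families.Poisson()
        else:
            fam = sm.families.Gaussian()
        mu = np.asarray(sm.GLM(y, D, family=fam).fit(maxiter=200).predict(D))
        if t == "binary":
            values[j] = float(((mu > 0.5) == (y > 0.5)).mean())
        else:
            tss = float(((y - y.mean()) ** 2).sum())
            rss = float(((y - mu) ** 2).sum())
            values[j] = max(0.0, 1.0 - rss / tss) if tss > 0 else 0.0
    return PredictabilityReport(list(labels), measures, values, baselines, isolated)


# ---------------------------------------------------------------------------
# bootstrap accuracy & stability


def _edge_vector(net) -> np.ndarray:
    p = len(net.labels)
    iu = np.triu_indices(p, k=1)
    w = net.weights[iu]
    if isinstance(net, MGMNetwork):
        w = w * np.where(net.signs[iu] == 0, 1.0, net.signs[iu])
    return w


def _edge_index(labels) -> list[tuple[str, str]]:
    p = len(labels)
    return [(labels[i], labels[j]) for i in range(p) for j in range(i + 1, p)]


def bootstrap_edges(table, fit_fn, B: int = 1000, seed: int = 0) -> BootstrapSummary:
    """Nonparametric (n-out-of-n, with replacement) bootstrap of edge weights.

    ``fit_fn`` maps a resampled table to a fitted network.  Replicates whose
    fit fails are dropped and counted; more than 10% failures aborts.
    """
    if B < 50:
        raise ValueError("B must be >= 50")
    df = table if isinstance(table, pd.DataFrame) else pd.DataFrame(table)
    full = fit_fn(df)
    n = len(df)
    rng = np.random.default_rng(seed)
    draws = []
    failed = 0
    for _ in range(B):
        idx = rng.integers(n, size=n)
        try:
            net = fit_fn(df.iloc[idx].reset_index(drop=True))
            draws.append(_edge_vector(net))
        except Exception:
            failed += 1
            if failed > 0.1 * B:
                raise RuntimeError(
                    f"bootstrap aborted: {failed} of {B} replicates failed to fit"
                )
    M = np.vstack(draws)
    return BootstrapSummary(
        B=B,
        edge_index=_edge_index(full.labels),
        q025=np.quantile(M, 0.025, axis=0),
        q50=np.quantile(M, 0.5, axis=0),
        q975=np.quantile(M, 0.975, axis=0),
        inclusion=(M != 0).mean(axis=0),
        n_failed=failed,
    )


def case_drop_stability(
    table,
    fit_fn,
    drop_fractions=DROP_FRACTIONS,
    B: int = 100,
    seed: int = 0,
    corr_threshold: float = 0.7,
    certainty: float = 0.95,
) -> BootstrapSummary:
    """Case-dropping subsampling and the correlation-stability coefficient.

    For each drop fraction, ``B`` subsamples (without replacement) are
    refitted and their edge vectors correlated with the full-sample edge
    vector.  The CS coefficient is the largest fraction at which the
    correlation stays ≥ ``corr_threshold`` in at least ``certainty`` of
    replicates (requiring all smaller fractions to qualify as well).
    An undefined correlation (constant edge vector) counts as a failure.
    """
    if B < 50:
        raise ValueError("B must be >= 50")
    df = table if isinstance(table, pd.DataFrame) else pd.DataFrame(table)
    full = fit_fn(df)
    base = _edge_vector(full)
    n = len(df)
    rng = np.random.default_rng(seed)
    curve = []
    pass_rates = []
    for frac in drop_fractions:
        keep = max(3, int(round((1 - frac) * n)))
        corrs = []
        for _ in range(B):
            idx = rng.choice(n, size=keep, replace=False)
            try:
                net = fit_fn(df.iloc[idx].reset_index(drop=True))
                v = _edge_vector(net)
                if np.std(v) == 0 or np.std(base) == 0:
                    corrs.append(np.nan)
                else:
                    corrs.append(float(np.corrcoef(base, v)[0, 1]))
            except Exception:
                corrs.append(np.nan)
        corrs = np.array(corrs)
        ok = np.where(np.isnan(corrs), False, corrs >= corr_threshold)
        curve.append(float(np.nanmean(corrs)) if not np.isnan(corrs).all() else np.nan)
        pass_rates.append(ok.mean())
    cs = 0.0
    for frac, rate in zip(drop_fractions, pass_rates):
        if rate >= certainty:
            cs = frac
        else:
            break
    return BootstrapSummary(
        B=B,
        edge_index=_edge_index(full.labels),
        q025=np.array([]),
        q50=np.array([]),
        q975=np.array([]),
        inclusion=np.array([]),
        n_failed=0,
        case_drop_fractions=tuple(drop_fractions),
        case_drop_curve=np.array(curve),
        cs_coefficient=cs,
    )


# ---------------------------------------------------------------------------
# flow layout


def flow_layers(network, target: str) -> FlowLayout:
    """Layer nodes by unweighted shortest-path distance to a target node.

    Layer 0 holds the target alone; unreachable nodes (e.g. a morbidity
    isolated from the rest of the network) share a sentinel final layer.
    Within-layer vertical order is a single barycenter pass over the
    previous layer.
    """
    labels = list(network.labels)
    if target not in labels:
        raise ValueError(f"unknown target {target!r}; labels: {labels}")
    W = np.abs(network.weights)
    p = len(labels)
    G = nx.Graph()
    G.add_nodes_from(range(p))
    for i in range(p):
        for j in range(i + 1, p):
            if W[i, j] > 0:
                G.add_edge(i, j)
    tgt = labels.index(target)
    dist = nx.single_source_shortest_path_length(G, tgt)
    reachable = max(dist.values())
    sentinel = reachable + 1 if len(dist) < p else reachable + 1
    layer = np.array([dist.get(i, sentinel) for i in range(p)])

    order: list[list[str]] = []
    prev_pos: dict[int, float] = {}
    for lv in sorted(set(layer)):
        nodes = list(np.flatnonzero(layer == lv))
        if lv == 0:
            ranked = nodes
        else:
            def barycenter(i: int) -> float:
                ups = [prev_pos[j] for j in G.neighbors(i) if j in prev_pos]
                return float(np.mean(ups)) if ups else float(len(prev_pos))

            ranked = sorted(nodes, key=lambda i: (barycenter(i), labels[i]))
        prev_pos = {i: k for k, i in enumerate(ranked)}
        order.append([labels[i] for i in ranked])
    return FlowLayout(target, labels, layer, order, sentinel)


# ---------------------------------------------------------------------------
# export


def to_graphml(
    network,
    path,
    prevalence: dict | None = None,
    predictability: PredictabilityReport | None = None,
    partition: CommunityPartition | None = None,
    layout: FlowLayout | None = None,
) -> None:
    """Write a network with optional node annotations as GraphML."""
    G = nx.Graph()
    labels = network.labels
    pred = dict(zip(predictability.labels, predictability.value)) if predictability else {}
    comm = (
        dict(zip(labels, (int(c) for c in partition.assignment))) if partition else {}
    )
    lay = dict(zip(labels, (int(v) for v in layout.layer))) if layout else {}
    types = network.node_types if isinstance(network, MGMNetwork) else ["binary"] * len(labels)
    for i, name in enumerate(labels):
        attrs = {"node_type": types[i]}
        if prevalence and name in prevalence:
            attrs["prevalence"] = float(prevalence[name])
        if name in pred:
            attrs["predictability"] = float(pred[name])
        if name in comm:
            attrs["community"] = comm[name]
        if name in lay:
            attrs["layer"] = lay[name]
        G.add_node(name, **attrs)
    edges = network.edge_list()
    for row in edges.itertuples():
        G.add_edge(
            row.node_i,
            row.node_j,
            weight=float(row.weight),
            sign=int(row.sign),
            thickness=abs(float(row.weight)),
        )
    nx.write_graphml(G, path)
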
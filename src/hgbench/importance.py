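"""Edge-importance components and the combined percentile-rank measure.

For an edge population (typically the associations first published in a test
year), six per-edge components quantify how much the association mattered for
the later evolution of the network:

``ig``
    Integrated-gradients attribution of the edge toward a GCN link
    predictor's scores for edges added later (predictive impact).
``ec``
    Change in the edge-level eigenvector-centrality gap
    ``|C_E(u) - C_E(v)|`` between the test snapshot and the importance
    snapshot (structural impact; sign is kept).
``bc``
    Edge betweenness restricted to pairs of nodes involved in future
    connections (information-flow impact).
``jc2``
    Second-order Jaccard similarity of the endpoints' two-hop
    neighbourhoods on the snapshot *before* discovery; similar
    neighbourhoods make a connection trivial, so this component enters the
    combination negated.
``ment``
    Number of distinct documents mentioning the pair up to the importance
    year.
``cit``
    Sum of citation counts (taken as-is, not log-scaled) of those
    documents, restricted to citations up to the importance year.

The combined measure is the arithmetic mean of the six percentile ranks
(midrank convention), so it always lies inside the unit interval and is
invariant to any strictly monotone transform of a raw component.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .attribution import AttributionResult, LinkPredictor, TrainConfig
from .dyngraph import CitationGraph, DynamicGraph, canonical_edge

__all__ = [
    "COMPONENTS",
    "ImportanceConfig",
    "edge_betweenness_restricted",
    "eigenvector_node_centrality",
    "edge_eigenvector_delta",
    "second_order_jaccard",
    "mention_score",
    "citation_score",
    "percentile_rank",
    "combine_importance",
    "component_correlation",
    "EdgeImportance",
    "ImportanceResults",
]

COMPONENTS = ("ig", "ec", "bc", "jc2", "ment", "cit")


@dataclass
class ImportanceConfig:
    """Timestamp triple and knobs for the importance computation.

    ``train_year < test_year <= importance_year``: predictor systems under
    benchmark train on data up to ``train_year``, the scored edge population
    is the associations first published at ``test_year``, and every component
    accumulates impact up to ``importance_year``.
    """

    train_year: int
    test_year: int
    importance_year: int
    ig_steps: int = 100
    n_bins: int = 3

    def __post_init__(self) -> None:
        if not (self.train_year < self.test_year <= self.importance_year):
            raise ValueError(
                "require train_year < test_year <= importance_year, got "
                f"{self.train_year}/{self.test_year}/{self.importance_year}"
            )
        if self.ig_steps < 1 or self.n_bins < 1:
            raise ValueError("ig_steps and n_bins must be >= 1")


# -- graph-based components -------------------------------------------------


def edge_betweenness_restricted(
    graph: nx.Graph, focus_nodes: Iterable[str], exact: bool = False
) -> dict:
    """Edge betweenness over unordered pairs of *focus_nodes*.

    ``C_B(e) = sum_{s != t in focus} sigma_st(e) / sigma_st`` with unweighted
    shortest paths; pairs with no connecting path contribute 0.  Edges
    incident to s or t on a shortest path are counted (standard sigma
    semantics).  Computed exactly in rational arithmetic (Brandes-style
    accumulation with restricted targets); set *exact* to receive Fractions.
    """
    focus = set(focus_nodes)
    unknown = focus - set(graph.nodes())
    if unknown:
        raise ValueError(f"focus nodes not in graph: {sorted(unknown)[:5]}")
    scores: dict[tuple, Fraction] = {
        canonical_edge(u, v): Fraction(0) for u, v in graph.edges()
    }
    if not focus:
        warnings.warn("empty focus set: all betweenness scores are zero")
        return {e: (v if exact else 0.0) for e, v in scores.items()}

    for s in focus:
        # BFS with path counting
        sigma: dict = {s: 1}
        dist: dict = {s: 0}
        preds: dict = {s: []}
        order: list = []
        queue = deque([s])
        while queue:
            v = queue.popleft()
            order.append(v)
            for w in graph[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    sigma[w] = 0
                    preds[w] = []
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta: dict = {v: Fraction(0) for v in order}
        for w in reversed(order):
            is_target = 1 if (w in focus and w != s) else 0
            coeff = (delta[w] + is_target) / sigma[w]
            for v in preds[w]:
                c = sigma[v] * coeff
                scores[canonical_edge(v, w)] += c
                delta[v] += c
    # ordered pairs counted twice
    half = {e: v / 2 for e, v in scores.items()}
    return half if exact else {e: float(v) for e, v in half.items()}


def eigenvector_node_centrality(
    graph: nx.Graph, weight: str | None = "weight"
) -> dict[str, float]:
    """Principal-eigenvector centrality of the weighted adjacency.

    Computed independently per connected component via shifted power
    iteration (start vector all-ones, shift = max row sum, tolerance 1e-10,
    max 10,000 iterations; dense eigendecomposition fallback on
    non-convergence).  Each component's sub-vector is non-negative with unit
    L2 norm; isolated nodes score 0.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    out: dict[str, float] = {n: 0.0 for n in graph.nodes()}
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        if len(nodes) == 1:
            # singleton: no edges -> centrality 0
            continue
        A = nx.to_scipy_sparse_array(
            graph.subgraph(nodes), nodelist=nodes, weight=weight, format="csr"
        ).astype(float)
        vec = _principal_vector(A)
        for n, x in zip(nodes, vec):
            out[n] = float(x)
    return out


def _principal_vector(A: sp.csr_matrix) -> np.ndarray:
    n = A.shape[0]
    shift = float(np.abs(A).sum(axis=1).max())
    x = np.ones(n) / np.sqrt(n)
    converged = False
    for _ in range(10000):
        y = A @ x + shift * x
        nrm = np.linalg.norm(y)
        if nrm == 0.0:
            break
        y /= nrm
        if np.max(np.abs(y - x)) < 1e-10:
            x = y
            converged = True
            break
        x = y
    if not converged:
        w, v = np.linalg.eigh(A.toarray())
        x = v[:, int(np.argmax(w))]
    if x.sum() < 0:
        x = -x
    x = np.clip(x, 0.0, None)
    nrm = np.linalg.norm(x)
    return x / nrm if nrm > 0 else x


def edge_eigenvector_delta(
    G: DynamicGraph, t: int, t_future: int | None = None
) -> dict[tuple[str, str], float]:
    """Change of the edge centrality gap between snapshots t and t_future.

    ``C_E(e)|_tau = |C_E(u) - C_E(v)|`` on snapshot tau; the result is
    ``C_E(e)|_{t_future} - C_E(e)|_t`` for every edge of snapshot t (an
    endpoint absent from a snapshot contributes centrality 0 there).
    Defaults to the next year; may be negative (the gap can shrink).
    """
    tf = t + 1 if t_future is None else t_future
    G._check_year(t)
    G._check_year(tf)
    snap_t = G.snapshot(t)
    snap_f = G.snapshot(tf)

    def edge_vals(snap: nx.Graph) -> dict:
        if snap.number_of_nodes() == 0:
            return {}
        cent = eigenvector_node_centrality(snap)
        return cent

    cent_t = edge_vals(snap_t)
    cent_f = edge_vals(snap_f)
    out: dict[tuple[str, str], float] = {}
    for u, v in snap_t.edges():
        e = canonical_edge(u, v)
        val_t = abs(cent_t.get(u, 0.0) - cent_t.get(v, 0.0))
        val_f = abs(cent_f.get(u, 0.0) - cent_f.get(v, 0.0))
        out[e] = val_f - val_t
    return out


def second_order_jaccard(
    graph: nx.Graph, pairs: Iterable[tuple[str, str]]
) -> dict[tuple[str, str], float]:
    """Second-order Jaccard similarity J2 for node pairs on *graph*.

    ``N2(u)`` is the union of the neighbours of u's neighbours — by the
    literal definition it may contain u itself (some libraries exclude it).
    Pairs with an endpoint missing from the graph are skipped with a warning;
    two empty second-order neighbourhoods give J2 = 0.
    """
    cache: dict[str, frozenset] = {}

    def n2(u: str) -> frozenset:
        if u not in cache:
            acc: set = set()
            for w in graph[u]:
                acc.update(graph[w])
            cache[u] = frozenset(acc)
        return cache[u]

    out: dict[tuple[str, str], float] = {}
    for u, v in pairs:
        if u not in graph or v not in graph:
            warnings.warn(f"pair ({u}, {v}) has an endpoint outside the graph; skipped")
            continue
        a, b = n2(u), n2(v)
        union = len(a | b)
        out[canonical_edge(u, v)] = (len(a & b) / union) if union else 0.0
    return out


# -- literature-based components ---------------------------------------------


def mention_score(G: DynamicGraph, edge: tuple[str, str], t_imp: int) -> int:
    """Distinct documents mentioning *edge* in years <= t_imp."""
    e = canonical_edge(*edge)
    if e not in G.birth_year:
        warnings.warn(f"edge {e} never observed; mention score 0")
        return 0
    return len(G.edge_documents(e, up_to_year=t_imp))


def citation_score(
    G: DynamicGraph, C: CitationGraph, edge: tuple[str, str], t_imp: int
) -> int:
    """Sum of citation counts (<= t_imp) of all documents mentioning *edge*.

    Citation counts are used as-is (no log scale); a document absent from the
    citation graph contributes 0.
    """
    e = canonical_edge(*edge)
    if e not in G.birth_year:
        warnings.warn(f"edge {e} never observed; citation score 0")
        return 0
    return sum(C.in_degree(d, up_to_year=t_imp) for d in G.edge_documents(e, t_imp))


# -- combination --------------------------------------------------------------


def percentile_rank(values: Sequence[float]) -> np.ndarray:
    """Midrank percentile: (#{x_j < x_i} + 0.5 #{x_j = x_i}) / n, in (0, 1)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("percentile_rank of an empty sequence")
    return (scipy.stats.rankdata(arr, method="average") - 0.5) / arr.size


def combine_importance(
    raw_components: Mapping[tuple[str, str], Mapping[str, float]],
) -> pd.DataFrame:
    """Combine the six raw components into the mean-percentile-rank measure.

    Returns a DataFrame indexed by canonical edge with columns ``<comp>``
    (raw), ``pct_<comp>`` and ``combined``.  ``jc2`` is negated before
    ranking: the more similar two neighbourhoods already were, the more
    trivial — hence less important — the connection.  A missing ``ig`` value
    (edge outside the attribution scope) is taken as raw 0 with a warning.
    """
    edges = sorted(raw_components)
    if not edges:
        raise ValueError("no edges to combine")
    data: dict[str, list[float]] = {c: [] for c in COMPONENTS}
    missing_ig = 0
    for e in edges:
        comps = raw_components[e]
        for c in COMPONENTS:
            if c == "ig" and c not in comps:
                missing_ig += 1
                data[c].append(0.0)
                continue
            if c not in comps:
                raise ValueError(f"edge {e} lacks component {c!r}")
            data[c].append(float(comps[c]))
    if missing_ig:
        warnings.warn(f"{missing_ig} edge(s) outside attribution scope: ig raw set to 0")

    df = pd.DataFrame(data, index=pd.Index(edges, name="edge", tupleize_cols=False))
    for c in COMPONENTS:
        col = np.asarray(df[c], dtype=float)
        if np.isnan(col).any():
            raise ValueError(f"component {c!r} contains NaN values")
        oriented = -col if c == "jc2" else col
        df[f"pct_{c}"] = percentile_rank(oriented)
    df["combined"] = df[[f"pct_{c}" for c in COMPONENTS]].mean(axis=1)
    return df


def component_correlation(records: pd.DataFrame) -> pd.DataFrame:
    """6x6 Spearman correlation matrix between raw components (midrank ties).

    A constant component has an undefined correlation; its row/column is
    reported as NaN (missing), never coerced to 0.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records for a correlation matrix")
    cols = list(COMPONENTS)
    mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        xa = np.asarray(records[a], dtype=float)
        if np.all(xa == xa[0]):
            mat.loc[a, :] = np.nan
            mat.loc[:, a] = np.nan
            continue
        for b in cols[i + 1 :]:
            xb = np.asarray(records[b], dtype=float)
            if np.all(xb == xb[0]):
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = scipy.stats.spearmanr(xa, xb).statistic
            mat.loc[a, b] = rho
            mat.loc[b, a] = rho
    return mat


# -- model facade -------------------------------------------------------------


class EdgeImportance:
    """Importance model for the edges first published at the test year.

    Component alignment: ``jc2`` is computed on the snapshot before discovery
    (test_year - 1); ``bc`` on the test snapshot with focus nodes drawn from
    edges added in (test_year, importance_year]; ``ec`` is the delta between
    the test and importance snapshots; ``ig`` trains the link predictor on
    the test snapshot with those same future edges as targets; ``ment`` and
    ``cit`` accumulate to the importance year.

    *population* selects the scored edge set: ``"new_edges"`` (default) scores
    the associations first published at the test year — the benchmark's
    positives — while ``"all"`` scores every edge of the test snapshot, the
    natural population for network-wide analyses such as planted-signal
    recovery.  Percentile ranks are taken within the chosen population.
    """

    def __init__(
        self,
        graph: DynamicGraph,
        citations: CitationGraph,
        config: ImportanceConfig,
        features: Mapping[str, np.ndarray] | None = None,
        train_config: TrainConfig | None = None,
        population: str = "new_edges",
    ):
        if population not in ("new_edges", "all"):
            raise ValueError(f"unknown population {population!r}")
        self.graph = graph
        self.citations = citations
        self.config = config
        self.train_config = train_config or TrainConfig()
        self._features = features
        self.population = population

    def fit(self) -> "ImportanceResults":
        G, cfg = self.graph, self.config
        t_test, t_imp = cfg.test_year, cfg.importance_year
        if self.population == "new_edges":
            population = G.new_edges(t_test)
        else:
            population = sorted(G.edges_at(t_test))
        if not population:
            raise ValueError(f"no eligible edges first published at {t_test}")

        snap_test = G.snapshot(t_test)
        nodes_test = set(snap_test.nodes())
        future = G.edges_in_window(t_test, t_imp, restrict_to=nodes_test)

        # integrated gradients
        attribution: AttributionResult | None = None
        if future:
            feats = self._features
            if feats is None:
                order = sorted(nodes_test)
                mat = G.feature_matrix(order)
                if mat is None:
                    raise ValueError(
                        "node features required for the link predictor; none supplied"
                    )
                feats = {n: mat[i] for i, n in enumerate(order)}
            model = LinkPredictor(snap_test, feats, future, self.train_config)
            fitted = model.fit()
            attribution = fitted.integrated_gradients(steps=cfg.ig_steps)
            ig_map = attribution.edge_scores
        else:
            warnings.warn(
                f"no future edges in ({t_test}, {t_imp}]; ig component is all zero"
            )
            fitted = None
            ig_map = {}

        # structural components
        if future:
            focus = {n for e in future for n in e}
            bc_map = edge_betweenness_restricted(snap_test, focus)
        else:
            bc_map = {canonical_edge(u, v): 0.0 for u, v in snap_test.edges()}
        ec_map = edge_eigenvector_delta(G, t_test, t_imp)
        snap_prev = G.snapshot(t_test - 1)
        jc2_map = second_order_jaccard(snap_prev, population)

        raw: dict[tuple[str, str], dict[str, float]] = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # per-edge lookups warn individually
            for e in population:
                raw[e] = {
                    "ig": ig_map.get(e, 0.0),
                    "ec": ec_map.get(e, 0.0),
                    "bc": bc_map.get(e, 0.0),
                    "jc2": jc2_map.get(e, 0.0),
                    "ment": float(mention_score(G, e, t_imp)),
                    "cit": float(citation_score(G, self.citations, e, t_imp)),
                }
        frame = combine_importance(raw)
        return ImportanceResults(self, frame, attribution, fitted)


class ImportanceResults:
    """Fitted importance records with summary and correlation views."""

    def __init__(self, model: EdgeImportance, frame: pd.DataFrame,
                 attribution: AttributionResult | None, predictor):
        self.model = model
        self.frame = frame
        self.attribution = attribution
        self.predictor = predictor

    @property
    def combined(self) -> pd.Series:
        return self.frame["combined"]

    def component_correlation(self) -> pd.DataFrame:
        return component_correlation(self.frame)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Edge importance summary",
            "=======================",
            f"timestamps: train={cfg.train_year} test={cfg.test_year} "
            f"importance={cfg.importance_year}",
            f"edges scored: {len(self.frame)}",
            "",
            "raw component means:",
        ]
        for c in COMPONENTS:
            lines.append(f"  {c:>5}: {self.frame[c].mean():+.6g}")
        if self.attribution is not None:
            lines.append(
                f"IG completeness error: {self.attribution.completeness_error:.3e} "
                f"(steps={self.attribution.steps})"
            )
        lines.append("")
        lines.append("top 5 edges by combined importance:")
        top = self.frame.sort_values("combined", ascending=False).head(5)
        for e, row in top.iterrows():
            lines.append(f"  {e[0]}--{e[1]}: I = {row['combined']:.4f}")
        return "\n".join(lines)
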
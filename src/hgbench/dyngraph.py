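"""Cumulative time-sliced concept co-occurrence networks.

The central object is :class:`DynamicGraph`: a sequence of yearly snapshots
``G_t = (N_t, E_t)`` built from timestamped pairwise co-occurrence
observations ``(u, v, year, doc_id)``.  Snapshots are *cumulative* — an edge
present at year ``t`` is present at every later year — simple and undirected.
The node set ``N_t`` is induced by the edge set: a concept enters the network
when its first association is observed.

A companion :class:`CitationGraph` holds a directed document-level citation
network (citing document -> cited document, with the citation year); the
in-degree of a document is its citation count.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ConceptNode",
    "EdgeObservation",
    "DynamicGraph",
    "CitationGraph",
    "canonical_edge",
    "build_dynamic_graph",
    "read_graph_dir",
    "write_graph_dir",
]


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Return the undirected pair in canonical (lexicographic) order."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class ConceptNode:
    """A concept with a semantic-type label and an optional feature vector."""

    node_id: str
    semantic_type: str
    features: tuple[float, ...] | None = None

    def feature_array(self) -> np.ndarray | None:
        return None if self.features is None else np.asarray(self.features, dtype=float)


@dataclass(frozen=True, order=True)
class EdgeObservation:
    """One co-occurrence record: concept pair, year, supporting document.

    Pairs are undirected and stored canonically (smaller node id first);
    self-loops are rejected.
    """

    u: str
    v: str
    year: int
    doc_id: str

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise ValueError(f"self-loop observation rejected: ({self.u}, {self.v})")
        if self.u > self.v:
            u, v = self.u, self.v
            object.__setattr__(self, "u", v)
            object.__setattr__(self, "v", u)

    @property
    def edge(self) -> tuple[str, str]:
        return (self.u, self.v)


class DynamicGraph:
    """Cumulative snapshot sequence built from co-occurrence observations.

    Use :func:`build_dynamic_graph` to construct one with validation.
    """

    def __init__(
        self,
        nodes: Mapping[str, ConceptNode],
        observations: Sequence[EdgeObservation],
        years: Sequence[int],
    ):
        self.nodes: dict[str, ConceptNode] = dict(nodes)
        self.observations: list[EdgeObservation] = sorted(set(observations))
        self.years: list[int] = list(years)

        # edge -> sorted list of (year, doc_id); distinct documents per edge
        self._edge_docs: dict[tuple[str, str], list[tuple[int, str]]] = {}
        self._doc_year: dict[str, int] = {}
        for obs in self.observations:
            self._edge_docs.setdefault(obs.edge, []).append((obs.year, obs.doc_id))
            prev = self._doc_year.get(obs.doc_id)
            if prev is None or obs.year < prev:
                self._doc_year[obs.doc_id] = obs.year
        self.birth_year: dict[tuple[str, str], int] = {
            e: docs[0][0] for e, docs in self._edge_docs.items()
        }

    # -- basic accessors ---------------------------------------------------

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self._edge_docs)

    @property
    def documents(self) -> dict[str, int]:
        """Mapping doc_id -> first year the document is observed."""
        return dict(self._doc_year)

    def edge_documents(
        self, edge: tuple[str, str], up_to_year: int | None = None
    ) -> list[str]:
        """Distinct documents mentioning *edge* in years <= up_to_year."""
        docs = self._edge_docs.get(canonical_edge(*edge), [])
        seen: dict[str, None] = {}
        for year, doc in docs:
            if up_to_year is None or year <= up_to_year:
                seen.setdefault(doc, None)
        return list(seen)

    def _check_year(self, t: int) -> None:
        if not self.years or t < self.years[0] or t > self.years[-1]:
            lo = self.years[0] if self.years else "?"
            hi = self.years[-1] if self.years else "?"
            raise ValueError(f"year {t} outside known range [{lo}, {hi}]")

    # -- snapshot operations -----------------------------------------------

    def snapshot(self, t: int) -> nx.Graph:
        """Static undirected snapshot ``G_t``.

        Each edge carries ``weight`` = number of distinct documents mentioning
        the pair in years <= t.  ``N_t`` is exactly the endpoints of ``E_t``:
        a declared-but-unobserved concept does not appear.
        """
        self._check_year(t)
        G = nx.Graph()
        for edge, docs in self._edge_docs.items():
            w = len({doc for year, doc in docs if year <= t})
            if w > 0:
                G.add_edge(edge[0], edge[1], weight=w)
        return G

    def nodes_at(self, t: int) -> set[str]:
        self._check_year(t)
        out: set[str] = set()
        for (u, v), birth in self.birth_year.items():
            if birth <= t:
                out.add(u)
                out.add(v)
        return out

    def edges_at(self, t: int) -> set[tuple[str, str]]:
        self._check_year(t)
        return {e for e, birth in self.birth_year.items() if birth <= t}

    def new_edges(self, t: int) -> list[tuple[str, str]]:
        """Edges first appearing at year ``t`` with both endpoints in ``N_{t-1}``.

        This is the restricted target set for link prediction: pairs of
        concepts that already existed before the association was published.
        """
        self._check_year(t)
        if t == self.years[0]:
            raise ValueError(
                f"year {t} is the first snapshot; no prior node set exists"
            )
        prior = self.nodes_at(t - 1)
        return sorted(
            e
            for e, birth in self.birth_year.items()
            if birth == t and e[0] in prior and e[1] in prior
        )

    def edges_in_window(
        self, after: int, up_to: int, restrict_to: set[str] | None = None
    ) -> list[tuple[str, str]]:
        """Edges first appearing in ``(after, up_to]``, optionally restricted
        to pairs whose endpoints are both in *restrict_to*."""
        out = [
            e
            for e, birth in self.birth_year.items()
            if after < birth <= up_to
            and (restrict_to is None or (e[0] in restrict_to and e[1] in restrict_to))
        ]
        return sorted(out)

    def feature_matrix(self, node_order: Sequence[str]) -> np.ndarray | None:
        """Stacked feature matrix for *node_order*, or None if featureless."""
        feats = [self.nodes[n].features for n in node_order]
        if any(f is None for f in feats):
            return None
        return np.asarray(feats, dtype=float)


class CitationGraph:
    """Directed document citation network: (citing_doc, cited_doc, year)."""

    def __init__(self, edges: Iterable[tuple[str, str, int]]):
        self.edges: list[tuple[str, str, int]] = []
        self._cited_by: dict[str, list[int]] = {}
        seen: set[tuple[str, str]] = set()
        for citing, cited, year in edges:
            if citing == cited:
                raise ValueError(f"self-citation rejected: {citing}")
            if (citing, cited) in seen:
                continue
            seen.add((citing, cited))
            self.edges.append((citing, cited, int(year)))
            self._cited_by.setdefault(cited, []).append(int(year))
        self.edges.sort()
        for years in self._cited_by.values():
            years.sort()

    def in_degree(self, doc: str, up_to_year: int | None = None) -> int:
        """Citation count of *doc*, optionally restricted to years <= up_to_year."""
        years = self._cited_by.get(doc, [])
        if up_to_year is None:
            return len(years)
        return int(np.searchsorted(years, up_to_year, side="right"))


def build_dynamic_graph(
    observations: Iterable[EdgeObservation],
    nodes: Iterable[ConceptNode],
    years: Sequence[int] | None = None,
) -> DynamicGraph:
    """Validate observations against the node table and build the graph.

    Observations are deduplicated on ``(u, v, year, doc_id)``.  Every
    observation endpoint must be declared in *nodes*; declared nodes never
    observed stay in the vocabulary (available for negative sampling) but are
    absent from every ``N_t``.
    """
    node_list = list(nodes)
    node_map = {n.node_id: n for n in node_list}
    if len(node_map) < len(node_list):
        raise ValueError("duplicate node ids in the node table")
    dims = {len(n.features) for n in node_map.values() if n.features is not None}
    if len(dims) > 1:
        raise ValueError(f"inconsistent feature dimensions: {sorted(dims)}")

    obs_list = sorted(set(observations))
    for obs in obs_list:
        for endpoint in (obs.u, obs.v):
            if endpoint not in node_map:
                raise ValueError(f"observation references unknown node id: {endpoint!r}")
    if years is None:
        if obs_list:
            y0 = min(o.year for o in obs_list)
            y1 = max(o.year for o in obs_list)
            years = list(range(y0, y1 + 1))
        else:
            years = []
    return DynamicGraph(node_map, obs_list, years)


# -- on-disk format --------------------------------------------------------
#
# edges.tsv:      u <TAB> v <TAB> year <TAB> doc_id
# nodes.tsv:      node_id <TAB> semantic_type [<TAB> f0 <TAB> f1 ...]
# citations.tsv:  citing_doc <TAB> cited_doc <TAB> year
#
# Writers emit UTF-8, LF endings, deterministic row order.


def write_graph_dir(
    out_dir: str | os.PathLike,
    graph: DynamicGraph,
    citations: CitationGraph | None = None,
) -> None:
    os.makedirs(out_dir, exist_ok=True)
    rows = sorted((o.u, o.v, o.year, o.doc_id) for o in graph.observations)
    _write_tsv(
        os.path.join(out_dir, "edges.tsv"),
        pd.DataFrame(rows, columns=["u", "v", "year", "doc_id"]),
    )
    node_rows = []
    for nid in sorted(graph.nodes):
        node = graph.nodes[nid]
        row: list[object] = [nid, node.semantic_type]
        if node.features is not None:
            row.extend(repr(float(x)) for x in node.features)
        node_rows.append(row)
    width = max((len(r) for r in node_rows), default=2)
    cols = ["node_id", "semantic_type"] + [f"f{i}" for i in range(width - 2)]
    _write_tsv(os.path.join(out_dir, "nodes.tsv"), pd.DataFrame(node_rows, columns=cols))
    if citations is not None:
        _write_tsv(
            os.path.join(out_dir, "citations.tsv"),
            pd.DataFrame(sorted(citations.edges), columns=["citing_doc", "cited_doc", "year"]),
        )


def _write_tsv(path: str, df: pd.DataFrame) -> None:
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())


def read_graph_dir(
    in_dir: str | os.PathLike,
) -> tuple[DynamicGraph, CitationGraph | None]:
    edges_path = os.path.join(in_dir, "edges.tsv")
    nodes_path = os.path.join(in_dir, "nodes.tsv")
    for p in (edges_path, nodes_path):
        if not os.path.exists(p):
            raise FileNotFoundError(f"required input file missing: {p}")
    edf = pd.read_csv(edges_path, sep="\t", dtype={"u": str, "v": str, "doc_id": str})
    ndf = pd.read_csv(nodes_path, sep="\t", dtype={"node_id": str, "semantic_type": str})
    feat_cols = [c for c in ndf.columns if c.startswith("f")]
    nodes = []
    for _, r in ndf.iterrows():
        feats = tuple(float(r[c]) for c in feat_cols) if feat_cols else None
        nodes.append(ConceptNode(r["node_id"], r["semantic_type"], feats))
    observations = [
        EdgeObservation(r.u, r.v, int(r.year), r.doc_id)
        for r in edf.itertuples(index=False)
    ]
    graph = build_dynamic_graph(observations, nodes)
    citations = None
    cit_path = os.path.join(in_dir, "citations.tsv")
    if os.path.exists(cit_path):
        cdf = pd.read_csv(cit_path, sep="\t", dtype={"citing_doc": str, "cited_doc": str})
        citations = CitationGraph(
            (r.citing_doc, r.cited_doc, int(r.year)) for r in cdf.itertuples(index=False)
        )
    return graph, citations
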
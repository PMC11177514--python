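"""Stratified evaluation harness for link scorers.

Any object with a ``score(subject, object) -> float`` method and a ``name``
can be benchmarked; higher means more plausible, and scores only need to be
mutually comparable within one scorer.  Positives are associations first
published after the training cut; for each positive (s, o), N corrupted
pairs (s, o') are drawn whose object shares o's semantic type and which
collide with no known association ("subdomain recommendation" sampling).

Ranking quality is pairwise ROC AUC:

    AUC(f) = (1 / |D0||D1|) sum_{t0 in D0} sum_{t1 in D1} 1[f(t0) < f(t1)]

with the conventional half credit for ties (a constant scorer gets 0.5); a
``strict`` mode reproduces the literal strict-inequality formula.  Results
can be stratified by semantic-type pair, by bins of the combined importance
measure, or by test year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from hashlib import blake2b
from typing import Callable, Iterable, Mapping, Protocol, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .dyngraph import ConceptNode, DynamicGraph, canonical_edge

__all__ = [
    "Scorer",
    "EvaluationSample",
    "StratumScore",
    "StratifiedResult",
    "sample_negatives",
    "roc_auc",
    "evaluate_semantic",
    "evaluate_importance_bins",
    "evaluate_temporal",
    "baseline_scorers",
    "CommonNeighborsScorer",
    "JaccardScorer",
    "PreferentialAttachmentScorer",
    "RandomScorer",
    "GNNScorer",
]


class Scorer(Protocol):
    name: str

    def score(self, subject: str, obj: str) -> float: ...


@dataclass
class EvaluationSample:
    """One positive pair with its type-matched negative pairs and labels."""

    subject: str
    obj: str
    year: int
    type_pair: str
    negatives: list[tuple[str, str]]  # corrupted pairs, e.g. (subject, o')
    flagged: bool = False  # no eligible negative existed

    @property
    def positive(self) -> tuple[str, str]:
        return (self.subject, self.obj)


@dataclass
class StratumScore:
    auc: float
    n_pos: int
    n_neg: int


@dataclass
class StratifiedResult:
    strata: dict[str, StratumScore]
    scorer_name: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stratum": k, "auc": v.auc, "n_pos": v.n_pos, "n_neg": v.n_neg}
            for k, v in self.strata.items()
        ]
        return pd.DataFrame(rows)

    def __getitem__(self, label: str) -> StratumScore:
        return self.strata[label]


def type_pair_label(type_a: str, type_b: str) -> str:
    a, b = sorted((type_a, type_b))
    return f"{a}<->{b}"


def sample_negatives(
    positives: Sequence[tuple[str, str, int]],
    vocabulary: Iterable[ConceptNode],
    N: int,
    known_edges: Iterable[tuple[str, str]],
    seed: int,
    corrupt: str = "object",
) -> list[EvaluationSample]:
    """Type-constrained negative sampling ("subdomain recommendation").

    For each positive ``(subject, object, year)`` draw up to *N* distinct
    corrupted pairs ``(subject, o')`` with o' != object sharing the object's
    semantic type, uniformly without replacement, excluding the subject
    itself and any pair present in *known_edges* (associations known at any
    time).  With ``corrupt="both"`` the candidate pool additionally contains
    subject-corrupted pairs ``(s', object)`` with s' of the subject's type.
    Deterministic given *seed*; a positive with fewer than N candidates
    keeps what exists (with a warning), and one with zero candidates is
    flagged.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if corrupt not in ("object", "both"):
        raise ValueError(f"unknown corruption mode {corrupt!r}")
    vocab = list(vocabulary)
    type_of = {n.node_id: n.semantic_type for n in vocab}
    by_type: dict[str, list[str]] = {}
    for n in sorted(vocab, key=lambda n: n.node_id):
        by_type.setdefault(n.semantic_type, []).append(n.node_id)
    known = {canonical_edge(u, v) for u, v in known_edges}

    rng = np.random.default_rng(seed)
    out: list[EvaluationSample] = []
    short = 0
    for s, o, year in positives:
        t_o = type_of.get(o)
        if t_o is None:
            raise ValueError(f"positive object {o!r} missing from the vocabulary")
        t_s = type_of.get(s)
        if t_s is None:
            raise ValueError(f"positive subject {s!r} missing from the vocabulary")
        pool = [
            (s, c)
            for c in by_type.get(t_o, [])
            if c != o and c != s and canonical_edge(s, c) not in known
        ]
        if corrupt == "both":
            pool += [
                (c, o)
                for c in by_type.get(t_s, [])
                if c != s and c != o and canonical_edge(c, o) not in known
            ]
        k = min(N, len(pool))
        if k < N:
            short += 1
        chosen = (
            [pool[int(i)] for i in rng.choice(len(pool), size=k, replace=False)]
            if k
            else []
        )
        out.append(
            EvaluationSample(
                subject=s,
                obj=o,
                year=year,
                type_pair=type_pair_label(t_s, t_o),
                negatives=chosen,
                flagged=(k == 0),
            )
        )
    if short:
        warnings.warn(f"{short} positive(s) had fewer than N={N} eligible negatives")
    return out


# -- ROC AUC ------------------------------------------------------------------


def _auc_counts(
    positive_scores: Sequence[float], negative_scores: Sequence[float]
) -> tuple[int, int, int]:
    """Exact pair counts: (#strict wins, #ties, n_pos * n_neg)."""
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.sort(np.asarray(negative_scores, dtype=float))
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    left = np.searchsorted(neg, pos, side="left")
    right = np.searchsorted(neg, pos, side="right")
    wins = int(left.sum())
    ties = int((right - left).sum())
    return wins, ties, pos.size * neg.size


def roc_auc(
    positive_scores: Sequence[float],
    negative_scores: Sequence[float],
    strict: bool = False,
) -> float:
    """Pairwise ROC AUC; ties earn 0.5 unless *strict* (literal indicator)."""
    wins, ties, total = _auc_counts(positive_scores, negative_scores)
    if strict:
        return wins / total
    return (2 * wins + ties) / (2 * total)


# -- stratified evaluation ----------------------------------------------------


def _score_samples(
    samples: Sequence[EvaluationSample], scorer: Scorer
) -> list[tuple[EvaluationSample, float, list[float]]]:
    out = []
    for smp in samples:
        p = float(scorer.score(smp.subject, smp.obj))
        n = [float(scorer.score(a, b)) for a, b in smp.negatives]
        out.append((smp, p, n))
    return out


def _auc_over(scored) -> StratumScore | None:
    pos = [p for _, p, _ in scored]
    neg = [x for _, _, n in scored for x in n]
    if not neg:
        return None
    return StratumScore(roc_auc(pos, neg), len(pos), len(neg))


def evaluate_semantic(
    samples: Sequence[EvaluationSample], scorer: Scorer
) -> StratifiedResult:
    """AUC per unordered semantic-type pair, plus a pooled overall AUC."""
    scored = _score_samples(samples, scorer)
    strata: dict[str, StratumScore] = {}
    groups: dict[str, list] = {}
    for rec in scored:
        groups.setdefault(rec[0].type_pair, []).append(rec)
    for label in sorted(groups):
        res = _auc_over(groups[label])
        if res is None:
            warnings.warn(f"semantic group {label} has no negatives; omitted")
            continue
        strata[label] = res
    pooled = _auc_over(scored)
    if pooled is not None:
        strata["pooled"] = pooled
    return StratifiedResult(strata, scorer.name)


def importance_bin_labels(n_bins: int) -> list[str]:
    if n_bins == 3:
        return ["low", "medium", "high"]
    return [f"bin{i}" for i in range(n_bins)]


def evaluate_importance_bins(
    samples: Sequence[EvaluationSample],
    scorer: Scorer,
    importance: Mapping[tuple[str, str], float] | pd.DataFrame,
    n_bins: int = 3,
) -> StratifiedResult:
    """AUC per equal-sized bin of the combined importance measure.

    Positives are sorted by combined importance and split into *n_bins*
    contiguous bins (any remainder spread to the lowest bins); each
    positive's negatives follow it into its bin.
    """
    if n_bins > len(samples):
        raise ValueError(f"n_bins={n_bins} exceeds {len(samples)} positives")
    if isinstance(importance, pd.DataFrame):
        imp_map = {e: float(v) for e, v in importance["combined"].items()}
    else:
        imp_map = {canonical_edge(*e): float(v) for e, v in importance.items()}

    def lookup(smp: EvaluationSample) -> float:
        e = canonical_edge(smp.subject, smp.obj)
        if e not in imp_map:
            raise KeyError(f"positive {e} has no combined importance score")
        return imp_map[e]

    scored = _score_samples(samples, scorer)
    scored.sort(key=lambda rec: (lookup(rec[0]), rec[0].positive))
    base, rem = divmod(len(scored), n_bins)
    sizes = [base + (1 if i < rem else 0) for i in range(n_bins)]
    labels = importance_bin_labels(n_bins)
    strata: dict[str, StratumScore] = {}
    start = 0
    for label, size in zip(labels, sizes):
        chunk = scored[start : start + size]
        start += size
        res = _auc_over(chunk)
        if res is None:
            warnings.warn(f"importance bin {label} has no negatives; omitted")
            continue
        strata[label] = res
    return StratifiedResult(strata, scorer.name)


def evaluate_temporal(
    G: DynamicGraph,
    scorer_factory: Callable[[int], Scorer],
    train_year: int,
    test_years: Sequence[int],
    N: int = 10,
    seed: int = 0,
) -> StratifiedResult:
    """AUC per test year for a scorer trained once at *train_year*.

    Each test year's positives are the edges first discovered that year whose
    endpoints were both known at the training year; negatives are freshly
    sampled per year (seed derived from the master seed and the year).
    """
    test_years = sorted(test_years)
    if not test_years or train_year >= test_years[0]:
        raise ValueError("require train_year < every test year")
    scorer = scorer_factory(train_year)
    known_at_train = G.nodes_at(train_year)
    known_edges = G.edges_at(max(test_years))
    vocab = list(G.nodes.values())
    strata: dict[str, StratumScore] = {}
    for year in test_years:
        eligible = [
            e
            for e in G.edges_in_window(year - 1, year, restrict_to=known_at_train)
        ]
        if not eligible:
            warnings.warn(f"test year {year} adds no eligible edges; omitted")
            continue
        positives = [(u, v, year) for u, v in eligible]
        sub_seed = int(
            np.random.SeedSequence([seed, year]).generate_state(1)[0] % (2**31)
        )
        samples = sample_negatives(positives, vocab, N, known_edges, sub_seed)
        res = _auc_over(_score_samples(samples, scorer))
        if res is None:
            warnings.warn(f"test year {year} has no negatives; omitted")
            continue
        strata[str(year)] = res
    return StratifiedResult(strata, scorer.name)


# -- built-in baseline scorers -----------------------------------------------


class _GraphScorer:
    def __init__(self, graph: nx.Graph):
        self.graph = graph


class CommonNeighborsScorer(_GraphScorer):
    name = "common_neighbors"

    def score(self, subject: str, obj: str) -> float:
        g = self.graph
        if subject not in g or obj not in g:
            return 0.0
        return float(len(set(g[subject]) & set(g[obj])))


class JaccardScorer(_GraphScorer):
    name = "jaccard"

    def score(self, subject: str, obj: str) -> float:
        g = self.graph
        if subject not in g or obj not in g:
            return 0.0
        a, b = set(g[subject]), set(g[obj])
        union = len(a | b)
        return float(len(a & b) / union) if union else 0.0


class PreferentialAttachmentScorer(_GraphScorer):
    name = "preferential_attachment"

    def score(self, subject: str, obj: str) -> float:
        g = self.graph
        du = g.degree(subject) if subject in g else 0
        dv = g.degree(obj) if obj in g else 0
        return float(du * dv)


class RandomScorer:
    """Seeded random-uniform control; deterministic per (seed, pair)."""

    name = "random"

    def __init__(self, seed: int = 0):
        self.seed = seed

    def score(self, subject: str, obj: str) -> float:
        u, v = canonical_edge(subject, obj)
        h = blake2b(f"{self.seed}|{u}|{v}".encode(), digest_size=8).digest()
        return int.from_bytes(h, "big") / 2**64


class GNNScorer:
    """Decoder scores of a fitted link predictor; unknown nodes score 0."""

    name = "gnn"

    def __init__(self, results):
        self.results = results

    def score(self, subject: str, obj: str) -> float:
        idx = self.results.model.index
        if subject not in idx or obj not in idx:
            return 0.0
        return self.results.score(subject, obj)


def baseline_scorers(
    G_train: nx.Graph, gnn_results=None, seed: int = 0
) -> list[Scorer]:
    """The built-in scorer set: neighbourhood heuristics, the GNN decoder
    (when a fitted predictor is supplied) and a random control."""
    if G_train.number_of_nodes() == 0:
        raise ValueError("empty training snapshot")
    scorers: list[Scorer] = [
        CommonNeighborsScorer(G_train),
        JaccardScorer(G_train),
        PreferentialAttachmentScorer(G_train),
        RandomScorer(seed),
    ]
    if gnn_results is not None:
        scorers.insert(3, GNNScorer(gnn_results))
    return scorers
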
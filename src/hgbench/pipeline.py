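"""End-to-end demonstration pipeline on synthetic data.

Wires the full workflow together: generate a synthetic dynamic network with
planted catalyst edges, compute the combined edge-importance measure, and
run all three stratified benchmark protocols with the built-in scorers.
Everything is deterministic given one master seed.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import asdict, replace

import numpy as np
import scipy.stats

from . import benchmark as bm
from .attribution import LinkPredictor, TrainConfig
from .dyngraph import DynamicGraph, write_graph_dir
from .importance import EdgeImportance, ImportanceConfig, ImportanceResults
from .synthdata import SynthConfig, generate_citation_graph, generate_dynamic_graph

__all__ = ["default_importance_config", "run_demo", "catalyst_separation"]


def default_importance_config(synth: SynthConfig) -> ImportanceConfig:
    """Timestamp triple used throughout the synthetic experiments.

    The test year sits three years before the end of the simulated range
    (so several years of future impact are observable) and scorers train on
    the year before it.
    """
    y0, y1 = synth.years
    test = max(y0 + 2, y1 - 3)
    return ImportanceConfig(
        train_year=test - 1, test_year=test, importance_year=y1
    )


def catalyst_separation(
    results: ImportanceResults, catalysts: set[tuple[str, str]]
) -> dict:
    """How well combined importance separates planted catalyst edges.

    Returns the rank-sum (Mann-Whitney) p-value and the separation AUC
    (probability a random catalyst outranks a random non-catalyst).
    """
    frame = results.frame
    is_cat = np.asarray([e in catalysts for e in frame.index])
    cat = frame["combined"].to_numpy()[is_cat]
    non = frame["combined"].to_numpy()[~is_cat]
    if len(cat) == 0 or len(non) == 0:
        return {"auc": float("nan"), "p_value": float("nan"),
                "n_catalyst": int(len(cat)), "n_other": int(len(non))}
    stat = scipy.stats.mannwhitneyu(cat, non, alternative="greater")
    auc = stat.statistic / (len(cat) * len(non))
    return {
        "auc": float(auc),
        "p_value": float(stat.pvalue),
        "n_catalyst": int(len(cat)),
        "n_other": int(len(non)),
    }


def run_demo(
    out_dir: str | None = None,
    synth_config: SynthConfig | None = None,
    importance_config: ImportanceConfig | None = None,
    train_config: TrainConfig | None = None,
    n_negatives: int = 10,
    log=lambda msg: None,
) -> dict:
    """Run the full pipeline; returns a JSON-serialisable result record.

    Stages: synthesise data, build the dynamic network, train the link
    predictor and attribute edges, combine the importance measure, then
    benchmark the built-in scorers under semantic, importance-bin and
    temporal stratification.  When *out_dir* is given, the data files,
    importance table and results.json are written there.
    """
    synth = synth_config or SynthConfig()
    seed = synth.seed
    icfg = importance_config or default_importance_config(synth)
    tcfg = train_config or TrainConfig(seed=seed)

    log("stage: build (synthetic dynamic network + citation graph)")
    graph, catalysts = generate_dynamic_graph(synth)
    citations = generate_citation_graph(graph, synth, catalysts)

    log("stage: importance (attribute + combine)")
    imp_model = EdgeImportance(
        graph, citations, icfg, train_config=tcfg, population="all"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        imp_results = imp_model.fit()
    separation = catalyst_separation(imp_results, catalysts)

    log("stage: benchmark scorers")
    # The GNN scorer sees only data up to the training cut: it propagates on
    # the cut-year snapshot and is supervised by that year's new edges, so
    # the test year's associations never enter training.
    train_snap = graph.snapshot(icfg.train_year)
    order = sorted(train_snap.nodes())
    feats = graph.feature_matrix(order)
    feat_map = {n: feats[i] for i, n in enumerate(order)}
    gnn_targets = graph.new_edges(icfg.train_year)
    gnn = LinkPredictor(train_snap, feat_map, gnn_targets, tcfg).fit()
    scorers = bm.baseline_scorers(train_snap, gnn_results=gnn, seed=seed)

    positives = [(u, v, icfg.test_year) for u, v in graph.new_edges(icfg.test_year)]
    known = graph.edges_at(icfg.importance_year)
    vocab = list(graph.nodes.values())
    samp_seed = int(np.random.SeedSequence([seed, 17]).generate_state(1)[0] % 2**31)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        samples = bm.sample_negatives(positives, vocab, n_negatives, known, samp_seed)

        semantic = {}
        bins = {}
        for scorer in scorers:
            semantic[scorer.name] = _strata_dict(bm.evaluate_semantic(samples, scorer))
            bins[scorer.name] = _strata_dict(
                bm.evaluate_importance_bins(
                    samples, scorer, imp_results.frame, icfg.n_bins
                )
            )

        log("stage: benchmark temporal")
        test_years = [
            y for y in range(icfg.test_year, synth.years[1] + 1)
        ]
        temporal = {}
        for factory_name, factory in {
            "common_neighbors": lambda t: bm.CommonNeighborsScorer(graph.snapshot(t)),
            "gnn": lambda t: bm.GNNScorer(gnn),
        }.items():
            temporal[factory_name] = _strata_dict(
                bm.evaluate_temporal(
                    graph, factory, icfg.train_year, test_years,
                    N=n_negatives, seed=seed,
                )
            )

    result = {
        "config": {
            "synth": asdict(synth),
            "importance": asdict(icfg),
            "train": asdict(tcfg),
            "n_negatives": n_negatives,
            "master_seed": seed,
        },
        "n_edges_total": len(graph.edges),
        "n_test_edges": len(imp_results.frame),
        "catalyst_separation": separation,
        "ig_completeness_error": (
            imp_results.attribution.completeness_error
            if imp_results.attribution is not None
            else None
        ),
        "semantic": semantic,
        "importance_bins": bins,
        "temporal": temporal,
    }

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_graph_dir(out_dir, graph, citations)
        _write_catalysts(out_dir, graph, catalysts)
        _write_importance_tsv(
            os.path.join(out_dir, "importance.tsv"), imp_results, seed
        )
        with open(os.path.join(out_dir, "results.json"), "w", encoding="utf-8") as fh:
            json.dump(result, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return result


def _strata_dict(res: bm.StratifiedResult) -> dict:
    return {
        label: {"auc": s.auc, "n_pos": s.n_pos, "n_neg": s.n_neg}
        for label, s in res.strata.items()
    }


def _write_catalysts(out_dir: str, graph: DynamicGraph, catalysts) -> None:
    with open(os.path.join(out_dir, "catalysts.tsv"), "w", encoding="utf-8",
              newline="\n") as fh:
        fh.write("u\tv\tbirth_year\n")
        for u, v in sorted(catalysts):
            fh.write(f"{u}\t{v}\t{graph.birth_year[(u, v)]}\n")


def _write_importance_tsv(path: str, results: ImportanceResults, seed: int) -> None:
    cfg = results.model.config
    frame = results.frame.copy()
    frame.insert(0, "u", [e[0] for e in frame.index])
    frame.insert(1, "v", [e[1] for e in frame.index])
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            f"# hgbench importance seed={seed} train={cfg.train_year} "
            f"test={cfg.test_year} importance={cfg.importance_year} "
            f"ig_steps={cfg.ig_steps}\n"
        )
        frame.to_csv(fh, sep="\t", index=False, lineterminator="\n")
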
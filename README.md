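# hgbench

Benchmarking harness for **hypothesis-generation (HG) / literature-based
discovery** systems — tools that predict not-yet-published associations
between biomedical concepts. Any system that can assign a comparable score
to a concept pair can be evaluated; `hgbench` supplies everything around the
scorer: the temporal network construction, a per-edge *importance* measure
quantifying how much an association mattered for later discoveries, a
semantic-type-constrained negative-sampling protocol, and three
stratified ROC-AUC evaluation modes.

## The method

**Time-sliced networks.** Timestamped co-occurrence observations
(*u*, *v*, year, document) build a cumulative dynamic graph
G = {G_t = (N_t, E_t)}: the snapshot at year *t* contains every association
published in or before *t*, weighted by the number of distinct supporting
documents. Predictors are trained on data before a cut year and tested on
the pairs Ê_t that first appear afterwards between already-known concepts
(time-slicing).

**Edge importance.** Each test edge *e* gets six components:

- **IG** — Integrated-Gradients attribution of *e* toward a trained GCN link
  predictor's scores for the edges added later:
  `IG_i(x) = (x_i − x'_i) ∫₀¹ ∂F(x' + α(x − x'))/∂x_i dα`, where the input
  *x* is the binary adjacency of G_t and the baseline *x'* is the zero
  matrix (predictive impact);
- **EC** — change of the eigenvector-centrality gap |C_E(u) − C_E(v)|
  between the test and importance snapshots;
- **BC** — edge betweenness `C_B(e) = Σ_{s≠t} σ_st(e)/σ_st` restricted to
  node pairs involved in future connections;
- **JC2** — second-order Jaccard similarity
  `J₂ = |N₂(u) ∩ N₂(v)| / |N₂(u) ∪ N₂(v)|` with `N₂(u) = ∪_{w∈N(u)} N(w)`
  on the snapshot *before* discovery, entering **negated** (similar
  neighbourhoods ⇒ trivial connection);
- **Ment** — distinct documents mentioning the pair;
- **Cit** — summed citation counts of those documents (taken as-is).

The combined measure is the mean percentile rank,
`I_t(e) = (1/|C|) Σ PCTRank(C_i(e))`, so it lies in the unit interval and
depends only on each component's ranking.

**Evaluation.** For every positive (subject, object) pair, *N* = 10
negatives (subject, object′) are drawn with object′ of the same semantic
type, excluding known associations ("subdomain recommendation"). Ranking
quality is the pairwise ROC AUC
`AUC(f) = (1/|D⁰||D¹|) Σ Σ 1[f(t₀) < f(t₁)]` (ties get half credit;
a `strict` mode keeps the literal indicator). Results are stratified by
semantic-type pair, by low/medium/high bins of the combined importance, or
by test year.

A seeded synthetic generator makes the whole stack testable without any
corpus: it grows a cumulative network with semantic types, mention
documents, a heavy-tailed citation graph, and a planted set of *catalyst*
edges that disproportionately seed future edges — ground truth for
importance recovery.

## Worked example

```sh
hgbench demo --seed 1 --out demo_out
```

runs the full pipeline on the default synthetic conditions (1,000 nodes,
years 2000–2009, 150 new edges/year, 10% catalysts at five-fold boost) and
prints:

```
scored 1050 test edges; catalyst separation AUC=0.644 (p=5.89e-07)
```

i.e. the combined importance of a randomly chosen planted catalyst edge
exceeds a random ordinary edge's 64% of the time — the rank-sum test
confirms the planted signal is recovered (with `catalyst_boost: 1` in the
config this separation disappears). `demo_out/results.json` holds the
stratified benchmark, e.g. for the common-neighbors baseline:

```
importance bins : low 0.790   medium 0.715   high 0.575
temporal        : 2006 0.691  2007 0.683  2008 0.668  2009 0.636
```

High-importance pairs are markedly harder to predict than low-importance
ones, and performance decays as the test year moves away from the training
cut — the two qualitative signatures the stratified protocols are built to
expose. `demo_out/importance.tsv` lists every scored edge with its six raw
components, their percentile ranks and the combined score.

The same stages are available individually (`hgbench synth`, `build`,
`attribute`, `importance`, `correlate`, `benchmark`) on any data in the
simple TSV formats documented in `hgbench.dyngraph`, and as library calls
(`EdgeImportance(...).fit()`, `evaluate_semantic`, `evaluate_temporal`, …).

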
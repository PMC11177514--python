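# Methods

## Dynamic network model

The data atom is one co-occurrence observation `(u, v, year, doc_id)`:
concepts *u* and *v* mentioned together in one document. Observations are
deduplicated on the full tuple; pairs are undirected and stored with the
lexicographically smaller id first. The snapshot `G_t` contains an edge iff
some observation of the pair has year ≤ *t*, so edge sets are nested and
`|E_t|` is non-decreasing — the package asserts this invariant on every
constructed graph. `N_t` is induced by `E_t`: a concept declared in the
node table but never observed stays in the vocabulary (it can serve as a
negative-sampling candidate) without ever appearing in a snapshot. Edge
weights count *distinct* documents rather than raw observation rows, so a
document mentioning a pair several times counts once. Timestamps are
opaque ordered integers; nothing assumes they are calendar years, so
monthly slicing works unchanged.

The prediction target at year *t* is the restricted set Ê_t: edges first
appearing at *t* whose endpoints both existed at *t − 1*. Predicting the
debut of a brand-new concept is a different (and ill-posed) task, so such
edges are excluded from targets and from the scored population.

## Link predictor and attribution

The link predictor is a two-layer graph-convolutional encoder
(`H₁ = relu(S X W₁ + b₁)`, `H₂ = S H₁ W₂`, with `S` the symmetrically
normalised adjacency with self-loops) and an inner-product decoder
`s(u, v) = ⟨H₂[u], H₂[v]⟩` — symmetric by construction. Training minimises
binary cross-entropy with the future edges as positives and, per epoch, a
fresh uniform sample of non-edges among the snapshot's nodes as negatives
(one per positive by default). Optimisation is full-batch Adam; forward and
backward passes are written directly in NumPy/SciPy-sparse, which is ample
for the intended scale (snapshots of at most a few thousand nodes).
Defaults: embedding and hidden width 64, 200 epochs, learning rate 1e-2,
Glorot-style init from the config seed. Mention-count edge weights are
used in the training propagation by default; attribution always uses the
binary adjacency.

Integrated Gradients treats the scalar objective `F(x)` — the sum of
decoder scores over the target edges — as a function of the message-passing
adjacency `x`, integrated along the straight path from the zero matrix to
the binary adjacency. Normalisation degrees are computed once from the full
snapshot and held fixed along the path, so the propagation operator is
linear in `x` and the gradient is exact backpropagation through two sparse
layers. Symmetric entries `(i, j)` and `(j, i)` are folded into one
undirected attribution. The default reduction sums over all target edges
(it preserves the completeness axiom and is linear in per-edge objectives);
a per-target mode returns one attribution map per future edge.

Numerical choice worth noting: the path integral is approximated by a
midpoint rule on a partition **refined at the ReLU breakpoints**. Because
the pre-activations are linear in the interpolation coefficient α, every
kink location is available in closed form; splitting the partition there
makes the integrand a smooth cubic within each piece. A plain uniform
midpoint grid aliases against the kinks and its completeness error
oscillates with the step count instead of decaying; with the refined
partition the error decays smoothly (relative completeness error ~1e-5 at
200 steps on the test fixtures, monotone from 50 to 400 steps). When more
than 2,000 breakpoints fall inside (0, 1) — large snapshots — an evenly
spaced subset is kept, bounding the cost while removing almost all
aliasing. `steps` keeps its usual meaning as the target resolution.

## Importance components and alignment

For a timestamp triple `train < test ≤ importance` (the experiments here
use 2005/2006/2009 on a 2000–2009 synthetic range; the design mirrors a
2015/2016/2022-style split on real corpora):

- **jc2** is computed on the snapshot *before* discovery (`test − 1`); the
  second-order neighbourhood keeps the node itself when it is two-hop
  reachable — the literal set definition, which some libraries silently
  exclude. Two empty neighbourhoods give J₂ = 0.
- **bc** uses the test snapshot with focus nodes drawn from the edges added
  in `(test, importance]`; shortest paths are unweighted, pairs are
  unordered, and edges incident to the endpoints of a path count (standard
  σ-semantics). The accumulation is Brandes-style with restricted targets,
  carried out in exact rational arithmetic and converted to float on
  output.
- **ec** is the change of the edge-level centrality gap between the test
  and importance snapshots. Eigenvector centrality uses the
  mention-weighted adjacency, computed per connected component by shifted
  power iteration (shift = max row sum, which handles bipartite components
  where the plain iteration oscillates; all-ones start, tolerance 1e-10,
  at most 10,000 iterations, dense eigendecomposition only as a
  non-convergence fallback). Each component's sub-vector is non-negative
  with unit L2 norm; isolated nodes score 0. The delta's sign is kept — a
  shrinking gap is informative, and the percentile rank handles either
  sign.
- **ig** trains on the test snapshot with the `(test, importance]` edges as
  targets; a scored edge outside the attribution's receptive field gets raw
  0 with a warning.
- **ment** and **cit** accumulate to the importance year; citation counts
  are used as-is (no log), and a document absent from the citation graph
  contributes 0.

Percentile ranks use the midrank convention
`(#{x_j < x_i} + ½·#{x_j = x_i}) / n`, so ranks lie strictly inside (0, 1)
and any strictly monotone transform of a raw component leaves the combined
measure unchanged (asserted by tests). `jc2` is negated before ranking.
The scored population is either the test year's new edges (the benchmark's
positives) or every edge of the test snapshot — the latter is the natural
population for network-wide analyses such as planted-signal recovery, and
subset orderings agree between the two choices.

The component correlation matrix uses Spearman's ρ with midrank ties; a
constant component is reported as missing (NaN), never coerced to 0.

## Evaluation protocol

Negatives share the positive's subject and the object's semantic type, are
drawn uniformly without replacement, and exclude every association known at
any time up to the importance year — the conservative reading that avoids
mislabelling a to-be-discovered pair as negative. The first element of the
canonical pair acts as subject. One sample set per (seed, test set) is
shared across scorers for a fair comparison. If fewer than *N* candidates
exist the sample keeps what there is (warned); zero candidates flag the
sample.

The AUC as printed with a strict inequality would score a constant
predictor 0.0; the default applies the conventional half-credit for ties
(constant ⇒ 0.5) and `strict=True` reproduces the literal formula. The
implementation counts wins and ties exactly (integers via sorted search),
and the tests compare it to a brute-force double loop in rational
arithmetic.

Importance stratification sorts positives by combined score and splits them
into equal bins, any remainder going to the lowest bins (10 positives,
3 bins → 4/3/3); each positive's negatives follow it. Temporal
stratification trains the scorer once and samples fresh negatives per test
year (sub-seed derived from the master seed and the year).

## Synthetic data generator

The generator emulates the statistical shape of a literature-derived
network without modelling any corpus: cumulative yearly growth, hub
formation via degree-preferential attachment, triadic closure, per-edge
mention documents, and a Price-model citation graph whose in-degree tail is
governed by `citation_tail_exponent` (attractiveness ∝ in-degree + a with
`a = m(γ − 2)`; large γ approaches the uniform, Poisson-like regime —
verified within the first-year exposure cohort, where documents share
identical citation exposure). Each document emits Poisson(3) citations to
strictly older documents.

Catalyst edges are the planted ground truth: a `catalyst_fraction` of each
year's new edges is marked, and marked edges get `catalyst_boost`-fold
weight when future triangle-closure events pick their pivot edge; documents
supporting catalysts get the same boost in citation attractiveness. With
`catalyst_boost = 1` the flag has no effect and catalysts are exchangeable
with ordinary edges — the tests verify both the recovery (rank-sum
p < 0.01 per seed at boost 5) and the null (non-significant at boost 1).
In the recovered signal the citation component separates most strongly,
with smaller structural contributions (IG, BC, EC); the second-order
Jaccard component actually runs slightly against catalysts, because edges
that seed triangles around themselves make their own endpoint
neighbourhoods similar. The combined measure still separates cleanly —
a useful reminder that it is an *aggregate* of distinct impact notions.

Defaults — the study conditions used throughout the tests and the
acceptance script: 1,000 nodes, 4 semantic types with proportions
0.4/0.3/0.2/0.1, years 2000–2009, 150 new edges/year (40% proposed as
triangle closures), 16-dim features, 10% catalysts at boost 5, mention
rate 0.3/edge/year (minimum one document at birth), citation tail exponent
3. Node features are per-type cluster centres plus noise; an optional
seeded random walk (sd 0.05/year) emulates time-dependent text embeddings.
All sub-streams (topology, features, citations, drift) derive from one
master seed with fixed offsets, so each artefact can be regenerated
independently and the whole pipeline is byte-deterministic.

What passing these tests does *not* show: the generator makes no attempt to
match real corpus magnitudes (edge counts in the millions, the exact
degree-distribution shape of text-mined networks, concept-normalisation
noise), so absolute AUC levels and correlation values here do not transfer
to real literature data — only the protocol mechanics and the qualitative
trends (high-importance pairs are harder; performance decays with the
train-test gap) are validated.

## Known limitations

- Associations are untyped, undirected binary pairs; predicate labels and
  directionality are out of scope.
- The GCN is a deliberately small reference predictor, not a
  state-of-the-art HG system; it exists to make attribution and the
  benchmark self-demonstrating.
- Restricted betweenness in exact arithmetic is O(|focus|·|E|) with
  rational overhead; fine for the intended snapshot sizes, not for
  million-edge graphs.
- The evaluation treats the subject of a pair as fixed during corruption;
  an option to corrupt both orientations exists at the sampling level but
  the built-in protocols use the canonical subject.
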
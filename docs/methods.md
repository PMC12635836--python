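# Methods

## The model

`gnmlab` grows binary, undirected, spatially embedded networks one edge at
a time. Given a wiring-cost matrix *D* (Euclidean interregional distance,
mm) and a pairwise feature *F* ∈ [0, 1], every node pair (i, j) not yet
connected receives a wiring weight

- additive rule: `w_ij = e^(−η·D_ij) / max(e^(−η·D)) + α · F_ij^γ / max(F^γ)`
- multiplicative rule: `w_ij = [e^(−η·D_ij) / max(e^(−η·D))] · [F_ij^γ / max(F^γ)]`

with each `max` taken over the currently absent pairs only. A power-law
option replaces the exponential kernel with `D^(−η)`. Weights become
probabilities by normalising over absent pairs,

    P_ij = w_ij (1 − A_ij) / Σ_{u<v} w_uv (1 − A_uv),

and exactly one pair is added per step until the target edge count *m* is
reached. Three feature sources cover the model families studied here:

- **spatial** — no feature term: pure wiring-cost minimisation;
- **static similarity** — a fixed node × node matrix in [0, 1], e.g. the
  correlation structure of (random, spatially autocorrelated) nodal
  features;
- **matching** — the matching index of the *growing* network itself:
  `|N(i) ∩ N(j)| / |N(i) ∪ N(j)|` with neighbourhoods excluding i and j,
  recomputed after every added edge (topological homophily).

The mean per-pair connection probability across steps is tracked with the
convention that a pair contributes only for the steps at which it was
still absent: a pair added at step *t* averages over steps 1..t, a
never-added pair over all *m* steps.

### Parameters

| parameter | meaning | default search box |
|---|---|---|
| η (1/mm) | distance-penalty strength | [0, 2] exponential, [0, 10] power-law |
| γ | feature exponent (positive rewards similarity) | [−20, 200] static features, [−10, 10] matching |
| α | feature-term weight, additive rule only | [0, 10] |

η is a rate per millimetre: the kernel is informative where η·D ~ O(1).
On a 100 mm (cortex-sized) embedding the upper half of the η ∈ [0, 2] box
is saturated — all such values pick essentially the same shortest pairs —
which is why the parameter-recovery study below uses a 10 mm embedding.

### Numerical choices

- Both normalised terms are evaluated in log space relative to their
  extremum over absent pairs: `exp(γ·(log F_ij − log F_ext))` with
  `F_ext` the max (γ > 0) or min (γ < 0). This is algebraically identical
  to `F^γ / max(F^γ)` but does not underflow at γ = 200. The same shift
  is applied to the distance term.
- Features are clamped below at `F_EPS = 1e-6` before exponentiation so
  negative exponents remain defined.
- When every raw feature value over the absent pairs is at or below the
  clamp floor — the matching model's empty-network start — the feature
  carries no information and its term is dropped (additive) or set to one
  (multiplicative). The first step of a matching model therefore
  coincides exactly with the spatial model. This convention is this
  package's choice; the behaviour of `0^γ` at the empty start is not
  otherwise defined.
- Sampling is one multinomial draw per step from the exact probability
  vector (inverse-CDF on the condensed pair array); no top-k shortcuts.
- For the spatial model and static multiplicative rules, the *relative*
  weights over absent pairs never change between steps (the max- and
  sum-normalisers cancel in the probability), so sequential growth is
  distributionally identical to weighted sampling without replacement.
  `grow_network(method="auto")` exploits this with an exponential-race
  draw (`Exp(1)/w` keys) when no probability trace is requested; the
  stepwise loop remains the reference path and the equivalence is
  property-tested. Additive feature rules are never eligible: their two
  normalisers drift at different rates.
- A debug flag asserts per-step probability conservation (sum over
  absent pairs within 1e-12 of 1) and records the worst deviation.

## Fitting: Voronoi-tessellation search

The objective is max(KS): the largest of the four two-sample
Kolmogorov–Smirnov statistics comparing degree, clustering, betweenness
and edge-length distributions between a grown network and the target (or
the mean of max(KS) over an ensemble of targets). Each sampled parameter
point is scored by growing a single stochastic realisation (a
`n_realizations` knob exists, default 1). The search samples an initial
uniform batch in the parameter box, then repeatedly partitions the box
into Voronoi cells of the evaluated points and draws the next batch from
cells with probability ∝ `score^(−β)`, with β stepping through
0.5, 1, 1.5, 2 across four rounds. Reference budget: 2,000 + 4 × 2,000 =
10,000 evaluations; the `small` budget (500 + 4 × 250) is used in the
desk-scale studies here.

Choices where the procedure is underdetermined:

- Parameters are rescaled to the unit box before nearest-seed distances;
  otherwise γ's range ([−20, 200]) dominates the tessellation.
- Within-cell sampling is exact rejection (uniform candidates kept when
  their nearest evaluated point is the drawn cell's seed), batched; after
  1,000 rejections a clipped Gaussian perturbation of the cell seed
  (σ = 5% of the box width) is used.
- Scores are floored at 1e-6 before the `^(−β)` power so a perfect fit
  cannot blow up the allocation.
- Growth seeds vary across evaluated points and are recorded per row in
  the evaluation table.

## Rewiring null model

Each ORIGINAL edge is processed exactly once — in random order, or
shortest-to-longest, or longest-to-shortest (length ties randomised) —
deleted, and replaced by a pair chosen from the pairs absent in the
original network that have not yet been used as replacements: uniformly
at random, or minimising |length difference| to the removed edge
("similar"; ties randomised), or maximising it ("dissimilar"). Vacated
slots never re-enter the pool, which makes the overlap law exact: after
*t* rewires the rewired network retains exactly (m − t)/m of the original
edges, at constant density. "Existing connections" is read as the
original edge set (not the current one); whether a vacated slot may be
refilled later is left open by the procedure's description, and excluding
it is what guarantees termination and the exact overlap law. Fit measures
against the original are recorded every `max(1, ⌊m/100⌋)` rewires by
default; 30 runs are averaged pointwise.

## Synthetic data

The generator emulates the statistical structure the analyses assume,
not any particular dataset:

- **Embeddings**: uniform points on a hemispheric shell (default,
  cortex-like, 100 mm scale), a planar sheet, or a cloud; wiring cost is
  the Euclidean centroid-to-centroid distance (real parcellations average
  vertex-to-vertex distances; the centroid is the synthetic stand-in).
- **Targets**: m edges sampled without replacement with probability
  ∝ `e^(−λ·D)` (λ = 0.05–0.1/mm gives realistic length distributions and
  distance-driven clustering), optionally after planting `n_planted`
  edges between spatially dispersed hub nodes (farthest-point sampling)
  with length ≥ a long-range cutoff (90 mm). The planted edges give the
  target the property real connectomes have and distance-penalised
  growth models miss: long-range hub-to-hub connectivity.
- **Cohorts**: "individual" networks derived from a base network by
  relocating `n_swaps` edges to length-matched originally-absent pairs
  (the rewiring engine with random ordering / similar targets), so every
  subject keeps the base density and exactly (m − n_swaps)/m of its
  edges.
- **Features**: each of 20 features starts uniform on [0, 1] per node
  and is smoothed by 5 synchronous rounds of neighbour averaging over a
  surface-adjacency graph; interregional similarity is the Pearson
  correlation of node profiles mapped to [0, 1]. Real cortical surfaces
  are unavailable synthetically, so "adjacent on the surface" is the
  union-symmetrised 6-nearest-neighbour graph of the node coordinates
  (augmented minimally if disconnected) — the same local-averaging
  semantics on any embedding.

What the generator does **not** emulate: hemispheric geometry and
interhemispheric connections, measurement noise in tractography,
weighted connectivity, and the specific biophysiological similarity
gradients of real cortex. Passing tests therefore demonstrate the
machinery's correctness and the distance/topology trade-off phenomenon
on networks with known ground truth — not fidelity to any empirical
connectome.

### Feature-similarity orientation

Converting a correlation to a "Pearson distance rescaled to the unit
interval", read literally, yields a DISSIMILARITY (anticorrelated pairs
score high). Because a positive γ (searched up to 200) rewards large
feature values, the default here orients F as a similarity,
`F = (r + 1)/2`, so that γ > 0 favours similar pairs;
`feature_similarity(..., orientation="distance")` gives the literal
reading, and the two are exact complements (`F ↦ 1 − F`). Neither is
asserted to be the original intent; both are supported.

## Distance-resolved diagnostics

- **Binned recovery / FDR**: target (or model) edges are split into
  short/mid/long half-open length bins, default [0, 30), [30, 90),
  [90, ∞) mm; recovery is the per-bin fraction of target edges the model
  reproduces, FDR the per-bin fraction of model edges absent from the
  target. Empty bins are flagged invalid, never reported as 0.
- **Thresholded degree**: degree recomputed from edges below (or at or
  above) a length threshold, correlated (Pearson) with the full degree;
  the two modes decompose the full degree exactly at every threshold.
- **Sliding-window precision**: for window centres on a 1 mm grid and a
  ±5 mm half-width, all node pairs in the window are ranked by mean
  growth probability; precision of the top ⌈f·count⌉ pairs (ties
  randomised, ceiling so f > 0 selects at least one) is compared with
  the window's base rate of target edges — the "equally probable" null.
  Windows with fewer than 10 pairs are flagged rather than reported.

## Alternative whole-network measures

The exact constituent sets of the global-summary distance (TND) and the
feature-correlation distance (TF_diff) are registry-configurable; the
defaults are:

- TND: Euclidean distance between z-scored vectors of {global
  transitivity, global efficiency, Louvain modularity Q (seeded), degree
  assortativity}, z-scored across the two networks being compared.
- TF_diff: Frobenius norm of the difference of the 4 × 4 correlation
  matrices of the nodal vectors {degree, clustering, betweenness, mean
  incident edge length}.
- max(r_d): maximum Pearson distance (1 − r) across the four matched
  nodal vectors.
- max(RMSE): maximum root-mean-square difference across {degree,
  clustering, harmonic closeness, mean incident edge length}, each
  min-max rescaled jointly across both networks (harmonic closeness so
  the measure stays defined on disconnected graphs).

A per-edge quantity has no canonical nodal form; "nodal connection
length" is the mean incident edge length, 0 (flagged) for isolated
nodes. Betweenness is kept as raw Brandes dependency counts: KS and
correlation comparisons are invariant to the common n-dependent
normalisation when both networks share n.

## Problem sizes and study conditions

The shipped studies run on one CPU in minutes: probability conservation
on full n = 60 runs; brute-force oracle comparisons on 200 random graphs
with n ≤ 8; rewiring sensitivity on a clustered geometric target with
n = 200, m = 1000, 30 runs; parameter recovery at n = 100, m = 400
against a 21-point grid oracle with 20 realisations per grid point
(the target's η* = 1.0 on a 10 mm embedding, where the exponential
kernel is informative — see Parameters); and the planted-hub study at
n = 150, m = 670 with 10% of edges planted beyond 90 mm, three model
families fitted with a 100 + 2 × 50 budget and evaluated over ensembles
of 10 regrown networks.

## Known limitations

- One growth realisation per evaluated point makes the objective noisy;
  the argmin is reliable for the 1-D spatial model but parameter
  estimates for 3-parameter feature models at small budgets should be
  treated as approximate.
- The matching model's incremental update recomputes only the two
  touched rows of the matching matrix; this is exact (verified against a
  from-scratch reference) but the stepwise loop is still O(n²) per step.
- Degenerate inputs: zero-variance degree sequences (e.g. rings) make
  degree correlation undefined — reported as NaN with a warning, never
  silently 0. Same policy for zero-variance vectors inside TF_diff and
  max(r_d).
- The rewiring null preserves density only (deliberately); no
  degree-preserving rewiring is provided.
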
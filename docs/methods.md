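# Methods

`lesionhub` implements a multivariate lesion-model framework for
whole-brain functional network topology: it asks *which brain regions'
damage predicts how integrated or segregated the remaining functional
network is*, and answers it with linear support-vector regression over
per-region lesion fractions.

## Network construction and topology

Each subject enters as a symmetric region x region connectivity matrix
of Fisher-z-transformed Pearson correlations, diagonal zero.  Because
lesion effects on edge *strength* and on *topology* are confounded,
all topology is computed on binary graphs: at sparsity `s` the
`round(s * n(n-1)/2)` strongest strictly-positive weights become
edges.  Rank ties at the cutoff are broken by lexicographic node-pair
order, which makes thresholding deterministic across platforms and
monotone in `s` (the edge set at a lower sparsity is a subset of the
set at a higher one).

Binary efficiencies follow the Latora–Marchiori conventions:

* network global efficiency `gE = mean over pairs of 1/d(i,j)`,
  unreachable pairs contributing 0 (integration);
* network local efficiency `locE = mean over nodes of the global
  efficiency of the subgraph induced on the node's neighbours`,
  neighbourhoods with fewer than two nodes scoring 0 (segregation);
* nodal `gE_i = mean over j != i of 1/d(i,j)`.

Shortest paths are computed by breadth-first search expressed as
boolean matrix products (BLAS-backed), verified exactly against an
exhaustive Floyd–Warshall oracle on all 1 024 five-node graphs and
against networkx on random graphs.

The small-world index is efficiency-based:

    sigma = (locE / <locE_null>) / (gE / <gE_null>)

where `<.>_null` is the mean over 100 degree-matched null networks
obtained by attempted double-edge swaps (default `10 x |E|` attempts;
swaps creating self-loops or multi-edges are rejected, so the degree
sequence is preserved exactly).  Nulls do not enforce connectedness.
Rewiring runs through igraph's C implementation driven by a seeded
RNG.  `sigma > 1` indicates clustering in excess of a degree-matched
random graph at comparable path length; on an Erdős–Rényi-like graph
sigma is ~1 by construction (self vs own null class), which the test
suite uses as a calibration check.

Single-threshold arbitrariness is removed by the area under the
metric-versus-sparsity curve (trapezoidal rule on a uniform grid,
default step 0.01).  The cohort-wide grid runs from the smallest grid
sparsity at which every subject's graph is connected up to the
smallest grid sparsity retaining every positive weight of every
subject.

## Lesion models

For each patient, the lesion fraction of region `i` is the fraction
of the region's voxels overlapped by the lesion mask (`lp_i` in
[0, 1]); regions lesioned in no patient are dropped from the design
matrix.  Optional covariate columns (total lesion volume, age, time
post onset) are min–max scaled to [0, 1] so they stay commensurate
with the lesion fractions; the lesion features themselves are never
standardised.

The model is a linear epsilon-SVR, `Y = w^T X + b`, fitted with the
reference implementation's default parameters (C = 1, epsilon = 0.1).
One numerical choice matters here: topology labels live on arbitrary
scales (gE spreads over ~0.01 while sigma spreads over ~0.05 in the
synthetic cohorts), and an absolute epsilon of 0.1 would swallow a
label whose whole spread is smaller than the insensitive tube — the
fit would return all-zero weights regardless of how strong the
coupling is.  The label is therefore z-scored inside each training
fold (epsilon then means "0.1 label standard deviations"), and
predictions and weights are mapped back to raw label units.  Pearson
accuracy and weight signs are invariant to this linear map.

Accuracy is the Pearson correlation between leave-one-out predictions
and actual labels.  Significance is permutation-based: labels are
shuffled, the entire LOOCV repeated, and

    P = (#{null accuracy >= actual accuracy} + 1) / (n_perm + 1),

the standard one-tailed rank P (lower-bounded by `1/(n_perm+1)`).
Per-feature significance reuses *the same* label shuffles: each
permutation also refits the full-data model, giving every feature a
null weight distribution; a weight outside its null's [2.5, 97.5]
percentile band is significant (two-tailed, alpha = 0.05).  Sharing
the shuffles between the two tests is an explicit contract — both
draw one permutation per iteration from the same seeded stream.

A caution worth stating: LOOCV Pearson accuracy is *negatively*
biased under the null (the left-out label pulls the training mean
away from itself), so null accuracies centre around noticeably
negative values at small n.  This does not affect the permutation
test — the null distribution carries the same bias — but raw LOOCV r
values should never be compared against zero informally.

Significant features are "lesion hubs", classified by sign pattern:
damage that *lowers* locE or sigma or *raises* gE shifts the network
toward integration; the opposite signs toward segregation.  Features
matching both patterns are flagged unclassified.  Split-half
validation refits the full pipeline in two random half-cohorts, and
single-region group comparisons use a two-sample t-test per sparsity
level with Benjamini–Hochberg FDR across levels.

## Healthy-connectome hubs

The healthy reference network is the element-wise mean of the
subjects' Fisher-z matrices.  Modules come from Newman's
leading-eigenvector spectral algorithm (igraph) followed by a
Kernighan–Lin-style refinement (greedy single-node moves accepted
while modularity Q increases); module labels are canonicalised by
descending size.  Stability is assessed by re-detecting modules over
sparsities 0.05–0.20 (step 0.01): the reported partition is the one
at the representative sparsity 0.15, with nodes flagged whose
(overlap-matched) assignment differs from it in more than half the
levels, plus a mean pairwise adjusted-Rand stability score.

Nodal hub metrics at the representative sparsity:

* participation coefficient `PC_i = 1 - sum_s (k_is/k_i)^2`
  (isolated nodes: 0) — connector hubs have PC > 0.3;
* within-module degree z-score (Guimera–Amaral), standardised with
  the *population* sd within each module (singleton or zero-spread
  modules: 0) — provincial hubs have WMD > 0;
* nodal gE z-scored across all nodes of the network — high-gE nodes
  have z > 0.

## Synthetic cohorts

The generator provides cohorts with the statistical structure the
analysis assumes, so every stage is testable without patient data.
Defaults are the study conditions: 96 patients, 180 nodes in 4
modules.

*Healthy base.*  Block-structured Fisher-z weights: within-module
mean 0.6 (r ~ 0.54), between-module mean 0.15, sd 0.12 — typical
group-level resting-state values.  Two designated connectors per
module have their cross-module weight distribution shifted up by
0.35, so that only its upper tail clears a typical sparsity cutoff:
connectors become genuine high-degree hubs (mean degree ~63 against a
median of ~26 at s = 0.15) while retained cross-module edges stay a
minority of all edges — the planted modules remain exactly
recoverable (ARI = 1 for the spectral detector).  This balance is
deliberate: boosting *all* connector cross-edges past the within
weights merges the modules, while giving connectors only a handful of
strong bridges leaves their deletion impact indistinguishable from an
ordinary node's.

*Lesions.*  Node coordinates are module-clustered 3-D Gaussians;
contiguity is a symmetric 6-nearest-neighbour graph, over which 1–2
blobs per patient (mean 8 nodes) grow from seed nodes.  Seed
probabilities model vascular vulnerability: lognormal(sd = 1) node
weights, with the 6 *effector* nodes (placed on connectors by
default) carrying a fixed mass of 120 — effectors then host most blob
seeds and are lesioned in roughly 12–23 % of patients, the hotspot
concentration seen in arterial-territory cohorts, while node-wise
lesion frequency stays strongly heterogeneous elsewhere.  Within a
blob, lesion fractions follow a core–penumbra gradient: the seed node
draws `lp ~ Beta(4, 1.5)` and each step away from the core halves it.

*Forward model.*  `w_ij = base_ij (1-lp_i)^a (1-lp_j)^a + N(0, 0.08)`
with a = 1 — multiplicative attenuation keeps lesion fractions acting
approximately linearly on topology, matching the linear-SVR working
assumption.  At these settings the lesion-driven label variance
dominates the noise-driven part by a factor of 3–4.

*Ground truth.*  Expected effect signs per (effector, label) are not
asserted a priori but computed by a deletion oracle: each effector is
fully lesioned alone (no noise) and the sign of the metric change at
the representative sparsity recorded.  The sigma oracle uses 200
rewired nulls (double the per-patient default) so its Monte-Carlo
sign error stays below the per-patient label noise.

*Null mode* reassigns the lesion patterns across patients *after* the
matrices are generated: both marginals are preserved exactly while
the lesion–topology pairing is destroyed — the right null for
calibrating the permutation test.

One structural fact the synthetic experiments exposed, worth knowing
when interpreting results: in a redundant network, single-node
deletion changes gE by almost the same amount for *every* node (the
loss is dominated by the deleted node's own distance row), so gE acts
as a lesion-volume meter and cannot discriminate which node was hit.
Node-specific recovery works through the locE and sigma channels,
where connector damage moves the metric in the *opposite* direction
to ordinary-node damage.

## What the tests establish — and what they do not

The acceptance suite verifies, at full scale: the small-world bound
(sigma > 1 on a Watts–Strogatz graph against 100 rewired nulls);
exact efficiency kernels (exhaustive 5-node sweep); frequentist
calibration of the permutation P on 200 decoupled cohorts (40
patients x 60 nodes, 99 permutations; rejection rate within
[0.02, 0.09] at alpha = 0.05); and planted-effector recovery on the
full-size cohort (recall >= 0.8 with deletion-oracle-consistent
signs, all three models significant at 199 permutations).  Problem
sizes were chosen so the whole suite runs on a single CPU in well
under half an hour; n_perm = 199 for the recovery check and 99 for
calibration are the smallest counts at which the relevant thresholds
(P < 0.05, percentile bands) are still comfortably resolved.

The generator emulates the *statistical* structure of a lesion cohort
— modular connectome, contiguous heterogeneous lesions, linear
lesion→topology coupling — not its physiology: no hemodynamics, no
time series, no diaschisis or compensatory rewiring, no registration
error, and lesion effects are purely attenuating.  Passing tests
therefore show the pipeline recovers what it assumes; they do not
show that real lesions satisfy those assumptions (real effects
include connectivity *increases* that this forward model cannot
produce).

## Known limitations

* AUC-mode sigma labels recompute rewired nulls at every grid
  sparsity for every patient and are expensive at scale; the
  single-sparsity path reuses one null ensemble per patient.
* Permutation model and feature tests share shuffles by reusing the
  seeded stream, not by caching: calling the two functions separately
  doubles the LOOCV cost (use `fit_lesion_model` for one pass).
* Weighted-network topology, directed graphs, modularity/rich-club of
  patient networks, and nonlinear kernels are out of scope.
* The spectral detector with KL refinement is deterministic for
  well-separated modules but, like all modularity maximisers, may
  return one of several near-degenerate partitions on weakly modular
  graphs — the consensus stability flags exist for exactly that case.
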
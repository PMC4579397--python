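# Methods

## Model and assumptions

`phosflow` models the propagation of kinase-inhibitor perturbations through
a phosphorylation network as monotone Boolean dynamics on a directed graph
of kinase/phosphatase → site edges and site → host-protein *integrator*
edges. The core assumptions:

* **Two-state measurements.** Each phosphopeptide's response across the
  condition panel is either unimodal (untouched by every drug) or bimodal
  (a control and a perturbed population). Only peptides whose effect
  estimates are best fit by exactly two Gaussian components, with ≤ 10%
  density overlap, carry Boolean evidence.
* **Pseudo steady state.** Data are taken at one characteristic time after
  perturbation; a candidate model's prediction is its least fixpoint when
  the drug targets are set to the perturbed state. Monotonicity (states
  flip only control → perturbed) makes the fixpoint unique and independent
  of update order, so the worklist simulator, synchronous sweeps and random
  asynchronous updates provably agree (property-tested on 1,000 random
  instances).
* **Knowledge-bounded search.** Candidate models are drawn only from paths
  compatible with the K/P-S resource; anything outside it cannot be found.
  Edges express a *change of activity on perturbation*, not activity per se.
* **No inhibitory logic.** Negative regulation and multi-level states
  (control/up/down) are out of scope.

## Stage parameters (defaults, units, rationale)

| Parameter | Default | Notes |
|---|---|---|
| S-score call threshold | ±0.5 | `perturbed` below −0.5, `control` above +0.5, else undetermined (log₁₀ probability-ratio units) |
| Mixture overlap ceiling | 0.10 | unnormalized min-density area; a convention normalized by the smaller component mass is available (`overlap_normalized`), since either reading of a "10% overlap" rule is defensible |
| Mixture components | 1–9, BIC | BIC = −2·logL + (3K−1)·ln n, ties to smaller K; EM: k-means++, 10 restarts, tol 1e−8, ≤ 500 iterations |
| Variance floor | 0.01 (log2FC²) | the square of a plausible residual sd (0.1) of a log2 fold-change estimate; a merely numerical floor lets near-coincident estimates collapse into delta spikes that defeat BIC and the overlap filter at small condition counts |
| Component count cap | max(2, n/2) | an unequal-variance component needs ≥ 2 observations; inactive at ≥ 18 conditions |
| S-score clamp | ±10 | saturates underflowing responsibilities |
| NetworKIN-style score cutoff | 0.5 | predicted edges need motif and context scores ≥ 0.5 |
| Path budgets | 7 / 5 nodes | protein-level node counts including endpoints, among targets / from the target network to site kinases; an edge is kept when it lies on a directed walk within the budget (decided by BFS distances through it) |
| Population size `n` | 5,000 | reference configuration; desk-scale benchmarks use 500 |
| `cap` | 5 (alt. 20) | ceiling on virtual copies per input and generation |
| Best-family tolerance | 0.30 (alt. 0.15) | family = scores ≤ s\* + tol·\|s\*\| (an absolute-offset mode exists; scores are typically negative) |
| `sizeP` | 1 (alt. 0) | per-selected-edge additive penalty; the printed settings pair (cap 5, tol 30%, sizeP 1) and (cap 20, tol 15%, sizeP 0) |
| Generations | 50 | hard cap; convergence when \|Δ mean score\| < 0.01·\|best\| and every sampling frequency moves < 0.01 for 3 consecutive generations |
| Runs / consensus tolerance | 3 / 0.20 | final-population combination frequencies averaged across runs; consensus keeps inputs within 20% of each node's maximum |

**Weight correction.** Each input receives `base + cap·f` virtual copies
(`f` = its best-family frequency), normalized per node; intermediate nodes
update per-edge inclusion probabilities the same way and average the AND
probability with the family's AND frequency. By default the base is the
*previous* probabilities (compounding), so evidence accumulates and a
uniquely-determined input converges to frequency 1; a non-compounding mode
(base = uniform each generation) is available but caps any probability at
(1+cap)/(k+cap). Both modes produce identical first corrections from the
uniform state, which is the state the worked reference probabilities
describe.

**Score comparability.** Negative evidence at sites a background cannot
reach enters every model's score as a constant false-negative penalty.
Within one optimization it shifts nothing; across settings (true vs
shuffled resource, true vs wrong target) it is what makes the final scores
comparable.

## Synthetic studies: what they emulate, and what they do not

`synthetic.generate_truth` builds a kinome with a loose hierarchy (upstream
kinases phosphorylate regulatory sites on downstream ones; occasional
feedback edges, so cycles occur), measured sites on substrate proteins with
1–5 candidate kinases each, and a drug panel of one top-tier target per
drug. A ground-truth logic model is drawn with the package's own sampler,
*conditioned on no silent (NONE) inputs*: a planted truth in which a node
ignores its documented inputs leaves no trace in any dataset, so nothing
downstream of it could ever be recovered — a recovery benchmark requires
the planted signal to traverse the network. Training itself still samples
the full space, silent inputs included. The background is then rebuilt from
the truly perturbed sites and the draw is kept only if the planted model is
sampleable from that background and reproduces the same perturbation
pattern.

`synthetic.simulate_dataset` draws log2 intensities with control level
N(22, 1.5²), total replicate noise σ = 0.3 split σ_bio = 2σ_tech, a global
batch offset per biological replicate (N(0, 0.2²), removed by the model's
replicate factor), two biological × three technical replicates, and an
inhibition shift of −Δ (default Δ = 5 log2 units) on truly perturbed
(site, condition) pairs. Four unaffected filler peptides per data site
times three (12×) emulate the bulk of a discovery phosphoproteome: with a
small proteome and a ≫1% perturbed fraction, quantile normalization itself
distorts the estimates, which is an artefact of scale, not of the method.

Passing benchmarks on these data show that the pipeline recovers a
recoverable truth under the stated noise/effect regime. They do **not**
demonstrate robustness to MS-specific missingness (only uniform
missing-at-random is modelled), peptide-identification errors, ambiguous
site localization, compensatory (non-Boolean) signalling, or inhibitor
off-target effects.

### Recovery metrics

`recovery_metrics` reports edge precision/recall of the consensus against
the planted model and two per-node accuracies: **edge-level** (the node's
top-frequency input edge is a planted edge — the headline, since the
method's result is edge frequencies and multi-edge gate combinations
structurally stay at moderate frequency under the normalized correction)
and **exact-combination** (edges plus gate equal the planted input).
Analytic random baselines for both are provided. Identifiability bounds
recovery: with four drugs some network regions are provably
indistinguishable (verified by single-node flips against the truth), and
the structural ceiling, not the optimizer, limits exact-combination
accuracy.

## Benchmark problem sizes

The shipped benchmarks use 20 kinases, 50 measured sites, 4 drugs,
Δ/σ ≈ 17, populations of 500 for 20 generations and 3 runs — sizes chosen
so a full end-to-end run (data simulation through consensus) completes in
minutes on one core while leaving every stage's behaviour observable. The
randomization control trains on a single drug's evidence with the true
target, another drug's target, and three enzyme-shuffled resources.

## Degenerate inputs and tie-breaks

* Non-positive intensities are masked; a peptide-condition with fewer than
  two raw observations is dropped; peptides whose control level cannot be
  estimated are excluded.
* Quantile normalization with missing values matches each sample on the
  quantiles of its observed entries; ties receive the mean normalized value
  of their group.
* Zero residual variances are offset to 1e−5 × median before empirical-Bayes
  moment matching.
* Consensus ties break deterministically by combination key (sorted source
  ids, then gate), so reruns are byte-identical.
* A drug whose targets are absent from the network is excluded from scoring
  with a warning; a background with no reachable evidence refuses to train.

## Known limitations

* Sink nodes take exactly one kinase input; combinatorial regulation of
  measured sites is only representable at relay nodes.
* The per-edge normalization of intermediate-node weights means AND/OR
  combinations over k edges cannot dominate a single strong edge without
  combination treatments — visible in benchmarks as exact-combination
  accuracy plateauing below edge-level accuracy.
* With few conditions the mixture stage has limited resolution; peptides
  perturbed in nearly all conditions risk merging populations.
* Backgrounds grow quickly with path budgets; poorly constrained regions
  are reported via the consensus tolerance rather than pruned.
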
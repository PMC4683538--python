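# Methods

## Model

`hmdbn` infers *time-varying* gene regulatory networks from a discrete
expression time course `x(0..T)` (N genes, binary states after
thresholding).  The model is a dynamic Bayesian network whose edges point
from time slice `t−1` to slice `t` (no contemporaneous edges), with the
stationarity assumption relaxed per node: each node `i` carries a small
set of candidate parent configurations — *hidden graphs*
`G_i^(1..H_i)` — and a first-order Markov chain `q_i(t)` over them, with
prior `π_i` and transition matrix `A_i`.  At each time point the active
hidden graph emits the observation through the multinomial conditional
distribution of node `i` given its parents' states at `t−1`:

    P(x_i(t) | q_i(t)=h, x(t−1)) = θ_{h, j(t−1), x_i(t)},

where `j(t−1)` is the mixed-radix index of the joint parent state.  Node
chains are mutually independent, so the likelihood factorises over nodes
and every node's sub-network (hidden graphs + chain + CPDs) can be
learned separately; the per-node models are then unioned into one
time-varying adjacency.  The time points where a node's decoded graph
changes are its *transition times* (reported 1-based, as the first point
governed by the new graph).

Because emissions are an arbitrary `H × T` matrix (the conditioning
parent states change every step), off-the-shelf HMM fitting APIs that
assume a fixed emission law per state do not apply; the forward–backward,
Viterbi and Baum–Welch recursions are implemented directly (numba
kernels, Rabiner per-step scaling; emissions floored at 1e-12; the
exhaustive-path enumeration oracle in the test suite pins them down to
1e-10).

## Scores

**BWBIC** (the score of record) is a Laplace/BIC approximation to the
marginal likelihood in which the hidden-graph posteriors
`γ_h(t) = P(q_i(t)=h | x)` from forward–backward replace hard assignments:
counts become expected counts `Ñ_{hjk} = Σ_t γ_h(t) δ(...)`, and the
penalty uses the *expected sample size* `N̂_h = Σ_t γ_h(t)`:

    BWBIC_i = Σ_h [ Σ_{jk} Ñ_{hjk} log θ̂_{hjk} − (d_h/2) log N̂_h ]
              − (d_HMM/2) log T,

with `d_h = q_h (r_i − 1)` free CPD parameters per graph and
`d_HMM = (H−1) + H(H−1)` free chain parameters (prior + transitions; the
transition term is dropped when an ablation freezes `A`).  The chain term
is the part of the complexity penalty that grows with the number of
hidden graphs; without it a model can buy likelihood by splitting the
series into gratuitous regimes, and precision collapses.  `log N̂_h` is
floored at 0 for graphs with expected occupancy below one observation,
keeping the score finite.  With one hidden graph and `γ ≡ 1` every extra
term vanishes and BWBIC is exactly the stationary BIC (asserted in the
tests).

**BIC / BDe baselines** score the same models after each time point is
assigned wholly to its most probable graph (`argmax_h γ_h(t)`, the
Viterbi-training-style demarcated-samples view): per-graph BIC on hard
counts, and the Dirichlet–multinomial marginal likelihood with an
equivalent sample size `α = 1` spread uniformly over CPD cells
(`α/(q_h r_i)` per cell).  The search is identical for all three scores —
only the scoring call differs.

## Learning

The outer loop is a structural EM: per node, greedy hill-climbing over
*stationary* parent sets with single-parent add/delete moves, starting
from the empty set, accepting only strict improvements (ties favour the
smaller set; deletions are enumerated first), terminating when no move
improves.  Fan-in is capped at 3 by default.  Each stationary candidate S
is transformed into a non-stationary model before scoring:

1. for each `j ∈ S`, a two-graph HMM {∅, {j}} is fitted by inner EM,
   giving the time-resolved posterior that edge `j→i` is active
   ("presence"); these are cached per (node, parent) across all moves;
2. presences are combined per time point under independence into a
   posterior over all `2^|S|` configurations;
3. configurations whose summed posterior exceeds 5% of T are kept as
   putative hidden graphs (the dominant one always; at most `H_max = 6`);
   the full set S itself is always included, because single-edge
   posteriors can assign a jointly-active configuration zero mass when
   one parent's CPD differs between regimes;
4. the resulting model is refined by inner Baum–Welch EM over
   (π, A, Θ) with the graph set fixed, then scored.

This keeps the number of candidate structures examined per move linear
in N instead of exponential in the hidden-graph space.

### Numerical choices in the inner EM

These were the genuinely open design decisions; each default below fixes
a reproducible failure mode observed while validating on synthetic
change-point data:

- **Transition initialisation** `a_hh = max(0.9, 1 − 1/T)`: regime
  switches are rare relative to T, and a flat 0.9 start at T ≈ 1000
  encodes ~100 expected switches, from which EM settles into a flickering
  local optimum with dozens of spurious decoded transitions per node.
- **CPD smoothing prior centred on the child's marginal** (pseudo-count
  ε = 0.5 · r · marginal during EM only; scoring always re-estimates with
  ε = 0): with a uniform-centred prior, a hidden graph that temporarily
  loses all responsibility degrades to a uniform CPD that is *worse* than
  the marginal model and can never win mass back, so edge deletions go
  undetected.  Centred on the marginal, a starving graph stays a null
  model and re-engages where the data are locally independent of the
  putative parents.
- **Initial responsibilities** blended 50/50 between the combined
  single-edge posterior and uniform, so no putative graph starts dead.
- **Convergence**: relative log-likelihood change < 1e-5, capped at 200
  iterations for single-edge chains and 100 for refinement;
  non-convergence returns the best iterate with a logged warning.
- **Tie-breaks**: Viterbi and posterior-argmax both resolve ties toward
  the lower graph index; candidate enumeration order is ascending node
  index; no random restarts by default, so a run is deterministic given
  the data.

Decoding defaults to the per-time marginal posterior argmax (threshold-
free); the joint Viterbi path is available as an option — the two can
differ where a single aberrant observation briefly flips the marginal
but not the joint path.

## Ablations

Two switches remove the learned inter-regime dependency structure:
`fixed_equal_transitions` freezes `A` at row-uniform (never re-estimated,
including inside the single-edge HMMs), and `fixed_self_transition = s`
freezes `a_hh = s` with uniform off-diagonal mass.  Under either, BWBIC
degrades gracefully while the hard-segmented BIC/BDe baselines overfit
the fragmented segmentations — the soft expected counts share every
observation across regimes, the hard counts do not.

## Synthetic benchmark generator

The generator emulates two standard designs: a 10-node binary network
with 7 epochs, exactly one edge added or deleted at each of the 6
boundaries, epoch lengths drawn uniformly in [20, 400] and rescaled to
1019 total observations (~10 base edges, fan-in ≤ 3); and a 100-node
network with 50 edges over 5 segments totalling 5000 samples, 1–3 edge
changes per boundary.  Sampling: `x(0)` uniform; thereafter each child
takes a designated boolean function of its parents' previous states with
probability `dependence_strength = 0.9`, else the opposite state — so
strength 0.5 severs the dependence exactly, which makes the no-signal
control analytic.

The designated function defaults to a **random logic map** drawn once per
(node, parent set), rejection-sampled so every parent has a non-zero
marginal effect.  The alternatives are instructive failures kept as
options: noisy-OR saturates in cascades (an OR-child of OR-children is
almost always 1, and per-edge mutual information vanishes), and
noisy-parity hides every individual edge from any marginal test, making
the truth unrecoverable in principle for a single-edge-driven search.
A Dirichlet random-table variant is also available.

What the generator does *not* emulate about real expression data:
continuous dynamics collapsed by thresholding, measurement noise
correlated across genes, unobserved regulators, and transition times
shared across nodes by a common upstream event.  Passing benchmarks
therefore demonstrate correct recovery of the model's own data-generating
class, not performance on biological data.

## Evaluation protocol

Predictions are scored per observation: at each time point the predicted
edge set is compared with the true time-varying adjacency, giving
precision (1 if nothing predicted) and recall (1 if nothing true); both
are averaged over all time points and F1 is the harmonic mean of the
averages (per-time F1 averaging is available as an option).  Benchmark
ensembles report per-dataset values and medians; each dataset draws its
own random topology (a fixed-topology mode exists).

## Problem sizes and observed behaviour

The acceptance script and test suite run 25-dataset ensembles per
condition for the 10-node design and a 2-dataset reduced variant of the
100-node design.  At these sizes the BWBIC search recovers the 10-node
benchmark with median precision ≈ 0.99, recall ≈ 0.94–0.96 and
F1 ≈ 0.95–0.97, degrades to F1 ≈ 0.84 at 20 samples per segment, and
keeps F1 ≈ 0.7–0.8 under both transition ablations while the BIC/BDe
baselines drop to ≈ 0.59–0.62.  The ablation gap reproduces the
qualitative ordering (BWBIC above both baselines under every transition
setting) but not the near-total baseline collapse reported for a single
fixed benchmark topology elsewhere; on random topologies with a fan-in
cap the baselines cannot fall that far (a capped search bounds the number
of predictable edges, hence precision, from below), and uncapped or
hard-EM variants were measured to self-limit around F1 ≈ 0.5–0.65.

## Known limitations

- Greedy single-edge moves cannot recover relationships invisible at the
  single-parent margin (parity-like logic).
- No missing data, no replicates, binary discretization only
  (per-gene mean or median threshold).
- No uncertainty quantification on transition times; the decoded
  segmentation is a point estimate.
- The inner EM is a local optimiser; pathological initialisations are
  mitigated by the choices above but not eliminated.  Optional seeded
  restarts are available via the search configuration.
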
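"""Transforming a stationary parent set into a non-stationary model.

Given a candidate stationary parent set S for node i, the builder:

1. fits, for each j in S, a two-state HMM whose hidden graphs are the empty
   set and {j}, yielding the time-resolved posterior that the edge j→i is
   active ("presence");
2. combines the single-edge presences into a posterior over all 2^|S|
   parent-set configurations by a per-time independence product;
3. keeps the configurations with enough expected occupancy as the putative
   hidden graphs;
4. refines the resulting model (prior, transitions, CPDs) by an inner
   Baum-Welch EM with the graph set held fixed, and scores it.

This is the step that lets the outer structure search walk over stationary
parent sets only — O(N) candidates per move — instead of the exponential
space of hidden-graph combinations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_model import DiscreteTimeSeries
from .hmm import NodeHMMSpec, Posteriors, forward_backward, reestimate_A, reestimate_pi
from .scoring import (
    CPDTable,
    ExpectedCounts,
    HiddenGraphSet,
    bwbic_score,
    emission_matrix,
    expected_counts,
    mle_cpd,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EdgePosterior",
    "RefinedModel",
    "single_edge_hmm",
    "combine_edge_posteriors",
    "identify_hidden_graphs",
    "refine_hmdbn",
]

#: inner Baum-Welch convergence: relative log-likelihood change below this
EM_RTOL = 1e-5
#: iteration caps (single-edge chains are cheap, full refinements less so)
EM_MAX_ITER_EDGE = 200
EM_MAX_ITER_REFINE = 100
#: pseudo-count used for CPDs *during* EM (keeps emissions off zero);
#: scoring always re-estimates with zero smoothing
EM_SMOOTHING = 0.5
#: EM initialisation: minimum self-transition mass of the transition
#: matrix.  Regime switches are rare relative to T, so the starting value
#: scales as 1 - 1/T (a prior expectation of one switch per series); a
#: loose constant start (e.g. 0.9 on T ~ 1000) seeds ~100 expected
#: switches and EM then settles in a flickering local optimum.
INIT_SELF_TRANSITION = 0.9


@dataclass
class EdgePosterior:
    """Posterior activity profile of one candidate edge j→i.

    ``presence[t]`` is the probability, under the converged two-graph HMM,
    that x_i(t) was generated with parent j rather than with no parents.
    """

    parent: int
    presence: np.ndarray
    model: "RefinedModel"


@dataclass
class RefinedModel:
    """A converged node model: graph set, HMM, CPDs, posteriors, score."""

    hgs: HiddenGraphSet
    spec: NodeHMMSpec
    cpd: CPDTable
    post: Posteriors
    counts: ExpectedCounts
    bwbic: float
    converged: bool
    n_iter: int


def _frozen_A(H: int, fixed_equal: bool, fixed_self: float | None) -> np.ndarray | None:
    """The frozen transition matrix requested by an ablation, or None."""
    if fixed_equal:
        return np.full((H, H), 1.0 / H)
    if fixed_self is not None:
        if not 0.0 < fixed_self < 1.0:
            raise ValueError("fixed self-transition must lie in (0, 1)")
        if H == 1:
            return np.ones((1, 1))
        A = np.full((H, H), (1.0 - fixed_self) / (H - 1))
        np.fill_diagonal(A, fixed_self)
        return A
    return None


def _init_A(H: int, T: int) -> np.ndarray:
    if H == 1:
        return np.ones((1, 1))
    self_mass = max(INIT_SELF_TRANSITION, 1.0 - 1.0 / max(T, 2))
    A = np.full((H, H), (1.0 - self_mass) / (H - 1))
    np.fill_diagonal(A, self_mass)
    return A


def _child_marginal(data: DiscreteTimeSeries, node: int) -> np.ndarray:
    """Marginal distribution of the child over t = 1..T (the EM prior
    centre: a starving hidden graph then stays a null/marginal model)."""
    r = data.arities[node]
    counts = np.bincount(data.values[node, 1:], minlength=r).astype(float)
    return counts / counts.sum()


def refine_hmdbn(data: DiscreteTimeSeries, node: int, hgs: HiddenGraphSet,
                 init_gamma: np.ndarray | None = None,
                 fixed_equal: bool = False,
                 fixed_self: float | None = None,
                 max_iter: int = EM_MAX_ITER_REFINE) -> RefinedModel:
    """Inner EM over (π, A, Θ) with the hidden-graph set held fixed.

    ``init_gamma`` seeds the CPDs (soft counts under an initial
    responsibility guess); without it, responsibilities start uniform.
    The ablation flags freeze the transition matrix (row-uniform, or fixed
    self-transition with uniform off-diagonal mass) and skip its update.
    The log-likelihood sequence is monitored; non-convergence within
    ``max_iter`` returns the last iterate with a logged warning.
    """
    H = hgs.n_graphs
    T = data.n_transitions
    if init_gamma is None:
        init_gamma = np.full((H, T), 1.0 / H)
    marg = _child_marginal(data, node)
    cpd = mle_cpd(expected_counts(data, node, hgs, init_gamma),
                  EM_SMOOTHING, prior=marg)
    pi = np.full(H, 1.0 / H)
    frozen = _frozen_A(H, fixed_equal, fixed_self)
    A = frozen.copy() if frozen is not None else _init_A(H, T)

    prev_ll = -np.inf
    post = None
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        B = emission_matrix(data, node, hgs, cpd)
        spec = NodeHMMSpec(pi=pi, A=A, B=B)
        post = forward_backward(spec)
        # E-step responsibilities feed the M-step updates
        pi = reestimate_pi(post)
        if frozen is None and H > 1:
            A = reestimate_A(post, prev_A=A)
        cpd = mle_cpd(expected_counts(data, node, hgs, post.gamma),
                      EM_SMOOTHING, prior=marg)
        if post.loglik - prev_ll <= EM_RTOL * max(abs(prev_ll), 1.0):
            converged = True
            break
        prev_ll = post.loglik
    if not converged and H > 1:
        logger.warning(
            "inner EM for node %d (H=%d) did not converge in %d iterations",
            node, H, max_iter,
        )

    spec = NodeHMMSpec(pi=pi, A=A, B=emission_matrix(data, node, hgs, cpd))
    post = forward_backward(spec)
    counts = expected_counts(data, node, hgs, post.gamma)
    # free chain parameters: H-1 for pi, plus H(H-1) for A when optimised
    n_hmm = (H - 1) + (0 if frozen is not None else H * (H - 1))
    score = bwbic_score(counts, mle_cpd(counts, 0.0), data.arities[node],
                        n_hmm_params=n_hmm)
    return RefinedModel(hgs=hgs, spec=spec, cpd=cpd, post=post, counts=counts,
                        bwbic=score, converged=converged, n_iter=n_iter)


def single_edge_hmm(data: DiscreteTimeSeries, node: int, parent: int,
                    fixed_equal: bool = False,
                    fixed_self: float | None = None) -> EdgePosterior:
    """Time-resolved activity posterior of the single edge parent→node.

    Fits the two-graph HMM {∅, {parent}} by inner EM, seeding the
    parentless graph with the child's marginal distribution and the
    with-parent graph with the full conditional contingency table.
    """
    if node == parent:
        raise ValueError("a node cannot be its own parent")
    hgs = HiddenGraphSet(node=node, graphs=[(), (parent,)])
    # seed both graphs from all data: marginal vs conditional counts
    T = data.n_transitions
    model = refine_hmdbn(
        data, node, hgs,
        init_gamma=np.full((2, T), 0.5),
        fixed_equal=fixed_equal, fixed_self=fixed_self,
        max_iter=EM_MAX_ITER_EDGE,
    )
    return EdgePosterior(parent=parent, presence=model.post.gamma[1].copy(),
                         model=model)


def combine_edge_posteriors(edges: list[EdgePosterior]
                            ) -> tuple[list[tuple[int, ...]], np.ndarray]:
    """Per-time posterior over all parent-set configurations of S.

    Treats the single-edge presences as independent per time point:
    ``P(config c | t) ∝ Π_{j∈c} p_j(t) · Π_{j∉c} (1 − p_j(t))``,
    renormalised per t.  Returns the configurations (all subsets of S,
    enumerated with the first parent as the lowest bit) and the
    ``2^|S| × T`` posterior matrix.
    """
    if not edges:
        raise ValueError("need at least one edge posterior")
    parents = [e.parent for e in edges]
    if len(set(parents)) != len(parents):
        raise ValueError("duplicate parents in edge posteriors")
    T = edges[0].presence.shape[0]
    k = len(edges)
    configs: list[tuple[int, ...]] = []
    combined = np.ones((2 ** k, T))
    for c in range(2 ** k):
        members = []
        for b, e in enumerate(edges):
            if c >> b & 1:
                members.append(e.parent)
                combined[c] *= e.presence
            else:
                combined[c] *= 1.0 - e.presence
        configs.append(tuple(sorted(members)))
    col = combined.sum(axis=0)
    col[col <= 0] = 1.0  # degenerate column: leave unnormalised zeros
    combined /= col
    return configs, combined


def identify_hidden_graphs(node: int, configs: list[tuple[int, ...]],
                           combined: np.ndarray,
                           support_fraction: float = 0.05,
                           h_max: int = 6
                           ) -> tuple[HiddenGraphSet, np.ndarray]:
    """Select the putative hidden graphs from the combined posterior.

    Keeps configurations whose expected occupancy ``Σ_t P(c | t)`` strictly
    exceeds ``support_fraction · T``; the globally dominant configuration
    is always kept; at most ``h_max`` graphs survive (ties broken toward
    the earlier, smaller configuration).  Returns the graph set and the
    rows of the combined posterior for the kept graphs, renormalised as an
    initial responsibility matrix.
    """
    T = combined.shape[1]
    occ = combined.sum(axis=1)
    keep = set(np.flatnonzero(occ > support_fraction * T).tolist())
    keep.add(int(np.argmax(occ)))
    # cap: retain the h_max highest-occupancy survivors; stable ascending
    # config order favours fewer parents on ties
    kept = sorted(keep)
    if len(kept) > h_max:
        kept = sorted(sorted(kept, key=lambda c: -occ[c])[:h_max])
    hgs = HiddenGraphSet(node=node, graphs=[configs[c] for c in kept])
    gamma0 = combined[kept].copy()
    col = gamma0.sum(axis=0)
    col[col <= 0] = 1.0
    gamma0 /= col
    return hgs, gamma0


def build_nonstationary(data: DiscreteTimeSeries, node: int,
                        parents: tuple[int, ...],
                        edge_cache: dict[int, EdgePosterior],
                        support_fraction: float = 0.05,
                        h_max: int = 6,
                        fixed_equal: bool = False,
                        fixed_self: float | None = None) -> RefinedModel:
    """Full step-3 pipeline for one candidate stationary parent set.

    ``edge_cache`` memoises single-edge HMMs per parent (they depend only
    on (node, parent), not on the rest of the candidate set).
    """
    if not parents:
        hgs = HiddenGraphSet(node=node, graphs=[()])
        return refine_hmdbn(data, node, hgs,
                            fixed_equal=fixed_equal, fixed_self=fixed_self)
    edges = []
    for j in parents:
        if j not in edge_cache:
            edge_cache[j] = single_edge_hmm(data, node, j,
                                            fixed_equal=fixed_equal,
                                            fixed_self=fixed_self)
        edges.append(edge_cache[j])
    if len(parents) == 1:
        ep = edges[0]
        occ = ep.model.post.gamma.sum(axis=1)
        T = data.n_transitions
        # collapse to a stationary model if one graph dominates everywhere
        keep = [h for h in range(2) if occ[h] > support_fraction * T]
        if int(np.argmax(occ)) not in keep:
            keep.append(int(np.argmax(occ)))
        if sorted(keep) == [0, 1]:
            return ep.model
        hgs = HiddenGraphSet(node=node,
                             graphs=[ep.model.hgs.graphs[h] for h in sorted(keep)])
        return refine_hmdbn(data, node, hgs,
                            fixed_equal=fixed_equal, fixed_self=fixed_self)
    configs, combined = combine_edge_posteriors(edges)
    hgs, gamma0 = identify_hidden_graphs(node, configs, combined,
                                         support_fraction, h_max)
    full = tuple(sorted(parents))
    if full not in hgs.graphs and hgs.n_graphs < h_max:
        # the stationary candidate itself is always a putative hidden
        # graph: single-edge posteriors can miss a jointly-active config
        # when one parent's CPD differs between regimes
        hgs = HiddenGraphSet(node=node, graphs=hgs.graphs + [full])
        gamma0 = np.vstack([gamma0, np.zeros(gamma0.shape[1])])
    # blend with uniform so no putative graph starts with zero
    # responsibility (a dead start is unrecoverable under EM)
    H = hgs.n_graphs
    gamma0 = 0.5 * gamma0 + 0.5 / H
    return refine_hmdbn(data, node, hgs, init_gamma=gamma0,
                        fixed_equal=fixed_equal, fixed_self=fixed_self)
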
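"""Expected-count CPD estimation and the three structure scores.

The score of record is BWBIC, a BIC-style Laplace approximation to the
marginal likelihood in which hard contingency counts are replaced by
*expected* counts weighted by the hidden-graph posteriors gamma, and the
sample size in the complexity penalty by the *expected sample size*
``N̂_h = Σ_t γ_h(t)`` of each hidden graph.  With a single hidden graph
(γ ≡ 1) it reduces exactly to the ordinary BIC of a stationary DBN node.

Hard-segmented BIC and BDe baselines score the same hidden-graph models
after assigning each time point wholly to its most probable graph
(Viterbi-training-style demarcated samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .data_model import DiscreteTimeSeries, parent_config_table

__all__ = [
    "HiddenGraphSet",
    "CPDTable",
    "ExpectedCounts",
    "expected_counts",
    "mle_cpd",
    "emission_matrix",
    "bwbic_score",
    "bic_score",
    "bde_score",
    "hard_segments",
]


@dataclass
class HiddenGraphSet:
    """The candidate parent-set configurations G_i^(1..H) of one node.

    ``graphs[h]`` is a sorted tuple of parent indices; parent sets must be
    distinct and may not contain the node itself (edges run from the
    previous time slice, so self-loops are meaningless here).
    """

    node: int
    graphs: list[tuple[int, ...]]

    def __post_init__(self) -> None:
        self.graphs = [tuple(sorted(int(p) for p in g)) for g in self.graphs]
        if len(self.graphs) < 1:
            raise ValueError("need at least one hidden graph")
        if len(set(self.graphs)) != len(self.graphs):
            raise ValueError("hidden graphs must be distinct parent sets")
        for g in self.graphs:
            if self.node in g:
                raise ValueError("a node cannot be its own parent")

    @property
    def n_graphs(self) -> int:
        return len(self.graphs)

    def config_tables(self, data: DiscreteTimeSeries):
        """Per-graph (jidx, q): parent-config index at t-1 for t = 1..T."""
        return [parent_config_table(data, g) for g in self.graphs]


@dataclass
class CPDTable:
    """Per-hidden-graph multinomial CPDs θ_{hjk} = P(X_i = k | parents = j)."""

    theta: list[np.ndarray]

    def __post_init__(self) -> None:
        self.theta = [np.asarray(t, dtype=np.float64) for t in self.theta]
        for t in self.theta:
            if t.ndim != 2:
                raise ValueError("each CPD must be q_h × r_i")


@dataclass
class ExpectedCounts:
    """Soft contingency counts Ñ_{hjk} and expected sample sizes N̂_h."""

    counts: list[np.ndarray]
    occupancy: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.occupancy is None:
            self.occupancy = np.array([c.sum() for c in self.counts])


def expected_counts(data: DiscreteTimeSeries, node: int,
                    hgs: HiddenGraphSet, gamma: np.ndarray) -> ExpectedCounts:
    """Accumulate γ-weighted (parent config at t-1, child state at t) counts.

    ``Ñ_{hjk} = Σ_{t=1..T} γ[h, t] · δ(x_i(t) = k, parents_h(t-1) = j)``.
    """
    T = data.n_transitions
    if gamma.shape != (hgs.n_graphs, T):
        raise ValueError(
            f"gamma shape {gamma.shape} does not match "
            f"({hgs.n_graphs} graphs, T={T})"
        )
    r = data.arities[node]
    child = data.values[node, 1:]
    counts = []
    for h, (jidx, q) in enumerate(hgs.config_tables(data)):
        flat = np.bincount(jidx * r + child, weights=gamma[h], minlength=q * r)
        counts.append(flat.reshape(q, r))
    return ExpectedCounts(counts=counts, occupancy=gamma.sum(axis=1))


def mle_cpd(counts: ExpectedCounts, smoothing: float = 0.5,
            prior: np.ndarray | None = None) -> CPDTable:
    """Row-normalised (pseudo-counted) CPD estimates.

    ``θ̂_{hjk} = (Ñ_{hjk} + ε_k) / (Σ_k Ñ_{hjk} + Σ_k ε_k)`` with
    ``ε_k = smoothing · r · prior_k`` (uniform prior by default, giving the
    plain ``(Ñ + ε) / (ΣÑ + εr)`` form).  A prior centred on the child's
    marginal keeps a hidden graph with no expected counts at the null
    (marginal) model instead of degrading it to uniform.  A row with zero
    total and ε = 0 falls back to the prior.
    """
    theta = []
    for c in counts.counts:
        q, r = c.shape
        p = np.full(r, 1.0 / r) if prior is None else np.asarray(prior, float)
        eps = smoothing * r * p
        tot = c.sum(axis=1, keepdims=True) + eps.sum()
        num = c + eps
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(tot > 0, num / np.maximum(tot, 1e-300), p)
        theta.append(t)
    return CPDTable(theta=theta)


def emission_matrix(data: DiscreteTimeSeries, node: int,
                    hgs: HiddenGraphSet, cpd: CPDTable) -> np.ndarray:
    """Emission probabilities ``B[h, t] = θ_{h, j(t-1), x_i(t)}``, H × T."""
    child = data.values[node, 1:]
    B = np.empty((hgs.n_graphs, data.n_transitions))
    for h, (jidx, _q) in enumerate(hgs.config_tables(data)):
        B[h] = cpd.theta[h][jidx, child]
    return B


def _loglik_term(counts: np.ndarray, theta: np.ndarray) -> float:
    """Σ_{j,k} Ñ log θ̂ with the 0·log 0 := 0 convention."""
    mask = counts > 0
    return float(np.sum(counts[mask] * np.log(theta[mask])))


def bwbic_score(counts: ExpectedCounts, cpd: CPDTable, arity: int,
                n_hmm_params: int = 0) -> float:
    """Baum-Welch BIC of one node's hidden-graph model (higher is better).

    ``Σ_h [ Σ_{jk} Ñ_{hjk} log θ̂_{hjk} − (d_h / 2) · log N̂_h ]`` with
    ``d_h = q_h (r_i − 1)`` free CPD parameters per graph, minus
    ``(n_hmm_params / 2) · log T`` for the chain's own free parameters
    (prior and, when optimised, transition matrix) — the part of the
    complexity penalty that grows with the number of hidden graphs, so a
    model cannot buy likelihood by splitting into gratuitous regimes.
    Graphs with expected sample size below 1 take a zero log penalty
    (floored), which keeps the score finite while still disfavouring
    unsupported graphs through their vanishing likelihood share.  With a
    single hidden graph and γ ≡ 1 every extra term vanishes and the score
    is exactly the stationary BIC.
    """
    score = 0.0
    for c, th, nh in zip(counts.counts, cpd.theta, counts.occupancy):
        q, r = c.shape
        d = q * (arity - 1)
        score += _loglik_term(c, th) - 0.5 * d * np.log(max(float(nh), 1.0))
    if n_hmm_params:
        T = float(counts.occupancy.sum())
        score -= 0.5 * n_hmm_params * np.log(max(T, 1.0))
    return score


def hard_segments(gamma: np.ndarray) -> np.ndarray:
    """Per-time argmax of γ (ties toward the lower graph index)."""
    return np.argmax(gamma, axis=0)


def _hard_counts(data: DiscreteTimeSeries, node: int, hgs: HiddenGraphSet,
                 segments: np.ndarray) -> list[np.ndarray]:
    T = data.n_transitions
    if segments.shape != (T,):
        raise ValueError("hard segmentation must assign every t in 1..T")
    r = data.arities[node]
    child = data.values[node, 1:]
    out = []
    for h, (jidx, q) in enumerate(hgs.config_tables(data)):
        sel = segments == h
        flat = np.bincount(jidx[sel] * r + child[sel], minlength=q * r)
        out.append(flat.reshape(q, r).astype(float))
    return out


def bic_score(data: DiscreteTimeSeries, node: int, hgs: HiddenGraphSet,
              segments: np.ndarray) -> float:
    """Hard-segmented BIC: per-graph BIC on demarcated counts, summed.

    Each time point belongs entirely to one graph; a graph with an empty
    segment contributes 0.  Coincides with :func:`bwbic_score` when a
    single graph covers every time point.
    """
    score = 0.0
    r = data.arities[node]
    for h, c in enumerate(_hard_counts(data, node, hgs, segments)):
        n_h = c.sum()
        if n_h == 0:
            continue
        q = c.shape[0]
        tot = c.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.where(tot > 0, c / np.maximum(tot, 1e-300), 1.0 / r)
        score += _loglik_term(c, theta) - 0.5 * q * (r - 1) * np.log(max(n_h, 1.0))
    return score


def bde_score(data: DiscreteTimeSeries, node: int, hgs: HiddenGraphSet,
              segments: np.ndarray, alpha: float = 1.0) -> float:
    """Hard-segmented BDe: Dirichlet-multinomial marginal log-likelihood.

    Uniform prior mass ``α / (q_h r_i)`` per CPD cell, independently per
    hidden graph and parent configuration; computed via log-gamma.
    """
    if alpha <= 0:
        raise ValueError("equivalent sample size alpha must be positive")
    r = data.arities[node]
    score = 0.0
    for c in _hard_counts(data, node, hgs, segments):
        q = c.shape[0]
        a_jk = alpha / (q * r)
        a_j = alpha / q
        nj = c.sum(axis=1)
        score += float(
            np.sum(gammaln(a_j) - gammaln(a_j + nj))
            + np.sum(gammaln(a_jk + c) - gammaln(a_jk))
        )
    return score
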
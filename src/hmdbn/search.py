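"""Outer structural-EM loop: greedy hill-climbing over stationary parent sets.

Each node is learned independently (edges point from the previous time
slice, so no cycle bookkeeping is needed and the per-node scores add up to
the network score).  Starting from the empty parent set, every single-parent
addition and deletion is converted into a non-stationary model by the
hidden-graph builder and scored; the best strictly improving move is
accepted, and the search stops when no move improves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .builder import EdgePosterior, RefinedModel, build_nonstationary, _frozen_A
from .data_model import DiscreteTimeSeries
from .hmm import NodeHMMSpec
from .scoring import bde_score, bic_score, hard_segments

logger = logging.getLogger(__name__)

__all__ = ["SearchConfig", "NodeHMDBN", "learn_node", "learn_network",
           "apply_ablation"]

SCORES = ("bwbic", "bic", "bde")


@dataclass
class SearchConfig:
    """Knobs of the structure search.

    ``score`` selects the structure criterion; ``fixed_equal_transitions``
    and ``fixed_self_transition`` are the two transition ablations
    (row-uniform frozen A, or frozen self-transition s with uniform
    off-diagonal mass) and are mutually exclusive; ``candidate_parents``
    optionally restricts the regulator pool.
    """

    score: str = "bwbic"
    max_fanin: int = 3
    h_max: int = 6
    support_fraction: float = 0.05
    bde_alpha: float = 1.0
    fixed_equal_transitions: bool = False
    fixed_self_transition: float | None = None
    candidate_parents: list[int] | None = None
    max_outer_iters: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.score not in SCORES:
            raise ValueError(f"score must be one of {SCORES}")
        if self.fixed_equal_transitions and self.fixed_self_transition is not None:
            raise ValueError("set at most one transition ablation")
        if self.fixed_self_transition is not None and not (
                0.0 < self.fixed_self_transition < 1.0):
            raise ValueError("fixed self-transition must lie in (0, 1)")
        if self.max_fanin < 1:
            raise ValueError("max_fanin must be >= 1")


@dataclass
class NodeHMDBN:
    """Converged non-stationary sub-network for one node."""

    node: int
    model: RefinedModel
    score: float
    parents: tuple[int, ...] = field(default=None)  # type: ignore[assignment]
    trace: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.parents is None:
            union: set[int] = set()
            for g in self.model.hgs.graphs:
                union.update(g)
            self.parents = tuple(sorted(union))


def apply_ablation(spec: NodeHMMSpec, cfg: SearchConfig) -> NodeHMMSpec:
    """Replace a model's transition matrix per the configured ablation."""
    A = _frozen_A(spec.n_states, cfg.fixed_equal_transitions,
                  cfg.fixed_self_transition)
    if A is None:
        return spec
    return NodeHMMSpec(pi=spec.pi.copy(), A=A, B=spec.B.copy())


def _score_model(data: DiscreteTimeSeries, node: int, model: RefinedModel,
                 cfg: SearchConfig) -> float:
    if cfg.score == "bwbic":
        return model.bwbic
    seg = hard_segments(model.post.gamma)
    if cfg.score == "bic":
        return bic_score(data, node, model.hgs, seg)
    return bde_score(data, node, model.hgs, seg, alpha=cfg.bde_alpha)


def learn_node(data: DiscreteTimeSeries, node: int,
               cfg: SearchConfig | None = None) -> NodeHMDBN:
    """Greedy structure search for one node's non-stationary sub-network.

    Deterministic: candidates are enumerated in ascending node index, a
    move is accepted only on strict score improvement, and equal-scoring
    moves favour the smaller parent set (deletions are tried first).
    """
    cfg = cfg or SearchConfig()
    pool = cfg.candidate_parents
    if pool is None:
        pool = [j for j in range(data.n_vars) if j != node]
    else:
        pool = sorted(j for j in pool if j != node)

    edge_cache: dict[int, EdgePosterior] = {}
    memo: dict[tuple[int, ...], RefinedModel] = {}
    trace: list[dict] = []

    def evaluate(parents: tuple[int, ...]) -> tuple[RefinedModel, float]:
        if parents not in memo:
            memo[parents] = build_nonstationary(
                data, node, parents, edge_cache,
                support_fraction=cfg.support_fraction, h_max=cfg.h_max,
                fixed_equal=cfg.fixed_equal_transitions,
                fixed_self=cfg.fixed_self_transition)
        model = memo[parents]
        return model, _score_model(data, node, model, cfg)

    current = ()
    cur_model, cur_score = evaluate(current)
    for _ in range(cfg.max_outer_iters):
        candidates: list[tuple[int, ...]] = []
        # deletions first: ties favour the smaller parent set
        for j in current:
            candidates.append(tuple(p for p in current if p != j))
        if len(current) < cfg.max_fanin:
            for j in pool:
                if j not in current:
                    candidates.append(tuple(sorted(current + (j,))))
        best = None
        for cand in candidates:
            model, score = evaluate(cand)
            accepted = score > cur_score and (best is None or score > best[2])
            trace.append({"node": node, "parents": cand,
                          "H": model.hgs.n_graphs, "score": score,
                          "accepted": bool(accepted)})
            if accepted:
                best = (cand, model, score)
        if best is None:
            break
        current, cur_model, cur_score = best
        logger.debug("node %d: accepted parents %s (score %.4f)",
                     node, current, cur_score)
    return NodeHMDBN(node=node, model=cur_model, score=cur_score, trace=trace)


def learn_network(data: DiscreteTimeSeries,
                  cfg: SearchConfig | None = None) -> list[NodeHMDBN]:
    """Learn every node's sub-network independently and collect them.

    Node sub-problems share nothing, so the result is identical for any
    execution order; failures are re-raised tagged with the node identity.
    """
    cfg = cfg or SearchConfig()
    out = []
    for i in range(data.n_vars):
        try:
            out.append(learn_node(data, i, cfg))
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(
                f"learning failed for node {i} ({data.var_names[i]!r}): {exc}"
            ) from exc
    return out
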
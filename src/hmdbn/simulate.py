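"""Synthetic time-varying networks, sampling, and the evaluation protocol.

The benchmark generator draws random binary networks whose topology changes
at epoch boundaries by single-edge additions/deletions, then samples a
discrete time course from them: at each step a child copies a designated
boolean function of its parents' previous states with probability
``dependence_strength`` and is otherwise uniform.  The default function is
a random logic map drawn once per (node, parent set), rejection-sampled so
that every parent has a non-zero marginal effect — for a single parent
this is a noisy copy (or inversion), and at higher fan-in it keeps each
edge individually detectable while leaving node marginals roughly
balanced.  Fixed noisy-OR, noisy-parity and Dirichlet random-table
variants are selectable (note that OR cascades saturate marginals toward 1
and parity hides edges from any marginal test, so neither supports full
structure recovery in general).

Evaluation scores the predicted edge set at every time point against the
true time-varying adjacency (per-observation precision/recall, averaged
over time; F1 from the averaged values).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import DiscreteTimeSeries
from .decode import TimeVaryingNetwork, assemble
from .search import SearchConfig, learn_network

__all__ = [
    "TrueNetworkSpec",
    "EvalResult",
    "make_benchmark_10node",
    "make_benchmark_100node",
    "simulate",
    "true_adjacency",
    "evaluate",
    "run_benchmark",
]

#: probability a child takes its parents' designated value; the remaining
#: mass is uniform over the other states, so 0.5 on a binary child means
#: no dependence at all
DEFAULT_DEPENDENCE = 0.9


@dataclass
class TrueNetworkSpec:
    """Ground-truth time-varying topology and its generating mechanism.

    ``epochs`` is a list of ``(length, parents)`` pairs where ``parents``
    maps each node to its parent tuple during that epoch; consecutive
    epochs must differ.  ``cpd_map`` names the parent→child function
    (random-map, noisy-or, noisy-parity, or random-table).
    """

    n_nodes: int
    epochs: list[tuple[int, list[tuple[int, ...]]]]
    dependence_strength: float = DEFAULT_DEPENDENCE
    cpd_map: str = "random-map"
    seed: int = 0
    tables: list[list[np.ndarray]] | None = field(default=None, repr=False)
    logic_maps: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("need at least one epoch")
        for length, parents in self.epochs:
            if length < 1:
                raise ValueError("epoch lengths must be >= 1")
            if len(parents) != self.n_nodes:
                raise ValueError("each epoch must list parents for every node")
        for (l1, p1), (l2, p2) in zip(self.epochs, self.epochs[1:]):
            if p1 == p2:
                raise ValueError("consecutive epochs must differ")
        if self.cpd_map not in {"random-map", "noisy-or", "noisy-parity",
                                "random-table"}:
            raise ValueError(f"unknown cpd_map {self.cpd_map!r}")
        if self.cpd_map == "random-table" and self.tables is None:
            rng = np.random.default_rng(self.seed ^ 0x5EED)
            self.tables = [
                [rng.dirichlet(np.ones(2), size=2 ** len(parents[i]))
                 for i in range(self.n_nodes)]
                for _, parents in self.epochs
            ]
        if self.cpd_map == "random-map" and self.logic_maps is None:
            rng = np.random.default_rng(self.seed ^ 0x10C1C)
            self.logic_maps = {}
            for _, parents in self.epochs:
                for i, ps in enumerate(parents):
                    if ps and (i, ps) not in self.logic_maps:
                        self.logic_maps[(i, ps)] = _draw_logic_map(
                            rng, len(ps))

    @property
    def total_samples(self) -> int:
        return sum(length for length, _ in self.epochs)

    @property
    def n_edge_changes(self) -> int:
        n = 0
        for (_, p1), (_, p2) in zip(self.epochs, self.epochs[1:]):
            for i in range(self.n_nodes):
                n += len(set(p1[i]) ^ set(p2[i]))
        return n


def _draw_logic_map(rng: np.random.Generator, k: int) -> np.ndarray:
    """Random boolean function of k parents with every parent effective.

    Output per parent configuration is a fair coin, rejection-sampled
    until each parent has a non-zero *marginal* effect (averaging the
    output over the other parents' uniform states differs between that
    parent's two values).  This excludes constant maps, dummy parents and
    parity-style maps, all of which would make an edge unrecoverable from
    data in principle.
    """
    q = 2 ** k
    while True:
        m = rng.integers(0, 2, size=q)
        ok = True
        for b in range(k):
            hi = [c for c in range(q) if c >> b & 1]
            lo = [c for c in range(q) if not c >> b & 1]
            if m[hi].mean() == m[lo].mean():
                ok = False
                break
        if ok:
            return m


def _random_parent_map(rng: np.random.Generator, n: int, n_edges: int,
                       max_fanin: int) -> list[set[int]]:
    parents: list[set[int]] = [set() for _ in range(n)]
    pairs = [(j, i) for i in range(n) for j in range(n) if i != j]
    rng.shuffle(pairs)
    placed = 0
    for j, i in pairs:
        if placed == n_edges:
            break
        if len(parents[i]) < max_fanin:
            parents[i].add(j)
            placed += 1
    return parents


def _perturb_one_edge(rng: np.random.Generator, parents: list[set[int]],
                      max_fanin: int) -> list[set[int]]:
    """Add or delete one random edge, respecting the fan-in cap."""
    n = len(parents)
    new = [set(p) for p in parents]
    addable = [(j, i) for i in range(n) for j in range(n)
               if i != j and j not in new[i] and len(new[i]) < max_fanin]
    deletable = [(j, i) for i in range(n) for j in sorted(new[i])]
    moves = []
    if addable:
        moves.append("add")
    if deletable:
        moves.append("del")
    if rng.choice(moves) == "add":
        j, i = addable[rng.integers(len(addable))]
        new[i].add(j)
    else:
        j, i = deletable[rng.integers(len(deletable))]
        new[i].remove(j)
    return new


def _epoch_lengths(rng: np.random.Generator, k: int, lo: int, hi: int,
                   total: int) -> list[int]:
    """k lengths drawn uniformly in [lo, hi], rescaled to sum to total."""
    raw = rng.integers(lo, hi + 1, size=k).astype(float)
    lengths = np.maximum(np.round(raw * total / raw.sum()).astype(int), lo)
    # distribute the rounding residual over the largest epochs
    order = np.argsort(-lengths)
    i = 0
    while lengths.sum() != total:
        step = 1 if lengths.sum() < total else -1
        idx = order[i % k]
        if lengths[idx] + step >= lo:
            lengths[idx] += step
        i += 1
    return lengths.tolist()


def make_benchmark_10node(seed: int, mean_segment_samples: int | None = None,
                          dependence_strength: float = DEFAULT_DEPENDENCE,
                          cpd_map: str = "random-map") -> TrueNetworkSpec:
    """Ten-node binary benchmark: 7 epochs, 6 single-edge changes.

    Epoch lengths are drawn uniformly in [20, 400] and rescaled to total
    1019 observations.  ``mean_segment_samples`` instead resamples the
    lengths around the requested per-segment average (the sample-size
    robustness setting): uniform in [m/2, 3m/2], total 7m.
    """
    rng = np.random.default_rng(seed)
    base = _random_parent_map(rng, 10, n_edges=10, max_fanin=3)
    maps = [base]
    for _ in range(6):
        nxt = _perturb_one_edge(rng, maps[-1], max_fanin=3)
        maps.append(nxt)
    if mean_segment_samples is None:
        lengths = _epoch_lengths(rng, 7, 20, 400, 1019)
    else:
        m = mean_segment_samples
        lengths = _epoch_lengths(rng, 7, max(m // 2, 2), 3 * m // 2, 7 * m)
    epochs = [(L, [tuple(sorted(p)) for p in mp])
              for L, mp in zip(lengths, maps)]
    return TrueNetworkSpec(n_nodes=10, epochs=epochs, seed=seed,
                           dependence_strength=dependence_strength,
                           cpd_map=cpd_map)


def make_benchmark_100node(seed: int,
                           dependence_strength: float = DEFAULT_DEPENDENCE,
                           cpd_map: str = "random-map") -> TrueNetworkSpec:
    """Hundred-node benchmark: 50 base edges, 5 segments, 5000 samples,
    1-3 single-edge changes at each of the 4 boundaries."""
    rng = np.random.default_rng(seed)
    base = _random_parent_map(rng, 100, n_edges=50, max_fanin=3)
    maps = [base]
    for _ in range(4):
        nxt = maps[-1]
        for _ in range(int(rng.integers(1, 4))):
            nxt = _perturb_one_edge(rng, nxt, max_fanin=3)
        if nxt == maps[-1]:  # all changes cancelled out; force one
            nxt = _perturb_one_edge(rng, nxt, max_fanin=3)
        maps.append(nxt)
    lengths = _epoch_lengths(rng, 5, 800, 1200, 5000)
    epochs = [(L, [tuple(sorted(p)) for p in mp])
              for L, mp in zip(lengths, maps)]
    return TrueNetworkSpec(n_nodes=100, epochs=epochs, seed=seed,
                           dependence_strength=dependence_strength,
                           cpd_map=cpd_map)


def _target_state(spec: TrueNetworkSpec, node: int, parents: tuple[int, ...],
                  parent_states: np.ndarray) -> int:
    if spec.cpd_map == "noisy-or":
        return int(parent_states.max())
    if spec.cpd_map == "noisy-parity":
        return int(parent_states.sum() % 2)
    c = 0  # random-map: bit b is the state of parents[b]
    for b, s in enumerate(parent_states):
        c |= int(s) << b
    return int(spec.logic_maps[(node, parents)][c])


def simulate(spec: TrueNetworkSpec, seed: int | None = None) -> DiscreteTimeSeries:
    """Sample a binary time course of ``total_samples + 1`` time points.

    ``x(0)`` is uniform; thereafter each child takes the designated parent
    function of the previous slice with probability
    ``dependence_strength`` and the opposite state otherwise (so strength
    0.5 severs the dependence entirely).  Parentless nodes are uniform.
    Fully determined by the seed (``spec.seed`` unless overridden).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n, T = spec.n_nodes, spec.total_samples
    x = np.zeros((n, T + 1), dtype=np.int64)
    x[:, 0] = rng.integers(0, 2, size=n)
    copy = rng.random((n, T)) < spec.dependence_strength
    noise = rng.integers(0, 2, size=(n, T))
    t = 1
    for e, (length, parents) in enumerate(spec.epochs):
        for _ in range(length):
            prev = x[:, t - 1]
            for i in range(n):
                ps = parents[i]
                if not ps:
                    x[i, t] = noise[i, t - 1]
                    continue
                if spec.cpd_map == "random-table":
                    j = 0
                    for p in ps:
                        j = j * 2 + prev[p]
                    probs = spec.tables[e][i][j]
                    x[i, t] = int(rng.random() < probs[1])
                else:
                    target = _target_state(spec, i, ps, prev[np.array(ps)])
                    # designated state w.p. strength, else the other state
                    x[i, t] = target if copy[i, t - 1] else 1 - target
            t += 1
    names = [f"X{i}" for i in range(n)]
    return DiscreteTimeSeries(x, names, [2] * n)


def true_adjacency(spec: TrueNetworkSpec) -> np.ndarray:
    """T × N × N boolean truth: edge j→i active at t (1-based t index 0)."""
    n, T = spec.n_nodes, spec.total_samples
    adj = np.zeros((T, n, n), dtype=bool)
    t = 0
    for length, parents in spec.epochs:
        for i in range(n):
            for j in parents[i]:
                adj[t:t + length, j, i] = True
        t += length
    return adj


@dataclass
class EvalResult:
    """Per-observation-averaged precision/recall and their F1."""

    precision: float
    recall: float
    f1: float


def evaluate(truth: TrueNetworkSpec | np.ndarray,
             predicted: TimeVaryingNetwork | np.ndarray,
             per_time_f1: bool = False) -> EvalResult:
    """Precision/recall of the predicted edges at each time point,
    averaged over all time points; F1 from the averaged P and R.

    Conventions at empty sets: a time point with no predicted edges has
    precision 1 (nothing asserted, nothing wrong); one with no true edges
    has recall 1.
    """
    true_adj = truth if isinstance(truth, np.ndarray) else true_adjacency(truth)
    pred_adj = (predicted if isinstance(predicted, np.ndarray)
                else predicted.adjacency)
    if true_adj.shape != pred_adj.shape:
        raise ValueError(
            f"shape mismatch: truth {true_adj.shape} vs "
            f"prediction {pred_adj.shape}")
    tp = (true_adj & pred_adj).sum(axis=(1, 2)).astype(float)
    n_pred = pred_adj.sum(axis=(1, 2))
    n_true = true_adj.sum(axis=(1, 2))
    prec_t = np.where(n_pred > 0, tp / np.maximum(n_pred, 1), 1.0)
    rec_t = np.where(n_true > 0, tp / np.maximum(n_true, 1), 1.0)
    if per_time_f1:
        denom = prec_t + rec_t
        f1_t = np.where(denom > 0, 2 * prec_t * rec_t / np.maximum(denom, 1e-300), 0.0)
        p, r, f1 = float(prec_t.mean()), float(rec_t.mean()), float(f1_t.mean())
    else:
        p, r = float(prec_t.mean()), float(rec_t.mean())
        f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return EvalResult(precision=p, recall=r, f1=f1)


def run_benchmark(design: str = "ten-node", n_datasets: int = 25,
                  cfg: SearchConfig | None = None, seed: int = 1,
                  mean_segment_samples: int | None = None,
                  dependence_strength: float = DEFAULT_DEPENDENCE,
                  cpd_map: str = "random-map",
                  fixed_topology: bool = False) -> pd.DataFrame:
    """Generate, learn, decode and evaluate ``n_datasets`` benchmark runs.

    By default each dataset gets its own random topology (seed + k); with
    ``fixed_topology`` a single topology is drawn from ``seed`` and only
    the observations are resampled.  Returns a tidy per-dataset table
    (dataset, seed, precision, recall, f1); medians via ``.median()``.
    Per-dataset failures are recorded as NaN rows, not raised.
    """
    cfg = cfg or SearchConfig()
    rows = []
    for k in range(n_datasets):
        ds_seed = int(seed) * 10_000 + k
        try:
            if design == "ten-node":
                topo_seed = int(seed) * 10_000 if fixed_topology else ds_seed
                spec = make_benchmark_10node(
                    topo_seed, mean_segment_samples=mean_segment_samples,
                    dependence_strength=dependence_strength, cpd_map=cpd_map)
            elif design == "hundred-node":
                topo_seed = int(seed) * 10_000 if fixed_topology else ds_seed
                spec = make_benchmark_100node(
                    topo_seed, dependence_strength=dependence_strength,
                    cpd_map=cpd_map)
            else:
                raise ValueError(f"unknown design {design!r}")
            data = simulate(spec, seed=ds_seed)
            nets = learn_network(data, cfg)
            res = evaluate(spec, assemble(nets))
            rows.append({"dataset": k, "seed": ds_seed,
                         "precision": res.precision, "recall": res.recall,
                         "f1": res.f1})
        except ValueError:
            raise
        except Exception:  # pragma: no cover - per-dataset robustness
            rows.append({"dataset": k, "seed": ds_seed, "precision": np.nan,
                         "recall": np.nan, "f1": np.nan})
    return pd.DataFrame(rows)
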
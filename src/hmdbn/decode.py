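"""Decoding transition times and assembling the global time-varying network.

Each learned node carries a posterior over its hidden graphs at every time
point.  Decoding picks one graph per time point — by default the marginal
posterior argmax, which needs no threshold, or optionally the Viterbi joint
path — and the per-node decoded parent sets are unioned into a single
time-varying adjacency with merged breakpoints.

Transition times are reported 1-based: the value is the first time point
governed by the new hidden graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .hmm import viterbi
from .search import NodeHMDBN

__all__ = ["TimeVaryingNetwork", "decode_node", "assemble",
           "write_segments_tsv", "write_network_json", "write_sif"]


@dataclass
class TimeVaryingNetwork:
    """Per-time adjacency and its change-point structure.

    ``adjacency[t - 1, j, i]`` is True iff edge j→i is active at time t
    (t = 1..T): x_i(t) depends on x_j(t-1).  ``node_transition_times[i]``
    lists the 1-based indices where node i's decoded graph changes;
    ``global_segments`` merges all nodes' breakpoints into
    ``(start, end, edges)`` triples covering 1..T.
    """

    adjacency: np.ndarray
    node_paths: list[np.ndarray]
    node_graphs: list[list[tuple[int, ...]]]
    node_transition_times: list[list[int]]
    global_segments: list[tuple[int, int, list[tuple[int, int]]]]
    var_names: list[str]

    @property
    def n_times(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_vars(self) -> int:
        return self.adjacency.shape[1]


def decode_node(nh: NodeHMDBN, mode: str = "posterior-argmax"
                ) -> tuple[np.ndarray, list[int]]:
    """Decode one node's hidden-graph index per time point.

    ``posterior-argmax`` takes the per-time marginal MAP (ties toward the
    lower graph index); ``viterbi`` takes the joint MAP path.  Returns the
    path and the 1-based transition times.
    """
    if mode == "posterior-argmax":
        path = np.argmax(nh.model.post.gamma, axis=0)
    elif mode == "viterbi":
        path = viterbi(nh.model.spec)
    else:
        raise ValueError(f"unknown decode mode {mode!r}")
    changes = np.flatnonzero(np.diff(path)) + 1  # 0-based index into path
    times = [int(c) + 1 for c in changes]  # 1-based first index of new regime
    return path, times


def assemble(networks: list[NodeHMDBN], mode: str = "posterior-argmax"
             ) -> TimeVaryingNetwork:
    """Union the decoded per-node parent sets into one time-varying network."""
    if not networks:
        raise ValueError("no node models to assemble")
    lengths = {nh.model.post.gamma.shape[1] for nh in networks}
    if len(lengths) > 1:
        raise ValueError(f"nodes decoded over different T: {sorted(lengths)}")
    T = lengths.pop()
    N = len(networks)
    var_names = [f"X{i}" for i in range(N)]

    adjacency = np.zeros((T, N, N), dtype=bool)
    node_paths, node_graphs, node_times = [], [], []
    for nh in sorted(networks, key=lambda nh: nh.node):
        path, times = decode_node(nh, mode)
        graphs = nh.model.hgs.graphs
        node_paths.append(path)
        node_graphs.append(list(graphs))
        node_times.append(times)
        for t in range(T):
            for j in graphs[path[t]]:
                adjacency[t, j, nh.node] = True

    breaks = sorted({t for times in node_times for t in times})
    segments = []
    starts = [1] + breaks
    ends = [b - 1 for b in breaks] + [T]
    for s, e in zip(starts, ends):
        edges = [(int(j), int(i)) for j, i in np.argwhere(adjacency[s - 1])]
        segments.append((s, e, edges))
    return TimeVaryingNetwork(
        adjacency=adjacency, node_paths=node_paths, node_graphs=node_graphs,
        node_transition_times=node_times, global_segments=segments,
        var_names=var_names)


def write_segments_tsv(net: TimeVaryingNetwork, path: str | Path,
                       var_names: list[str] | None = None) -> None:
    """Per-segment edge list: segment_start, segment_end, parent, child."""
    names = var_names or net.var_names
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("segment_start\tsegment_end\tparent\tchild\n")
        for s, e, edges in net.global_segments:
            for j, i in sorted(edges):
                fh.write(f"{s}\t{e}\t{names[j]}\t{names[i]}\n")


def write_network_json(networks: list[NodeHMDBN], net: TimeVaryingNetwork,
                       path: str | Path,
                       var_names: list[str] | None = None) -> None:
    """Full decoded model: hidden graphs, γ, transition times, scores."""
    names = var_names or net.var_names
    payload = {
        "nodes": [
            {
                "node": nh.node,
                "name": names[nh.node],
                "hidden_graphs": [[names[j] for j in g]
                                  for g in nh.model.hgs.graphs],
                "gamma": np.round(nh.model.post.gamma, 6).tolist(),
                "transition_times": net.node_transition_times[nh.node],
                "score": nh.score,
                "loglik": nh.model.post.loglik,
            }
            for nh in sorted(networks, key=lambda nh: nh.node)
        ],
        "global_segments": [
            {"start": s, "end": e,
             "edges": [[names[j], names[i]] for j, i in sorted(edges)]}
            for s, e, edges in net.global_segments
        ],
    }
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def write_sif(net: TimeVaryingNetwork, outdir: str | Path,
              var_names: list[str] | None = None) -> list[Path]:
    """One SIF file per global segment, for network viewers."""
    names = var_names or net.var_names
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for s, e, edges in net.global_segments:
        p = outdir / f"segment_{s:05d}_{e:05d}.sif"
        with p.open("w", encoding="utf-8") as fh:
            for j, i in sorted(edges):
                fh.write(f"{names[j]}\tregulates\t{names[i]}\n")
        written.append(p)
    return written
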
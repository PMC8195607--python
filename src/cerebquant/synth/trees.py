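"""Stochastic branching-tree generator for arbor morphometry tests.

Growth starts at a soma node and extends tips segment by segment: each tip
either bifurcates (probability ``branch_prob``) into two daughters rotated
away from the parent direction, or continues with a small direction
jitter, until ``max_depth`` segments from the root.  ``planar=True``
confines growth to the xy-plane (dendrite-like), otherwise growth is 3-D
(axon-arbor-like).  With ``branch_prob=1`` the result is a full binary
tree of depth ``max_depth``; with ``branch_prob=0`` an unbranched path.
"""

from __future__ import annotations

import numpy as np

from ..morpho import NeuronTree
from .params import TreeSimParams

_DENDRITE = 3


def _rotate2d(v: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], 0.0])


def _perturb(rng: np.random.Generator, v: np.ndarray, sd: float, planar: bool) -> np.ndarray:
    j = rng.normal(0.0, sd, size=3)
    if planar:
        j[2] = 0.0
    w = v + j
    n = np.linalg.norm(w)
    return v if n == 0 else w / n


def generate_tree(params: TreeSimParams) -> NeuronTree:
    """Grow a random rooted tree; bit-reproducible under a fixed seed."""
    rng = np.random.default_rng(params.seed)
    ids = [1]
    types = [1]  # soma
    xyz = [np.zeros(3)]
    radius = [2.0]
    parent = [-1]

    start = np.array([0.0, 1.0, 0.0])
    # (parent_id, direction, depth) tips awaiting extension; list order is
    # deterministic (depth-first) so the node numbering is reproducible
    tips = [(1, start, 0)]
    next_id = 2
    index = {1: 0}
    while tips:
        pid, direction, depth = tips.pop()
        if depth >= params.max_depth:
            continue
        if rng.uniform() < params.branch_prob:
            angles = (rng.uniform(0.35, 0.9), -rng.uniform(0.35, 0.9))
            if params.planar:
                dirs = [_rotate2d(direction, a) for a in angles]
            else:
                dirs = []
                for a in angles:
                    axis = rng.normal(size=3)
                    axis -= axis.dot(direction) * direction
                    n = np.linalg.norm(axis)
                    axis = axis / n if n > 0 else np.array([1.0, 0.0, 0.0])
                    dirs.append(np.cos(a) * direction + np.sin(a) * axis)
            daughters = dirs
        else:
            daughters = [_perturb(rng, direction, 0.15, params.planar)]
        for d in daughters:
            length = params.segment_len_mean
            if params.segment_len_sd > 0:
                length = max(0.1, rng.normal(params.segment_len_mean, params.segment_len_sd))
            pos = xyz[index[pid]] + length * d
            index[next_id] = len(ids)
            ids.append(next_id)
            types.append(_DENDRITE)
            xyz.append(pos)
            radius.append(0.5)
            parent.append(pid)
            tips.append((next_id, d, depth + 1))
            next_id += 1

    return NeuronTree(
        np.array(ids), np.array(types), np.array(xyz), np.array(radius), np.array(parent)
    )
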
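"""Tetrad identification and assembly of vertical tetrad stacks.

A tetrad is a chordless 4-cycle in the base-pair graph whose members are
mutually near-coplanar and tightly clustered. Stacks chain tetrads joined
by enough face-to-face stacking contacts and order them along the common
axis, so that downstream refinement can reason about "the polyads of one
stacked formation".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .base_geometry import BaseFrame, tilt
from .interaction_graph import InteractionGraph

#: Planarity / compactness gates for accepting a 4-cycle as a tetrad.
TETRAD_TILT_MAX = 50.0   # deg, pairwise between member normals
TETRAD_RADIUS_MAX = 9.0  # Å, member base centroid to tetrad centroid


@dataclass(eq=False)
class Tetrad:
    """Four mutually paired, coplanar bases in cyclic pairing order."""

    members: tuple[str, str, str, str]     # residue keys, cyclic order
    centroid: np.ndarray                   # mean of member base centroids
    plane_normals: list[np.ndarray]        # member frame normals
    frames: list[BaseFrame]

    @property
    def key(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))

    @property
    def mean_normal(self) -> np.ndarray:
        ref = self.plane_normals[0]
        acc = np.zeros(3)
        for n in self.plane_normals:
            acc += n if np.dot(n, ref) >= 0 else -n
        return acc / np.linalg.norm(acc)

    @property
    def mean_pairwise_tilt(self) -> float:
        angles = [tilt(a, b)
                  for a, b in combinations(self.plane_normals, 2)]
        return float(np.mean(angles))

    @property
    def sort_key(self) -> tuple:
        return tuple(sorted(self.members))


def _canonical_cycle(cycle: tuple[str, str, str, str]) -> tuple[str, ...]:
    """Lexicographically smallest rotation/reflection of a 4-cycle."""
    best = None
    seq = list(cycle)
    for start in range(4):
        for step in (1, -1):
            cand = tuple(seq[(start + step * i) % 4] for i in range(4))
            if best is None or cand < best:
                best = cand
    return best


def _cycle_is_tetrad(members: tuple[str, ...], graph_nx: nx.Graph,
                     frames: dict[str, BaseFrame],
                     tilt_max: float, radius_max: float) -> bool:
    sub = graph_nx.subgraph(members)
    if sub.number_of_edges() != 4 or any(d != 2 for _, d in sub.degree()):
        return False  # chord or missing closing pair
    fs = [frames[m] for m in members]
    for fa, fb in combinations(fs, 2):
        if tilt(fa.normal, fb.normal) > tilt_max:
            return False
    centroid = np.mean([f.base_centroid for f in fs], axis=0)
    return all(np.linalg.norm(f.base_centroid - centroid) <= radius_max
               for f in fs)


def _make_tetrad(cycle: tuple[str, ...],
                 frames: dict[str, BaseFrame]) -> Tetrad:
    members = _canonical_cycle(cycle)
    fs = [frames[m] for m in members]
    return Tetrad(members=members,
                  centroid=np.mean([f.base_centroid for f in fs], axis=0),
                  plane_normals=[f.normal for f in fs],
                  frames=fs)


def find_tetrads(graph: InteractionGraph,
                 frames: dict[str, BaseFrame],
                 tilt_max: float = TETRAD_TILT_MAX,
                 radius_max: float = TETRAD_RADIUS_MAX) -> list[Tetrad]:
    """Enumerate tetrads: chordless, planar, compact 4-cycles of pairs.

    Each simple 4-cycle passing the gates is emitted once, in canonical
    member order. Cycles sharing three or more residues — and, more
    strictly, any two accepted tetrads sharing a residue — are reduced
    greedily, keeping the most planar (lowest mean pairwise tilt), so every
    residue belongs to at most one reported tetrad.
    """
    g = nx.Graph()
    g.add_nodes_from(frames)
    for p in graph.pairs:
        if p.res_a.key in frames and p.res_b.key in frames:
            g.add_edge(p.res_a.key, p.res_b.key)

    cycles: dict[tuple[str, ...], tuple[str, ...]] = {}
    nodes = sorted(g.nodes)
    for a, c in combinations(nodes, 2):
        if g.has_edge(a, c):
            continue  # a and c are the diagonal of the candidate cycle
        common = sorted(set(g.neighbors(a)) & set(g.neighbors(c)))
        for b, d in combinations(common, 2):
            members = (a, b, c, d)
            cycle = (a, b, c, d)  # pairing order a-b-c-d-a
            if _cycle_is_tetrad(cycle, g, frames, tilt_max, radius_max):
                cycles[tuple(sorted(members))] = cycle

    candidates = sorted((_make_tetrad(cy, frames) for cy in cycles.values()),
                        key=lambda t: (t.mean_pairwise_tilt, t.sort_key))
    chosen: list[Tetrad] = []
    used: set[str] = set()
    for t in candidates:
        if used.isdisjoint(t.members):
            chosen.append(t)
            used.update(t.members)
    chosen.sort(key=lambda t: t.sort_key)
    return chosen


@dataclass(eq=False)
class TetradStack:
    """Tetrads of one vertical stack, ordered from one end to the other."""

    tetrads: list[Tetrad]
    order: int | None = field(default=None)  # shared polyad order, set later

    @property
    def mean_normal(self) -> np.ndarray:
        ref = self.tetrads[0].mean_normal
        acc = np.zeros(3)
        for t in self.tetrads:
            n = t.mean_normal
            acc += n if np.dot(n, ref) >= 0 else -n
        return acc / np.linalg.norm(acc)

    def position_of(self, tetrad: Tetrad) -> int:
        return next(i for i, t in enumerate(self.tetrads) if t is tetrad)

    def is_end(self, tetrad: Tetrad) -> bool:
        return tetrad is self.tetrads[0] or tetrad is self.tetrads[-1]


def build_stacks(tetrads: list[Tetrad],
                 graph: InteractionGraph,
                 min_stack_edges: int = 2) -> list[TetradStack]:
    """Group tetrads into maximal stacks joined by stacking contacts.

    Two tetrads are consecutive layers when at least ``min_stack_edges``
    member-to-member stacking edges join them. Within a stack, tetrads are
    ordered by projecting their centroids onto the stack's mean normal.
    Isolated tetrads form singleton stacks.
    """
    meta = nx.Graph()
    meta.add_nodes_from(range(len(tetrads)))
    for i, j in combinations(range(len(tetrads)), 2):
        n_edges = sum(
            1 for a in tetrads[i].members for b in tetrads[j].members
            if frozenset((a, b)) in graph.stackings)
        if n_edges >= min_stack_edges:
            meta.add_edge(i, j)

    stacks: list[TetradStack] = []
    for comp in nx.connected_components(meta):
        group = [tetrads[i] for i in sorted(comp)]
        stack = TetradStack(tetrads=group)
        axis = stack.mean_normal
        group.sort(key=lambda t: (float(np.dot(t.centroid, axis)), t.sort_key))
        stack.tetrads = group
        stacks.append(stack)
    stacks.sort(key=lambda s: s.tetrads[0].sort_key)
    return stacks
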
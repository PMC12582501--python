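"""Candidate evaluation, scoring and refinement: the polyad detector core.

For every detected tetrad the spatial neighbourhood is searched for
nucleotides that could extend it into a pentad/hexad/heptad/octad. Each
(extension, tetrad) hypothesis is measured and filtered through four
criteria, evaluated in a fixed order chosen for cheapest elimination:

1. connectivity — the candidate must touch the tetrad through at least two
   distinct members, by base pairing or covalent strand continuity;
2. planarity — its base normal must be near-parallel to all four member
   normals (mean tilt ≤ tt_avg, each tilt ≤ tt_max);
3. proximity — its innermost atom must lie within ``dist_in_max`` of the
   tetrad centroid, and its distances to the two nearest members must not
   differ by more than ``dist_spread_max`` (approximate ring symmetry);
4. height — both probe atoms (innermost atom A_in and glycosidic nitrogen
   A_out) must sit near the tetrad plane: |ΔH| ≤ ht_max against every
   member plane and mean |ΔH| ≤ ht_avg, for each probe set separately.

Survivors are scored (the score grows with the margin left to every
threshold and with the number of base pairs formed), cross-tetrad
conflicts are resolved by score, and orders are standardized within each
stack unless lax mode is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .base_geometry import (BaseFrame, dist, height_projection,
                            innermost_base_atom, tilt)
from .interaction_graph import InteractionGraph
from .structure_io import Atom, Residue, Structure
from .tetrad_core import Tetrad, TetradStack

#: Score weights and exponents for the six margin terms
#: (mean tilt, max tilt, mean |ΔH_in|, max |ΔH_in|, mean |ΔH_out|, max |ΔH_out|).
SCORE_WEIGHTS = (1.0, 0.5, 1.0, 0.75, 1.0, 0.75)
SCORE_EXPONENTS = (2.0, 2.0, 1.75, 1.75, 1.75, 1.75)

CRITERIA = ("connectivity", "planarity", "proximity", "height")


@dataclass
class Thresholds:
    """Filtering thresholds; defaults are the tool's calibrated values."""

    tt_avg: float = 40.0          # deg, mean candidate-member tilt
    tt_max: float = 50.0          # deg, single tilt tolerance
    ht_avg: float = 3.15          # Å, mean |ΔH| over the four member planes
    ht_max: float = 3.7           # Å, single |ΔH| tolerance
    dist_in_max: float = 13.0     # Å, A_in to tetrad centroid
    dist_out_max: float = 13.0    # Å, A_out to tetrad centroid
    dist_spread_max: float = 2.0  # Å, two nearest member distances

    def __post_init__(self) -> None:
        vals = (self.tt_avg, self.tt_max, self.ht_avg, self.ht_max,
                self.dist_in_max, self.dist_out_max, self.dist_spread_max)
        if any(v <= 0 for v in vals):
            raise ValueError("all thresholds must be positive")
        if self.tt_avg > self.tt_max or self.ht_avg > self.ht_max:
            raise ValueError("average thresholds cannot exceed max thresholds")


@dataclass(eq=False)
class PolyadCandidate:
    """An (extension residue, tetrad) hypothesis with all measurements."""

    residue: Residue
    tetrad: Tetrad
    a_in: Atom
    a_out: Atom
    con_count: int
    pair_count: int
    tilts: list[float]          # vs each member, folded degrees
    member_dists: list[float]   # min base-heavy-atom distance to each member
    centroid_dist: float        # A_in to tetrad centroid, Å
    out_dist: float             # A_out to tetrad centroid, Å
    dh_in: list[float]          # signed heights of A_in vs member planes
    dh_out: list[float]
    passed: dict[str, bool] = field(default_factory=dict)
    score: float | None = None

    def __post_init__(self) -> None:
        assert self.pair_count <= self.con_count

    @property
    def all_passed(self) -> bool:
        return all(self.passed.get(c, False) for c in CRITERIA)

    @property
    def azimuth(self) -> float:
        """Angle of the candidate around the tetrad axis, degrees."""
        n = self.tetrad.mean_normal
        v = self.a_in.position - self.tetrad.centroid
        v = v - np.dot(v, n) * n
        e1 = self.tetrad.frames[0].base_centroid - self.tetrad.centroid
        e1 = e1 - np.dot(e1, n) * n
        e1 = e1 / np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        return float(np.degrees(np.arctan2(np.dot(v, e2), np.dot(v, e1))))

    @property
    def sort_key(self) -> tuple:
        return (self.residue.sort_key, self.tetrad.sort_key)


@dataclass(eq=False)
class Polyad:
    """A tetrad plus its accepted extensions."""

    tetrad: Tetrad
    extensions: list[PolyadCandidate]

    @property
    def order(self) -> int:
        return 4 + len(self.extensions)


def classify_polyad(polyad: Polyad) -> str:
    """Label by total residue count; order-4 objects stay plain tetrads."""
    order = polyad.order
    if order < 4:
        raise ValueError(f"polyad with order {order} < 4 is a contract violation")
    labels = {4: "tetrad", 5: "pentad", 6: "hexad", 7: "heptad", 8: "octad"}
    return labels.get(order, f"polyad-{order}")


def _min_base_atom_dist(res_a: Residue, res_b: Residue) -> float:
    pa = np.array([a.position for a in res_a.base_atoms()])
    pb = np.array([b.position for b in res_b.base_atoms()])
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    return float(d.min())


def _connection_counts(res: Residue, tetrad: Tetrad,
                       graph: InteractionGraph) -> tuple[int, int]:
    """(con_count, pair_count): distinct connected members / paired members.

    A member that is both paired and chain-adjacent to the candidate counts
    once (distinct-neighbour counting), preserving pair_count ≤ con_count.
    """
    paired = {m for m in tetrad.members if graph.paired(res.key, m)}
    seq = {m for m in tetrad.members if graph.sequential_with(res.key, m)}
    return len(paired | seq), len(paired)


def measure_candidate(residue: Residue, tetrad: Tetrad,
                      graph: InteractionGraph,
                      frame: BaseFrame) -> PolyadCandidate:
    """Populate every criterion measurement for one hypothesis."""
    a_in = innermost_base_atom(residue, tetrad.centroid)
    a_out = frame.glyco_atom
    con, pc = _connection_counts(residue, tetrad, graph)
    tilts = [tilt(frame.normal, n) for n in tetrad.plane_normals]
    member_dists = [_min_base_atom_dist(residue, f.residue)
                    for f in tetrad.frames]
    dh_in = [height_projection(tetrad.centroid, a_in.position, n)
             for n in tetrad.plane_normals]
    dh_out = [height_projection(tetrad.centroid, a_out.position, n)
              for n in tetrad.plane_normals]
    return PolyadCandidate(
        residue=residue, tetrad=tetrad, a_in=a_in, a_out=a_out,
        con_count=con, pair_count=pc, tilts=tilts,
        member_dists=member_dists,
        centroid_dist=dist(a_in.position, tetrad.centroid),
        out_dist=dist(a_out.position, tetrad.centroid),
        dh_in=dh_in, dh_out=dh_out)


def enumerate_candidates(tetrad: Tetrad, structure: Structure,
                         graph: InteractionGraph,
                         frames: dict[str, BaseFrame],
                         thresholds: Thresholds | None = None,
                         tetrad_members: set[str] | None = None
                         ) -> list[PolyadCandidate]:
    """All extension hypotheses for one tetrad, measurements populated.

    ``tetrad_members`` is the union of members of *all* detected tetrads;
    residues already in a tetrad never extend another one.
    """
    th = thresholds or Thresholds()
    exclude = set(tetrad.members) | (tetrad_members or set())
    out: list[PolyadCandidate] = []
    for res in structure.residues:
        if res.key in exclude or res.key not in frames:
            continue
        a_in = innermost_base_atom(res, tetrad.centroid)
        if dist(a_in.position, tetrad.centroid) > th.dist_in_max:
            continue
        a_out = frames[res.key].glyco_atom
        if dist(a_out.position, tetrad.centroid) > th.dist_out_max:
            continue
        out.append(measure_candidate(res, tetrad, graph, frames[res.key]))
    out.sort(key=lambda c: c.sort_key)
    return out


# --- the four criteria -------------------------------------------------

def criterion_connectivity(candidate: PolyadCandidate) -> bool:
    """At least two distinct tetrad members reached by pairing/continuity."""
    return candidate.con_count >= 2


def criterion_planarity(candidate: PolyadCandidate,
                        thresholds: Thresholds) -> bool:
    """Mean tilt within tt_avg and every single tilt within tt_max."""
    return (float(np.mean(candidate.tilts)) <= thresholds.tt_avg
            and max(candidate.tilts) <= thresholds.tt_max)


def criterion_proximity(candidate: PolyadCandidate,
                        thresholds: Thresholds) -> bool:
    """Near the tetrad centroid, and symmetric between its two neighbours.

    The spread is the difference between the candidate's distances to its
    two *nearest* members — the neighbours it would bond in the polyad
    ring; the far side of the tetrad is irrelevant to ring symmetry.
    """
    if candidate.centroid_dist > thresholds.dist_in_max:
        return False
    d1, d2 = sorted(candidate.member_dists)[:2]
    return (d2 - d1) <= thresholds.dist_spread_max


def criterion_height(candidate: PolyadCandidate,
                     thresholds: Thresholds) -> bool:
    """Both probe atoms near the tetrad plane, per member and on average."""
    for dhs in (candidate.dh_in, candidate.dh_out):
        mags = [abs(v) for v in dhs]
        if max(mags) > thresholds.ht_max:
            return False
        if float(np.mean(mags)) > thresholds.ht_avg:
            return False
    return True


def evaluate_candidate(candidate: PolyadCandidate, thresholds: Thresholds,
                       verbose: bool = False) -> bool:
    """Run criteria 1→4 with short-circuiting; record outcomes in-place.

    With ``verbose`` every criterion is evaluated even after a failure, so
    reports can show the full breakdown.
    """
    checks = (
        ("connectivity", lambda: criterion_connectivity(candidate)),
        ("planarity", lambda: criterion_planarity(candidate, thresholds)),
        ("proximity", lambda: criterion_proximity(candidate, thresholds)),
        ("height", lambda: criterion_height(candidate, thresholds)),
    )
    ok = True
    for name, check in checks:
        if not ok and not verbose:
            break
        result = check()
        candidate.passed[name] = result
        ok = ok and result
    return ok


def score_candidate(candidate: PolyadCandidate,
                    thresholds: Thresholds) -> float:
    """Score a fully passing candidate from its six threshold margins.

    Each margin (degrees or Å left to the corresponding gate) is scaled by
    100, raised to its exponent and weighted; the half-sum plus the number
    of base pairs formed with tetrad members is the score. Negative margins
    clamp to zero. Scores are used ordinally, to rank hypotheses.
    """
    if not candidate.all_passed:
        raise ValueError("scoring a candidate that failed the criteria")
    mean_tilt = float(np.mean(candidate.tilts))
    max_tilt = max(candidate.tilts)
    in_mags = [abs(v) for v in candidate.dh_in]
    out_mags = [abs(v) for v in candidate.dh_out]
    margins = (
        thresholds.tt_avg - mean_tilt,
        thresholds.tt_max - max_tilt,
        thresholds.ht_avg - float(np.mean(in_mags)),
        thresholds.ht_max - max(in_mags),
        thresholds.ht_avg - float(np.mean(out_mags)),
        thresholds.ht_max - max(out_mags),
    )
    total = sum(w * (max(m, 0.0) * 100.0) ** p
                for w, p, m in zip(SCORE_WEIGHTS, SCORE_EXPONENTS, margins))
    score = total / 2.0 + candidate.pair_count
    candidate.score = score
    return score


# --- refinement --------------------------------------------------------

def resolve_conflicts(candidates: list[PolyadCandidate]
                      ) -> list[PolyadCandidate]:
    """Keep each residue only for its best-scoring tetrad.

    Ties break deterministically: higher pair count, then smaller centroid
    distance, then tetrad chain/sequence order.
    """
    by_res: dict[str, list[PolyadCandidate]] = {}
    for c in candidates:
        by_res.setdefault(c.residue.key, []).append(c)
    kept = []
    for group in by_res.values():
        group.sort(key=lambda c: (-c.score, -c.pair_count,
                                  c.centroid_dist, c.tetrad.sort_key))
        kept.append(group[0])
    kept.sort(key=lambda c: c.sort_key)
    return kept


def _min_angular_separation(cands: list[PolyadCandidate]) -> float:
    if len(cands) < 2:
        return 360.0
    az = sorted(c.azimuth % 360.0 for c in cands)
    gaps = [az[i + 1] - az[i] for i in range(len(az) - 1)]
    gaps.append(360.0 - az[-1] + az[0])
    return min(gaps)


def _trim_one(cands: list[PolyadCandidate]) -> list[PolyadCandidate]:
    """Drop the lowest-scoring candidate; among score ties prefer the
    removal that best preserves angular uniformity around the tetrad."""
    low = min(c.score for c in cands)
    tied = [c for c in cands if c.score == low]
    if len(tied) == 1:
        victim = tied[0]
    else:
        def remaining_sep(victim: PolyadCandidate) -> tuple:
            rest = [c for c in cands if c is not victim]
            return (_min_angular_separation(rest), victim.sort_key)
        victim = max(tied, key=remaining_sep)
    return [c for c in cands if c is not victim]


def standardize_order(stack: TetradStack,
                      extensions: dict[tuple[str, ...], list[PolyadCandidate]],
                      lax: bool = False
                      ) -> dict[tuple[str, ...], list[PolyadCandidate]]:
    """Equalize polyad orders within a stack (unless lax).

    In strict mode every extended tetrad of the stack is trimmed to the
    minimum extension count found among the stack's extended tetrads,
    dropping lowest scores first. Plain tetrads (no extensions) stay plain
    and do not force the minimum to zero. Lax mode keeps all survivors.
    """
    if lax:
        return {k: sorted(v, key=lambda c: c.sort_key)
                for k, v in extensions.items()}
    counts = [len(v) for v in extensions.values() if v]
    target = min(counts) if counts else 0
    out: dict[tuple[str, ...], list[PolyadCandidate]] = {}
    for key, cands in extensions.items():
        cands = list(cands)
        while len(cands) > target and cands:
            cands = _trim_one(cands)
        out[key] = sorted(cands, key=lambda c: c.sort_key)
    return out


def detect_polyads(structure: Structure, graph: InteractionGraph,
                   frames: dict[str, BaseFrame],
                   tetrads: list[Tetrad], stacks: list[TetradStack],
                   thresholds: Thresholds | None = None,
                   lax: bool = False, verbose: bool = False
                   ) -> tuple[list[Polyad], list[PolyadCandidate]]:
    """Full candidate pipeline over all tetrads of a structure.

    Returns the classified polyads (order ≥ 5) and the list of all
    evaluated candidates (for verbose reporting).
    """
    th = thresholds or Thresholds()
    all_members = {m for t in tetrads for m in t.members}
    evaluated: list[PolyadCandidate] = []
    passing: list[PolyadCandidate] = []
    for tetrad in tetrads:
        for cand in enumerate_candidates(tetrad, structure, graph, frames,
                                         th, all_members):
            if evaluate_candidate(cand, th, verbose=verbose):
                score_candidate(cand, th)
                passing.append(cand)
            evaluated.append(cand)

    resolved = resolve_conflicts(passing)
    by_tetrad: dict[tuple[str, ...], list[PolyadCandidate]] = {
        t.key: [] for t in tetrads}
    for c in resolved:
        by_tetrad[c.tetrad.key].append(c)

    polyads: list[Polyad] = []
    for stack in stacks:
        stack_ext = {t.key: by_tetrad[t.key] for t in stack.tetrads}
        stack_ext = standardize_order(stack, stack_ext, lax=lax)
        orders = {4 + len(v) for v in stack_ext.values() if v}
        stack.order = max(orders) if orders else 4
        for t in stack.tetrads:
            exts = stack_ext[t.key]
            if exts:
                polyads.append(Polyad(tetrad=t, extensions=exts))
    polyads.sort(key=lambda p: p.tetrad.sort_key)
    return polyads, evaluated
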
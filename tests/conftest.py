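"""Shared fixtures and independent oracles for the test suite.

Oracles here deliberately take different computational routes from the
package (SVD plane fit, exhaustive contact enumeration, brute-force
4-subset scan) so they can arbitrate correctness.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

import polyads as pl
from polyads.base_geometry import base_frame, tilt
from polyads.interaction_graph import PairingConfig, build_connectivity, detect_base_pairs
from polyads.report import RunConfig, analyze_structure
from polyads.structure_io import Atom, Residue, Structure, read_structure


@pytest.fixture()
def tmp_pdb(tmp_path):
    """Write fixture PDB text to disk and parse it back."""
    def _build(spec: pl.FixtureSpec):
        pdb, truth = pl.make_polyad_fixture(spec)
        p = tmp_path / "fixture.pdb"
        p.write_text(pdb)
        return read_structure(p), truth, p
    return _build


@pytest.fixture()
def hexad_structure(tmp_pdb):
    return tmp_pdb(pl.spec_for_order(6, n_layers=1))


def frames_of(structure: Structure) -> dict:
    frames = {}
    for r in structure.residues:
        f = base_frame(r)
        if f is not None:
            frames[r.key] = f
    return frames


def graph_of(structure: Structure):
    frames = frames_of(structure)
    cfg = PairingConfig()
    pairs = detect_base_pairs(structure, frames, cfg)
    return build_connectivity(structure, pairs, frames, cfg), frames


def run_on(structure: Structure, **cfg_kwargs):
    return analyze_structure(structure, RunConfig(input_path="<memory>",
                                                  **cfg_kwargs))


def transform_structure(structure: Structure, rot: np.ndarray,
                        trans: np.ndarray, chain_map=None) -> Structure:
    """Apply one rigid motion (and optional chain relabeling) to a copy."""
    residues = []
    for r in structure.residues:
        atoms = [Atom(a.name, a.element, rot @ a.position + trans)
                 for a in r.atoms]
        residues.append(Residue(
            chain_id=(chain_map or {}).get(r.chain_id, r.chain_id),
            seq_num=r.seq_num, icode=r.icode, res_name=r.res_name,
            atoms=atoms, parent_base=r.parent_base))
    return Structure(pdb_id=structure.pdb_id, model_num=structure.model_num,
                     residues=residues)


def random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


# --- independent oracles ------------------------------------------------

def svd_plane_normal(coords: np.ndarray) -> np.ndarray:
    """Plane normal via full SVD of the centered coordinates."""
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[-1]


def brute_force_contacts(res_a: Residue, res_b: Residue,
                         cutoff: float = 3.5) -> int:
    """Count polar base-atom contacts by direct double enumeration."""
    n = 0
    for aa in res_a.base_atoms():
        if aa.element not in ("N", "O"):
            continue
        for ab in res_b.base_atoms():
            if ab.element not in ("N", "O"):
                continue
            if float(np.linalg.norm(aa.position - ab.position)) <= cutoff:
                n += 1
    return n


def brute_force_tetrads(graph, frames, tilt_max=50.0, radius_max=9.0):
    """Exhaustive 4-subset scan: cycle test + planarity + compactness.

    Applies the same greedy one-tetrad-per-residue reduction contract as
    the implementation, but discovers candidate cycles by scanning every
    4-subset rather than walking the graph.
    """
    pair_set = {frozenset((p.res_a.key, p.res_b.key)) for p in graph.pairs}
    keys = sorted(frames)
    accepted = []
    for subset in combinations(keys, 4):
        edges = [frozenset((a, b)) for a, b in combinations(subset, 2)
                 if frozenset((a, b)) in pair_set]
        if len(edges) != 4:
            continue
        degree = {k: sum(1 for e in edges if k in e) for k in subset}
        if any(d != 2 for d in degree.values()):
            continue
        fs = [frames[k] for k in subset]
        if any(tilt(a.normal, b.normal) > tilt_max
               for a, b in combinations(fs, 2)):
            continue
        centroid = np.mean([f.base_centroid for f in fs], axis=0)
        if any(np.linalg.norm(f.base_centroid - centroid) > radius_max
               for f in fs):
            continue
        mean_tilt = float(np.mean([tilt(a.normal, b.normal)
                                   for a, b in combinations(fs, 2)]))
        accepted.append((mean_tilt, tuple(sorted(subset))))
    accepted.sort()
    chosen, used = [], set()
    for _, subset in accepted:
        if used.isdisjoint(subset):
            chosen.append(subset)
            used.update(subset)
    return sorted(chosen)


def random_fixture_spec(rng) -> pl.FixtureSpec:
    """A random small fixture (≤ 24 residues) for oracle comparisons."""
    order = int(rng.integers(4, 9))
    layers = int(rng.integers(1, 4))
    noise = float(rng.choice([0.0, 0.05, 0.1, 0.2]))
    return pl.spec_for_order(order, n_layers=layers, noise_sd=noise,
                             seed=int(rng.integers(0, 2**31 - 1)))
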
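"""Ground-truth synthetic structures: idealized tetrads, stacks and polyads.

Everything the test suite and the acceptance checks consume is generated
here from standard planar base geometries (literature ideal bond lengths
and angles, heavy atoms only — crystal structures rarely resolve
hydrogens, and the pair detector proxies H-bonds by donor–acceptor
distance anyway).

Construction is analytic plus two small cached least-squares solves:

* the G-tetrad pose: one guanine is placed so that its C4-symmetric copies
  form the cyclic Hoogsteen network with N1–O6 and N2–N7 neighbour
  distances of 2.85 Å, O6 atoms ringing the central channel;
* the extension pose per base type: the extension's Watson–Crick edge is
  H-bonded (two ≈3 Å contacts) to the sugar edge of one tetrad member,
  balanced toward the middle of the gap between that member and the next.

Each extension additionally gets a covalent O3'–P link to the next member
around the ring, so its connectivity count is 2 (one base pair + one
sequential link) — the same route by which experimentally validated hexad
adenines satisfy the connectivity criterion. A rigid planar base cannot
H-bond two tetrad members at once: the inter-member gap is wider than any
base edge.

Planted tilt is applied as a hinge rotation about the axis through the two
H-bonded edge atoms, so pairing survives and the base normal tilts by
exactly the requested angle. Planted height is a vertical translation;
heights beyond ≈1.8 Å necessarily stretch the H-bonds past detection —
that is physics, not a generator limitation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from .structure_io import Atom, Residue, Structure

# --- standard planar base templates (heavy atoms + C1'), xy-plane, Å ----

GUANINE = {
    "C1'": (-2.477, 5.399, 0.0),
    "N9": (-1.289, 4.551, 0.0), "C8": (0.023, 4.962, 0.0),
    "N7": (0.870, 3.969, 0.0), "C5": (0.071, 2.833, 0.0),
    "C6": (0.424, 1.460, 0.0), "O6": (1.554, 0.955, 0.0),
    "N1": (-0.700, 0.641, 0.0), "C2": (-1.999, 1.087, 0.0),
    "N2": (-2.949, 0.139, 0.0), "N3": (-2.342, 2.364, 0.0),
    "C4": (-1.265, 3.177, 0.0),
}
ADENINE = {
    "C1'": (-2.479, 5.346, 0.0),
    "N9": (-1.291, 4.498, 0.0), "C8": (0.024, 4.897, 0.0),
    "N7": (0.877, 3.902, 0.0), "C5": (0.071, 2.771, 0.0),
    "C6": (0.369, 1.398, 0.0), "N6": (1.611, 0.909, 0.0),
    "N1": (-0.668, 0.532, 0.0), "C2": (-1.912, 1.023, 0.0),
    "N3": (-2.320, 2.290, 0.0), "C4": (-1.267, 3.124, 0.0),
}
URACIL = {
    "C1'": (-2.481, 5.354, 0.0),
    "N1": (-1.284, 4.500, 0.0), "C2": (-1.462, 3.131, 0.0),
    "O2": (-2.563, 2.608, 0.0), "N3": (-0.302, 2.397, 0.0),
    "C4": (0.989, 2.884, 0.0), "O4": (1.935, 2.094, 0.0),
    "C5": (1.089, 4.311, 0.0), "C6": (-0.024, 5.053, 0.0),
}
THYMINE = dict(URACIL, C7=(2.466, 4.961, 0.0))
CYTOSINE = {
    "C1'": (-2.477, 5.402, 0.0),
    "N1": (-1.285, 4.542, 0.0), "C2": (-1.472, 3.158, 0.0),
    "O2": (-2.628, 2.709, 0.0), "N3": (-0.391, 2.344, 0.0),
    "C4": (0.837, 2.868, 0.0), "N4": (1.875, 2.027, 0.0),
    "C5": (1.056, 4.275, 0.0), "C6": (-0.023, 5.068, 0.0),
}

TEMPLATES = {"G": GUANINE, "A": ADENINE, "U": URACIL,
             "T": THYMINE, "C": CYTOSINE}
#: extension edge atoms H-bonded to the tetrad member's sugar edge (N3, N2)
EXTENSION_PROBES = {"A": ("N6", "N1"), "U": ("O4", "N3"),
                    "T": ("O4", "N3"), "C": ("N4", "N3")}

PURINE_RING = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")


def _rz(deg: float) -> np.ndarray:
    t = math.radians(deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _place(template: dict, rot: np.ndarray, trans: np.ndarray) -> dict:
    return {k: rot @ np.asarray(v) + trans for k, v in template.items()}


def _atoms_array(atoms: dict) -> np.ndarray:
    return np.array(list(atoms.values()))


def _ring_centroid(atoms: dict, base: str) -> np.ndarray:
    ring = PURINE_RING if base in ("A", "G") else PYRIMIDINE_RING
    return np.mean([atoms[n] for n in ring], axis=0)


# --- cached ideal poses -------------------------------------------------

@lru_cache(maxsize=1)
def _tetrad_pose() -> tuple[float, float, float]:
    """In-plane pose (rotation deg, tx, ty) of guanine 0 of the tetrad.

    Guanine k is the Rz(90k°) copy; the solve enforces the neighbour
    Hoogsteen-network distances N1(k)–O6(k+1) = N2(k)–N7(k+1) = 2.85 Å.
    """
    def resid(p):
        g0 = _place(GUANINE, _rz(p[0]), np.array([p[1], p[2], 0.0]))
        g1 = {k: _rz(90.0) @ v for k, v in g0.items()}
        return [np.linalg.norm(g0["N1"] - g1["O6"]) - 2.85,
                np.linalg.norm(g0["N2"] - g1["N7"]) - 2.85]

    best = None
    for a0 in range(0, 360, 30):
        sol = least_squares(resid, [float(a0), 5.0, 0.0])
        g0 = _place(GUANINE, _rz(sol.x[0]), np.array([sol.x[1], sol.x[2], 0.0]))
        if np.linalg.norm(g0["O6"]) > np.linalg.norm(g0["N9"]):
            continue  # O6 atoms must face the central channel
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None and best.cost < 1e-10
    return tuple(float(v) for v in best.x)


def _tetrad_member_atoms(k: int) -> dict:
    a, tx, ty = _tetrad_pose()
    g0 = _place(GUANINE, _rz(a), np.array([tx, ty, 0.0]))
    return {name: _rz(90.0 * k) @ v for name, v in g0.items()}


@lru_cache(maxsize=8)
def _extension_pose(base: str) -> dict:
    """In-plane pose of an extension base in gap 0 (between members 0, 1).

    Two edge atoms are H-bonded to member 0's sugar edge (N3, N2) at
    ≈2.95 Å while a balance term pulls the base toward the middle of the
    gap; a hinge-floor keeps every interatomic distance above ≈2.6 Å.
    Rotating by Rz(90k°) yields the pose for gap k.
    """
    tmpl = TEMPLATES[base]
    p1, p2 = EXTENSION_PROBES[base]
    g0 = _tetrad_member_atoms(0)
    g_all = np.array([v for k in range(4)
                      for v in _tetrad_member_atoms(k).values()])
    c0 = _ring_centroid(_tetrad_member_atoms(0), "G")
    c1 = _ring_centroid(_tetrad_member_atoms(1), "G")

    def resid(p):
        atoms = _place(tmpl, _rz(p[0]), np.array([p[1], p[2], 0.0]))
        mid = 0.5 * (atoms[p1] + atoms[p2])
        res = [np.linalg.norm(atoms[p1] - g0["N3"]) - 2.95,
               np.linalg.norm(atoms[p2] - g0["N2"]) - 2.95,
               np.linalg.norm(mid - c0) - np.linalg.norm(mid - c1)]
        d = np.linalg.norm(
            _atoms_array(atoms)[:, None, :] - g_all[None, :, :], axis=-1)
        return np.concatenate([res, (3.0 * np.maximum(0.0, 2.6 - d)).ravel()])

    gap_az = math.radians(-156.5)
    best = None
    for b0 in range(0, 360, 30):
        for r0 in (7.5, 9.0):
            sol = least_squares(
                resid, [float(b0), r0 * math.cos(gap_az), r0 * math.sin(gap_az)])
            atoms = _place(tmpl, _rz(sol.x[0]),
                           np.array([sol.x[1], sol.x[2], 0.0]))
            mind = float(np.min(np.linalg.norm(
                _atoms_array(atoms)[:, None, :] - g_all[None, :, :], axis=-1)))
            b1 = np.linalg.norm(atoms[p1] - g0["N3"])
            b2 = np.linalg.norm(atoms[p2] - g0["N2"])
            if mind < 2.5 or b1 > 3.4 or b2 > 3.4:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise RuntimeError(f"no feasible extension pose for base {base}")
    a, tx, ty = (float(v) for v in best.x)
    return _place(tmpl, _rz(a), np.array([tx, ty, 0.0]))


def _rotation_about_axis(axis: np.ndarray, deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    t = math.radians(deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(t) * k + (1 - math.cos(t)) * (k @ k)


def _align_z_to(normal: np.ndarray) -> np.ndarray:
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, n)
    s = np.linalg.norm(v)
    if s < 1e-12:
        return np.eye(3) if np.dot(z, n) > 0 else np.diag([1.0, -1.0, -1.0])
    return _rotation_about_axis(v, math.degrees(math.atan2(s, float(np.dot(z, n)))))


# --- fixture specification ---------------------------------------------

@dataclass
class ExtensionSpec:
    """One planted extension: which layer/gap, base type, and geometry."""

    layer: int = 0
    base: str = "A"                 # A / U / T / C
    gap: int = 0                    # between tetrad members gap and gap+1
    tilt: float = 10.0              # deg, hinge rotation about the bonded edge
    height: float = 0.5             # Å, vertical offset off the tetrad plane
    radial_offset: float = 0.0      # Å, shift away from the tetrad axis
    azimuth_offset: float = 0.0     # deg, rotation about the tetrad axis


@dataclass
class FixtureSpec:
    """A parametric quadruplex-core fixture with planted extensions."""

    n_layers: int = 1
    layer_rise: float = 3.4         # Å
    layer_twist: float = 30.0       # deg
    extensions: list[ExtensionSpec] = field(default_factory=list)
    noise_sd: float = 0.0           # Å, isotropic Gaussian per coordinate
    seed: int = 0
    include_ions: bool = True       # K+ in the channel between layers

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("need at least one layer")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class FixtureTruth:
    """What the generator planted, in pipeline-report vocabulary."""

    tetrads: list[list[str]]                 # member keys per layer, sorted
    polyads: list[dict]                      # {"order", "tetrad", "extensions"}

    def to_json(self) -> str:
        return json.dumps({"tetrads": self.tetrads, "polyads": self.polyads},
                          indent=1, sort_keys=True)


def spec_for_order(order: int, n_layers: int = 1, noise_sd: float = 0.0,
                   seed: int = 0, bases: str = "A") -> FixtureSpec:
    """Convenience: same polyad order planted on every layer.

    Gaps are filled in the spread-out preference order 0, 2, 1, 3 so that
    pentads/hexads stay as symmetric as the order permits.
    """
    if not 4 <= order <= 8:
        raise ValueError("supported polyad orders are 4 (plain tetrad) to 8")
    gaps = [0, 2, 1, 3][:order - 4]
    exts = [ExtensionSpec(layer=lay, base=bases[i % len(bases)], gap=g)
            for lay in range(n_layers) for i, g in enumerate(gaps)]
    return FixtureSpec(n_layers=n_layers, extensions=exts,
                       noise_sd=noise_sd, seed=seed)


# --- builders -----------------------------------------------------------

def make_tetrad_layer(center=(0.0, 0.0, 0.0), normal=(0.0, 0.0, 1.0),
                      twist: float = 0.0, chain_id: str = "A",
                      start_seq: int = 1) -> list[Residue]:
    """Four idealized guanines in cyclic Hoogsteen order as one tetrad."""
    rot = _align_z_to(np.asarray(normal, dtype=float)) @ _rz(twist)
    center = np.asarray(center, dtype=float)
    residues = []
    for k in range(4):
        atoms = {n: rot @ v + center
                 for n, v in _tetrad_member_atoms(k).items()}
        residues.append(_residue_from_atoms(
            "G", chain_id, start_seq + k, atoms))
    return residues


def _residue_from_atoms(base: str, chain_id: str, seq: int,
                        atoms: dict) -> Residue:
    return Residue(
        chain_id=chain_id, seq_num=seq, icode="", res_name=base,
        atoms=[Atom(n, ("P" if n == "P" else n[0]), np.asarray(p))
               for n, p in atoms.items()],
        parent_base=base)


class FixtureGeometryError(ValueError):
    """Planted geometry is self-clashing or otherwise infeasible."""


def _build_extension_atoms(ext: ExtensionSpec) -> dict:
    """Pose one extension in layer-local coordinates (tetrad at origin)."""
    atoms = dict(_extension_pose(ext.base))
    p1, p2 = EXTENSION_PROBES[ext.base]
    if ext.tilt:
        axis = atoms[p2] - atoms[p1]
        rot = _rotation_about_axis(axis, ext.tilt)
        pivot = atoms[p1]
        atoms = {n: rot @ (v - pivot) + pivot for n, v in atoms.items()}
    if ext.radial_offset:
        cen = _ring_centroid(atoms, ext.base)
        radial = np.array([cen[0], cen[1], 0.0])
        radial /= np.linalg.norm(radial)
        atoms = {n: v + ext.radial_offset * radial for n, v in atoms.items()}
    if ext.azimuth_offset:
        rot = _rz(ext.azimuth_offset)
        atoms = {n: rot @ v for n, v in atoms.items()}
    if ext.height:
        dz = np.array([0.0, 0.0, ext.height])
        atoms = {n: v + dz for n, v in atoms.items()}
    rot = _rz(90.0 * ext.gap)
    return {n: rot @ v for n, v in atoms.items()}


def make_polyad_fixture(spec: FixtureSpec) -> tuple[str, FixtureTruth]:
    """Emit PDB text and ground-truth labels for a parametric fixture.

    Layer L lives on chain "ABC..."[L]; within a chain, residues run around
    the ring so that every extension immediately precedes the member it is
    covalently linked to (gap-k extensions pair member k and link to member
    k+1), giving each planted extension one base pair plus one sequential
    connection.
    """
    rng = np.random.default_rng(spec.seed)
    chain_ids = "ABCDEFGH"
    if spec.n_layers > len(chain_ids):
        raise ValueError("too many layers")

    all_residues: list[Residue] = []
    truth_tetrads: list[list[str]] = []
    truth_polyads: list[dict] = []

    for layer in range(spec.n_layers):
        chain = chain_ids[layer]
        layer_rot = _rz(spec.layer_twist * layer)
        layer_dz = np.array([0.0, 0.0, spec.layer_rise * layer])

        members = {k: _tetrad_member_atoms(k) for k in range(4)}
        layer_exts = [e for e in spec.extensions if e.layer == layer]
        ext_by_gap: dict[int, ExtensionSpec] = {}
        for e in layer_exts:
            if e.gap in ext_by_gap:
                raise ValueError(f"two extensions in layer {layer} gap {e.gap}")
            ext_by_gap[e.gap] = e

        # ring order: [gap-3 ext] m0 [gap-0 ext] m1 [gap-1 ext] m2 [gap-2 ext] m3
        entries: list[tuple[str, str, dict]] = []  # (kind, base, atoms)
        if 3 in ext_by_gap:
            entries.append(("e3", ext_by_gap[3].base,
                            _build_extension_atoms(ext_by_gap[3])))
        for k in range(4):
            entries.append((f"m{k}", "G", members[k]))
            if k in ext_by_gap and k != 3:
                entries.append((f"e{k}", ext_by_gap[k].base,
                                _build_extension_atoms(ext_by_gap[k])))

        # covalent O3'–P links: extension at position i links to entry i+1
        for i, (kind, _, atoms) in enumerate(entries):
            if not kind.startswith("e"):
                continue
            nxt = entries[i + 1][2]  # extensions never sit last in ring order
            a = atoms["C1'"]
            b = nxt["C1'"]
            u = (b - a) / np.linalg.norm(b - a)
            mid = 0.5 * (a + b)
            atoms["O3'"] = mid - 0.8 * u
            nxt["P"] = mid + 0.8 * u

        placed: list[Residue] = []
        for seq, (kind, base, atoms) in enumerate(entries, start=1):
            world = {n: layer_rot @ v + layer_dz for n, v in atoms.items()}
            placed.append(_residue_from_atoms(base, chain, seq, world))

        member_keys = sorted(r.key for r in placed if r.res_name == "G")
        ext_keys = sorted(r.key for r in placed if r.res_name != "G")
        truth_tetrads.append(member_keys)
        if ext_keys:
            truth_polyads.append({"order": 4 + len(ext_keys),
                                  "tetrad": member_keys,
                                  "extensions": ext_keys})
        all_residues.extend(placed)

    _check_clashes(all_residues)

    ions: list[Residue] = []
    if spec.include_ions and spec.n_layers >= 2:
        for layer in range(spec.n_layers - 1):
            z = spec.layer_rise * (layer + 0.5)
            ions.append(_residue_from_atoms(
                "K", "Z", layer + 1, {"K": np.array([0.0, 0.0, z])}))
            ions[-1].parent_base = None
            ions[-1].res_name = "K"

    if spec.noise_sd > 0:
        for res in all_residues:
            res.atoms = [
                Atom(a.name, a.element,
                     a.position + rng.normal(0.0, spec.noise_sd, 3))
                for a in res.atoms]

    structure = Structure(pdb_id="FIXT", model_num=1,
                          residues=all_residues, ions=ions)
    from .structure_io import write_pdb
    return write_pdb(structure), FixtureTruth(tetrads=truth_tetrads,
                                              polyads=truth_polyads)


def _check_clashes(residues: list[Residue], min_dist: float = 2.0) -> None:
    linked = {"O3'", "P"}
    for i, ra in enumerate(residues):
        for rb in residues[i + 1:]:
            if ra.chain_id != rb.chain_id:
                continue
            for aa in ra.atoms:
                for ab in rb.atoms:
                    if aa.name in linked and ab.name in linked:
                        continue
                    if np.linalg.norm(aa.position - ab.position) < min_dist:
                        raise FixtureGeometryError(
                            f"{ra.key}:{aa.name} clashes with {rb.key}:{ab.name}"
                            " — increase the radial distance of the extension")


# --- small auxiliary fixtures -------------------------------------------

def make_strand(n_residues: int = 2, chain_id: str = "A",
                base: str = "G", connected: bool = True) -> Structure:
    """A short helical single strand, covalently continuous unless not.

    Used for sequential-connectivity behaviour: with ``connected`` the
    O3'(i)–P(i+1) linkage is present; without it the phosphates are
    omitted, which must read as a chain break.
    """
    residues = []
    atoms_list = []
    for i in range(n_residues):
        rot = _rz(36.0 * i)
        dz = np.array([6.0, 0.0, 3.4 * i])
        atoms_list.append({n: rot @ np.asarray(v) + dz
                           for n, v in TEMPLATES[base].items()})
    if connected:
        for i in range(n_residues - 1):
            a = atoms_list[i]["C1'"]
            b = atoms_list[i + 1]["C1'"]
            u = (b - a) / np.linalg.norm(b - a)
            mid = 0.5 * (a + b)
            atoms_list[i]["O3'"] = mid - 0.8 * u
            atoms_list[i + 1]["P"] = mid + 0.8 * u
    for i, atoms in enumerate(atoms_list):
        residues.append(_residue_from_atoms(base, chain_id, i + 1, atoms))
    return Structure(pdb_id="STRND", model_num=1, residues=residues)


@lru_cache(maxsize=1)
def _wc_gc_pose() -> dict:
    """Cytosine posed Watson–Crick against the guanine template."""
    g = {k: np.asarray(v) for k, v in GUANINE.items()}
    g_arr = np.array(list(g.values()))

    def resid(p):
        c = _place(CYTOSINE, _rz(p[0]), np.array([p[1], p[2], 0.0]))
        res = [np.linalg.norm(g["O6"] - c["N4"]) - 2.9,
               np.linalg.norm(g["N1"] - c["N3"]) - 2.9,
               np.linalg.norm(g["N2"] - c["O2"]) - 2.9]
        d = np.linalg.norm(
            _atoms_array(c)[:, None, :] - g_arr[None, :, :], axis=-1)
        return np.concatenate([res, (3.0 * np.maximum(0.0, 2.6 - d)).ravel()])

    best = None
    for b0 in range(0, 360, 30):
        sol = least_squares(resid, [float(b0), 9.0, 0.0])
        if best is None or sol.cost < best.cost:
            best = sol
    return _place(CYTOSINE, _rz(best.x[0]), np.array([best.x[1], best.x[2], 0.0]))


def make_duplex(n_pairs: int = 2) -> Structure:
    """A short canonical G:C double helix — contains pairs but no tetrad."""
    residues = []
    cyt = _wc_gc_pose()
    for i in range(n_pairs):
        rot = _rz(36.0 * i)
        dz = np.array([0.0, 0.0, 3.4 * i])
        g_atoms = {n: rot @ np.asarray(v) + dz for n, v in GUANINE.items()}
        c_atoms = {n: rot @ v + dz for n, v in cyt.items()}
        residues.append(_residue_from_atoms("G", "A", i + 1, g_atoms))
        residues.append(_residue_from_atoms("C", "B", n_pairs - i, c_atoms))
    return Structure(pdb_id="DPLX", model_num=1, residues=residues)
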
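"""Per-base reference frames and the elementary geometric measurements.

Every analyzable nucleotide gets a :class:`BaseFrame`: the unit normal of
the least-squares plane through its ring atoms, the ring centroid, and the
glycosidic nitrogen (N9 for purines, N1 for pyrimidines). Three scalar
measurements build on these frames:

* ``tilt`` — angle between two base normals, folded into [0°, 90°] so that
  a flipped (anti-parallel) frame of a coplanar base reads as coplanar;
* ``dist`` — plain Euclidean distance;
* ``height_projection`` — signed height of a point over a base plane,
  the dot product (C − A)·n with n the base normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import PURINE_RING, PYRIMIDINE_RING, Atom, Residue


@dataclass
class BaseFrame:
    """Reference frame of one base: plane normal, centroid, glycosidic atom."""

    residue_key: str
    normal: np.ndarray          # unit vector
    base_centroid: np.ndarray   # mean of ring-atom coordinates, Å
    glyco_atom: Atom            # N9 (purine) / N1 (pyrimidine) = A_out
    residue: Residue

    def __post_init__(self) -> None:
        assert abs(np.linalg.norm(self.normal) - 1.0) < 1e-9


def ring_atom_names(residue: Residue) -> tuple[str, ...]:
    return PURINE_RING if residue.is_purine else PYRIMIDINE_RING


def base_frame(residue: Residue) -> BaseFrame | None:
    """Fit the base plane and return the residue's frame.

    Returns None when ring atoms are missing (the residue is then flagged
    non-analyzable upstream rather than raising).

    The normal is the eigenvector of smallest variance of the ring-atom
    covariance; its sign is fixed so it has positive dot product with
    (C1'→glyco) × (glyco→ring centroid). Any fixed convention works because
    tilt folds anti-parallel normals.
    """
    names = ring_atom_names(residue)
    coords = []
    for n in names:
        a = residue.atom(n)
        if a is None:
            return None
        coords.append(a.position)
    coords = np.asarray(coords)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    normal = eigvecs[:, 0]  # smallest variance direction

    glyco_name = "N9" if residue.is_purine else "N1"
    glyco = residue.atom(glyco_name)
    if glyco is None:
        return None
    c1p = residue.atom("C1'")
    if c1p is not None:
        ref = np.cross(glyco.position - c1p.position,
                       centroid - glyco.position)
    else:
        ref = np.cross(coords[1] - coords[0], coords[2] - coords[0])
    if np.dot(normal, ref) < 0:
        normal = -normal
    normal = normal / np.linalg.norm(normal)
    return BaseFrame(residue_key=residue.key, normal=normal,
                     base_centroid=centroid, glyco_atom=glyco,
                     residue=residue)


def tilt(normal_a: np.ndarray, normal_b: np.ndarray) -> float:
    """Angle between base normals in degrees, folded into [0°, 90°].

    Folding (|a·b| before the arccos) makes anti-parallel normals, which
    occur between syn and anti bases of one planar multiplet, read as
    parallel: planarity is orientation-free.
    """
    d = float(np.clip(abs(np.dot(normal_a, normal_b)), -1.0, 1.0))
    return float(np.degrees(np.arccos(d)))


def dist(point_a: np.ndarray, point_b: np.ndarray) -> float:
    """Euclidean distance in Å."""
    return float(np.linalg.norm(np.asarray(point_a) - np.asarray(point_b)))


def height_projection(centroid: np.ndarray, atom_pos: np.ndarray,
                      normal: np.ndarray) -> float:
    """Signed height (C − A)·n of atom A over the plane with normal n.

    Criteria consume the absolute value; the sign is kept for reporting.
    """
    return float(np.dot(np.asarray(centroid) - np.asarray(atom_pos),
                        np.asarray(normal)))


def innermost_base_atom(residue: Residue, point: np.ndarray) -> Atom:
    """The base heavy atom of ``residue`` closest to ``point`` (= A_in).

    Restricted to base atoms (no sugar or phosphate) so the measure does
    not depend on backbone conformation.
    """
    atoms = residue.base_atoms()
    if not atoms:
        raise ValueError(f"residue {residue.key} has no base atoms")
    return min(atoms, key=lambda a: float(np.linalg.norm(a.position - point)))
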
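"""Reading nucleic-acid coordinate files into a uniform residue/atom model.

PDB and mmCIF files (optionally gzip-compressed, detected by magic bytes)
are parsed with gemmi and reduced to the minimal hierarchy the detection
pipeline needs: ordered nucleotide residues with heavy-atom coordinates.
Waters, ligands and amino acids are dropped; monoatomic ions are kept in a
side channel for reporting.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: Base ring atom names. Purines carry both rings (9 atoms), pyrimidines one.
PURINE_RING = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")

#: Atoms that belong to the sugar/phosphate moiety rather than the base.
_BACKBONE = {"P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P"}

_STANDARD_PARENT = {
    "A": "A", "DA": "A", "ADE": "A", "RA": "A",
    "G": "G", "DG": "G", "GUA": "G", "RG": "G",
    "C": "C", "DC": "C", "CYT": "C", "RC": "C",
    "U": "U", "URA": "U", "RU": "U", "URI": "U",
    "T": "T", "DT": "T", "THY": "T",
}

_ION_NAMES = {"K", "NA", "MG", "CA", "ZN", "MN", "SR", "BA", "TL", "CS",
              "LI", "RB", "NH4", "CL", "BR", "I", "PB", "CD", "CO", "NI"}

_WATER_NAMES = {"HOH", "H2O", "WAT", "DOD"}


@dataclass(frozen=True, eq=False)
class Atom:
    """A heavy atom with a label, element symbol and position in Å."""

    name: str
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not np.all(np.isfinite(self.position)) or self.position.shape != (3,):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")


@dataclass(eq=False)
class Residue:
    """One nucleotide, identified by (chain, author seq number, icode)."""

    chain_id: str
    seq_num: int
    icode: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    #: parent base A/C/G/U/T for modified nucleotides, or None if unmappable
    parent_base: str | None = None

    @property
    def key(self) -> str:
        """Residue selector ``chain/number[icode]`` in author numbering."""
        return f"{self.chain_id}/{self.seq_num}{self.icode}"

    @property
    def sort_key(self) -> tuple:
        return (self.chain_id, self.seq_num, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_purine(self) -> bool:
        return self.parent_base in ("A", "G")

    def base_atoms(self) -> list[Atom]:
        """Heavy atoms of the base moiety (no sugar, no phosphate)."""
        return [a for a in self.atoms
                if "'" not in a.name and a.name not in _BACKBONE]

    def has_ring(self) -> bool:
        names = {a.name for a in self.atoms}
        ring = PURINE_RING if self.is_purine else PYRIMIDINE_RING
        return set(ring) <= names


@dataclass
class Structure:
    """A single model of a parsed structure: ordered nucleotide residues."""

    pdb_id: str
    model_num: int
    residues: list[Residue] = field(default_factory=list)
    ions: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.residues.sort(key=lambda r: r.sort_key)
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            dup = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate residue identifiers: {dup}")

    def __len__(self) -> int:
        return len(self.residues)

    def by_key(self, key: str) -> Residue:
        for r in self.residues:
            if r.key == key:
                return r
        raise KeyError(f"residue {key!r} not found in structure")

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)


class ParseError(ValueError):
    """Raised when an input file cannot be parsed as PDB or mmCIF."""


def _classify_parent(res_name: str, atom_names: set[str]) -> str | None:
    """Map a residue to its parent base, via name or ring-atom superset."""
    parent = _STANDARD_PARENT.get(res_name.strip().upper())
    if parent is not None:
        return parent
    if set(PURINE_RING) <= atom_names:
        return "G" if "O6" in atom_names else "A"
    if set(PYRIMIDINE_RING) <= atom_names:
        if "N4" in atom_names:
            return "C"
        if "C7" in atom_names or "C5M" in atom_names:
            return "T"
        if "O2" in atom_names and "O4" in atom_names:
            return "U"
    return None


def _read_bytes(path: str | Path) -> bytes:
    raw = Path(path).read_bytes()
    if raw[:2] == b"\x1f\x8b":  # gzip magic, regardless of file extension
        raw = gzip.decompress(raw)
    return raw


def _looks_like_cif(text: str) -> bool:
    for line in text.splitlines()[:200]:
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if s.startswith("data_") or s.startswith("loop_") or s.startswith("_"):
            return True
        if s[:6] in ("HEADER", "ATOM  ", "HETATM", "MODEL ", "REMARK",
                     "CRYST1", "COMPND", "TITLE ", "SEQRES"):
            return False
    return False


def _parse_gemmi(text: str, path: str) -> gemmi.Structure:
    try:
        if _looks_like_cif(text):
            doc = gemmi.cif.read_string(text)
            return gemmi.make_structure_from_block(doc.sole_block())
        return gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc


def _dedupe_altloc(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy alternate location per atom name."""
    best: dict[str, gemmi.Atom] = {}
    for at in res:
        prev = best.get(at.name)
        if prev is None or at.occ > prev.occ:
            best[at.name] = at
    return list(best.values())


def read_structure(path: str | Path, model: int = 1) -> Structure:
    """Parse a PDB/mmCIF file (gzip-aware) into a nucleotide-only Structure.

    Parameters
    ----------
    path:
        Input file. Gzip compression is detected from the leading magic
        bytes, not the file extension.
    model:
        1-based model number to extract (NMR ensembles deposit many; the
        default is the representative first model).
    """
    text = _read_bytes(path).decode("utf-8", errors="replace")
    st = _parse_gemmi(text, str(path))
    if len(st) == 0:
        raise ParseError(f"{path}: no models found")
    if not (1 <= model <= len(st)):
        raise ValueError(
            f"model {model} out of range: {path} has models 1..{len(st)}")
    gmodel = st[model - 1]

    residues: list[Residue] = []
    ions: list[Residue] = []
    skipped: list[str] = []
    for chain in gmodel:
        for gres in chain:
            name = gres.name.strip().upper()
            if name in _WATER_NAMES:
                continue
            atoms = [
                Atom(a.name, a.element.name.upper(),
                     np.array([a.pos.x, a.pos.y, a.pos.z]))
                for a in _dedupe_altloc(gres) if a.element.name != "H"
            ]
            if not atoms:
                continue
            res = Residue(
                chain_id=chain.name,
                seq_num=gres.seqid.num,
                icode=(gres.seqid.icode or "").strip(),
                res_name=name,
                atoms=atoms,
            )
            if name in _ION_NAMES and len(atoms) <= 2:
                ions.append(res)
                continue
            parent = _classify_parent(name, {a.name for a in atoms})
            if parent is None:
                skipped.append(res.key)
                continue
            res.parent_base = parent
            residues.append(res)
    if skipped:
        logger.warning("excluded %d non-nucleotide residues: %s",
                       len(skipped), ", ".join(skipped[:10]))
    return Structure(pdb_id=(st.name or "").strip(),
                     model_num=model, residues=residues, ions=ions)


def write_pdb(structure: Structure) -> str:
    """Serialize a Structure back to minimal PDB text (ATOM/TER/END)."""
    lines: list[str] = []
    serial = 1
    last_chain = None
    ion_ids = {id(r) for r in structure.ions}
    for res in structure.residues + structure.ions:
        if last_chain is not None and res.chain_id != last_chain:
            lines.append("TER")
        last_chain = res.chain_id
        record = "HETATM" if id(res) in ion_ids else "ATOM  "
        for at in res.atoms:
            name = at.name if len(at.name) >= 4 else f" {at.name:<3s}"
            x, y, z = at.position
            lines.append(
                f"{record}{serial:>5d} {name:<4s} {res.res_name:>3s} "
                f"{res.chain_id:1s}{res.seq_num:>4d}{res.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {at.element:>2s}")
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
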
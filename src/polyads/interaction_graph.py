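"""Connectivity substrate: base pairs, sequential links, stacking contacts.

The candidate filter needs to know, for every nucleotide, which tetrad
members it is base-paired with and which it follows along a covalently
continuous strand. A deliberately permissive geometric pair detector is
built in (crystal structures carry no hydrogens, so donor–acceptor
heavy-atom distance proxies the hydrogen bond); alternatively a JSON
annotation file produced by an external annotator can be imported verbatim.

The built-in detector's constants are module configuration, not literature
values; downstream criteria re-check candidate geometry much more strictly,
so pair detection only has to be generous without fabricating contacts
between stacked (face-to-face) bases — that is what the vertical-offset
gate is for.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .base_geometry import BaseFrame, tilt
from .structure_io import Residue, Structure

#: Best-effort Leontis–Westhof-style edge membership of base atoms.
_EDGE_ATOMS = {
    "purine": {
        "W": {"N1", "C2", "N2", "N6", "O6"},
        "H": {"N7", "C8", "O6", "N6", "C5"},
        "S": {"N3", "N2", "C2", "O2'"},
    },
    "pyrimidine": {
        "W": {"N3", "N4", "O4", "O2"},
        "H": {"C5", "C6", "N4", "O4", "C7", "C5M"},
        "S": {"O2", "N3", "O2'"},
    },
}


@dataclass(eq=False)
class BasePair:
    """An unordered base pair with per-residue edge labels and H-bond count."""

    res_a: Residue
    res_b: Residue
    edge_a: str       # W / H / S, best-effort
    edge_b: str
    n_hbonds: int

    def __post_init__(self) -> None:
        if self.res_a is self.res_b:
            raise ValueError("a residue cannot pair with itself")
        if self.n_hbonds < 2:
            raise ValueError("a base pair needs at least 2 hydrogen bonds")

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.res_a.key, self.res_b.key))

    def partner(self, res_key: str) -> str:
        a, b = self.res_a.key, self.res_b.key
        if res_key == a:
            return b
        if res_key == b:
            return a
        raise KeyError(res_key)


@dataclass
class PairingConfig:
    """Gates of the built-in detector (module defaults, user-adjustable)."""

    hbond_max: float = 3.5          # donor–acceptor heavy-atom distance, Å
    min_hbonds: int = 2
    pair_tilt_max: float = 60.0     # deg
    pair_centroid_max: float = 12.0  # Å
    pair_vertical_max: float = 2.5  # Å; face-to-face geometries are stacking
    seq_o3p_max: float = 2.5        # covalent O3'(i)–P(i+1) distance, Å
    stack_centroid_max: float = 5.5  # Å
    stack_tilt_max: float = 30.0    # deg
    stack_inplane_max: float = 4.0  # Å


@dataclass
class InteractionGraph:
    """Base-pair, sequential (strand-continuity) and stacking edges."""

    pairs: list[BasePair] = field(default_factory=list)
    sequential: set[frozenset[str]] = field(default_factory=set)
    stackings: set[frozenset[str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._pair_map: dict[frozenset[str], BasePair] = {
            p.key: p for p in self.pairs}

    def paired(self, key_a: str, key_b: str) -> bool:
        return frozenset((key_a, key_b)) in self._pair_map

    def pair_between(self, key_a: str, key_b: str) -> BasePair | None:
        return self._pair_map.get(frozenset((key_a, key_b)))

    def sequential_with(self, key_a: str, key_b: str) -> bool:
        return frozenset((key_a, key_b)) in self.sequential

    def pair_partners(self, key: str) -> list[str]:
        return sorted(p.partner(key) for p in self.pairs if key in p.key)


def _polar_base_atoms(res: Residue) -> list:
    return [a for a in res.base_atoms() if a.element in ("N", "O")]


def _edge_label(res: Residue, contact_atoms: list[str]) -> str:
    kind = "purine" if res.is_purine else "pyrimidine"
    votes = {e: sum(1 for n in contact_atoms if n in atoms)
             for e, atoms in _EDGE_ATOMS[kind].items()}
    # deterministic preference W > H > S on ties
    return max(("W", "H", "S"), key=lambda e: (votes[e], e == "W", e == "H"))


def detect_base_pairs(structure: Structure,
                      frames: dict[str, BaseFrame],
                      config: PairingConfig | None = None) -> list[BasePair]:
    """Geometric base-pair detection from donor/acceptor heavy atoms.

    A pair is emitted when at least ``min_hbonds`` polar (N/O) base-atom
    contacts within ``hbond_max`` exist, the bases are not too tilted
    against each other, their centroids are near, and they are side by side
    rather than stacked (vertical centroid offset below
    ``pair_vertical_max`` along the mean normal).
    """
    cfg = config or PairingConfig()
    keys = [r.key for r in structure.residues if r.key in frames]
    pairs: list[BasePair] = []
    for i, ka in enumerate(keys):
        fa = frames[ka]
        for kb in keys[i + 1:]:
            fb = frames[kb]
            dc = fb.base_centroid - fa.base_centroid
            if np.linalg.norm(dc) > cfg.pair_centroid_max:
                continue
            if tilt(fa.normal, fb.normal) > cfg.pair_tilt_max:
                continue
            nb = fb.normal if np.dot(fa.normal, fb.normal) >= 0 else -fb.normal
            mean_n = fa.normal + nb
            mean_n = mean_n / np.linalg.norm(mean_n)
            if abs(float(np.dot(dc, mean_n))) > cfg.pair_vertical_max:
                continue
            contacts_a: list[str] = []
            contacts_b: list[str] = []
            n_contacts = 0
            for aa in _polar_base_atoms(fa.residue):
                for ab in _polar_base_atoms(fb.residue):
                    if np.linalg.norm(aa.position - ab.position) <= cfg.hbond_max:
                        n_contacts += 1
                        contacts_a.append(aa.name)
                        contacts_b.append(ab.name)
            if n_contacts >= cfg.min_hbonds:
                pairs.append(BasePair(
                    res_a=fa.residue, res_b=fb.residue,
                    edge_a=_edge_label(fa.residue, contacts_a),
                    edge_b=_edge_label(fb.residue, contacts_b),
                    n_hbonds=n_contacts))
    return pairs


def build_connectivity(structure: Structure,
                       pairs: list[BasePair],
                       frames: dict[str, BaseFrame],
                       config: PairingConfig | None = None) -> InteractionGraph:
    """Assemble the full graph: pairs + sequential + stacking edges.

    Sequential edges require covalent O3'(i)–P(i+1) linkage between chain
    neighbors, so chain breaks do not fabricate connections. Stacking edges
    join near-parallel bases whose centroids sit face to face.
    """
    cfg = config or PairingConfig()
    graph = InteractionGraph(pairs=list(pairs))

    by_chain: dict[str, list[Residue]] = {}
    for r in structure.residues:
        by_chain.setdefault(r.chain_id, []).append(r)
    for chain_res in by_chain.values():
        for ra, rb in zip(chain_res, chain_res[1:]):
            o3 = ra.atom("O3'")
            p = rb.atom("P")
            if o3 is not None and p is not None and \
                    np.linalg.norm(o3.position - p.position) <= cfg.seq_o3p_max:
                graph.sequential.add(frozenset((ra.key, rb.key)))

    keys = [r.key for r in structure.residues if r.key in frames]
    for i, ka in enumerate(keys):
        fa = frames[ka]
        for kb in keys[i + 1:]:
            fb = frames[kb]
            dc = fb.base_centroid - fa.base_centroid
            d = float(np.linalg.norm(dc))
            if d > cfg.stack_centroid_max:
                continue
            if tilt(fa.normal, fb.normal) > cfg.stack_tilt_max:
                continue
            nb = fb.normal if np.dot(fa.normal, fb.normal) >= 0 else -fb.normal
            mean_n = fa.normal + nb
            mean_n = mean_n / np.linalg.norm(mean_n)
            vertical = abs(float(np.dot(dc, mean_n)))
            inplane = float(np.sqrt(max(d * d - vertical * vertical, 0.0)))
            if inplane <= cfg.stack_inplane_max and vertical > 1.0:
                graph.stackings.add(frozenset((ka, kb)))
    return graph


def import_annotations(path: str | Path, structure: Structure,
                       config: PairingConfig | None = None) -> InteractionGraph:
    """Build the graph from an external annotation JSON instead of detection.

    Schema::

        {"pairs": [{"nt1": "A/1", "nt2": "A/5",
                    "edge1": "H", "edge2": "S", "hbonds": 2}, ...],
         "stackings": [["A/1", "A/2"], ...]}

    Residue selectors are ``chain/number[icode]`` in author numbering and
    must resolve against the structure. Sequential edges are always derived
    from the structure's own backbone.
    """
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed annotation JSON {path}: {exc}") from exc

    def resolve(key: str) -> Residue:
        try:
            return structure.by_key(key)
        except KeyError:
            raise KeyError(
                f"annotation references residue {key!r} absent from structure")

    pairs = []
    for entry in data.get("pairs", []):
        ra = resolve(entry["nt1"])
        rb = resolve(entry["nt2"])
        pairs.append(BasePair(res_a=ra, res_b=rb,
                              edge_a=entry.get("edge1", "W"),
                              edge_b=entry.get("edge2", "W"),
                              n_hbonds=int(entry.get("hbonds", 2))))
    graph = build_connectivity(structure, pairs, frames={}, config=config)
    for ka, kb in data.get("stackings", []):
        resolve(ka)
        resolve(kb)
        graph.stackings.add(frozenset((ka, kb)))
    return graph
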
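"""Pipeline orchestration, report assembly and the precision utility."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .base_geometry import BaseFrame, base_frame
from .interaction_graph import (InteractionGraph, PairingConfig,
                                build_connectivity, detect_base_pairs,
                                import_annotations)
from .polyad_engine import (Polyad, PolyadCandidate, Thresholds,
                            classify_polyad, detect_polyads)
from .structure_io import Structure, read_structure
from .tetrad_core import TetradStack, build_stacks, find_tetrads


@dataclass
class RunConfig:
    """Everything one detection run needs."""

    input_path: str
    model: int = 1
    lax_order: bool = False
    thresholds: Thresholds = field(default_factory=Thresholds)
    annotation_path: str | None = None
    output_format: str = "text"     # text | json
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.output_format not in ("text", "json"):
            raise ValueError("output_format must be 'text' or 'json'")


@dataclass
class Report:
    """Detection results plus provenance, serializable to text or JSON."""

    structure: Structure
    polyads: list[Polyad]
    stacks: list[TetradStack]
    candidates: list[PolyadCandidate]
    config: RunConfig

    def to_dict(self) -> dict:
        th = self.config.thresholds
        polyad_entries = []
        for p in self.polyads:
            stack, pos = self._locate(p)
            polyad_entries.append({
                "label": classify_polyad(p),
                "order": p.order,
                "tetrad": list(p.tetrad.key),
                "stack": stack,
                "stack_position": pos,
                "extensions": [_candidate_dict(c) for c in p.extensions],
            })
        stack_entries = []
        extended = {p.tetrad.key for p in self.polyads}
        for si, stack in enumerate(self.stacks):
            for t in stack.tetrads:
                stack_entries.append({
                    "tetrad": list(t.key),
                    "stack": si,
                    "stack_position": stack.position_of(t),
                    "at_end": stack.is_end(t),
                    "extended": t.key in extended,
                })
        return {
            "provenance": {
                "tool": "polyads",
                "version": __version__,
                "input": str(self.config.input_path),
                "model": self.config.model,
                "lax_order": self.config.lax_order,
                "thresholds": {
                    "tilt_avg": th.tt_avg, "tilt_max": th.tt_max,
                    "height_avg": th.ht_avg, "height_max": th.ht_max,
                    "dist_in_max": th.dist_in_max,
                    "dist_out_max": th.dist_out_max,
                    "dist_spread_max": th.dist_spread_max,
                },
            },
            "polyads": polyad_entries,
            "stack_tetrads": stack_entries,
        }

    def _locate(self, polyad: Polyad) -> tuple[int, int]:
        for si, stack in enumerate(self.stacks):
            for t in stack.tetrads:
                if t is polyad.tetrad:
                    return si, stack.position_of(t)
        return -1, -1

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    def to_text(self) -> str:
        d = self.to_dict()
        lines = [f"polyads {__version__} — {d['provenance']['input']} "
                 f"(model {d['provenance']['model']})"]
        if not d["polyads"]:
            lines.append("no polyadic motifs found")
        for e in d["polyads"]:
            lines.append(f"{e['label']} (order {e['order']}) on tetrad "
                         f"{':'.join(e['tetrad'])} [stack {e['stack']}, "
                         f"layer {e['stack_position']}]")
            for x in e["extensions"]:
                lines.append(
                    f"  + {x['residue']} ({x['base']})  score={x['score']:.1f}"
                    f"  pairs={x['pair_count']} links={x['con_count']}"
                    f"  tilt_avg={x['tilt_avg']:.1f}deg"
                    f"  dh_in_avg={x['dh_in_avg']:.2f}A"
                    f"  dh_out_avg={x['dh_out_avg']:.2f}A"
                    f"  dist={x['centroid_dist']:.2f}A")
        lines.append("stacked tetrads:")
        for s in d["stack_tetrads"]:
            role = "end" if s["at_end"] else "middle"
            mark = "polyad core" if s["extended"] else "plain tetrad"
            lines.append(f"  stack {s['stack']} layer {s['stack_position']}"
                         f" ({role}): {':'.join(s['tetrad'])} — {mark}")
        return "\n".join(lines) + "\n"


def _candidate_dict(c: PolyadCandidate) -> dict:
    import numpy as np
    return {
        "residue": c.residue.key,
        "base": c.residue.parent_base or c.residue.res_name,
        "score": round(float(c.score), 3) if c.score is not None else None,
        "con_count": c.con_count,
        "pair_count": c.pair_count,
        "tilt_avg": round(float(np.mean(c.tilts)), 3),
        "tilt_max": round(float(max(c.tilts)), 3),
        "dh_in_avg": round(float(np.mean([abs(v) for v in c.dh_in])), 3),
        "dh_out_avg": round(float(np.mean([abs(v) for v in c.dh_out])), 3),
        "centroid_dist": round(c.centroid_dist, 3),
        "member_dists": [round(v, 3) for v in c.member_dists],
        "passed": dict(c.passed),
    }


REPORT_REQUIRED_KEYS = {
    "provenance": {"tool", "version", "input", "model", "lax_order",
                   "thresholds"},
    "polyad_entry": {"label", "order", "tetrad", "stack", "stack_position",
                     "extensions"},
    "stack_entry": {"tetrad", "stack", "stack_position", "at_end", "extended"},
}


def validate_report_dict(d: dict) -> None:
    """Minimal structural validation of a report dictionary."""
    for key in ("provenance", "polyads", "stack_tetrads"):
        if key not in d:
            raise ValueError(f"report missing top-level key {key!r}")
    missing = REPORT_REQUIRED_KEYS["provenance"] - set(d["provenance"])
    if missing:
        raise ValueError(f"report provenance missing {sorted(missing)}")
    for e in d["polyads"]:
        missing = REPORT_REQUIRED_KEYS["polyad_entry"] - set(e)
        if missing:
            raise ValueError(f"polyad entry missing {sorted(missing)}")
        if e["order"] != 4 + len(e["extensions"]):
            raise ValueError("polyad order inconsistent with extension count")
    for e in d["stack_tetrads"]:
        missing = REPORT_REQUIRED_KEYS["stack_entry"] - set(e)
        if missing:
            raise ValueError(f"stack entry missing {sorted(missing)}")


def analyze_structure(structure: Structure, config: RunConfig,
                      graph: InteractionGraph | None = None) -> Report:
    """Run detection on an already-parsed structure."""
    frames: dict[str, BaseFrame] = {}
    for res in structure.residues:
        f = base_frame(res)
        if f is not None:
            frames[res.key] = f
    if graph is None:
        if config.annotation_path:
            graph = import_annotations(config.annotation_path, structure)
        else:
            cfg = PairingConfig()
            pairs = detect_base_pairs(structure, frames, cfg)
            graph = build_connectivity(structure, pairs, frames, cfg)
    tetrads = find_tetrads(graph, frames)
    stacks = build_stacks(tetrads, graph)
    polyads, candidates = detect_polyads(
        structure, graph, frames, tetrads, stacks,
        thresholds=config.thresholds, lax=config.lax_order,
        verbose=config.verbose)
    return Report(structure=structure, polyads=polyads, stacks=stacks,
                  candidates=candidates, config=config)


def run_pipeline(config: RunConfig) -> Report:
    """Read the input file and run the full detection workflow."""
    structure = read_structure(config.input_path, model=config.model)
    return analyze_structure(structure, config)


def compute_precision(tp: int, fp: int) -> float:
    """Positive predictive value TP/(TP+FP) of a validated detection run."""
    if tp < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0:
        raise ValueError("precision undefined for TP+FP = 0")
    return tp / (tp + fp)


def format_precision(tp: int, fp: int) -> str:
    """Two-decimal rendering used in text output."""
    return f"{compute_precision(tp, fp):.2f}"
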
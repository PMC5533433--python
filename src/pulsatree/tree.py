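"""Arterial network data model, validation and I/O.

The spatial domain of the 1-D solver is a rooted, acyclic tree of tapered
elastic segments.  Leaves carry 3-element Windkessel terminals standing in
for the distal vascular beds; named measurement sites map clinical labels
("aortic_root", "brachial", ...) onto (segment, fractional position).

Configs are plain-text YAML with an explicit unit header; ``si`` and
``clinical`` (cm / mmHg·s/mL / mL/mmHg) unit systems are supported.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .units import MMHG, R_CLINICAL, C_CLINICAL
from .wall import WallLaw

__all__ = [
    "ArterialSegment",
    "WindkesselTerminal",
    "ArterialTree",
    "Diagnostic",
    "validate_tree",
    "read_tree",
    "write_tree",
    "tree_io",
]

DX_MAX_DEFAULT = 2.5e-3  # m, default spatial resolution bound


@dataclass
class ArterialSegment:
    """One tapered arterial segment (linear taper in diameter)."""

    id: int
    name: str
    length: float  # m
    diameter_prox: float  # m
    diameter_dist: float  # m
    parent: int | None  # parent segment id, None at the root
    wall: WallLaw | None = None
    n_grid: int = 0  # spatial nodes; 0 = derive from dx_max

    @property
    def mean_diameter(self) -> float:
        return 0.5 * (self.diameter_prox + self.diameter_dist)

    def diameters(self, n: int) -> np.ndarray:
        """Nodal diameters on an n-point uniform grid along the segment."""
        return np.linspace(self.diameter_prox, self.diameter_dist, n)

    def grid_nodes(self, dx_max: float = DX_MAX_DEFAULT) -> int:
        if self.n_grid >= 3:
            return self.n_grid
        return max(3, int(math.ceil(self.length / dx_max)) + 1)


@dataclass
class WindkesselTerminal:
    """3-element RCR terminal: R1 in series with C parallel R2 to P_out."""

    R1: float  # Pa.s/m^3
    R2: float  # Pa.s/m^3
    C: float  # m^3/Pa
    P_out: float = 0.0  # Pa

    @property
    def total_resistance(self) -> float:
        return self.R1 + self.R2


@dataclass
class Diagnostic:
    segment_id: int | None
    rule: str
    message: str

    def __str__(self):  # pragma: no cover - cosmetic
        return f"[{self.rule}] segment {self.segment_id}: {self.message}"


@dataclass
class ArterialTree:
    """Rooted tree of segments with terminal Windkessels and named sites."""

    segments: dict[int, ArterialSegment]
    terminals: dict[int, WindkesselTerminal]
    named_sites: dict[str, tuple[int, float]] = field(default_factory=dict)

    # ---- topology helpers -------------------------------------------------
    @property
    def root_id(self) -> int:
        roots = [s.id for s in self.segments.values() if s.parent is None]
        if len(roots) != 1:
            raise ValueError(f"tree has {len(roots)} roots")
        return roots[0]

    def children_of(self, seg_id: int) -> list[int]:
        return sorted(s.id for s in self.segments.values() if s.parent == seg_id)

    def leaves(self) -> list[int]:
        has_child = {s.parent for s in self.segments.values() if s.parent is not None}
        return sorted(i for i in self.segments if i not in has_child)

    def parallel_terminal_resistance(self) -> float:
        g = sum(1.0 / t.total_resistance for t in self.terminals.values())
        return 1.0 / g

    def copy(self) -> "ArterialTree":
        return ArterialTree(
            segments={i: replace(s) for i, s in self.segments.items()},
            terminals={i: replace(t) for i, t in self.terminals.items()},
            named_sites=dict(self.named_sites),
        )

    def segment_table(self) -> pd.DataFrame:
        """Segment geometry as a DataFrame (lengths m, diameters m)."""
        rows = [
            dict(id=s.id, name=s.name, parent=s.parent, length_m=s.length,
                 diameter_prox_m=s.diameter_prox, diameter_dist_m=s.diameter_dist,
                 mean_diameter_m=s.mean_diameter,
                 terminal=s.id in self.terminals)
            for s in sorted(self.segments.values(), key=lambda s: s.id)
        ]
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

def validate_tree(tree: ArterialTree, dx_max: float = DX_MAX_DEFAULT) -> list[Diagnostic]:
    """Check every structural invariant; return one diagnostic per violation.

    An empty list means the tree is usable by the solver.
    """
    diags: list[Diagnostic] = []
    segs = tree.segments

    for s in segs.values():
        if s.length <= 0:
            diags.append(Diagnostic(s.id, "positive-length",
                                    f"segment '{s.name}' has length {s.length}"))
        if s.diameter_prox <= 0 or s.diameter_dist <= 0:
            diags.append(Diagnostic(s.id, "positive-diameter",
                                    f"segment '{s.name}' has a non-positive diameter"))
        if s.parent is not None and s.parent not in segs:
            diags.append(Diagnostic(s.id, "parent-exists",
                                    f"parent id {s.parent} not in tree"))

    roots = [s.id for s in segs.values() if s.parent is None]
    if len(roots) != 1:
        diags.append(Diagnostic(None, "single-root", f"found {len(roots)} root segments"))
        return diags

    # connectivity / acyclicity by walk-to-root
    for s in segs.values():
        seen, cur = set(), s.id
        while cur is not None:
            if cur in seen:
                diags.append(Diagnostic(s.id, "acyclic", "cycle detected on path to root"))
                break
            seen.add(cur)
            cur = segs[cur].parent if cur in segs else None

    leaves = set(tree.leaves())
    for leaf in sorted(leaves):
        if leaf not in tree.terminals:
            diags.append(Diagnostic(leaf, "leaf-terminal",
                                    f"leaf segment '{segs[leaf].name}' lacks a Windkessel terminal"))
    for tid in sorted(tree.terminals):
        if tid not in segs:
            diags.append(Diagnostic(tid, "terminal-segment", "terminal attached to unknown segment"))
        elif tid not in leaves:
            diags.append(Diagnostic(tid, "terminal-on-leaf",
                                    f"internal segment '{segs[tid].name}' carries a terminal"))

    for tid, t in tree.terminals.items():
        if t.R1 < 0 or t.R2 <= 0 or t.C <= 0:
            diags.append(Diagnostic(tid, "windkessel-parameters",
                                    f"terminal needs R1 >= 0, R2 > 0, C > 0 (got {t.R1}, {t.R2}, {t.C})"))

    if tree.terminals and not any(d.rule == "windkessel-parameters" for d in diags):
        rp = tree.parallel_terminal_resistance()
        if not (np.isfinite(rp) and rp > 0):
            diags.append(Diagnostic(None, "finite-load", "parallel terminal resistance not finite/positive"))

    for label, (sid, frac) in tree.named_sites.items():
        if sid not in segs:
            diags.append(Diagnostic(sid, "site-segment", f"site '{label}' references unknown segment"))
        elif not 0.0 <= frac <= 1.0:
            diags.append(Diagnostic(sid, "site-fraction", f"site '{label}' fraction {frac} outside [0,1]"))

    for s in segs.values():
        n = s.grid_nodes(dx_max)
        if s.length / (n - 1) > dx_max * (1 + 1e-9):
            diags.append(Diagnostic(s.id, "grid-spacing",
                                    f"grid spacing exceeds dx_max={dx_max}"))
    return diags


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

_SCHEMA_VERSION = 1


def _tree_to_doc(tree: ArterialTree, units: str) -> dict:
    if units not in ("si", "clinical"):
        raise ValueError("units must be 'si' or 'clinical'")
    lf = 1.0 if units == "si" else 1e2  # m -> cm
    rf = 1.0 if units == "si" else 1.0 / R_CLINICAL
    cf = 1.0 if units == "si" else 1.0 / C_CLINICAL
    pf = 1.0 if units == "si" else 1.0 / MMHG
    doc = {
        "format": "pulsatree-tree",
        "version": _SCHEMA_VERSION,
        "units": units,
        "segments": [],
        "terminals": [],
        "named_sites": {k: [int(v[0]), float(v[1])] for k, v in sorted(tree.named_sites.items())},
    }
    for s in sorted(tree.segments.values(), key=lambda s: s.id):
        row = {
            "id": int(s.id),
            "name": s.name,
            "length": float(s.length * lf),
            "diameter_prox": float(s.diameter_prox * lf),
            "diameter_dist": float(s.diameter_dist * lf),
            "parent": None if s.parent is None else int(s.parent),
        }
        if s.n_grid:
            row["n_grid"] = int(s.n_grid)
        if s.wall is not None:
            row["wall"] = {"A_m": s.wall.A_m, "P0": s.wall.P0, "P1": s.wall.P1,
                           "gamma": s.wall.gamma}
        doc["segments"].append(row)
    for tid in sorted(tree.terminals):
        t = tree.terminals[tid]
        doc["terminals"].append({
            "segment": int(tid),
            "R1": float(t.R1 * rf),
            "R2": float(t.R2 * rf),
            "C": float(t.C * cf),
            "P_out": float(t.P_out * pf),
        })
    return doc


def _doc_to_tree(doc: dict) -> ArterialTree:
    if not isinstance(doc, dict) or doc.get("format") != "pulsatree-tree":
        raise ValueError("not a pulsatree tree config (missing 'format: pulsatree-tree')")
    units = doc.get("units", "si")
    if units not in ("si", "clinical"):
        raise ValueError(f"unknown unit system '{units}'")
    lf = 1.0 if units == "si" else 1e-2
    rf = 1.0 if units == "si" else R_CLINICAL
    cf = 1.0 if units == "si" else C_CLINICAL
    pf = 1.0 if units == "si" else MMHG

    segments: dict[int, ArterialSegment] = {}
    for i, row in enumerate(doc.get("segments", [])):
        for fld in ("id", "name", "length", "diameter_prox", "diameter_dist"):
            if fld not in row:
                raise ValueError(f"segment row {i}: missing field '{fld}'")
        if "parent" not in row:
            raise ValueError(f"segment row {i} (id={row['id']}): missing field 'parent' "
                             "(use null for the root)")
        sid = int(row["id"])
        if sid in segments:
            raise ValueError(f"duplicate segment id {sid}")
        wall = None
        if "wall" in row and row["wall"] is not None:
            w = row["wall"]
            wall = WallLaw(A_m=float(w["A_m"]), P0=float(w["P0"]), P1=float(w["P1"]),
                           gamma=float(w.get("gamma", 0.0)))
        segments[sid] = ArterialSegment(
            id=sid, name=str(row["name"]), length=float(row["length"]) * lf,
            diameter_prox=float(row["diameter_prox"]) * lf,
            diameter_dist=float(row["diameter_dist"]) * lf,
            parent=None if row["parent"] is None else int(row["parent"]),
            wall=wall, n_grid=int(row.get("n_grid", 0)))

    terminals: dict[int, WindkesselTerminal] = {}
    for i, row in enumerate(doc.get("terminals", [])):
        for fld in ("segment", "R1", "R2", "C"):
            if fld not in row:
                raise ValueError(f"terminal row {i}: missing field '{fld}'")
        tid = int(row["segment"])
        if tid in terminals:
            raise ValueError(f"duplicate terminal for segment {tid}")
        terminals[tid] = WindkesselTerminal(
            R1=float(row["R1"]) * rf, R2=float(row["R2"]) * rf,
            C=float(row["C"]) * cf, P_out=float(row.get("P_out", 0.0)) * pf)

    sites = {str(k): (int(v[0]), float(v[1]))
             for k, v in (doc.get("named_sites") or {}).items()}
    return ArterialTree(segments=segments, terminals=terminals, named_sites=sites)


def write_tree(tree: ArterialTree, path, units: str = "si") -> None:
    doc = _tree_to_doc(tree, units)
    text = yaml.safe_dump(doc, sort_keys=False, default_flow_style=None, width=100)
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text)


def read_tree(path) -> ArterialTree:
    if hasattr(path, "read"):
        doc = yaml.safe_load(path.read())
    else:
        doc = yaml.safe_load(Path(path).read_text())
    return _doc_to_tree(doc)


def tree_io(path_or_stream, mode: str = "read", tree: ArterialTree | None = None,
            units: str = "si"):
    """Single entry point for tree config I/O.

    ``mode='read'`` parses a config and returns the tree; ``mode='write'``
    serializes ``tree``.  write∘read is the identity on all fields up to
    float round-trip precision.
    """
    if mode == "read":
        return read_tree(path_or_stream)
    if mode == "write":
        if tree is None:
            raise ValueError("mode='write' requires a tree")
        return write_tree(tree, path_or_stream, units=units)
    raise ValueError(f"unknown mode '{mode}'")


def tree_to_yaml(tree: ArterialTree, units: str = "si") -> str:
    buf = io.StringIO()
    write_tree(tree, buf, units=units)
    return buf.getvalue()
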
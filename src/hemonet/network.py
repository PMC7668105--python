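"""Vascular network data model, validation and I/O.

A :class:`VesselNetwork` is a directed multigraph of :class:`Node` objects
joined by :class:`VesselSegment` objects.  Segment orientation records the
*nominal* flow direction; solvers may report negative flow (reversal) but
never rewrite topology.  Node coordinates (2D, micrometres) are optional for
purely topological solvers (flow, hematocrit splitting) and required by the
tissue-oxygen module.

Two interchange formats are supported:

* edge-list CSV with header
  ``segment_id,source,target,length_um,diameter_um,perfused`` plus optional
  geometry/metadata columns (node coordinates, CFL annotations);
* GraphML with the same attribute names (via :mod:`networkx`).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "Node",
    "VesselSegment",
    "VesselNetwork",
    "BoundaryConditions",
    "NetworkValidationError",
    "validate_network",
    "read_network",
    "write_network",
]

#: optional per-segment annotation columns understood by the CSV/GraphML I/O
_SEGMENT_META_KEYS = ("turn", "cfl_thin_side", "plane_relation", "generation", "channel")
_CSV_COLUMNS = (
    "segment_id",
    "source",
    "target",
    "length_um",
    "diameter_um",
    "perfused",
    "source_x",
    "source_y",
    "target_x",
    "target_y",
) + _SEGMENT_META_KEYS


class NetworkValidationError(ValueError):
    """Raised when an operation requires a valid network and validation fails."""


class NetworkParseError(ValueError):
    """Raised when a network file cannot be parsed."""


@dataclass(frozen=True)
class Node:
    """A network node.

    Parameters
    ----------
    id:
        Unique opaque identifier.
    x, y:
        Optional 2D position in micrometres.
    role:
        One of ``inlet``, ``outlet``, ``junction``.  If left as ``auto`` the
        role is inferred from the topology (no incoming segment -> inlet, no
        outgoing segment -> outlet).
    """

    id: str
    x: float | None = None
    y: float | None = None
    role: str = "auto"

    @property
    def position(self) -> tuple[float, float] | None:
        if self.x is None or self.y is None:
            return None
        return (self.x, self.y)


@dataclass
class VesselSegment:
    """A straight vessel segment (edge) with length and diameter in um."""

    id: str
    source: str
    target: str
    length: float
    diameter: float
    perfused: bool | None = None
    meta: dict = field(default_factory=dict)


class VesselNetwork:
    """Directed vascular network: nodes, segments and free-form metadata."""

    def __init__(
        self,
        nodes: Iterable[Node] = (),
        segments: Iterable[VesselSegment] = (),
        metadata: Mapping | None = None,
    ):
        self.nodes: dict[str, Node] = {}
        self.segments: dict[str, VesselSegment] = {}
        self.metadata: dict = dict(metadata or {})
        for n in nodes:
            self.add_node(n)
        for s in segments:
            self.add_segment(s)

    # -- construction -----------------------------------------------------
    def add_node(self, node: Node) -> Node:
        if node.id in self.nodes:
            raise ValueError(f"duplicate node id {node.id!r}")
        self.nodes[node.id] = node
        return node

    def add_segment(self, seg: VesselSegment) -> VesselSegment:
        if seg.id in self.segments:
            raise ValueError(f"duplicate segment id {seg.id!r}")
        self.segments[seg.id] = seg
        return seg

    # -- queries ----------------------------------------------------------
    def out_segments(self, node_id: str) -> list[VesselSegment]:
        return [s for s in self.segments.values() if s.source == node_id]

    def in_segments(self, node_id: str) -> list[VesselSegment]:
        return [s for s in self.segments.values() if s.target == node_id]

    def node_role(self, node_id: str) -> str:
        """Explicit role, or the topology-inferred one for ``auto`` nodes."""
        node = self.nodes[node_id]
        if node.role != "auto":
            return node.role
        has_in = any(s.target == node_id for s in self.segments.values())
        has_out = any(s.source == node_id for s in self.segments.values())
        if not has_in:
            return "inlet"
        if not has_out:
            return "outlet"
        return "junction"

    def inlet_nodes(self) -> list[str]:
        return [n for n in self.nodes if self.node_role(n) == "inlet"]

    def outlet_nodes(self) -> list[str]:
        return [n for n in self.nodes if self.node_role(n) == "outlet"]

    def has_coordinates(self) -> bool:
        return all(n.position is not None for n in self.nodes.values())

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) over node positions; requires coordinates."""
        if not self.has_coordinates():
            raise NetworkValidationError("network has nodes without coordinates")
        xs = [n.x for n in self.nodes.values()]
        ys = [n.y for n in self.nodes.values()]
        return (min(xs), min(ys), max(xs), max(ys))

    def to_multidigraph(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for n in self.nodes.values():
            g.add_node(n.id, x=n.x, y=n.y, role=n.role)
        for s in self.segments.values():
            g.add_edge(s.source, s.target, key=s.id, length=s.length, diameter=s.diameter)
        return g

    def copy(self) -> "VesselNetwork":
        return VesselNetwork(
            nodes=list(self.nodes.values()),
            segments=[
                VesselSegment(s.id, s.source, s.target, s.length, s.diameter, s.perfused, dict(s.meta))
                for s in self.segments.values()
            ],
            metadata=dict(self.metadata),
        )


def validate_network(network: VesselNetwork) -> list[str]:
    """Check structural invariants; return a list of violations (empty = valid).

    Pure reporting: the input is never mutated and repeat calls give the same
    report.
    """
    violations: list[str] = []
    for seg in network.segments.values():
        if seg.source not in network.nodes:
            violations.append(f"segment {seg.id!r} references missing source node {seg.source!r}")
        if seg.target not in network.nodes:
            violations.append(f"segment {seg.id!r} references missing target node {seg.target!r}")
        if seg.source == seg.target:
            violations.append(f"segment {seg.id!r} is a self-loop at node {seg.source!r}")
        if not (seg.length > 0) or not math.isfinite(seg.length):
            violations.append(f"segment {seg.id!r}: nonpositive length")
        if not (seg.diameter > 0) or not math.isfinite(seg.diameter):
            violations.append(f"segment {seg.id!r}: nonpositive diameter")
    if not network.segments:
        violations.append("network has no segments")
    if not network.nodes:
        violations.append("network has no nodes")
    if network.nodes and network.segments and not violations:
        undirected = nx.Graph()
        undirected.add_nodes_from(network.nodes)
        for seg in network.segments.values():
            undirected.add_edge(seg.source, seg.target)
        if not nx.is_connected(undirected):
            violations.append("network is not weakly connected")
        if not network.inlet_nodes():
            violations.append("network has no inlet node")
        if not network.outlet_nodes():
            violations.append("network has no outlet node")
    return violations


def _require_valid(network: VesselNetwork) -> None:
    report = validate_network(network)
    if report:
        raise NetworkValidationError("; ".join(report))


@dataclass
class BoundaryConditions:
    """Inlet hematocrit plus per-boundary pressure or flow conditions.

    ``pressures`` maps node id -> pressure (Pa); ``flows`` maps node id ->
    signed boundary flow (um^3/s, positive = into the network).  At least one
    pressure condition is required to fix the gauge.  A convenience
    constructor converts a mean inlet velocity to a flow via
    ``Q0 = v * pi d^2 / 4``.
    """

    inlet_hematocrit: float
    pressures: dict[str, float] = field(default_factory=dict)
    flows: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.inlet_hematocrit < 1.0):
            raise ValueError("inlet hematocrit must lie in [0, 1)")
        overlap = set(self.pressures) & set(self.flows)
        if overlap:
            raise ValueError(f"nodes with both pressure and flow conditions: {sorted(overlap)}")
        if not self.pressures:
            total = sum(self.flows.values())
            scale = max((abs(q) for q in self.flows.values()), default=1.0)
            if self.flows and abs(total) > 1e-9 * scale:
                raise ValueError(
                    "all-flow boundary conditions must balance globally "
                    f"(net imbalance {total:g})"
                )
            raise ValueError("at least one pressure condition is required (gauge fixing)")

    @staticmethod
    def flow_from_velocity(mean_velocity: float, diameter: float) -> float:
        """Volumetric flow Q0 = v * pi d^2/4 (um/s, um -> um^3/s)."""
        return mean_velocity * math.pi * diameter**2 / 4.0


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _format_number(x: float) -> str:
    return repr(float(x))


def _segment_row(network: VesselNetwork, seg: VesselSegment) -> dict[str, str]:
    src = network.nodes[seg.source]
    tgt = network.nodes[seg.target]
    row = {
        "segment_id": seg.id,
        "source": seg.source,
        "target": seg.target,
        "length_um": _format_number(seg.length),
        "diameter_um": _format_number(seg.diameter),
        "perfused": "" if seg.perfused is None else str(int(seg.perfused)),
        "source_x": "" if src.x is None else _format_number(src.x),
        "source_y": "" if src.y is None else _format_number(src.y),
        "target_x": "" if tgt.x is None else _format_number(tgt.x),
        "target_y": "" if tgt.y is None else _format_number(tgt.y),
    }
    for key in _SEGMENT_META_KEYS:
        row[key] = "" if seg.meta.get(key) is None else str(seg.meta[key])
    return row


def write_network(network: VesselNetwork, path: str | Path, format: str = "csv") -> None:
    """Write a validated network to ``path`` in ``csv`` or ``graphml`` format.

    Field ordering is deterministic (segments sorted by id).  Writing an
    invalid network raises :class:`NetworkValidationError` before any file is
    created.
    """
    _require_valid(network)
    path = Path(path)
    if format == "csv":
        rows = [_segment_row(network, network.segments[k]) for k in sorted(network.segments)]
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
            writer.writeheader()
            writer.writerows(rows)
    elif format == "graphml":
        g = nx.DiGraph() if _is_simple(network) else nx.MultiDiGraph()
        for nid in sorted(network.nodes):
            n = network.nodes[nid]
            attrs = {"role": n.role}
            if n.x is not None:
                attrs["x"] = float(n.x)
                attrs["y"] = float(n.y)
            g.add_node(nid, **attrs)
        for sid in sorted(network.segments):
            s = network.segments[sid]
            attrs = {
                "segment_id": s.id,
                "length_um": float(s.length),
                "diameter_um": float(s.diameter),
            }
            if s.perfused is not None:
                attrs["perfused"] = int(s.perfused)
            for key in _SEGMENT_META_KEYS:
                if s.meta.get(key) is not None:
                    attrs[key] = s.meta[key]
            g.add_edge(s.source, s.target, **attrs)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'graphml')")


def _is_simple(network: VesselNetwork) -> bool:
    pairs = [(s.source, s.target) for s in network.segments.values()]
    return len(pairs) == len(set(pairs))


def _parse_optional_float(value: str | None) -> float | None:
    if value is None or value == "":
        return None
    return float(value)


def read_network(path: str | Path, format: str | None = None) -> VesselNetwork:
    """Read a network from CSV or GraphML; the result passes validation."""
    path = Path(path)
    if format is None:
        format = "graphml" if path.suffix.lower() in {".graphml", ".xml"} else "csv"
    if format == "csv":
        network = _read_csv(path)
    elif format == "graphml":
        network = _read_graphml(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    _require_valid(network)
    return network


def _read_csv(path: Path) -> VesselNetwork:
    network = VesselNetwork()
    node_coords: dict[str, tuple[float | None, float | None]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        required = {"segment_id", "source", "target", "length_um", "diameter_um"}
        missing = required - set(header)
        if missing:
            raise NetworkParseError(f"{path}: missing required columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                seg = VesselSegment(
                    id=row["segment_id"],
                    source=row["source"],
                    target=row["target"],
                    length=float(row["length_um"]),
                    diameter=float(row["diameter_um"]),
                    perfused=None if row.get("perfused", "") in ("", None) else bool(int(row["perfused"])),
                )
            except (TypeError, ValueError) as exc:
                raise NetworkParseError(f"{path}: line {lineno}: {exc}") from exc
            for key in _SEGMENT_META_KEYS:
                if row.get(key):
                    value = row[key]
                    seg.meta[key] = int(value) if key in ("generation", "channel") else value
            network.add_segment(seg)
            for nid, xk, yk in ((seg.source, "source_x", "source_y"), (seg.target, "target_x", "target_y")):
                try:
                    coords = (_parse_optional_float(row.get(xk)), _parse_optional_float(row.get(yk)))
                except ValueError as exc:
                    raise NetworkParseError(f"{path}: line {lineno}: {exc}") from exc
                if nid not in node_coords or coords != (None, None):
                    node_coords[nid] = coords
    for nid, (x, y) in node_coords.items():
        network.add_node(Node(nid, x=x, y=y))
    return network


def _read_graphml(path: Path) -> VesselNetwork:
    try:
        g = nx.read_graphml(path, force_multigraph=True)
    except Exception as exc:  # malformed XML etc.
        raise NetworkParseError(f"{path}: {exc}") from exc
    network = VesselNetwork()
    for nid, data in g.nodes(data=True):
        network.add_node(
            Node(
                str(nid),
                x=_parse_optional_float(str(data["x"])) if "x" in data else None,
                y=_parse_optional_float(str(data["y"])) if "y" in data else None,
                role=data.get("role", "auto"),
            )
        )
    for u, v, data in g.edges(data=True):
        if "length_um" not in data or "diameter_um" not in data:
            raise NetworkParseError(f"{path}: edge {u}->{v} lacks length_um/diameter_um")
        seg = VesselSegment(
            id=str(data.get("segment_id", f"{u}->{v}")),
            source=str(u),
            target=str(v),
            length=float(data["length_um"]),
            diameter=float(data["diameter_um"]),
            perfused=None if "perfused" not in data else bool(int(data["perfused"])),
        )
        for key in _SEGMENT_META_KEYS:
            if key in data:
                seg.meta[key] = data[key]
        network.add_segment(seg)
    return network
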
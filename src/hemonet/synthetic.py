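"""Synthetic vasculature generators.

Three generators are provided:

* :func:`build_symmetric_tree` -- the Murray's-law double-tree used for the
  in-silico oxygenation experiments: one inlet vessel splits symmetrically for
  a prescribed number of generations, after which the vessels converge
  pairwise, mirror-fashion, into a single outlet vessel.  Every vessel
  satisfies ``L = lambda * d`` with a single network-wide length-to-diameter
  ratio, and child diameters follow Murray's law ``d_p^3 = 2 d_c^3``.
* :func:`build_benchmark_geometry` -- the three two-bifurcation channel
  networks (double-t, cross, extended double-t) used to characterise
  cell-free-layer memory in fully resolved red-blood-cell simulations.
* :func:`generate_morphology_table` -- synthetic per-vessel morphology tables
  with independent log-normal lengths and diameters, emulating tumour
  morphometry (right-skewed, uncorrelated L and d).

Planar embedding of the double tree
-----------------------------------
Every bifurcation of the diverging half reproduces the benchmark channel
motif: one child continues straight, the other branches off perpendicularly.
The per-generation pattern fixes where the offtake departs relative to the
parent's disrupted cell-free-layer side: ``double-t`` places consecutive
offtakes on the same side (the side branch samples the red-cell-rich margin),
``cross`` on opposite sides (the straight continuation samples it), and
``perpendicular`` marks the bifurcation plane as orthogonal to the upstream
one, suppressing the inherited asymmetry.  The default pattern is double-t
at every generation.  Branches of different subtrees may cross in the plane;
crossings carry no topological meaning.

The converging (venous) half is a translated copy of the diverging half with
all orientations reversed -- countercurrent partner vessels offset laterally
by a quarter inlet diameter -- whose deepest segments start at the shared
leaf nodes, so it is isomorphic to the reversed diverging half.  Total
segment count is ``2^(G+2) - 2`` for ``G`` diverging generations.

Cell-free-layer annotations
---------------------------
At each diverging bifurcation the generator records, per child segment, the
turn direction and the side of the child cross-section whose cell-free layer
is disrupted (thin) at birth: the side facing the sibling offtake, whose
near-wall plasma was skimmed by the sibling.  These annotations are the
geometry metadata consumed by the memory hematocrit-splitting rule; a
``perpendicular`` entry in the bifurcation pattern marks a generation's
bifurcation planes as orthogonal to the upstream ones, which suppresses the
inherited asymmetry there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .network import Node, VesselNetwork, VesselSegment, validate_network

__all__ = [
    "TreeSpec",
    "BenchmarkGeometrySpec",
    "MorphTableSpec",
    "build_symmetric_tree",
    "build_benchmark_geometry",
    "generate_morphology_table",
]

#: diameters below this are rejected (degenerate Poiseuille conductances)
MIN_DIAMETER_UM = 1.0


@dataclass(frozen=True)
class TreeSpec:
    """Specification of a symmetric Murray's-law double tree.

    ``generations`` counts diverging bifurcation levels (the inlet vessel is
    generation 0).  ``pattern`` optionally assigns each generation ``1..G`` a
    bifurcation-plane relation: ``double-t``/``cross`` (coplanar with the
    upstream bifurcation, the default) or ``perpendicular``.
    """

    lmbda: float = 4.0
    generations: int = 6
    inlet_diameter: float = 50.0
    pattern: Sequence[str] | None = None
    murray_exponent: float = 3.0
    min_diameter: float = MIN_DIAMETER_UM

    def __post_init__(self) -> None:
        if not self.lmbda > 0:
            raise ValueError("lambda must be positive")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not self.inlet_diameter > 0:
            raise ValueError("inlet diameter must be positive")
        if self.pattern is not None:
            allowed = {"double-t", "cross", "perpendicular"}
            bad = set(self.pattern) - allowed
            if bad:
                raise ValueError(f"unknown pattern entries {sorted(bad)}")
            if len(self.pattern) != self.generations:
                raise ValueError("pattern must have one entry per generation")

    def diameter(self, generation: int) -> float:
        """Murray's-law diameter of generation-``g`` vessels."""
        return self.inlet_diameter * 2.0 ** (-generation / self.murray_exponent)


def _rot(u: tuple[float, float], turn: str) -> tuple[float, float]:
    if turn == "left":
        return (-u[1], u[0])
    return (u[1], -u[0])


def default_pattern(generations: int) -> list[str]:
    """Default bifurcation pattern: the double-t motif at every generation.

    Consecutive offtakes on the same side is the canonical configuration of
    the RBC benchmark (and of densely branched tumour vasculature); ``cross``
    and ``perpendicular`` entries can be mixed in per generation.
    """
    return ["double-t"] * generations


def build_symmetric_tree(spec: TreeSpec) -> VesselNetwork:
    """Build the mirrored Murray's-law double tree described by ``spec``."""
    G = spec.generations
    d_deepest = spec.diameter(G)
    if d_deepest < spec.min_diameter:
        raise ValueError(
            f"deepest generation diameter {d_deepest:.3g} um underflows the "
            f"minimum of {spec.min_diameter:g} um"
        )
    lengths = [spec.lmbda * spec.diameter(g) for g in range(G + 1)]
    pattern = list(spec.pattern) if spec.pattern is not None else default_pattern(G)
    offset = spec.inlet_diameter / 4.0  # lateral offset of the venous twin

    net = VesselNetwork(metadata={
        "kind": "symmetric-tree",
        "lambda": spec.lmbda,
        "generations": G,
        "inlet_diameter_um": spec.inlet_diameter,
        "murray_exponent": spec.murray_exponent,
        "pattern": ",".join(pattern),
    })
    root = net.add_node(Node("inlet", x=-lengths[0], y=0.0, role="inlet"))
    net.add_node(Node("d0_0", x=0.0, y=0.0))
    net.add_segment(VesselSegment(
        "gen0", root.id, "d0_0", lengths[0], spec.diameter(0),
        meta={"generation": 0, "turn": "straight", "cfl_thin_side": "none",
              "plane_relation": "coplanar"},
    ))
    # per-segment drawing state: direction and thin-CFL side of the segment
    # feeding each bifurcation node
    state = {"d0_0": {"dir": (1.0, 0.0), "thin": "none"}}

    for g in range(1, G + 1):
        entry = pattern[g - 1]
        relation = "perpendicular" if entry == "perpendicular" else "coplanar"
        for slot in range(2 ** g):
            parent_slot = slot // 2
            pid = f"d{g - 1}_{parent_slot}"
            pstate = state[pid]
            u = pstate["dir"]
            # offtake side relative to the parent's thin-CFL side: double-t
            # repeats the upstream offtake side, cross flips it
            thin = pstate["thin"] if pstate["thin"] != "none" else "left"
            side_turn = thin if entry != "cross" else ("left" if thin == "right" else "right")
            is_side = slot % 2 == 1  # odd slots are the offtakes
            if is_side:
                child_dir = _rot(u, side_turn)
                turn = side_turn
                child_thin = "right" if turn == "left" else "left"  # outer wall
            else:
                child_dir = u
                turn = "straight"
                child_thin = side_turn  # faces the sibling offtake
            nid = f"d{g}_{slot}"
            pnode = net.nodes[pid]
            net.add_node(Node(
                nid,
                x=pnode.x + child_dir[0] * lengths[g],
                y=pnode.y + child_dir[1] * lengths[g],
            ))
            state[nid] = {"dir": child_dir, "thin": child_thin}
            net.add_segment(VesselSegment(
                f"gen{g}_{slot}", pid, nid, lengths[g], spec.diameter(g),
                meta={"generation": g, "turn": turn, "cfl_thin_side": child_thin,
                      "plane_relation": relation},
            ))

    # converging (venous) half: translated copy with reversed orientation,
    # deepest segments starting at the shared diverging leaves
    def conv_pos(nid: str) -> tuple[float, float]:
        n = net.nodes[nid]
        return (n.x + offset, n.y + offset)

    for g in range(G, 0, -1):
        for slot in range(2 ** g):
            parent_slot = slot // 2
            conv_parent_id = f"c{g - 1}_{parent_slot}"
            if conv_parent_id not in net.nodes:
                cx, cy = conv_pos(f"d{g - 1}_{parent_slot}")
                net.add_node(Node(conv_parent_id, x=cx, y=cy))
            start = f"d{G}_{slot}" if g == G else f"c{g}_{slot}"
            net.add_segment(VesselSegment(
                f"cgen{g}_{slot}", start, conv_parent_id,
                lengths[g], spec.diameter(g),
                meta={"generation": g, "turn": "merge", "cfl_thin_side": "none",
                      "plane_relation": "coplanar"},
            ))
    outlet = net.add_node(Node(
        "outlet", x=-lengths[0] + offset, y=offset, role="outlet",
    ))
    net.add_segment(VesselSegment(
        "cgen0", "c0_0", outlet.id, lengths[0], spec.diameter(0),
        meta={"generation": 0, "turn": "merge", "cfl_thin_side": "none",
              "plane_relation": "coplanar"},
    ))

    report = validate_network(net)
    assert not report, report
    return net


# ---------------------------------------------------------------------------
# benchmark channel geometries
# ---------------------------------------------------------------------------

#: (interbifurcation distance over d, side-branch angle at bifurcation 2)
_BENCHMARK_KINDS = {
    "DT": (4.0, math.pi / 2),
    "X": (4.0, 3 * math.pi / 2),
    "EDT": (25.0, math.pi / 2),
}


@dataclass(frozen=True)
class BenchmarkGeometrySpec:
    """Two-bifurcation channel network: double-t, cross or extended double-t.

    ``delta`` (interbifurcation distance) and ``alpha`` (second side-branch
    angle, clockwise from the reversed parent axis) are fixed per kind:
    DT -> (4d, pi/2), X -> (4d, 3pi/2), EDT -> (25d, pi/2).  Supplying
    inconsistent explicit values raises.
    """

    kind: str = "DT"
    diameter: float = 20.0
    delta: float | None = None
    alpha: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _BENCHMARK_KINDS:
            raise ValueError(f"unknown benchmark kind {self.kind!r}")
        if not self.diameter > 0:
            raise ValueError("channel diameter must be positive")
        delta_d, alpha = _BENCHMARK_KINDS[self.kind]
        if self.delta is not None and not math.isclose(self.delta, delta_d * self.diameter):
            raise ValueError(f"kind {self.kind}: delta must equal {delta_d:g} d")
        if self.alpha is not None and not math.isclose(self.alpha, alpha):
            raise ValueError(f"kind {self.kind}: alpha must equal {alpha:g} rad")

    @property
    def resolved_delta(self) -> float:
        return _BENCHMARK_KINDS[self.kind][0] * self.diameter

    @property
    def resolved_alpha(self) -> float:
        return _BENCHMARK_KINDS[self.kind][1]

    @property
    def interbifurcation_diameters(self) -> float:
        return _BENCHMARK_KINDS[self.kind][0]


def build_benchmark_geometry(spec: BenchmarkGeometrySpec) -> VesselNetwork:
    """Build channels 0-4 of a benchmark geometry with CFL annotations.

    Channel 0 (length 25d) feeds bifurcation 1, where channel 1 (length
    delta) continues straight and channel 2 (length 25d) branches clockwise
    by pi/2 (drawn toward -y, i.e. a right turn).  Channel 1 feeds
    bifurcation 2, where channel 3 continues straight and channel 4 branches
    at alpha (same side as channel 2 for DT/EDT, opposite for X).  Outlet
    flow fractions Q2 = Q0/2 and Q3 = Q4 = Q0/4 (equal split at each
    bifurcation) are annotated in the metadata.
    """
    d = spec.diameter
    delta = spec.resolved_delta
    long = 25.0 * d
    same_side = spec.kind in ("DT", "EDT")

    net = VesselNetwork(metadata={
        "kind": f"benchmark-{spec.kind}",
        "channel_diameter_um": d,
        "delta_um": delta,
        "alpha_rad": spec.resolved_alpha,
        "side_branch_relation": "same-side" if same_side else "opposite-side",
        "outlet_flow_fractions": {"c2": 0.5, "c3": 0.25, "c4": 0.25},
    })
    n0 = net.add_node(Node("n0", x=0.0, y=0.0, role="inlet"))
    b1 = net.add_node(Node("b1", x=long, y=0.0))
    b2 = net.add_node(Node("b2", x=long + delta, y=0.0))
    o2 = net.add_node(Node("o2", x=long, y=-long, role="outlet"))
    o3 = net.add_node(Node("o3", x=2 * long + delta, y=0.0, role="outlet"))
    y4 = -long if same_side else long
    o4 = net.add_node(Node("o4", x=long + delta, y=y4, role="outlet"))

    def seg(sid, a, b, L, channel, turn, thin):
        net.add_segment(VesselSegment(sid, a, b, L, d, meta={
            "channel": channel, "turn": turn, "cfl_thin_side": thin,
            "plane_relation": "coplanar",
        }))

    seg("c0", n0.id, b1.id, long, 0, "straight", "none")
    # bifurcation 1: channel 2 turns right (clockwise pi/2); the straight
    # channel 1 is skimmed on its right side, the turning channel 2 on its
    # left (the side facing its straight sibling)
    seg("c1", b1.id, b2.id, delta, 1, "straight", "right")
    seg("c2", b1.id, o2.id, long, 2, "right", "left")
    # bifurcation 2: channel 4 turns to the same side as channel 2 for
    # DT/EDT (right) and to the opposite side for X (left)
    turn4 = "right" if same_side else "left"
    thin3 = "right" if same_side else "left"   # faces its sibling
    thin4 = "left" if same_side else "right"
    seg("c3", b2.id, o3.id, long, 3, "straight", thin3)
    seg("c4", b2.id, o4.id, long, 4, turn4, thin4)

    report = validate_network(net)
    assert not report, report
    return net


# ---------------------------------------------------------------------------
# synthetic morphology tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorphTableSpec:
    """Log-normal per-vessel morphology table specification.

    Defaults emulate the measured MC38 allograft group means (mean length
    128.6 um, mean diameter 33.0 um) with right-skewed log-normal marginals
    and independent L and d.  ``sigma_log_*`` are log-scale standard
    deviations; the log-means are set so the arithmetic means match
    ``exp(mu + sigma^2/2)``.
    """

    n_segments: int = 1000
    mean_length: float = 128.6
    sigma_log_length: float = 0.60
    mean_diameter: float = 33.0
    sigma_log_diameter: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segments < 2:
            raise ValueError("need at least two segments")
        if min(self.mean_length, self.mean_diameter) <= 0:
            raise ValueError("means must be positive")
        if min(self.sigma_log_length, self.sigma_log_diameter) <= 0:
            raise ValueError("log-scale sigmas must be positive")

    @property
    def mu_log_length(self) -> float:
        return math.log(self.mean_length) - self.sigma_log_length**2 / 2

    @property
    def mu_log_diameter(self) -> float:
        return math.log(self.mean_diameter) - self.sigma_log_diameter**2 / 2


def generate_morphology_table(spec: MorphTableSpec) -> pd.DataFrame:
    """Draw an (L, d) table with independent log-normal marginals.

    Identical seeds yield identical tables.  Columns: ``length_um``,
    ``diameter_um``.
    """
    rng = np.random.default_rng(spec.seed)
    lengths = rng.lognormal(spec.mu_log_length, spec.sigma_log_length, spec.n_segments)
    diameters = rng.lognormal(spec.mu_log_diameter, spec.sigma_log_diameter, spec.n_segments)
    return pd.DataFrame({"length_um": lengths, "diameter_um": diameters})
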
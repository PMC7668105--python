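import pytest

from hemonet.network import BoundaryConditions, Node, VesselNetwork, VesselSegment
from hemonet.synthetic import TreeSpec, build_symmetric_tree


@pytest.fixture
def minimal_network():
    """Two nodes, one segment: the smallest valid network."""
    return VesselNetwork(
        nodes=[Node("a", x=0.0, y=0.0, role="inlet"), Node("b", x=100.0, y=0.0, role="outlet")],
        segments=[VesselSegment("s1", "a", "b", 100.0, 25.0)],
    )


@pytest.fixture
def small_tree():
    """Three-generation lambda=4 double tree (30 segments)."""
    return build_symmetric_tree(TreeSpec(lmbda=4.0, generations=3))


@pytest.fixture
def tree_bc():
    return BoundaryConditions(
        inlet_hematocrit=0.2,
        pressures={"inlet": 2000.0, "outlet": 0.0},
    )


def rbc_flux_residuals(network, flows, hematocrit):
    """Max relative red-cell flux imbalance over interior nodes."""
    worst = 0.0
    for nid in network.nodes:
        if network.node_role(nid) != "junction":
            continue
        influx = outflux = 0.0
        for seg in network.segments.values():
            q = flows[seg.id]
            h = hematocrit[seg.id]
            if seg.target == nid:
                influx += q * h if q > 0 else 0.0
                outflux += -q * h if q < 0 else 0.0
            if seg.source == nid:
                outflux += q * h if q > 0 else 0.0
                influx += -q * h if q < 0 else 0.0
        scale = max(influx, outflux, 1e-300)
        worst = max(worst, abs(influx - outflux) / scale)
    return worst
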
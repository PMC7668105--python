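"""Blood rheology and network flow.

Flow in each segment follows Poiseuille's law with an apparent viscosity
``mu(d, H) = mu_plasma * mu_rel(d, H)``, where the relative viscosity follows
the standard empirical in-vivo diameter/hematocrit parametrization of the
Fahraeus-Lindqvist effect (Pries-Secomb in-vivo law, with the 1.1-um
effective lumen reduction of the endothelial surface layer).  All viscosity
constants live in this module only.

The network flow problem is the Ohm's-law analogy: per-segment conductance
``g = pi d^4 / (128 mu L)``, Kirchhoff current balance at interior nodes,
Dirichlet pressure and/or Neumann flow boundary conditions, solved with a
sparse direct factorization.  Units: um for lengths/diameters, Pa for
pressures, Pa*s for viscosity, hence flows in um^3/s.

:func:`coupled_solve` alternates the linear flow solve with topological
hematocrit propagation (:mod:`hemonet.splitting`) under successive
substitution with under-relaxation on hematocrit, and returns a
:class:`FlowHematocritState` whose hematocrit field satisfies red-blood-cell
flux conservation exactly for the returned flow field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import BoundaryConditions, NetworkValidationError, VesselNetwork, validate_network

__all__ = [
    "ViscosityModel",
    "SolverSettings",
    "FlowHematocritState",
    "ConvergenceError",
    "relative_viscosity",
    "segment_conductance",
    "solve_flow",
    "coupled_solve",
]


class ConvergenceError(RuntimeError):
    """Outer flow-hematocrit iteration failed to converge."""

    def __init__(self, message: str, log: list | None = None):
        super().__init__(message)
        self.log = log or []


@dataclass(frozen=True)
class ViscosityModel:
    """Apparent-viscosity model.

    ``law`` is ``"pries-invivo"`` (default) or ``"constant"`` (relative
    viscosity 1 regardless of d and H; useful to decouple flow from
    hematocrit in tests).  ``plasma_viscosity`` is in Pa*s.
    """

    plasma_viscosity: float = 1.2e-3
    law: str = "pries-invivo"

    def __post_init__(self) -> None:
        if self.plasma_viscosity <= 0:
            raise ValueError("plasma viscosity must be positive")
        if self.law not in ("pries-invivo", "constant"):
            raise ValueError(f"unknown viscosity law {self.law!r}")

    def apparent_viscosity(self, diameter: float, hematocrit: float) -> float:
        """mu_plasma * mu_rel(d, H), Pa*s."""
        return self.plasma_viscosity * relative_viscosity(diameter, hematocrit, self)


def _eta_45(d: float) -> float:
    """Relative apparent viscosity at the 0.45 reference discharge hematocrit."""
    return 6.0 * math.exp(-0.085 * d) + 3.2 - 2.44 * math.exp(-0.06 * d**0.645)


def _shape_exponent(d: float) -> float:
    """Hematocrit-dependence shape exponent C(d) of the in-vivo law."""
    big = 1.0 / (1.0 + 1e-11 * d**12)
    return (0.8 + math.exp(-0.075 * d)) * (-1.0 + big) + big


def relative_viscosity(d: float, H: float, model: ViscosityModel | None = None) -> float:
    """Relative apparent blood viscosity for diameter ``d`` (um), hematocrit ``H``.

    Monotone nondecreasing in ``H`` at fixed ``d``; equals 1 for ``H = 0``
    up to the endothelial-surface-layer factor.  Raises for ``H >= 1``.
    """
    if model is not None and model.law == "constant":
        if not (0.0 <= H < 1.0):
            raise ValueError("hematocrit must lie in [0, 1)")
        return 1.0
    if d <= 0:
        raise ValueError("diameter must be positive")
    if not (0.0 <= H < 1.0):
        raise ValueError("hematocrit must lie in [0, 1)")
    wall = (d / (d - 1.1)) ** 2 if d > 1.1 else 1.0
    if H == 0.0:
        return wall
    C = _shape_exponent(d)
    frac = ((1.0 - H) ** C - 1.0) / ((1.0 - 0.45) ** C - 1.0)
    return (1.0 + (_eta_45(d) - 1.0) * frac * wall) * wall


def segment_conductance(length: float, diameter: float, viscosity: float) -> float:
    """Poiseuille conductance g = pi d^4 / (128 mu L), um^3 / (Pa s)."""
    return math.pi * diameter**4 / (128.0 * viscosity * length)


# ---------------------------------------------------------------------------
# linear flow solve
# ---------------------------------------------------------------------------

def solve_flow(
    network: VesselNetwork,
    bc: BoundaryConditions,
    hematocrit: dict[str, float] | None = None,
    model: ViscosityModel | None = None,
    settings: "SolverSettings | None" = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Solve the Ohm's-law network flow problem.

    Returns ``(pressures, flows)``: node pressures (Pa) and per-segment flows
    (um^3/s), signed with respect to segment orientation.  ``hematocrit``
    defaults to the inlet hematocrit everywhere.
    """
    report = validate_network(network)
    if report:
        raise NetworkValidationError("; ".join(report))
    model = model or ViscosityModel()
    if hematocrit is None:
        hematocrit = {sid: bc.inlet_hematocrit for sid in network.segments}

    node_ids = sorted(network.nodes)
    index = {nid: i for i, nid in enumerate(node_ids)}
    n = len(node_ids)
    unknown = [nid for nid in node_ids if nid not in bc.pressures]
    if not bc.pressures:
        raise ValueError("at least one pressure boundary condition is required")
    missing = (set(bc.pressures) | set(bc.flows)) - set(node_ids)
    if missing:
        raise ValueError(f"boundary conditions reference unknown nodes {sorted(missing)}")

    conduct = {}
    for sid, seg in network.segments.items():
        mu = model.apparent_viscosity(seg.diameter, hematocrit.get(sid, bc.inlet_hematocrit))
        conduct[sid] = segment_conductance(seg.length, seg.diameter, mu)

    # full weighted Laplacian, then restrict to non-Dirichlet nodes
    lap = sp.lil_matrix((n, n))
    for sid, seg in network.segments.items():
        i, j = index[seg.source], index[seg.target]
        g = conduct[sid]
        lap[i, i] += g
        lap[j, j] += g
        lap[i, j] -= g
        lap[j, i] -= g
    rhs = np.zeros(n)
    for nid, q in bc.flows.items():
        rhs[index[nid]] += q

    free = [index[nid] for nid in unknown]
    fixed = [index[nid] for nid in node_ids if nid in bc.pressures]
    p = np.zeros(n)
    for nid, val in bc.pressures.items():
        p[index[nid]] = val
    lap = lap.tocsr()
    if free:
        A = lap[free, :][:, free].tocsc()
        b = rhs[free] - lap[free, :][:, fixed] @ p[fixed]
        # a singular block means some component is not anchored by a pressure BC
        try:
            sol = spla.spsolve(A, b)
        except Exception as exc:
            raise RuntimeError(f"flow system could not be solved: {exc}") from exc
        if not np.all(np.isfinite(sol)):
            raise RuntimeError(
                "singular flow system: some connected component has no pressure "
                "boundary condition"
            )
        p[free] = sol

    pressures = {nid: float(p[index[nid]]) for nid in node_ids}
    flows = {
        sid: float(conduct[sid] * (p[index[seg.source]] - p[index[seg.target]]))
        for sid, seg in network.segments.items()
    }
    return pressures, flows


@dataclass(frozen=True)
class SolverSettings:
    """Outer-iteration settings for the coupled flow-hematocrit solve."""

    tolerance: float = 1e-8
    max_iterations: int = 500
    relaxation: float = 0.5
    h_max: float = 0.95
    zero_flow_fraction: float = 1e-14

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max iterations must be >= 1")
        if not (0.0 < self.relaxation <= 1.0):
            raise ValueError("relaxation factor must lie in (0, 1]")


@dataclass
class FlowHematocritState:
    """Converged per-segment flow and discharge hematocrit, per-node pressure."""

    flows: dict[str, float]
    pressures: dict[str, float]
    hematocrit: dict[str, float]
    iterations: int = 0
    converged: bool = True
    log: list = field(default_factory=list)
    warnings: list = field(default_factory=list)


def coupled_solve(
    network: VesselNetwork,
    bc: BoundaryConditions,
    hs_rule: str = "memory",
    model: ViscosityModel | None = None,
    settings: SolverSettings | None = None,
    hs_params=None,
) -> FlowHematocritState:
    """Alternate flow solves and hematocrit propagation to a joint fixed point.

    ``hs_rule`` selects the splitting rule at diverging bifurcations:
    ``proportional``, ``pries`` (no memory) or ``memory``.  Convergence is
    declared when the relative change in all flows and the absolute change
    between the current hematocrit field and its freshly propagated update
    both drop below the tolerance; the returned hematocrit is the propagated
    field, so red-cell flux balance holds exactly for the returned flows.
    When the flow field is stationary (decoupled viscosity), the hematocrit
    update takes a full step, so the decoupled limit converges in at most two
    outer iterations.
    """
    from .splitting import propagate_hematocrit  # deferred: circular import

    model = model or ViscosityModel()
    settings = settings or SolverSettings()
    H = {sid: bc.inlet_hematocrit for sid in network.segments}
    prev_flows: dict[str, float] | None = None
    prev_state_keys: list[tuple] = []
    log: list[dict] = []
    warnings: list[str] = []

    for it in range(1, settings.max_iterations + 1):
        pressures, flows = solve_flow(network, bc, H, model, settings)
        H_prop, prop_warnings = propagate_hematocrit(
            network, flows, bc.inlet_hematocrit, hs_rule,
            params=hs_params, settings=settings, return_warnings=True,
        )
        capped = [sid for sid, h in H_prop.items() if h > settings.h_max]
        for sid in capped:
            H_prop[sid] = settings.h_max
            warnings.append(f"iteration {it}: hematocrit capped at {settings.h_max} in {sid}")
        warnings.extend(prop_warnings)

        q_scale = max((abs(q) for q in flows.values()), default=1.0) or 1.0
        dq = 0.0 if prev_flows is None else max(
            abs(flows[sid] - prev_flows[sid]) for sid in flows
        ) / q_scale
        dh = max(abs(H_prop[sid] - H[sid]) for sid in H_prop)
        log.append({"iteration": it, "dq": dq, "dh": dh})

        flow_stationary = prev_flows is not None and dq < settings.tolerance
        if dh < settings.tolerance and (prev_flows is None or flow_stationary):
            return FlowHematocritState(flows, pressures, H_prop, it, True, log, warnings)

        # oscillation detection: exact recurrence of an earlier iterate
        key = tuple(round(H_prop[sid], 12) for sid in sorted(H_prop))
        if key in prev_state_keys[:-1]:
            raise ConvergenceError(
                f"oscillating hematocrit iteration detected at iteration {it}", log
            )
        prev_state_keys.append(key)

        # full replacement on the first pass and whenever flow is stationary
        # (no feedback to damp); under-relaxation engages in between
        omega = 1.0 if (prev_flows is None or flow_stationary) else settings.relaxation
        H = {sid: H[sid] + omega * (H_prop[sid] - H[sid]) for sid in H_prop}
        prev_flows = flows

    raise ConvergenceError(
        f"no convergence after {settings.max_iterations} outer iterations "
        f"(last dq={log[-1]['dq']:.3g}, dh={log[-1]['dh']:.3g})",
        log,
    )
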
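"""Vessel-morphometry statistics.

The central metric is the network length-to-diameter ratio

    lambda = sum(L_i) / sum(d_i) = Lbar / dbar,

computed over all vessel segments of a network; low lambda means the
cell-free layer cannot recover symmetry between consecutive bifurcations.
Additional metrics: bifurcation density (branch points per unit area) and
the perfused fraction among vessels below a diameter cutoff.

Display values are rounded half-away-from-zero to one decimal; rounding is
presentation-only and never feeds back into computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .network import VesselNetwork

__all__ = [
    "MorphologySummary",
    "GroupSummary",
    "summarize_network",
    "group_average",
    "bifurcation_density",
    "perfused_fraction",
    "lambda_ratio",
    "display_round",
    "load_allograft_morphometry",
]


def display_round(x: float, decimals: int = 1) -> float:
    """Round half away from zero at the given decimal (display convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def lambda_ratio(mean_length: float, mean_diameter: float) -> float:
    """lambda = Lbar / dbar (full precision; round for display only)."""
    if mean_length <= 0 or mean_diameter <= 0:
        raise ValueError("means must be positive")
    return mean_length / mean_diameter


@dataclass(frozen=True)
class MorphologySummary:
    """Per-network morphometry: n, Lbar, dbar, lambda, Pearson r^2(L, d)."""

    n_segments: int
    mean_length: float
    mean_diameter: float
    lmbda: float
    r_squared: float | None

    @property
    def lambda_display(self) -> float:
        return display_round(self.lmbda, 1)


@dataclass(frozen=True)
class GroupSummary:
    """Group (e.g. cell-line) averages of per-network summaries.

    The group lambda is the arithmetic mean of per-network lambda values,
    not the ratio of group-mean length to group-mean diameter.
    """

    summaries: tuple[MorphologySummary, ...]
    mean_length: float
    mean_diameter: float
    mean_lambda: float


def _as_table(data) -> pd.DataFrame:
    if isinstance(data, VesselNetwork):
        rows = [
            {"length_um": s.length, "diameter_um": s.diameter, "perfused": s.perfused}
            for s in data.segments.values()
        ]
        return pd.DataFrame(rows)
    return pd.DataFrame(data)


def summarize_network(data) -> MorphologySummary:
    """Summarize a vessel table (or network): Lbar, dbar, lambda, r^2.

    ``lambda = sum(L)/sum(d)``, identical to ``Lbar/dbar`` over the same
    rows.  Raises on empty tables or nonpositive entries.
    """
    table = _as_table(data)
    if table.empty:
        raise ValueError("empty vessel table")
    L = table["length_um"].to_numpy(dtype=float)
    d = table["diameter_um"].to_numpy(dtype=float)
    if np.any(L <= 0) or np.any(d <= 0):
        raise ValueError("vessel lengths and diameters must be positive")
    r2 = None
    if len(L) >= 2 and np.std(L) > 0 and np.std(d) > 0:
        r2 = float(np.corrcoef(L, d)[0, 1] ** 2)
    return MorphologySummary(
        n_segments=len(L),
        mean_length=float(np.mean(L)),
        mean_diameter=float(np.mean(d)),
        lmbda=float(np.sum(L) / np.sum(d)),
        r_squared=r2,
    )


def group_average(summaries: Sequence[MorphologySummary]) -> GroupSummary:
    """Arithmetic means of Lbar, dbar and lambda across networks."""
    if not summaries:
        raise ValueError("need at least one summary")
    return GroupSummary(
        summaries=tuple(summaries),
        mean_length=float(np.mean([s.mean_length for s in summaries])),
        mean_diameter=float(np.mean([s.mean_diameter for s in summaries])),
        mean_lambda=float(np.mean([s.lmbda for s in summaries])),
    )


def bifurcation_density(network: VesselNetwork, region_area: float) -> float:
    """Branch points (degree >= 3 nodes) per unit area (um^-2)."""
    if not region_area > 0:
        raise ValueError("region area must be positive")
    count = 0
    for nid in network.nodes:
        degree = len(network.in_segments(nid)) + len(network.out_segments(nid))
        if degree >= 3:
            count += 1
    return count / region_area


def perfused_fraction(table, diameter_cutoff: float = 50.0) -> float:
    """Fraction of perfused vessels among those with d < cutoff.

    Requires a ``perfused`` flag on every row; raises if no vessel falls
    below the cutoff (undefined fraction).
    """
    df = _as_table(table)
    if "perfused" not in df.columns or df["perfused"].isna().any():
        raise ValueError("perfusion flags are required for every vessel")
    small = df[df["diameter_um"] < diameter_cutoff]
    if small.empty:
        raise ValueError(f"no vessels with diameter below {diameter_cutoff:g} um")
    return float(small["perfused"].astype(bool).mean())


def load_allograft_morphometry() -> pd.DataFrame:
    """Shipped per-mouse tumour-allograft morphometry means.

    Columns: ``cell_line``, ``mouse``, ``mean_length_um``,
    ``mean_diameter_um`` -- last-day per-mouse averages over all imaged
    vessels for the MC38, B16F10 and LLC allograft groups.
    """
    with resources.files("hemonet.data").joinpath("allograft_morphometry.csv").open() as fh:
        return pd.read_csv(fh)
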
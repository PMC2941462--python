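"""Interfacial water coordination and per-bond hydration parameters.

From explicit-solvent frames this module builds the water-water hydrogen
bond graph (O-O < 3.2 Å with an O-H-O angle in [120°, 180°]), from which
each molecule's coordination number g is its graph degree.  Per backbone
hydrogen bond it records d_min — the minimum carbonyl-O to water-O
distance — and g_min, the coordination of the water realizing it, both
averaged over frames.  The coordination field g(r) averages g inside a
2.5 Å ball (one water layer) around query positions.  The action functional
A[g] = Σ_j Σ_{n∈M(j)} (g_j − g_n)² penalizes coordination differences
between hydrogen-bonded neighbors; it vanishes exactly when g is constant
on every connected component, expressing the low coordination resilience
of water.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .bhb_wrapping import BackboneHydrogenBond
from .structure_model import SolventFrame, StructureError

logger = logging.getLogger(__name__)

__all__ = [
    "WaterHBGraph",
    "CoordinationField",
    "HydrationRecord",
    "ActionValue",
    "water_hb_graph",
    "coordination_field",
    "bhb_hydration",
    "theta_profiles",
    "action",
    "OO_CUTOFF",
    "HB_ANGLE_RANGE",
    "FIELD_RADIUS",
]

OO_CUTOFF = 3.2  # Å, water-water O-O distance
HB_ANGLE_RANGE = (120.0, 180.0)  # degrees, O-H-O angle at the hydrogen
FIELD_RADIUS = 2.5  # Å, single water layer around a query position


@dataclass
class WaterHBGraph:
    """Hydrogen-bond graph of one solvent frame; g(j) = degree of water j."""

    frame_index: int
    graph: nx.Graph
    distance_only: bool = False

    @property
    def g(self) -> np.ndarray:
        return np.array([self.graph.degree(j) for j in sorted(self.graph.nodes)])

    @property
    def edges(self) -> list[tuple[int, int]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def coordination(self, j: int) -> int:
        return int(self.graph.degree(j))


def _hb_angle_ok(
    o_donor: np.ndarray,
    h: np.ndarray,
    o_acceptor: np.ndarray,
    lo: float,
    hi: float,
) -> bool:
    """O-H-O angle at the hydrogen within [lo, hi] degrees."""
    u = o_donor - h
    v = o_acceptor - h
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-9 or nv < 1e-9:
        return False
    c = float(np.dot(u, v) / (nu * nv))
    ang = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
    return lo <= ang <= hi


def water_hb_graph(
    frame: SolventFrame,
    oo_cutoff: float = OO_CUTOFF,
    angle_range: tuple[float, float] = HB_ANGLE_RANGE,
    distance_only: bool = False,
) -> WaterHBGraph:
    """Build the water-water hydrogen-bond graph of one frame.

    An edge joins waters j and n when their O-O distance is below
    ``oo_cutoff`` and at least one of the four O-H...O arrangements (either
    hydrogen of either molecule as donor) has its O-H-O angle inside
    ``angle_range``.  ``distance_only=True`` drops the angle test for
    hydrogen-free trajectories; the result is flagged.
    """
    if frame.n_waters == 0:
        return WaterHBGraph(
            frame_index=frame.frame_index, graph=nx.Graph(), distance_only=distance_only
        )
    if not distance_only and not frame.has_hydrogens:
        raise StructureError(
            "frame carries no hydrogens; pass distance_only=True to use the "
            "distance-only fallback criterion"
        )
    o = frame.oxygens
    graph = nx.Graph()
    graph.add_nodes_from(range(len(o)))
    if len(o) >= 2:
        pairs = cKDTree(o).query_pairs(oo_cutoff, output_type="ndarray")
        lo, hi = angle_range
        for j, n in pairs:
            if float(np.linalg.norm(o[j] - o[n])) >= oo_cutoff:
                continue  # strict inequality at the cutoff
            if distance_only:
                graph.add_edge(int(j), int(n))
                continue
            bonded = False
            for donor, acceptor in ((j, n), (n, j)):
                for h in frame.hydrogens[donor]:
                    if np.all(np.isfinite(h)) and _hb_angle_ok(
                        o[donor], h, o[acceptor], lo, hi
                    ):
                        bonded = True
                        break
                if bonded:
                    break
            if bonded:
                graph.add_edge(int(j), int(n))
    return WaterHBGraph(
        frame_index=frame.frame_index, graph=graph, distance_only=distance_only
    )


@dataclass
class CoordinationField:
    """Frame-averaged coordination g(r) at query positions."""

    queries: np.ndarray  # (q, 3)
    radius: float
    g_of_r: np.ndarray  # (q,), NaN where no water ever enters the ball
    n_contributions: np.ndarray  # (q,) count of (frame, water) pairs

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.g_of_r)


def coordination_field(
    frames: list[SolventFrame],
    queries: np.ndarray,
    radius: float = FIELD_RADIUS,
    graphs: list[WaterHBGraph] | None = None,
    distance_only: bool = False,
) -> CoordinationField:
    """Compute the scalar field g(r) over ``queries``.

    For each query the per-frame value is the mean coordination of waters
    whose oxygen lies within ``radius``; g(r) is the arithmetic mean over
    frames in which the ball is occupied.  Queries never visited by a water
    get NaN.
    """
    if not frames:
        raise ValueError("at least one solvent frame required")
    queries = np.asarray(queries, dtype=float).reshape(-1, 3)
    if graphs is None:
        graphs = [water_hb_graph(fr, distance_only=distance_only) for fr in frames]
    sums = np.zeros(len(queries))
    frames_hit = np.zeros(len(queries), dtype=int)
    contribs = np.zeros(len(queries), dtype=int)
    for fr, gr in zip(frames, graphs):
        if fr.n_waters == 0:
            continue
        tree = cKDTree(fr.oxygens)
        g = gr.g
        for qi, hits in enumerate(tree.query_ball_point(queries, radius)):
            if hits:
                sums[qi] += float(np.mean(g[hits]))
                frames_hit[qi] += 1
                contribs[qi] += len(hits)
    g_of_r = np.where(frames_hit > 0, sums / np.maximum(frames_hit, 1), np.nan)
    return CoordinationField(
        queries=queries, radius=radius, g_of_r=g_of_r, n_contributions=contribs
    )


@dataclass
class HydrationRecord:
    """Equilibrium hydration parameters of one backbone hydrogen bond."""

    bond: BackboneHydrogenBond
    d_min: float  # Å, frame-averaged closest water-O distance to carbonyl O
    g_min: float  # frame-averaged coordination of the closest water
    n_frames: int
    per_frame: pd.DataFrame = field(repr=False, default=None)


def bhb_hydration(
    bond: BackboneHydrogenBond,
    frames: list[SolventFrame],
    graphs: list[WaterHBGraph] | None = None,
    distance_only: bool = False,
) -> HydrationRecord:
    """Record d_min and g_min for ``bond`` over solvent frames.

    Per frame, d is the minimum distance from the bond's carbonyl oxygen to
    any water oxygen and g the coordination of the water realizing it
    (nearest-O tie broken toward the lowest water index); d_min and g_min
    are plain means over frames.  Waterless frames are skipped and logged.
    """
    o_pos = bond.carbonyl_o.position
    if graphs is None:
        graphs = [water_hb_graph(fr, distance_only=distance_only) for fr in frames]
    rows = []
    for fr, gr in zip(frames, graphs):
        if fr.n_waters == 0:
            logger.info("frame %d has no waters; skipped", fr.frame_index)
            continue
        d = np.linalg.norm(fr.oxygens - o_pos, axis=1)
        j = int(np.argmin(d))  # np.argmin returns the lowest index on ties
        rows.append(
            {"frame": fr.frame_index, "d": float(d[j]), "g": gr.coordination(j)}
        )
    if not rows:
        raise StructureError(f"no frames with waters for bond {bond.label}")
    per_frame = pd.DataFrame(rows)
    return HydrationRecord(
        bond=bond,
        d_min=float(per_frame["d"].mean()),
        g_min=float(per_frame["g"].mean()),
        n_frames=len(per_frame),
        per_frame=per_frame,
    )


def theta_profiles(
    records: list[HydrationRecord], bin_width: float = 0.25
) -> pd.DataFrame:
    """Mean d_min and g_min per ¼ Å θ bin (the curvature-hydration profile).

    Bonds are grouped by their summary θ coarse-grained to ``bin_width``;
    bonds without a θ (buried) are dropped, and empty bins are omitted.
    Columns: theta_bin (left edge), mean_d_min, mean_g_min, n_bonds.
    """
    rows = [
        {
            "theta": r.bond.summary_theta,
            "d_min": r.d_min,
            "g_min": r.g_min,
        }
        for r in records
        if r.bond.summary_theta is not None
    ]
    if not rows:
        return pd.DataFrame(columns=["theta_bin", "mean_d_min", "mean_g_min", "n_bonds"])
    df = pd.DataFrame(rows)
    df["theta_bin"] = np.floor(df["theta"] / bin_width) * bin_width
    out = (
        df.groupby("theta_bin")
        .agg(mean_d_min=("d_min", "mean"), mean_g_min=("g_min", "mean"), n_bonds=("d_min", "size"))
        .reset_index()
        .sort_values("theta_bin", ignore_index=True)
    )
    return out


@dataclass
class ActionValue:
    """Water-coordination action of one frame."""

    frame_index: int
    A: float


def action(graph: WaterHBGraph, normalization: float = 1.0) -> ActionValue:
    """Evaluate A[g] = Σ_j Σ_{n∈M(j)} (g_j − g_n)² on one frame's HB graph.

    Every ordered neighbor pair contributes, so each edge is counted twice
    (symmetric double counting).  A ≥ 0, with equality exactly when g is
    constant on each connected component.
    """
    g = {j: graph.graph.degree(j) for j in graph.graph.nodes}
    total = 0.0
    for j, n in graph.graph.edges:
        total += 2.0 * (g[j] - g[n]) ** 2
    return ActionValue(frame_index=graph.frame_index, A=normalization * total)
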
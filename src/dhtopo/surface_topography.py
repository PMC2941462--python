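"""Solvent-accessible envelope and osculating-sphere curvature spectra.

The protein envelope is the surface traced by the center of a 1.4 Å probe
rolling over van der Waals spheres.  It is sampled here as a quasi-uniform
dot surface (points on the non-buried patches of each atom's inflated
sphere).  At every sample point a sphere is fit by linear least squares to
the surrounding envelope patch; its radius θ is the local osculating-sphere
curvature radius, signed positive for concave regions (sphere center on the
solvent side — a water-confining cavity) and negative for convex ones.
Sub-nanoscale spectra keep 0 < θ < 10 Å, coarse-grained to ¼ Å bins, and
are attached to each backbone hydrogen bond through the surface groups
within 3 Å of the bond baricenter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .bhb_wrapping import BackboneHydrogenBond
from .data import PROBE_RADIUS
from .structure_model import ProteinStructure, StructureError

logger = logging.getLogger(__name__)

__all__ = [
    "SurfacePoint",
    "Envelope",
    "CurvatureSpectrum",
    "build_envelope",
    "estimate_theta",
    "fit_sphere",
    "bhb_vicinity_spectrum",
    "protein_theta_spectrum",
    "theta_histogram",
    "THETA_BIN_WIDTH",
    "SUBNANO_THETA_MAX",
    "FLATNESS_CUTOFF",
    "DEFAULT_POINT_SPACING",
    "DEFAULT_PATCH_RADIUS",
    "DEFAULT_VICINITY_RADIUS",
]

THETA_BIN_WIDTH = 0.25  # Å, figure coarse-graining
SUBNANO_THETA_MAX = 10.0  # Å, sub-nanoscale ruggedness bound
FLATNESS_CUTOFF = 20.0  # Å, |θ| beyond this is reported flat
DEFAULT_POINT_SPACING = 0.5  # Å between envelope sample points
DEFAULT_PATCH_RADIUS = 2.5  # Å, sphere-fit neighborhood
DEFAULT_VICINITY_RADIUS = 3.0  # Å around the bond baricenter
_CONDITION_LIMIT = 1e8  # degenerate-patch detection


@dataclass
class SurfacePoint:
    """One envelope sample with its signed curvature radius."""

    position: np.ndarray
    normal: np.ndarray
    parent_atom_index: int
    theta: float | None = None  # None: flat or not yet estimated


@dataclass
class Envelope:
    """Dot-sampled solvent-accessible envelope (structure of arrays).

    ``theta`` is NaN where flat or unestimated; ``parent_atom`` indexes
    ``atom_coords`` (the heavy atoms whose inflated spheres generated the
    points).
    """

    positions: np.ndarray  # (n, 3)
    normals: np.ndarray  # (n, 3) outward unit
    parent_atom: np.ndarray  # (n,) int
    atom_coords: np.ndarray  # (m, 3)
    point_area: np.ndarray  # (n,) Å² represented per point
    theta: np.ndarray | None = None  # (n,) signed radius, NaN = flat

    @property
    def n_points(self) -> int:
        return len(self.positions)

    def points(self) -> list[SurfacePoint]:
        th = self.theta
        return [
            SurfacePoint(
                position=self.positions[i],
                normal=self.normals[i],
                parent_atom_index=int(self.parent_atom[i]),
                theta=None if th is None or not np.isfinite(th[i]) else float(th[i]),
            )
            for i in range(self.n_points)
        ]

    @property
    def total_area(self) -> float:
        """Accessible surface area estimate (sum of per-point areas)."""
        return float(self.point_area.sum())


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit directions (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def build_envelope(
    structure: ProteinStructure,
    probe_radius: float = PROBE_RADIUS,
    point_spacing: float = DEFAULT_POINT_SPACING,
) -> Envelope:
    """Sample the solvent-accessible envelope of ``structure``.

    Each heavy atom is inflated to vdW + probe radius and its sphere is
    covered with a golden-spiral lattice of pitch ``point_spacing``; points
    buried inside a neighboring atom's inflated sphere are dropped.  Normals
    are radial from the parent atom; each retained point carries the patch
    area it represents.
    """
    heavy = [a for a in structure.atoms if a.element.upper() != "H"]
    if not heavy:
        raise StructureError("empty structure: no heavy atoms")
    centers = np.array([a.position for a in heavy])
    radii = np.array([a.vdw_radius + probe_radius for a in heavy])
    tree = cKDTree(centers)
    r_max = float(radii.max())

    pos_out, nrm_out, parent_out, area_out = [], [], [], []
    for i, (c, r) in enumerate(zip(centers, radii)):
        n_pts = max(12, int(round(4.0 * np.pi * r * r / point_spacing**2)))
        dirs = _fibonacci_sphere(n_pts)
        pts = c + r * dirs
        neighbors = [j for j in tree.query_ball_point(c, r + r_max) if j != i]
        keep = np.ones(n_pts, dtype=bool)
        if neighbors:
            nc = centers[neighbors]
            nr = radii[neighbors]
            # buried iff strictly inside a neighbor's inflated sphere
            d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            keep = ~np.any(d2 < (nr**2 - 1e-9)[None, :], axis=1)
        if not np.any(keep):
            continue
        pos_out.append(pts[keep])
        nrm_out.append(dirs[keep])
        parent_out.append(np.full(int(keep.sum()), i))
        area_out.append(np.full(int(keep.sum()), 4.0 * np.pi * r * r / n_pts))

    if not pos_out:
        raise StructureError("structure has no accessible surface")
    return Envelope(
        positions=np.vstack(pos_out),
        normals=np.vstack(nrm_out),
        parent_atom=np.concatenate(parent_out),
        atom_coords=centers,
        point_area=np.concatenate(area_out),
    )


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Algebraic (Coope) least-squares sphere fit.

    Solves ``|p|² = 2 c·p + k`` linearly for the center c and
    k = R² − |c|².  Returns (center, radius) or None for a degenerate
    (coplanar/collinear) patch.
    """
    p = np.asarray(points, dtype=float)
    if len(p) < 4:
        return None
    mean = p.mean(axis=0)
    q = p - mean  # center the patch for conditioning
    a = np.column_stack([2.0 * q, np.ones(len(q))])
    b = (q**2).sum(axis=1)
    ata = a.T @ a
    eig = np.linalg.eigvalsh(ata)
    if eig[0] <= 0 or eig[-1] / eig[0] > _CONDITION_LIMIT:
        return None
    sol = np.linalg.solve(ata, a.T @ b)
    c_local = sol[:3]
    r2 = sol[3] + (c_local**2).sum()
    if r2 <= 0:
        return None
    return c_local + mean, float(np.sqrt(r2))


def tangent_sphere_radii(
    point: np.ndarray, normal: np.ndarray, neighbors: np.ndarray
) -> np.ndarray:
    """Signed radii of spheres tangent at ``point`` through each neighbor.

    The sphere tangent to the surface at p (center on the normal line)
    passing through q has signed radius |q − p|² / (2 n·(q − p)):
    positive when q lies on the solvent side of the tangent plane
    (concave surface), negative on the protein side (convex).  Exact for
    every neighbor on a spherical patch, whatever the sampling.
    Near-tangent-plane neighbors give ±inf: flatness votes.
    """
    d = neighbors - point
    dist2 = (d * d).sum(axis=1)
    proj = d @ normal
    with np.errstate(divide="ignore", invalid="ignore"):
        radii = dist2 / (2.0 * proj)
    radii[np.isnan(radii)] = np.inf
    return radii


def estimate_theta(
    envelope: Envelope,
    patch_radius: float = DEFAULT_PATCH_RADIUS,
    min_patch_points: int = 6,
    flatness_cutoff: float = FLATNESS_CUTOFF,
    adaptive: bool = True,
    min_neighbor_sep: float | None = None,
) -> Envelope:
    """Fill ``envelope.theta`` with signed osculating-sphere radii.

    For every sample point, a sphere is least-squares fit to the envelope
    points within ``patch_radius``.  θ is its radius, positive when the
    fitted center lies on the solvent side of the point (concave cavity),
    negative on the protein side (convex bump).  Patches that are too
    sparse, degenerate, or flatter than ``flatness_cutoff`` get NaN.

    The radius at each point is the median of tangent-sphere radii over
    the patch annulus (same-scallop neighbors within ``min_neighbor_sep``
    are excluded, since they sample the generating atom sphere rather
    than the envelope shape).  With ``adaptive`` (default), each point is
    fit on an ascending ladder of patch scales, accepting the smallest
    scale whose |θ| is resolvable there (|θ| ≤ 2.5 × scale) with a tight
    vote spread; cavities smaller than the default patch are thus not
    washed out by their surroundings, while near-flat regions — whose
    small-scale radii are far larger than the patch — fall through to the
    full-patch estimate.
    """
    pts = envelope.positions
    nrm = envelope.normals
    tree = cKDTree(pts)
    theta = np.full(envelope.n_points, np.nan)

    # local point pitch: sampling resolution of the envelope
    nn_d, _ = tree.query(pts[:: max(1, envelope.n_points // 200)], k=2)
    pitch = float(np.median(nn_d[:, 1]))
    if min_neighbor_sep is None:
        min_neighbor_sep = max(2.0 * pitch, 0.4)

    def _fit_at(i: int, radius_i: float) -> tuple[float, float]:
        nbrs = np.asarray(tree.query_ball_point(pts[i], radius_i), dtype=int)
        d2 = ((pts[nbrs] - pts[i]) ** 2).sum(axis=1)
        nbrs = nbrs[d2 >= min_neighbor_sep**2]
        if len(nbrs) < min_patch_points:
            return np.nan, np.inf
        votes = tangent_sphere_radii(pts[i], nrm[i], pts[nbrs])
        med = float(np.median(votes))
        if not np.isfinite(med) or abs(med) > flatness_cutoff:
            return np.nan, np.inf
        finite = votes[np.isfinite(votes)]
        spread = float(np.median(np.abs(finite - med)))
        return med, spread

    scales = [patch_radius]
    if adaptive:
        r = max(min_neighbor_sep * 1.5, 3.0 * pitch, 0.6)
        ladder = []
        while r < patch_radius * 0.95:
            ladder.append(r)
            r *= 1.6
        scales = ladder + scales

    # accept a scale when |θ| is resolvable there and the votes agree
    accept_factor = 2.5
    spread_frac = 0.35
    for i in range(envelope.n_points):
        for k, r_k in enumerate(scales):
            t, spread = _fit_at(i, r_k)
            terminal = k == len(scales) - 1
            trusted = (
                np.isfinite(t)
                and abs(t) <= accept_factor * r_k
                and spread <= spread_frac * abs(t)
            )
            if trusted:
                theta[i] = t
                break
            if terminal:
                # flat or irregular at every scale
                theta[i] = t if np.isfinite(t) and spread <= spread_frac * abs(t) else np.nan
    envelope.theta = theta
    return envelope


def theta_histogram(
    thetas: np.ndarray,
    bin_width: float = THETA_BIN_WIDTH,
    theta_max: float = SUBNANO_THETA_MAX,
) -> tuple[np.ndarray, np.ndarray]:
    """Counts of concave sub-nanoscale θ in ¼ Å bins: (edges, counts)."""
    edges = np.arange(0.0, theta_max + bin_width / 2, bin_width)
    vals = np.asarray(thetas, dtype=float)
    vals = vals[np.isfinite(vals) & (vals > 0) & (vals < theta_max)]
    counts, _ = np.histogram(vals, bins=edges)
    return edges, counts


@dataclass
class CurvatureSpectrum:
    """θ values collected for one bond vicinity or a pooled bond class."""

    label: str
    thetas: np.ndarray
    summary_theta: float | None = None
    buried: bool = False
    bond: BackboneHydrogenBond | None = None
    bin_width: float = THETA_BIN_WIDTH
    theta_max: float = SUBNANO_THETA_MAX

    def histogram(self) -> tuple[np.ndarray, np.ndarray]:
        return theta_histogram(self.thetas, self.bin_width, self.theta_max)

    def density(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit-mass histogram (edges, probability per bin)."""
        edges, counts = self.histogram()
        total = counts.sum()
        return edges, counts / total if total else counts.astype(float)

    @property
    def concave(self) -> np.ndarray:
        t = self.thetas[np.isfinite(self.thetas)]
        return t[t > 0]


def _summary_theta(thetas: np.ndarray) -> float | None:
    """One θ per bond: median of concave values, else median of all."""
    t = thetas[np.isfinite(thetas)]
    if t.size == 0:
        return None
    concave = t[t > 0]
    return float(np.median(concave)) if concave.size else float(np.median(t))


def bhb_vicinity_spectrum(
    bond: BackboneHydrogenBond,
    envelope: Envelope,
    vicinity_radius: float = DEFAULT_VICINITY_RADIUS,
) -> CurvatureSpectrum:
    """Collect θ of envelope points vicinal to ``bond``.

    A point is vicinal when its parent atom lies within ``vicinity_radius``
    of the bond baricenter.  A bond with no such exposed points is buried
    (empty spectrum, flagged).  Sets ``bond.summary_theta`` and
    ``bond.buried``.
    """
    if envelope.theta is None:
        raise StructureError("θ not estimated; run estimate_theta() first")
    atom_d = np.linalg.norm(envelope.atom_coords - bond.baricenter, axis=1)
    vicinal_atoms = np.nonzero(atom_d <= vicinity_radius)[0]
    mask = np.isin(envelope.parent_atom, vicinal_atoms)
    thetas = envelope.theta[mask]
    thetas = thetas[np.isfinite(thetas)]
    spectrum = CurvatureSpectrum(
        label=bond.label,
        thetas=thetas,
        summary_theta=_summary_theta(thetas),
        buried=thetas.size == 0,
        bond=bond,
    )
    bond.summary_theta = spectrum.summary_theta
    bond.buried = spectrum.buried
    return spectrum


def protein_theta_spectrum(
    spectra: list[CurvatureSpectrum],
) -> tuple[CurvatureSpectrum, CurvatureSpectrum]:
    """Pool per-bond spectra into (all-BHB, EBHB-only) class spectra.

    Pooling concatenates vicinal θ multisets, so the all-BHB histogram is
    exactly the EBHB histogram plus the well-wrapped histogram bin by bin.
    """
    all_t = [s.thetas for s in spectra]
    ebhb_t = [s.thetas for s in spectra if s.bond is not None and s.bond.is_ebhb]
    bhb = CurvatureSpectrum(
        label="BHB",
        thetas=np.concatenate(all_t) if all_t else np.empty(0),
    )
    ebhb = CurvatureSpectrum(
        label="EBHB",
        thetas=np.concatenate(ebhb_t) if ebhb_t else np.empty(0),
    )
    return bhb, ebhb
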
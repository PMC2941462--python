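"""Synthetic fixtures with known ground truth for every pipeline stage.

Generators for: ideal polyalanine helices with a known i -> i+4 bond set;
single-bond structures with an exact prescribed wrapping count; atom shells
whose accessible envelope contains a spherical pit of prescribed curvature
radius θ*; water lattices of prescribed uniform hydrogen-bond coordination
g*; and jointly solvated bonds whose nearest water sits at a prescribed
distance d* with coordination g*.  All generators are deterministic under
their seed and serialize to ordinary PDB/XYZ.

These fixtures encode geometry and statistics only — they are not
physically realistic solvent or protein models.  The solvated-bond
generator optionally applies a water-exclusion placement rule: a cavity of
curvature radius θ* below 4.5 Å cannot host a water molecule together with
its g = 3 coordination shell, so the nearest water is placed at the cavity
mouth (5 Å standoff) instead of at hydration contact (3 Å).
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

from .data import PROBE_RADIUS
from .structure_model import (
    AtomRecord,
    ProteinStructure,
    Residue,
    SolventFrame,
    classify_nonpolar_groups,
    place_amide_hydrogens,
)

__all__ = [
    "make_helix",
    "make_wrapped_bond",
    "make_cavity_surface",
    "make_water_lattice",
    "make_solvated_bond",
    "water_standoff",
    "PENETRATION_THETA",
    "HYDRATION_CONTACT",
    "MOUTH_STANDOFF",
]

# Ideal backbone geometry (Å, degrees)
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_B_CA_CB = 1.530
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_A_CA_C_O = 120.8
_A_N_CA_CB = 110.5

PHI_HELIX = -57.0
PSI_HELIX = -47.0
OMEGA_TRANS = 180.0

#: Curvature radius above which a cavity admits a water plus its g = 3 shell.
PENETRATION_THETA = 4.5
#: Å, carbonyl-O to water-O distance at hydration contact.
HYDRATION_CONTACT = 3.0
#: Å, standoff of the excluded water at a sub-penetration cavity mouth.
MOUTH_STANDOFF = 5.0

_OO = 2.75  # lattice O-O spacing, inside the 3.2 Å bond cutoff with jitter margin
_JITTER_CLIP = 0.12  # Å per axis; keeps jittered O-O below 3.2 and angles above 120°


def _nerf(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float
) -> np.ndarray:
    """Place atom d from internal coordinates (natural extension frame)."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _atom(name, element, res: Residue, pos, serial=0) -> AtomRecord:
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        residue_name=res.name,
        residue_index=res.number,
        chain_id=res.chain_id,
        position=np.asarray(pos, dtype=float),
    )


def make_helix(
    n_residues: int,
    seed: int = 0,
    residue_name: str = "ALA",
    phi: float = PHI_HELIX,
    psi: float = PSI_HELIX,
) -> ProteinStructure:
    """Ideal α-helix (φ = −57°, ψ = −47°) with standard bond geometry.

    Polyalanine by default (``residue_name='GLY'`` drops Cβ).  The i -> i+4
    backbone hydrogen-bond ladder is the known ground truth: n − 4
    candidate bonds.  The build is fully deterministic; ``seed`` is part of
    the fixture signature but unused.
    """
    if n_residues < 5:
        raise ValueError("a helix fixture needs at least 5 residues")
    del seed
    # seed coordinates of residue 1
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = n0 + np.array([_B_N_CA, 0.0, 0.0])
    c0 = _nerf(
        n0 + np.array([0.0, 1.0, 0.0]), n0, ca0, _B_CA_C, _A_N_CA_C, phi + 60.0
    )
    backbone: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = [(n0, ca0, c0)]
    for _ in range(1, n_residues):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_i = _nerf(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psi)
        ca_i = _nerf(ca_prev, c_prev, n_i, _B_N_CA, _A_C_N_CA, OMEGA_TRANS)
        c_i = _nerf(c_prev, n_i, ca_i, _B_CA_C, _A_N_CA_C, phi)
        backbone.append((n_i, ca_i, c_i))

    structure = ProteinStructure()
    for i, (n_i, ca_i, c_i) in enumerate(backbone):
        res = Residue(chain_id="A", number=i + 1, name=residue_name, seq_pos=i)
        res.atoms["N"] = _atom("N", "N", res, n_i)
        res.atoms["CA"] = _atom("CA", "C", res, ca_i)
        res.atoms["C"] = _atom("C", "C", res, c_i)
        # carbonyl O in the peptide plane, anti to the next amide nitrogen
        res.atoms["O"] = _atom("O", "O", res, _nerf(n_i, ca_i, c_i, _B_C_O, _A_CA_C_O, psi - 180.0))
        if residue_name != "GLY":
            res.atoms["CB"] = _atom("CB", "C", res, _cb_position(n_i, ca_i, c_i))
        structure.residues.append(res)
    return structure


def _cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    u1 = (n - ca) / np.linalg.norm(n - ca)
    u2 = (c - ca) / np.linalg.norm(c - ca)
    bis = (u1 + u2) / np.linalg.norm(u1 + u2)
    perp = np.cross(u1, u2)
    perp /= np.linalg.norm(perp)
    cos_t = math.cos(math.radians(_A_N_CA_CB))
    x = cos_t / float(np.dot(bis, u1))
    y = math.sqrt(max(0.0, 1.0 - x * x))
    direction = x * bis + y * perp
    return ca + _B_CA_CB * direction / np.linalg.norm(direction)


def make_wrapped_bond(
    w: int,
    desolvation_radius: float = 6.0,
    seed: int = 0,
    min_separation: float = 1.0,
    max_attempts: int = 20000,
) -> ProteinStructure:
    """One ideal backbone hydrogen bond with exactly ``w`` wrappers.

    A 5-residue glycine helix supplies a single i -> i+4 bond and no
    intrinsic CH_n carbons; ``w`` pseudo-methyl carbons (single-atom
    alanine-like residues) are placed uniformly inside the two-sphere
    desolvation domain, at least ``min_separation`` Å from every existing
    atom, so the ground-truth wrapping is ρ = w.
    """
    if w < 0:
        raise ValueError("w must be nonnegative")
    structure = make_helix(5, residue_name="GLY")
    place_amide_hydrogens(structure)
    donor = structure.residues[4]
    acceptor = structure.residues[0]
    ca_a = donor.atoms["CA"].position
    ca_b = acceptor.atoms["CA"].position

    rng = np.random.default_rng(seed)
    placed: list[np.ndarray] = []
    existing = np.array([a.position for a in structure.atoms])
    lo = np.minimum(ca_a, ca_b) - desolvation_radius
    hi = np.maximum(ca_a, ca_b) + desolvation_radius
    attempts = 0
    while len(placed) < w:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not pack {w} wrappers at separation {min_separation} Å; "
                "try a larger desolvation radius"
            )
        p = rng.uniform(lo, hi)
        if (
            np.linalg.norm(p - ca_a) > desolvation_radius
            and np.linalg.norm(p - ca_b) > desolvation_radius
        ):
            continue
        if np.any(np.linalg.norm(existing - p, axis=1) < min_separation):
            continue
        if placed and np.any(
            np.linalg.norm(np.array(placed) - p, axis=1) < min_separation
        ):
            continue
        placed.append(p)

    for k, p in enumerate(placed):
        res = Residue(chain_id="A", number=10 + k, name="ALA", seq_pos=5 + k)
        res.atoms["CB"] = _atom("CB", "C", res, p)
        structure.residues.append(res)
    classify_nonpolar_groups(structure)
    return structure


# ---------------------------------------------------------------------------
# Cavity surfaces


def _fibonacci_cap(n: int, zmax: float) -> np.ndarray:
    """Quasi-uniform unit vectors with z-component ≤ zmax."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    keep = z <= zmax
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])[keep]


def _shell_residues(
    positions: np.ndarray, chain: str, start_number: int, start_seq: int
) -> list[Residue]:
    out = []
    for k, p in enumerate(positions):
        res = Residue(
            chain_id=chain, number=start_number + k, name="SHL", seq_pos=start_seq + k
        )
        res.atoms["C"] = _atom("C", "C", res, p)
        out.append(res)
    return out


def make_cavity_surface(
    theta_star: float,
    seed: int = 0,
    probe_radius: float = PROBE_RADIUS,
    atom_spacing: float = 1.0,
    shell_spacing: float | None = None,
    margin: float = 5.0,
    flat: bool = False,
    include_bond: bool = False,
    opening_radius: float = 1.6,
) -> ProteinStructure:
    """Atom slab whose accessible envelope carries a spherical pit of radius θ*.

    Shell atoms (inert 'SHL' residues, carbon vdW) tile a plane plus a
    spherical-cap depression whose accessible envelope — atom centers
    inflated by vdW + probe — is a concave pit of curvature radius exactly
    ``theta_star``.  ``flat=True`` returns the bare slab (no sub-nanoscale
    curvature anywhere).  ``include_bond=True`` opens a small mouth at the
    pit bottom and hangs an ideal backbone hydrogen bond beneath it, its
    carbonyl oxygen exposed on the pit axis — the geometry of an exposed
    bond sealed by surface ruggedness.

    The pit shell is tiled more finely than the slab (``shell_spacing``,
    by default scaled to θ*): envelope ripple between atoms grows as the
    square of their spacing, and tight pits need a smooth wall for their
    curvature to be the ground truth.
    """
    if not flat and not (1.0 <= theta_star <= 10.0):
        raise ValueError("theta_star must lie in [1, 10] Å")
    del seed  # construction is deterministic
    if shell_spacing is None:
        shell_spacing = min(0.8, max(0.18, 0.2 * theta_star))
    offset = 1.7 + probe_radius  # carbon vdW + probe
    z_c = offset  # pit-sphere center height above the slab plane
    r_shell = theta_star + offset

    residues: list[Residue] = []
    if flat:
        lateral = 0.0
        halfwidth = margin + 6.0
    else:
        lateral = math.sqrt(max(r_shell**2 - z_c**2, 0.0))
        halfwidth = lateral + margin

    xs = np.arange(-halfwidth, halfwidth + 1e-9, atom_spacing)
    grid = np.array([[x, y, 0.0] for x in xs for y in xs])
    if not flat:
        grid = grid[np.linalg.norm(grid[:, :2], axis=1) >= lateral + 0.5 * atom_spacing]
    residues += _shell_residues(grid, "S", 1, 0)

    if not flat:
        n_total = max(64, int(round(4.0 * np.pi * r_shell**2 / shell_spacing**2)))
        zmax_dir = -z_c / r_shell  # cap from the bottom up to the slab plane
        dirs = _fibonacci_cap(n_total, zmax_dir)
        if include_bond:
            # clear the floor: the bond's carbonyl oxygen will take its place
            sin_a = min(0.95, opening_radius / r_shell)
            dirs = dirs[dirs[:, 2] > -math.sqrt(1.0 - sin_a**2)]
        shell = np.array([0.0, 0.0, z_c]) + r_shell * dirs
        residues += _shell_residues(shell, "S", len(residues) + 1, len(residues))

    structure = ProteinStructure(residues=residues)
    if include_bond and not flat:
        _attach_bond_below_pit(structure, theta_star, probe_radius)
    structure.hydrogens_placed = True  # fixture hydrogens are explicit
    classify_nonpolar_groups(structure)
    return structure


def _attach_bond_below_pit(
    structure: ProteinStructure, theta_star: float, probe_radius: float = PROBE_RADIUS
) -> None:
    """Embed an ideal N-H...O=C bond with its carbonyl O forming the pit floor.

    The oxygen sits on the pit axis at the depth where its own inflated
    sphere (vdW 1.52 + probe) coincides with the pit sphere, so the floor
    of the cavity is seamlessly the bond's exposed carbonyl.  The donor
    amide tucks against the wall with a_HB ≈ 126° (N-H pointing down onto
    the oxygen, C=O pointing up the axis toward the solvent).
    """
    z_c = 1.7 + probe_radius
    o_pos = np.array([0.0, 0.0, z_c - (theta_star + 1.52 + probe_radius)])
    c_pos = o_pos + np.array([0.0, 0.0, -_B_C_O])  # C=O points up the axis
    n_pos = o_pos + np.array([-2.4, 0.0, 1.75])  # |N-O| = 2.97
    h_pos = n_pos + (o_pos - n_pos) / np.linalg.norm(o_pos - n_pos)

    acceptor = Residue(chain_id="B", number=1, name="GLY", seq_pos=0)
    acceptor.atoms["C"] = _atom("C", "C", acceptor, c_pos)
    acceptor.atoms["O"] = _atom("O", "O", acceptor, o_pos)
    ca_a = c_pos + np.array([1.2, 0.6, -0.7]) * (_B_CA_C / np.linalg.norm([1.2, 0.6, -0.7]))
    acceptor.atoms["CA"] = _atom("CA", "C", acceptor, ca_a)
    acceptor.atoms["N"] = _atom(
        "N", "N", acceptor, ca_a + np.array([0.8, -1.0, -0.6]) * (_B_N_CA / np.linalg.norm([0.8, -1.0, -0.6]))
    )

    donor = Residue(chain_id="B", number=4, name="GLY", seq_pos=3)
    donor.atoms["N"] = _atom("N", "N", donor, n_pos)
    donor.atoms["H"] = _atom("H", "H", donor, h_pos)
    ca_d = n_pos + np.array([-1.0, 0.0, -1.1]) * (_B_N_CA / np.linalg.norm([-1.0, 0.0, -1.1]))
    donor.atoms["CA"] = _atom("CA", "C", donor, ca_d)
    c_d = ca_d + np.array([-0.6, 1.1, -0.8]) * (_B_CA_C / np.linalg.norm([-0.6, 1.1, -0.8]))
    donor.atoms["C"] = _atom("C", "C", donor, c_d)
    donor.atoms["O"] = _atom(
        "O", "O", donor, c_d + np.array([-0.9, 0.3, -0.8]) * (_B_C_O / np.linalg.norm([-0.9, 0.3, -0.8]))
    )
    structure.residues += [acceptor, donor]


def pit_point_mask(
    positions: np.ndarray,
    theta_star: float,
    probe_radius: float = PROBE_RADIUS,
    shell_tol: float = 0.4,
    cone_cos: float = 0.5,
) -> np.ndarray:
    """Boolean mask of envelope points on the floor of a generated pit.

    Ground-truth selector for ``make_cavity_surface`` fixtures: points
    within ``shell_tol`` of the ideal pit sphere (radius θ* around the pit
    center) and inside the downward cone (direction cosine below
    ``-cone_cos``), i.e. the pit floor away from the rim lip.
    """
    center = np.array([0.0, 0.0, 1.7 + probe_radius])
    rel = np.asarray(positions, dtype=float) - center
    r = np.linalg.norm(rel, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        down = rel[:, 2] / np.maximum(r, 1e-12)
    return (np.abs(r - theta_star) < shell_tol) & (down < -cone_cos)


# ---------------------------------------------------------------------------
# Water lattices


def _lattice_sites(g_star: int, n: int) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """O sites and intended HB edges for uniform target coordination g*."""
    if g_star == 1:  # isolated dimers, 6 Å apart
        n_pairs = max(1, n // 2)
        sites, edges = [], []
        for k in range(n_pairs):
            base = np.array([6.0 * k, 0.0, 0.0])
            sites += [base, base + np.array([_OO, 0.0, 0.0])]
            edges.append((2 * k, 2 * k + 1))
        return np.array(sites), edges
    if g_star == 2:  # zigzag chain with tetrahedral bend
        half = math.radians(109.47 / 2.0)
        step = np.array([_OO * math.sin(half), 0.0, _OO * math.cos(half)])
        sites = []
        p = np.zeros(3)
        for k in range(n):
            sites.append(p.copy())
            s = step.copy()
            s[2] *= -1 if k % 2 else 1
            p = p + s
        return np.array(sites), [(k, k + 1) for k in range(n - 1)]
    if g_star == 3:  # honeycomb sheet
        a1 = np.array([_OO * math.sqrt(3.0), 0.0, 0.0])
        a2 = np.array([_OO * math.sqrt(3.0) / 2.0, _OO * 1.5, 0.0])
        basis = [np.zeros(3), np.array([0.0, _OO, 0.0])]
        m = int(math.ceil(math.sqrt(n / 2.0))) + 2
        sites = [
            i * a1 + j * a2 + b
            for i in range(-m, m + 1)
            for j in range(-m, m + 1)
            for b in basis
        ]
        return _trim_cluster(np.array(sites), n)
    if g_star == 4:  # diamond lattice
        a = _OO * 4.0 / math.sqrt(3.0)
        fcc = [np.zeros(3), np.array([0, 0.5, 0.5]), np.array([0.5, 0, 0.5]), np.array([0.5, 0.5, 0])]
        basis = [f * a for f in fcc] + [f * a + a * 0.25 for f in fcc]
        m = int(math.ceil((n / 8.0) ** (1 / 3))) + 2
        sites = [
            np.array([i, j, k]) * a + b
            for i in range(-m, m + 1)
            for j in range(-m, m + 1)
            for k in range(-m, m + 1)
            for b in basis
        ]
        return _trim_cluster(np.array(sites), n)
    raise ValueError("g_star must be in {1, 2, 3, 4}")


def _trim_cluster(sites: np.ndarray, n: int) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Keep the n sites nearest a central lattice site; edges by distance < 3.2 Å."""
    centroid = sites.mean(axis=0)
    seed_site = sites[np.argmin(np.linalg.norm(sites - centroid, axis=1))]
    order = np.argsort(np.linalg.norm(sites - seed_site, axis=1), kind="stable")
    kept = sites[order[:n]]
    from scipy.spatial import cKDTree

    pairs = cKDTree(kept).query_pairs(3.2)
    return kept, sorted((min(a, b), max(a, b)) for a, b in pairs)


def _orient_hydrogens(
    sites: np.ndarray, edges: list[tuple[int, int]], rng: np.random.Generator
) -> np.ndarray:
    """Assign two hydrogens per water so every intended edge has a donor.

    An Eulerian-circuit orientation of the intended graph (odd-degree
    vertices paired through a dummy node) gives every node out-degree
    ≤ ⌈degree/2⌉ ≤ 2; each out-edge gets a hydrogen on the O-O axis
    (O-H-O angle exactly 180°).  Spare hydrogens point away from all
    lattice neighbors so no unintended bond forms.
    """
    n = len(sites)
    graph = nx.MultiGraph()
    graph.add_nodes_from(range(n))
    graph.add_edges_from(edges)
    odd = [v for v in graph.nodes if graph.degree(v) % 2]
    dummy = n
    for v in odd:
        graph.add_edge(dummy, v)
    donates: dict[int, list[int]] = {j: [] for j in range(n)}
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp).copy()
        if sub.number_of_edges() == 0:
            continue
        for u, v in nx.eulerian_circuit(sub):
            if u != dummy and v != dummy and len(donates[u]) < 2:
                donates[u].append(v)
    # any edge left without a donor (circuit credited a saturated node): flip
    covered = {frozenset(e) for j, vs in donates.items() for e in ((j, v) for v in vs)}
    for e in edges:
        if frozenset(e) not in covered:
            u, v = e
            tgt = u if len(donates[u]) < 2 else v
            other = v if tgt == u else u
            if len(donates[tgt]) >= 2:
                raise RuntimeError("hydrogen orientation failed; lattice degree > 4?")
            donates[tgt].append(other)
            covered.add(frozenset(e))

    neighbor_dirs: dict[int, list[np.ndarray]] = {j: [] for j in range(n)}
    for u, v in edges:
        d = sites[v] - sites[u]
        d /= np.linalg.norm(d)
        neighbor_dirs[u].append(d)
        neighbor_dirs[v].append(-d)

    hydrogens = np.full((n, 2, 3), np.nan)
    for j in range(n):
        dirs = [
            (sites[v] - sites[j]) / np.linalg.norm(sites[v] - sites[j])
            for v in donates[j]
        ]
        while len(dirs) < 2:
            dirs.append(_spare_direction(neighbor_dirs[j], dirs, rng))
        for k, d in enumerate(dirs[:2]):
            hydrogens[j, k] = sites[j] + 1.0 * d
    return hydrogens


def _spare_direction(
    neighbors: list[np.ndarray], taken: list[np.ndarray], rng: np.random.Generator
) -> np.ndarray:
    """A direction pointing away from every lattice neighbor."""
    if not neighbors:
        cand = np.array([0.0, 0.0, 1.0])
        if not taken or min(np.linalg.norm(cand - t) for t in taken) > 0.3:
            return cand
    # deterministic candidates: anti-mean, plane normals, singular directions
    candidates: list[np.ndarray] = []
    mean = np.sum(neighbors, axis=0)
    if np.linalg.norm(mean) > 1e-6:
        candidates.append(-mean / np.linalg.norm(mean))
    mat = np.array(neighbors)
    _, _, vt = np.linalg.svd(mat, full_matrices=True)
    candidates += [vt[-1], -vt[-1]]
    for a in range(len(neighbors)):
        for b in range(a + 1, len(neighbors)):
            cr = np.cross(neighbors[a], neighbors[b])
            if np.linalg.norm(cr) > 1e-6:
                cr /= np.linalg.norm(cr)
                candidates += [cr, -cr]
    for cand in candidates:
        if all(float(cand @ v) <= 1e-9 for v in neighbors) and (
            not taken or min(np.linalg.norm(cand - t) for t in taken) > 0.3
        ):
            return cand
    for _ in range(2000):
        cand = rng.standard_normal(3)
        cand /= np.linalg.norm(cand)
        if all(float(cand @ v) <= 0.05 for v in neighbors) and (
            not taken or min(np.linalg.norm(cand - t) for t in taken) > 0.3
        ):
            return cand
    raise RuntimeError("no admissible spare hydrogen direction")


def make_water_lattice(
    g_star: int, n_molecules: int, seed: int = 0
) -> SolventFrame:
    """Water cluster whose interior molecules have HB coordination g*.

    The O sites form the pruned ice-like geometry matching g* (dimers,
    tetrahedral-bend chain, honeycomb sheet, or diamond lattice); hydrogens
    are oriented so the geometric HB criterion holds on every intended edge
    and fails on every non-edge.  ``expected_g`` carries the intended
    per-molecule coordination (boundary molecules fall below g*).
    """
    if n_molecules < g_star + 1:
        raise ValueError(f"g*={g_star} unachievable with {n_molecules} molecules")
    rng = np.random.default_rng(seed)
    sites, edges = _lattice_sites(g_star, n_molecules)
    degree = np.zeros(len(sites), dtype=int)
    for u, v in edges:
        degree[u] += 1
        degree[v] += 1
    if int(degree.max(initial=0)) < g_star:
        raise ValueError(
            f"g*={g_star} unachievable with {n_molecules} molecules (max degree {degree.max(initial=0)})"
        )
    hydrogens = _orient_hydrogens(sites, edges, rng)
    return SolventFrame(
        frame_index=0, oxygens=sites, hydrogens=hydrogens, expected_g=degree
    )


# ---------------------------------------------------------------------------
# Jointly solvated bonds


def water_standoff(theta_star: float) -> float:
    """The generator's water-exclusion placement rule.

    A cavity with curvature radius below ``PENETRATION_THETA`` (4.5 Å)
    cannot host a water molecule together with its g = 3 coordination
    shell, so the nearest water stands off at the cavity mouth (5 Å);
    wider cavities admit hydration contact (3 Å).
    """
    return HYDRATION_CONTACT if theta_star >= PENETRATION_THETA else MOUTH_STANDOFF


def _rotation_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


_SQ89 = math.sqrt(8.0) / 3.0


def _cluster_base(g_star: int) -> np.ndarray:
    """Unit directions of the coordination shell, opening toward +z.

    Tetrahedral mutual angles (109.47°) arranged symmetrically about +z so
    every neighbor sits on the solvent side: the shell of a water at an
    interface, missing its partners toward the surface.
    """
    half = math.radians(109.47 / 2.0)
    if g_star == 1:
        return np.array([[0.0, 0.0, 1.0]])
    if g_star == 2:
        return np.array(
            [
                [math.sin(half), 0.0, math.cos(half)],
                [-math.sin(half), 0.0, math.cos(half)],
            ]
        )
    if g_star == 3:
        return np.array(
            [
                [_SQ89 * math.cos(a), _SQ89 * math.sin(a), 1.0 / 3.0]
                for a in (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)
            ]
        )
    if g_star == 4:
        return np.array(
            [
                [0.0, 0.0, 1.0],
                [2.0 * math.sqrt(2) / 3.0, 0.0, -1.0 / 3.0],
                [-math.sqrt(2) / 3.0, math.sqrt(2.0 / 3.0), -1.0 / 3.0],
                [-math.sqrt(2) / 3.0, -math.sqrt(2.0 / 3.0), -1.0 / 3.0],
            ]
        )
    raise ValueError("g_star must be in {0, 1, 2, 3, 4}")


def _coordination_cluster(
    center: np.ndarray,
    g_star: int,
    up: np.ndarray,
    obstacles: np.ndarray,
    rng: np.random.Generator,
    anchor: np.ndarray | None = None,
    anchor_min: float = 0.0,
    clearance: float = 2.6,
    max_attempts: int = 600,
) -> np.ndarray:
    """Positions of g* neighbor oxygens around ``center``.

    Neighbors stay ``clearance`` from every obstacle atom and, when an
    ``anchor`` is given, at least ``anchor_min`` from it (so the probe
    water remains the anchor's closest water under frame jitter).
    """
    if g_star == 0:
        return np.empty((0, 3))
    base = _cluster_base(g_star)
    up = up / np.linalg.norm(up)
    axis = np.cross(np.array([0.0, 0.0, 1.0]), up)
    if np.linalg.norm(axis) < 1e-9:
        rot0 = np.eye(3) if up[2] > 0 else _rotation_from_axis_angle(np.array([1.0, 0.0, 0.0]), np.pi)
    else:
        rot0 = _rotation_from_axis_angle(axis, math.acos(np.clip(up[2], -1, 1)))
    max_tilt = 0.1 if g_star == 4 else 0.3
    for _ in range(max_attempts):
        spin = _rotation_from_axis_angle(up, rng.uniform(0, 2 * np.pi))
        tilt = _rotation_from_axis_angle(
            rng.standard_normal(3) + 1e-9, rng.uniform(0, max_tilt)
        )
        pts = center + _OO * (base @ rot0.T @ spin.T @ tilt.T)
        if anchor is not None and np.min(np.linalg.norm(pts - anchor, axis=1)) < anchor_min:
            continue
        if obstacles.size and np.min(
            np.linalg.norm(pts[:, None, :] - obstacles[None, :, :], axis=2)
        ) < clearance:
            continue
        return pts
    raise RuntimeError(
        f"cannot fit a g*={g_star} coordination shell; joint spec infeasible"
    )


def make_solvated_bond(
    d_star: float | None = None,
    g_star: int = 3,
    theta_star: float | None = None,
    n_frames: int = 10,
    seed: int = 0,
    sigma: float = 0.1,
    n_bulk: int = 6,
    wrappers: int = 0,
) -> tuple[ProteinStructure, list[SolventFrame]]:
    """A bond plus solvent frames with known nearest-water ground truth.

    The nearest water oxygen is placed at ``d_star`` from the bond's
    carbonyl oxygen (when ``d_star`` is None the water-exclusion rule
    derives it from ``theta_star``) and surrounded by ``g_star``
    hydrogen-bonded neighbors; bulk waters sit far above.  With
    ``theta_star`` the bond hangs beneath a cavity shell of that curvature
    radius; otherwise it is a bare 5-residue helix bond.  ``wrappers`` adds
    that many pseudo-CH3 carbons below the bond (outside the water approach
    path) to control ρ.  Frames jitter every water rigidly by clipped
    Gaussian noise (σ = 0.1 Å, |component| ≤ 0.12 Å), preserving the
    intended HB topology, so ``bhb_hydration`` recovers (d*, g*) within
    the noise.
    """
    if d_star is None:
        if theta_star is None:
            raise ValueError("give d_star or theta_star")
        d_star = water_standoff(theta_star)
    if d_star <= 2.4:
        raise ValueError("d_star must exceed 2.4 Å (steric contact)")
    rng = np.random.default_rng(seed)

    if theta_star is not None:
        structure = make_cavity_surface(theta_star, include_bond=True)
        bond_chain = "B"
        up = np.array([0.0, 0.0, 1.0])
    else:
        structure = make_helix(5, residue_name="GLY")
        place_amide_hydrogens(structure)
        bond_chain = "A"
        acc = structure.residues[0]
        # open direction: radially away from the helix body through the O
        o = acc.atoms["O"].position
        centroid = np.mean([a.position for a in structure.atoms], axis=0)
        up = o - centroid
        up /= np.linalg.norm(up)

    # the bond whose hydration is controlled: first-residue carbonyl
    if theta_star is not None:
        acceptor = next(
            r for r in structure.residues if r.chain_id == "B" and r.number == 1
        )
    else:
        acceptor = structure.residues[0]
    o_carbonyl = acceptor.atoms["O"].position

    protein_atoms = np.array([a.position for a in structure.atoms])
    probe_o = o_carbonyl + d_star * up
    neighbors = _coordination_cluster(
        probe_o,
        g_star,
        up,
        protein_atoms,
        rng,
        anchor=o_carbonyl,
        anchor_min=d_star + (0.3 if g_star == 4 else 0.5),
    )

    if wrappers:
        _add_wrappers_below(structure, bond_chain, wrappers, rng)
    classify_nonpolar_groups(structure)

    # bulk waters on a ring far above, mutually and cluster separated
    bulk = []
    z_top = float(protein_atoms[:, 2].max()) if theta_star is not None else None
    for k in range(n_bulk):
        ang = 2 * np.pi * k / max(n_bulk, 1)
        radial = np.array([math.cos(ang), math.sin(ang), 0.0])
        if theta_star is not None:
            p = np.array([0.0, 0.0, z_top + 6.0]) + 7.0 * radial
        else:
            p = o_carbonyl + (d_star + 8.0) * up + 6.0 * radial
        bulk.append(p)
    bulk = np.array(bulk) if bulk else np.empty((0, 3))

    oxygens = np.vstack([probe_o[None, :], neighbors, bulk])
    hydrogens = _solvated_hydrogens(oxygens, g_star, rng)

    frames = []
    for f in range(n_frames):
        if f == 0 and sigma == 0:
            jitter = np.zeros((len(oxygens), 3))
        else:
            jitter = np.clip(
                rng.normal(0.0, sigma, size=(len(oxygens), 3)),
                -_JITTER_CLIP,
                _JITTER_CLIP,
            )
        frames.append(
            SolventFrame(
                frame_index=f,
                oxygens=oxygens + jitter,
                hydrogens=hydrogens + jitter[:, None, :],
            )
        )
    return structure, frames


def _add_wrappers_below(
    structure: ProteinStructure, bond_chain: str, w: int, rng: np.random.Generator
) -> None:
    """Pseudo-CH3 wrappers in the desolvation domain, below the bond plane."""
    bond_res = [r for r in structure.residues if r.chain_id == bond_chain]
    cas = np.array([r.atoms["CA"].position for r in bond_res if "CA" in r.atoms])
    z_floor = float(
        min(a.position[2] for r in bond_res for a in r.atoms.values())
    )
    existing = np.array([a.position for a in structure.atoms])
    placed: list[np.ndarray] = []
    attempts = 0
    start_num = max(r.number for r in structure.residues) + 10
    start_seq = max(r.seq_pos for r in structure.residues) + 1
    while len(placed) < w:
        attempts += 1
        if attempts > 40000:
            raise RuntimeError("could not pack wrappers below the bond")
        ca = cas[rng.integers(len(cas))]
        p = ca + rng.uniform(-6.0, 6.0, size=3)
        if np.min(np.linalg.norm(cas - p, axis=1)) > 6.0:
            continue
        if p[2] > z_floor - 0.3:
            continue  # stay below the bond, clear of the water approach
        if np.any(np.linalg.norm(existing - p, axis=1) < 1.2):
            continue
        if placed and np.any(np.linalg.norm(np.array(placed) - p, axis=1) < 1.2):
            continue
        placed.append(p)
    for k, p in enumerate(placed):
        res = Residue(
            chain_id=bond_chain,
            number=start_num + k,
            name="ALA",
            seq_pos=start_seq + k,
        )
        res.atoms["CB"] = _atom("CB", "C", res, p)
        structure.residues.append(res)


def _solvated_hydrogens(
    oxygens: np.ndarray, g_star: int, rng: np.random.Generator
) -> np.ndarray:
    """Hydrogens: probe water donates to ≤ 2 neighbors, extras donate back."""
    n = len(oxygens)
    hydrogens = np.full((n, 2, 3), np.nan)
    probe = oxygens[0]
    neighbor_idx = list(range(1, 1 + g_star))

    used = 0
    for v in neighbor_idx[:2]:
        d = oxygens[v] - probe
        hydrogens[0, used] = probe + d / np.linalg.norm(d)
        used += 1
    while used < 2:
        hydrogens[0, used] = probe + _spare_direction(
            [
                (oxygens[v] - probe) / np.linalg.norm(oxygens[v] - probe)
                for v in neighbor_idx
            ],
            [],
            rng,
        )
        used += 1
    for v in neighbor_idx:
        d = probe - oxygens[v]
        d /= np.linalg.norm(d)
        if v - 1 < 2:  # probe already donates to this one; point H away
            h1 = _spare_direction([d], [], rng)
            hydrogens[v, 0] = oxygens[v] + h1
            hydrogens[v, 1] = oxygens[v] + _spare_direction([d], [h1], rng)
        else:  # this neighbor donates back to the probe
            hydrogens[v, 0] = oxygens[v] + d
            hydrogens[v, 1] = oxygens[v] + _spare_direction([d], [d], rng)
    for j in range(1 + g_star, n):  # bulk: arbitrary orientation, no close pairs
        hydrogens[j, 0] = oxygens[j] + np.array([1.0, 0.0, 0.0])
        hydrogens[j, 1] = oxygens[j] + np.array(
            [math.cos(math.radians(104.5)), math.sin(math.radians(104.5)), 0.0]
        )
    return hydrogens
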
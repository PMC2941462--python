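# Methods

This note documents the models, conventions, numerical choices and known
limitations of `dhtopo`. Defaults are given with units; every one is a
named field of `RunConfig`.

## Backbone hydrogen bonds and wrapping

A backbone hydrogen bond (BHB) is purely geometric: donor amide N to
acceptor carbonyl O distance < 3.2 Å, and the angle a_HB between the N→H
and O→C bond directions (180° when the four atoms are collinear) in
[120°, 180°]. No electrostatic or energetic scoring is applied. Crystal
structures lack amide hydrogens, so they are placed at 1.0 Å from N in the
peptide plane, opposite the bisector of the C(prev)–N and Cα–N directions
(ideal trans-amide geometry); proline and chain N-termini get none, and
experimentally present hydrogens are never moved. This placement is a
stand-in convention: any near-planar amide geometry gives a_HB values well
inside the acceptance window for genuinely bonded pairs.

Same-chain pairs closer than 2 in residue numbering, and donors whose N is
covalently bonded to the acceptor C (< 1.8 Å), are excluded as
peptide-geometry artifacts; both rules are configurable. A donor hydrogen
satisfying the geometry with two acceptors yields two bonds (bifurcation
is counted per pair, not per donor). Inter-chain bonds are off by default
(monomeric use case) behind a flag.

The wrapping ρ of a bond counts side-chain carbonaceous CH_n carbons
(n = 0–3) whose centers lie in the desolvation domain: the union of two
spheres of radius 6 Å (≈ three water layers) centered on the paired Cα
atoms, each carbon counted once. Carbons qualify by covalent topology from
a bundled amino-acid connectivity table — a side-chain carbon with no N, O
or S neighbor. Under the strict reading the Cβ of Ser/Thr/Cys is excluded
(bonded to O/S); a flag relaxes this. Per-residue counts under the strict
rule: GLY 0, ALA 1, VAL 3, LEU 4, ILE 4, PRO 2, PHE 7, TRP 7, MET 1,
SER 0, THR 1, CYS 0, TYR 6, ASN 1, GLN 2, ASP 1, GLU 2, LYS 3, ARG 2,
HIS 1. Bonds with ρ ≤ 19 are dehydrons (exposed BHBs); the cutoff is the
population mean 26.6 minus one standard deviation 7.5 reported for soluble
PDB structures, floored. A mode recomputes floor(mean − SD) from the
analyzed structure's own bond population instead.

## Surface topography

The solvent-accessible envelope is the locus of probe centers: each heavy
atom inflated by its Bondi vdW radius plus the 1.4 Å probe. It is sampled
as a dot surface — a golden-spiral lattice of pitch `point_spacing`
(default 0.5 Å) on each inflated sphere, dropping points buried inside a
neighboring sphere. Normals are radial from the parent atom and exact for
this piecewise-spherical surface.

The signed osculating-sphere radius θ at a sample point p with outward
normal n is estimated by **tangent-sphere votes**: each neighbor q in a
patch annulus contributes the radius |q − p|²/(2 n·(q − p)) of the sphere
tangent at p through q — positive when q lies on the solvent side
(concave, water-confining cavity), negative on the protein side (convex).
This form is exact for every neighbor of a spherical patch regardless of
sampling, which matters on dot-sampled envelopes: a plain algebraic
(Coope) sphere fit is biased small on near-flat noisy patches and is
contaminated by the convex parent-sphere scallops between atoms. The
Coope fit remains available as `fit_sphere` and is cross-checked in the
tests on exact spheres.

Per point, θ is the median vote over the patch, with three guards:

- **Annulus floor** (`min_neighbor_sep`, auto ≈ 2× the sampling pitch,
  ≥ 0.4 Å): same-scallop neighbors sample the generating atom sphere, not
  the envelope shape, and are excluded.
- **Scale ladder**: votes are taken on an ascending ladder of patch radii
  (from ≈ 3× pitch up to `patch_radius`, default 2.5 Å). A scale is
  accepted when |θ| ≤ 2.5× the scale (the curvature is resolvable there)
  and the vote spread (median absolute deviation) is ≤ 0.35 |θ|. Tight
  cavities are thus measured at their own scale instead of being washed
  out; near-flat regions fall through to the full patch.
- **Flatness**: |θ| > 20 Å, degenerate patches, or no trusted scale →
  the point is flat (NaN) and excluded from spectra.

Spectra keep concave sub-nanoscale values 0 < θ < 10 Å in ¼ Å bins with
left-edge convention. A bond's vicinity is the set of surface points whose
parent atom lies within 3 Å of the bond baricenter (midpoint of amide N
and carbonyl O; a residue-level vicinity mode is exposed). The per-bond
summary θ is the median of concave vicinal values, falling back to the
median of all values — one declared reduction among several defensible
ones (minimum and mode are alternatives); bonds with no exposed vicinal
points are flagged buried. Pooled class spectra concatenate vicinal
multisets, so all-BHB mass equals dehydron mass plus well-wrapped mass
bin by bin, before and after unit-mass normalization.

Known discretization properties: on generated spherical pits the median θ
over the pit floor is within ±6% of truth across θ* ∈ [1, 10] Å with
correct sign (fixture suite), and refining `point_spacing` 0.5 → 0.35 Å
moves the recovered value by < 5%. θ values are *not* bit-identical under
rigid-body motion — the dot lattice is generated in fixed global axes —
but bond geometry, ρ, classifications, and the action are exactly
invariant, and θ summaries agree to discretization tolerance.

## Hydration

Water–water hydrogen bonds use O–O < 3.2 Å plus an O-H-O angle at the
hydrogen in [120°, 180°], testing all four donor arrangements of the two
molecules. Coordination g is the degree in this graph. Hydrogen-free
trajectories can opt into a distance-only criterion; the output is flagged.
Frames are assumed whole/unwrapped (no periodic-boundary imaging in v1; a
box-vectors option is stubbed).

Per bond and frame, d is the minimum carbonyl-O-to-water-O distance
(oxygen-to-oxygen for simplicity, the water O being near the molecular
baricenter) and g the coordination of the argmin water, ties broken toward
the lowest water index for determinism. d_min and g_min are plain means
over frames — the frame mean, not the mode, is used for g_min. Water
partners hydrogen-bonded to the protein are not counted in g (g is
water–water coordination); water-mediated protein interactions are out of
scope. The field g(r) averages, over frames, the mean g of waters inside a
2.5 Å ball (one water layer) of each query; never-visited queries are NaN
with a contribution count of zero.

The action of one frame's graph is

    A[g] = Σ_j Σ_{n ∈ M(j)} (g(r_j) − g(r_n))²,

with M(j) the HB neighbors of molecule j; ordered pairs both contribute
(each edge twice), normalization constant 1, both pluggable. This is the
minimal form with the defining properties: A ≥ 0, A invariant under
relabeling, and A = 0 exactly when g is constant on every connected
component — so any local change in coordination between bonded neighbors
raises the action, which is the sense in which interfacial water resists
losing partners.

## Synthetic data

The generator produces every input class the pipeline consumes, with the
ground truth a test can assert:

- **Helices**: ideal φ = −57°, ψ = −47° polyalanine (glycine optionally)
  with standard bond geometry; the i→i+4 ladder gives n − 4 bonds
  (N–O 3.09 Å, a_HB 167°).
- **Wrapped bonds**: a 5-residue glycine helix (one bond, zero intrinsic
  CH_n) plus exactly w pseudo-methyl carbons placed uniformly in the
  desolvation domain, ≥ 1 Å from existing atoms, so ρ = w identically.
- **Cavity surfaces**: a slab of inert carbon-radius shell atoms plus a
  spherical-cap depression whose accessible envelope is a pit of curvature
  radius exactly θ*. The pit shell is tiled more finely than the slab
  (auto ≈ 0.2 θ*, floor 0.18 Å) because envelope ripple between atoms
  grows quadratically with spacing and must stay below the pit sagitta.
  With `include_bond`, the pit floor atom is replaced by the bond's
  carbonyl oxygen, placed so its inflated sphere continues the pit sphere;
  the donor amide tucks against the wall (a_HB ≈ 126°).
- **Water lattices**: uniform interior coordination g* by geometry class —
  dimers (1), tetrahedral-bend chains (2), honeycomb sheets (3), diamond
  lattices (4) — with O–O = 2.75 Å so only intended neighbors fall under
  the 3.2 Å cutoff. Hydrogens are assigned by an Eulerian-circuit
  orientation (out-degree ≤ 2), each donor H on the O–O axis (angle
  exactly 180°) and spare hydrogens pointing away from every neighbor, so
  the recovered graph equals the intended one exactly.
- **Solvated bonds**: the nearest water O at d* from the bond's carbonyl O
  along the open direction, surrounded by g* neighbors on tetrahedral
  directions opening toward the solvent, bulk waters far above, and
  per-frame rigid jitter of each molecule by clipped Gaussian noise
  (σ = 0.1 Å, |component| ≤ 0.12 Å) — small enough that no intended HB
  edge can break and no unintended one can form, while still exercising
  frame averaging. When d* is not given, the **water-exclusion rule**
  derives it from the cavity: θ* < 4.5 Å cannot host a water plus its
  g = 3 shell, so the water stands off at the mouth (5 Å); wider cavities
  admit hydration contact (3 Å). A g* = 4 shell at contact distance is
  geometrically infeasible against the surface and the generator raises —
  the interfacial-coordination limit, encoded as a constraint.

What the generator does *not* emulate: water dynamics, force-field
energetics, realistic protein packing, crystallographic disorder, or
periodic solvent boxes. Passing tests therefore demonstrate that the
pipeline measures what the fixtures encode (geometry and coordination
statistics), not that the biological distributions are reproduced; the
reduced-scale hydration contrast (dehydrons dry at ~5 Å, wrapped bonds
hydrated at ~3 Å) is built into the fixtures by the exclusion rule, and
the tests verify the pipeline recovers it end to end.

## Scale choices

Default problem sizes keep every check on one CPU in minutes: curvature
recovery uses one shape per θ* with denser sampling only for tight pits
(point spacing 0.3/0.4/0.5 Å below 1.75/2.25/above); the hydration
contrast uses 50 bonds × 3 frames; oracle equivalence runs exhaustive
O(n²) recounts up to 30 residues and 400 waters. These sizes are the
package's study conditions, chosen to give stable medians and exact
combinatorial checks.

## Limitations

- No mmCIF input, no side-chain hydrogen placement, no protonation logic.
- The solvent-accessible envelope is the only surface (no Connolly/SES);
  pockets are characterized by θ only, not enumerated.
- θ under rigid motion is stable only to discretization tolerance (above).
- The per-bond summary θ reduction and the exact action normalization are
  declared package conventions; alternatives plug in via parameters.
- Insertion codes are ignored; author numbering is otherwise preserved in
  all reports, with 0-based arrays internally.
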
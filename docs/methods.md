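# Methods

## Scope and data model

The package analyses trajectories of a membrane-embedded tetrameric
channel in a rectangular periodic box. The in-memory model is a
`Topology` (per-atom name, residue, chain, element, mass, vdW radius)
shared by ordered `Frame`s (coordinates in nm, three box edges, time in
ps). Lengths are nm everywhere; Å appears only at PDB output and in
report text. File serials are 1-based (GRO/PDB/NDX convention), memory
indices 0-based; the reader/writer is the boundary. Only rectangular
boxes are supported — triclinic box rows are rejected with an explicit
error. vdW radii come from a bundled per-element table (Bondi-style;
helium 0.14 nm, from half the LJ σ of a monatomic gas site) with
per-atom override.

GRO files carry no chain column, so chain-dependent selections (the gate
Cα pair, the site OD1 quadrilateral, per-chain every-5th-Cα references)
are exported and consumed as named NDX index groups in file-based
workflows; in-memory topologies keep chain ids directly.

## PBC cleanup

Three pure coordinate transforms mirror the standard pre-analysis
sequence: `make_whole` (breadth-first traversal from each molecule's
lowest-index atom, shifting every neighbour by the lattice vector that
minimises the bond length), `center_group` (rigid shift putting the
group's unweighted geometric center at box/2, then atom-wise wrapping),
and `compact_pack` (each whole molecule translated to whichever of the
27 neighbouring images puts its geometric center nearest the box
center). All three preserve image-minimum pairwise geometry and are
idempotent; the anchor/tie-break choices exist purely for determinism.

## Superposition and clustering

`kabsch_superpose` is the weighted SVD solution; the smallest singular
direction is reflected when needed so the rotation is always proper,
which doubles as the documented tie-break for degenerate (collinear)
point sets. `rmsd_series` superposes each frame on a fit group and
measures RMSD over a measure group (default: same group), so the value
at the reference frame is exactly zero.

Conformational clustering is the greedy neighbour-count algorithm: the
frame with the most neighbours within the cutoff (itself included)
becomes a centroid, its neighbourhood is removed, repeat. Ties on
neighbour count go to the lowest frame index; clusters are reported by
descending size. Pairwise distances are superposition RMSDs over the
same group used for the RMSD series, and the clustering window defaults
to the final half of the trajectory. Occupancy summaries report the
biggest cluster's probability rounded half away from zero to two
decimals (full precision retained internally) and the first / middle /
last member timestamps, middle being the member at ordinal ⌈k/2⌉.

## Density and RDF layouts

`density_profile` wraps each atom's coordinate into [0, box) along the
chosen axis, accumulates masses into bins, averages over frames and
converts to kg·m⁻³ with the slab volume; Σ(density × slab volume)
equals the group mass to 1e-6 relative — the unit test for the unit
chain. `rdf` uses image-minimum distances, shell normalisation
4πr²dr, and the whole-box target density N/V averaged over frames
(bulk-region densities are a documented alternative; the whole-box
convention is the default because no excluded-volume correction is
applied anywhere else either). Self-pairs are excluded when the groups
overlap. `r_max` beyond half the smallest box edge is an error, never a
silent truncation. Bin width defaults to 0.02 nm.

A *layout* summarises solvation along a chain: for every 5th Cα
(starting at the first resolved residue) one RDF per sampling window,
g averaged over 0–3.4 nm (an unweighted mean over bins — the plain
reading of averaging a curve over a range; a shell-weighted mean is a
flag away), then mean ± standard error (n−1) across windows. Sampling
windows are a (start, width, gap) triple; the canonical 50–100 ns
schedule with 5 ns windows and 10 ns gaps yields four windows.
Normalisation to control is the row-wise ratio of means with
first-order error propagation SE(a/b) = |a/b|·√((SEa/a)² + (SEb/b)²);
rows whose control mean is below ε are flagged rather than divided.

## Order parameters

United-atom tails carry no hydrogens, so the two geminal hydrogens of
each sp³ chain carbon are reconstructed from the triplet
(C_prev, C, C_next): both C–H unit vectors lie in the plane through C
perpendicular to (C_next − C_prev), at the exact tetrahedral angle from
both C–C bonds whatever the local C–C–C angle (cos φ = ⅓ / cos(γ/2)).
Prochirality: the hydrogen with positive scalar triple product
det[C_prev−C, C_next−C, H−C] is pro-R. The convention is internal —
the original descriptor tool's sign convention is not restated anywhere
— but it is self-consistent: mirroring the coordinates swaps the two
columns exactly, which is asserted as a property test. sp² carbons
(C9=C10) get a single in-plane hydrogen on the exterior bisector,
reported under both labels. C–H length is fixed at 0.109 nm (S_ch uses
only the direction; the length matters only for exported coordinates).
Terminal carbons are excluded. S_ch = ⟨3cos²θ − 1⟩/2 against the
bilayer normal is averaged over frames and lipids per carbon and label,
with the standard error taken across lipids.

## Volumes

`excluded_volume` computes the solvent-excluded volume on a voxel grid
local to the group's padded bounding box: (a) the signed clearance
field f(x) = min_i(|x − aᵢ| − rᵢ − p) is evaluated exactly at voxel
centers; (b) the probe-accessible exterior is the f ≥ 0 component
connected to the grid boundary (6-connectivity), so enclosed cavities
the probe cannot reach count as volume; (c) the non-exterior region is
eroded by the probe radius using a Euclidean distance transform whose
reference is corrected from the nearest exterior voxel's own clearance
— near the erosion boundary the corrected distance is re-minimised over
the 27-neighbourhood of that voxel, restoring sub-voxel accuracy of the
surface (a single 0.2 nm sphere at 0.02 nm spacing comes out within
0.7 % of (4/3)πr³; a plain grid erosion is several percent high);
(d) vdW-occupied voxels are unioned in. Volume is monotone in the probe
radius, and halving the grid spacing moves fixture volumes by well
under 3 %. Defaults: 0.05 nm spacing for molecules (1.4 Å probe),
0.1 nm for the gas bubble (6 Å probe); spacing must not exceed half the
probe radius.

`gas_phase_volume` applies the 6 Å probe to the gas atoms inside the
inter-leaflet z-bounds — by default the two phosphate density peaks —
with a 0.14 nm gridding radius for the gas (half the LJ σ, rounded). A
slab containing fewer than two atoms, or resolving to more than one
connected body, is flagged as non-continuous. Percent change is
100·(V − V_ref)/V_ref, rounded half away from zero to two decimals in
reports.

## Pore, site, gate, helix

The pore profile replaces a full Voronoi tunnel search with slice-wise
maximal inscribed circles along a user-given axis (the channel is
axis-aligned after centering, and the surface is used only for
size/shape comparison): per z-slice, atoms within a slab (half-width
max(slice thickness, 0.2 nm)) bound the circle; the center maximising
the lateral clearance min(|p − aᵢ|_xy − rᵢ) is found by a coarse grid
around the previous slice's center refined with Nelder–Mead, with the
search confined to a ±0.5 nm box — the inscribed circle is only
meaningful while the wall confines it. The surface is sampled at 36
azimuths per slice; extents are bounding-box lengths of the surface
cloud along Z and X. A slice with no wall atoms within 2 nm truncates
the profile with a warning.

Site geometry projects four labelled OD1 atoms onto XY, orders the
vertices by polar angle about their centroid (so sides are well defined
whatever the input order), and reports sides, diagonals, the
shorter/longer diagonal ratio and the acute diagonal crossing angle in
Å — ratio ≈ 1 for the rectangular arrangement, < 1 as it shears toward
a diamond. Three collinear projections set a degenerate flag.

The gate distance is the Euclidean Cα–Cα distance of the gate residue
on the two GluN1 chains, in Å, labelled "open" at or above a 28 Å
threshold — a configurable value chosen between the published open
(33.6 Å) and closed (23.43 Å) reference distances; the raw distance
always accompanies the label. Helix comparison is superposition RMSD
only (secondary-structure assignment is out of scope).

## The synthetic generator

The generator emulates statistical structure, not dynamics: frames are
independent redraws of a stationary ensemble (every analysis in scope
is a time average of a stationary observable), so there is no time
correlation, no kinetics, no forces. It is not MD and must not be read
as such.

* **Box and bilayer.** Default 8 × 8 × 24 nm; phosphate planes at
  12 ± 1.5 nm; 128 lipids on two 64-site leaflet lattices
  (1.0 nm²/lipid, a loose but membrane-like area per lipid); two
  16-carbon united-atom tails per lipid.
* **Order-parameter truth.** Each tail is a rigid all-anti zig-zag
  (C–C 0.153 nm, tetrahedral angles) whose axis is tilted at a fixed β
  from the bilayer normal with uniform random tilt azimuth and spin per
  lipid and frame. For an ideal zig-zag both reconstructed C–H vectors
  are exactly perpendicular to the chain axis, so the ensemble
  S_ch = −P₂(cos β)/2 at every carbon; β is solved from the requested
  target (feasible range −0.5 < S ≤ 0.25, default 0.20 → β ≈ 75°).
  The per-carbon profile is therefore flat by construction; the
  generator trades carbon-resolved shape for an exact analytic target.
* **Gas.** Each of the 2000 atoms goes into the inter-leaflet gap slab
  (12 ± 0.8 nm) with probability f_gap, else uniformly outside it —
  exact Bernoulli statistics, so the slab count is binomial. Hard-core
  insertion at the LJ contact distance 0.256 nm uses a periodic cell
  list with sequential rejection (deterministic given the seed). The
  default gap density (~18 atoms/nm³) makes the slab a genuinely
  continuous phase for the 6 Å probe, whose volume then matches the
  constructed slab volume.
* **Water and dehydration.** 5000 water beads, uniform; inside the TMD
  shell (the whole cross-section for z within the TMD range padded by
  3.5 nm) each candidate is relocated with probability d (the
  dehydration factor) to a reservoir slab at z = 4–6.5 nm — far enough
  from every RDF reference, including the periodic images of the
  top-of-chain rows, that near-protein bulk density and the global
  target density both remain equal to the control's. The normalised
  layout truth is then exactly 1 − d at rows whose 3.4 nm sphere lies
  inside the shell and 1 at rows whose sphere misses it; rows partially
  overlapping the shell boundary are classified as neither and not
  asserted against.
* **Channel placeholder.** Four chains of 60 single-Cα residues descend
  from z = 23 to the TMD bottom at 10.5 nm; TMD residues sit on the
  analytic pore surface (radius profile: 0.8 nm cylinder with a
  Gaussian pinch to 0.3 nm at the bilayer center) with azimuths
  staggered along the chain, plus two sidechain pseudo-atoms per TMD
  residue at larger radii so the wall has thickness and the inscribed
  circle stays confined. Residue names/numbers are assigned so the
  standard selectors resolve: the gate residue (GLU 299) on both GluN1
  chains at the extracellular radius (2.2 nm, hence a 44 Å gate
  distance), and OD1-bearing ASN 606/598 whose OD1 atoms sit at
  configurable rectangle corners (±0.55, ±0.45 nm → 11 Å and 9 Å sides,
  equal diagonals) just above the bilayer center.
* **Determinism.** All randomness flows from one `numpy` generator
  seeded by the spec; identical spec + seed reproduces byte-identical
  trajectories, asserted by hash.

What passing the recovery suite does **not** show: anything about time
correlation, gas percolation kinetics, force-field realism, per-carbon
order profiles, or protein conformational change — the generator has
none of these by design.

## Problem sizes and numerical choices

The default study conditions (2000 gas, 128 lipids, 5000 waters, 20
frames, ~11.6 k atoms) are the recovery-suite conditions; the analysis
scripts and the reproduction script run at exactly these sizes. The
published cluster and volume tables enter as printed inputs to the
summary arithmetic — the original ~100 ns trajectories were never
deposited, so their headline magnitudes (absolute RMSD, cluster counts,
absolute volumes) are not recomputable and are not claimed. Statistical
recovery tests use 3-standard-error bands (binomial bands for counts);
grid estimators use the tolerances stated above. Report rounding is
half away from zero throughout. Degenerate inputs (empty selections,
empty slabs, collinear triplets, fewer than two windows, NaN distances)
raise or warn explicitly rather than returning silent values.

## Known limitations

Rectangular boxes only; no velocities/forces/TPR; no triclinic cells;
no time-correlation or spectral analyses; the pore profiler assumes an
axis-aligned, singly-connected channel (no branched tunnels); layouts
assume chains long enough for at least one every-5th-Cα row; the
generator's lipids are geometric, not thermodynamic, objects.
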
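# Methods

This note records the models, conventions, and numerical choices behind
memprobe, and what the synthetic test system does and does not emulate.

## Coordinate conventions

All lengths are in Ångström, energies in kcal/mol, temperatures in
Kelvin (R = 1.987×10⁻³ kcal/(mol·K), pinned in `memprobe.constants`
together with Avogadro's number and the Å³→L conversion).

The bilayer midplane defines z = 0 and is recomputed per frame as the
mean z of all lipid phosphorus atoms; depths are measured from it. A
lipid belongs to the upper leaflet if its phosphorus sits above the
midplane; a peptide joins the leaflet whose phosphorus center of mass
is nearer; waters and ions follow the sign of their position. For
lower-leaflet analyses the frame is mirrored (z → −z) so every leaflet
is analysed with outward normal +z and positive depths; mirroring is an
involution and the two-leaflet system is treated as two symmetry
copies.

The cell is periodic in x and y (minimum-image displacements wrap those
axes only); z is non-periodic for analysis because the water slab
separates periodic images along the normal. This is also why the
per-frame midplane is our choice: harmonic restraints in the source
simulations fix only the *average* phosphorus height, so the
instantaneous mean is the natural frame-level reference.

## Geometry probes

The helix-region vector **h** joins the mass-weighted centers of the
first and last halves of a residue span (all heavy atoms, not Cα only);
for an odd span the middle residue is dropped from both halves, which
keeps the construction symmetric and deterministic. Tilt
γ = arccos(h_z/|h|) ∈ [0°, 180°]; 90° is parallel to the membrane.
Default tilt span: residues 6–14, with 15–20 as the C-terminal
alternative.

Rotation β is measured for one residue (default Lys19) in the frame
x̂′ ∥ **h**, ŷ′ = ẑ×**h** normalized, ẑ′ = x̂′×ŷ′: β = atan2(v·ẑ′, v·ŷ′)
mapped to [0°, 360°), where v is the component of (Cα − helix axis)
perpendicular to **h** and the axis passes through the span's heavy-atom
center of mass. β = 90°/270° point toward/away from water. A helix
axis parallel to ẑ leaves ŷ′ undefined; that case raises instead of
silently returning a number. β is averaged arithmetically, not
circularly: the distributions of interest sit far from the 0/360 wrap,
and this matches how the reference means were evidently taken; a
wrap-adjacent distribution would need the circular mean (documented
limitation).

The dimer angle α = arccos(ĥ₁·ĥ₂) keeps the signed N→C direction of
both vectors (span 15–20, where dimer contacts concentrate), so
antiparallel pairs give 180°, not 0°.

A residue is inserted in a frame iff its heavy-atom center of mass sits
strictly below z_P = 17.56 Å, the average phosphorus height of the
peptide-free bilayer at 330 K.

## Contacts and the periodic-image screen

A contact is a pair of side-chain heavy-atom centroids strictly closer
than 6.5 Å (the onset of side-chain hydration); Gly, lacking side-chain
heavy atoms, uses Cα so Gly7/Gly11 stay in the contact alphabet. C_d
counts interpeptide contacts within a leaflet; cross-leaflet pairs are
not mixed in.

The screen flags a frame when any pair of side-chain centroids — on two
peptides or within one — is in contact *only* through an x/y periodic
image: minimum-image distance below the cutoff while the direct
distance is not. The criterion used in the source study is not spelled
out; this discrepancy rule is our operationalization, and it is exact
on the generator's planted boundary frames while never firing on
interior configurations (direct and minimum-image distances coincide
there). Flagged frames keep their rows in every table but carry weight
zero in all averages.

## Bilayer maps

n(r, z) accumulates species heavy atoms in annular cells around each
(leaflet, peptide) reference choice — four copies for the 2×2 system —
with r the lateral minimum-image distance to the reference peptide's
center of mass and z the canonical depth. Cell volumes are
2π r̄ Δr Δz, which is exact for an annulus, so the density integral
returns the mean in-grid atom count (a tested conservation law).
Defaults Δr = 1 Å, Δz = 0.5 Å, r_max = 25 Å resolve the 6 / 21.5 Å
region boundaries.

The boundary z_b(r) is the first z (ascending, linear interpolation
between bin centers) at which a column falls below half the distant-
region plateau, the plateau being the mean density over distant cells
in a core band (default z ∈ [2, 12] Å). Thickness D(r) = 2 z_b(r);
thinning ΔD = ⟨D⟩_distant − ⟨D⟩_near. Columns that never cross are
reported missing, never zero-filled.

Lipids are represented by their phosphorus atoms and classified by the
lateral distance to the *nearest* same-leaflet peptide (near < 6 Å,
proximal ≤ 21.5 Å, distant beyond) — the nearest-peptide rule is the
natural two-peptide extension of a per-peptide definition and is what
produces cross-correlated lipid shells when peptides sit ~15 Å apart.
Region areas come from Monte-Carlo integration of the same rule over
the periodic cell (20 000 points, fixed internal seed 1234); the three
areas tile the cell exactly because each sample lands in exactly one
region. Surface densities are per-frame counts/area, weight-averaged,
with the DMPC:DMPG near ratio and the near-vs-distant total-density
drop exposed as derived statistics.

## Water wires

A hydrogen bond requires donor–acceptor oxygen distance strictly below
4 Å and ∠DHA strictly above 150°, minimum-image in x/y. The wire graph
is undirected (either water may donate) over waters with oxygen below
z_P plus a 4 Å bulk buffer above it, so connectivity to bulk is
decidable locally; a connected component is a wire iff it contains both
a sub-z_P water and one at or above z_P. Wire depth is the smallest
member-oxygen z. P_ww(z) pools wires over frames and leaflets (the
per-frame-deepest alternative sits behind a flag); the median is the
smallest z with P_ww ≥ 0.5.

## Free-energy landscapes and states

G = −RT ln P on sampled histogram cells, offset to min 0; unsampled
cells are masked, never zero-filled, so free-energy differences are
independent of the normalization. The 2D landscape uses z_DCM (depth of
the two-peptide center of mass in a leaflet, Δz = 0.5 Å) and C_d at
integer resolution.

Basins: 8-neighbor steepest descent to local minima (ties broken by
cell index). Saddles: cells sorted by ascending G and merged union-find
style; the G at which two basins first connect is their saddle, which
equals the max-min path height between their minima (tested against an
exhaustive threshold-sweep search). States: the basin whose minimum has
C_d = 0 is the inserted monomer IM; basins with minima at
C_d ≥ dimer_threshold (default 8, approximating the drawn monomer/dimer
divide) are mature dimers D; contact-bearing cells that drain into the
monomer basin, and basins with minima at 1 ≤ C_d < threshold, are
nascent dimers. Per-direction barriers ΔG†(k→l) = G†_k,min − G(k) are
reported from each state's exit saddle without forcing the two
directions to share one transition state: the published barrier pair
(3.8 / 1.2 kcal/mol against a 1.0 kcal/mol gap) cannot come from a
single shared saddle, so no consistency is imposed.

State probabilities are weighted frame fractions; nascent frames are
deliberately a third category (the published IM and D probabilities,
0.71 + 0.15, do not sum to 1). For the dimer equilibrium
ΔG_d = −RT ln(c₀ V P_d / P_m²), P_m is the IM fraction, P_d = 1 − P_m
(nascent counts as dimerized), V is the per-leaflet volume
(Lx·Ly·Lz/2), and c₀V is made dimensionless via Avogadro's number. The
bound fraction P_b uses a 4 Å heavy-atom peptide–lipid criterion (the
source reports P_b ≈ 1.0 without defining it).

## WHAM

Binless self-consistent WHAM in log space:
f_m = −ln Σ_j exp(−β_m U_j)/Σ_k N_k exp(f_k − β_k U_j), iterated with
no damping to a 10⁻⁷ max-change tolerance (gauge f₀ = 0), then
per-sample weights ∝ exp(−β_target U_j)/Σ_k N_k exp(f_k − β_k U_j).
With a single ladder state the same formula reduces to plain Boltzmann
reweighting (uniform at the native temperature). Solute-tempering
ensembles enter through user-supplied reduced energies, so plain
temperature replica exchange and solute tempering share one interface.
Standard errors for trajectory-level observables treat each independent
trajectory as one sample: SE = s/√n at n = 3 in the study design.

## Synthetic system

The generator emulates the study conditions as its defaults: a
59×59×74 Å cell, 30 DMPC + 19 DMPG pseudo-lipids per leaflet (98 lipids,
~1:25 peptide:lipid at two peptides per leaflet), head groups at
z_P = 17.56 Å, peptides planted at z_CM = 11.6 Å, γ = 107°, β = 105°
(Lys19), 14.8 Å apart, a 6.3 Å planted thinning, a 16% lipid depletion
probability around peptides (the published near-vs-distant density
drop), water wires to 8.5 Å, 8.5% of frames planted on the periodic
boundary, and 0.5 Å Gaussian thermal jitter.

Design choices worth knowing:

* **Lipids** are 5-bead stacks (L1/L2/L3 head beads, L2 = phosphorus;
  L4/L5 tails). Tail beads are resampled uniformly between the midplane
  and the head each frame ("melted tails"), which gives density columns
  a plateau-then-drop shape the half-maximum boundary can cross; the
  head height is lowered by half the planted thinning inside the near
  region with a linear ramp to the distant radius. Depletion relocates
  near-region lipids with a configurable probability rather than
  carving a hard void, so the near region stays sampled; the hard-void
  regime is reachable by raising `depletion_strength`.
* **Peptides** are ideal α-helices (1.5 Å rise, 100°/residue, Cα at
  2.3 Å) with one side-chain pseudo-atom per residue (CB at 4.3 Å; Gly
  uses Cα). Backbone N/C/O sit opposite the Cα/CB side at a radius that
  zeroes each residue's radial mass moment, so every residue's
  heavy-atom center of mass lies exactly on the helix axis. This makes
  planted (γ, β, z_CM) recovery *exact* at zero noise — the recovery
  tests measure the probes, not the generator's fidelity. Planted dimer
  contact counts are hit exactly by scanning lateral separation,
  azimuth, and axial offset against a brute-force pair count.
* **Water** is a sparse rigid lattice (no inter-water hydrogen bonds by
  spacing); wires are rigid vertical O–H···O chains with 2.5 Å links
  and collinear hydrogens, descending to an exact planted depth. Waters
  are excluded from thermal jitter so the planted hydrogen-bond
  geometry stays valid link by link.
* Lateral coordinates are wrapped into [0, L), as an MD engine would
  store them, so boundary-planted frames genuinely straddle the image.

What the generator does **not** emulate: realistic lipid packing or
area-per-lipid, force-field energetics, water structure beyond the
hydrogen-bond geometry, secondary-structure fluctuations coupled to
coordinates (labels are an independent Bernoulli fixture), or
correlated slow dynamics. Passing tests therefore demonstrate that the
*estimators* recover planted truth under idealized geometry and iid
noise — not that the pipeline is robust to force-field artifacts or
sampling error in real trajectories.

The replica-ladder fixture is a 1D harmonic oscillator (U = ½kx²)
sampled at each ladder temperature, whose closed-form moment
⟨x²⟩_T = k_B T/k is the independent oracle for WHAM.

## Problem sizes and numerics

Tests run the generator at 20–200 frames (60–100 where sub-degree
angle precision is needed: β varies by ~13° per frame at 0.5 Å jitter,
so means pool four peptides), WHAM at 16 ladder levels × 20 000
samples, and Monte-Carlo areas at 20 000–200 000 points; these sizes
put sampling error comfortably inside the asserted tolerances while
keeping the whole suite at a few minutes on one core. Histogram
boundary conventions are strict-left (numpy); ties in basin descent and
flooding break by cell index; degenerate inputs (empty selections,
all-zero weights, vertical helices, single-leaflet bilayers,
unconverged WHAM) raise typed exceptions rather than returning
defaults.

## Known limitations

* Multi-model PDB carries one box per file in practice; per-frame box
  fluctuations survive only through DCD input.
* β's arithmetic mean is wrap-sensitive (see above).
* The half-maximum boundary needs a sampled distant plateau; sparse
  short trajectories can leave near columns undefined, which is
  reported as missing rather than interpolated.
* Region areas ignore peptide-occluded area; whether the reference
  analysis subtracted it is unknown, so the areas are the plain
  partition of the cell.
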
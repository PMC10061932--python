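# Methods

This note documents the models and procedures implemented in `monofilm`,
the assumptions behind them, the parameters that matter, what the synthetic
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## System and conventions

The package analyses simulation boxes holding **two lipid monolayers** at
the two air–water interfaces of a central water slab: the lower leaflet's
chains point toward −z, the upper leaflet's toward +z.  All coordinates are
nm, times ns, pressures bar, tensions and surface pressures mN/m, areas per
lipid Å².  Only orthorhombic boxes are supported; the monolayers of
interest are square in xy, and triclinic cells would complicate the
minimum-image arithmetic for no modeled benefit.

Atom **roles** drive every analysis and are assigned from residue/atom
names (CHARMM36 nomenclature by default, fully overridable via TOML):
the phosphate phosphorus (one per phospholipid), the 10th acyl-chain
carbons C210/C310 (two per phospholipid) and cholesterol's C14 as
phase-clustering markers, and all protein heavy atoms.  Heavy atoms are
those whose first alphabetic character is not H.  Leaflets are assigned by
splitting the phosphorus z distribution with an exact 1D two-means scan;
molecules without a phosphorus (cholesterol, protein residues) join the
leaflet whose phosphorus population mean is nearest to their heavy-atom
mean depth.  A population-mean separation below 1 nm is treated as a
single-leaflet configuration error unless single-leaflet mode is requested.

## Isotherms

Surface tension from the pressure tensor, for n planar interfaces:

    γ [mN/m] = 0.1 · (L_z / n) · (P_zz − (P_xx + P_yy)/2)

with the 0.1 converting bar·nm to mN/m; monolayer boxes have n = 2.
Surface pressure is Π = γ₀ − γ.  γ₀ is a required configuration value
(defaults 71.7 mN/m at 298 K, 69.4 mN/m at 310 K — the experimental clean
water–air tensions) rather than a hard-coded constant, because the correct
reference for a simulation is the water model's own clean-interface
tension, which depends on the force field.  Negative Π values are reported,
not clipped; they are physically meaningful near full expansion.

Area per lipid is interface area divided by lipids per leaflet; protein
area is **never** subtracted, so APL remains comparable across
protein-free and protein-containing systems.

Compression simulations are out of equilibrium, so isotherms are extracted
by binning APL and Π into consecutive **non-overlapping 100 ns windows**
(time-based, not frame-count) and reporting window means with standard
errors; a trailing partial window is kept and flagged.  The shift between
two isotherms is the mean of ΔΠ on a common linear-interpolation grid over
their APL overlap, truncated to [50, 85] Å² by default: "across the
isotherm" is ill-posed at the collapse and full-expansion extremes, where
the curves are no longer parallel.  The shift's standard error combines
the per-window SEs of both curves scaled by the number of independent
windows in the overlap (grid points oversample windows and are not counted
as independent); with replicas, the between-replica spread of per-replica
shifts is the appropriate error instead.

## Condensed-phase detection

L_c packing is detected by clustering the chain-marker points of one
leaflet, projected to xy, with DBSCAN under periodic boundary conditions.
The DBSCAN is implemented in full (k-d tree neighbor search with periodic
topology, BFS core expansion) rather than delegated, because the border
rule must be deterministic: a border point reachable from several clusters
joins the one with the **smallest cluster id**, and cluster ids are ordered
by their smallest core-point index, so the partition is independent of
point order.  Neighborhood counts include the point itself, matching
scikit-learn's convention.  The implementation is verified against an
independently coded O(n²) brute-force reference (exact partition equality
on randomized instances) and cross-checked against scikit-learn's DBSCAN
with precomputed minimum-image distances on the tie-free core points.
It is also exposed as a scikit-learn-compatible estimator
(`PeriodicDBSCAN`) for use in sklearn pipelines.

Defaults: **ε = 0.55 nm, min_pts = 4, min_cluster_size = 10**.  These are
mandatory configuration entries, chosen so that a 0.48 nm hexagonal lattice
(every interior site has 6 neighbors within ε) clusters while disordered
markers with a guaranteed minimum spacing of 0.55 nm have no ε-neighbors at
all.  A marker is L_c iff its cluster, border members included, has at
least min_cluster_size markers; everything else, noise included, is L_e.

Distance-from-protein profiles use **2D minimum-image distances** to the
nearest protein heavy atom, because the phases are defined in the monolayer
plane; contact counting (below) uses 3D distances, because the protein's
transverse position matters there.  Both conventions are documented on the
respective functions; a 3D option exists behind a flag.  Empty distance
bins are reported as missing, never as zero.

## Density maps and thickness

Per frame and leaflet, atom depths are re-expressed as
z′ = −s·(z − ⟨z_P⟩), where ⟨z_P⟩ is the leaflet's mean phosphorus z and s
the outward-normal sign.  This per-leaflet, per-frame alignment is what
makes "the phosphorus plane stays at the same depth" exact, and it puts the
chain (air) side at negative z′ for both leaflets so they can be pooled.
Mass-weighted histograms (masses from the leading element letter of the
atom name) are averaged within surface-pressure regimes; each frame's
regime is the window-mean Π of the 100 ns isotherm window containing it.
The **extent** of a species is the outermost pair of bin centers where its
profile exceeds 5% of its maximum, and monolayer thickness is the extent
span of the pooled phospholipid density.  Profiles integrate back to the
total species mass (relative error < 1e−6) when the bin range covers all
atoms — a standing invariant in the tests.

## Tilt

Chain tilt is the angle between the first→last chain-carbon vector and the
outward leaflet normal (+z upper, −z lower), in [0°, 180°]; chains missing
their end atoms are skipped with a logged count.  The protein axis is the
largest-variance principal component of the centered backbone coordinates,
sign-fixed from the N to the C terminus (so a head-down helix reads >90°,
not its supplement); two points degenerate to their connecting vector.
Both are invariant under rotations about z and translations.

## Contacts

A contact is one (protein heavy atom, lipid heavy atom) pair within
**0.3 nm** 3D minimum-image distance, counted per protein residue and lipid
type with a periodic k-d tree whose output is checked against all-pairs
counting.  Raw counts are normalized by the number of **possible contact
partners**: the heavy-atom abundance of each lipid type in the
protein-containing leaflet.  This interpretation corrects for both copy
number and molecular size (a CHOL has far fewer heavy atoms than a DPPC);
a per-molecule alternative is available behind a flag.  Per-residue maps
are additionally divided by the lipid-type mole fraction so residue-level
preferences are composition-corrected.  Zero-abundance types yield missing
values, not infinities.  Frames are averaged within each pressure regime;
when replica labels are provided the independent samples are the
monolayers, so means are per-replica first and the standard error is taken
across replicas (absent with fewer than two).  Contacts are averaged per
frame, then pooled — pooling before normalizing would change only the SE.

## Diffusion

Lateral displacements are taken per molecule over **non-overlapping 10 ns
lag windows** of the unwrapped reference-atom track (phosphorus for
phospholipids, the hydroxyl oxygen for cholesterol, heavy-atom center of
mass for the protein; the tracking atom is configurable since the lipid
body moves rigidly on these time scales).  Non-overlapping windows give
independent samples and therefore valid standard errors without
autocorrelation corrections.  The leaflet center-of-mass displacement is
subtracted by default — the two monolayers of a box drift independently.
Lags are rounded to whole frame intervals; the actual lag used is logged
and reported.

For free 2D diffusion the displacement magnitude is Rayleigh distributed,
p(r) = (r/2Dt)·exp(−r²/4Dt), and the MLE is closed-form:
D̂ = Σr²/(4tn) with se(D̂) = D̂/√n.  A Kolmogorov–Smirnov distance against
the fitted density is attached as a goodness-of-fit diagnostic (large
values flag confined or multi-population motion, where the free-diffusion
D is only an effective value).  The estimator is exactly unbiased on
model-generated data (verified to <1% over 200 seeds).  No finite-size
periodic-boundary hydrodynamic correction is applied; reported values and
ratios (relative diffusion normalized to the 0–15 mN/m regime, slowdown
percentages 100·(1 − D/D_ref)) are meant for trends, which the correction
largely cancels.

RMSD uses the least-squares Kabsch superposition (via quaternion
alignment) after centering; with fewer than 3 points superposition is
refused, and an unsuperposed RMSD is available.

## Synthetic generator

The generator exists so that every stage has an oracle.  Study conditions
it encodes: 60/20/10/10 DPPC/POPC/POPG/CHOL composition; two mirrored
leaflets; compression between 90 and 45 Å² per lipid; 100 ns isotherm
windows; 10 ns diffusion lags; four Π regimes; 169 lipids per leaflet in
the default fixture set (the protein-to-lipid ratio of the emulated
systems).  All generators are deterministic in their seed, and every
stochastic construct emits its ground truth (phase labels, true D, true γ
schedule).

**Monolayer.**  Chain markers per leaflet: 2 per phospholipid, 1 per
CHOL.  A planted fraction f_lc of them is placed on hexagonal patches of
spacing 0.48 nm (compact blobs; the patch count falls back automatically
when the requested number cannot be placed without overlap, and a patch
that cannot fit at all is a geometry error).  The remaining markers are
placed as **blue noise with a guaranteed minimum distance of 0.55 nm**:
a pseudo-hexagonal grid stretched to tile the periodic box exactly, with
each site jittered by half the slack between the lattice's shortest
neighbor distance and the guarantee.  A guaranteed-minimum-distance
construction was chosen over rejection sampling because the required
marker densities (≈2.1–3.2 nm⁻²) sit near the random-sequential-adsorption
jamming limit for 0.55 nm discs, where dart-throwing is slow and
unreliable; the guarantee, not the sampler, is what makes the plant
DBSCAN-separable.  Expanded markers additionally keep 0.65 nm from every
condensed lattice site so they cannot become border members of a condensed
cluster.  Molecules are assembled with the phosphate above the chain
pair's midpoint (z scatter σ = 0.15 nm about the interface), markers
1.0 nm outward, chain start/end carbons at 0.45/1.6 nm, cholesterol O3,
C3, C14, C17 along the same axis.  Residue-name order is fixed per
leaflet so an entire compression stack shares one topology (multi-frame
GRO requires it); condensed sites are filled from the front of the type
list, i.e. DPPC condenses preferentially, which is also the physically
expected behavior.

**Pseudo-protein.**  A rigid two-layer disc of ~100 CA beads on a
sunflower spiral, placed at the center of the upper leaflet, spanning the
head-group-to-chain region.  It makes no attempt to mimic SP-B or SP-C
structure — the analyses only consume heavy-atom positions and residue
identities.  Condensed lattice sites within `halo_width` of any bead are
demoted to expanded with probability `halo_lc_suppression` (always, inside
the disc footprint); ground truth is the **realized** labels, so with a
full-suppression halo the realized condensed fraction is below the nominal
f_lc by construction.  Expanded markers may approach beads to 0.3 nm so
lipid–protein contacts exist.

**Brownian tracks.**  Independent Gaussian steps of per-axis variance
2·D·dt, wrapped into the box with the unwrapped coordinates retained as
truth; tracers are single-atom phosphorus-tagged molecules.

**Pressure series.**  P_zz is held at 1 bar and the lateral components
absorb the anisotropy so the two-interface tension formula recovers the
scheduled γ exactly before Gaussian noise is added to P_xx and P_yy; the
APL column ramps linearly in box edge between its endpoints.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: thermal disorder inside condensed patches (the
lattice is exact), chain conformational entropy and tilt disorder (chains
are built along the normal), water, electrostatics and any real
protein–lipid energetics (the halo is imposed, not emergent), correlated
lipid motion and momentum conservation in diffusion, and collapse physics
below ~50 Å² per lipid, where the marker density would exceed the
packing limit and the generator raises a geometry error instead.  The
tests therefore validate the *analysis machinery* — that each estimator
recovers what is truly in the data — not the force-field science.

## Pipeline and reproducibility

The `run` pipeline derives every stratification from a single source of
truth (the window-mean Π per frame), writes tidy one-observation-per-row
TSVs, and embeds a SHA-256 hash of the configuration in `report.json`;
output depends only on (inputs, config) and reruns are byte-identical.
Stage failures abort with the stage name and remove partial outputs.
Protein-dependent stages (contacts, distance profiles, RMSD) are skipped
with a logged reason on protein-free input.  When no pressure regime spans
the diffusion lag — e.g. a stack of widely spaced configurations — a
single whole-trajectory estimate at the achievable lag is reported and
flagged in the log; on such stacks it measures configurational
decorrelation, not physical diffusion.

Problem sizes in the shipped tests and the acceptance script (400 lipids
per leaflet for phase recovery, 300 for the halo, 5000 displacements, 200
estimator-bias seeds, 45 isotherm windows) were chosen so each planted
quantity is recovered with sampling error several times smaller than its
tolerance while the whole suite runs in well under a minute.

## Known limitations

GRO fixed-column precision (0.001 nm) bounds round-trip fidelity; ITP/PSF
topology files are not parsed (roles come from name maps); no triclinic
cells; no hydrogen-bond or residence-time contact kinetics; the isotherm
shift assumes the two curves are vertically parallel over the averaging
range (the package reports, but does not model, shape changes); replica
discovery across files is manual (a replica column is supported
throughout).
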
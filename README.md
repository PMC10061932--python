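# monofilm

Trajectory analysis for molecular-dynamics simulations of pulmonary-surfactant
lipid monolayers, with or without the hydrophobic surfactant proteins (SP-B,
SP-C).  The package turns compression trajectories of a
DPPC/POPC/POPG/CHOL (60/20/10/10) film at the air–water interface into the
standard observables of monolayer biophysics:

* **Surface pressure–area isotherms** from the pressure tensor:
  γ = 0.1·(L_z/n_interfaces)·(P_zz − (P_xx+P_yy)/2) in mN/m, Π = γ₀ − γ,
  binned into non-overlapping 100 ns time windows (compression runs are out
  of equilibrium), plus the mean vertical shift between two isotherms.
* **Liquid-condensed (L_c) phase detection**: DBSCAN with minimum-image
  distances on the 10th acyl-chain carbons and the cholesterol C14 projected
  into the monolayer plane; clusters above a size threshold are L_c, the rest
  liquid-expanded (L_e).  Includes the L_c fraction as a function of the
  shortest distance from the protein.
* **Transverse density maps**: per-species mass density vs depth, aligned so
  the phosphate plane sits at z′ = 0 in every frame and leaflet, with
  5%-of-maximum extent curves and monolayer thickness.
* **Tilt**: acyl-chain tilt and the protein principal-axis tilt relative to
  the outward monolayer normal.
* **Lipid–protein contacts**: heavy-atom pairs within 0.3 nm, normalized by
  the number of possible contact partners per lipid type, stratified by
  surface-pressure regime (0–15, 15–30, 30–45, >45 mN/m).
* **Lateral diffusion**: maximum-likelihood fit of the 2D free-diffusion
  displacement distribution p(r) = (r/2Dt)·exp(−r²/4Dt) over 10 ns lags
  (D̂ = Σr²/4tn), relative normalization and slowdown percentages, and
  Kabsch-superposed protein RMSD.

Because multi-microsecond atomistic trajectories cannot be shipped or
regenerated at desk scale, the package carries a first-class
**synthetic-configuration generator** (`monofilm.synth`) that plants known
ground truth for every stage: hexagonally packed L_c patches among
blue-noise L_e markers, a pseudo-protein disc with a tunable L_c-depletion
halo, 2D Brownian tracks with known D, and pressure-tensor series with an
exact planted surface-tension schedule.  Every analysis is validated by
recovering these plants.

## Worked example

Generate a 300-lipid-per-leaflet monolayer with a 40% condensed plant and a
protein disc that fully suppresses condensed packing within 1.5 nm, then
recover the plant:

```python
import numpy as np
import monofilm as mf
from monofilm.synth import MonolayerSpec, ProteinSpec, generate_monolayer

spec = MonolayerSpec(n_lipids_per_leaflet=300, f_lc=0.4, seed=3,
                     protein=ProteinSpec(radius=1.2, halo_width=1.5))
topology, frame, truth = generate_monolayer(spec)
labeling = mf.phase_labels(frame, topology, "upper")
print("planted L_c fraction (upper):", round(truth.lc_fraction("upper"), 3))
print("recovered L_c fraction      :", round((labeling.phase == "Lc").mean(), 3))

prot_xy = frame.positions[topology.role_mask("protein"), :2]
prof = mf.lc_fraction_vs_distance(labeling, prot_xy, frame.box[:2],
                                  np.arange(0, 5.1, 1.0))
print(prof.to_string(index=False))
```

Output:

```
planted L_c fraction (upper): 0.4
recovered L_c fraction      : 0.4
 bin_lo  bin_hi  n_markers  lc_fraction
    0.0     1.0         29     0.000000
    1.0     2.0         50     0.100000
    2.0     3.0         71     0.309859
    3.0     4.0         99     0.414141
    4.0     5.0        113     0.584071
```

The DBSCAN labels reproduce the planted condensed fraction exactly, and the
distance profile shows the protein's L_e halo: no condensed packing within
the 1.5 nm halo (the 1–2 nm bin mixes halo and bulk), rising toward the
bulk plant beyond it — the depleted-vicinity signature that, in real
simulations, distinguishes proteins that fluidize their surroundings.

## Command line

```bash
monofilm synth --out fixtures/                 # synthetic compression fixture set
monofilm run --trajectory fixtures/trajectory.gro \
             --pressure fixtures/pressure.xvg --out results/
monofilm isotherm --pressure fixtures/pressure.xvg --stdout
```

`run` writes tidy TSV tables (isotherm, phases, lc_vs_distance, density_map,
extents, contacts_by_type, contacts_by_residue, diffusion, rmsd) and a
`report.json` with parameters, a config hash and per-stage record counts;
reruns are byte-identical.  Inputs are GRO coordinate files (single- or
multi-frame) and GROMACS-style XVG pressure series; atom roles follow
CHARMM36 names by default and are overridable via a TOML role map.

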
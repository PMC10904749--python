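# memprobe

Trajectory analysis for membrane-bound antimicrobial peptides — built
around the system of PGLa, a 21-residue cationic amphipathic helix from
*Xenopus laevis*, bound to an anionic DMPC/DMPG (3:2) bilayer at one or
two peptides per leaflet. The package turns raw coordinate trajectories
(PDB topology plus multi-model PDB or DCD frames) into the standard
structural and thermodynamic observables of membrane-peptide studies,
and ships a synthetic-system generator with planted ground truth so
every stage is testable without simulation data.

## What it computes

**Geometry probes.** Peptide center-of-mass depth z_CM above the bilayer
midplane; per-residue depth profiles P(z; i) with insertion calls
(inserted iff z(i) < z_P = 17.56 Å, the phosphorus plane); the helix
tilt γ = ∠(**h**, ẑ) where **h** joins the centers of mass of the two
halves of a helix region (γ = 90° means parallel to the membrane); the
azimuthal rotation β of a residue's Cα about the helix axis (β = 90°
points toward water); the dimer angle α between two peptides' C-terminal
**h** vectors; the radius of gyration.

**Helicity.** Aggregation of external per-residue secondary-structure
labels (STRIDE one-letter codes; helical = {H, G, I}) into per-residue
helix/turn/coil fractions, region means, and the count of residues with
H(i) > 0.5.

**Contacts and dimerization.** Side-chain centroid contacts at a 6.5 Å
cutoff (Gly uses Cα), the per-leaflet interpeptide contact count C_d,
contact probability tables, and a periodic-image screen that removes
frames whose peptide contacts exist only through an x/y image.

**Bilayer maps.** Cylindrical lipid and water densities n(r, z) around
each peptide (leaflets and peptides permuted as symmetry copies), the
bilayer boundary z_b(r) by half-maximum against the distant plateau,
thickness D = 2 z_b and thinning ΔD = D(distant) − D(near), and
Table-style surface number densities n_s,l, n_s,DMPG, n_s,DMPC in the
near (r < 6 Å), proximal (6–21.5 Å), and distant (r > 21.5 Å) lipid
regions, with Monte-Carlo region areas.

**Water wires.** Hydrogen bonds (d(D–A) < 4 Å, ∠DHA > 150°) among
waters, connected chains linking the bulk above z_P to depth, and the
cumulative penetration probability P_ww(z) with its median depth.

**Free-energy landscapes.** Weighted histograms; G(z_DCM, C_d) =
−RT ln P with basin assignment by steepest descent and saddle points by
union-find flooding; inserted-monomer (IM), nascent-dimer, and mature-
dimer (D) states with per-state probabilities, free energies
G(k) = −RT ln[P(k)/P(IM)], barriers ΔG† and observable means; the
monomer–dimer equilibrium free energy

    ΔG_d = −RT ln(c₀ V P_d / P_m²)

and WHAM reweighting of replica-exchange ensembles to a target
temperature (binless self-consistent iteration in log space).

## Worked example

```python
from memprobe import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    out_dir="out", seed=42,
    synthetic=dict(n_frames=24, seed=42),   # planted study-condition system
)
summary = run_pipeline(cfg)
for key in ("mean_gamma", "mean_beta", "mean_z_cm", "thinning",
            "wire_median_depth", "excluded_fraction"):
    print(key, round(summary[key], 2))
```

prints

```
mean_gamma 107.07
mean_beta 106.05
mean_z_cm 11.6
thinning 6.17
wire_median_depth 8.5
excluded_fraction 0.08
```

— the tilt, rotation, and insertion depth recover the generator's
planted 107° / 105° / 11.6 Å within thermal noise, the bilayer is
thinner near the peptides by ~6.3 Å as planted, half the water wires
reach 8.5 Å, and 8% of frames were excluded by the periodic-image
screen (2 of 24 planted at the box boundary). The same pipeline runs on
file input by replacing `synthetic` with `topology:` and
`coordinates:` paths, or from the shell:

```sh
memprobe all --config config.yaml --out out --seed 42
```

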
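# graymorph

Morphometry of brain cells for diffusion-MRI microstructure modelling.

Biophysical models of the diffusion-MRI (dMRI) signal in grey matter need
quantitative priors on cellular geometry: how big somas are, how thick,
long, wiggly and branched dendritic and glial projections are, how
dispersed their orientations are, and how fast water exchanges across cell
membranes. `graymorph` computes those quantities from 3D cell
reconstructions in the standard SWC format (e.g. from NeuroMorpho.org) and
translates them into experiment-design thresholds — at which diffusion
times each morphological feature leaves a measurable imprint on the
signal. It is aimed at dMRI modellers, microstructure-imaging researchers,
and anyone validating simulators against realistic cellular substrates.

## What it computes

**Structural descriptors** (per cell, per branch). After stripping axons
and dendritic spines, the soma is separated from projections at the
root-radius threshold and each projection is split into branches between
bifurcation/termination nodes, modelled as chains of cylindrical
sub-segments along a curvilinear path *s*:

- domain radius R_domain, number of primary projections N_proj, branch
  order BO, whole-cell S/V;
- soma equivalent radius R_soma = (3V/4π)^⅓, effective MR radius
  R_MRsoma = (⟨R⁷⟩/⟨R³⟩)^¼, projection surface coverage η_soma, soma S/V
  (measured on a marching-cubes or convex-hull surface of the soma nodes);
- branch length L_branch, mean radius ⟨R_branch⟩, effective MR radius
  (⟨R⁶⟩/⟨R²⟩)^¼, beading CV_branch = σ_R/⟨R⟩, S/V_branch, undulation
  µOD_branch (mean sub-segment-to-chord angle), curvature radius ⟨R_c⟩,
  straightness τ_branch = chord/path ∈ (0,1], bifurcation angle θ_branch.

**Shape descriptors.** Projections are cut into ~10 µm line segments; the
volume-weighted scatter matrix of their axial orientations gives
eigenvalues τ₁ ≤ τ₂ ≤ τ₃ (trace 1),

    FA = sqrt( 3/2 · Σ(τᵢ − τ̄)² / Στᵢ² ),

an adjusted FA with τ₁ := τ₂ (correcting depth-of-field Z-compression),
Watson/Bingham concentration fits, and orientation dispersion
OD = (2/π)·arctan(1/κ).

**Topological descriptors.** The topological morphology descriptor (TMD):
path-length persistence barcodes (one bar per terminal, built by
eliminating the shorter sibling at each bifurcation), unit-sum persistence
images, the L1 topological distance D ∈ [0, 2], and a resampling bootstrap
for group differences.

**Exchange & relevance.** Residence time τᵢ = 1/((S/V)·κ) for membrane
permeability κ, exchange time τ_ex = τᵢ·f_ec, restriction / curvedness /
branching / soma-exchange thresholds, a spine surface-to-volume
adjustment, and a mechanism-by-mechanism relevance report for water
(D = 2 µm²/ms) and metabolites (D = 0.4 µm²/ms).

**Synthetic cells.** A generator produces SWC cells with exact ground
truth (soma radius, branch lengths/radii/taper/beading, undulation,
Watson-distributed projection orientations, optional Z-compression,
spines, axon), so the whole pipeline is validated by parameter recovery
without external data.

**Meshing.** Watertight triangle meshes of the implicit union of node
spheres and edge capsules (marching cubes), exportable to PLY/OBJ/STL for
Monte Carlo diffusion simulators.

## Worked example

```python
from graymorph.synthetic import SyntheticCellSpec, generate_cell
from graymorph.morphometry import structural_record
from graymorph.shape import shape_record
from graymorph.exchange import relevance_report, WATER

cell, truth = generate_cell(SyntheticCellSpec(), seed=1)
rec = structural_record(cell)
shp = shape_record(cell)
print(f"N_proj={rec.N_proj}  BO={rec.BO}  R_soma={rec.R_soma:.2f} um")
print(f"L_branch={rec.L_branch:.1f} um  S/V_branch={rec.SV_branch:.2f} 1/um")
print(f"tau_branch={rec.tau_branch:.3f}  muOD={rec.muOD_branch:.3f} rad")
print(f"FA={shp.FA:.3f}  adjFA={shp.adjFA:.3f}  OD={shp.OD:.3f}")

rep = relevance_report(
    {"R_soma": rec.R_soma, "R_branch": rec.R_branch_mean,
     "N_proj": rec.N_proj, "R_domain": rec.R_domain, "R_c": rec.R_c,
     "L_branch": rec.L_branch, "SV_branch": rec.SV_branch,
     "muOD_branch": rec.muOD_branch}, WATER)
print(rep.to_table())
```

prints

```
N_proj=7  BO=3  R_soma=4.98 um
L_branch=57.7 um  S/V_branch=10.50 1/um
tau_branch=0.918  muOD=0.371 rad
FA=0.491  adjFA=0.348  OD=0.282
mechanism                          threshold (ms)  verdict
soma_restriction                              2.5  measurable
soma_projection_exchange                     86.6  negligible
domain_restriction                         4681.1  negligible
curvedness                                  515.4  negligible
undulation                                    0.0  measurable
branching                                   832.6  negligible
permeative_exchange                           2.9  measurable
```

i.e. for this synthetic neuron (5 µm soma, seven projections, ~58 µm
branches) at a typical in vivo acquisition (t_d = 60 ms), soma restriction,
undulation and permeative exchange are measurable while domain
restriction, curvedness and branching exchange are safely negligible —
exactly the kind of statement a model builder needs per mechanism.

The same pipeline runs from the shell:

```sh
graymorph simulate --n 10 --seed 1 --out-dir pop/
graymorph batch pop/ --out-prefix pop
graymorph report pop_cells.csv
graymorph mesh pop/cell_0000.swc --out cell0.ply
```

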
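# Methods

This note documents the model implemented by `eruptsim`: what is computed,
under which assumptions, with which parameters and units, and where the
approach stops.

## Units

Millimetres, Newtons, MPa (N/mm²). Muscle cross-sections are given in cm²
and muscle force constants in N/cm², following the convention
F = X · K · EMG; the resulting force is in N. BRU (hydrostatic stress ×
element volume) carries N·mm.

## Synthetic model

The domain is a rectangular bone block voxelized at a uniform pitch
(default 1 mm). Regions, by integer code:

| code | region | E (MPa) | ν |
|---|---|---|---|
| 1 | cortical bone | 13 700 | 0.30 |
| 2 | cancellous bone | 7 930 | 0.30 |
| 3 | enamel | 80 350 | 0.33 |
| 4 | dentine | 17 600 | 0.25 |
| 5 | pulp | 2.07 | 0.45 |
| 6 | follicle / PDL | 0.68 | 0.49 |
| 7 | anterior condylar cartilage | 0.79 | 0.49 |
| 8 | posterior condylar cartilage | 6.8 | 0.49 |

All materials are homogeneous, isotropic, linear elastic. Values can be
overridden per region (`MaterialTable.with_overrides`); ν is validated to
(−1, 0.5) and E to be positive.

The unerupted tooth is a capsule (line segment of length `root_length`
swept by `crown_radius`) along a configurable long axis; voxels whose
centre lies within the capsule are tooth, with enamel assigned where the
axial coordinate is within the crown cap and dentine elsewhere (an optional
coaxial pulp core can be enabled via `pulp_radius`). The follicle is a
distance band of `follicle_thickness` around the capsule, followed by one
pass of 26-connected binary dilation so that no bone voxel ever touches a
tooth voxel — the shell is guaranteed at least one voxel thick in every
direction. A cortical shell of `cortical_thickness` lines the box surface;
everything else is cancellous. The generator rejects configurations where
the tooth-plus-follicle reaches the domain boundary, where the follicle
would be thinner than one voxel, or where the capsule captures no voxel
centre.

Each labelled voxel is split into 6 tetrahedra (Kuhn subdivision) with a
globally consistent main diagonal, giving a conforming mesh with positively
oriented elements; voxel volume is conserved exactly.

### Default scenario

The shipped default (`RunConfig()`) is a 32 × 12 × 14 mm block with the
tooth at mid-span (crown centre (16, 6, 10.5), crown radius 1.8 mm, root
length 5.5 mm, axis pointing down). The block is simply supported on its
bottom edges at both x-ends; two mirrored adductor muscles (cross-section
6 cm², constant 40 N/cm²) pull upward near the top ends; bite contact is
modelled as vertical fixity of a patch of occlusal-surface nodes **away
from the unerupted tooth** — at 25 % of span for the incisive mode
(activation 0.4) and 75 % for the unilateral-molar mode (activation 0.8).
The offset reflects that occlusal contact occurs on erupted teeth, not over
the crypt; the unerupted tooth then sits in the beam's bending field, which
places the coronal follicle cap in the compressive fibre and the apical cap
in the tensile fibre.

## FE solver

4-node constant-strain tetrahedra (tet4), small strains, engineering shear
in Voigt notation. Element stiffness Ke = V·BᵀDB with the isotropic D from
(λ, μ); global assembly is vectorized COO→CSR. Dirichlet conditions
(including non-zero prescribed values, needed for the patch test) are
applied by reduction to free DOFs: K_ff u_f = f_f − K_fc u_c, solved with
a sparse LU factorization (`scipy.sparse.linalg.splu`). Fewer than six
constrained DOFs, or a singular reduced system, raises an error. After each
solve the global equilibrium residual ‖K u − f‖/‖f‖ is checked against
1e-6 (observed ~1e-13 on the default scenario). Strain is recovered as the
symmetric displacement gradient per element and stress via Hooke's law.

## Field metrics

Per element: volume |det J|/6; principal strains S1 ≥ S2 ≥ S3 by symmetric
eigendecomposition; equivalent strain
S_e = (1/(1+ν)) · √(((S1−S2)² + (S2−S3)² + (S3−S1)²)/2), zero for purely
volumetric strain and positively homogeneous of degree 1; hydrostatic
stress σ_h = tr(σ)/3 with negative values meaning net compression; and
BRU = σ_h · V.

## Cap analysis

The tooth long axis is the principal covariance direction of the tooth
element centroids, oriented crown→apex using the enamel centroid; a
spherical (ambiguous within 1 %) centroid cloud is rejected. Coronal and
apical caps are the follicle elements within 3 mm (default `cap_depth`) of
the extreme axial coordinates; a follicle too short for disjoint caps is
rejected, while an infinite depth selects the whole follicle.

Compression percentages: by volume, 100 · Σ V(σ_h<0) / Σ V; by BRU,
100 · Σ|BRU|(σ_h<0) / Σ|BRU|. Elements with σ_h = 0 count in the
denominator only. Histograms use half-open bins [lo, hi) with explicit
underflow/overflow rows; each curve (compression and tension, volume- and
BRU-weighted) is normalized to 100 % independently. Default stress bins are
0.005–0.07 MPa in 0.005 steps; BRU bins are 0.00029–0.00250 N·mm in
0.00017 steps (coronal) and 0.000050 N·mm in 0.000045 steps with a final
partial bin ending at 0.000630 (apical).

Pooling recomputes percentages over the concatenated element records of
several caps (never by averaging percentages), excluding second molars by
default. Exception classification requires the full tooth × side × cap ×
load grid, flags coronal caps with compression < 50 % and apical caps with
compression > 50 %, treats exactly 50 % as conforming, and marks near
misses within 4 points of 50 % (inclusive).

A printed reference table of 64 cap compression percentages (canines,
premolars and second molars; two sides, two loads, two bases) ships as
package data for exercising the classification logic; on it the volume
basis yields 7 exceptions of 24 eruptive-tooth instances and the BRU basis
5 of 24, of which 4 are near misses.

## Direct-field generator

For statistical tests a direct sampler bypasses the FE solve: per-cap
hydrostatic stresses are drawn i.i.d. normal (means `mu_c`, `mu_a`, common
`sigma`) and volumes lognormal, giving records with a known compressive
volume fraction Φ(−μ/σ) against which `compression_volume_percent` is
verified within Monte-Carlo error (effective sample size
(Σw)²/Σw² for volume weights).

## I/O and reproducibility

Meshes and fields are written as legacy ASCII VTK unstructured grids
(tetra cells only; region as CELL_DATA scalars, tensors in Voigt order as
FIELD arrays) and can be read back bit-consistently. A pipeline run writes
its configuration, solutions, CSV summaries and a manifest with SHA-256
hashes of every artifact; reruns with the same configuration and seed are
byte-identical.

## Limitations

- Linear elasticity, small strains, static loading; no contact, no
  time-dependence, no remodelling feedback — BRU is a per-solve dose proxy,
  not a simulated biological response.
- tet4 elements are stiff in bending and constant-strain per element;
  field resolution is limited by the voxel pitch.
- The geometry is a schematic block, not an anatomical jaw: muscle
  attachments, bite patches and supports are idealized node sets, and
  condylar cartilage materials are available but unused by the default
  scene.
- The follicle/PDL is modelled as a compressible-enough linear solid
  (ν = 0.49), not as a fluid-filled or fibre-reinforced tissue.
- Cap percentages quantify the sign pattern of σ_h only; no threshold for
  biological activation is applied.
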
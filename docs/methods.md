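# Methods

## Problem and model

Two triangle meshes sample the same rigid anatomy: a *reference* with full
coverage but coarse sampling (a CT-derived crown-and-root model) and a
*target* with partial coverage at much finer sampling (an optical
crown-only scan), displaced by an unknown rigid motion. The estimand is
the proper rigid transform (R, T), acting as q = R p + T on column
vectors, that maps target coordinates into the reference frame. The
squared-error objective e = Σᵢ ‖qᵢ − (R pᵢ + T)‖² over corresponding
point pairs is minimized in closed form by the Arun/Kabsch SVD estimator:
demean both sets, decompose the cross-covariance H = Σ p'ᵢ q'ᵢᵀ = U S Vᵀ,
take R = V diag(1, 1, det(V Uᵀ)) Uᵀ and T from the centroids. The
determinant factor negates the singular direction of smallest singular
value whenever the unconstrained orthogonal optimum is a reflection, so
the estimator always returns a proper rotation and is exact on noise-free
rigid correspondences. Configurations with fewer than three pairs or
collinear source points leave the rotation undetermined and are rejected.

## Discrete curvature and feature points

Vertex curvature is the angle deficit over the one-ring area,
K = (2π − Σθⱼ)/A, with A the **full** one-ring area. For a fine
triangulation of a smooth surface the deficit ≈ (Gaussian curvature) ×
(A/3), so this K reads about one third of the pointwise Gaussian
curvature; a barycentric mode (divide by A/3) is exposed for users who
want the pointwise scale. Two consequences matter in practice:

* **Scale dependence.** K scales as 1/s² under uniform scaling; a feature
  threshold α is meaningful only for a given unit system and sampling
  density. The package default α = 0.01 mm⁻² suits tooth-sized geometry
  (cusps of millimetre curvature radius) sampled below ~1 mm.
* **Noise amplification.** The deficit is a second difference, so vertex
  noise of sd σ on edge length h produces curvature noise of order σ/h².
  On a 0.47 mm grid with 0.05 mm noise that is ~0.23 mm⁻² — larger than
  a cusp's signal (~0.08). Feature extraction on fine noisy scans
  therefore needs denoising first; the pipeline offers per-input Taubin
  λ/μ smoothing (uniform-Laplacian shrink/inflate passes, λ = 0.5,
  μ = −0.53), applied where the noise is. Smoothing alters no coordinate
  frame, so the estimated transform applies to the original coordinates.

Boundary vertices lack a full ring and are excluded from features
(diagnostic (π − Σθ)/A available). The Gauss–Bonnet identity — summed
deficits of a closed genus-0 mesh equal 4π — is used as an exactness
check on the implementation, not an approximation: it holds to rounding
for any triangulation.

## Coarse registration

Three reference points are drawn from the top curvature decile of the
reference's feature set, with a floor of 30 eligible points so that
sparse feature sets still admit a spatially spread triple; among eligible
points the triple maximizing the minimum pairwise distance is chosen
(exhaustively for ≤ 50 eligible, else a farthest-point heuristic).
Collinear triples are rejected. The pipeline additionally requires each
anchor to have at least ~10 curvature-similar candidates in the target:
a cusp so sharp that denoising shifted its curvature out of every target
vertex's reach can only attract spurious candidates and must not anchor
the search.

For each anchor, target features within `curv_tol` of its curvature form
a candidate list (ascending deviation, capped at `candidate_cap`). A
candidate triple must reproduce the anchor triangle's three side lengths
within `dist_tol` and its Heron area within `area_tol` — both rigid
invariants. The printed area formula in the source material is a
corrupted Heron's formula; the standard S = √(s(s−a)(s−b)(s−c)) is the
only dimensionally consistent reading and is what the area constraint
uses.

**Choosing among survivors.** With tight curvature tolerance (exact-copy
or same-resolution inputs) the constraint survivors are few and the
smallest normalized residual identifies the planted triple reliably.
With the loose tolerance that cross-resolution matching forces, ~10⁶
candidate triples contain coincidental triangles matching the reference
geometry to 0.01 mm while the true correspondence sits ~0.3–0.5 mm off
(each matched vertex is displaced by up to the coarse mesh's sampling
spacing); the minimum-residual rule then fails almost always. The
survivors are therefore re-ranked by the quality of the transform each
implies: the mean nearest-neighbour misalignment of high-curvature
target points against the reference feature cloud. The winner still
satisfies every constraint — verification only decides among admissible
triples, and no random sampling or consensus counting is involved.

The coarse transform follows from the two local frames (t₁ along
m₃ − m₁, t₂ along the triangle normal, t₃ = t₁ × t₂):
R = T_n T_mᵀ, T = centroid(n) − R centroid(m). On exact rigid triples it
agrees with the SVD estimator to rounding.

Default tolerances `dist_tol` = 2 mm and `area_tol` = 20 mm² budget for
the matched vertices sitting up to one coarse-mesh spacing away from the
true corresponding surface points on either end of a side.

## ICP refinement

From the coarse initialization: transform the target points, find
correspondences in the reference cloud (k-d tree), compute the mean
(unsquared) corresponding-point distance r, stop when
|r⁽ᵏ⁺¹⁾ − r⁽ᵏ⁾| ≤ μ or after `max_iter` updates, otherwise estimate the
incremental transform between the current points and their
correspondences by SVD, accumulate, and repeat. The residual history and
the summed-squares objective are both recorded; with the classic
closest-point rule the objective is provably non-increasing. When the
initialization is exactly the identity the first step is seeded with the
SVD estimate of the initial correspondences (a literal identity first
step would reproduce r⁰ and trip the stopping rule before moving).

Two correspondence modes:

* **classic** — each target point takes its nearest reference point
  (Besl–McKay); reference points may be shared.
* **unique** — no reference point is claimed twice. All candidate pairs
  are conceptually scanned by ascending (distance, reference index) and
  kept when both ends are free; the implementation realizes this exact
  global greedy rule lazily with a priority queue and on-demand k-NN
  growth, and is verified against an exhaustive oracle. Requires
  |P| ≤ |Q|.

Uniqueness is attractive when duplicate correspondences would let a
degenerate transform collapse many points onto one; but when a dense
partial scan locally outnumbers the coarser reference samples, unique
assignment must claim ever-farther reference points and biases the fit
by degrees even from a perfect start. The cross-resolution preset
therefore uses the classic rule; `unique` remains the package default
and both are exposed.

**Surface refinement.** Point-to-point correspondence against a coarsely
*sampled* surface quantizes to the nearest vertex; two regular grids then
lock into lattice-preferred relative orientations 1–3° from truth. The
optional closing pass (`refine="surface"`) pairs each target point with
its exact closest point **on** the reference triangle mesh (Ericson's
point-triangle region test over candidate faces from a centroid k-d
tree) and still applies the rigid point-to-point SVD update — this is
the original closest-point-on-model formulation, not a point-to-plane
linearization. It converges to ~0.05° on the synthetic studies. A
cheaper `refine="cloud"` pass against the midpoint-subdivided reference
vertex cloud is also available.

## Synthetic phantom

`make_phantom` builds a triangulated height field: a smooth arch-like
dome (height 3 mm, width ~base/2) plus n Gaussian cusps with seeded
centers (≥ two mean widths apart), heights 1.5–2.5 mm and widths (σ)
1.5–2.5 mm on a 30 mm square sampled 64×64 — cusp apex curvatures of
~0.1–0.25 mm⁻², millimetre-scale curvature radii, i.e. tooth-like
numbers. `make_pair` derives the study pair:

* reference: structured vertex subsample keeping ~30% of vertices on a
  regular coarser grid, re-triangulated (regular, like a CT-derived
  mesh; a random subsample would create sliver one-rings whose curvature
  spikes are pure artifacts);
* target: all faces of the full-resolution mesh inside a square window
  of half the surface area centred on the cusp-rich region (clamped into
  the footprint, so crop fraction 1 is the whole surface), Gaussian
  noise of sd 0.05 mm along vertex normals (surface-measurement
  analogue; isotropic mode available), then a seeded rigid displacement
  with rotation ≤ 30° and translation ≤ 20 mm;
* the ground-truth transform mapping the displaced target back into the
  reference frame.

Generation is bit-reproducible per seed. A closed bumpy icosphere (via
trimesh) supplies the genus-0 fixture for Gauss–Bonnet checks.

What the phantom does *not* emulate: real occlusal anatomy (fissures,
ridges), CT reconstruction artefacts, scanner-specific noise spectra,
outlier patches, or soft-tissue differences between modalities. Passing
the synthetic studies shows the geometry pipeline is correct and
self-consistent under controlled resolution asymmetry and noise; it does
not certify clinical accuracy on patient data.

## Numerical choices and degeneracies

* Welding merges vertices within 1e-6 mm (k-d-tree pairs + union–find;
  representative = first occurrence, so welding is idempotent and binary
  STL round-trips are bit-exact). Faces degenerate after welding
  (repeated index or area < 1e-12 mm²) are dropped and counted.
* Collinearity guards: frames require ‖u × v‖ ≥ 1e-9·‖u‖‖v‖; the SVD
  estimator rejects source sets whose second singular value vanishes.
* Heron's formula clamps small negative radicands to zero and rejects
  genuine triangle-inequality violations.
* Ties in unique assignment break on the lower reference index —
  determinism, which the report reproducibility tests rely on.
* ICP defaults μ = 1e-6 mm, 100 iterations. The surface pass has a long
  shallow residual tail, so the cross-resolution preset stops at
  μ = 1e-5 mm (hundredths of a micron per iteration) within 200
  iterations; accuracy is unchanged to three decimals.
* The cross-resolution preset's curvature tolerance (0.08 mm⁻²) covers
  both the sampling-density shift of the discrete estimate and the
  roughly curvature-proportional attenuation that denoising applies to
  sharp cusps. The same-resolution default (1.5e-4) is far stricter
  because identical sampling makes curvatures directly comparable.

## Study sizes

The shipped studies use 64×64 phantoms (≈ 4k vertices; ≈ 1.2k after
reference decimation, ≈ 1.9k in the target crop): 50-seed end-to-end
recovery in the test suite, 20 registration pairs plus 50 coarse-stage
recovery seeds in the acceptance script. At these sizes the full suite
runs in about a minute and each registered pair takes ~1 s.

## Known limitations

* Rigid motion only; no scale or deformation.
* Curvature matching assumes both meshes expose the same anatomical
  high-curvature structures; a crop containing no cusp is rejected
  rather than registered.
* The one-ring angle-deficit estimator is the method's definition here;
  no Voronoi mixed-area or higher-order curvature estimators.
* `MeshSurface` candidate search (k nearest face centroids) can in
  principle miss the true closest face on meshes with extremely
  anisotropic triangles; k is configurable.
* Thresholds are manual per model complexity; no adaptive selection.
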
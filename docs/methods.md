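# Methods

## Model

The torso is a passive, homogeneous, isotropic volume conductor: the
extracellular potential u_T in the domain Ω_T between the epicardium Γ_H
and the external torso surface Γ_ext satisfies the Laplace equation with
an insulated outer boundary and Dirichlet data u_H on Γ_H.  The
conductivity σ_T cancels for Dirichlet-data transfer and is fixed at 1.
Discretization yields A x = b with m ≥ n; the inverse problem is solved
by Tikhonov regularization in the SVD basis of A (zero order) or the
GSVD basis of {A, L} (first order), with all selection criteria
evaluated through closed-form spectral sums.

### FEM transfer matrix

The annular domain is tetrahedralized by radial extrusion of the heart
surface toward the torso surface (matched vertex directions when both
surfaces are concentric icospheres; ray casting from the heart centroid
otherwise).  Prisms split into three conforming tetrahedra via the
sorted-index diagonal rule; elements are linear (P1).  Two refinement
knobs: `refinement` (radial layers, default 8, geometrically graded
toward the heart where harmonic solutions vary fastest) and
`angular_refine` (internal 4:1 surface subdivisions, default 1).  When a
surface is detected to be a sphere, subdivision midpoints are projected
back onto it, so refinement converges to the curved geometry instead of
the coarse polyhedron — without projection the forward error stalls at
the chord-sagitta level (about 1 % of radius at 162 vertices), which the
inverse amplifies strongly.  The epicardial unknowns stay at the coarse
heart vertices; refined boundary data is their piecewise-linear
interpolant.  Eliminating interior nodes gives A = −R K_II⁻¹ K_IH.

The discrete Dirichlet-to-Neumann operator D (heart-outward normal
current density per unit epicardial potential) is recovered
variationally: the weak residual of the discrete harmonic extension at
heart-boundary nodes equals the boundary flux integral against each hat
function; restriction to the coarse basis and division by the lumped
(one-third-area) boundary mass gives pointwise normal derivatives.  D
annihilates constants to round-off, so the constant mode carries an
infinite generalized singular value and is never penalized.

### MFS transfer matrix

Sources are torso vertices inflated by 1.5 and heart vertices deflated
by 0.6 about the heart centroid.  These ratios were fixed by validation
against the analytic annulus solution: the closer placements sometimes
used in practice (1.2/0.8) leave percent-level boundary-fit error at
this surface resolution, an order of magnitude above the ≤1 % target
for harmonic degrees l ≤ 4.  Rows are Dirichlet (kernel values at
electrodes, leading column 1 for the constant term a₀) followed by
Neumann rows (kernel normal derivatives at all torso vertices, leading
column 0); b = [BSP; 0].  When heart and torso meshes have similar
cardinality the default one-source-per-vertex layout would make the
system underdetermined; since source placement is a free discretization
choice, the pipeline thins the heart-source cloud evenly in index just
enough to keep m ≥ n.  With millimetre units the Neumann rows are
numerically much weaker than the Dirichlet rows; this softly weights the
flux condition and is left as-is (reconstruction quality is insensitive
to it, and the spectral machinery is scale-aware).

### Analytic annulus oracle

On concentric spheres with inner radius a and outer radius b, the
response to epicardial data Y_lm is (A_l r^l + B_l r^−(l+1)) Y_lm with
B_l = A_l·l·b^(2l+1)/(l+1) and u(a) = Y_lm.  The phantom forward map
expands the epicardial pattern in real spherical harmonics (least
squares at the heart vertices, l ≤ 10 by default at 162 vertices),
attenuates each degree in closed form, and evaluates at the torso
vertices.  This operator shares no code or discretization with the
FEM/MFS matrices under test — the inverse-crime guard.

## Phantom design and what it does (not) show

Defaults: heart radius 50 mm, torso radius 70 mm, subdivision-2
icospheres (162 vertices each), 60 frames, 20 dB SNR.  Three pattern
kinds: band-limited harmonic time series (AR(1) random walk on
coefficients with degree weight 1/(1+l), 20 mV scale), a paced
activation wavefront (activation time = geodesic distance / speed,
logistic transition, electrogram-like convention: 0 mV baseline dropping
to −80 mV on activation so the paced site is the early potential
minimum), and a static two-level step map.  Noise is white Gaussian
scaled from the clean signal power; the same seed gives bit-identical
datasets.

The radius ratio 1.4 is a deliberate compromise established by a
convergence study before the evaluation suite was frozen.  Steeper,
more torso-like ratios (≥ 1.5) raise the noise-free reconstruction
floor above 5 %: the oracle models boundary data as a truncated harmonic
series while the FEM models it as a piecewise-linear interpolant, and at
162 vertices this percent-level representation mismatch is amplified
through the annulus attenuation into the reconstruction.  The flip side
is a shallow FEM spectrum (condition number ≈ 31, about 1.5 decades), so
criterion behavior on the FEM branch is compressed relative to severely
ill-posed clinical geometries; the MFS system (condition number ≈ 2·10⁹)
retains the classic deep-spectrum behavior.  Passing tests on these
phantoms demonstrate correctness of the machinery and the qualitative
method ranking, not clinical-scale error levels.  Two known consequences
are accepted and reported rather than tuned away: CRESO and the U-curve
have no meaningful optimum on the shallow FEM-ZOT spectrum (their
oracle-optimality gap exceeds a factor 2 there), and the L1 scheme's
edge-preservation advantage on step patterns cannot be expressed at
20 dB because every mode carrying the edge is below the noise floor (its
baseline-preservation advantage, from the unpenalized constant mode, is
demonstrable).

## Regularization and criteria — numerical choices

* **λ grid**: 300 geometric points from 1e−8·s_max to 10·s_max, where
  s_max is the largest finite (generalized) singular value; all criteria
  share it so branch comparisons are fair.
* **GSVD**: QR of the stacked [A; L] followed by SVD of the upper block
  (a cosine-sine construction); σ increasing, ν decreasing, generalized
  singular values σ/ν nondecreasing; ν below 1e−14 is treated as exactly
  zero (infinite generalized singular value, filter factor 1) — the
  normal case for the DtN operator's constant null vector.
* **GCV denominator**: m − Σ filter factors is evaluated as
  (m − n) + Σ λ²/(s² + λ²); the naive subtraction loses all precision at
  small λ, where the complement is tiny.
* **GCV/RGCV detection**: on the prescribed wide grid, R = [γ +
  (1−γ)ξ]·G decays to zero as λ → ∞ (ξ → 0 while G flattens), so a bare
  global argmin is degenerate.  The chosen λ is the first interior local
  minimum with prominence ≥ 1e−3 of the curve range (the small-λ plateau
  wiggles at round-off-amplified levels, and shallow tail dips are
  artifacts of the flattening influence trace); fallback is the argmin
  restricted to λ ≤ s_max.  A flat-curve warning fires when the set
  {λ : value ≤ 1.01 × minimum} spans at least one decade — measured on
  low-noise FEM frames this near-minimal shelf spans 1.1–1.3 decades
  while well-behaved curves show 0.1–0.2.
* **CRESO**: first interior local maximum (same prominence filter)
  scanning λ upward; if none exists, the global argmax with a warning.
* **U-curve**: minimized on the grid restricted to
  [δ_n^{2/3}, δ_1^{2/3}] (smallest/largest nonzero spectral value);
  points with zero residual are excluded.  The criterion is
  dimensionally inconsistent (1/ρ and 1/η scale differently), so unlike
  GCV/RGCV/CRESO its choice genuinely depends on the data's units; this
  is a property of the criterion, verified in the tests.
* **ADPC**: per frame, a degree-5 polynomial is fitted to the log
  spectral coefficients in decreasing-spectral-value indexing and the
  Picard break is the last index where log s_i stays above the fit; the
  chosen λ is the median of the per-frame break values (possibly
  off-grid).  Both curves are normalized to their leading values
  (s_i/s_0 and |c_i|/max|c|): the Picard condition concerns relative
  decay, and the raw curves carry incommensurate units (singular values
  versus millivolt data).  Infinite generalized singular values are
  excluded from the fit.
* **Ties** break toward larger λ (more regularization), conservative
  under GCV's known tendency to under-regularize.
* **L1 scheme**: β = 1e−5 (fixed); weights W_ii = 1/(2√((Dx₀)_i² + β))
  at the zero-order seed x₀, whose λ comes from the same criterion being
  evaluated; effective operator W^{1/2}D (the half-quadratic
  normal-equation form; the WD variant is selectable via
  `weight_power=1.0`); a single linearization by default, with an
  optional fixed-point iteration (tolerance 1e−6, max 25) for study.
* **"Near-zero" λ** for noise-free round trips is a fixed fraction of
  each operator's spectral scale — 1e−4·s_max (FEM, shallow spectrum),
  1e−6·s_max (MFS, whose s_max is dominated by the constant column),
  1e−8·max finite gsv (weighted GSVD, unbounded above through the DtN
  null space) — i.e. below the informative band in every case.

## Evaluation

RE and CC are computed spatially (per frame over vertices) and
temporally (per vertex over frames); report means and standard
deviations are recomputed from the stored per-item values.  Pacing-site
detection takes the most negative reconstructed potential at an early
post-pacing frame (a −dV/dt variant is available); when the frame's
potential spread is under 5 % of its amplitude the detection is
indeterminate (N.A), mirroring how flat reconstructions cannot localize.
Localization error is the edge-graph Dijkstra geodesic, which
overestimates smooth-surface geodesics by roughly 5–8 % on spheres —
adequate because errors are judged against the mesh edge length.
Missing-electrode interpolation is discrete-harmonic (cotangent-weight
graph Laplacian with Dirichlet constraints; uniform weights on
degenerate triangles).  Ischemic-electrode thresholding removes
electrodes whose plateau-sample amplitude exceeds half the maximum.

## Forward-model validation resolution

The acceptance-level validation compares both forward maps against the
closed-form annulus solution for l ≤ 4: MFS on subdivision-3 meshes
(≤ 1 % required, ≈ 0.2 % achieved), FEM on subdivision-3 surfaces with
one internal angular refinement and 16 radial layers at radius ratio 1.5
(≤ 2 % required, ≈ 0.4 % achieved).  At the phantom's own working
resolution the worst FEM error over l ≤ 4 is about 3 % — the number the
acceptance script reports, since that is the operator the pipeline
actually inverts.

## Known limitations

* Homogeneous torso only; no lungs/bone inhomogeneities, no
  boundary-element method, no moving geometry.
* Spherical phantoms: the spherical-projection trick that accelerates
  FEM convergence has no analogue for general surfaces, where the
  forward error is limited by the polyhedral geometry.
* Desk-scale meshes (162 vertices) cap the representable spatial
  frequency at roughly harmonic degree 11; conclusions about sharp-front
  recovery are resolution-limited as discussed above.
* The pacing-site detector is a stand-in rule (potential minimum); real
  electrogram-based detectors use activation-time estimation.
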
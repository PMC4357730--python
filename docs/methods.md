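# Methods

## Scope and data model

The package analyses single-molecule AFM observations of protein–DNA
complexes: traced DNA backbones (ordered 2-D point sequences in nm),
per-complex annotations (arc position, bend angle, particle volume), and
2-AP fluorescence emission spectra. All estimators operate on these
containers regardless of origin, so real traced data can substitute for
the synthetic generator at every stage.

## Worm-like-chain DNA simulation

Fragments are sampled as 2-D equilibrated worm-like chains: successive
turning angles are i.i.d. `N(0, δ/P)` for step length δ and persistence
length P, giving the tangent correlation `⟨t(0)·t(s)⟩ = e^(−s/2P)` and
mean squared end-to-end distance `4PL[1 − (2P/L)(1 − e^(−L/2P))]`.
Defaults: P = 50 nm (dsDNA), δ = 2.5 nm. The 2-D equilibrated convention
treats molecules as having relaxed on the mica surface before drying;
kinetic trapping (a projected 3-D conformation) would roughly halve the
apparent persistence length but is not modelled — deposition conditions
in this kind of experiment are typically chosen for equilibration.

The helical rise defaults to 0.3005 nm/bp so a 549 bp fragment has a
165 nm contour, matching surface-measured length distributions; the
B-form 0.34 nm/bp systematically overestimates lengths measured on mica.

Lesion-site and protein-induced bends are imposed as deterministic kinks:
the turning angle at the vertex nearest the site is replaced by the
sampled bend (random sign) and the downstream arm rigidly rotated. A
protein-bound bend overrides the intrinsic lesion bend at the same site.

## Binding-position model and the specificity statistic

Measured positions are distances to the closer fragment end, normalised
to fragment length — the observable lives on [0, 50] % with a fold at
the centre. The generator draws, per complex: an end binder (probability
`end_bound_fraction`, default 0.15, uniform over [0, 5)%), otherwise a
specific binder with probability φ = r/(1+r), r = (S_true − 1)/N — the
exact inverse of the specificity statistic — from `N(46, 3.2)` %, else a
uniform nonspecific position; all draws are folded into [0, 50].

The estimator histograms positions above the 5% end-exclusion at 4%
bins (final edge clipped to 50%, densities computed per-bin so the
narrow last bin stays unbiased) and fits occupancy density with a
fixed-width Gaussian peak over a flat background. Because a peak at 46%
with width 3.2% pushes ~11% of its mass past the centre where it folds
back, the model includes the mirror image of the peak reflected at 50%:

    y(x) = y0 + A [G(x − c; w) + G(x − (100 − c); w)],  w = 3.2 fixed.

The mirror term is the package's own correction: without it the
estimator over-recovers S by 8–15% at realistic conditions; with it the
bias is ≤3% and the total specific occupancy remains `A_spec = A·w·√2π`.
Far from the centre the model reduces to the plain single Gaussian.
`A_nsp = 45·y0` and `S = N·A_spec/A_nsp + 1` with
`N = round(bp · 0.9)` considered sites (494 for 549 bp). The amplitude is
constrained non-negative and the centre bounded to (5, 50).

Replicate convention: S is computed per experiment and averaged with SD
across experiments; histograms are pooled across experiments for display
only. Occupancies are normalised per experiment before fitting (S is a
ratio statistic, so this choice is cosmetic and pinned only for plot
parity). At three experiments of ~370 complexes the recovered S has a
per-run SD of roughly 15% of its value; averaging over ≥10 master seeds
brings the benchmark estimates within a few percent of truth.

## Bend angles and conformational states

β = 180° − α, with α the angle between total-least-squares lines fit to
each backbone arm over a 10 nm window starting 5 nm (the protein
half-footprint) away from the site. β is unsigned in [0, 180], invariant
under rigid motions and polyline reversal; complexes whose arms would
leave the fragment are flagged unmeasurable and excluded. On constructed
polylines the estimator reproduces kinks exactly; on flexible chains the
tangent fluctuation across the ~20 nm gap contributes ~20–30° of
measurement spread (P = 50 nm), which is why straight protein-free DNA
shows a broad semi-Gaussian at 0° rather than a spike.

Angle distributions are binned at 8° and decomposed by least squares
into k ∈ {1,2,3} Gaussians with one shared width (free by default,
optionally frozen to an external value). With `fold_at_zero` the first
mean is pinned at 0 and every component is evaluated together with its
reflection at 0, modelling the unsigned observable; each component then
integrates to `A_i·σ·√2π` over the half-line, so state fractions reduce
to amplitude ratios and always sum to 100%. Fits are performed on
histogram counts (matching how such distributions are analysed in
curve-fitting software, with R² reported); a raw-angle MLE would be
statistically tighter but is deliberately not the reference path.
Initial means default to 0/30/70° (straight / search complex /
interrogation complex); fits are deterministic given inputs.

Recovery precision at published per-condition sample sizes (100 seeded
replicates, strongly-bent fraction, ±8 percentage points): ~92% of
replicates for the 29/68° two-state model at n = 128, ~100% for the
three-state model at n = 450, but only ~85% for the 26/65° model with
15° shared width at n = 155 — a Cramér–Rao calculation shows ~91% is the
ceiling for any estimator there even with means and width known, so this
is an intrinsic sample-size limit, not an estimator defect. Median
recovery is within ~0.5 points in all conditions.

State fractions from replicate experiments or conditions are compared
with a pooled-variance two-sample t-test, one-tailed in the direction of
the observed difference (t = 0 ⇒ p = 0.5); significance classes
* p < 0.05, ** p < 0.01, *** p < 0.005.

## Image synthesis and tracing

Rendering: DNA is a ridge with Gaussian cross-section (height 0.5 nm,
σ = 2 nm), proteins are rotationally symmetric Gaussian bumps
(σ = 2.5 nm) whose analytic integral equals the sampled volume; heights
compose by pixel-wise maximum, the surface is broadened by grayscale
dilation with a spherical 2 nm tip, and N(0, 0.05 nm) pixel noise is
added. Pixel size 2 nm. Fragments are placed with random pose and a
20 nm clearance; exhausting the retry budget raises a placement error.

Tracing: per-scanline polynomial flattening (order ≤ 3, two-pass with a
robust background mask so features do not bias the fit; note that a
ridge running exactly along a scanline is inherently ambiguous for
line-wise flattening), thresholding at background median + 3·1.4826·MAD
(floored at 0.1 nm for noiseless images), skeletonisation, and an
ordered walk between the geodesically farthest endpoint pair, which
prunes side branches. Paths are smoothed with a 3-point moving average —
chosen because it cancels the pixel-quantisation zigzag that otherwise
inflates contour lengths; traced lengths are then unbiased within ~1%
for persistence lengths 30–60 nm. Fragments touching the margin are
flagged excluded; cyclic skeletons are flagged unresolvable.

Complexes are detected as local maxima exceeding the DNA ridge height
(median height along the traces) by 0.3 nm within 5 nm of a backbone,
anchored at the nearest arc position. Volumes integrate
(height − background) over a 10 nm disc with the background taken as the
median in a surrounding annulus; on-DNA particles therefore include a
small backbone contribution (~15 nm³ under default geometry), mirroring
the same effect in real AFM volumes, which the empirical MW calibration
absorbs. The detection margin is a free parameter: the underlying manual
procedure has no numeric criterion, so it is surfaced in configuration
rather than hidden.

## Filters

Complexes are retained only on fragments whose contour length lies
within ±2 SD of a Gaussian fit to the length distribution (e.g.
165 ± 24 nm); positions below 5% are flagged end-bound and excluded from
specificity fits; complexes within 50 nm of another complex on the same
fragment are flagged neighbour-excluded and dropped from bend-angle
analysis. Specific complexes are those within ±2 fitted widths of the
peak centre (boundary inclusive).

## 2-AP fluorescence

Spectra are two-column (wavelength nm, CPS) on a common grid; reference
(protein-only) spectra are subtracted pointwise, grids must match
exactly — no interpolation. ΔI is evaluated at the grid point nearest
373 nm with a ±1 nm tolerance; coarser grids are rejected. Replicates
(≥2) are summarised as mean ± sample SD and compared with the same
one-tailed t-test. The synthetic titration generator uses a Gaussian
emission band at 373 nm whose peak rises by a saturable binding term
`ΔI_max·c/(c + K)` plus a concentration-scaled flat protein/buffer
contribution and additive noise, so reference subtraction and endpoint
quantification are exercised end to end.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the estimators
assume: mixture-distributed bend states with one shared width, a
Gaussian specific peak over uniform background with end binding, WLC
thermal conformations, monomer/dimer volume mixtures, tip-broadened
topography with additive noise. It does not emulate scan-line artifacts
beyond a polynomial background, tip asymmetry, molecule–molecule
aggregation, surface-induced anisotropy, or sequence-dependent local
flexibility. Passing recovery tests therefore validates the estimators
and their conventions, not the instrument-level robustness of the
tracing chain on real micrographs.

## Benchmark problem sizes

The acceptance script uses the published per-condition sample sizes
(371/375 positions × 3 experiments; 128–450 bend angles; 241 intrinsic
site angles; 500 fragments for the length distribution), 16 master seeds
for the specificity averages and 100 seeds for the bend-fraction
medians — sizes chosen to keep Monte-Carlo error well below the
reporting precision while completing in seconds.
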
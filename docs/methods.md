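# Methods

## Compressed-cell force balance (`nichemech.shape`)

**Model.**  The adherent cell is axisymmetric.  Uncompressed, it is a
hemisphere of radius r₀ (≈ 8.7 μm for the cells that motivated the model)
meeting its substrate at 90°.  When a rigid plate limits the height to
H < r₀ the cell keeps its volume (compression is fast compared to
volume regulation) and its cortex carries a uniform tension T with an
intracellular excess pressure ΔP.  Normal force balance on the free surface
is then Young–Laplace, c_m + c_h = ΔP/T = const, where c_m is the meridional
and c_h the hoop (azimuthal-direction) principal curvature.  The shape is
the classic squeezed droplet:

* a flat contact disc under the plate (the plate carries the normal load;
  both curvatures vanish there),
* a constant-mean-curvature free surface that leaves the plate tangentially
  at the disc edge and meets the substrate at the 90° contact angle
  inherited from the uncompressed hemisphere,
* enclosed volume fixed at V₀ = (2/3)πr₀³.

Two scalars — the contact-disc radius and the mean curvature ΔP/T — are
determined by the substrate-angle and volume conditions.

A note on the closure: treating the tension–curvature closure
T ∼ k(1/c_m + 1/c_h) as a pointwise *equation* of the shape, rather than as
a read-out, makes the problem degenerate — the relation factorises into
branches with a fixed curvature ratio, admits a trivial spherical-cap
family, and forces flat regions on which surface-averaged tensions diverge
with grid resolution; discrete solvers then select arbitrary branch
mixtures.  The package therefore solves the well-posed uniform-tension
shape problem and applies the closure afterwards as the local tension
estimate.  A variational check is part of the test suite: the same surface
is recovered (to < 0.2%) by directly minimising cortical area at fixed
volume under the plate obstacle, which is the energetic statement of the
same model.

**Numerics.**  The free surface is integrated in tangent-angle/arclength
form (dρ/ds = cos ψ, dz/ds = −sin ψ, dψ/ds = h − sin ψ/ρ) with an
8th-order Runge–Kutta pair at tolerance 1e−10; the two unknowns are found
by a hybrid Powell root solve on the shooting map, warm-started from a
strain-indexed table.  Everything is solved in units of r₀ (the geometry is
exactly scale invariant) and rescaled.  Fields are reported on a uniform
polar-angle grid θ ∈ [0, π/2] with increment dθ = π/1000 (configurable);
nodes with θ below the contact angle lie on the plate disc and carry zero
curvature.  Volume errors of converged shapes are at solver precision
(≪ the accepted 1% tolerance).  The standalone volume quadrature uses
V = π∫R² sin²θ (R sinθ − R′ cosθ) dθ, which reduces to (2/3)πR₀³ for
constant R.

**Tension summaries.**  On the free surface the directional tension
estimates are t_overall = k/c_m and t_axial = k/c_h (k ≡ 1; only ratios to
the uncompressed value k·r₀ are reported).  The hoop curvature vanishes at
the tangential departure from the plate, so t_axial has an integrable
logarithmic singularity there: its arithmetic area mean grows with
resolution and is not a stable summary.  The primary summary is therefore
the **area-weighted geometric mean** — the natural average for a positive,
scale-like quantity spanning orders of magnitude; it is parameter free,
finite, monotone in strain, and coincides with the arithmetic mean on the
uniform hemisphere (so both relative tensions are exactly 1 at zero
strain).  Two alternatives are always reported: the arithmetic area mean
with a one-grid-cell (dθ) collar excluded at the contact line, and the
harmonic mean (reciprocal mean curvature).  At 54% strain the three give
overall/axial relative tensions of 0.447/1.97, 0.449/2.51 and 0.445/1.72
respectively; the choice of summary moves the axial figure, the ~2× rise
and the ~55–60% overall drop are robust.

**Parameters.** `GeometryParams(r0, height, dtheta=π/1000, volume_tol=0.01)`.
`dtheta` fixes the reporting grid and the collar of the secondary
arithmetic summary only; the primary summaries are computed on a fixed fine
arclength quadrature (4001 points) and are stable under grid refinement.

## AFM small-indentation model (`nichemech.afm`)

A spread cell is a hemispherical cap of spreading radius r₀ at uniform
tension T = ΔP·r₀/2.  For indentation depths within 10% of r₀ the indented
surface is expanded in a four-term Fourier series of the polar angle; the
adhesion condition R(π/2) = r₀ and the indented-apex condition
R(0) = r₀ − H eliminate two coefficients analytically.  Volume conservation
enters through a Lagrange multiplier density λ; its force contribution uses
δV/δR = 2πR² sinθ, the functional derivative of the axisymmetric volume
integral.  The remaining freedom is fixed by solving the volume constraint
exactly (1-D root in a₂) and minimising the spread of λ(θ) over
θ ∈ [0.2, π/2) (the least-squares form of dλ/dθ = 0) over b₂ — the
objective is smooth and unimodal, so a bracketed scan plus Brent refinement
suffices.  The cantilever feedback force per unit contact area,
F = (ΔP + λV/A) − T(c_m + c_h) at the contact-patch edge (default contact
angle 0.07 rad, the edge of a ~1 μm² patch on a ~8 μm cell; the
substrate-edge evaluation is available as an option), divided by
P′ = ΔP + λV/A, is a universal function of the indentation strain: it
starts at 0 (Laplace equilibrium) and increases monotonically.  All solves
are in units of r₀ with ΔP = 1, which makes the universal curve exactly
scale invariant and the forward-then-fit round trip exact.

Fitting a measured strain–stress curve is ordinary least squares in the
single scaling constant P′; the overall-tension estimate is P′·L with
L = r₀ by default.  At least 10 indentation points are required; no
depth-dependent weighting is applied (configurable fit window documented in
the API).

## Imaging quantification (`nichemech.imaging`)

Bright-field images are smoothed (Gaussian, sd 0.5 px), converted to a
Sobel gradient magnitude, Otsu-thresholded and hole-filled; the filled mask
is eroded by a 2 px disk so that measurements stay strictly inside the
contour band (the threshold band straddles the true boundary, and an
outward-biased mask dilutes edge and cytoplasm means with background
pixels).  DAPI is traced with the same smoothing plus Otsu.  Objects below
200 px or containing any number of nuclei other than one (clusters) are
excluded.  The local background of a cell is the mean intensity between the
10 px and 25 px dilations of its boundary, excluding pixels of other cells;
it is subtracted pixel-wise before averaging.  Levels may be negative for
sub-background cells and are reported as-is with a flag.  The positivity
cutoff defaults to the 99th percentile of negative-control levels
(distribution-free; mean+2sd/mean+3sd available).  The edge/center ratio
erodes the cell by round(0.2 × mean boundary-to-nucleus distance) with a
disk element; nuclear/cytoplasmic is the ratio of background-corrected
means, with a flagged infinity for zero cytoplasmic signal.  Stack volumes
use the rectangle-rule slice-area sum Σ A(z)·δz.

## Statistics (`nichemech.stats`)

Fate categories follow the Pax7/MyoD scheme (stem +/−, progenitor +/+,
committed −/+, double negative); positivity is strict (> cutoff).  The
population comparison is the 2×2×K Cochran–Mantel–Haenszel chi-square test
per category (category vs rest), one stratum per experimental repeat, no
continuity correction; the 1-df upper tail is inherently two-sided.
Degenerate strata (zero margins) are dropped with a warning.  The
implementation delegates to statsmodels' StratifiedTable; the test suite
checks it to 1e−10 against an independently coded evaluation of the CMH
sums and verifies type-I calibration by simulation.  A generalised
multi-category (I×J×K) CMH is out of scope.  Gene-list overlap uses the
one-tailed hypergeometric enrichment tail P(X ≥ k) (Fisher exact); the
universe size is always an explicit parameter.

## Synthetic data (`nichemech.synth`)

Scenes place elliptical cells (axis ratio ≤ 1.5, semi-axes 40–52 px at
0.23 μm/px — the scale of spread MuSCs) with nucleus discs, a bright-field
contour ring, optional touching pairs (clusters), and antigen channels with
constant or ramped background plus additive Gaussian noise.  Peripheral
enrichment is painted over Euclidean depths [1, w+2] px, where
w = round(0.2 × boundary-to-nucleus distance) is the measurement-convention
band width; the 1–2 px cushion covers the segmentation's deliberate inward
bias so the measured band samples the enriched plateau.  Ground truth
(label images, per-cell contrasts, ratios, positivity) is sufficient to
score every estimator directly.  AFM curves are the package's own universal
curve scaled by a true P′ with multiplicative Gaussian noise (one shared
forward model; the fit is still validated against an independent dense-grid
oracle).  Confocal stacks sample analytic cross-sections at slice centers,
optionally rasterised.  Fate tables are per-repeat multinomials; the
default condition probabilities mirror the motivating contrast
(uncompressed: committed-dominated, ~65%; compressed: committed < 10%).
All generators are bit-reproducible under their seed.

What the generators do *not* emulate: point-spread blur, shot noise,
illumination shading, irregular cell outlines, partial adhesion, or
correlated biological variability between repeats.  Passing tests therefore
demonstrate correctness of the estimators under their stated assumptions,
not robustness to every imaging artefact.

## Orchestration (`nichemech.pipeline`)

YAML configs are validated (stage names, seed, log level) before anything
runs; stage failures halt downstream stages; reruns of an unchanged config
and seed are bit-identical, and every output carries a header naming the
config hash, seed and package version.  Exit codes of the `nichemech run`
command: 0 success, 2 config error, 3 stage failure.

## Problem sizes and determinism

The default test suite and the acceptance script use: shape solves at
dθ = π/1000 with a 4001-point tension quadrature; AFM recovery with 100
replicate curves of 50 steps; scenes of 3–6 cells at 768²; 1000 null
replicates for type-I calibration.  All randomness flows through explicit
integer seeds.

## Known limitations

* The shape model has no adhesion energetics, contact-line pinning,
  viscoelasticity or non-axisymmetric modes; the 90° substrate angle is an
  assumption carried over from the uncompressed hemisphere.
* The axial-tension summary at high strain depends on the averaging
  convention (see above); all three conventions are reported.
* The AFM model's Fourier truncation (two harmonics) is part of the model
  definition, not a numerical approximation to be refined.
* Imaging defaults (Otsu thresholds, minimum object size, annulus radii)
  are tuned for high-contrast, sparsely plated cells.
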
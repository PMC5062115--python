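# Methods

## Forward model and its inversion

The mechanical core assumes quasi-static indentation of an elastic
half-space by a rigid cone. Loading follows Sneddon's solution
P(h) = (2/π)·tanθ·E′·h² with E′ = E/(1−ν²); this is the unique elastic
contact law for the stated tip geometry, so it serves both as the
synthetic-data forward model and as the exactness oracle for the analysis
chain. Unloading is parametrised as P = P_max·((h−h_f)/(h_max−h_f))², a
power law anchored at the load peak with residual (plastic) depth h_f; with
h_f = 0 the retract retraces the loading path bit-for-bit before noise, and
h_f > 0 gives the loading/unloading distinction that motivates fitting the
unloading branch in the first place. Adhesion, when enabled, is a constant
pull force subtracted from the in-contact retract load — a deliberately
minimal model whose only purpose is to exercise QC.

The inversion (Oliver–Pharr) fits P = α·hᵐ to the unloading branch by
nonlinear least squares seeded from a log–log regression, takes
S = α·m·h_max^(m−1), and evaluates E = (1−ν²)(√π/2)·S/√A. The exponent is
left free and reported with a warning flag outside [1, 3]; for ideal conical
contact m = 2 exactly, and the per-curve exponent is itself a useful
diagnostic of contact quality. Residual depth is *not* subtracted by default
(the fit is P = α·hᵐ, not α·(h−h_f)ᵐ); an `h_offset` parameter exists for
callers who know h_f.

Two contact-area conventions are exposed because the choice matters at the
20–40% level and published descriptions are often ambiguous:

- `contact_depth` (default): A = π·tan²θ·h_c², h_c = h_max − ε·P_max/S with
  ε = 2(π−2)/π. For a Sneddon cone this chain is algebraically exact — the
  noiseless pipeline recovers E to better than 1e-9 relative, which the test
  suite asserts at 1e-3.
- `at_h_max`: A = π·tan²θ·h_max², the literal cross-section of the cone at
  peak depth. It overstates the contact radius (the surface sinks around the
  tip) and deterministically yields (2/π)·E ≈ 0.637·E for quadratic curves.
  It is provided so results computed under that literal reading can be
  reproduced and compared.

## Calibration

Optical-lever sensitivity is the reciprocal of the mean least-squares slope
(V/m) of the constant-compliance region of force curves taken on a rigid
substrate; the window is the last 30% of the contact region (configurable),
and curves with non-positive or visibly non-linear compliance (R² < 0.9) are
rejected. The spring constant uses raw equipartition on the linearly
detrended thermal deflection series, k = k_B·T/⟨d²⟩, with temperature
defaulting to 298 K (configurable). The first-flexural-mode shape correction
(~0.971) is deliberately not applied by default, matching the original
thermal-noise procedure; it is exposed as `mode_correction`.

## Contact-point detection

Detection runs on the approach segment in two stages. A persistence test —
load above baseline mean + c·σ (c = 3) for w = 5 consecutive samples —
establishes that contact exists and brackets it; curves with no persistent
crossing are flagged for discard. The location is then refined by
back-extrapolating the contact fit to zero load: for each candidate z₀ the
model b₀ + b₁·z + a·x^p, with x = (z−z₀) − P/k the indentation implied by
z₀ (piezo travel past contact minus cantilever deflection), is fitted
linearly and its residual minimised over z₀ — a grid scan over the samples
up to the crossing followed by bounded continuous minimisation. Two details
are load-bearing:

- The residual baseline offset and tilt (b₀, b₁) are estimated *jointly*
  with the contact term. A baseline fitted on the pre-contact window alone
  and extrapolated across the curve leaves a tilt error that biases z₀ by
  ~10 nm at realistic noise; the joint fit brings the z₀ error near the
  information limit (≈2–4 nm at 0.5 nm deflection noise on the softest
  gels).
- The design matrix spans ~14 orders of magnitude across its columns, so the
  linear solve is performed on unit-norm-scaled columns; without scaling the
  contact column is numerically truncated.

The assumed contact exponent p defaults to 2 (conical tips are the package's
scope) and is configurable. Indentation is then h = (z−z₀) − P/k, the
soft-sample correction; on a rigid substrate h ≡ 0 and such curves are
flagged rather than fitted.

## Quality control

A curve is discarded when (i) no contact point is found, (ii) baseline noise
exceeds 30% of its peak load, or (iii) its smoothed in-contact approach load
is non-monotone beyond 20% of its range. The monotonicity test deliberately
ignores the pre-contact portion, where the load is baseline noise and
apparent drops are meaningless. Filtering is idempotent, the discarded
fraction is reported, and discarding everything is an error carrying
per-reason counts.

## Unloading-fit window

The power law is fitted over the top 80% of the retract force range —
standard practice that keeps the fit inside the elastic-recovery region. The
window is selected on a lightly smoothed load (boxcar, ≤31 samples): cutting
on the raw noisy load correlates the selection with the noise and biases the
exponent low (m ≈ 1.75 instead of 2 at 10% load noise), which propagates to
a ~−8% modulus bias. With the smoothed cut the estimator is unbiased within
Monte-Carlo resolution.

## Group statistics

Per-condition moduli are reported as mean ± sample SD (n−1). Pairwise
comparisons use the two-sided Mann–Whitney U test: exact enumeration when
n·m ≤ 400 and the pooled sample is tie-free, otherwise the normal
approximation with midrank-tie and continuity corrections (delegated to
scipy; the test suite checks the exact path against an independent
enumeration oracle). Formulations are merged into stiffness categories by
single-linkage grouping of pairs that are *not* significantly different at
α = 0.05 — an operational stand-in for "overlapping stiffness ranges", chosen
because it reuses the same significance machinery as the pairwise
comparisons; merging by eyeballing mean±SD overlap would be a different,
undeclared rule. No multiple-testing correction is applied by default (a
Bonferroni option exists), matching common practice for this design.

## Morphometry

Objects are segmented with a global Otsu threshold (cells dark on light
background by convention; polarity is a flag). A bimodality guard returns an
empty mask when the two classes Otsu produces are separated by less than 4×
the within-class spread — an automatic threshold always splits a histogram,
including a pure-noise one. Components use 8-connectivity with a 10 px
minimum-area filter. Area is pixel count × pixel_size²; ellipse axes come
from second-order central moments; circularity 4πA/P² is capped at 1
(discretisation can push the raw ratio above the isoperimetric bound);
roundness is minor/major.

Perimeter defaults to the length of the marching-squares contour of the
Gaussian-smoothed (σ = 1.5 px) component. Pixel boundary walks overestimate
smooth outlines by ~5% (staircase effect), which would put a large disk's
circularity near 0.90; the sub-pixel contour is accurate to <1% for both a
disk of radius 200 px and a 300 px square (circularity 0.997 and 0.792
against π/4 = 0.785). The classic weighted walk (diagonals ×√2) and the
Crofton estimate remain available via `perimeter_method`.

Cluster sizes (major axis, µm) are binned left-closed into occurrence
percentages. Two presets ship: `default` covers 0–∞ contiguously
(<10, 10–30, 30–50, 50–100, 100–150, 150–200, 200–250, >250 µm), while
`paper` reproduces a published bin list that omits 50–100 µm; sizes falling
into that gap are counted in an explicit `unbinned` bucket, never silently
dropped. Cluster density is 100 × foreground/ROI pixels after thresholding,
with the applied threshold returned for audit. A cluster, when detected
automatically, is a connected component whose area exceeds twice the median
component area — a heuristic for "larger than a single cell" (configurable).

## Synthetic data: what it does and does not emulate

The generators reproduce the study's stated acquisition geometry: 16×16
curves over 5×5 µm, 100 nm maximum indentation, 6 µm/s vertical speed,
conical tip of 22° half-angle, gels of 150–4000 kPa with ν = 0.5, at least
three maps per gel (≥690 retained measurements at the ~10% artefact rate).
Where the study reports no value, package constants were chosen as typical
for this class of measurement and are declared, not inferred: spring
constant 0.1 N/m and sensitivity 20 nm/V (soft sharp-tip probes on a
four-quadrant detector), deflection noise 0.5 nm SD (liquid-cell operation),
500 samples per segment, thermal calibration at 298 K. Corrupted
acquisitions are emulated as contact-free detector noise at round(fraction·n)
random grid positions.

Real data differ in ways the generators deliberately do not model: no
viscoelastic (rate-dependent) response — the elastic inversion applied to a
viscoelastic gel would overestimate E in a speed-dependent way; no surface
roughness or tilt of the sample; no long-range interactions before contact;
noise is white Gaussian rather than 1/f; cells are ideal ellipses and
clusters ideal disk packings with sharp edges. Passing tests therefore
demonstrate the correctness of the analysis chain under its stated
assumptions, not the accuracy of absolute moduli on viscoelastic gels —
consistent with treating relative stiffness differences, not absolute
values, as the robust output.

Images are rasterised at a declared µm/px scale carried in metadata, since
all reported metrics are in µm. The image truth tables store analytic areas
and perimeters (Ramanujan for ellipses) alongside realised pixel counts, and
flag overlapping footprints.

## Reproducibility and numerics

A single user seed fans out to per-stage sub-seeds via
`numpy.random.SeedSequence.spawn` (31-bit), so stages are independently
reproducible and a rerun with the same configuration is bit-identical;
every report embeds a SHA-256 hash of its configuration and a schema
version. Degenerate inputs fail loudly: constant images have no threshold,
zero mean-square deflection no spring constant, all-curves-discarded maps no
summary. Continuous z₀ refinement uses bounded Brent with a relative
tolerance of 1e-12 of the bracket. Problem sizes in the test suite (maps of
64–256 curves, 10⁴ null replicates for the type-I-error check, 10⁶
thermal-noise samples) were chosen to hold Monte-Carlo error comfortably
below the asserted tolerances.

## Known limitations

- Conical tips only; no spherical/pyramidal area functions.
- Elastic-only inversion; no loss-modulus extraction.
- The contact-exponent assumption (p = 2) in the detector matches the
  package's tip scope but is a model commitment; materials with strongly
  different contact exponents would need the configurable p.
- Mann–Whitney on per-curve estimates treats curves as independent,
  ignoring map-level clustering.
- The manual-review component of semi-automatic curve processing is not
  reproducible; the automated QC rules are the package's declared behaviour.
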
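# Methods

`cylmre` implements an end-to-end analysis of ex vivo tabletop magnetic
resonance elastography (MRE) of cylindrical tissue samples — as used to
characterize colorectal liver metastases (CRLM) after chemotherapy —
together with the quantitative histology and response statistics that such a
study pairs with it. Because no public dataset accompanies this kind of
study, every input is synthesized by the package itself from known ground
truth, and the test suite checks that each stage recovers that truth.

## Wave model and acquisition

A sample is a homogeneous, isotropic viscoelastic cylinder (radius R = 3.5
mm) driven concentrically from the tube wall, with displacement polarized
along the cylinder axis. For a time-harmonic drive at angular frequency
ω = 2πf the axial displacement is the lowest mode of the z-infinite
cylinder,

    u(r, t) = Re[ A · J0(k r) · e^{iωt} ],

with complex wavenumber k = k′ + i k″ (k′ > 0, k″ < 0 by branch
convention). The acquisition geometry follows the 0.5 T tabletop setup:
64 × 64 matrix, 150 µm in-plane resolution, 7 mm inner tube diameter,
drive frequencies 500–5300 Hz in 400 Hz steps, four time offsets per
vibration period. The motion-encoding gain (default 1e5 rad/m) converts
displacement to MR signal phase; phases are wrapped to (−π, π] and carry
additive Gaussian noise.

**Amplitude convention.** The `amplitude` parameter is the *peak*
displacement over the tube cross-section. For lossy media the Bessel mode
grows strongly toward the wall (at α = 0.5 and 5300 Hz, |k″|R ≈ 15, i.e. a
factor e^15 between axis and wall), so normalizing the drive at the axis
would wrap the near-wall phase thousands of times — physically, it is the
wall that the actuator drives. With the default amplitude of 20 µm the peak
encoded phase is 2 rad.

**SNR convention.** `snr_noise_sd` defines SNR on the encoded phase: the
RMS of the noiseless in-tube phase over all offsets and frequencies,
divided by the per-pixel noise SD; 30 dB therefore means noise SD ≈ RMS/31.6.

## Viscoelastic model

The spring-pot (fractional element) has complex shear modulus

    G*(ω) = µ^(1−α) (iωη)^α,     η ≡ 1 Pa·s,

with µ > 0 the shear modulus (Pa) and α ∈ [0, 1] the power-law exponent
(α = 0 elastic solid, α = 1 viscous fluid). Fixing the reference viscosity
η at 1 Pa·s is a parameterization convention that leaves (µ, α) as the two
free parameters with µ carrying the stiffness scale; descriptions of the
tabletop method in the literature do not fix this convention, so it is
documented here and used consistently in simulation and fitting. Tissue
density is fixed at ρ = 1000 kg/m³ (soft-tissue convention; not reported in
this literature).

The Helmholtz relation k = ω √(ρ/G*) links the modulus to the wavenumber;
taking the branch with k′ > 0, k″ ≤ 0 yields the per-frequency dispersion
proxies

    c = ω / k′   (shear wave speed, m/s — stiffness proxy)
    a = −ω / (2π k″)   (shear penetration rate, m/s — inverse-viscosity proxy)

with the closed forms c = √(|G*|/ρ)/cos(απ/4) and
a = √(|G*|/ρ)/(2π sin(απ/4)); a → ∞ as α → 0.

## Inversion

Per frequency: (1) each offset image is unwrapped inside the tube mask with
a reliability-sorted 2D unwrapper (the contract asserted by tests is the
mod-2π identity, not the algorithm); (2) the first temporal Fourier
coefficient gives the complex wave image, normalized so a unit-amplitude
cosine time course yields modulus 1; (3) the field is radially averaged
around the estimated tube axis; (4) the profile is fit by A·J0(k r) over
complex A and k; (5) c and a follow from k, and validity rules are applied.

**Radial binning.** By default every distinct pixel radius is its own bin.
For a radially symmetric field this averaging is exact, so the noiseless
round trip is bias-free even at the highest frequency, where the wavelength
(≈ 0.6 mm) is only four pixels and annular bins of one pixel width would
bias c and a by several percent. Annular bins of explicit width (assigned
the mean pixel radius) remain available, as does weighting bins by pixel
count (off by default).

**Axis estimation.** The axis is the magnitude²-weighted centroid of the
above-threshold (20% of peak) harmonic magnitude, snapped to the nearest
half-pixel. Weighting makes the estimate continuous in the data — a plain
mask centroid is unstable when attenuation leaves only a thin bright ring
at the wall — and snapping restores the radius degeneracy that makes exact
binning cheap.

**Fit.** For each trial k the complex amplitude has the closed-form
least-squares solution, so the search is two-dimensional over (c, a),
parameterized in logs: a 40 × 40 log-spaced grid on c ∈ [0.5, 20] m/s,
a ∈ [0.1, 20] m/s, followed by a deterministic zoom refinement (9 × 9
window shrunk by 5× per level, 14 levels, ≈1e-9 final relative step). The
inner loop evaluates a vectorized complex-argument J0 (power series for
|z| ≤ 11, Hankel asymptotics above; `cylmre.bessel`), validated against
scipy's AMOS implementation to ~3e-10. A flat or empty profile, or a
normalized residual above 0.5, flags the point as `fit-failure` rather than
raising.

**Validity.** A point whose wavelength λ = c/f strictly exceeds twice the
tube diameter is excluded (`reason="wavelength"`); λ exactly equal to 2d is
retained ("exceeding" is strict). With the default 7 mm tube this removes
the lowest acquisition frequencies for any sample with c ≥ 7.1 m/s at
500 Hz — the rule, not a hard-coded frequency list, so other geometries
work. An acquisition-level amplitude-overshoot flag (set when wrapping is
disabled and the excursion passes π; a quantitative threshold for this
failure mode is not established in the literature) propagates to `reason="overshoot"`.

## Spring-pot fitting

Each valid frequency yields a complex modulus observation
G*obs = ρω²/k², with k rebuilt from (c, a). The fit minimizes
Σ_ω |G*obs − G*SP(µ, α)|² over (log µ, α) with α box-constrained to [0, 1]
(bounded trust-region least squares, stacked real/imaginary residuals).
Fitting in complex-modulus space uses the storage and loss components
coherently; note that arg G* = απ/2 makes every frequency an independent
α measurement, which is why α is recovered to ~1e-4 at 30 dB SNR even
though the µ estimate amplifies α errors by |log µ − log(ωη)|/(1−α).
Warm starts: α₀ from the log-log slope of c(f) (d log c/d log ω = α/2 for
the spring-pot), µ₀ by inverting |G*| at the lowest retained frequency.
A curve-space alternative (relative residuals on c(f), a(f)) is available
for sensitivity checks. α < 0.5 labels a sample elastic-solid, α > 0.5
viscous-fluid, α = 0.5 boundary.

## Quantitative histology

Tiles default to 5000 px ↔ 1105 µm geometry (0.221 µm/px). Nucleus-area
segmentation is classical: colour deconvolution to the hematoxylin channel,
gamma correction (default γ = 1.5; the source pipelines do not state a
value), greyscale, Otsu threshold, connected-component labelling. Tissue is
defined as pixels with HSV saturation above 0.04 (stained vs. clear glass);
this definition is a package choice. Single-nucleus instances come from the
ground-truth label mask on synthetic data, or from a distance-transform
watershed surrogate on real RGB input — a deterministic stand-in for
learned star-convex detection, treated as a representative sample of
single nuclei (in practice only a minority, 10–30%, of nuclei are
individually detected on real slides).

Per nucleus: area = pixel count × pixel_size², axes from the second-moment
equivalent ellipse, aspect ratio = major/minor (defined as 1.0 for
degenerate single-pixel regions). Slide summaries take medians over
single-nucleus records and sum areas over tiles (fsum, so tile order is
irrelevant to the last bit); nucleus density is

    density = (total nucleus area / tissue area) / mean single-nucleus area,

which for N disjoint identical nuclei in tissue area T collapses exactly to
N/T — a property the tests assert.

The mask generator places non-overlapping constant-area ellipses (area
spread in measurements then reflects rasterization only, a few percent)
with uniform random centres and orientations, one-pixel clearance, and a
hard feasibility bound of 0.5 on the implied area fraction; placement
failure after bounded retries raises. Renderings compose hematoxylin
optical density 0.65 on nuclei over eosin 0.10 background through the
standard HED stain matrix with 2% multiplicative stain noise.

## Cohorts and statistics

The synthetic cohort reproduces the reference cohort's group structure: grade counts
3/2/6/15/8 (grades 1–5, n = 34); viability drawn from each grade's observed
value multiset (e.g. grade 5 ∈ {80, 90, 100}%); response classes
grades 1–2 → major, 3 → partial, 4–5 → none. Group-level variables are
drawn normal around the published medians with sd = IQR width/1.349,
truncated to physical ranges: α 0.43 (0.36–0.47) / 0.53 (0.50–0.54) /
0.51 (0.48–0.55) for major/partial/none; nucleus area 19.82/20.9/23.4 µm²;
density 0.0019/0.0034/0.0055 µm⁻². Where a published median is unavailable
the defaults are the package's own choices, fixed once: µ 2600/2100/2000 Pa
with broadly overlapping IQRs (major stiffest, consistent with the higher
wave speeds at major response, but not significantly separated), and
major-group aspect ratio 1.53 (1.47–1.60) (only the partial-vs-none pair,
1.54 vs 1.49, is published). Per-frequency (c, a) values follow each
sample's spring-pot closed form with 3% multiplicative noise. RECIST
classes derive from simulated baseline/follow-up diameters whose change
distribution depends on the pathological class (P(rPR) = 0.8 for major,
0.27 otherwise), and 7 samples lose their radiological assessment at
random, mirroring the observed concordance pattern and missingness.

Statistics follow the standard toolkit of such studies: Spearman rank correlation per
frequency of c or a against grade (1–5) or response coded ordinally
none = 0 < partial = 1 < major = 2 (the coding, unstated in the source,
makes positive correlation with c match the reported direction);
Kruskal-Wallis omnibus plus pairwise Mann-Whitney (raw p by default,
Benjamini-Hochberg behind a flag); type-7 quartiles; percentages rounded
half-up to one decimal as printed tables do; ROC AUC by the midrank
Mann-Whitney statistic, oriented ≥ 0.5 with the direction recorded, and the
cutpoint maximizing Youden's J over midpoints of adjacent distinct values.
Constant inputs flag the correlation as undefined rather than raising;
single-member groups make the comparison degenerate without p-values.

## What the synthetic data does and does not show

The generator reproduces the geometry, frequency comb, noise character and
group structure of a real tabletop-MRE tumour study, so passing tests demonstrate that the
*pipeline* is correct and that parameters are recoverable under the stated
conditions (e.g. median |Δα| < 0.05 and median |Δµ|/µ < 10% at 30 dB SNR —
in practice orders of magnitude better). It does not emulate heterogeneous
tissue, imperfect wall coupling, off-axis slices, B0/B1 artefacts, stain
variability of real H&E, or the patient-level correlation structure between
mechanics and histology — those are imposed, not emergent. Patient-level
correlation coefficients and AUCs from real cohorts are therefore not
reproduction targets; the parameter-recovery study is the
substitute.

## Problem sizes and numerics

Defaults keep a full run light: the end-to-end pipeline simulates all 34
cohort samples but pushes 8 (configurable, `n_wave_samples`) through wave
simulation + inversion (~15 s); the recovery study uses 3 × 20 seeds at 11
frequencies (~90 s); morphometry tiles default to 1000 px in the pipeline
(the 5000 px tile geometry is kept as the pixel-size reference). All
randomness flows through explicitly passed seeds or `numpy` Generators; a
fixed seed makes every output byte-identical. Degenerate inputs (flat
profiles, empty masks, single-class labels, singleton groups) are handled
by the documented flag-or-raise contracts above.
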
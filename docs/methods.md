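# Methods

## Mechanical model

The bubble–integrin–cytoskeleton linkage is modelled as a linear
Kelvin–Voigt element: a spring of stiffness *k* in parallel with a dashpot
of viscosity *η*, driven by the acoustic radiation force treated as a step
force during each ultrasound pulse. The governing equation
k·x + η·ẋ = F(t) has the closed-form creep solution
x(t) = x∞(1 − e^(−t/τ)) with retardation time τ = η/k (seconds) and creep
limit x∞ = F/k (µm), and exponential recovery with the same τ when the force
is removed. Trajectories under pulse trains are evaluated exactly as a chain
of piecewise exponentials — no ODE stepping — so the simulated record is the
analytic solution at every sample regardless of sample rate. A test-suite
oracle independently integrates the ODE (stiff solver, chained per phase)
and agrees to better than 10⁻⁵ relative error.

Two optional terms emulate the nonlinear creep stages seen at long pulses,
which the linear model cannot produce: a secondary-creep rate β (µm/s,
linear drift added during the on-phase) and a plastic fraction (share of
each pulse's peak displacement that never recovers). Both default to zero;
the creep-stage classifier (`viscoelastic.classify_creep_stage`) labels an
on-phase window primary/secondary/tertiary from the sign of the late-window
curvature relative to a tolerance (default 5% of the window's maximum
curvature magnitude; the call is invariant to amplitude scaling).

## Calibration from five-pulse means

With a = e^(−t_on/τ) and b = e^(−t_off/τ), per-pulse peaks follow
p_{n+1} = x∞(1−a) + a·b·p_n and residuals r_n = b·p_n. Given measured
five-pulse mean peak P̄ and mean residual R̄, the parameters follow in closed
form: b = R̄/P̄; τ = t_off/(−ln b); q = a·b;
p₁ = 5P̄(1−q)/Σ_{n=1..5}(1−qⁿ); x∞ = p₁/(1−a). The built-in calibrations
invert the measured pairs (1.45, 0.28) µm at 5% duty cycle and
(4.74, 2.97) µm at 50% (PRF 1 Hz), giving τ = 0.5777 s, x∞ = 15.038 µm and
τ = 1.0696 s, x∞ = 8.842 µm respectively. Forward simulation through the
metrics module reproduces the measured means to ≈0.2% (the residual is read
one sample before each period boundary, a 1 ms quantization at 1 kHz). No
peak value is available for the 25% condition, so no calibration is defined
there.

A deliberate limitation: the measured displacement integrals
(2.81 / 10.88 / 20.28 µm·s for 5/25/50% duty) are *not* reproducible
jointly with the peak/residual means by any single linear Kelvin–Voigt
parameter pair — the linear model that matches the 5% peaks yields
≈3.6 µm·s. The AUC of real trajectories reflects nonlinear creep stages and
inter-bubble variability; AUC is therefore reported as a descriptive metric
only and not used for calibration.

## Acoustic force models

The primary radiation force is implemented exactly as
F = 2π P_A² R₀/(δ_tot ρ₀ c ω₀) with ω₀ = 2π f₀, defaults δ_tot = 0.16,
ρ₀ = 1000 kg·m⁻³, c = 1500 m·s⁻¹, f₀ = 1.25 MHz. Evaluated at
P_A = 0.034–0.035 MPa and R₀ = 1.5–2.0 µm this yields ≈5.8–7.9 nN. Values
of 17–25 nN are sometimes quoted for this configuration; that range is not
reproducible from the formula as written with these constants (a factor ≈3
apart), and the implementation follows the formula rather than the quoted
range. No downstream computation depends on the absolute force scale — the
simulation is parameterized by x∞, which absorbs F/k.

The secondary Bjerknes coupling uses the standard volume-coupling magnitude
F = |κ|·R₁³R₂³/d², directed along the line of centers, with a user-set
signed κ (negative = attractive, the default sense). Only the d⁻² scaling
and the direction are constrained physically; the cubic radius dependence
is the conventional monopole-scattering choice. Net force directions are
computed once at the rest geometry (bubble displacements, ≤5 µm, are small
against typical inter-bubble distances).

Pulse trains use a half-open on-interval [kT, kT + duty·T) for pulse k, so
windowing of metrics is unambiguous; pressure is piecewise constant over
user-defined segments (a ramped protocol is three 10-minute segments at
0.035/0.045/0.055 MPa), and the effective creep limit scales with
(P/P_ref)² relative to the first segment, force being quadratic in pressure.

## Synthetic data

The trajectory generator embeds each bubble's 1-D Kelvin–Voigt displacement
along its net-force direction from its rest position, adds per-frame
Gaussian localization noise (default sd 0.1 µm — a generator choice; real
localization noise is not characterized here), and decays the radius
exponentially (default 0.2%/s, ≈1% over a five-pulse record, emulating slow
gas leakage). The renderer draws each bubble as a 2-D Gaussian spot of
σ = 0.5·R/pixel-size on a constant background (default pixel size 0.33 µm,
frame rate 1000 fps with 100 fps used for rendered-stack runs), with
optional signal-proportional Gaussian noise (Poisson-like; SNR is defined
as spot peak over the noise sd at the peak). Nuclei images are
non-overlapping ellipses on a jittered grid: a DNA-stain channel and a
marker channel with separate nuclear/cytoplasmic/background levels, a
configurable fraction of cells generated with nuclear ≥ 1.1× cytoplasmic
marker, per-cell lognormal staining gain (ratio-preserving), and pixelwise
Gaussian noise. All generators are seeded and bit-reproducible, and every
output carries its ground-truth table.

What the generators do **not** emulate: bright-field point-spread functions
and diffraction rings, cell-body background texture, bubble detachment,
touching/overlapping nuclei, and illumination gradients. Passing tests
therefore validate the algorithms' correctness on well-posed inputs, not
robustness to every artifact of real microscopy.

## Tracking

Detection is the classic blob recipe: band-pass (Gaussian at ~diameter/8
minus a boxcar background over ~2× diameter), local maxima separated by at
least the expected diameter, then iterated intensity-weighted centroids
over a disc window, recentering while the estimate moves > 0.5 px. Mass is
the integrated band-passed intensity and size the radius of gyration; spots
closer than the expected diameter merge into one detection (documented
behavior, matched by a test). Localization RMS error is < 0.2 px noise-free
and < 0.5 px at SNR 5 on rendered fixtures.

Linking solves, per frame, the augmented assignment problem: matching a
track to a detection costs squared displacement (forbidden beyond the
search range), and each unmatched track or detection costs the squared
search range. This makes the optimum well-defined and testable — the suite
checks exact agreement with a brute-force enumeration oracle on fixtures
with ≤ 4 spots and ≤ 6 frames. Tracks may skip up to `memory` (default 3)
frames and are linearly interpolated across gaps so pulse metrics see
gap-free series; ties break deterministically by (cost, track id, detection
index). Radius-over-time estimates come from per-frame radially symmetric
Gaussian least-squares fits at the tracked center, median-smoothed
(default window 5).

## Pulse metrics

The displacement magnitude is the Euclidean distance from the origin (mean
position over a pre-pulse window, default the first frame). For pulse k
covering [kT, (k+1)T): peak = maximum over the whole period (robust to
response lag; equals the on-phase maximum for creep-like responses),
residual = value at the last sample before (k+1)T, relative = peak −
residual. AUC is the trapezoidal integral over the first five periods by
default; cumulative displacement is the 2-D path length (the
displacement-from-origin reading is available separately since the
convention is ambiguous in common usage). Summaries average over the first
five pulses per bubble, then report mean/median/sd/sem and box-plot
quartiles with 1%/99% whiskers across bubbles.

## Image quantification

The DNA-stain channel is linearly min–max rescaled to 8-bit. The background
level is the histogram mode and its spread a MAD-based robust sigma of the
sub-mode pixels; the nuclear threshold is mode + k·spread (default k = 3),
with Otsu's method as fallback when the background estimate degenerates
(e.g. noise-free images with zero spread). Components under 25 px are
removed and holes filled; touching nuclei are not split (the generator
produces non-overlapping nuclei, so watershed splitting is out of scope).
Per nucleus, the marker mean inside the mask is divided by the image-mean
DNA-stain intensity (per-image normalization absorbs staining-batch
variation; the division uses the image average, not per-nucleus values).
Cytoplasmic intensity is the marker mean in a 3-px dilation ring excluding
all nuclear pixels, and a cell is nuclear-positive when the
nuclear/cytoplasmic ratio is ≥ 1.1 (boundary inclusive by convention
fixed here).

## Statistics

Each group is gated by Shapiro–Wilk at α = 0.05; two normal groups get a
Welch two-sample t-test (unequal variances — the safer default where the
pooled variant is not specified), otherwise a two-sided Mann–Whitney U
(exact null distribution for groups ≤ 8). Significance is declared at
p < 0.05 with no multiple-testing correction (flagged in the report
output). Box summaries use linearly interpolated percentiles
(25/50/75/1/99). Metric–marker correlations across conditions use Pearson r
on paired per-condition medians with Spearman alongside; with only 3–4
condition points the coefficients are descriptive and no p-value is
attached. Simulation checks: the gated test's type-I error over 1000 null
replicates lies in [0.03, 0.07], and a planted negative metric–marker
effect has its sign recovered in ≥ 95% of replicates.

## Problem sizes and numerical choices

Default analysis runs use 5 pulses at PRF 1 Hz sampled at 1 kHz for metric
extraction; rendered-stack runs use 100 fps over 5 s with 96×96 px fields
and two bubbles; fitting studies use 100 noisy replicates at 100 Hz; nuclei
studies use 200 nuclei. Kelvin–Voigt fitting is bounded least squares over
(τ, x∞) with 8 log-spaced τ starts over [0.01, 10] s; convergence is
reported honestly (non-convergence for degenerate input, an at-bound
optimum, or an RMS misfit above half the signal amplitude). Confidence
half-widths are 1-σ Gauss–Newton values. Floating-point comparisons in
windowing use 10⁻¹² absolute slack to keep half-open intervals stable.

## Known limitations

- The linear Kelvin–Voigt model cannot reproduce measured AUC values
  jointly with peak/residual means (see above); β/plastic terms are
  emulations, not fitted material laws.
- Net Bjerknes directions are static (rest geometry); truly coupled
  dynamics would update forces along the trajectory.
- The detector assumes bright spots of roughly known diameter; it is not an
  adaptive multi-scale detector, and overlapping bubbles merge.
- Image-level statistics (which sampling unit forms a test's n) follow the
  image level; cell-level resampling is not implemented.
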
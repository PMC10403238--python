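# Methods

This note records the models behind `anomtrans`, the conventions the numbers
are reported in, the defaults that matter, and the choices made where more
than one reasonable design existed.

## Conventions

All positions are micrometres, times seconds, wave vectors inverse
micrometres.  The ensemble mean-squared displacement uses the half-sum
convention

    MSD(dt) = 0.5 ( <dx(dt)^2> + <dy(dt)^2> ),

so for isotropic motion the MSD equals the per-axis displacement variance.
The generalized transport coefficient `K` is defined on this convention,
`MSD = K dt^alpha`; for normal diffusion with per-axis `<dx^2> = 2 D dt`
this means `K = 2D`.  The intermediate scattering function of Gaussian
displacements is then `f(q, dt) = exp(-q^2 MSD(dt) / 2)`, which links the
real-space and reciprocal-space observables: for Brownian motion
`tau(q) = 1/(D q^2)`, i.e. `beta = 2` and `alpha_DDM = 2/beta = 1`.

## Synthetic motion models (`syntraj`)

The generator exists so that every analysis stage can be validated against
known ground truth.  It emulates the statistical structure of tracer motion
in crowded, motor-driven biopolymer networks — not the networks themselves
(no filament-level or hydrodynamic modeling, no photobleaching or
illumination-depth effects).

**Fractional Brownian motion.**  Sub- and superdiffusion with a prescribed
exponent `alpha` in (0, 2) are generated per axis as exact fractional
Gaussian noise via circulant embedding (Davies–Harte).  The circulant
eigenvalues of the fGn covariance are non-negative for Hurst `H = alpha/2`
in (0, 1), so one FFT of complex Gaussians yields exact stationary
increments; no approximate integrator is involved.  This matters because a
biased synthesis would corrupt exponent-recovery checks, which are the core
validation surface.  Axes are independent; increments are scaled so the
ensemble MSD is exactly `K dt^alpha`.

**Ballistic (advective) motion.**  Each particle receives a constant
velocity: magnitude from a normal truncated at zero (mean `velocity_mean`,
sd `velocity_sd`; a matched-moment uniform option exists for benchmark
setups that specify uniform speeds), direction either isotropic or spread
normally about a drift axis (default -y, emulating the anisotropy imposed
by an elongated sample chamber).  Quenched per-particle velocities are the
simplest model reproducing both the `MSD = 0.5 v^2 dt^2` ballistic
signature and non-zero van Hove modes; the true displacement distribution
of network-entrained tracers is unknown, and this stand-in is exactly that.

**Caged/hopping motion.**  Per-axis Ornstein–Uhlenbeck relaxation toward a
cage center, with stationary sd `cage_size` and relaxation time
`cage_relax_time` (an added parameter — confinement needs a timescale;
default 1 s), plus Poisson-timed cage-center jumps of exponential length.
Between hops the MSD plateaus at `2 cage_size^2`; hopping adds the
exponential van Hove tails characteristic of heterogeneous transport.

**Multimode motion.**  Sum of a subdiffusive fBm term and an advective term
whose amplitude is set from `crossover_time`: the two analytic MSD terms
`K1 dt^a1` and `K2 dt^a2` are equal at the crossover.  The advective term
is ballistic (`alpha_long = 2`, sample mean-square speed rescaled so the
analytic amplitude holds exactly) or a superdiffusive fBm for
`alpha_long < 2`.  Metadata records the inputs, the analytic location of
the MSD/dt minimum, and `multimode_effective_exponents()` evaluates the
slopes an unbiased estimator should recover over any fit window.  This
"effective truth" is what recovery tests compare against: over a finite
window the slope of a sum of two power laws sits strictly between the
component exponents, so comparing a fit to the bare inputs would conflate
estimator error with window bias.

**Rendering.**  Frames are a constant background plus a symmetric Gaussian
per in-field particle (sigma 0.4 um, emulating a ~1 um emitter under the
optics), with Poisson noise on signal + background by default (counting
statistics of a sCMOS-like detector); Gaussian and noiseless options exist.
Particles outside the field are not rendered but stay in the track table,
mirroring real tracking truncation without biasing the MSD code.  Output is
16-bit TIFF plus a plain-text calibration sidecar.

## SPT analysis (`spt_msd`)

MSDs are time-averaged within each track (FFT algorithm for contiguous
tracks, NaN-aware direct sums across gaps) and pooled across the ensemble
weighted by pair count — i.e. the grand mean over all displacement pairs.
Pooled weighting was chosen over per-trajectory averaging for statistical
efficiency; both schemes coincide for equal-length tracks.  Lags with fewer
than `min_pairs` (default 50) pairs are dropped; tracks shorter than
`min_track_length` (default 10 frames) are excluded at load time, with
counts logged.

Regime extraction:

* `detect_t1` — expanding log-log regression from the smallest lag; t1 is
  the largest window end with R^2 > 0.99.  The minimum window is 5 lags
  (R^2 on fewer points is uninformative).  All lags in the window are used
  by default.  If no window passes, the minimum-window end is returned as a
  conservative floor.
* `detect_t2` — first strict local minimum of MSD/dt after a centered
  5-point moving average (raw MSD/dt at long lags is noise-dominated); ties
  break toward the smaller lag.  When a t1 is supplied only lags beyond it
  are eligible; a single-power-law curve therefore reports no t2.  A curve
  increasing from the first lag (purely advective input) degenerately
  reports the first lag and logs a warning.
* `fit_regimes` — unweighted log-log least squares per regime, after
  subsampling the lag grid to at most 30 log-spaced points per decade so
  densely sampled long lags do not dominate; `fit_cap` truncates fitting
  where low statistics dominate (typical values 40–100 s depending on the
  data).  The intermediate exponent is fitted only when its window holds at
  least 4 lags; any regime with fewer than 3 lags reports no exponent
  rather than extrapolating.

Fitting in log space (unweighted) matches the R^2 criterion used for t1.
Drift subtraction is deliberately absent: directional motion is part of the
signal under study, and drift enters only through the generator.

## Van Hove analysis (`vanhove`)

Distributions are unit-area histograms on uniform, zero-centered bins
(default width 0.05 um, roughly the localization-precision scale of SPT
experiments; support covers the 99.9th percentile of |dd|).  The pooled
axis concatenates x and y displacements.

The mode is located by 3-point parabolic interpolation through the maximal
bin — deterministic and robust to half a bin, with no kernel smoothing.
Half-maximum crossings are linearly interpolated on each side.  The leading
edge is the side sharing the sign of the mode (displacements larger in
magnitude); a mode within one bin of zero defaults leading to the positive
side and flags the distribution symmetric.  The asymmetry statistic is
`(HWHM_trailing - HWHM_leading) / HWHM_leading`.  Under this definition
mirroring the displacements negates the mode but maps the leading edge onto
the mirrored leading edge, so the statistic is mirror-invariant and zero
for symmetric inputs.

Practical operating point: the raw-histogram mode estimate is reliable when
the bin width is a few tenths of the distribution width.  Much finer bins
leave the flat top of a Gaussian dominated by counting noise, and the mode
(hence the half-width split) wanders by more than a bin; the shape tests
in this repository use bin/sigma ≈ 0.1–0.2 and 1e5–2e6 displacements
accordingly.

Mixture fits use `G(dd) = A exp(-(dd-c)^2 / 2 sigma^2) + B exp(-|dd-c|/lam)`
with both terms sharing the center `c` — the mode for skewed distributions,
exactly zero when the symmetric flag is set.  One-sided fits restrict the
bins to the leading or trailing side of the center but keep the full
functional form (not renormalized half-densities), so the amplitude ratio
`a = A/(A+B)` reads the same way on either side.  Non-negative amplitudes
are enforced and the fit is multi-started over lam to escape the local
minimum where the exponential collapses onto the Gaussian core.

FWHM scaling fits regress `log FWHM^2` on `log dt` (the exponent is then
directly `alpha`; regressing FWHM gives alpha/2, identically).  The default
regime split at 1 s is inclusive on both sides; split `None` gives a single
fit.  Default lag set: 0.1, 0.2, 0.3, 0.5, 1, 2, 3, 5, 10, 15 s — two
decades.

Not computed: kurtosis-based non-Gaussianity parameters and per-trial
directional bookkeeping (the per-axis machinery is provided; aggregation is
the caller's).

## DDM analysis (`ddm`)

The structure function averages `|FFT2(I(t+dt) - I(t))|^2 / Npix` over up to
300 evenly strided frame pairs per lag (deterministic stride), on ~20
log-spaced lags per decade, then over annuli one FFT bin wide (zero
frequency excluded; centers at the annulus mean |q|).  The 1/Npix
normalization makes the unaveraged q-plane satisfy Parseval's identity
against the summed squared pixel differences.  No window function is
applied by default; a Hann option exists for stacks with strong
edge-crossing artifacts.  Default maximum lag is half the stack duration
(pair statistics degrade beyond that), and fits cap at 100 s.

Per-q stretched-exponential fits initialize `B0 = min D`, `A0 = max D - B0`,
`tau0` at the `1 - 1/e` crossing and `gamma0 = 1`, with `gamma` bounded in
[0.2, 3] — generous margins around the confined (<1) through compressed
(>1) range of physical interest.  Non-converged q values are flagged and
excluded downstream; bins far above the fit band are skipped outright.

`tau(q)` is fit over q = 1–4 um^-1 by default (1.5–4 recommended for
advection-dominated data); two guard flags mark the regimes where the power
law is untrustworthy: a low-q plateau (|local slope| < 0.5 over the three
smallest converged q — finite image size and lag range) and a high-q uptick
(tau increasing at the top of the band — resolution limit).  The q-averaged
stretching exponent is reported with its standard error and a gamma-vs-q
slope as an insensitivity diagnostic.  Anisotropic (direction-resolved) DDM
is out of scope; everything is radially averaged.

## Pipeline (`pipeline`, `cli`)

One config drives all stages per condition; stage failures null that
condition's metrics and continue (config errors abort up front).  The
summary table carries fit standard errors for every exponent and the
standard error over q for gamma.  `compute_detectability_timescale`
implements the order-of-magnitude estimate `dt_a = resolution / speed` for
when advective motion rises above the localization floor: with a 100 nm
floor, network speeds of 2.2–85 nm/s give roughly 45 s down to 1.2 s.

## What the benchmarks do and do not show

The acceptance suite (`tests/test_acceptance.py`, `scripts/acceptance.py`)
verifies closed-form limit recovery on synthetic data at desk scale:
Brownian stacks recover `beta = 2`, `gamma = 1`; straight-line motion
recovers `beta = 1`; fBm ensembles recover their exponents within 0.05; the
multimode crossover is found where the analytic terms predict it; the three
alpha estimates agree on a common Brownian synthetic.  Problem sizes —
150–200 particles, 800–2000 frames, 256 px fields — were chosen as the
smallest ensembles at which the estimators' statistical error is comfortably
inside those tolerances.  Passing these benchmarks shows the estimator
chain is unbiased and internally consistent under the generator's
assumptions (Gaussian or quenched-velocity motion, ideal PSF, Poisson
noise).  It does not certify behavior on real microscopy, where localization
error, bleaching, depth effects and non-stationary activity enter; those
effects are intentionally outside the generator.

## Known limitations

* The half-sum MSD convention differs by a factor of 2 from the common 2-D
  `<dr^2>` convention; exported prefactors must be interpreted accordingly.
* The expanding-window t1 criterion depends on the noise level through R^2;
  very noisy curves can report a floor value (logged) rather than a
  meaningful transition.
* One-sided mixture fits need the mode resolved to within about one bin;
  with too-fine binning the side split becomes noisy (see the van Hove
  operating point above).
* The renderer clips negative intensities and quantizes to 16 bits;
  extremely low-contrast configurations can lose the dynamic signal in the
  quantization floor.
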
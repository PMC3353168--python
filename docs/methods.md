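# Methods

`chronowave` estimates time-varying period, phase and amplitude of
oscillatory biological records — bioluminescence reporter traces,
wheel-running counts, and similar circadian readouts — and provides a
complementary discrete-wavelet toolbox for band decomposition,
significance testing, denoising and detrending. This note documents the
models, the defaults and why they are what they are, the numerical
choices, and the known limitations.

## Continuous transform

The analysis wavelet is the analytic Morlet,
psi(eta) = pi^(-1/4) exp(i*omega0*eta) exp(-eta^2/2), with center
frequency omega0 = 6 (dimensionless). omega0 >= 5 keeps the zero-mean
(admissibility) error of the analytic form negligible; 6 is the standard
compromise between period resolution and time localization for circadian
work, and is exposed as a parameter.

Scales map to periods via lambda = 4*pi*s / (omega0 + sqrt(2 + omega0^2)),
the value at which the wavelet's frequency response peaks; at omega0 = 6
the scale/period ratio is 0.968. The period grid is logarithmic,
`min_period * 2^(k/voices_per_octave)`, with 16 voices per octave by
default (about 4.4% spacing — smooth heatmaps at circadian resolution)
over the default range [6, 48] hours at a default sampling interval of
1 hour. Requested bounds are clamped to the record's capabilities
(Nyquist 2*dt below, half the record n*dt/2 above), with a warning
naming the bound actually used.

The transform is computed by multiplication in the Fourier domain after
subtracting the mean (to stop DC leaking into long-period rows; can be
disabled) and zero-padding on the right to the next power of two. The
frequency response is scaled by A = 2*exp(delta^2/2),
delta = (sqrt(2+omega0^2) - omega0)/2, so that a unit-amplitude cosine at
an on-grid period reads out ridge modulus 1.000 in the record interior:
reported amplitudes are in signal units. A brute-force time-domain
convolution oracle in the test suite pins the engine to 1e-6.

### Edge handling

Zero-padding makes boundary coefficients unreliable out to roughly one
envelope e-folding time sqrt(2)*s. Three treatments are offered:

- `pad` — keep the zero-padded numerics (padding is part of the base
  transform, so this mode changes nothing further);
- `reweight` — divide each coefficient by the fraction of its wavelet's
  Gaussian envelope mass inside the observed window (first power, not
  squared), which approximately unbiases edge amplitudes of a stationary
  oscillation; interior coefficients change by < 1e-6;
- `truncate` (default) — leave coefficients untouched but mask every cell
  within sqrt(2)*s of a boundary; masked cells are reported as missing in
  all tables and blacked out in heatmaps.

The cone of influence reported per time point is the longest period whose
scale satisfies that criterion.

A consequence worth knowing: under `truncate` the *unmasked* cells
adjacent to the cone boundary are still mildly damping-biased (the bias
is what the cone bounds, not what it removes), and the bias is asymmetric
in scale — longer-period rows are damped more — so a ridge read exactly
at the cone boundary sits up to one voice step below the true period even
for a stationary tone. On a chirp whose period is still changing at the
boundary this combines with the fact that the first reportable time point
is ~1.4 scale units into the record: endpoint ridge readings are not
estimates of the generating period *at t = 0* but at the first reportable
time. The bundled chirp (24 -> 18 h over 240 h) therefore reads ~22-23 h
at the first reportable column and ~18.5-19 h at the last, while tracking
the true instantaneous period to within one voice step + 2% everywhere
in the reportable region.

## Ridge extraction and features

The default extractor seeds at the global modulus maximum (robust to edge
artifacts) and grows the ridge outward, taking the columnwise argmax
within `max_jump` rows of the previous ridge row (default one quarter
octave per sample — permits chirp rates like the bundled test signal
while suppressing octave hopping). Ties break toward shorter periods.
One ridge is returned; multi-component records are handled by re-running
with restricted period bounds.

The stochastic alternative ("crazy climber") runs annealed random
walkers over the plane: column steps always accepted with reflecting
boundaries, row steps Metropolis-accepted on the modulus at temperature
T0 = 1 cooled geometrically (0.99 per 100-move block). Visits accumulate
modulus into an occupation map; a triangular row-smoothing kernel
(half-width 1) is applied, and the same continuity chaining as the greedy
method runs on the occupation map. The scheme is deterministic given its
seed and is a simplified single-stage variant of the full
occupation-density ridge machinery.

Instantaneous phase is the argument of the ridge coefficient, amplitude
its calibrated modulus. Peaks are sub-sample times where the unwrapped
ridge phase crosses even multiples of pi, troughs odd multiples — the
convention under which a cosine's coefficient is real-positive at its
maxima (verified by a property test: ridge phase at a cosine peak is 0
within 0.1 rad). Events inside edge-masked regions are dropped, matching
the masking-first presentation of the tables; peaks closer together than
half the shortest analyzed period are merged. Peak-to-trough excursions
evaluate the *raw* series at the nearest sample, so they are insensitive
to mean level but sensitive to noise; the Rayleigh statistic
R = |mean(exp(i*phi_k))| with the standard second-order p-value
approximation exp(-Z)(1 + (2Z - Z^2)/(4n)), Z = nR^2, summarizes phase
synchronization across a batch (exact permutation tests are out of
scope; the approximation's null p-values are uniform to KS < 0.05 at
n = 8).

## Discrete transform

The maximal-overlap (undecimated, shift-invariant) DWT uses Daubechies
extremal-phase filters, length 8 (`db4`) by default — a balance of band
sharpness against edge spread; lengths 2-20 are available. Filters are
MODWT-rescaled (divided by sqrt(2)) and applied by circular convolution
in the Fourier domain through the standard pyramid transfer functions.
Two outputs coexist because they satisfy different exact identities:

- multiresolution details and smooth (band projections): sum exactly to
  the input, and the smooth carries the mean — this is what denoising,
  detrending and the decomposition tables use;
- analysis coefficients and level-J scaling coefficients: satisfy the
  energy identity exactly — this is what significance testing uses.

Level j nominally covers periods [2^j*dt, 2^(j+1)*dt); at hourly
sampling level 4 is the circadian 16-32 h band, at 15-minute sampling
level 6. The default depth is floor(log2 n). Circular boundaries are
used throughout (no reflection option): a trend or baseline step between
the last and first sample wraps around and contaminates roughly one
filter width at each end of every band — visible as boundary distortion
in detrended output whose interior is clean (interior correlation with a
known embedded tone is ~0.996 where the full-record value can drop to
~0.7 purely from the wrapped step).

### Significance, denoising, detrending

Under additive white Gaussian noise of variance sigma^2, level-j MODWT
coefficients have variance sigma^2 * 2^-j. The noise scale is estimated
robustly from the level-1 coefficients, sigma_hat^2 =
2 * (MAD(|W_1|)/0.6745)^2 (the factor 2 converts the level-1 coefficient
scale back to the input scale; MAD keeps the estimate insensitive to
oscillatory signal living in coarser bands). The level energy, scaled by
the equivalent degrees of freedom dof_j = max(n/2^j, 1), is referred to
the upper tail of chi-squared(dof_j). At alpha = 0.05, N = 512, the
empirical type-I error pooled over levels 2-5 is 0.067 (1000 seeded
replicates). Per level it is not flat: fine levels over-reject (~0.09 at
level 2) because the sampling noise of sigma_hat dominates the narrow
chi-squared spread at large dof, while the dof floor formula itself is
conservative; users needing exact per-level calibration should prefer
coarse levels or larger alpha margins. Level 1's test is nearly
self-referential (sigma_hat comes from level 1) and should not be
interpreted.

Denoising reconstructs from the significant detail levels plus (by
default) the smooth, so nonzero means and slow baselines survive.
Detrending reconstructs only the details whose nominal band intersects
the requested period interval and always drops the smooth, so its output
is mean-free by construction (detail bands have zero DC gain).

## Synthetic fixtures

The generators produce the study conditions every stage is tested on:

- `make_signal_a` — chirp with instantaneous period interpolating
  linearly from 24 h to 18 h over a 240 h hourly record (phase computed
  in closed form, 2*pi*log1p(r*t/P0)/r), amplitude decaying at 0.005/h
  (to ~30% by the record end), zero baseline, optional Gaussian noise.
- `make_signal_b` — stable 24 h cosine with the middle 20% of the record
  censored (mask false), for gap-bridging tests.
- `make_activity` — non-sinusoidal count record: Poisson(50) counts
  during the active half of each 24 h cycle, a Poisson(2) noise floor
  throughout, 15-minute bins for 10 days (960 samples).
- `make_white_noise` — i.i.d. Gaussian null for significance-test
  calibration.

All generators are pure functions of their spec including the seed.
What they deliberately do not emulate: bioluminescence shot noise,
slowly wandering baselines, inter-animal variability, or limit-cycle
dynamics — so passing tests demonstrate correctness of the estimators
under their stated models, not robustness to every artifact of real
recordings.

## Degenerate inputs and tie-breaks

All-zero CWT planes yield an all-invalid ridge at row 0. A noiseless
record makes sigma_hat = 0; levels with nonzero energy then report the
smallest positive p-value rather than dividing by zero. Ridge argmax
ties break toward the smaller row (shorter period). Missing values must
be imputed before either transform (linear interpolation by default,
with edge gaps held at the nearest observation); analyses hard-error on
masked input rather than guessing. Batch runs skip failing series with a
logged warning and fail only when every series fails.

## Problem sizes

The bundled analyses are desk-scale: 240-960 samples per trace, 49
period rows, FFTs at most 1024 long; the significance-test calibration
runs 1000 replicates of length 512 in about a second. These sizes were
chosen to match the study conditions the fixtures emulate.
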
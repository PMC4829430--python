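# Methods

## The kinetic model

A microtubule with `n_pf` protofilaments (default 13) of dimer length
`l_dim` (8 nm) is treated as a one-dimensional filament whose maximal
linear density of EB binding sites is `n_x0 = n_pf / l_dim = 1.625 /nm`.
During steady growth at speed `v_g`, freshly added sites mature into
ordinary lattice at rate `k_m`, so the site density behind the end is
exponential with comet length `L_comet = v_g / k_m` and the total site
number at washout is `N(0) = n_x0 v_g / k_m`.

After tubulin washout the cap decays by (i) continued maturation, which
multiplies the whole profile by `exp(-k_m t)`, and (ii) slow shrinkage of
the end at `v_s`, which advances the front through ever-denser cap. Both
the total number and the terminal ("end") density therefore decay at

    k_cap = k_m (v_s / v_g + 1),

and since the lattice-subtracted EB end intensity is proportional to the
site number, the intensity decays at the same rate. Catastrophe is modelled
as a threshold crossing; the implemented variants are

- **end density**: terminal density falls to a fraction `f_crit` of `n_x0`;
  delay `T = -ln(f_crit) / k_cap`, independent of cap length at fixed
  `k_cap` — delays saturate with growth speed;
- **total number**: `N(t)` falls to `N_crit`; because `N(0)` grows with
  `v_g`, delays keep rising with speed — the feature that lets speed-sorted
  data discriminate the models;
- **window L**: the number of sites within a fixed length `L` of the end
  falls to `NL_crit`; interpolates between the two (end density as
  `L -> 0`, total number as `L -> infinity`), and ties the delay data to
  the intensity data through `I(0) = F v_g` and the closed form for
  `I(T_L)` with a camera factor `F`;
- **two-step maturation**: a fast first step `k_1 > k_m` (a freshly added,
  not-yet-EB-binding but stabilising state) modifies the density/number
  expressions; the delays are obtained by bracketed Brent root-finding on
  [0, 10/k_m] (tolerance 1e-6 s; `k_1 = k_m` is rejected as singular rather
  than taking the limit, since the regime of interest is `k_1 >> k_m`,
  typically 5-20 k_m). The printed two-step total-number prefactor at t=0
  is `n_x0 (v_g/k_m)(1 + k_m/k_1)` — implemented exactly as stated, noting
  it exceeds the one-step `n_x0 v_g/k_m` at first order in `k_m/k_1`.

All closed forms are anchored in end-following coordinates; the lab-frame
front position `v_s t` is handled inside `total_sites` and is not part of
the API. Units are nm, s and sites package-wide; intensities are arbitrary
units with the explicit factor `F` (a.u. s / nm).

Two printed values for the slow shrinkage speed of the EB-rich condition
circulate (40 and 38 nm/s); `v_s` is always an input here, and the worked
examples use 40 nm/s, which reproduces the 0.35 1/s decay rate.

## Trace analysis

- **Washout**: the soluble-tubulin background is fitted over the full
  record with `lo + (hi-lo)/2 (1 - erf((t - t_wo)/(2 tau)))`; `t_wo` is the
  inflection point and the 5-95% exchange interval is `4 tau erfinv(0.9)`.
  A transition is accepted only if the amplitude exceeds 5x the noise sd
  (estimated from first differences of the early record). The fit window
  is the whole record; no sub-window is defined.
- **Growth speed**: OLS slope over a 10 s window ending at washout
  (shifted windows for the memory analysis). With 30 nm position noise at
  4 Hz the slope sd is `sigma sqrt(12/(n(n^2-1)))/dt ~ 1.6 nm/s`.
- **Catastrophe**: post-washout positions are fitted with the analytic
  antiderivative of `v(t) = (v1+v2)/2 + (v1-v2)/2 erf((t0-t)/(2 sigma))`
  (the erf argument divides by `2 sigma`; the alternative reading is
  dimensionally absurd). Initialisation: `t0` from the most negative
  3-frame position drop, `v1` from the first half of the segment, `v2` from
  the last second, `sigma = 0.5 s`; five starts jitter `t0` by up to 1 s.
  The catastrophe time is the 25% point of the speed transition,
  `t_cat = t0 - 2 sigma erfinv(0.5)`, independent of the speeds.
- **Metrics**: `v_s` is the OLS slope of raw positions on `[t_wo, t_cat]`
  (magnitude); `v_f = |v2|`; the measured shrinkage length is the fitted
  position difference between washout and catastrophe, the predicted one
  `v_s (t_cat - t_wo)`. Because the speed at `t_cat` is by construction
  already 25% into the transition, the measured `v_s` is inflated by
  roughly 10% and the measured shrinkage length systematically exceeds the
  predicted one; both effects are properties of the estimator, not bugs,
  and they propagate into threshold fits (recovered `f_crit` runs a few
  hundredths low of truth). Intensities `I_wo`, `I_cat` are 1 s window
  means centred on `t_wo` and `t_cat` (the windows are short against the
  slow decay, so the centring bias is a few percent); `I_lat` is the
  time-average of the lattice channel 1.5 um behind the end, and the cap
  fraction at catastrophe is `(I_cat - I_lat)/(I_wo - I_lat)`.
- **Aligned averaging**: tracks are interpolated onto a 0.25 s grid
  relative to their own catastrophe time (position traces also aligned at
  the catastrophe position); the grid is truncated where fewer than half
  the tracks have data. The mono-exponential decay fit of the mean
  intensity runs from the mean washout time to catastrophe with two
  deliberate choices: samples before a track's own washout are excluded
  (they sit on the pre-washout plateau, which is not part of the decay and
  flattens the apparent rate), and the offset is fixed at the measured
  cohort-mean lattice intensity (a free offset is unidentifiable over a
  window of roughly one decay time).
- **Orientation**: the pre-washout mean orientation per track, expressed
  as magnitude of deviation from the cohort mean, is Pearson-correlated
  with the delay as a control that stability is not orientation-biased.

Tracks whose washout or catastrophe fit fails are excluded and logged with
the failure reason, never silently dropped.

## Comet analysis

The averaged EB intensity profile is the binding-site density (exponential
of length `L_comet` plus a lattice step, both starting at offset `xc` from
the detected end) convolved with a Gaussian PSF of width `sigma_psf`. The
closed form uses the exponentially-modified-Gaussian expression, evaluated
through the scaled complementary error function in two branches so neither
tail overflows. The kernel is normalised to unit area (a reparameterisation
of the unnormalised Gaussian sometimes written; amplitudes then retain
physical meaning). Fits are unweighted least squares — after averaging
thousands of frames the per-point sems are nearly uniform. `k_m` follows as
`v_g / L_comet`.

On a 107 nm pixel grid with per-frame noise at the imaging regime's SNR of
~3, the 5500-frame average constrains `k_m = 0.16` to about 0.006 1/s
(1 sd); this is the information limit of the profile, with strong
amplitude-length-offset correlations in the fit. Short comets
(`L_comet ~ 120 nm`) under a broad PSF carry an additional few-percent
discretization bias.

## Speed-sorted model fitting

Tracks are sorted by measured `v_g` into contiguous equal-size groups
(remainder to the slowest groups; stable sort for determinism) and the
threshold models are fitted to the group means weighted by `1/sem^2` — the
fits operate on averages, exactly as the delay data are presented; no
individual-track likelihood is offered, since the observed per-track
dispersion exceeds what the deterministic threshold model produces. `v_s`
inside the model predictions comes either from the fitted linear relation
`v_s = a v_g + b` (concentration-series data) or from fixed cohort means
(condition comparisons). The global window-`L` fit holds `L` fixed,
frees one `NL_crit` per dataset (thresholds are per-condition) plus one
camera factor `F` per intensity dataset, and scans `L` to produce the
reduced-chi-square curve; the intensity block enters through the washout
and catastrophe intensity closed forms.

Optimisation is bounded nonlinear least squares with multi-start
(`f_crit` in (1e-3, 1), starts {0.1, 0.3, 0.5}; number thresholds start at
{0.1, 0.3, 0.5} of the smallest initial count). Parameter errors come from
the Jacobian, scaled by the reduced chi-square when it exceeds 1.

## Cohort statistics

Spearman's rank correlation uses midranks for ties and the t-distribution
approximation for two-sided p-values (an exact permutation p is feasible
only for tiny n and is used as a test oracle at n = 5). The shifted-window
analysis re-measures growth speed (10 s windows) or end intensity (1 s
windows) ending `dt` before washout and correlates with the delay; tracks
whose window leaves the record are dropped for that shift with the pair
count reported. The relative variance `D = var/mean` per intensity series
separates genuine cap-size variability from measurement noise (D scales
with intensity, so comparisons assume a common intensity scale).

## The synthetic generator

`SyntheticConfig` defaults encode the experimental regime the analysis
assumes: 4 Hz sampling, ~100 s growth, 30 nm tracking noise, growth speeds
truncated-normal with mean 33 and sd 12 nm/s (uniform optional; the
distributional form is not constrained by data, only histograms),
`v_s = 0.28 v_g + 22 nm/s` with 5 nm/s residual sd, 480 nm/s fast
depolymerisation, `k_m = 0.16 1/s`, an end-density threshold (default
`f_crit = 0.28`, the EB-rich value), an erf background drop with
`tau = 42.8 ms` (199 ms 5-95% exchange), and 7.3 deg orientation scatter.

Choices the data do not fix directly:

- **Delay dispersion.** The deterministic threshold model predicts a single
  delay per speed; observed delays scatter more. The generator injects
  dispersion through a per-track lognormal cap-size factor `xi`
  (`delay = (ln xi - ln f_crit)/k_cap`), a modelling device rather than a
  mechanism claim. Its sd defaults to 0.2, chosen so the default cohort
  reproduces the observed correlation structure (rank correlation of delay
  with cap intensity ~0.8-0.9 and with growth speed ~0.6); the
  concentration-series recovery cohort uses 0.3.
- **Transition anchoring.** The threshold crossing defines catastrophe
  onset and is placed at the 25% point of the erf-smoothed speed
  transition (width 0.5 s), i.e. the transition centre sits
  `2 sigma erfinv(0.5)` later; the analysis pipeline applied to a noiseless
  track then recovers the true delay exactly. The end intensity decays at
  `k_cap` until the transition centre and collapses at
  `k_m (v_f/v_g + 1)` afterwards, as the fast-depolymerising end consumes
  the remaining cap.
- **Speed memory.** With `tau_mem` set, the speed follows a stationary
  mean-reverting (Ornstein-Uhlenbeck) process with exponential
  autocorrelation (default memory 5 s when enabled); the pre-washout end
  intensity then tracks the momentary speed. This makes the
  correlation-decay analysis testable; the real memory mechanism is not
  parameterised by data.
- **Noise models.** Intensity noise is multiplicative Gaussian (CV 0.15),
  not a photon model; comet frames carry additive noise at per-frame SNR
  ~3. Fixed-rate cohorts (`k_decay`) derive `v_s` from
  `(k_decay/k_m - 1) v_g` so the generated decay rate is exact.

What passing recovery tests shows — and does not. The generator shares the
analytic forms of the analysis (erf transitions, exponential decays), so
recovery tests validate the estimators, identifiability and the fitting
machinery under realistic noise, sampling and dispersion; they cannot
validate the kinetic model itself against nature, nor cover real-data
pathologies (bent or crossing microtubules, photobleaching, tracking
failures, non-Gaussian noise).

## Problem sizes and numerics

Simulated studies use the cohort sizes of the corresponding experiments
(100-210 tracks; 5500 comet frames); recovery-bias checks average a
handful of seeds. Root-finding tolerance is 1e-6 s; least-squares
tolerances 1e-12 to 1e-14; all randomness flows from a single integer seed
per study. Degenerate inputs (constant background, flat comet, monotone
shrinkage, constant correlation input) raise typed exceptions rather than
returning numbers.

## Known limitations

- The erf-transition tail inflates measured `v_s` (~10%) and shrinkage
  lengths; threshold fractions recovered through the full pipeline run a
  few hundredths below truth. Quantities derived directly from closed
  forms are unaffected.
- The intensity windows centred on washout/catastrophe carry small
  (few-percent) biases relative to instantaneous values.
- Only the end-density threshold drives the generator; cohorts generated
  under the other threshold models are supported at the group level.
- No Bayesian uncertainty, no model selection beyond reduced chi-square,
  no multiple-testing correction, no ageing effects, and no image-space
  processing (the package consumes tracked time series).
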
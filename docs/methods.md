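# Methods

This note documents the models, estimators and numerical choices behind
`eispec`, in the order the pipeline runs: recurrent network → LFP →
spectral readouts → Hurst estimation → BOLD forward model → experiment
orchestration → cohort statistics. It also states what the synthetic data
do and do not emulate.

## Recurrent network model

The circuit is a standard two-population cortical model: `N_E = 4000`
excitatory and `N_I = 1000` inhibitory conductance-based leaky
integrate-and-fire neurons (desk-scale preset: 400 + 100, below), randomly
connected with probability `p_conn = 0.2` (no autapses). Membrane dynamics

    C_m dV/dt = -g_L (V - V_leak) - g_AMPA(t) (V - E_AMPA)
                                  - g_GABA(t) (V - E_GABA)

with a spike emitted at `V >= V_threshold`, reset to `V_reset`, and an
absolute refractory clamp at the reset value during which synaptic
conductances keep evolving. Baseline single-neuron and synaptic parameters
(leak −70 mV, threshold −52 mV, reset −59 mV, refractory 2/1 ms, leak
conductance 25/20 nS, capacitance 500/200 pF; AMPA reversal 0 mV, GABA
reversal −80 mV; AMPA rise/decay 0.4/2 ms onto E and 0.2/1 ms onto I; GABA
rise/decay 0.25/5 ms; recurrent AMPA 0.178/0.233 nS, thalamic AMPA
0.234/0.317 nS, intracortical AMPA 0.187/0.254 nS, GABA 2.01/2.7 nS onto
E/I; zero synaptic latency) follow the conductance-based parameter set
conventional for this model family.

Each synaptic pathway is a peak-normalized difference of exponentials: a
presynaptic spike adds the pathway's peak conductance to a rise/decay gate
pair, so one spike produces a conductance excursion whose maximum equals
the tabulated value. Integration is exponential-Euler for the gates
(exact decay per step) and forward-Euler for the membrane, `dt = 0.05 ms`
by default; a divergence guard raises if the membrane leaves the finite
range. Identical `(config, seed)` reproduces runs bit-for-bit. A naive
reference integrator (plain Euler at `dt/10`, per-neuron loops) is kept in
the test suite as an independent oracle; at matched inputs the production
integrator reproduces its spike trains to < 0.1 ms.

**E:I ratio.** `g = g_GABA(onto E) / g_AMPA,rec(onto E)`; the baseline
table gives the reference `g = 2.01 / 0.178 ≈ 11.3`. `configure_ei_ratio`
scales both GABA conductances by one common factor (AMPA untouched), so
conditions are indexed by `g` alone. Chemogenetic-like manipulations:
enhanced excitability of excitatory cells = lowering their spike threshold
(−52 → −53 mV); pan-neuronal silencing = lowering the leak (resting)
potential of both populations (−70 → −75 mV).

**External drive and its calibration.** Each neuron receives two external
AMPA pathways: thalamic (constant rate `nu0` per synapse, default 1.5 or
2 spikes/s) and intracortical (rate `max(0, x(t))` with `x` a shared
zero-mean OU process, `tau = 16 ms`, `sigma = 0.2 * nu0`). The effective
number of external synapses per pathway, `n_ext`, is not a measurable
biological quantity here but the free drive parameter: with the tabulated
synaptic conductances a neuron needs roughly 8–9 nS of sustained AMPA
conductance to reach threshold from rest, so `n_ext = 8200` was calibrated
once so that the reference network sits in an asynchronous, irregular
regime (excitatory rates ~20 Hz, inhibitory ~10 Hz) in which all of the
qualitative E:I signatures hold simultaneously: both aperiodic slopes
flatten and H falls as `g` decreases below the reference; H plateaus above
the reference; threshold lowering reduces H while pan-neuronal silencing
slightly raises it. The OU amplitude matters for the low-frequency slope:
at `sigma = 0.4 * nu0` the shared slow drive masks the low-band trend at
10-s trace length; `0.2 * nu0` preserves it. These two constants are the
package's calibration and are not tuned per analysis.

**Desk-scale preset.** `reduced_config()` keeps the architecture but with
500 neurons made fully connected (`p_conn = 1`), which preserves as much
of the recurrent in-degree as a 10× smaller network allows (400/100 vs
800/200), and keeps single-synapse conductances at their baseline values:
upscaling them to compensate the in-degree shortfall inflates per-event
fluctuations (the few-neuron analogue of synchrony artifacts) and, in our
scans, reverses the spectral trends. The residual loss of mean recurrent
drive is absorbed by the shared external-drive calibration. All shipped
trend results and the acceptance computations use this preset with 10-s
simulations; the full-size preset is provided but was not exhaustively
validated at desk scale.

**LFP proxy.** `LFP(t) = |sum_E I_AMPA(t)| + |sum_E I_GABA(t)|`, the
summed absolute AMPA and GABA currents onto excitatory cells, including
both recurrent and external synapses, sampled at 1 kHz. Absolute values
are taken because the two synapse classes produce dipoles of the same sign
along pyramidal dendrites (apical AMPA vs peri-somatic GABA). The trace is
non-negative by construction.

## Spectral readouts

PSDs use Welch's method with ten Hamming-tapered segments at 50% overlap
(segment length derived from the trace length). The aperiodic shape is
summarized by two least-squares lines in (log10 f, log10 P): 1–30 Hz
("low") and 30–100 Hz ("high"). Band-power time courses use a Hamming
spectrogram (1-s windows, 0.5-s steps) integrated over the band;
LFP-power-to-BOLD coupling is the Pearson correlation of the band-power
course (linearly interpolated to the BOLD sampling grid) with the BOLD
series at non-negative lags. fALFF is the ratio of spectral amplitude
summed over 0.01–0.08 Hz to the amplitude summed over the full detectable
band (DC excluded, up to 0.25 Hz at the 0.5 Hz BOLD rate).

## Hurst exponent (wavelet-domain ML under a FIP model)

The series is modelled as a fractionally integrated process with spectral
density `S(f) ∝ sigma2 |2 sin(pi f)|^(-2d)` and `H = d + 1/2`; white noise
has H = 0.5, a random walk H = 1.5, and `H > 1` marks non-stationary
long-memory series. An orthonormal Haar DWT (periodized) approximately
whitens such processes; detail coefficients at octave j are modelled as
independent zero-mean Gaussians whose variance is the FIP density
integrated over the octave's dyadic band (48-node Gauss–Legendre per
octave, normalized so white noise has unit coefficient variance at every
octave). The Gaussian likelihood is maximized over `(d, sigma2)` in the
box `d ∈ [−0.5, 1.5]` (so `H ∈ [0, 2]`), `sigma2 ∈ [0, 10]`, by L-BFGS-B
from five deterministic starts; input series are standardized first, which
makes the estimate exactly affine-invariant and keeps `sigma2` inside its
box. Scales `j = 2 … floor(log2 n) − 3` are used: the finest octave
carries most filter/boundary bias and the coarsest need at least 8
coefficients. Estimates whose optimum touches a bound are flagged
`converged = False` but still returned.

Calibration (reproduced by the test suite): mean estimate on length-512
white noise = 0.50 ± 0.01 (100 seeds); mean absolute bias < 0.02 for
d ∈ {0, 0.2, 0.4, 0.9, 1.0} at n = 4096; agreement within 0.05 with an
independent log2-wavelet-variance regression estimator. The sliding-window
variant applies the estimator to windows of 512 samples (step 1 by
default), the configuration used for dynamic biomarker time courses.

The companion simulator draws ARFIMA(0, d, 0) realizations by fractional
differencing (recursive MA coefficients, burn-in ≥ max(n, 1024)); for
`d ≥ 0.5` it integrates an ARFIMA(0, d−1, 0) increment series.

## BOLD forward model

Ten-second LFP traces are pooled into three `g` groups (`g < 7.5`,
`7.5 ≤ g ≤ 11`, `g > 11`) and concatenated — 20 draws with replacement per
repetition — into 200-s signals. Frequencies below 1 Hz (the lower edge of
the slope fit) are then replaced by the power-law continuation of the
fitted low-frequency line: amplitudes follow `f^(slope_low/2)` anchored at
the geometric-mean amplitude over [1, 2] Hz, phases are redrawn uniformly
(seeded), DC is preserved, and the series is reconstructed by inverse
rfft. An exact power-law input is a fixed point of this operation.

The extrapolation belongs to the *spectral-shape* analyses (H of BOLD,
BOLD power peak): concatenating independent 10-s snippets leaves the
sub-0.1 Hz spectrum unphysical, and the continuation restores a
plausible shape. It must **not** precede band-power-to-BOLD correlation
analyses: the information linking BOLD to LFP band envelopes lives
precisely in the rectified LFP's own sub-Hz Fourier components (the
absolute value demodulates band amplitude into slow components), and the
extrapolation redraws those phases, decoupling the two series by
construction. The correlation analyses therefore run on the
non-extrapolated aggregate.

The BOLD transform is spectral:
`FFT(BOLD) = FFT(LFP) · |HPF| · FFT(HRF) + eta`, followed by inverse
transform and resampling to 0.5 Hz. Anti-aliasing is performed in the same
spectral step: only components below the output Nyquist (0.25 Hz) enter
the inverse transform at the output rate — an exact brick-wall, natural
here because the transform is already a spectral product (a time-domain
decimation filter at a 2000:1 ratio would be numerically degenerate).

**High-pass filter.** A second-order resonant high-pass with magnitude
`w^2 / sqrt((w0^2 − w^2)^2 + (2 zeta w0 w)^2)`, its two parameters solved
numerically so the response peaks at 20 Hz and is 3 dB below peak at
12.5 Hz on the rising flank. The filter expresses the empirically stronger
coupling of high (gamma) LFP frequencies to BOLD. Its stop band has a flat
leakage floor, default 5 × 10⁻³ of the peak (−46 dB; still far below the
1%-of-peak DC requirement): an idealized response falling as f² to zero
would attenuate the entire BOLD band (≤ 0.25 Hz) by ~10⁻⁵, pushing the
slow signal under the noise term and severing the H(BOLD)–H(LFP)
correspondence the model exists to carry. The floor makes low-frequency
attenuation *partial* — a uniform damping of the slow spectrum — which is
also what any realized finite-rejection filter does.

**HRF.** Two kernels, unit peak, sampled at the LFP rate. "canonical":
the conventional double-gamma (response peak 6 s, undershoot peak 16 s,
undershoot area ratio 1/6; it decays below 10⁻³ of peak by ~33 s, its 16-s
undershoot is still ~2 × 10⁻³ at exactly 30 s). "gamma_band_derived"
(default): a biphasic gamma-difference stand-in for the empirically
measured gamma-band-to-BOLD response — positive lobe peaking at 4 s,
undershoot centered at 18 s with 0.9 of the positive area, terminated by a raised-cosine fade by ~31 s. The deep slow
undershoot suppresses the kernel's DC response and gives it a band-pass
character peaking at a few hundredths of a Hz; its parameters were fixed
once so that the full forward chain, run at the reference `g`, places the
BOLD power peak at 0.03 Hz — the empirical BOLD peak frequency the model
is designed to reproduce — and were not revisited afterwards.

**Noise.** `eta` is complex white noise added to the spectrum (Hermitian
by construction of the inverse rfft), default amplitude 10⁻⁴ × the median
LFP spectral amplitude; it stands for neurovascular variability at
frequencies the BOLD acquisition cannot resolve. Results are insensitive
to its exact level over two orders of magnitude.

## Experiment orchestration

`run_g_sweep` / `run_dreadd_sweep` run (condition × thalamic level ×
repetition) grids — default grid 12 log-spaced `g` in [4, 16], thalamic
levels {1.5, 2.0} spikes/s, 5 repetitions, 10-s simulations — and emit one
tidy row per run (rates, both slopes, H of the LFP); rows already present
in a supplied table are skipped, so sweeps resume. Diverged runs are
flagged, not fatal. `group_h_by_g` splits the distinct `g` values into
equal-size ordered tertiles (largest-remainder with a warning otherwise)
and pools H samples per group. The shipped trend checks use a 6-point grid
{4, 5.6, 8, 11.3, 13.5, 16} with 3–4 repetitions — sizes chosen so the
seed-averaged direction margins measured during calibration are several
standard errors wide.

## Cohort statistics

**Camouflaging.** Within the autism sample only: each instrument is
mean-centered and divided by its maximum possible score (defaults AQ 50,
RMET 36, ADOS social-communication total 22, configurable), giving S_AQ,
S_ADOS, S_RMET. CF1 = S_AQ − S_ADOS (self-report vs observed behavior),
CF2 = −S_RMET − S_ADOS (mentalizing vs observed behavior); the reported CF
is the first principal component of (CF1, CF2), sign-oriented to correlate
positively with CF1 + CF2 so that higher CF = more camouflaging. The score
is interpretable only relatively, and only within the autistic sample
(TD subjects lack the observational instrument).

**Enrichment.** Over-representation of one deduplicated, case-normalized
gene list in another against a fixed background size: the 2×2 table's
sample odds ratio and the one-tailed hypergeometric `P(overlap ≥
observed)`. Zero-margin tables report OR 0/∞ with a flag.

**Fisher r-to-z.** `z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3))`
with a two-tailed normal p; requires n > 3 per group.

**Contrast PLS.** Contrast-driven (non-rotated) task PLS: the cross-block
matrix between grand-mean-centered group means (group order TD-M,
autism-M, TD-F, autism-F) and the contrast (default [1, −1, −1, 1], the
sex-by-diagnosis interaction) is decomposed; with contrasts given
directly, saliences are the unit-normalized cross-block rows and the
singular value its norm. Significance: free permutation of subject group
labels (default 10,000), add-one p. Reliability: within-group stratified
bootstrap (default 10,000), each resample sign-aligned to the original LV;
BSR = salience / bootstrap SE; the top 20% of parcels by |BSR| form the
reported mask. A standardized effect (observed singular value vs the
permutation null's mean and SD) is reported alongside. Constant parcels
are excluded with a warning.

**Synthetic cohorts.** Four groups with the study's final sample sizes
(29/23/33/25) by default, 180 Gaussian parcels (H mean 0.90, SD 0.10 —
the plausible human parcel-wise range). Affected parcels in autistic
subjects are shifted by −d·SD with d = 1.30 in males and −0.27 in females
(a large male deficit, a small female surplus: the planted
sex-by-diagnosis interaction). For autistic subjects a latent camouflaging
trait is drawn with the requested correlation to affected-parcel H (0.60
in females, −0.10 in males) and the three instruments are generated from
it with noise weights balanced so the *derived* CF score carries
approximately the requested correlation (realized ≈ 0.60 on average).
What this generator does not emulate: spatial covariance between parcels,
site/motion confounds beyond a nuisance meanFD column, non-Gaussian H
distributions, and any coupling between H and IQ. Recovery tests passing
on it show the estimators and inference machinery work under the planted
effect structure — not that real cohorts satisfy that structure.

## Known limitations

- The external-drive constants (`n_ext`, OU sigma) are a calibration, not
  a measurement; the full-size 5000-neuron preset inherits them but was
  validated only qualitatively.
- The forward model is linear and cannot produce negative low-frequency
  LFP–BOLD coupling; with the high-pass filter removed, the gamma-first
  ordering of band–BOLD correlations is not guaranteed.
- The gamma-band-derived HRF is a parameterized stand-in constrained by
  its spectral behaviour (0.03 Hz BOLD peak), not a fit to physiological
  recordings.
- H of a 100-sample BOLD series rests on two wavelet octaves; it is a
  coarse, high-variance estimate and is only used in seed-averaged form.
  In the shipped desk-scale regime it is moreover dominated by the
  hemodynamic kernel's steep spectral roll-off, which pushes H(BOLD)
  *above* H(LFP) and decouples its ranking across `g` from H(LFP)'s
  (whose plateau above the reference contributes near-ties); the
  corresponding chain-level properties are encoded as acceptance tests
  and currently fail, by design left as honest negatives.
- In this regime the threshold-lowering manipulation flattens only the
  30–100 Hz band while slightly steepening the 1–30 Hz band, so the
  forward-modelled fALFF rises rather than falls under enhanced
  excitability — likewise encoded as a currently failing acceptance test.
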
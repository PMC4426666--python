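# Methods

## Trace model

A slice recording is modelled as

    L(t) = b0·e^(−k·t) + A·e^(−λ·t)·cos(2π(t − t_peak)/τ) + ε,   ε ~ N(0, σ²)

with τ the free-running period (default 24 h), A the initial oscillation
amplitude (default 100 counts/s), λ the damping rate (default 0.01 /h,
i.e. the amplitude halves in ~69 h as cellular oscillators desynchronise),
b0 and k the baseline level and its decay (defaults 300 counts/s, 0.01 /h —
slice luminescence decays monotonically as luciferin is consumed), σ the
additive noise (default 5 counts/s = 5 % of amplitude), sampled every 10 min.
The absolute luminescence scale and the noise magnitude of real luminometers
are free parameters; the defaults are typical of organotypic recordings and
are exposed in every config.

A treatment at time T_p acts instantaneously: the oscillator phase jumps by

    Δ(φ, d) = PRC(φ) · d^n / (d^n + EC50^n)      [hours; delays negative]

where φ is the oscillator phase at T_p in the degree convention below, d the
dose, and PRC a two-harmonic sinusoid
a0 + a1·sin φ + b1·cos φ + a2·sin 2φ + b2·cos 2φ.  A delay (Δ < 0) moves all
subsequent peaks |Δ| hours later.  Optionally the post-treatment amplitude is
multiplied by a damping factor in [0, 1] (clock resetting often transiently
dampens ensemble rhythms).  A vehicle event (dose 0) is a strict no-op.
No transient relaxation is modelled: the net shift is applied at the event,
which matches how shifts are measured (extrapolated peak-time differences);
an acute-transient toggle was considered and left out because the estimator
skips the post-treatment transient window anyway.

### Packaged calibrations

One file per peptide under `circaluc/configs/`:

| peptide | PRC (a0, a1, b1, a2, b2) h | EC50 (nM) | n | meaning |
|---|---|---|---|---|
| OXM | (−2.5, 0, 4, 0, −1.5) | 5 | 1.5 | max delay −8 h at 180°, 0 at 0°, −1 h at 270° |
| GCG | OXM × 3/8 | 60 | 1.5 | max delay −3 h, only at high doses |
| GLP-1, GLP-2, GRPP | 0 | — | — | no resetting |
| DEX | (0, 0, 0, −2.5, 0) | 1000 | 1 | biphasic: delays 0–90°, advances 100–180°, ~0 at 270° |
| PBS | 0 | — | — | vehicle |

The Hill parameters place 450 nM at ≥ 95 % of Emax and 0.5 nM at ≤ 15 % for
the active peptides.  Cohort generators treat each simulated slice once,
inside a requested phase window (computed exactly from the generator's own
oscillator state), with per-slice jitter of the initial peak time (±2 h).
Packaged cohorts use 8-day recordings (192 h; 204 h for full-cycle PRC
cohorts) so that, after all window exclusions below, two full cycles remain
on each side of the latest possible treatment.

## Degree convention and phase formula

The ascending zero crossing of the oscillation is 0°/360°, the peak 90°, the
descending crossing 180°, the trough 270°.  A treatment at T_p with preceding
fitted peak P_bt and period τ sits at

    φ = ((T_p − P_bt)/τ)·360 + 90,   reduced mod 360 into [0, 360).

Both the raw (pre-reduction) and wrapped values are reported; the anchors
are φ = 90° for T_p = P_bt and a raw 360° (wrapped 0°) for
T_p = P_bt + 0.75·τ.  P_bt is taken from the pre-treatment sine-fit
extrapolation rather than raw extrema: the shift procedure is fit-based and
the fit is far more stable near the treatment time.

## Detrending and extrema

Detrending subtracts a centred running average of width 24 h (converted to an
odd sample count).  At the trace edges the centred window shrinks rather than
dropping samples, keeping the output on the input grid and the early cycles
usable; the cost is a known phase distortion within half a window of each
edge, which the estimator handles by trimming (below).  Troughs are local
minima of the median-smoothed detrended signal (default 2-h window) separated
by ≥ 12 h with prominence ≥ 20 % of the half peak-to-peak range, refined by
parabolic interpolation; peaks are defined as midpoints of consecutive
troughs, and the period as the mean of the first 2–3 inter-peak intervals
(3 when four peaks are available).

## Damped-sine fitting

`fit_sine` minimises least squares of A·e^(−λ(t−t₀))·cos(2π(t − t_peak)/τ)
over a window, with A > 0, λ ≥ 0 (λ = 0 recovers a plain sine; fits default
to the damped form since explant rhythms visibly damp), and τ bounded to a
plausibility band (default 16–32 h).  Initial values come from the
extrema-based period and the peak nearest the window centre; up to four
restarts perturb the initial period (±5, ±10 %) and peak (±τ/4).  Windows
shorter than ~2 cycles of the initial period estimate (with 5 % slack for
estimation noise) are rejected; non-convergence or residual RMS above 80 %
of the amplitude flags the fit rather than failing.  The reference peak is
re-indexed to the fitted peak nearest the window centre to keep it
well-identified.

## Phase-shift estimation

For a trace with one treatment event:

1. detrend with the 24-h running average;
2. fit the pre-treatment window, from half a detrend window after the trace
   start to half a window before the event;
3. find the first detected trough at least half a window after the event and
   fit the post-treatment window from there to half a window before the
   trace end;
4. the shift is (pre-fit extrapolated peak nearest the first post-treatment
   fitted peak) − (that post-treatment peak), wrapped into (−τ/2, τ/2]; a
   later observed peak therefore gives a negative value (delay).

The half-window exclusions exist because the running average straddles both
the trace edges and the treatment discontinuity, distorting the detrended
phase within ±12 h of each; fitting through those regions biased recovered
shifts by up to an hour, while with the exclusions the zero-noise round trip
recovers injected shifts to < 0.05 h and the period to < 0.1 %.  Starting
the post window at a trough additionally skips the acute induction transient
that follows a real treatment.  Nearest-cycle wrapping is unambiguous for
the ≤ 8-h effects considered here; shifts approaching τ/2 would alias and
are reported wrapped.

## PRC regression and dose-response statistics

The phase-response curve is ordinary least squares of individual per-slice
shifts on {1, sin φ, cos φ, sin 2φ, cos 2φ} (unweighted: each slice is one
observation), requiring ≥ 8 points spanning ≥ 3 quadrants.  Predictions are
tabulated on a 1° grid; the extremum is the grid argmin (ties → smallest
phase).  A model whose predictions span < 0.5 h is reported "flat" — well
below the smallest real effect modelled (3 h) but above the fitting noise of
a null cohort of ≥ 16 slices.

Dose-response tables report mean ± SEM per peptide × dose with a one-way
ANOVA across all dose groups plus vehicle, and pairwise comparisons of each
dose against vehicle using the pooled within-group mean square (t statistic
on the ANOVA residual df) with Bonferroni correction over the number of
doses, capped at 1; stars at p < 0.05/0.01/0.001.  All groups identical is
reported as F = 0.  Mann–Whitney (two-sided) serves simple two-group
comparisons; the two-way ANOVA helper (statsmodels OLS + anova_lm, type II)
adds per-block Bonferroni post-tests in the same pooled-t style.

## qPCR quantification

Relative expression is the efficiency-corrected ratio

    R = E_t^(Cq_cal,t − Cq_s,t) / E_r^(Cq_cal,r − Cq_s,r)

with per-primer efficiencies E ∈ (1, 2] (default 2.0, the classic ΔΔCq) and
technical replicates collapsed by mean Cq before ratios.  Circadian profiles
are normalised by the grand mean over all timepoints (profile mean = 1);
induction time courses by the mean of the untreated 0-min group.  Both are
scale-invariant.  The synthetic Cq generator inverts this exactly
(Cq = base − log_E fold), so the noiseless round trip is an identity test of
the quantification.

## What the synthetic data does and does not show

The generator emulates the features the pipeline must be robust to: baseline
decay, amplitude damping, additive Gaussian noise, phase- and dose-dependent
instantaneous resetting, per-slice phase jitter.  It does not emulate
multiplicative/shot noise, slow period drift, inter-slice period variance,
acute bioluminescence transients after medium changes, or desynchrony-driven
waveform distortion.  Passing tests therefore demonstrate the correctness of
the algorithms and their noise robustness under the stated model, not
performance on arbitrary real recordings; parameters most likely to need
retuning on real data are the trough prominence threshold, the smoothing
window, and the fit plausibility band.

## Numerical and design choices

- Times are float hours since recording start; phases degrees in [0, 360);
  shifts hours with delays negative throughout.
- The sampling default is 10 min (typical luminometer cadence) and the
  generic trace duration default 120 h; packaged cohorts are longer (above).
- Pipeline runs derive all per-trace seeds from one root seed
  (`numpy.random.SeedSequence.spawn`), making every output byte-identical
  for a fixed (config, seed); summary floats are rounded to 6 decimals to
  keep the JSON stable.
- Degenerate inputs fail loudly: constant traces raise "insufficient
  cycles", rank-deficient PRC designs and missing vehicle/reference/0-min
  groups are errors, vehicle rows carry no test statistics.
- The acceptance script scales the stochastic checks to desk size — n = 5
  per dose for the dose cohorts and 48 phase-spread slices for the PRC —
  the same sizes as the packaged experimental design.
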
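# Methods

This note documents the models, estimators and design choices behind
`fretkin`, in the spirit of a methods section: what is assumed, what the
tunable parameters mean, and what the synthetic-data validation does and
does not demonstrate.

## Generative model

A trace alternates between *unbound* and *bound* intervals in continuous
time:

- bound dwells are `Exponential(k_off)`;
- unbound waits are the two-component mixture
  `frac_fast·Exp(k_on_fast) + (1−frac_fast)·Exp(k_on_slow)`, modelling a
  fast population binding from nearby and a slow population limited by
  arrival at the substrate (pseudo-first-order rates at fixed protein
  concentration). The mixture weight is not reported for the system the
  defaults emulate; 0.5 is used throughout, which makes both
  components identifiable at realistic event counts.
- During a bound interval the complex switches among discrete FRET
  states by a continuous-time Markov chain (`ctmc_rates`, off-diagonal
  rates in s⁻¹; Gillespie simulation). The initial state is drawn from
  the chain's stationary distribution — binding events are observed
  mid-equilibrium — with a uniform option (`initial_state="uniform"`).
- A per-trace Bernoulli flag (`p_dynamic`) decides whether bound
  intervals switch states at all; static traces hold a single state.

Rendering integrates the piecewise-constant FRET signal over each 80 ms
frame (a camera integrates photons, so a sub-frame switch produces one
intermediate frame), maps the frame-averaged efficiency `Ē` to noiseless
channels `I_D = T(1−Ē)`, `I_A = T·Ē` with `T = total_intensity`, adds
`leakage·I_D` to the acceptor (default 10%), then adds i.i.d. Gaussian
noise per channel and clips at zero. Unbound frames emit donor-only
signal (`unbound_fret_mean = 0`). With `noise_sd = 70` on `T = 1000` the
per-frame FRET scatter is ≈ 0.05, typical of EMCCD traces at this frame
time. Photobleaching, blinking, Poisson shot noise and baseline drift
are deliberately not modelled.

**Conditioning of dynamic intervals.** With a plain Markov chain, a
fraction of nominally dynamic bound intervals would contain no state
change (no jump falls inside the dwell) or only changes too fast to
resolve, so the generated dynamic fraction would not mean what per-event
classification measures. Intervals flagged dynamic are therefore
conditioned — truncated first holding time plus rejection sampling — on
containing at least one switch of ≥ 0.1 FRET whose flanking sojourns
both last at least two frame times, the shortest level a camera at this
frame time can register as a distinct segment. Intervals too short to
satisfy this (shorter than ~4 frames) keep their last draw and are, in
effect, unclassifiable; they are the dominant source of residual
classification misses. The unconditioned process is available
(`ensure_dynamic_switch=False`, or `require_jump=False` on
`simulate_state_path`) and is what the occupancy and dwell-law tests
exercise.

## Trace processing

Leakage is corrected as `acceptor − leakage·donor`, floored at zero —
the exact inverse of the simulator's leakage step — and recorded in the
trace provenance; `compute_fret` warns when the record is missing.
Frames with zero total intensity become NaN and stay NaN through
smoothing (excluded from window means, never interpolated). The
seven-point moving average uses shrinking centered windows at the trace
edges (the first frame averages frames 1–4) so dwell boundaries are not
truncated. Smoothing is applied when building FRET histograms; event
detection, HMM fitting and classification all run on unsmoothed FRET,
because a 7-frame average correlates noise across frames, fills short
unbound gaps (biasing `k_off` downward), and blurs genuine sub-second
transitions. Histograms default to 40 bins on [0, 1] and are summarized
by a bounded single-Gaussian least-squares fit initialized from the
histogram moments; a failed fit leaves the summary empty with a warning.

## Event detection and dwell-time kinetics

Bound events are maximal runs of frames with `E ≥ threshold` lasting at
least `min_frames`; interior gaps shorter than `min_frames` are merged
first (debounce). Defaults: `threshold = 0.25`, halfway between the
leakage-corrected unbound baseline and the lowest bound state, and
`min_frames = 2` (160 ms) to suppress single-frame noise spikes.
Intervals touching the trace boundaries are flagged censored and
excluded from dwell sets by default (their true length is unknown); an
inclusion flag exists for sensitivity analysis.

The empirical survival `S(t) = #(duration > t)/n` on the frame grid is
the fit target for both models, with the amplitude left free (the first
grid point already reflects frame quantization). Three standard
adjustments condition the curve for nonlinear least squares:

1. the flat `S = 1` head is dropped — below the detection dead time it
   only encodes that no dwell shorter than `min_frames` can be observed,
   and forcing the model through it biases the fast rate (by
   memorylessness, the remaining curve is still a mixture of the same
   exponentials with rescaled amplitudes);
2. dense curves are subsampled onto a log-spaced time grid (60 points
   for the double fit, 200 for the single), so the long, highly
   redundant slow tail does not dominate the residuals;
3. when the dwell count is known, points are weighted by the binomial
   standard error of `S(t)` with a continuity correction.

The double-exponential fit is multi-started over a small ladder of rate
initializations (fast start at least 10× the slow start) and reports
components fast-first; if the rates collapse within 5% or an amplitude
vanishes, it falls back to the single model with a warning and a flag.
Per-dataset fits at ~100 events scatter by 10–20% with a right skew, so
the recovery harness pools dwells across seeded replicates and fits the
pooled survival curve once, rather than averaging per-replicate
estimates. Frame quantization and the 2-frame dead time leave a small
downward bias in `k_off` (≈ 5% at `k_off·frame_time = 0.016`); recovery
tests assert 15% accuracy for all rates with `k·frame_time ≤ 0.03`.

The bound dwells determine `k_off` and the unbound waits determine the
on-rates — the physically standard mapping, which also matches the
magnitudes the defaults emulate.

## HMM idealization and transition density plots

Events longer than 60 s (strict) are pooled, frames outside FRET
0.05–1.0 dropped, and a shared Gaussian-emission HMM (free per-state
variance) is fit by Baum–Welch with `hmmlearn` as the EM engine:
means initialized evenly over the analysis range and jittered per
restart, 0.9 self-transition, uniform initial vector, five restarts,
convergence at 10⁻⁶ log-likelihood gain per frame or 500 iterations.
Restarts that starve a state (expected occupancy under one frame) are
discarded; exhausting all restarts raises with a suggestion to reduce
the state count. States are relabeled so means ascend. Model selection
is out of scope: the state count is a parameter (default five).

Viterbi decoding returns the most likely state path and its log
probability; the test suite checks it against exhaustive path
enumeration on small instances, and EM monotonicity against the full
log-likelihood history.

TDPs histogram (initial, final) state-mean FRET pairs — one pair per
state change, none for self-persistence — on a 50×50 grid over [0, 1]²,
then smooth with a Gaussian kernel (bandwidth 0.02 FRET) using reflected
boundaries, which conserves total mass exactly; raw counts are kept
alongside. The symmetry score `1 − (½Σ|D−Dᵀ|)/(2ΣD)` is the fraction of
transition mass with a matching reverse transition: 1 for a perfectly
reversible system, 0.5 when no transition has a reverse partner.

## Static/dynamic classification

The published criterion — a FRET change ≥ 0.1 lasting ≥ 50 ms — is
implemented as maximum-likelihood change-point segmentation, since the
original analysis used an unpublished script: recursive binary splitting
under a constant-mean Gaussian model with profiled variance, a split
accepted when `n·log(RSS₀/RSS₁) > 2·log n` (BIC with one extra mean and
one change-point location). Candidate segments keep at least two frames
on each side of a split for events of ≥ 7 frames — one-frame provisional
segments carry no variance information and would turn single noise
outliers into spurious splits — while shorter events fall back to
single-frame splits, where the subsequent merging makes the test reduce
to the direct FRET-change criterion. After splitting, adjacent segments
closer than 0.1 FRET are merged (smallest difference first), then
segments shorter than the duration criterion are merged into the
neighbor with the closer mean. At 80 ms frames the 50 ms duration
criterion is satisfied by any one-frame segment; the parameter matters
at faster frame rates.

Classification runs on unsmoothed FRET inside each detected event, with
one frame trimmed from each end of events long enough to afford it: the
camera integrates over the frame, so the first and last frame of an
event average bound and unbound signal and would register as a spurious
FRET change. An event is dynamic iff it has ≥ 2 segments, a sustained
inter-segment change ≥ 0.1, and every segment at least 50 ms. On
pure-static noisy events at FRET noise 0.05 the false-dynamic rate is
≈ 2–4% (calibration test asserts ≤ 5%). Population summaries report the
dynamic fraction with an exact (Clopper–Pearson) 95% CI.

Resolution limits: events shorter than ~4 frames cannot exhibit a
classifiable change, and switches with a sub-frame sojourn on one side
are attenuated by frame averaging. At the default conditions this
leaves the recovered dynamic percentage a few points below the generated
one at the ~50% level (e.g. ≈ 45% recovered for 49% generated), within
the binomial CI of the generating fraction at ~100 events — which is
also the criterion the acceptance checks apply.

## Named condition presets and recovery experiments

`fretkin.presets` fixes one generative configuration per experimental
condition: the published `k_on,fast / k_on,slow / k_off` triples and
event counts N for wild-type and exonuclease-deficient mutant on each
primer-terminus substrate, and the two dynamic-fraction conditions
(49% of 100 events wild-type, 21% of 96 mutant, off-rate 0.30 s⁻¹).
Kinetics presets place the bound states at 0.4–0.7 FRET, the band where
the transition density is highest, keeping every bound state well above
the detection threshold; dynamic-fraction presets use two states at
0.40/0.65 (separation 0.25) with symmetric 0.7 s⁻¹ exchange. For the
double-mismatch rows whose on-rates were not determined, typical
wild-type values (0.6 / 0.02 s⁻¹) generate the waiting times and only
the off-rate is a recovery target.

Recovery experiments (`fretkin.recovery`, `scripts/acceptance.py`)
simulate ten seeded replicates per condition at the condition's N,
run the full pipeline, and report pooled-survival rate estimates and
mean dynamic percentages. Problem sizes (N ≈ 100 events per replicate,
ten replicates) mirror the per-condition event counts of the emulated
study; a full acceptance run completes in well under a minute on one
CPU.

## What passing tests do and do not show

The simulator reproduces the statistical structure the analysis assumes
— exponential dwell mixtures, Markovian state exchange, Gaussian
detector noise, linear leakage — so recovery tests validate estimator
correctness, identifiability at realistic event counts, and the
advertised tolerances. They do not probe non-idealities of real
recordings: photophysics (bleaching, blinking), baseline drift,
non-Markovian conformational memory, heterogeneity between molecules,
or mis-specified leakage. Conclusions about real data rest on the same
assumptions the field's standard pipelines make.
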
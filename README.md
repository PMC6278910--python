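# fretkin

Kinetics and conformational dynamics from single-molecule FRET binding
trajectories.

`fretkin` is a Python library for analyzing camera-based smFRET
recordings of a protein binding reversibly to a surface-immobilized,
donor-labelled DNA substrate — the assay used to study how the *E. coli*
replicative polymerase (Pol III core, with its β₂ sliding clamp)
explores polymerase and exonuclease conformations while bound at a
primer/template junction. Because such recordings are rarely deposited,
the package pairs every estimator with a trajectory simulator that has
full ground truth, so the whole analysis chain can be validated by
parameter recovery.

## What it computes

Given per-frame donor/acceptor intensities `I_D`, `I_A` (80 ms frames by
default):

- **Apparent FRET**: `E = I_A / (I_D + I_A)` after subtracting 10%
  donor→acceptor spectral leakage; optional seven-point moving average;
  pooled FRET histograms summarized by a Gaussian center `X₀` and width
  `σ`.
- **Binding kinetics**: threshold-based event detection, then survival
  fits of the dwell times. Bound dwells follow `f(t) = A·exp(−k_off·t)`;
  waiting times between events follow
  `f(t) = A₁·exp(−k_on,fast·t) + A₂·exp(−k_on,slow·t)`
  (pseudo-first-order rates at fixed protein concentration).
- **HMM idealization**: binding events longer than 60 s are pooled and
  fit with a shared Gaussian-emission hidden Markov model (five states
  by default, FRET restricted to 0.05–1.0), then Viterbi-decoded.
- **Transition density plots**: 2-D histograms of (FRET before, FRET
  after) over all idealized state changes, with a transposition-symmetry
  score that quantifies reversibility.
- **Static/dynamic classification**: each binding event is labelled
  dynamic when it contains a FRET change ≥ 0.1 sustained for ≥ 50 ms,
  implemented as BIC-penalized Gaussian change-point segmentation;
  population fractions come with exact binomial confidence intervals.
- **Simulation**: continuous-time generative model (exponential bound
  dwells, biexponential unbound waits, Markov switching between FRET
  states during binding, frame-integrated rendering, leakage, Gaussian
  detector noise) with a `GroundTruth` record per trace.

## Worked example

`examples/03_dwell_kinetics.py` simulates one wild-type condition
(104 binding events at `k_off = 0.20 s⁻¹`, `k_on,fast = 0.8 s⁻¹`,
`k_on,slow = 0.030 s⁻¹`), runs the detection and fitting chain, and
prints:

```
uncensored dwells:  97 bound, 86 unbound
k_off      = 0.218 s^-1   (generated 0.20)
k_on,fast  = 0.880 s^-1   (generated 0.80)
k_on,slow  = 0.0268 s^-1  (generated 0.030)
```

A single ~100-event dataset recovers the generating rates to within
10–20%, the statistical resolution of one experimental condition;
pooling seeded replicates (see `fretkin.recovery`) tightens this to a
few percent. The other scripts in `examples/` walk through simulation,
FRET histograms, HMM + TDP analysis and static/dynamic classification
the same way.

A thin CLI mirrors the library
(`fretkin simulate|process|kinetics|hmm|tdp|classify|run|recover`), e.g.

```bash
fretkin recover --preset wt-gddc --seed 1
```

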
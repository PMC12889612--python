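# Methods

`swimstate` simulates and analyzes a closed-loop virtual-reality paradigm for
larval zebrafish in which repeated *futile* swimming induces a disengaged
internal state, and quantifies how that state reshapes the brainwide
transformation from visual input to motor output. Everything the analysis
chain consumes is produced by the package's own generative model, so every
analysis can be validated against ground truth.

## The paradigm

The stimulus is whole-field forward motion whose velocity obeys the
closed-loop rule

    v_stim = v_flow − m · G_ms

with `v_flow` the experimenter-imposed flow, `m` the fictive swim vigor
decoded from a ventral-root-like recording and `G_ms` the motosensory gain.
Trials alternate between two types:

* **Effective** — the Evoke epoch runs in closed loop (`G_ms > 0`); swimming
  produces visual feedback and the fish stays *Engaged*.
* **Futile** — the Evoke epoch is open loop (`G_ms = 0`); swimming has no
  visual consequence, the fish eventually gives up (*Disengaged*), and five
  seconds of detected quiescence trigger the next epoch.

A Pause epoch (`v_flow = 0`) lasts 8 s on Effective trials and 3 s on Futile
trials, so that pre-Probe quiescence is 8 s on both. The Probe epoch then
presents 1 s forward-motion pulses alternating with 1 s gaps (pulse speed =
Evoke flow / 2.5) until the fish responds or 60 s elapse. The latency from
Probe onset to the probe-evoked swim is the behavioral readout.

## The latent internal state

A scalar state `s ∈ [0, 1]` is a leaky integrator of futile vigor:
`s ← s·exp(−dt/τ_a) + k·m·dt` while swimming in open loop, with slow passive
decay (`τ_a = 150 s`) during quiescence. Two additional transitions shape
its dynamics:

* **Active clearing.** Effective (closed-loop) swimming clears the state with
  a fast time constant (`τ_clear = 3 s`), mirroring the return of the
  astrocytic proxy signal to baseline once the animal is engaged again. This
  is what resets the state between trials.
* **Stochastic resolution.** During Probe quiescence the state spontaneously
  resolves after a random delay (10 s + Exponential(12 s)), collapsing with
  `τ_res = 3 s`. Resolution precedes the behavioral response: the neural
  state difference between trial types shrinks toward the moment of the
  probe-evoked swim, and response amplitudes grow progressively beforehand.

Passivity begins when `s` crosses a threshold (0.72). Two manipulation modes
emulate loss and gain of function of the astrocytic state signal: `calex`
clamps `s ≡ 0` (calcium extrusion), `trpv1` forces `s` high during the second
half of a session regardless of behavior (chemogenetic activation; all trials
then run in closed loop, so suppression occurs without futile swimming).

The behaving agent decides when to swim during Probe by accumulating the
stimulus with a state-dependent memory, `dE/dt = −E/τ(s) + v_stim` plus
diffusion noise, where `τ(s)` interpolates linearly from 11.2 s (engaged) to
5.9 s (disengaged); a swim is emitted when `E` crosses a per-trial log-normal
bound. Bound (21.0), evidence noise (2.0 mm·s^-1/2) and resolution timing
were calibrated once so that default latencies bracket the reference values
of 21.8 s (Effective) and 31.5 s (Futile); the calibration is part of the
generator's definition and is not revisited per analysis.

## The neural population model

ΔF/F traces are built per cell class from a latent rate on the 0.1 s behavior
grid, convolved with a fast calcium-indicator kernel (difference of
exponentials, 50 ms rise, 500 ms decay, unit DC gain), averaged into imaging
frames (3 Hz default) and corrupted with Gaussian noise (σ = 0.05).

The stimulus drive shared by all sensory classes is `v_stim` rectified,
**saturated** at the Probe-pulse height (response to whole-field motion
saturates with speed) and passed through an **adaptation** stage with
asymmetric kinetics (depletion τ = 4 s while the stimulus is on, recovery
τ = 1 s while off, depth 0.9). Sustained Evoke flow is thereby reduced to an
onset transient while the sparse Probe pulses remain nearly fully effective —
without this, the accumulated Evoke residual swamps the pulse responses and,
because Futile trials carry ~5 s of extra motion exposure inside the
passivity-detection window, produces a spurious state difference even when
the latent state is clamped.

Classes (defaults for a 200-cell population):

| class | n | latent rate |
|---|---|---|
| sensory-positive | 22 | `drive · (1 − 0.17·s) · amp(t)` |
| sensory-negative | 6 | baseline − dips `· (1 − 0.82·s)` |
| integrator | 22 | `0.2·sensory + 2·I/τ_eng · (1 − 0.87·s)`, `dI/dt = −I/τ(s) + drive` |
| motor-preparatory | 8 | linear ramp over 3 s before each swim onset |
| motor-related | 30 | ∝ vigor |
| anti-motor (L-MO-like) | 12 | baseline + slow oscillation − 2·vigor − unreliable pulse dips `· (1 − s)` |
| noise | 100 | 0 |

`amp(t)` is a recovery-linked gain `1 + 0.8·exp(−(t_swim − t)/5 s)` applied
inside the Probe epoch before the probe-evoked swim: visual responses are
amplified progressively in the lead-up to behavioral recovery on both trial
types. The suppression depths (17%, 82%, 87%) and the time-constant pair
(11.2 s / 5.9 s) are the study's reported effect sizes and serve as the
generator's effect-size parameters. The integrator carries a small fast
component because sensory-integration neurons are a subclass of the
sensory-encoding population; it also keeps the two-component trace
identifiable for the single-τ fit (the disengaged trace collapses onto the
fast component, the engaged trace onto the slow one).

Region labels serve as a coarse stand-in for a brain map: the combined
sensory pool is distributed over six regions with integrator fractions
rising from 0.10 (tectal neuropil) to 0.80 (inferior olive), so the
across-region link between modulation depth and integrator prevalence is an
emergent property, not an annotation.

The ephys forward model renders each bout as a 60 Hz amplitude-modulated
burst (RMS ∝ vigor) in Gaussian noise. 6 kHz matches the recording hardware
convention; all algorithms take the rate as a parameter and the test suite
runs at 1 kHz.

## Analysis chain

1. **Swim detection.** Vigor is the sliding 10 ms standard deviation of the
   raw trace. The envelope `x = sqrt(((y − y*ker1)²)*ker2)` uses unit-area
   Gaussian kernels (σ = 100 ms and 20 ms, truncated at ±4σ; boxcar
   available), with edge-normalized convolution so a constant trace maps to
   zero everywhere. The automatic threshold is `x_max + c·|x_min − x_max|`
   (`c = 1.8` by default) where `x_max` is the histogram mode
   (Freedman–Diaconis widths, floor of 200 bins, ties toward smaller x) and
   `x_min` the upper edge of the mode's contiguous density lobe at 1% of the
   mode density. Two deliberate robustness choices: the absolute value fixes
   the sign of the spread term, and stopping at the first density gap keeps a
   dense burst lobe from dragging the threshold above the bursts themselves.
   Supra-threshold runs closer than 200 ms are merged and runs shorter than
   50 ms dropped (post-hoc rules, exposed in config).
2. **Trial structuring.** Epoch boundaries come from the stimulus log;
   labels follow the swim pattern during Evoke. Engaged: continuous
   closed-loop swimming (inter-swim interval ≤ 3 s) to the Evoke end
   (variant rule 3.3 s available). Disengaged: terminal no-swim gap of at
   least the passivity window minus a 0.5 s tolerance for detector smearing
   (the online detector produces gaps of exactly the window length).
   Perseverant: open-loop swimming through to the transition. Latency is
   measured from Probe onset (boundary inclusive) and censored at the cap.
3. **Cell classification.** Spearman rank correlations with exact
   permutation p-values for n ≤ 7 and the t-approximation otherwise.
   Sensory cells: correlation with the stimulus over the first six Probe
   pulses of non-swimming trials; the pipeline supplies an
   indicator-convolved stimulus regressor because slow cells' pulse-locked
   ripple lags the raw pulse train by the indicator decay. Motor cells:
   correlation with vigor at m > 0 frames of open-loop Evoke. Preparatory
   cells: rank correlation of pre-swim samples with elapsed time toward the
   swim in all of the 3–7 s windows, requiring ρ > 0, p < 0.05 and the top
   5% of cells per window (conjunctive rule; both thresholds configurable).
4. **Integration metrics.** The leaky-integration model
   `ΔF/F(t) = β ∫ v_flow(t−t′) e^(−t′/τ) dt′` is fit over the first six
   Probe pulses with β solved in closed form per τ on a 64-point log grid
   (0.1–100 s) plus golden-section refinement; the discrete integral uses
   exact exponential-hold updates so the recovery oracle is exact. The
   session-level fits use the Probe-epoch pulse series with a 2 s pre-Probe
   baseline. Indicator kinetics are deliberately ignored (0.5 s ≪ every τ of
   interest). Inverse leakiness is the sixth-pulse OFF endpoint over the
   perfect-integrator sum of incremental ON responses. Per-pulse response
   areas are trapezoids over one pulse period measured against the
   *pre-pulse* value (the incremental, fast component); pulse-integration
   areas remove the first-pulse template before integrating the residual.
5. **State modulation.** d′ between Engaged and Disengaged per-pulse areas;
   modulation duration is the first pulse from which rank-sum
   indistinguishability is sustained through all later pulses (the sustained
   rule avoids flicker); prevalence is the percent of cells with rank-sum
   p < 0.05 at a paradigm-aligned time. Rank-sum p-values are exact for
   combined n ≤ 20 without ties. The across-fish comparison is a two-way
   fixed-effects ANOVA (fish, trial type, interaction). No multiple-testing
   correction is applied at the cell level.
6. **Recovery analyses.** Dual alignment copies fixed-length segments at
   Probe onset and at the last pulse before the probe-evoked swim and
   linearly resamples the middle to 20 scaled-time-unit bins (trials with
   latency < 20 s are excluded so segments cannot overlap). Progressive
   amplification is the mean ± SEM pulse area versus pulse index relative to
   the swim. The latency decoder is a gradient-boosted regression ensemble
   (host library defaults) trained per condition on a seeded stratified
   half-split of trials, with features restricted to behavior-predictive
   cells (pulse response anticorrelated with the latency remaining from that
   pulse, ρ < 0, p < 0.05).

## Problem sizes and numerics

Default study conditions are 5 fish × 20 trials × 200 cells at 3 Hz imaging;
the decoder analysis uses an 80-trial session so each condition retains
enough training trials for the ensemble. The test suite simulates ephys at
1 kHz. All randomness flows from one session seed through named substreams
(behavior, ephys noise, calcium noise), so equal seeds give bitwise-equal
sessions. Degenerate inputs have defined outcomes rather than exceptions
where a sentinel is meaningful: constant traces give ρ = 0 with p = 1, a
non-positive perfect-integrator denominator gives NaN leakiness, a zero
trace gives β = 0 with undefined τ.

## What the generator does and does not emulate

It reproduces the statistical structure the analyses rely on: closed-loop
kinematics, the equalized pre-Probe quiescence, state-dependent integration
and suppression with the reported effect sizes, resolution-linked recovery
dynamics, and loss/gain-of-function controls. It does not emulate imaging
physics (point-spread, motion artifacts), spatial anatomy beyond coarse
region labels, spike-to-calcium nonlinearities, neuromodulator dynamics, or
across-fish heterogeneity beyond independent seeds. Passing tests therefore
demonstrate correctness of the analysis algorithms and internal consistency
of the model — not that real recordings satisfy the model's assumptions.

Known limitations: the calcium-extrusion control retains a small positive
median d′ (≈ 0.05–0.15) because Futile trials carry extra motion exposure
during the passivity-detection window and the first Probe pulses inherit a
slightly different adaptation state; the paradigm itself creates this
asymmetry and the adaptation stage only suppresses most of it. The fitted
disengaged time constants are compressed toward the fast component of the
mixed integrator trace, so the engaged/disengaged fitted-τ contrast is
directional rather than quantitative.
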
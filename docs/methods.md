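# Methods

`iemg` quantifies the signal quality of chronically implanted EMG
electrodes (epimysial vs intramuscular) along four axes: electrical
impedance, movement-vs-rest SNR, feature-space separability and
repeatability, and each electrode's contribution to separability. This
note records the models, the parameter choices that matter, and the
numerical decisions, so results are interpretable and reproducible.

## Impedance

A sinusoidal test current of known amplitude (38.4 nA at 1 kHz, 19.2 nA
at 500 Hz by default) is injected between every pair of connectors
(each electrode plus the common reference) and the voltage amplitude is
measured. Impedance magnitude is the pairwise Ohm's-law reading
|Z| = V/I — no resistive-network correction is applied, and phase is out
of scope. Pairs containing the reference give *direct* impedance; pairs
of electrodes give *cross-channel* impedance. The isolation summary is
the cross/direct ratio.

Decisions:

* **Ratio pairing.** Nothing singles out one of a pair's two direct
  impedances as the denominator, so both ordered ratios
  cross{i,j}/direct{i} and cross{i,j}/direct{j} are emitted and
  summaries pool all ordered ratios. Per-electrode and per-pair views of
  the same data are both derivable from the ordered-ratio dict.
* **Open circuits.** `OPEN` is a dedicated sentinel, not IEEE infinity:
  it sorts above every finite value, serializes as the literal string
  `"OPEN"`, and survives quantile summaries (a quantile that lands on or
  interpolates toward an OPEN order statistic is OPEN). A measured open
  circuit is distinct from a missing measurement, which is simply absent
  and reported by `ImpedanceMatrix.missing_pairs`.
* **Quantiles** use linear interpolation between order statistics
  ("type 7"), quartiles at 0.25/0.75 — one fixed, documented rule.
* **Duplicate log rows** for the same (participant, frequency, pair) are
  an error rather than averaged; averaging could mask instrument faults.
* An OPEN *direct* impedance together with a finite cross-channel path
  is physically suspect (no path to ground but a path to a neighbour);
  the ratio is reported as 0 and the pair flagged anomalous.

## SNR

Per electrode and movement class,
`SNR_dB = 10·log10(RMS_movement² / RMS_rest²)`. Steady-state signal is
isolated by trimming a fixed fraction (default 0.25) of each contraction
interval from both ends — a seed-independent, testable stand-in for
manual steady-state selection. The rest reference is the pooled RMS over
all rest intervals (one noise floor per electrode, since movement
epochs are not paired with specific rest epochs). A movement counts as
*viable* for an electrode when its annotations supply at least one
analysis window (200 ms) of steady-state signal. Per electrode the
maximum SNR is reported separately over the gross-movement and
finger-movement groups.

## Features, separability, repeatability

EMG is segmented into 200 ms windows advanced by 50 ms, each annotated
interval windowed independently (windows never straddle a class
boundary, preventing label leakage; trailing partial windows are
dropped, giving `floor((N−W)/inc)+1` windows per interval). Four
time-domain features per channel and window: mean absolute value,
slope sign changes, zero crossings, waveform length — the canonical
definitions of the Hudgins time-domain set, with a zero-crossing /
slope-sign deadband threshold defaulting to 0 (assumption-free).

Between two classes i, j the directed half-Mahalanobis statistics are
`dist_ji = ½(μi−μj)ᵀ Si⁻¹ (μi−μj)` and symmetrically with Sj. The plain
quadratic form is used (not its square root); a `sqrt_distance` switch
provides the root form for comparability, since "half the Mahalanobis
distance" is ambiguous between the metric and its square. The two
directions combine as `a·b/(a+b)` — half the harmonic mean, bounded by
min(a, b).

* **IDNN** (separability) for movement i is the minimum combined term
  over all other movements: a class is only as separable as its nearest
  confusable neighbour. Higher is better.
* **WD** (repeatability) applies the same combined term between
  repetitions of one movement and averages over all unordered repetition
  pairs, making the value independent of an arbitrary reference
  repetition. Lower is better.
* **Leave-one-electrode-out** recomputes either statistic with all
  feature columns except the electrode of interest; the change relative
  to the full set is that electrode's contribution.

Numerics: covariances are inverted via Cholesky. When (and only when)
the sample covariance is not positive definite — common when a short
repetition yields fewer windows than feature dimensions — it is shrunk
toward its diagonal, `(1−λ)S + λ·diag(S)` with λ = 1e−3, escalating to a
ridge `λ·mean(diag)·I` when the diagonal itself is degenerate.
Regularizing only on failure keeps IDNN and WD exactly invariant under
invertible affine maps of the feature space whenever covariances are
well conditioned (a Mahalanobis property the test suite checks at 1e−8
relative). Coincident classes give a combined term of 0 by convention.

## Sequential forward selection

Set separability of an electrode subset is the unweighted mean of
per-movement IDNN over the subset's columns (median and min are
available; the mean is the symmetric default since no aggregation rule
is canonical). The ranking is greedy: start from the best single
electrode, repeatedly add the electrode yielding the highest new value.
Ties break toward the lowest electrode index so rankings are
deterministic. Monotone improvement is *not* assumed — under regularized
covariances adding an electrode can lower mean IDNN, and the greedy step
takes the best candidate regardless of the sign of the change. A
separately coded brute-force transcription (`greedy_oracle`, ≤ 8
electrodes) cross-checks the implementation. Gross-hand and finger
movements are analyzed as disjoint class sets per run.

## Group statistics

Electrode types are compared with the two-sided Wilcoxon rank-sum test.
For pooled sizes up to 12 the permutation distribution of the rank-sum
statistic is enumerated over all group assignments of the pooled
midranks — exact even under ties; larger samples use the normal
approximation with tie correction and a 0.5 continuity correction.
The rank-sum test is an unpaired test and is applied as such. OPEN
values enter rank tests as the largest ranks (rank statistics need only
ordinal structure). All comparisons within one report form a single
Holm-Bonferroni family — the conservative choice when no family is
prescribed — using the step-down adjustment
`adj(i) = max_{k≤i} min(1, (m−k+1)·p(k))`. Electrodes are pooled across
participants (each electrode is one observation); the report flags this
pooling explicitly. Metrics for which only one electrode type is present
(single-type cohorts) are summarized but not tested, and listed under
`skipped`.

## Synthetic cohorts

No public recordings of this kind exist, so the generator emulates the
study conditions:

* **Sources.** One muscle source per electrode: Gaussian noise band-pass
  filtered to 20–250 Hz (4th-order Butterworth, zero-phase; the upper
  edge is clipped to 0.45·fs at 500 Hz sampling), then normalized to
  unit RMS so the planted movement/rest amplitude ratio — and hence the
  planted SNR — is known in closed form.
* **Activation.** A trapezoidal envelope per contraction (linear ramps
  over 10% of the contraction at each end) gives distinct transient and
  steady-state phases. Cohort templates use a spread activation pattern
  (each movement drives a primary muscle at gain 1.0 plus two weaker
  synergists at 0.5 and 0.25) so every electrode sees activity in both
  movement groups, as muscles do across a real protocol; the one-hot
  pattern is available for controlled constructions.
* **Mixing and noise.** Channels observe a non-negative mixing of the
  sources plus i.i.d. Gaussian noise (default RMS 0.05 against unit-RMS
  sources, i.e. roughly 26 dB peak SNR, in the range reported for
  implanted recordings). The off-diagonal mixing mass is the crosstalk
  knob: epimysial rows use 0.35, intramuscular rows 0.10, encoding the
  better isolation expected of intramuscular electrodes.
* **Protocols.** Six gross movements (hand open/close, wrist
  flex/extend, pronate/supinate; plus elbow flex/extend for
  trans-humeral templates) and ten finger movements (flex/extend per
  digit), default 3 repetitions of 2 s contractions separated by 1 s
  rest, at the template's sampling rate (500/1000/2000 Hz).
* **Impedance scenes.** Direct and cross-channel values are independent
  planted parameters (no network solve — the analysis consumes pairwise
  Ohm's-law readings only): lognormal draws centred near 230 Ω
  (epimysial direct), 2 kΩ (intramuscular direct), with cross-channel
  paths two or more orders of magnitude higher and open-circuit
  probability 0.25 for intramuscular pairs, 0.10 mixed, 0 epimysial.
  `make_crosstalk_scene` couples cross impedance inversely to the mixing
  mass so one knob drives both the impedance ratio and downstream
  separability in sweeps.
* **Templates.** Six participant layouts mirror the cohort structure the
  analysis targets: two mixed-type participants (4 epimysial + 8
  intramuscular), three epimysial-only (8 electrodes, bipolar or mixed
  polarity) and one intramuscular-only (12), with TMR/RPNI construct
  tags carried as metadata.
* **Determinism.** One master seed; per-participant streams are derived
  through fixed-offset seed sequences, so cohorts are reproducible
  element-wise and byte-for-byte after serialization.

What the generator does **not** emulate: motor-unit physiology, volume
conduction, electrode geometry, non-stationary fatigue or electrode
drift, movement artifacts, or the inter-participant variability of real
muscles. The generator is deliberately not calibrated to any patient
data — absolute IDNN/WD magnitudes on synthetic cohorts are far larger
than on real recordings, whose classes overlap much more. Passing tests
therefore certify the *computations* (inversion identities, closed
forms, oracle equivalence, invariances, qualitative monotonicity), not
clinical magnitudes.

## Problem sizes

Default analysis-scale choices: property tests use 2–6 features, 2–5
classes and tens of windows per class; monotonicity sweeps use 4
channels, 3 movements × 2 repetitions of 1.2 s at 500 Hz over 20 seeds
per crosstalk level; the end-to-end report runs the full 12-electrode
mixed-type template (16 movements × 3 × 2 s at 500 Hz, ≈ 145 s of
signal). These sizes give stable medians while keeping a full run in
seconds.

## Known limitations

* The pairwise Ohm's-law reading ignores current leakage through third
  electrodes; a full conductance-network inversion is out of scope.
* Electrodes are pooled across participants in group tests, ignoring
  the nesting of electrodes within participants; a mixed-effects
  treatment is out of scope.
* WD's pairwise-mean aggregation is one documented choice among several
  reasonable normalizations of a within-class pairwise sum.
* With very few windows per repetition the regularized covariances make
  absolute WD values sensitive to λ; comparisons within one windowing
  configuration remain meaningful.
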
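# Methods

This note records the models, conventions and design choices behind
`ethoaccel`, in the order the pipeline runs.

## Data model

Timestamps are integers counting sample periods (seconds at the default
1 Hz). Sub-second timestamps in input files are truncated: both the
acceleration and the behaviour stream are coded at the sensor rate, so
behaviours shorter than one sample are unrepresentable by construction. A
*contiguous segment* is a maximal run with an inter-sample gap of exactly one
period; any other gap starts a new segment, and no transform or window ever
crosses a segment boundary. Acceleration units are carried opaquely (the
bundled scenarios behave like milli-g with |g| = 1000); every transform and
feature is unit-agnostic.

Labels come from a closed vocabulary of seven wild-boar behaviours plus
`Other`; `Unknown` is legal only as a placeholder in prediction mode.
Merging labels onto acceleration is an inner join on timestamps; records
dropped on either side are counted and logged.

## Signal transforms

**Jerk.** Per-axis first difference scaled by the sampling rate
(`scale_by_rate=True`, the default). At 1 Hz the scaled and unscaled
conventions coincide; the flag exists because the convention matters at
other rates. The jerk series of a segment is one sample shorter than the
segment; when raw and jerk channels are windowed together the first raw
sample of each segment is dropped so all channels align in one rectangular
block. Directional change is the angle between consecutive acceleration
vectors, computed as `atan2(|a×b|, a·b)` (stable near 0° and 180°) and
defined as 0 when either vector is null.

**ODBA.** Static component per axis = centred moving average over a 3-s
window, *shrinking symmetrically* at segment edges (half-width
`min(w//2, i, n−1−i)`), so a constant signal is reproduced exactly
everywhere and ODBA is strictly translation-invariant, including at edges.
Dynamic = raw − static; ODBA = Σ|dynamic| over axes. The smoothing window
must span an odd number of samples (3 at 1 Hz).

## Windows and labels

Windows of `W` seconds tile each segment from its start with stride
`step = max(1, round(W·(1−overlap)))` (overlap 0.5 by default); the terminal
remainder shorter than `W` is discarded. With the one-sample jerk alignment
a segment of L samples has N = L−1 usable samples and
`floor((N−W)/step)+1` windows. The window label is the modal behaviour of
its seconds, ties broken by earliest first occurrence — deterministic and
order-stable. Mixed windows are intended behaviour (they model the applied
situation where bout boundaries are unknown); `label_purity` records the
contamination so its effect can be studied directly.

## Features

Eleven statistics per channel — mean, median, sd, variance, skewness,
kurtosis, min, max, range, IQR, RMS. Conventions: sd/variance use the
sample (n−1) denominator; skewness and kurtosis the population (biased)
moment estimators, kurtosis *non-excess* (a Gaussian scores 3); both are
imputed as 0 for zero-variance windows so every feature is finite. IQR uses
linear interpolation between order statistics (configurable through the
NumPy quantile methods). The statistic set itself is replaceable
(`custom_stats`) for users who want a different summary family.

Spectral features are raw periodogram ordinates of the mean-centred window
at frequencies k/W, k = 1..⌊W/2⌋ — nothing exists above the Nyquist
frequency, the defining constraint at 1 Hz. The one-sided normalisation
satisfies Parseval (the ordinates sum to n·variance), and the full set of
ordinates is kept rather than a "top-k" selection, which would require an
arbitrary ranking rule. Column names are `<stat>_<channel>` /
`pow<freq>_<channel>` with channels x, y, z, xj, yj, zj, so importance
listings show at a glance which axis mattered and whether it was
jerk-corrected. The angular-change channel is available behind a flag but
off by default; ODBA is deliberately not a model feature (it adds nothing
over the dispersion statistics that already encode intensity) and is
reported separately.

## Classifier and protocol

Windows are assigned at random to train/validation/test at 50/25/25 %
(sizes rounded per subset, test takes the remainder). If any class misses
any subset the assignment is redrawn with an incremented seed up to a
bounded retry count; classes with fewer than 3 windows are rejected up
front. The default model is a random forest of 100 trees with all other
hyperparameters at scikit-learn defaults, `n_jobs=1` and a fixed seed, so
the train→predict path is fully deterministic. Class imbalance is left
untreated by design; balanced accuracy does the correcting at evaluation
time. The validation subset is used for logging and model comparison only —
forests need no early stopping.

The parity feed-forward network (two hidden layers of 225 units behind a
standard scaler) uses the fitter's internal early-stopping split because the
backing implementation cannot consume an external validation set; the
protocol's validation subset is scored afterwards. The network is provided
for comparison and carries no accuracy claim.

Variable importance is the forest's mean decrease in impurity, scaled so
the top feature equals 1.0 and sorted descending. This is a deliberate
simplification — the importance measure is a property of the backing
forest, and the package only relies on qualitative statements (which
*family* of features dominates), which are robust to the measure.

## Metrics

All percentages are computed from exact integer cell counts and rounded
half-away-from-zero only at presentation. Per class: sensitivity
= 100·diag/row-total, specificity = 100·(1 − (col-total − diag)/(N −
row-total)), balanced accuracy their mean; a class with zero actual
occurrences has undefined sensitivity, reported as NaN and excluded from
the mean balanced accuracy with a warning — a class that is merely never
*predicted* contributes exactly 50, never 0. Overall accuracy carries an
exact Clopper–Pearson 95 % interval. Cohen's unweighted kappa is
`(p_o − p_e)/(1 − p_e)` with the convention κ = 1 when two raters agree
perfectly on a constant sequence (p_e = 1).

## Window-size sweep

Comparing window sizes fairly requires the *same seconds* to be test
seconds at every size. The sweep therefore assigns fixed 120-s time blocks
of each animal's timeline to train/validation/test (hash-based, independent
of traversal order and of which sizes are swept) and gives each window the
subset of its start-time block. Classes with fewer than 10 training windows
at a given size are dropped from that size's model and metrics with a
warning rather than skipping the size: on strongly imbalanced data the rare
classes vanish at large windows, and skipping would silently remove exactly
the sizes the experiment is about. A size is skipped only if fewer than two
classes remain.

## Synthetic generator

Each behaviour is a `BehaviourProfile`: a gravity direction (posture) of
magnitude 1000 with a slow angular wobble (stationary Ornstein–Uhlenbeck
drift, ~2-min correlation time, so posture wobble is absorbed by the static
component rather than appearing as a low-frequency spectral peak), a
dynamic component, and white sensor noise (sd 12). With
`oscillation_freq_hz = 0` (all defaults) the dynamic component is broadband
noise whose per-axis sd is the profile's `dynamic_amplitude` — class
information then lives in dispersion statistics, not in any single
spectral ordinate, which is exactly the regime 1-Hz sampling imposes on
real data. Amplitudes follow the observed mean-ODBA ladder
(RSP < RLP < Lactating < Standing < Foraging < Walking < Scrubbing, roughly
50 to 550 in milli-g-like units). Foraging and Walking share one profile up
to a 14 % amplitude shift with a ±20 % lognormal per-bout jitter: the pair
is deliberately confusable, and under the ~81 % foraging mix the rare
member collapses to chance-level balanced accuracy — the central
rare-behaviour failure mode of majority-window classification.

Scenario structure: every behaviour receives a per-animal time budget equal
to its mix proportion (largest-remainder apportioning), spent in bouts with
exponential durations (profile-specific means: resting hundreds of seconds,
walking/scrubbing tens) and shuffled into an alternating sequence — so
realised time shares match the mix up to rounding. Two realism features
matter for separability: (1) each animal's whole stream is rotated by a
uniform random matrix, because an ear tag is attached in an arbitrary
orientation — absolute axis means are not comparable across animals, which
is what pushes orientation-independent dispersion and jerk features to the
top of the importance ranking; (2) low-activity bouts (RLP, RSP, Lactating)
are consolidated into one resting phase per animal, entered and left
through sternal resting, as consolidated rest is how herds actually behave —
this keeps resting-bout boundaries adjacent to other low-amplitude
behaviours instead of to foraging, whose fivefold amplitude would otherwise
dominate any window it touches.

The canned benchmark (`wildboar_benchmark`) is 13 animals × 11 300 s at
1 Hz (~40 h), foraging-dominated, with RLP/RSP confined to the first 7
animals and lactation to the first 2 (the nursing sows). Its construction
guarantees — and its `notes` declare — the mean-ODBA ordering, four
well-separated classes (RLP, RSP, Lactating, Standing), and the
Walking↔Foraging confusion.

**What the generator does not model:** biomechanical gait, transitional
movements between postures (bout changes are instantaneous), temperature,
sensor saturation or drift, diurnal rhythm beyond rest consolidation, and
individual variation in behavioural style beyond tag orientation. Passing
tests on this generator therefore demonstrate that the pipeline recovers
behaviour classes whose signal follows the amplitude-ladder/posture model —
they do not certify field accuracy on any particular species or tag.

## Problem sizes and numerical conventions

The test suite and the acceptance script run the full benchmark (~147 000
labelled seconds, ~9 800 windows at W = 30) for the end-to-end checks and a
reduced two-point sweep (6 s vs 30 s) for the window-size comparison; the
seven-point sweep is exposed through the CLI and library. Determinism:
every random draw flows from explicit integer seeds through
`numpy.random.default_rng` (simulation), scikit-learn `random_state`
(models), and a hash-based block assignment (sweep partition); reruns are
bit-identical. Degenerate inputs are handled as stated above (constant
windows, zero-norm vectors, empty window sets warn rather than fail).

## Known limitations

- The split is by window, not by animal; with per-animal tag rotations the
  forest can exploit animal-specific posture signatures, so accuracies are
  optimistic relative to a leave-one-animal-out protocol. This mirrors the
  protocol the package reproduces and is flagged rather than fixed.
- Impurity-based importance is biased toward high-cardinality continuous
  features; only qualitative importance statements are made.
- The exact stochastic internals of other ML back-ends (e.g. different
  forest implementations) will produce different confusion matrices on
  identical inputs; published headline accuracies are reproduced through
  the metric path from count tables, not bit-wise through retraining.
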
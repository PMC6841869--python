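# Methods

This note documents the modelling choices, the synthetic study
conditions, and the numerical conventions used throughout `mricoder`.

## Data model and exam assembly

Modality logs have no public format, so the package defines a
JSON-lines event dialect with five event kinds: `registration`,
`sequence_start`, `sequence_end`, `table_move`, `contrast_injection`.
Timestamps are second-resolution ISO-8601; durations are seconds
throughout.  An exam spans from subject registration on the host
computer to the end of the last MR sequence.  Assembly rules:

- Each registration opens a new exam on its scanner; later events up to
  the next registration belong to it.  On timestamp ties, a
  `sequence_end` coinciding with the next registration closes the
  *earlier* exam (the exam is defined by its last sequence end).
- A `sequence_end` without a matching open `sequence_start` rejects
  that sequence but keeps the exam; events before any registration go
  to a rejects report.  Nothing is silently dropped.
- Exams with zero completed sequences are kept and flagged `aborted`
  (they occur in practice when scanning stops before diagnostic images
  exist); they are excluded from model training by default because
  their labelsets are empty.

Billing records are merged by exam id when present, else by timestamp
within an exam's span padded by a tolerance (default 30 minutes — the
merge key in real deployments is a timestamp, and registration and
billing-entry clocks differ; the value is configurable and not
critical because exams on one scanner are separated by more than the
tolerance).  A timestamp matching two exams is an error, not a guess.

## Sequence-name standardization

Weighting is derived from acquisition parameters, not from the raw
name: diffusion if any b-values were recorded; FLAIR for inversion
time 1800–3000 ms; STIR for 100–250 ms; T1 for TR < 800 ms and
TE < 30 ms; T2 for TR ≥ 2000 ms and TE ≥ 60 ms; PD for TR ≥ 2000 ms
and TE < 30 ms; anything else gets no weighting token.  These bands are
conventional clinical ranges at 1.5–3 T and live in a config
(`RuleTable`) because they shift with field strength.  Token order is
fixed — weighting, technique, `fs`, orientation, `bh` — and diffusion
EPI renders as the fused token `ep2d_diff` with no separate weighting
token, matching radiographers' naming convention.  The raw name is
consulted only when the structured technique field is unusable, via a
conservative keyword scan.  Oblique orientations render as `tra`
because the logs carry no angulation.

## Features

- ACQ = Σ sequence durations (value-added time); UOP = exam span − ACQ
  clipped at zero (idle time); the UOP/ACQ ratio separates MR-guided
  biopsies (long needle-work pauses between short acquisition cycles)
  from diagnostic exams.  For an aborted exam ACQ = 0; the ratio is
  reported as 0 and a separate `aborted` indicator carries the signal,
  avoiding infinities.
- Table features: total |Δposition| over the time-ordered trace,
  min/max position, and the mean |Δposition| between consecutive
  sequences' start positions.  An empty trace yields zeros.
- Sequence counts (not binary presence) over a vocabulary of
  standardized names fitted on training exams only; unseen names at
  prediction time land in a reserved overflow bin so the vector length
  is fixed.  Counts matter because repeat acquisitions drive
  additional-series surcharge codes.
- Coils are collapsed into six coarse groups (head, spine, body,
  extremity, breast, other) keyed by id substrings, keeping
  dimensionality stable across scanner coil inventories.
- No scaling happens in featurization; z-scoring is fitted inside each
  model pipeline so cross-validation folds never see test statistics.

## Label cleaning

Order is fixed and idempotent: (1) drop non-imaging-related codes
(intravenous access, narcosis surcharge, physician service in absence)
— these are real billing entries but leave no trace in the scanner
log; (2) cap each code at its per-exam maximum K_j, logging every
truncation; (3) prune codes appearing in fewer than 20 training exams
("instances" are exams containing the code, not charged units).
Pruning is fitted on the training split only and then applied
everywhere.  Corrections are applied automatically to training data;
for test data they are an explicit flag, mirroring the fact that a
held-out test set is ground-truthed manually while training data is
only rule-cleaned.

The shipped code catalogue is synthetic but structurally faithful: 22
imaging codes of which six may be charged twice and two more than
twice, including the auxiliary codes 39.5010 (additional series),
39.0410 (arthrogram) and 39.5020 (angiography add-on), plus three
non-imaging codes.  Tariff points are plausible magnitudes, not real
tariff values.

## Multi-output classifiers

Each code j is a multi-class problem over {0..K_j}.  Binary relevance
trains one independent classifier per code.  A chain trains along a
label order, augmenting the features with the *true* preceding label
values at training time and with its own hard predictions,
sequentially, at inference (hard labels keep base classifiers
interchangeable).  The ECC draws label orders independently at random
(duplicates allowed), trains each chain on the full training set, and
aggregates per label by majority vote; ties resolve to the smallest
tied count — a deliberate undercoding preference, since falsely
charging a service is worse than a conservative tie-break.  Labels
with a single observed training class become constant predictors.
Predictions are clipped into {0..K_j}.

MLP and SVM pipelines embed a standard scaler; forests are unscaled.
Hyperparameter search (`tune`) is an exhaustive grid scored by mean
micro-F1 over seeded k-fold cross-validation (default 10 folds).

### Chain advantage and its limits

`synthetic.label_dependency_scenario` constructs the situation that
motivates chains: a main label A ∈ {0,1,2} whose three classes sit at
the origin and at ±s along one random direction (pairwise linearly
separable, so one-vs-one multiclass learning works), and an auxiliary
label B = 1(A ≥ 1) whose binary partition is a sandwich no linear
boundary separates.  With a near-linear base classifier (RBF SVM,
gamma 5·10⁻⁴), binary relevance on B collapses to the majority class
while a chain ordered (A, B) reaches B through A at ≈ 0.96 accuracy.

The mirror image of this advantage is error propagation: a chain whose
order puts B *first* is blind on B, and its A-classifier — trained
with the perfectly correlated true-B feature — degrades at inference
when fed the bad B̂.  With only two labels, an ensemble whose random
orders put B first in the majority can therefore lose its advantage;
the effect shrinks as the number of labels grows and is part of why
ECC behaviour on small label spaces is seed-sensitive.  The billing
label space (q ≈ 12–22) is comfortably past this regime.

## Evaluation conventions

Counting for count-valued labels is by charged unit: TP = min(t, p),
FP = (p − t)₊, FN = (t − p)₊ per exam and code, summed over exams.  TN
is defined by K_j-slot expansion; it is recorded for completeness but
affects no reported metric (precision, recall and F1 ignore TN).
Micro-averaging applies the binary metric to pooled counts — the
standard pooled form, without any 1/q prefactor, which keeps precision
and recall inside [0, 1].  Macro-averaging averages per-code metrics
with equal weight.  Undefined ratios (zero denominators) report 0 with
a warning.  Label density takes the normalizing number of possible
codes as an explicit argument, since either the pre- or post-pruning
code count is defensible as |Y|.

The prevalence–F1 analysis computes Spearman's rank correlation
(average-rank ties, two-sided p) restricted to codes with F1 < 1, i.e.
the codes where more training data could still help.  Reimbursement
deltas weight missed (undercoding) and excess (overcoding) units by
tariff points, both normalized by total truth points.  The paired
comparison classifies each exam by exact-match correctness of two
coders into both/auto-only/manual-only/neither quadrant fractions.

## Synthetic study conditions

Eight procedure templates (head, knee, shoulder arthrography, spine,
contrast abdomen, neck, whole body, MR-guided biopsy) define sequence
archetypes with realistic parameter ranges, idle-time distributions,
table-motion patterns (static, stepped spine stations, whole-body
sweep, biopsy in/out cycles), contrast probabilities and billing
rules.  Every label is tied to an observable: main codes to the
template's sequence signature, the additional-series code to the
executed-sequence count beyond a free allowance (capped at 4), the
contrast code to the contrast event, spine segment counts to table
stations.  Auxiliary codes are never drawn marginally — only through
these conditional rules — so the label dependencies the chain models
exploit genuinely exist in the data.  The template mix is calibrated
so the expected label cardinality is ≈ 4.1 units per exam
(`expected_label_cardinality` computes this analytically from the
config and serves as the oracle for the empirical value); neck exams
average about six codes, the most of any template.  Raw names are
decorated with exactly the token classes the standardizer removes
(body region, slice thickness, post-contrast delay, accelerator tags).
About 1 % of exams abort after registration; 0.5 % carry a rare
procedure code (exercises pruning); 15 % carry a non-imaging code
(exercises exclusion).

The technologist simulator drops each charged unit independently with
a forget rate (auxiliary codes at 2.5× the base rate — manually added
surcharge codes dominate real coding errors) and adds one spurious
unit per exam with a smaller add rate.  Forget > add yields the
precision > recall asymmetry characteristic of manual coding.

What the generator does **not** emulate: vendor log payloads, label
noise correlated with features, inter-technologist variance, analogous
coding of procedures without dedicated codes, scanner clock drift, and
real tariff point values.  Because noise-free labels are deterministic
functions of observables, the end-to-end pipeline can approach perfect
scores on synthetic data; passing tests demonstrate that the machinery
recovers recoverable structure, not that real-world coding reaches
these numbers.

## Problem sizes and determinism

Default experiment sizes — 2000 exams for end-to-end runs (temporal
70/30 split), 500 training instances for the dependency scenario,
200 random trials for metric-oracle checks — are chosen so the whole
suite runs in minutes on a single CPU while keeping empirical medians
stable.  All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; no global RNG state is used.  Event and
report files are serialized with sorted keys and fixed float rounding,
so identical configurations reproduce outputs byte for byte.

## Known limitations

- The weighting rule table is heuristic; exotic protocols (e.g.
  dual-echo, spectroscopy) fall into the `none`/`other` buckets.
- Timestamp-keyed billing merge cannot disambiguate simultaneous exams
  on different scanners without a scanner key; such records raise an
  ambiguity error by design.
- The ECC offers no probability calibration; votes are hard counts.
- Tariff economics use per-code points only; inter-code legality rules
  beyond per-exam maxima are out of scope.
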
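# Methods

## Model

The classifier is a two-stage hierarchy built on the observation that the
two clinically critical beat classes are separable along different axes:
ventricular ectopics (VEB) differ from normal beats in *morphology* (wide
QRS, absent P wave) and in rhythm, while supraventricular ectopics (SVEB)
share normal morphology and differ almost only in *rhythm* (a premature
beat shortens the preceding RR interval). Stage 1 therefore uses waveform
features and a learned classifier; stage 2 uses a single rhythm statistic
and a threshold.

### Preprocessing

Beats are cut from the raw signal at the annotated R fiducials — QRS
detection is out of scope, annotations are trusted — as 200-sample windows
`[r−100, r+99]` (the nominal 0.278 s at 360 Hz rounds to 100 samples; the
window is symmetric to within one sample and deterministic). Each window
is z-normalized with the population standard deviation (divide by n); the
convention is a normalization target, not an inference, and is fixed here.
No filtering or denoising is applied anywhere: filters can erase the very
morphology details stage 1 classifies on.

Degenerate beats are dropped rather than repaired, with per-recording
accounting: windows that exit the signal (padding would fabricate
morphology), flat windows (z-normalization undefined), and the first beat
of every recording (no preceding RR interval; both stages need one). The
conservation identity `annotations = retained + non_beat + first_beat +
boundary + flat` is asserted in tests.

`rr_ratio` divides the preceding RR interval by the mean RR interval of
the entire recording, computed once per recording from all annotated-beat
intervals before any classification. Normalizing by the recording mean —
rather than using raw RR — removes per-patient heart-rate offsets
(persistently fast rhythms produce short RR intervals for perfectly normal
beats) and makes the statistic dilation-invariant, which tests exploit.

### Stage 1: random-projection SVM ensemble

A bank of M = 15 Gaussian random matrices (d = 50 rows, m = 200 columns,
i.i.d. N(0,1)) is generated from one integer seed — the model's only
randomness — and reused across every cross-validation fold and parameter
combination. Full row rank is checked at generation with a singular-value
tolerance of `m·ε·σ_max` (Gaussian matrices are full rank almost surely;
the redraw is a safety valve).

The feature map is `F = X A⁺` with `A⁺` the Moore–Penrose pseudo-inverse:
each beat's least-squares coefficients in the row space of A. The
commonly written alternative `F = X Aᵀ` is provided as `mode="transpose"`;
for orthonormalized rows the two coincide, and the pinv mode is the one
whose reconstruction property (`F A` minimizes ‖X − FA‖) the tests verify
against a normal-equations oracle. The preceding RR interval is appended
in seconds, unscaled: the projection coefficients of z-normalized beats
are already on comparable scales, so no per-feature standardization is
applied (a deliberate, documented choice — not an omission).

Each of the M feature groups trains one RBF-kernel SVM (scikit-learn
`SVC`, libsvm one-vs-one multi-class); all members share one (C, δ), with
δ used as the RBF γ. No class weighting is applied: imbalance is handled
by the hierarchy itself (stage 2 exists because stage-1 classifiers do
poorly on SVEB), and weighting is left off by default.

Voting: the winner is the class with the most member votes. Ties break by
the larger summed one-vs-one decision margin across members (for each
class pair the libsvm decision value is credited to the favoured class and
debited from the other, summed over pairs and members), then by the fixed
priority V > S > N > F > Q. Both steps are order-independent, so permuting
members never changes a winner — a property test.

Only the V / non-V split of the stage-1 winner is consequential: non-V
winners are retained for diagnostics, but beats not labelled V all proceed
to stage 2 regardless of whether a member thought them S, F or Q.

### Model selection

Leave-one-recording-out cross-validation on the training division: each
recording is held out exactly once, folds partition by record — never by
beat — and the per-fold guarantee that no held-out beat appears in
training is asserted inside the loop. Per-fold confusion matrices are
summed and the criterion Ave = (Se_N + PP_N + Se_V + PP_V)/4 is computed
from the summed matrix; computing Ave per fold and averaging would weight
recordings unequally and is intentionally not the contract. The grid is
C ∈ {1, 10, 100} × δ ∈ {0.4, 0.7, 1.0, 1.3}; Ave ties prefer smaller C,
then smaller δ (simpler model). Lead configurations (A, B, A+B) compare by
best Ave with canonical-order tie-breaking. Defaults are C = 1, δ = 1.3,
lead A — the optimum of that selection procedure on the reference
benchmark.

### Stage 2: RR-ratio threshold

Among beats not labelled V, label S iff `rr_ratio < threshold` (strict
inequality; ratios are rounded to 10 decimal places first so beats sitting
exactly on a grid value are never flipped by floating-point representation
noise). Everything else becomes N: the final system never emits F or Q,
and reference F/Q beats count in the accuracy denominator as permanent
errors of the 3-class output.

Threshold selection scans 0.70–0.90 in 0.01 steps on the training beats
the fitted ensemble did not label V (the deployed hierarchy's own stage-2
input) and takes the smallest threshold whose SVEB sensitivity reaches a
configurable target (default 80%); if none qualifies the grid maximum is
returned with a warning. The deployment default 0.8 is exposed as
`DEFAULT_THRESHOLD`.

## Evaluation

All metrics derive from confusion matrices with reference classes as rows
(N, S, V, F, Q) and algorithm classes as columns (N, S, V for the final
system; all five at stage 1). Sensitivity = 100·TP/row total; positive
predictive value = 100·TP/column total; accuracy = 100·(shared-class
diagonal)/grand total. Zero denominators yield `None`/`null`/`-`, never
0.0. Display rounding is half-up to one decimal; internal comparisons use
full precision, and the report writer is tested never to store a
percentage disagreeing with its own matrix by more than 0.05. Per-recording
report tables carry a Total row computed from the pooled confusion matrix,
not from averaging rows.

## Synthetic data generator

Recordings are wave trains of three Gaussian bumps per beat (P, QRS, T at
−0.17 s, 0, +0.22 s relative to the fiducial) on white baseline noise,
two leads (lead B is the same wave train under an independent gain with
its own noise). This is deliberately not a dynamical ECG model: the
generator's job is to realize exactly the two discriminative axes the
method uses, with analytically checkable statistics.

* **Templates.** N: P 0.15 / σ 0.02 s, QRS 1.0 / σ 0.012 s, T 0.3 /
  σ 0.06 s. V: no P wave, QRS 1.2 / σ 0.032 s (≥ 2× the N width),
  inverted T. S duplicates N exactly (rhythm is its only signature).
  F is the 50/50 parameter midpoint of N and V at near-normal rhythm.
  Q is not generated (15 such beats exist in the whole reference corpus;
  they carry no structure this method uses). Per-beat parameter jitter is
  5% fractional.
* **Rhythm.** Base RR 0.8 s with 0.04 s jitter; S beats draw their
  preceding RR at ratio N(0.65, 0.05) of base, V beats at N(0.6, 0.05)
  with a 1.4× compensatory pause after; all intervals truncate above
  0.2 s. Class mix N/S/V/F = 0.80/0.10/0.08/0.02.
* **Inter-patient variation.** Per recording, base RR ~ N(0.8, 0.06) s,
  QRS width and amplitude factors ~ N(1, 0.1), noise σ ~ U(0.03, 0.07),
  lead-B gain ~ U(0.5, 0.9). Train/test record ids are disjoint.

What passing tests on this generator do show: the pipeline recovers known
class structure across patients whose morphology, rate and noise differ,
the feature map preserves QRS-width information through 50 random
coefficients, and the RR-ratio rule separates early beats as designed.
What they do not show: performance on real ECG — real data has baseline
wander, electrode artefacts, morphology drift within a patient, atrial
fibrillation (which produced most of the benchmark's false SVEBs), and
class overlap far beyond three Gaussian bumps. Synthetic results are
correctness checks, not clinical claims.

## Problem sizes and numerical choices

The test suite and the acceptance run use 3+3 recordings of 500 beats
(end-to-end) and 4 recordings of 150 beats (full-grid cross-validation
checks) — sizes at which the SVM fits are seconds-fast while every class
still appears in every recording with high probability. The end-to-end
recovery run uses the deployment threshold 0.8: the on-train selection
rule by construction lands at the ~80th percentile of the S-ratio
distribution, so its held-out sensitivity sits at the target boundary;
the selection procedure itself is validated separately (unit and property
tests, and the `fit()` selection path).

Ties, degenerate inputs and tolerances: vote ties and Ave ties have fixed,
order-independent rules (above); single-class training folds raise and
mark the grid combination failed; empty test sets produce empty outputs;
flat beats and boundary beats are dropped with counts; rank checks use
`m·ε·σ_max`. Reproducibility is exact: one seed determines the matrix
bank and the generator, libsvm training is deterministic given data, and
replay tests compare SHA-256 hashes of beat tables, predictions and
reports.

## Known limitations

* The stage-2 rule caps SVEB positive predictive value: any N beat with a
  short preceding RR (post-pause, rate changes, atrial fibrillation) is
  labelled S. On the reference benchmark this is the dominant error mode.
* The hierarchy never emits F or Q, so those reference beats are always
  errors; applications needing fusion-beat detection must extend stage 1.
* Feature scaling of the appended RR interval is fixed (seconds,
  unscaled); for very different rate regimes a rescaling step in front of
  `featurize` would be the place to intervene.
* The reader ingests the package's plain-text recording triplet, not the
  binary waveform format of the reference database; converting real
  recordings requires a one-off export step.
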
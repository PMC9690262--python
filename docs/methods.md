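# Methods

This note documents the models, conventions, and numerical choices
behind `thermoengage`, in the spirit of a statistical software methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and what the synthetic generator emulates

A session's ROI temperature series (10 Hz, ten 30 s + 30 s blocks,
6000 samples) is modelled as

```
T(t) = baseline(ROI) + session · drift + subject_intercept
       + activity(t) + noise(t)          [+ spikes, gaps]
```

* `baseline`: 34.0 °C (nose tip) / 35.5 °C (corrugator), typical
  resting facial skin temperatures.
* `drift` (°C per session step): the session-wise mean shift; negative
  values emulate progressive sympathetic cooling. No published effect
  amplitude exists for this paradigm (the source study reports
  boxplots only), so it is a free configuration parameter, not a
  calibrated value.
* `subject_intercept ~ N(0, 0.3² °C)`: stable inter-individual
  baseline differences, shared across sessions and ROIs.
* `noise(t)`: a zero-mean, unit-variance mixture
  `√(1−w)·AR(1) + √w·white`, scaled by `noise_sd` (default 0.1 °C,
  a realistic effective noise floor for facial IRT). The AR(1) pole is
  φ = 0.97 at 10 Hz (≈3 s correlation time), standing in for slow
  vasomotor fluctuations. The high-frequency weight per session is
  `w(s) = w₀·(1 − complexity_decay · s)` with w₀ = 0.5, clipped to
  [0, 1]. Because the mixture is renormalized to unit variance,
  `complexity_decay` moves sample entropy *without* moving the mean or
  total variance — mean level and complexity are independently
  controllable, mirroring the two effects the analysis is meant to
  detect.
* Spikes: Bernoulli per sample (`outlier_rate`), amplitude
  ±(0.5–1.5)·2 °C — motion residuals for the Hampel stage.
* Gaps: contiguous invalid runs (default 2 s), emulating tracking
  failures from head motion; run count is chosen so the invalid
  fraction matches `gap_rate` (default 0.12, the corrected-frame
  fraction expected under the acquisition protocol). Gap samples are
  additionally corrupted so that repairs are actually exercised.
* Reproducibility: each (subject, session, ROI) cell draws from its
  own substream derived from the global seed (CRC-keyed
  `SeedSequence`), so cohorts are bit-reproducible and cells
  independent.

What the generator does **not** emulate: breathing plumes, perspiration
physics, spatial thermogram structure, camera drift, or any coupling
between activity blocks and temperature (the per-block activity
component defaults to 0 because no within-block contrast values are
published). Passing tests therefore demonstrate correctness of the
pipeline's arithmetic and its statistical operating characteristics
under a plausible signal model — not clinical validity on real
recordings.

The synthetic clinical score table draws pre-scores uniformly from
10–50 (the published cohort's range) and adds a log-normally
noise-scaled improvement, guaranteeing all-positive differences for
any positive improvement (the regime that produces the extreme exact
signed-rank p of 2/2⁸ at n = 8).

## Preprocessing

* **Gap repair**: each maximal invalid run is replaced by the mean of
  the `flank` (default 6) nearest valid samples before *and* after the
  run (12 values averaged); at series edges the available side alone
  is used. "Six per side" is the plain reading of the protocol; the
  alternative 3+3 reading is available by setting `flank=3`.
* **Hampel filter**: centered window of `round(15 s · rate)` samples,
  forced odd; robust SD = 1.4826·MAD (the Gaussian-consistency
  constant, exposed as `mad_scale`); threshold n = 2. Edge windows
  shrink (truncate) rather than pad — no data is invented. Windows
  with MAD = 0 flag nothing, avoiding the infinite-z pathology on
  locally constant data. A window longer than the series degrades to a
  single global window with a warning. Order of operations is fixed:
  repair, then filter.
* The production scan keeps the window as a maintained sorted buffer
  and finds the MAD by two-pointer merging outward from the median
  (both are order statistics of an odd window). The test suite asserts
  bit-exact agreement with a naive sort-per-window reference across
  window lengths, including even-length truncated edge windows.

## Features

Each session is cut into its ten contiguous 600-sample blocks; metrics
are computed per block over the pooled active+rest samples (the
protocol evaluates "each block"; no phase split is published) and then
averaged unweighted across blocks.

Sample entropy follows the template-counting form with delay τ:
templates of length L at index i are (tᵢ, tᵢ₊τ, …); at each length the
template index ranges over [1, N − Lτ] and each template's match count
is normalized by N − (L+1)τ. Matches use the Chebyshev distance with
tolerance r = 0.2·SD of the analyzed segment (ddof = 1), computed per
block after preprocessing — "SD of the signal" is read as the segment
being analyzed; a session-level r is one line of code away but not a
supported option, to keep the definition unambiguous. Self-matches are
excluded; both (i, j) and (j, i) are counted, consistently in
numerator and denominator, so the ratio is unaffected by the
convention. Undefined results (constant segment ⇒ r = 0, or zero
matches at either length) are returned as NaN, never ±∞, and excluded
from the block average with their count recorded — this keeps the
downstream ANOVA well-defined. The optimized numba kernel is asserted
exactly equal (integer counts and final value) to a brute-force O(N²)
template counter on random segments up to N = 600.

SampEn's SD-proportional tolerance makes it invariant to offset and
positive rescaling; it is non-increasing in r; i.i.d. noise scores
higher than an equal-SD AR(1). All three are property-tested.

## Statistics

* **Wilcoxon signed-rank** (clinical pre/post): zero differences are
  dropped; |differences| get midranks. Exact mode computes the
  distribution of W⁺ over all 2ⁿ sign assignments by dynamic
  programming over doubled midranks (integer arithmetic, so ties are
  exact; identical by construction to explicit enumeration, and tested
  against it for n ≤ 12); two-sided p = 2·min(P(W ≤ w), P(W ≥ w))
  capped at 1. The reported z uses σ = √(Σrᵢ²)/2 (midrank tie
  correction, no continuity correction). On the bundled published
  cohort this gives p = 2/2⁸ = 0.0078125 → 0.008 and |z| = 2.524; the
  tie correction (8.3 appears twice among the differences) is what
  reproduces the published z exactly.
* **RM-ANOVA**: subjects with any missing session are dropped listwise
  and `n_complete` is always reported. SS is partitioned into
  subjects, sessions, error; F = MS_sessions/MS_error is referred to
  F(ε(k−1), ε(k−1)(n−1)) with Greenhouse–Geisser
  ε = tr(S̃)²/((k−1)·ΣS̃²) from the double-centered session covariance,
  clipped to [1/(k−1), 1]. GG is the default because fractional
  reported dfs in this literature imply ε-correction; Huynh–Feldt is
  available via `epsilon_method="hf"`. k = 2 reduces exactly to the
  squared paired t. The implementation is verified to 1e-10 against a
  naive sums-of-squares + contrast-eigenvalue oracle and cross-checked
  against `pingouin.rm_anova`.
* **Pairwise + FDR**: when an omnibus rejects at α (default 0.05,
  two-sided throughout), all three session contrasts get paired
  t-tests; the FDR family is the set of comparisons performed for that
  ROI × metric cell, adjusted by Benjamini–Hochberg step-up (via
  statsmodels). BH is order-preserving, ≥ raw, ≤ Bonferroni — but not
  idempotent in general (counterexample: p = [1.0, 0.25]), so no such
  claim is tested.
* **Clinical deltas**: Δ = T2−T0 and Δ% = 100·Δ/T0, rounded to one
  decimal with halves away from zero (banker's rounding would
  contradict the published table on an exactly representable tie,
  51.875 → 51.9). One published percentage cell (scores 12.40 → 16.30,
  printed 31.4) disagrees with its own scores (31.45… → 31.5) and is
  treated as a printing slip, like two other rows the table is known
  to misprint.

## Operating characteristics and problem sizes

The validation suite runs the *full* pipeline (generation with
artifacts at study defaults → repair → Hampel → features →
statistics):

* Type-I: 500 null cohorts (n = 5 subjects, 3 sessions, 2 ROIs × 3
  metrics). The pooled omnibus rejection rate is required to lie in
  0.05 ± 3·√(0.05·0.95/500) — the binomial band computed at the
  worst case of full dependence among the six tests within a
  replicate. GG correction makes the omnibus mildly conservative at
  n = 5, which this band accommodates.
* Power: 200 cohorts with drift −0.02 °C/session and complexity decay
  0.5. The suite measures the realized standardized effect (per-step
  session shift over the subject×session interaction SD) and requires
  it to be ≥ 1.2, detection of the affected cells in > 80% of
  replicates, and FDR-significant pairwise contrasts concentrating on
  T0 vs T2 (the widest session separation).

Replicate counts and the n = 5 cohort size were chosen as the smallest
configuration at which the binomial bands are meaningfully tight while
the suite stays fast enough for routine runs.

## Known limitations

* The external ROI tracker is out of scope; validity flags must
  arrive with the data (the generator supplies them). The ROI
  statistic is the plain mean of masked pixels — whether real
  acquisitions used mean or maximum is unstated in the source
  protocol; mean is the common IRT convention.
* SampEn at N = 600, m = 2 has non-negligible estimator variance;
  block averaging across the ten blocks is what makes the session
  summary usable at n = 5.
* The generator's effect amplitudes are assumptions, not estimates;
  nothing here calibrates them to real patients.
* Frame-stack TIFFs store float32 (≈1e-6 °C quantization); exactness
  claims hold for the in-memory float64 path.
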
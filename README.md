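# thermoengage

Psychophysiological engagement analysis from facial **infrared
thermography (IRT)** during block-paradigm therapy sessions.

Facial skin temperature is an autonomic readout: sympathetic
predominance cools the nose tip and forehead and lowers the complexity
of the temperature time course. During robot-assisted gait training
(RAGT) of children with cerebral palsy, these signals can be recorded
contactlessly with a thermal camera and used to track how engaged a
patient is across a course of therapy. `thermoengage` implements that
analysis end to end:

1. **ROI time courses** — mean pixel temperature of the *nose tip* and
   *corrugator* (forehead) regions, sampled at 10 Hz across a paradigm
   of ten 30 s-active / 30 s-rest blocks (600 s per session), with
   per-frame validity flags from the (external) ROI tracker.
2. **Artifact repair** — tracking-failure gaps are replaced by the mean
   of the six valid samples flanking each gap on both sides; residual
   motion spikes are removed with a centered 15 s **Hampel filter**
   (replace a sample by the local median when it deviates more than
   *n* = 2 robust SDs, 1.4826·MAD, from it).
3. **Per-block features** — for each 60 s block:
   MeanTemp = (1/N)∑Tᵢ, STD = √( (1/(N−1))∑(Tᵢ−MeanTemp)² ), and
   **sample entropy** SampEn(m, r, N) = −ln(U^{m+1}/U^m) with m = 2,
   r = 0.2·SD of the segment, delay τ = 1 and Chebyshev template
   matching; the block average feeds the statistics.
4. **Longitudinal statistics** — Shapiro–Wilk gate and **exact Wilcoxon
   signed-rank** for paired clinical scores (GMFM-88 at T0 vs T2);
   one-way **repeated-measures ANOVA** over sessions (T0, T1, T2) with
   **Greenhouse–Geisser** ε-corrected degrees of freedom per ROI ×
   metric; when the omnibus rejects, pairwise paired *t*-tests with
   **Benjamini–Hochberg FDR** adjustment.

Because clinical thermal recordings are privacy-restricted, the package
ships a first-class synthetic-data generator (`thermoengage.synthetic`)
that reproduces the paradigm's statistical structure — session-wise
cooling drift, controllable signal-complexity decay, spike outliers,
and contiguous tracking gaps covering ~12% of frames — with known
ground truth, so every stage is testable against oracles and the whole
pipeline against its operating characteristics (type-I error, power).

## Worked example

```python
from thermoengage import RunConfig, SynthConfig, run_pipeline

config = RunConfig(
    synth=SynthConfig(seed=7, n_subjects=5, drift_per_session=-0.02,
                      complexity_decay=0.5, outlier_rate=0.002),
    clinical_improvement=5.0,
    out_dir="demo_run",
)
report = run_pipeline(config)
for (roi, metric), r in report.omnibus.items():
    print(f"{roi:11s} {metric:9s} F({r.df1:.3f}, {r.df2:.3f}) = {r.f:.3f}; p = {r.p:.3f}")
```

prints the six session-effect omnibus tests (fractional degrees of
freedom are the GG-corrected ε(k−1) and ε(k−1)(n−1)):

```
corrugator  mean_temp F(1.776, 7.104) = 25.597; p = 0.001
corrugator  sampen    F(1.907, 7.627) = 122.055; p = 0.000
corrugator  std_temp  F(1.738, 6.952) = 0.780; p = 0.478
nose_tip    mean_temp F(1.520, 6.081) = 49.345; p = 0.000
nose_tip    sampen    F(1.791, 7.164) = 272.051; p = 0.000
nose_tip    std_temp  F(1.095, 4.379) = 0.339; p = 0.609
```

The generator injected a −0.02 °C/session cooling drift plus a
complexity decay, and the statistics recover exactly that pattern: mean
temperature and sample entropy change across sessions, block-to-block
variability does not. `report.to_markdown()` lists the FDR-adjusted
pairwise contrasts (significant differences concentrate on T0 vs T2,
the largest session separation), e.g.

```
| corrugator | sampen | T0 vs T2 | 12.782 | 0.0003 |
```

On the published clinical worked example (eight children, all of whom
improved their GMFM-88 score between T0 and T2):

```python
from thermoengage.datasets import gmfm88_cohort
from thermoengage.stats import clinical_deltas, wilcoxon_signed_rank

scores = gmfm88_cohort()
print(clinical_deltas(scores)[["subject", "delta", "delta_pct"]])
res = wilcoxon_signed_rank(scores["t0"], scores["t2"], mode="exact")
print(res.p)        # 0.0078125  (= 2/2^8, all eight differences positive)
print(round(res.z, 3))  # 2.524   (midrank tie-corrected normal approximation)
```

## Command line

```bash
thermoengage synth --seed 1 --n-subjects 5 --out cohort/
thermoengage preprocess cohort/manifest.csv --window-s 15 --n-sigma 2 --flank 6
thermoengage features preprocessed/manifest.csv
thermoengage stats features_out/features_sessions.csv --clinical cohort/clinical.csv
thermoengage run --config run.yaml --seed 1
```

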
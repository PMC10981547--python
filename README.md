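# tonguecolor

Quantitative tongue colorimetry for traditional-medicine (Kampo / TCM)
tongue diagnosis: does the patient's posture — sitting versus supine —
change the color a clinician sees?

`tonguecolor` implements the full analysis pipeline for that question:

- **Colorimetry.** sRGB → CIE L\*a\*b\* conversion (D65, 2° observer by
  default) and a complete, verification-suite-tested implementation of the
  CIEDE2000 color difference ΔE₀₀, including the G rescaling of a\*, the
  primed chroma/hue terms, the hue-mean wraparound rules, the weighting
  functions S_L, S_C, S_H and the rotation term R_T, with parametric
  coefficients kL : kC : kH = 1 : 1 : 1 by default.
- **Segmentation.** Chromaticity-based tongue extraction from calibrated
  photographs and a ratio-based partition of the tongue into four analysis
  regions — edge, posterior, middle, apex. The edge region, least affected
  by tongue coating, feeds the headline analysis.
- **Position comparison.** Per patient, ΔE₀₀ between the sitting (reference)
  and supine (sample) edge colors, so ΔL′ = L\*_supine − L\*_sitting, etc.
  A difference is *acceptable* when ΔE₀₀ < AT, with AT = 4.1 — the 50:50%
  acceptability threshold commonly used for gingival color — as the default.
- **Biometric associations.** Pearson r (numeric covariates) and the
  correlation ratio η² (sex, smoking, drug status) between ΔE₀₀ and patient
  characteristics, plus flagging of laboratory values above
  prompt-consultation reference criteria (SBP ≥ 160 / DBP ≥ 100 mmHg,
  TG ≥ 500, FPG ≥ 126, LDL-C ≥ 180 mg/dL, HbA1c ≥ 6.5%).
- **Synthetic data.** A generator that stands in for the integrating-sphere
  camera rig: paired tongue images with known region colors, position shifts
  specified directly in ΔE₀₀ units, and biometric tables with a controllable
  linear association to the true shift — every analysis step can be tested
  against ground truth.

A small example cohort (18 patients: paired edge L\*a\*b\* triples and a
biometric table) is bundled for the worked example below.

## Worked example

```python
from tonguecolor import (
    compare_patient, summarize_cohort,
    load_example_lab_pairs, load_example_biometrics,
)

pairs = load_example_lab_pairs()
comparisons = [compare_patient(sit, sup) for sit, sup in pairs]
summary = summarize_cohort(comparisons)
print(f"mean dE00   = {summary.mean_dE00:.2f}")
print(f"median dE00 = {summary.median_dE00:.2f}")
print(f"acceptable (< {summary.threshold_used}) = "
      f"{100 * summary.proportion_acceptable:.1f}%")
```

prints

```
mean dE00   = 2.84
median dE00 = 2.35
acceptable (< 4.1) = 77.8%
```

i.e. across the example cohort the sitting-vs-supine color difference
averages ΔE₀₀ ≈ 2.8 — well below the 4.1 acceptability threshold — and for
14 of 18 patients (77.8%) the change would be accepted by at least half of
observers: tongue-color diagnosis is largely robust to posture. Running
`python examples/cohort_analysis.py` extends this with the association table
(ΔE₀₀ correlates with fasting plasma glucose, r ≈ 0.55, HbA1c and systolic
blood pressure, |r| ≈ 0.49) and the reference-flag cross-tabulation (13/14
of the acceptable group have ≤ 1 flagged laboratory item; 3/4 of the
non-acceptable group have ≥ 2). `examples/simulate_and_recover.py` shows the
image pipeline recovering known synthetic shifts to ~0.1 ΔE₀₀.

## Command line

The same stages are available as a thin CLI:

```sh
tonguecolor simulate --seed 7 --out cohort/        # synthetic image pairs
tonguecolor segment cohort/S001_sitting.png --out seg/
tonguecolor compare --lab-pairs pairs.csv --out comparison.csv
tonguecolor cohort --lab-pairs pairs.csv --biometrics biom.csv --out report.json
```

## Layout

- `src/tonguecolor/` — library modules: `colorimetry`, `segmentation`,
  `comparison`, `biometrics`, `synthetic`, `io`, `cli`.
- `examples/` — narrative scripts, one per capability.
- `docs/methods.md` — models, parameters, numerical choices, limitations.
- `tests/` — unit, property (hypothesis) and end-to-end acceptance tests.
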
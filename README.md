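# tbiqmri

Multiparametric quantitative MRI analysis for preclinical traumatic
brain injury (TBI), with a built-in digital-phantom cohort generator so
the entire pipeline runs — and is tested — without scanner data.

## The problem

After a focal cortical contusion, secondary injury evolves over hours
to days, and early imaging markers that predict long-term behavioral
outcome are scarce. Amide proton transfer-weighted (APTw) imaging, a
chemical-exchange saturation-transfer contrast sensitive to mobile
protein content and tissue pH, is a candidate: the APTw signal drops
acutely in the injury core and overshoots in the perilesion cortex days
later, tracking neuroinflammation. Quantifying that requires a chain of
reconstructions and statistics: voxel-wise T1/T2/ADC/CBF/APTw/MTR
mapping, region-of-interest (ROI) quantification over seven regions
(injury core; ipsi-/contralateral cortex, hippocampus, thalamus),
contusion volumetry from T2w hyperintensity, and a group/correlation
analysis relating imaging to behavior and histology.

`tbiqmri` implements that chain for single-slice rodent protocols at
4.7 T, plus a phantom cohort generator that emulates the acquisition
(TE 30–90 ms, TI 0.05–3.5 s, b 0–1000 s/mm², ±3.5 ppm and 2 kHz
saturation at 1.3 μT/4 s, 192×192 over 32 mm, Rician noise with per-
sequence averaging) and a severity-graded injury/outcome model.

## The models

Voxel-wise reconstructions (magnitude images):

- T1: I = A + B·exp(−TI/T1), fitted on polarity-restored
  inversion-recovery data (exhaustive null-index search);
- T2: I = I₀·exp(−TE/T2);  ADC: I = I₀·exp(−b·ADC);
- CBF = 6000·(λ/T1)·(S_ctrl − S_lbl)/(2α·S_ctrl) mL/100 g/min
  (λ = 0.9 mL/g, α = 0.8);
- APTw = MTR_asym(3.5 ppm) = 100%·[S(−3.5)/S₀ − S(+3.5)/S₀];
- MTR = 100%·[1 − S_sat(2 kHz)/S₀].

Statistics follow the conventional small-animal design: uncorrected
independent-sample t-tests for sex effects, one-way ANOVA with Tukey's
HSD across sham/mild/moderate/severe, Pearson correlation for
brain–behavior pairs. See `docs/methods.md` for assumptions, defaults,
and limitations.

## Worked example

```bash
python examples/04_group_statistics.py
```

prints, for the default 56-subject synthetic cohort (7 sham / 16 mild /
17 moderate / 16 severe):

```
core APTw @1d, severity ANOVA: F(3, 52) = 272.59, p = 8.81e-32
  Tukey     sham vs mild: diff = +0.51%, adj. p = 1.96e-06
  Tukey     sham vs moderate: diff = +1.53%, adj. p = 5.11e-15
  Tukey     sham vs severe: diff = +2.03%, adj. p = 5.11e-15
core APTw @1d vs mNSS @28d: r = -0.555 (n = 37, p = 3.64e-04); configured r = -0.60
```

Day-1 core APTw falls with injury severity (positive sham-minus-injured
differences, all starred against sham), and across subjects it
correlates negatively with the 28-day modified neurological severity
score — depressed core APTw predicts worse outcome. The sample r of
−0.555 at n = 37 estimates the configured population correlation of
−0.60. The other examples build a phantom (`01`), reconstruct all six
maps for one subject (`02`), measure a 3-mm disk contusion at
42.5 mm³ against the analytic 42.4 mm³ (`03`), and run the whole
pipeline end to end (`05`).

A command-line interface mirrors the stages:

```bash
tbiqmri simulate --config cohort.yaml --out data/ --seed 1
tbiqmri fit --subject data/subjects/SH01/1d --out maps/
tbiqmri roi --maps maps/ --rois data/subjects/SH01/1d/rois.nii --out roi.csv
tbiqmri run-all --config run.yaml --out results/ --seed 1
```

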
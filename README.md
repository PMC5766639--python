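# spfmri

Estimation of microvascular perfusion from multi-b-value
diffusion-weighted MRI via the **simplified perfusion fraction (SPF)**
— a three-b-value surrogate for the IVIM perfusion fraction — together
with the reference methods it is validated against and the full cohort
statistics used for two-group (low/high grade) tumor grading studies:

- **signal_models** — closed-form IVIM biexponential, monoexponential
  and extended Tofts forward models; population AIF; analytic SPF limit
  (the test oracles for everything else).
- **dwi_fitting** — two-point ADC, three-point SPF components
  (`ADC_0_200`, `ADC_200_1000`, `ADC_perf`, `SPF` with the b=200 s/mm²
  cutoff), conventional `ADC_0_1000`, segmented-then-refined IVIM
  fitting, and voxelwise volume fitting to parametric maps.
- **dce_tofts** — bounded multi-start extended Tofts fitting
  (`Ktrans`, `v_e`, `v_p`) of tissue concentration curves.
- **roi_hotspot** — hot-spot ROI extraction (extreme-mean in-plane disc
  within a mask) and ROI propagation across co-registered maps.
- **cohort_stats** — Spearman correlation with Bonferroni control,
  Mann-Whitney U (exact for small tie-free samples), ICC(2,1), ROC with
  Youden-index thresholds, paired DeLong AUC comparison, leave-one-out
  cross-validated accuracy, and a full grading report.
- **synthetic** — Rician-noise DWI phantoms, Gaussian-noise DCE
  phantoms, and two-group cohorts drawn from log-normal distributions
  calibrated in closed form to published group medians/IQRs (shipped in
  `spfmri/data/reference_cohort.yaml`).
- **io / cli** — NIfTI + `.bval` readers/writers with JSON sidecars and
  the `spfmri` command-line interface.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(closed-form identities, noiseless recovery, grid-search and exhaustive
oracles, and Monte-Carlo cohort AUCs at ±0.03).

## CLI

```sh
spfmri simulate dwi    --seed 1 --out sim/          # synthetic DWI phantom
spfmri simulate dce    --seed 1 --out simdce/       # synthetic DCE phantom
spfmri simulate cohort --seed 1 --out cohort/       # calibrated cohort CSV

spfmri fit-dwi --in sim/dwi.nii.gz --bval sim/dwi.bval \
       --method spf --b-cut 200 --out-prefix maps/sub01_
spfmri fit-dce --in simdce/dce.nii.gz --config simdce/dce.json \
       --out-prefix maps/sub01_
spfmri hotspot --map maps/sub01_SPF.nii.gz --mask tumor.nii.gz \
       --radius-mm 5 --mode max --out roi.json
spfmri cohort-stats --table cohort/cohort.csv --out report/
```

Every run writes its resolved configuration (`run_config.json`) next to
its outputs; identical config + seed reproduces identical outputs.

## Conventions

- Diffusion coefficients are mm²/s internally, b-values s/mm², Ktrans
  1/min, times minutes, concentrations mM; the conventional reporting
  scale (×10⁻³ mm²/s, percent) appears only in the calibration file and
  reports.
- `compute_spf` uses exactly the three named b-values (0, b_cut, b_max);
  log-linear range regression is available via `endpoints_only=False`.
- Negative noise-driven `ADC_perf` values are retained (flagged), not
  clipped.
- Masked/unfittable voxels are serialized as NaN and restored as masked.
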
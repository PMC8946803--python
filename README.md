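# hsi-oncopipe

A tested, reusable implementation of an ex vivo near-infrared hyperspectral
tissue-classification pipeline for tumor vs. non-tumor discrimination:
snapshot-mosaic (5×5, 25 bands, 665–975 nm) demosaicing, white/dark
reflectance calibration, per-spectrum min–max normalization, glare/background
masking with tissue-edge erosion, 20×20-pixel patch averaging, histology
annotation registration (HSV thresholding + thin-plate-spline control-point
warp), a 19-feature spectral panel (intensities, band differences, band
ratios), and a class-weighted linear SVM evaluated with leave-one-patient-out
cross-validation (ROC/AUC, Youden operating point, sensitivity, specificity,
PPV, NPV, MCC, and cohort mean-row aggregation).

Because no public imaging data exists for this task, the package ships a
first-class synthetic cohort generator (`hsi_oncopipe.synthetic`) that
emulates the camera (mosaic layout, dark current, non-uniform illumination,
saturated glare, black-paper background) and the histopathology ground truth
(tumor / non-tumor / mixed regions with per-class reflectance spectra that
differ only by a multiplicative amplitude within a class).

## CLI

```bash
# 1. generate a synthetic cohort (raw/white/dark TIFFs, annotation PNGs,
#    control points, manifest)
hsi-oncopipe simulate --out scratch/cohort --n-patients 10 \
    --samples-per-patient 2 --seed 7 --separation 2.0

# 2. run the full pipeline and write the per-patient report
hsi-oncopipe run --cohort scratch/cohort --out scratch/results

# stage-by-stage alternatives
hsi-oncopipe preprocess --cohort scratch/cohort --out scratch/stage
hsi-oncopipe features --patches scratch/stage/patches.csv --out scratch/feat.csv
hsi-oncopipe crossval --features scratch/stage/features.csv --out scratch/cv

# verify the published-table aggregation (totals + mean row)
hsi-oncopipe table-check
```

`run` writes `patches.csv`, `features.csv`, `report.csv` (per-patient rows
plus a Mean row, `-` for undefined cells), `report.json` (with full ROC point
lists), a config snapshot and per-stage pixel/patch accounting.

## Layout

- `src/hsi_oncopipe/bands.py` — band table / mosaic geometry
- `src/hsi_oncopipe/synthetic.py` — synthetic cohort generator
- `src/hsi_oncopipe/preprocessing.py` — demosaic, calibrate, normalize, mask,
  erode, patch-average
- `src/hsi_oncopipe/annotation.py` — HSV masks, TPS registration, patch labels
- `src/hsi_oncopipe/features.py` — 19-feature panel, t-test/AUC screening
- `src/hsi_oncopipe/evaluation.py` — weighted linear SVM, ROC/Youden/MCC,
  leave-one-patient-out CV, mean-row aggregation
- `src/hsi_oncopipe/tables.py` + `data/*.csv` — published per-patient tables
  and exact-decimal aggregation checks
- `src/hsi_oncopipe/pipeline.py`, `cli.py` — orchestration and CLI
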
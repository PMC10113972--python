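# lungquant

Quantification of pulmonary contusion on chest CT, plus the cohort
statistics used to relate contusion burden to respiratory complications.

The pipeline:

1. **CT I/O** — NIfTI volumes or uncompressed DICOM series directories are
   loaded into HU-calibrated `(z, y, x)` volumes with mm spacing. Rescale
   slope/intercept are applied; implausible HU ranges are rejected early.
2. **Segmentation** — total lung by a rule-based surrogate (threshold at
   −250 HU, border-connected air removal, physical-radius closing with hole
   filling, largest-component retention), or an externally supplied
   total-lung mask used verbatim. Functionally normal lung is the HU window
   **[−950, −450]** (inclusive). Pneumothorax is found by a 3D mean filter
   (default 5³): homogeneous pleural air survives smoothing at ≤ −950 HU
   while aerated alveoli are pulled above it; surviving seeds are grown to
   their full raw-air pocket and airway-connected air is excluded.
3. **Volumetrics** — bucket volumes in mL, the contusion-to-total-lung ratio
   in percent, and the severity class (**≤ 20 % moderate, > 20 % severe**).
   Pneumothorax counts with normal lung by default (it re-expands after
   thoracostomy); `ptx_counts_as="contusion"` exposes the alternative
   bookkeeping. P/F ratio and a simplified ARDS flag
   (P/F ≤ 200 + bilateral infiltration + no CHF) are included.
4. **Cohort statistics** — Welch/Student t (raw data or summary statistics),
   exact/asymptotic Mann–Whitney, Pearson chi-square and minimum-likelihood
   Fisher exact tests, empirical ROC with Mann–Whitney AUC and the
   Youden-optimal threshold, the binormal AUC identity, and age adjustment
   by pooled OLS residuals.
5. **Synthetic data** — a thoracic CT phantom generator with exact truth
   masks (aerated lung, GGO/consolidation contusion, pleural air pocket,
   optional airway) and a cohort simulator whose group-conditional
   distributions default to the published summary tables. Both are seeded
   and bit-reproducible.

## CLI

```bash
# synthetic phantom with ground truth
lungquant phantom --out-dir runs/ph --contusion-fraction 25 --pneumothorax-fraction 10 --seed 1

# segment + quantify (accepts an external total-lung mask via --total-mask)
lungquant segment runs/ph/ct.nii --out-dir runs/seg --ptx-counts-as normal

# recompute volumes from saved masks
lungquant quantify --masks-dir runs/seg

# synthetic cohort and the full statistical report
lungquant cohort-simulate --n 73 --seed 7 --out runs/cohort.csv
lungquant cohort-analyze runs/cohort.csv --out runs/report.json --roc-csv runs/roc.csv

# human-readable summary of a run directory
lungquant report runs
```

Every report JSON echoes the HU window, smoothing kernel, pneumothorax
bookkeeping and seed, so runs regenerate bit-identically.

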
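# petquant

Automated brain-PET quantification as a tested Python library and CLI:

* **Automatic reference-region generation** — anatomical label extraction
  (FreeSurfer aseg/aparc numbering), anatomical correction (morphological
  erosion for cerebellar cortex, a lateral-ventricle cut for occipital
  cortex), and exclusion of voxels in the tails of the in-mask radioactivity
  distribution (FWHM bounds of a smoothed intensity density).
* **TAC extraction and SUV conversion** — per-frame in-mask means from 4-D
  NIfTI images, standardized uptake values from injected dose and body mass.
* **Kinetic models** — SRTM (regional NLS and voxelwise basis-function
  parametric maps), Logan and Patlak graphical analyses (plasma and
  reference input), SUV-ratio over a time window, fractional uptake ratio,
  and the regional two-tissue compartment model.
* **Operator-variability statistics** — spatial mask overlap, crossed
  study x operator random-effects variance components and ICCs (REML),
  AUC standardization, distribution descriptors and overlap, relative bias.
* **Synthetic phantoms** — triexponential bolus plasma input, forward
  kinetic models (frame-averaged to emulate scanner binning), 4-D phantoms
  with label volumes and duration-scaled Gaussian noise, and simulated
  multi-operator reference-region masks; this is the ground-truth test bed
  for everything above.

## CLI

```bash
# write default settings for a tracer (carfentanil | raclopride | madam | pib)
petquant config pib --out cfg.yaml

# generate a synthetic phantom (PET + labels + plasma + ground truth)
petquant simulate --out sim/ --seed 1 --noise-scale 0.05

# automatic reference region only
petquant refregion --pet sim/pet.nii.gz --timing sim/timing.tsv \
    --labels sim/labels.nii.gz --config cfg.yaml --out refdir/

# full pipeline: reference region -> TACs -> model -> fits (+ report JSON)
petquant run --pet sim/pet.nii.gz --timing sim/timing.tsv \
    --labels sim/labels.nii.gz --config cfg.yaml --rois 17,18 \
    --out outdir/ --seed 1 [--parametric]

# regional model fit from TAC files
petquant model --tac target.tsv --ref reference.tsv --config cfg.yaml --out fit.json

# voxelwise SRTM parametric maps
petquant parametric --pet sim/pet.nii.gz --timing sim/timing.tsv \
    --refmask refdir/refregion_mask_final.nii.gz --config cfg.yaml --out maps/

# operator-variability evaluation over studies and operators
petquant evaluate --auto-dir auto/ --manual-dir manual/ \
    --config cfg.yaml --out report/
```

Exit codes: 0 success, 2 validation error, 3 numerical failure.

File formats: NIfTI-1 images/masks; frame timing as 2-column TSV
(`frame_start_s`, `frame_end_s`) or Turku SIF; TACs as TSV with a
`# unit:` header line; plasma input as TSV (`t_min`, `activity_kbq_ml`);
configuration as YAML or JSON; run reports as JSON (timestamp-free, so
identical inputs and seed reproduce byte-identical reports).

## Conventions

Internal time unit is minutes (rate constants in 1/min); file timing is in
seconds and converted at the I/O boundary. Images are assumed
decay-corrected; no decay handling occurs anywhere. Preprocessing (motion
correction, coregistration, normalization, smoothing) and FreeSurfer
segmentation are out of scope — the label volume is an input.
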
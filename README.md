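# connforge

Construction of matched structural and functional connectomes from
parcellated MRI volumes, image-derived phenotype (IDP) quality metrics, and
their statistical validation against manual QC ratings.

The package covers the bespoke computational stages that sit downstream of
standard MRI preprocessing (registration, segmentation and tractography are
the caller's job):

- **`connforge.masks`** — tissue-mask refinement (subcortical merge, lesion
  reassignment), parcellation labeling of gray matter, and extraction +
  labeling of the gray-matter/white-matter interface used as tractography
  seed/target masks. ROI centroids and volumes.
- **`connforge.func`** — ROI-mean BOLD time series, Pearson functional
  connectivity, temporal SNR, framewise displacement and FC distribution
  summaries.
- **`connforge.sc`** — structural connectome assembly from streamline-count
  matrices (probability normalization, symmetrization, tract-length
  handling), SC summary metrics and export/import of TheVirtualBrain
  connectivity zip (`weights.txt`, `tract_lengths.txt`, `centres.txt`,
  `hemispheres.txt`, `cortical.txt`).
- **`connforge.pls`** — mean-centered PLS of subject-by-IDP matrices against
  ordinal QC ratings: saliences, design contrasts, singular values, %
  cross-block covariance, permutation p-values and bootstrap ratios
  (Procrustes-aligned, |BSR| ≥ 2 reliability rule).
- **`connforge.report`** — threshold-based pass/fail evaluation of IDPs and
  a self-contained single-file HTML QC report (color-coded IDP table, FC/SC
  heatmaps and histograms, carpet plot, motion trace).
- **`connforge.synth`** — synthetic fixtures with known ground truth: a
  spherical-shell brain phantom with analytic interface and parcellation,
  BOLD with planted ROI correlations, multinomial streamline counts, IDP
  tables with planted latent effects.

## CLI

Every stage is exposed through one `connforge` entry point:

```bash
# synthetic inputs with known ground truth
connforge simulate phantom --shape 24 --parcels 4 --seed 1 --out-dir work/phantom
connforge simulate bold --labeled-gm work/masks/labeled_gm.nii.gz -T 200 --out-dir work/bold
connforge simulate counts --n-rois 8 --streamlines 5000 --out-dir work/tract
connforge simulate idps --groups 5 --n-per-group 20 --effect-size 1.5 --out-dir work/idps

# analysis stages
connforge masks --gm gm.nii.gz --wm wm.nii.gz --parc parc.nii.gz \
    --lut lut.tsv --connectivity 26 --out-dir work/masks
connforge func --bold bold.nii.gz --labeled-gm work/masks/labeled_gm.nii.gz \
    --lut lut.tsv --motion motion.par --out-dir work/func
connforge sc --counts counts.txt --waytotal waytotal.txt --lengths lengths.txt \
    --lut lut.tsv --centroids work/masks/roi_centroids.tsv --out work/conn.zip
connforge pls --idps idps.tsv --n-perm 1000 --n-boot 500 --seed 7 --out-dir work/pls
connforge report --idps idps.json --thresholds thresholds.tsv --out report.html
```

File formats: NIfTI-1 volumes; tab-separated parcellation look-up tables
(`index  name  hemisphere  cortical`, hemisphere in `{L,R,M}`); 6-column
whitespace motion tables (rotations in radians, then translations in mm);
whitespace-delimited count/length matrices with one waytotal entry per seed
ROI; TSV IDP tables with a `rating` column.

## Conventions

- Voxel indices are 0-based; world coordinates follow the NIfTI affine (mm).
- Neighbor connectivity defaults to 26; voxels flagged both GM and WM are
  treated as GM; interface voxels take the majority label of adjacent
  labeled GM voxels, ties toward the smallest label index.
- SC weights = streamline counts / total streamlines successfully sent from
  all seed ROIs (per-seed row normalization available as an option); no
  thresholding is applied.
- PLS: IDP columns are median-imputed, z-scored, averaged per rating group
  and grand-mean-centered before the SVD; permutation p-values use the
  add-one estimator.
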
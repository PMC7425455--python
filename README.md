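# vrfmed

Tested, reusable pipeline linking a composite vascular-risk-factor (VRF)
score to gray-matter atrophy and cognitive decline:

* **`vrfmed.scoring`** — binarize six clinical risk factors (diabetes,
  hypertension, smoking, depression, low education, obesity) and build the
  weighted composite score (unit weights by default; relative-risk weight
  tables are YAML configuration).
* **`vrfmed.synthetic`** — seeded synthetic cohorts (four groups,
  CN/EMCI/LMCI/AD, default sizes 69/52/41/30) and smooth 3D GMV-like NIfTI
  volumes with a known VRF → ROI-atrophy → cognition mediation structure,
  so every downstream stage can be validated against ground truth.
* **`vrfmed.cohort_stats`** — one-way ANOVA (raw and from summary
  statistics), chi-square frequency tests, Bonferroni-corrected post-hoc
  pairwise tests, and partial correlation via residualization.
* **`vrfmed.glm`** — mass-univariate OLS on masked volumes (beta/t/z maps)
  and a voxel-wise ANCOVA partial-F map for group differences.
* **`vrfmed.cluster`** — Monte-Carlo cluster-extent correction: residual
  smoothness (FWHM) estimation, null max-cluster-size simulation, cluster
  extraction, and thresholding.
* **`vrfmed.conjunction`** — conjunction (logical AND) of corrected maps,
  connected-component ROI splitting, and ROI mean extraction.
* **`vrfmed.mediation`** — three-regression mediation (a, b, c, c′) with
  the Sobel test and percentile bootstrap CIs from case resampling; panel
  runner over ROIs × outcomes.
* **`vrfmed.pipeline` / `vrfmed.cli`** — one-config orchestration with a
  hashed reproducibility manifest.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact design
numbers, algebraic identities, oracle equivalences, Monte-Carlo
calibration and end-to-end parameter recovery).

## CLI

```sh
vrfmed simulate --out sim/ --seed 1          # synthetic cohort + images
vrfmed score --cohort sim/cohort.csv --out scored.csv
vrfmed cohort-stats --cohort scored.csv --out stats/
vrfmed glm --images sim/images.txt --mask sim/brain_mask.nii.gz \
           --cohort scored.csv --predictor vrf_score --out maps/
vrfmed clustsim --mask sim/brain_mask.nii.gz --fwhm 6 --pvox 0.01,0.005 \
                --alpha 0.05 --iters 5000 --seed 7 --out table.json
vrfmed conjoin --map-a corrected_vrf.nii.gz --map-b corrected_mmse.nii.gz --out conj/
vrfmed mediate --cohort scored.csv --rois roi_means.csv \
               --outcomes mmse,adascog --nboot 10000 --seed 11 --out mediation.tsv
```

Full pipeline from one YAML config (`vrfmed run --config cfg.yaml`):

```yaml
out_dir: run/
seed: 1
synthetic:
  group_sizes: [69, 52, 41, 30]
  grid_shape: [32, 32, 32]
voxel_p: 0.01
alpha: 0.05
cluster_n_iter: 2000
n_boot: 10000
```

Exit codes: 0 success, 1 configuration error, 2 runtime error.  Every run
writes `manifest.json` with the seed, settings and SHA-256 hashes of all
artifacts; identical configs reproduce identical hashes.

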
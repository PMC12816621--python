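# glycostrat

Glycolysis-based stratification of pancreatic ductal adenocarcinoma (PDAC)
transcriptomes, for computational biologists analyzing single-cell or bulk
expression cohorts. PDAC tumors differ markedly in how strongly their tumor
cells express the glycolytic program, and that difference tracks clinical
behavior. This package implements the full analysis chain around that
observation as a tested, reusable library:

- **Glycolytic scoring** — the per-sample (or per-cell) score is the mean
  normalized expression of a 14-gene glycolytic signature
  (*HK1, HK2, PGAM4, LDHA, SLC2A1, PKM2/PKM, ALDOA, ENO1, ALDOC, GPI,
  PGAM1, GAPDH, TPI1, PKLR*), shipped as a packaged GMT fixture.
- **Stratification** — High/Low at the cohort median (score must strictly
  exceed the median to be High), or Low/Intermediate/High at the tertiles
  of the score distribution.
- **Interpatient heterogeneity** — for cells embedded in a low-dimensional
  space (e.g. UMAP), the statistic is the mean pairwise Euclidean distance
  between per-patient centroids
  `D = mean_{i<j} ||c_i - c_j||`, tested against a null built by uniformly
  shuffling patient labels across cells (n = 1000 shuffles); the empirical
  p is the fraction of shuffled statistics ≥ the observed one.
- **Hypoxia signature** — intersection of tumor-upregulated genes with
  HIF-1α transcriptional targets; scored as the per-sample median
  expression of the intersection.
- **Molecular subtype** — Basal-like vs Classical, by argmax of the two
  published signatures' mean expression per sample.
- **Cohort statistics** — glycolytic-group associations with categorical
  clinical/molecular variables (chi-square + Fisher's exact, small-sample
  chooser, 4-decimal reporting, significance ranking), Benjamini–Hochberg
  FDR adjustment, and 3-year overall survival (administrative censoring at
  36 months, Kaplan–Meier per group, log-rank test, Cox trend test on the
  ordered group code).
- **ROI quality control** — the seven strict sequencing thresholds for
  spatial-profiling regions of interest (reads > 1000, aligned > 80%,
  saturation > 50%, minimum negative-control counts > 5, no-template
  control counts < 3000, nuclei > 100, area > 1000 µm²).
- **Synthetic data** — generators for patient-clustered embeddings,
  single-cell matrices with planted glycolytic programs, survival cohorts
  with a score-modulated hazard, and ROI QC records, so every stage is
  testable end to end with known ground truth.

## Worked example

```python
import glycostrat as g

cfg = g.SimConfig(n_patients=10, cells_per_patient=100, embed_dim=2,
                  between_sd=5.0, within_sd=0.5, seed=1)
coords, labels = g.gen_embedding(cfg)
cells = g.CellTable([f"c{i}" for i in range(len(labels))], labels, coords)
res = g.permutation_test(cells, n_perm=1000, seed=1)
print(res.observed, res.null_stats.mean(), res.p_empirical)
```

prints

```
7.3660456435283415 0.6859562606020868 0.0
```

The observed mean intercentroid distance (7.37) dwarfs the mean of the
label-shuffled null (0.69); none of the 1000 shuffles reaches it, so the
empirical p is 0 (< 0.001): the patients occupy genuinely distinct regions
of the embedding. The `examples/` directory has one short narrative script
per capability (scoring + stratification, the permutation test, survival +
associations, ROI QC + hypoxia scoring); each builds a small synthetic
input, runs the method, and explains what the printed numbers mean.

A thin CLI mirrors the library for shell-driven runs:

```bash
glycostrat simulate --n-patients 6 --glyco-shift 4 --seed 1 --out-dir sim/
glycostrat heterogeneity sim/cells.tsv --n-perm 1000 --seed 1 --out het.json
glycostrat run --config run.yaml   # full score → stratify → test pipeline
```

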
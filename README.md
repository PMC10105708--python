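# absp — brainstem neuromelanin and iron MRI quantification

`absp` is a 3D atlas-based segmentation and quantification pipeline for
paired neuromelanin-sensitive (NM-MRI) and iron-sensitive (SWI) brain MRI.
It targets the brainstem nuclei that degenerate in Parkinson's disease —
the substantia nigra pars compacta (SNc) and locus coeruleus (LC), which
lose neuromelanin, and the substantia nigra and red nucleus (RN), which
carry iron — and turns each subject's image pair into per-structure,
per-side, per-sequence measures, topographic profiles and group-level
diagnostics. It is written for imaging researchers studying idiopathic
and genetically determined (e.g. LRRK2 G2019S) parkinsonism.

Two read-outs drive everything:

* **contrast ratio** — `CR = (μ_S − μ_BS) / μ_BS`, the relative intensity
  of a structure's signal voxels against a brainstem reference mean;
  iron CRs are sign-inverted so larger always means more iron;
* **normalized volume** — `nVol = V_S / V_GM`, the structure's signal
  volume over the subject's total gray-matter volume.

Signal voxels are the hyperintense (NM) or hypointense (iron) voxels of
the segmented structure, thresholded at `μ_BS ± 2σ_BS`.

The pipeline stages (each usable alone, library or `absp` CLI):

| stage | module | what it does |
|---|---|---|
| phantom | `absp.phantom` | synthetic NM/iron cohorts with exact ground truth |
| image core | `absp.image` | volumes, masks, NIfTI I/O, transforms, Dice |
| segmentation | `absp.atlas` | multi-atlas registration + majority-vote label fusion, leave-one-out QC |
| alignment | `absp.alignment` | rigid NM–iron registration, SNc/SNr partition of the SN iron deposit |
| quantification | `absp.quantify` | CR and nVol per structure/side/sequence |
| topography | `absp.topography` | elliptical-cylinder SNc quadrants, probabilistic maps, L/R asymmetry |
| statistics | `absp.robust_stats` | trimmed-mean ANOVAs, bootstrap post hocs, robust d, Huber regression, shadow-feature selection |
| diagnostics | `absp.diagnostics` | ROC / logistic model ladder with bootstrap AUC CIs |
| orchestration | `absp.pipeline` | end-to-end phantom study with tidy CSV outputs |

Since no patient imaging data are publicly deposited for this problem,
the package ships a first-class synthetic-cohort generator whose ground
truth (contrast, volume, asymmetry, inter-sequence rigid offset) is exact
by construction; every downstream stage is validated against it. See
`docs/methods.md` for the model and its limits.

## Worked example

Clinical-table comparisons are recomputed directly from printed counts —
REM-sleep behavior disorder (RBD) in 24/39 iPD vs 6/24 LRRK2 patients,
and sex across the three groups:

```python
>>> from absp.robust_stats import pearson_chi2, kruskal_wallis, counts_to_coded_samples
>>> r = pearson_chi2([[24, 15], [6, 18]])
>>> print(f"RBD: chi2 = {r.statistic:.2f}, df = {r.df:.0f}, p = {r.p:.4f}")
RBD: chi2 = 7.95, df = 1, p = 0.0048
>>> h = kruskal_wallis(counts_to_coded_samples([(17, 15), (17, 22), (14, 10)]))
>>> print(f"Sex: H = {h.statistic:.2f}, p = {h.p:.2f}")
Sex: H = 1.41, p = 0.49
```

The chi-square of 7.95 (p < 0.01) says RBD is far more prevalent in
idiopathic PD than in LRRK2 carriers; sex is balanced across groups.

Quantifying a synthetic iPD subject against its own ground-truth masks
(noise SD 2.0, subject-specific anatomy):

```python
>>> from absp.phantom import PhantomSpec, build_template_geometry, \
...     default_signatures, synthesize_subject
>>> from absp.pipeline import measure_against_truth
>>> spec = PhantomSpec(noise_sd=2.0, deform_amplitude=0.5, rng_seed=0)
>>> template = build_template_geometry(spec)
>>> subject = synthesize_subject(template, default_signatures()["iPD"], spec, 42)
>>> table = measure_against_truth(subject).reset_index()
>>> print(table[table.side == "both"][["sequence", "structure", "cr", "cr_true",
...       "nvol", "nvol_true"]].round(4).to_string(index=False))
sequence structure     cr  cr_true   nvol  nvol_true
      NM       SNc 0.1881   0.1901 0.0003     0.0003
      NM        LC 0.1577   0.1571 0.0001     0.0001
    iron       SNc 0.1196   0.1182 0.0005     0.0005
    iron       SNr 0.1188   0.1182 0.0008     0.0008
    iron        SN 0.1191   0.1182 0.0013     0.0013
    iron        RN 0.1292   0.1286 0.0004     0.0004
```

Measured CRs recover the prescribed per-subject truths to ~1% at this
noise level (exactly, on noiseless phantoms), and the normalized volumes
match to within a voxel. This iPD subject shows the expected pattern:
reduced SNc NM contrast and volume, elevated iron.

A full study — generate a cohort, build an atlas, segment, align,
quantify, and run the statistics and ROC ladder — is one call:

```sh
absp run --out results/study --seed 0
```

which writes `measures.csv`, `loo_qc.csv`, `group_tests.csv`, `roc.csv`,
`asymmetry.csv` and a markdown report into `results/study/`.

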
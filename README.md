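# csfomics

Multi-omics biomarker discovery and honest validation for small
two-class CSF cohorts.

## The problem

A first demyelinating episode (clinically isolated syndrome, CIS) leads
to clinically defined multiple sclerosis — a second attack — in only
some patients. Predicting who converts, from cerebrospinal fluid taken
at onset, means classifying a cohort of a few dozen patients profiled
on thousands of features (clinical chemistry, ¹H-NMR metabolomics,
aptamer-based proteomics). At that sample-to-feature ratio a naive
analysis can report 70%+ accuracy on pure noise. This package
implements the analysis stack for that setting with the guard rails
built in:

* **OPLS-DA** (NIPALS orthogonal signal correction) fit from first
  principles, with R²Y, Q² (internal stratified 7-fold CV), scores,
  loadings, and projection VIP;
* **Ensemble external validation**: per iteration, classes are balanced
  by undersampling, a stratified 90/10 split is drawn, the model is fit
  on the training portion and scored on held-out samples; repeated 1000
  times and compared against a label-permuted ensemble (expected
  accuracy 50%) with a two-sample Kolmogorov–Smirnov test;
* **Elastic-net prefiltering** of the protein block inside each
  iteration, tuned by stratified 7-fold CV over a (α, λ) grid;
* **Diagnostics**: Welch t / chi-square screens with Bonferroni
  correction, empirical ROC with DeLong 95% CI, max-accuracy
  thresholds, and diagnostic odds ratios
  OR = (TP·TN)/(FN·FP) with the Haldane–Anscombe +0.5 correction when
  a cell is empty;
* **NMR utilities**: 0.02-ppm spectral binning over 0.83–8.47 ppm with
  water-region (4.13–5.22 ppm) exclusion, absolute quantification
  against a 1 mM maleic acid internal standard
  (conc = (A_met/H_met)/(A_ref/H_ref)·c_ref), Bland–Altman method
  agreement;
* **Panel search**: every 1–6 variable combination of a candidate
  shortlist pushed through the same validator with paired resampling
  seeds, ranked by pooled held-out AUC, with a no-further-gain
  stopping rule;
* **Synthetic cohorts** with the statistical structure of a 22 vs 32
  CIS cohort (calibrated clinical chemistry, ~50 Gaussian metabolites,
  log-normal proteins with planted informative features, Lorentzian
  spectra) for calibration studies and tests.

See `docs/methods.md` for the model details, numerical conventions and
known limitations.

## Worked example

End-to-end on a desk-scale synthetic cohort (22 converters vs 32
non-converters; 4 modest metabolite effects; 8 informative proteins out
of 200):

```python
from csfomics import CohortConfig, RunConfig, run_pipeline
from csfomics.selection import ElasticNetConfig

cfg = RunConfig(
    seed=17,
    outdir="demo/run",
    cohort=CohortConfig(
        n_proteins=200, n_informative_proteins=8, protein_effect=1.5,
        metabolite_effects={"myo-inositol": 0.8, "glucose": 0.6,
                            "lactate": 0.5, "creatine": -0.5},
        seed=17,
    ),
    n_iter=150, n_perm=150, shortlist_cap=9, k_min=1, k_max=3,
    search_n_iter=60, final_n_iter=300, search_budget=500,
    elastic_net=ElasticNetConfig(alpha_grid=(1.0,), n_lambda=15),
)
report = run_pipeline(cfg)
print(report)
```

Output (abridged; ~3 minutes on one core):

```text
panel            : ['PROT_0028', 'PROT_0104', 'PROT_0114']
panel_auc        : 0.980
panel_accuracy   : 0.824
ks_p_blocks      : chemistry 9.9e-05 | metabolite 1.00 | protein 1.9e-10
panel_ks_p       : 5.9e-35
```

Reading it: the clinical chemistry block (elevated leukocyte and
mononuclear counts in converters) and the elastic-net-filtered protein
block each beat their permutation nulls decisively; the metabolite
block's four sub-SD effects are drowned among 50 features at this
cohort size (ensemble accuracy 0.53, KS p ≈ 1 — the validator saying
"no evidence", which is the correct answer here); and the selected
3-protein panel reaches pooled held-out AUC 0.98 at 82% mean held-out
accuracy — all three panel members are genuinely informative features
planted by the generator. Per-block artifacts (screen table, ensemble
summaries and per-iteration CSVs, shortlist, ranked panels, final
marker report) land in `demo/run/`, each stamped with the config hash
and seed; re-running the same config reproduces them bit-identically.

The same stages are exposed as a CLI:

```bash
csfomics simulate --seed 17 --out matrix.csv --blocks blocks.tsv
csfomics screen   --matrix matrix.csv --blocks blocks.tsv --out screen.csv
csfomics validate --matrix matrix.csv --n-iter 1000 --n-perm 1000 --seed 17 --out val.json
csfomics select   --matrix proteins.csv --folds 7 --seed 17
csfomics search   --matrix matrix.csv --candidates shortlist.txt --kmax 6 --seed 17 --out panels.csv
csfomics bin      --spectrum spec.csv --out bins.csv --lo 0.83 --hi 8.47 --width 0.02 --exclude 4.13:5.22
csfomics run      --config run.yaml
```

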
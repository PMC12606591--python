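# fixelharm

Empirical-Bayes (ComBat) harmonisation of fixel-based diffusion-MRI
metrics across sites, scanner models, and acquisition protocols — with the
evaluation statistics to verify that scanner effects are removed while
biology is preserved, and a synthetic fixel-data generator so the whole
claim is testable without any imaging download.

## Who this is for

Fixel-based analysis (FBA) measures white-matter fibre populations per
*fixel* — fibre density (FD), log fibre cross-section (logFC), and their
product (FDC).  In multi-site studies these metrics shift by 8–15% between
scanner models and protocols, easily swamping disease effects.  `fixelharm`
is for researchers pooling FBA data across scanners: it reads the fixel
directory format (NIfTI-1 dialect), removes additive and multiplicative
batch effects per fixel, and writes harmonised data back so the FBA
pipeline can continue.

## The model

Each fixel f is an independent feature.  For scan j in batch i:

    Y_ijf = α_f + X_ij β_f + σ_f (γ_if + δ_if ε_ijf),   ε ~ N(0, 1)

with biological covariates X (age, sex, ICV) preserved, and batch location
γ and scale δ shrunk across fixels by parametric empirical Bayes
(normal prior for γ, inverse-gamma for δ²; hyperparameters by moment
matching; shrinkage by fixed-point iteration).  Harmonised values:

    Y*_ijf = σ̂_f (Z_ijf − γ*_if) / δ*_if + α̂_f + X_ij β̂_f,
    Z_ijf = (Y_ijf − α̂_f − X_ij β̂_f) / σ̂_f

Full details, conventions, and limitations: [docs/methods.md](docs/methods.md).

## Worked example

Simulate 23 subjects each scanned on two scanner models (one shifting FD by
~10% of baseline), harmonise, and measure the arm difference on the fixels
where it is family-wise-error significant:

```bash
python examples/01_travelling_subject_harmonisation.py
```

```
fixels: 998, FWE-significant arm differences: 687
mean |%diff| on significant fixels, before: 12.18%
mean |%diff| on the same fixels, after:    1.18%
```

The 12% pre-harmonisation difference is the injected scanner effect plus
noise; after harmonisation the same fixels differ by ~1%, i.e. the scanner
effect is gone.  The other examples show a case–control cohort whose tract
effect size is restored from d = 1.33 to d = 2.49 (confound-free value
2.47), and a cognition regression whose R² rises from 0.66 to 0.83 once
scanner noise stops diluting the FD measurement:

```bash
python examples/02_case_control_effect_size.py
python examples/03_cognitive_regression.py
```

## Command line

The same pipeline as composable commands (see `--help` on each):

```bash
fixelharm simulate config.yaml out/            # synthetic fixel dataset
fixelharm harmonize out/fixels out/covariates.csv --method eb \
    --covariates age,sex,icv                   # writes <scan>_combat.nii.gz
fixelharm evaluate pctdiff|permtest|effectsize|regress|batchvar ...
```

Inputs are a fixel directory (`index.nii[.gz]`, `directions.nii[.gz]`, one
`M×1×1` scalar image per scan) and a covariate CSV with columns
`subject_id, batch, age, sex, icv, datafile` (optional `group`, `mmse`,
`moca`).  Sex is accepted as M/F or 0/1 and stored as an F=1 indicator;
fixel indices and offsets are 0-based.

## Library surface

```python
import fixelharm as fh

template = fh.read_fixel_template("fixels/")
covars = fh.read_covariates("covariates.csv")
Y = fh.assemble_matrix(template, covars, "fixels/")
harmonised, model = fh.harmonize(Y, covars, method="eb")
model.save("combat_model.zip")      # reusable on held-out scans
```

Evaluation: `paired_permutation_test` (sign-flip, max-statistic FWE),
`group_permutation_test`, `percentage_difference`, `cohens_d`, `tract_mean`,
`ols_bootstrap`, `batch_variability_summary`.  Simulation:
`make_template`, `simulate_travelling`, `simulate_case_control`,
`export_dataset` — all deterministic given seeds, with ground truth retained.

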
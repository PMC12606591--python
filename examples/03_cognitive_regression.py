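"""Association between tract fibre density and cognition, with bootstrap.

Cognitive scores in the simulation are driven by the biological tract-mean
FD, so scanner noise attenuates the measured association; harmonisation
recovers it.  The regression adjusts for age, sex, and ICV and reports a
percentile bootstrap 95% CI for R².
"""

import fixelharm as fh
from fixelharm.evaluation import ols_bootstrap

template = fh.make_template((8, 8, 4), (1, 3), seed=11)
config = fh.SimulationConfig(mode="case_control", seed=11)
ds = fh.simulate_case_control(template, config)
tract = ds.truth.tract_label

df = ds.covariates.df.copy()
df["ad"] = (df["group"] == "AD").astype(int)
covars = fh.CovariateTable(df)
harmonised, _ = fh.harmonize(ds.Y, covars,
                             covariate_columns=("age", "sex", "icv", "ad"),
                             method="eb")

mmse = ds.covariates.df["mmse"].to_numpy(float)
adjust = ds.covariates.df[["age", "sex", "icv"]].to_numpy(float)

for label, Y in (("before", ds.Y.Y), ("after", harmonised.Y)):
    res = ols_bootstrap(mmse, Y[:, tract].mean(axis=1), adjust,
                        n_boot=2000, seed=11)
    print(f"MMSE ~ tract FD, {label} harmonisation: "
          f"coefficient={res.coefficient:.1f}, p={res.pvalue:.2g}, "
          f"R2={res.r_squared:.3f}, 95% CI [{res.ci95[0]:.3f}, {res.ci95[1]:.3f}]")
# the coefficient (score points per unit FD) and R2 rise after
# harmonisation because scanner noise no longer dilutes the FD measurement
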
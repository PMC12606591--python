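"""Recover a disease effect masked by scanner differences.

Simulates an AD/CN cohort on six scanner models whose effects are
confounded with the group mix, with a 15% fibre-density reduction confined
to a labelled tract.  Harmonisation (preserving age, sex, ICV, and group)
restores the tract Cohen's d toward its confound-free value.
"""

import fixelharm as fh

template = fh.make_template((8, 8, 4), (1, 3), seed=7)
config = fh.SimulationConfig(mode="case_control", seed=7)
ds = fh.simulate_case_control(template, config)

tract = ds.truth.tract_label
grp = ds.covariates.df["group"].to_numpy()


def tract_d(Y):
    tm = Y[:, tract].mean(axis=1)
    return fh.cohens_d(tm[grp == "CN"], tm[grp == "AD"])  # CN - AD: positive


df = ds.covariates.df.copy()
df["ad"] = (df["group"] == "AD").astype(int)
covars = fh.CovariateTable(df)
harmonised, _ = fh.harmonize(ds.Y, covars,
                             covariate_columns=("age", "sex", "icv", "ad"),
                             method="eb")

print(f"tract Cohen's d (CN - AD), before harmonisation: {tract_d(ds.Y.Y):.3f}")
print(f"tract Cohen's d, after harmonisation:            {tract_d(harmonised.Y):.3f}")
print(f"tract Cohen's d, confound-free counterfactual:   {tract_d(ds.confound_free_Y()):.3f}")
# scanner variance and the confounded scanner mix suppress d before
# harmonisation; afterwards d approaches the value the cohort would show
# had all subjects been scanned identically
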
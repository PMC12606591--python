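import numpy as np
import pandas as pd
import pytest

from fixelharm import CovariateTable, FixelDataMatrix, make_template


@pytest.fixture
def tiny_template():
    """2x1x1 grid with counts (2, 1): the smallest consistent template."""
    import fixelharm

    dirs = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
    return fixelharm.FixelTemplate(
        grid_shape=(2, 1, 1),
        affine=np.eye(4),
        counts=np.array([[[2]], [[1]]], dtype=np.int64),
        offsets=np.array([[[0]], [[2]]], dtype=np.int64),
        directions=dirs,
    )


@pytest.fixture
def random_template():
    return make_template((4, 3, 2), (1, 3), seed=13)


def make_covariates(batch_labels, rng=None, extra=None):
    """Covariate table with random age/sex/icv for the given batch labels."""
    rng = rng or np.random.default_rng(0)
    n = len(batch_labels)
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "batch": batch_labels,
            "age": rng.uniform(20, 80, n),
            "sex": rng.integers(0, 2, n),
            "icv": rng.normal(1.5e6, 1e5, n),
            "datafile": [f"s{i}.nii.gz" for i in range(n)],
        }
    )
    if extra:
        for k, v in extra.items():
            df[k] = v
    return CovariateTable(df)


def random_instance(rng, n_per_batch=(4, 5), m=4, with_covariates=True):
    """A small random two-batch dataset for oracle comparisons.

    ICV is expressed in litres here so the design stays well conditioned and
    two independent least-squares code paths agree to tight tolerances.
    """
    labels = sum([[f"b{k}"] * n for k, n in enumerate(n_per_batch)], [])
    n = len(labels)
    covars = CovariateTable(
        pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "batch": labels,
                "age": rng.uniform(20, 80, n),
                "sex": rng.integers(0, 2, n),
                "icv": rng.normal(1.5, 0.1, n),
                "datafile": [f"s{i}.nii.gz" for i in range(n)],
            }
        )
    )
    Y = rng.normal(0.5, 0.2, size=(n, m)) + rng.normal(0, 0.1, size=(n, 1))
    cols = ("age", "sex", "icv") if with_covariates else ()
    return FixelDataMatrix(Y=Y, scan_ids=list(covars.df["datafile"]), metric="FD"), covars, cols


def direct_combat_oracle(Y, batch_labels, X):
    """Independent per-fixel location-scale adjustment (scalar code path).

    Fits each fixel separately with statsmodels OLS under treatment coding
    of the batch factor, converts to the weighted sum-to-zero
    parametrisation, standardizes, and removes each batch's mean and scale
    (pooled-divisor variance).  Used as the oracle for the vectorised
    one-hot implementation.
    """
    import statsmodels.api as sm

    Y = np.asarray(Y, dtype=float)
    n, m = Y.shape
    labels = list(dict.fromkeys(batch_labels))  # first-appearance order
    codes = np.array([labels.index(b) for b in batch_labels])
    B = len(labels)
    n_i = np.array([(codes == b).sum() for b in range(B)])
    q = 0 if X is None else X.shape[1]
    out = np.empty_like(Y)
    for f in range(m):
        dummies = np.zeros((n, B - 1))
        for b in range(1, B):
            dummies[codes == b, b - 1] = 1.0
        cols = [np.ones(n), *dummies.T]
        if q:
            cols += [X[:, j] for j in range(q)]
        D = np.column_stack(cols)
        fit = sm.OLS(Y[:, f], D).fit()
        a0 = fit.params[0]
        d = np.concatenate([[0.0], fit.params[1 : B]])
        beta = fit.params[B:] if q else np.zeros(0)
        shift = float(np.dot(n_i, d) / n)
        alpha = a0 + shift
        loc = alpha + (X @ beta if q else 0.0)
        sigma = np.sqrt(np.mean(fit.resid**2))
        z = (Y[:, f] - loc) / sigma
        for b in range(B):
            zb = z[codes == b]
            g = zb.mean()
            scale = np.sqrt(np.mean((zb - g) ** 2))
            out[codes == b, f] = sigma * (z[codes == b] - g) / scale + (
                loc[codes == b] if q else loc
            )
    return out
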
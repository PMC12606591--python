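"""ComBat location–scale harmonisation for fixel-wise metrics.

Each template fixel f is treated as an independent feature.  A metric value
for scan j in batch i (site, scanner model, or protocol) is modelled as

    Y_{i,j,f} = alpha_f + X_{i,j} beta_f + sigma_f * (gamma_{i,f}
                + delta_{i,f} * eps_{i,j,f}),      eps ~ N(0, 1)

where alpha_f is the overall fixel mean, beta_f the coefficients of the
biological covariates X (age, sex, ICV by default), and gamma_{i,f} /
delta_{i,f} are additive and multiplicative batch effects expressed on the
standardized (residual-SD) scale.  Identifiability uses the sample-size
weighted constraint sum_i n_i gamma_{i,f} = 0, which makes alpha_f the pooled
mean of the covariate-adjusted data.

Batch-effect estimates are stabilised by borrowing strength across fixels
with parametric empirical-Bayes priors: gamma_{i,.} ~ N(gamma_bar_i, tau2_i)
and delta2_{i,.} ~ InverseGamma(lambda_i, theta_i), the hyperparameters
estimated by moment matching over fixels.  The shrunken estimates
(gamma_star, delta_star) solve the coupled conditional-posterior-mean
equations by fixed-point iteration.  Harmonised values are

    Y*_{i,j,f} = sigma_f * (Z_{i,j,f} - gamma_star_{i,f}) / delta_star_{i,f}
                 + alpha_f + X_{i,j} beta_f

with Z the standardized residual.  ``method="direct"`` skips shrinkage and
uses the raw per-batch estimates.

Conventions chosen for internal consistency (documented in the methods note):
sigma_f^2 uses divisor N; per-batch delta2_hat uses divisor n_i.  With these
divisors a single-batch dataset is returned exactly unchanged.
"""

from __future__ import annotations

import json
import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .errors import DesignError, NumericalError, ValidationError
from .fixel_io import CovariateTable, FixelDataMatrix, eligible_fixel_mask

logger = logging.getLogger(__name__)

EB_TOL = 1e-4
EB_MAX_ITER = 100
_CONDITION_WARN = 1e8

DEFAULT_COVARIATES = ("age", "sex", "icv")


@dataclass
class CombatModel:
    """Fitted ComBat model: per-fixel GLM, batch estimates, EB shrinkage.

    Arrays are length-M (fixels) or B×M (batches × fixels); unmasked fixels
    carry placeholder values and are never used in the adjustment.
    """

    alpha: np.ndarray  # (M,) overall fixel mean, metric units
    beta: np.ndarray  # (p, M) covariate coefficients
    sigma: np.ndarray  # (M,) residual SD, divisor N
    gamma_hat: np.ndarray  # (B, M) standardized additive batch estimates
    delta2_hat: np.ndarray  # (B, M) multiplicative batch estimates (divisor n_i)
    gamma_star: np.ndarray  # (B, M) EB-shrunken
    delta_star: np.ndarray  # (B, M) EB-shrunken scale (SD, > 0 on mask)
    gamma_bar: np.ndarray  # (B,) prior means
    tau2: np.ndarray  # (B,) prior variances
    lambda_: np.ndarray  # (B,) inverse-gamma shape
    theta: np.ndarray  # (B,) inverse-gamma scale
    batch_levels: list[str]
    batch_sizes: np.ndarray  # (B,)
    covariate_names: list[str]
    mask: np.ndarray  # (M,) bool
    method: str  # "eb" | "direct"
    eb_converged: np.ndarray = field(default=None)  # type: ignore[assignment]  # (B, M) bool
    eb_direct_fallback: np.ndarray = field(default=None)  # type: ignore[assignment]  # (B,) bool

    @property
    def n_batches(self) -> int:
        return len(self.batch_levels)

    # -- serialization -------------------------------------------------------

    def save(self, path) -> None:
        """Serialize all arrays plus a JSON sidecar into one zip archive."""
        path = Path(path)
        arrays = {
            k: getattr(self, k)
            for k in (
                "alpha", "beta", "sigma", "gamma_hat", "delta2_hat",
                "gamma_star", "delta_star", "gamma_bar", "tau2", "lambda_",
                "theta", "batch_sizes", "mask", "eb_converged",
                "eb_direct_fallback",
            )
        }
        meta = {
            "batch_levels": self.batch_levels,
            "covariate_names": self.covariate_names,
            "method": self.method,
            "eb_tol": EB_TOL,
            "eb_max_iter": EB_MAX_ITER,
            "version": __version__,
        }
        with zipfile.ZipFile(path, "w") as zf:
            import io

            buf = io.BytesIO()
            np.savez(buf, **{k: np.asarray(v) for k, v in arrays.items()})
            zf.writestr("arrays.npz", buf.getvalue())
            zf.writestr("meta.json", json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "CombatModel":
        with zipfile.ZipFile(Path(path), "r") as zf:
            import io

            with zf.open("arrays.npz") as fh:
                arrays = dict(np.load(io.BytesIO(fh.read())))
            meta = json.loads(zf.read("meta.json"))
        return cls(
            alpha=arrays["alpha"],
            beta=arrays["beta"],
            sigma=arrays["sigma"],
            gamma_hat=arrays["gamma_hat"],
            delta2_hat=arrays["delta2_hat"],
            gamma_star=arrays["gamma_star"],
            delta_star=arrays["delta_star"],
            gamma_bar=arrays["gamma_bar"],
            tau2=arrays["tau2"],
            lambda_=arrays["lambda_"],
            theta=arrays["theta"],
            batch_levels=list(meta["batch_levels"]),
            batch_sizes=arrays["batch_sizes"],
            covariate_names=list(meta["covariate_names"]),
            mask=arrays["mask"].astype(bool),
            method=meta["method"],
            eb_converged=arrays["eb_converged"].astype(bool),
            eb_direct_fallback=arrays["eb_direct_fallback"].astype(bool),
        )


@dataclass
class StandardizedData:
    """Standardized residuals Z = (Y - alpha - X beta) / sigma (dimensionless)."""

    Z: np.ndarray  # (N, M)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


def _design_matrices(covars: CovariateTable, covariate_columns):
    batch_codes = covars.batch_codes
    levels = covars.batch_levels
    B = len(levels)
    N = len(covars)
    onehot = np.zeros((N, B))
    onehot[np.arange(N), batch_codes] = 1.0
    if covariate_columns:
        X, names = covars.design_covariates(tuple(covariate_columns))
    else:
        X, names = np.empty((N, 0)), []
    return onehot, batch_codes, X, names


def fit_glm(Y: FixelDataMatrix, covars: CovariateTable, covariate_columns=DEFAULT_COVARIATES):
    """Per-fixel least-squares fit of the location model.

    Fits Y on [batch indicators | covariates] jointly, then re-expresses the
    batch coefficients under the weighted sum-to-zero constraint so that
    alpha is the pooled mean.  Returns ``(alpha, beta, sigma, gamma_hat_raw,
    batch_sizes)`` with gamma_hat_raw on the metric scale and sigma the
    residual SD with divisor N.
    """
    if len(covars) != Y.n_scans:
        raise ValidationError("covariate rows do not match data rows")
    onehot, batch_codes, X, names = _design_matrices(covars, covariate_columns)
    N, M = Y.Y.shape
    B = onehot.shape[1]
    p = len(names)
    if N <= p + B:
        raise ValidationError(
            f"need more scans ({N}) than design columns ({p + B}) to fit the model"
        )
    design = np.hstack([onehot, X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        cols = [f"batch:{lv}" for lv in covars.batch_levels] + list(names)
        raise DesignError(
            "rank-deficient design (batch confounded with a covariate?); "
            f"columns: {cols}"
        )
    cond = np.linalg.cond(design)
    if cond > _CONDITION_WARN:
        logger.warning(
            "design matrix poorly conditioned (cond=%.2e); consider rescaling "
            "covariates such as ICV", cond,
        )
    coef, *_ = np.linalg.lstsq(design, Y.Y, rcond=None)
    batch_coef = coef[:B]  # (B, M) per-batch intercepts, metric scale
    beta = coef[B:]  # (p, M)
    n_i = onehot.sum(axis=0)  # (B,)
    alpha = (n_i / N) @ batch_coef  # pooled mean intercept
    gamma_hat_raw = batch_coef - alpha  # weighted sum-to-zero by construction
    resid = Y.Y - design @ coef
    sigma = np.sqrt(np.mean(resid**2, axis=0))  # divisor N
    return alpha, beta, sigma, gamma_hat_raw, n_i.astype(int)


def standardize(Y: FixelDataMatrix, alpha, beta, sigma, covars: CovariateTable,
                covariate_columns=DEFAULT_COVARIATES) -> StandardizedData:
    """Remove the fitted location model and rescale to unit residual SD.

    On masked fixels ``Z = (Y - alpha - X beta) / sigma``; the inverse
    transform reconstructs Y exactly.  Unmasked fixels (sigma may be 0 there)
    get Z = 0.
    """
    _, _, X, _ = _design_matrices(covars, covariate_columns)
    loc = alpha[None, :] + X @ beta
    sigma_safe = np.where(Y.mask & (sigma > 0), sigma, 1.0)
    if np.any(Y.mask & (sigma == 0)):
        raise NumericalError("zero residual SD on a masked fixel")
    Z = (Y.Y - loc) / sigma_safe[None, :]
    Z[:, ~Y.mask] = 0.0
    return StandardizedData(Z=Z)


def batch_moments(Z: np.ndarray, batch_codes: np.ndarray):
    """Raw per-batch location and scale of the standardized data.

    gamma_hat[i, f] is the batch mean of Z; delta2_hat[i, f] the batch
    variance with divisor n_i (so a single batch has delta2_hat = 1 exactly
    given the divisor-N pooled sigma).
    """
    codes = np.unique(batch_codes)
    B = codes.size
    M = Z.shape[1]
    gamma_hat = np.zeros((B, M))
    delta2_hat = np.ones((B, M))
    for b, code in enumerate(codes):
        rows = Z[batch_codes == code]
        gamma_hat[b] = rows.mean(axis=0)
        delta2_hat[b] = np.mean((rows - gamma_hat[b]) ** 2, axis=0)
    return gamma_hat, delta2_hat


def estimate_hyperparameters(gamma_hat: np.ndarray, delta2_hat: np.ndarray):
    """Moment-matched EB hyperparameters per batch.

    Normal prior on gamma: gamma_bar_i = mean over fixels, tau2_i = variance
    (divisor M-1).  Inverse-gamma prior on delta2 by matching the first two
    moments: with m the mean and V the variance over fixels,
    lambda = (m^2 + 2V) / V and theta = (m^3 + m V) / V.  A batch with V = 0
    has a degenerate prior and is flagged for direct fallback.
    """
    gamma_hat = np.atleast_2d(gamma_hat)
    delta2_hat = np.atleast_2d(delta2_hat)
    if gamma_hat.shape[1] < 3:
        raise ValidationError("need at least 3 fixels to estimate hyperpriors")
    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    m = delta2_hat.mean(axis=1)
    V = delta2_hat.var(axis=1, ddof=1)
    fallback = V == 0
    V_safe = np.where(fallback, 1.0, V)
    lambda_ = (m**2 + 2 * V_safe) / V_safe
    theta = (m**3 + m * V_safe) / V_safe
    if fallback.any():
        logger.warning(
            "degenerate inverse-gamma prior (zero variance of delta2_hat) in "
            "%d batch(es); those batches use the direct estimates", int(fallback.sum()),
        )
    return gamma_bar, tau2, lambda_, theta, fallback


def eb_shrink(Z: np.ndarray, batch_codes: np.ndarray, gamma_hat, delta2_hat,
              gamma_bar, tau2, lambda_, theta,
              tol: float = EB_TOL, max_iter: int = EB_MAX_ITER):
    """Fixed-point iteration for the EB-shrunken batch effects.

    Per batch i and fixel f iterates

        gamma* = (n_i tau2_i gamma_hat + delta*^2 gamma_bar_i)
                 / (n_i tau2_i + delta*^2)
        delta*^2 = (theta_i + 0.5 sum_j (Z - gamma*)^2) / (n_i/2 + lambda_i - 1)

    from (gamma_hat, delta2_hat) until the maximum absolute change drops
    below ``tol`` (or ``max_iter``, flagged per batch×fixel).
    """
    codes = np.unique(batch_codes)
    B, M = gamma_hat.shape
    gamma_star = gamma_hat.copy()
    delta2_star = delta2_hat.copy()
    converged = np.zeros((B, M), dtype=bool)
    for b, code in enumerate(codes):
        rows = Z[batch_codes == code]
        n = rows.shape[0]
        g, d2 = gamma_hat[b].copy(), delta2_hat[b].copy()
        denom_d = n / 2.0 + lambda_[b] - 1.0
        for _ in range(max_iter):
            g_new = (n * tau2[b] * gamma_hat[b] + d2 * gamma_bar[b]) / (
                n * tau2[b] + d2
            )
            sum2 = ((rows - g_new[None, :]) ** 2).sum(axis=0)
            d2_new = (theta[b] + 0.5 * sum2) / denom_d
            if not (np.all(np.isfinite(g_new)) and np.all(np.isfinite(d2_new))):
                bad = np.flatnonzero(~(np.isfinite(g_new) & np.isfinite(d2_new)))[:5]
                raise NumericalError(
                    f"non-finite EB update in batch {code} at fixels {bad.tolist()}"
                )
            change = np.maximum(np.abs(g_new - g), np.abs(d2_new - d2))
            g, d2 = g_new, d2_new
            if np.max(change) < tol:
                converged[b] = True
                break
        else:
            converged[b] = change < tol
            n_bad = int((~converged[b]).sum())
            if n_bad:
                logger.warning(
                    "EB iteration did not converge for %d fixel(s) in batch %s; "
                    "last iterate used", n_bad, code,
                )
        gamma_star[b] = g
        delta2_star[b] = d2
    return gamma_star, np.sqrt(delta2_star), converged


def apply_adjustment(Y: FixelDataMatrix, model: CombatModel, covars: CovariateTable) -> FixelDataMatrix:
    """Back-transform with the shrunken batch effects removed.

    On masked fixels: Y* = sigma (Z - gamma*)/delta* + alpha + X beta;
    unmasked fixels are copied unchanged.
    """
    _, batch_codes, X, _ = _design_matrices(covars, model.covariate_names)
    mask = model.mask
    loc = model.alpha[None, :] + X @ model.beta
    sigma_safe = np.where(mask & (model.sigma > 0), model.sigma, 1.0)
    Z = (Y.Y - loc) / sigma_safe[None, :]
    g = model.gamma_star[batch_codes]  # (N, M)
    d = model.delta_star[batch_codes]
    d_safe = np.where(mask[None, :], d, 1.0)
    out = sigma_safe[None, :] * (Z - g) / d_safe + loc
    out = np.where(mask[None, :], out, Y.Y)
    if not np.all(np.isfinite(out)):
        raise NumericalError("non-finite harmonised values")
    return FixelDataMatrix(Y=out, scan_ids=list(Y.scan_ids), metric=Y.metric, mask=mask.copy())


def _harmonize_single(Y: FixelDataMatrix, covars: CovariateTable,
                      covariate_columns, method: str):
    mask = Y.mask & eligible_fixel_mask(Y.Y, covars.batch_codes)
    Ym = FixelDataMatrix(Y=Y.Y, scan_ids=list(Y.scan_ids), metric=Y.metric, mask=mask)
    alpha, beta, sigma, gamma_raw, n_i = fit_glm(Ym, covars, covariate_columns)
    mask = mask & (sigma > 0)
    Ym.mask = mask
    std = standardize(Ym, alpha, beta, sigma, covars, covariate_columns)
    gamma_hat, delta2_hat = batch_moments(std.Z, covars.batch_codes)
    # a batch scale of 0 would make the adjustment singular
    mask = mask & (delta2_hat > 0).all(axis=0)
    Ym.mask = mask
    B, M = gamma_hat.shape

    if method == "eb":
        mcols = np.flatnonzero(mask)
        gamma_bar, tau2, lambda_, theta, fallback = estimate_hyperparameters(
            gamma_hat[:, mcols], delta2_hat[:, mcols]
        )
        gamma_star = gamma_hat.copy()
        delta_star = np.sqrt(delta2_hat)
        g_s, d_s, conv = eb_shrink(
            std.Z[:, mcols], covars.batch_codes,
            gamma_hat[:, mcols], delta2_hat[:, mcols],
            gamma_bar, tau2, lambda_, theta,
        )
        converged = np.ones((B, M), dtype=bool)
        for b in range(B):
            if fallback[b]:
                continue  # keep direct estimates for degenerate-prior batches
            gamma_star[b, mcols] = g_s[b]
            delta_star[b, mcols] = d_s[b]
            converged[b, mcols] = conv[b]
    elif method == "direct":
        gamma_bar = np.zeros(B)
        tau2 = np.zeros(B)
        lambda_ = np.zeros(B)
        theta = np.zeros(B)
        fallback = np.ones(B, dtype=bool)
        gamma_star = gamma_hat.copy()
        delta_star = np.sqrt(delta2_hat)
        converged = np.ones((B, M), dtype=bool)
    else:
        raise ValidationError(f"unknown method {method!r}; use 'eb' or 'direct'")

    model = CombatModel(
        alpha=alpha, beta=beta, sigma=sigma,
        gamma_hat=gamma_hat, delta2_hat=delta2_hat,
        gamma_star=gamma_star, delta_star=delta_star,
        gamma_bar=gamma_bar, tau2=tau2, lambda_=lambda_, theta=theta,
        batch_levels=covars.batch_levels, batch_sizes=np.asarray(n_i),
        covariate_names=list(covariate_columns), mask=mask, method=method,
        eb_converged=converged,
        eb_direct_fallback=np.asarray(fallback, dtype=bool),
    )
    harmonised = apply_adjustment(Ym, model, covars)
    return harmonised, model


def harmonize(
    Y: FixelDataMatrix,
    covars: CovariateTable,
    covariate_columns=DEFAULT_COVARIATES,
    method: str = "eb",
    group_column: str | None = None,
    clip_negative: bool = False,
):
    """Full harmonisation pipeline: fit, standardize, shrink, adjust.

    Parameters
    ----------
    Y : FixelDataMatrix
        Scans × fixels metric values.
    covars : CovariateTable
        Row-aligned covariates; the table's ``batch`` column defines batches.
    covariate_columns : sequence of str
        Biological covariates preserved by the adjustment.
    method : {"eb", "direct"}
        Empirical-Bayes shrinkage (default) or raw per-batch estimates.
    group_column : str, optional
        Harmonise independently within each level of this column (e.g.
        diagnosis), restacking rows in input order.  A group containing a
        single batch passes through unharmonised with a warning.
    clip_negative : bool
        Clip harmonised values at 0 (off by default; harmonisation can push
        non-negative metrics slightly negative, which is reported).

    Returns
    -------
    (FixelDataMatrix, CombatModel) — or a dict of per-group models when
    ``group_column`` is given.
    """
    if group_column is None:
        harmonised, model = _harmonize_single(Y, covars, covariate_columns, method)
        result_model = model
    else:
        if group_column not in covars.df.columns:
            raise ValidationError(f"group column {group_column!r} not in covariates")
        out = Y.Y.copy()
        mask_all = np.ones(Y.n_fixels, dtype=bool)
        models = {}
        for level, sub_df in covars.df.groupby(group_column, sort=False, observed=True):
            rows = covars.df[group_column] == level
            sub_covars = covars.subset(rows.to_numpy())
            if len(sub_covars.batch_levels) < 2:
                logger.warning(
                    "group %r contains a single batch; left unharmonised", level
                )
                models[level] = None
                continue
            sub_Y = FixelDataMatrix(
                Y=Y.Y[rows.to_numpy()],
                scan_ids=[s for s, r in zip(Y.scan_ids, rows) if r],
                metric=Y.metric,
                mask=Y.mask,
            )
            h, m = _harmonize_single(sub_Y, sub_covars, covariate_columns, method)
            out[rows.to_numpy()] = h.Y
            mask_all &= m.mask
            models[level] = m
        harmonised = FixelDataMatrix(
            Y=out, scan_ids=list(Y.scan_ids), metric=Y.metric, mask=mask_all
        )
        result_model = models

    n_neg = int((harmonised.Y < 0).sum())
    if n_neg and Y.metric in ("FD", "FDC"):
        logger.info("%d harmonised values are negative", n_neg)
    if clip_negative:
        harmonised.Y = np.clip(harmonised.Y, 0.0, None)
    return harmonised, result_model
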
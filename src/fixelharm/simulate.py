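"""Synthetic fixel datasets with controlled multi-scanner batch effects.

Two study designs are emulated:

* **Travelling-subject (TS)**: the same participants are scanned under two
  conditions (scan–rescan at one site, or pairs of sites / scanner models /
  protocols), so the expected biological difference between arms is zero and
  any systematic arm difference is measurement bias.
* **Case–control**: two diagnostic groups (AD / CN) scanned on several
  scanner models, with a group effect restricted to a labelled "tract"
  subset of fixels (a stand-in for the fornix) and integer cognitive scores
  (MMSE / MoCA ranges) linked to the biological tract-mean fibre density.

Values are generated under the same location–scale model the harmonisation
assumes: for scan j of batch i at fixel f,

    Y = alpha_f + u_j + X_j beta + sigma_f * (gamma_{i,f} + delta_{i,f} eps)

with gamma_{i,f} ~ N(g_i alpha_f / sigma_f, tau_i^2) — so the additive batch
shift is g_i (a *fraction of baseline*) times alpha_f in metric units — and
delta2_{i,f} ~ InverseGamma(lambda_i, theta_i).  u_j is a subject-level
random intercept (shared across a subject's scans) providing biological
heterogeneity beyond the covariates.  Ground truth (all latent parameters
and the noise draws) is retained so batch-effect-free counterfactual data
can be reconstructed exactly.

Randomness is split into a *structure* stream (template geometry, per-fixel
parameters, covariates, batch assignment, batch-effect draws, tract labels)
and a *noise* stream (eps, cognitive noise): holding ``structure_seed``
fixed while varying ``noise_seed`` changes only the noise realisation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .fixel_io import (
    CovariateTable,
    FixelDataMatrix,
    FixelTemplate,
    write_fixel_data,
    write_fixel_template,
)

TS_MODES = ("scan_rescan", "site_diff", "scanner_diff", "protocol_diff")
MODES = TS_MODES + ("case_control",)


@dataclass
class BatchSpec:
    """One batch (site / scanner model / protocol) of a simulation.

    ``effect_mean`` is the additive batch effect as a fraction of the fixel
    baseline (0.10 = +10% of alpha_f); ``effect_sd`` the across-fixel spread
    of the additive effect on the standardized scale; the multiplicative
    effect delta^2 is drawn from InverseGamma(scale_lambda, scale_theta)
    (scale_lambda=36, scale_theta=35 gives mean 1, SD ~0.17).
    """

    label: str
    effect_mean: float = 0.0
    effect_sd: float = 0.02
    scale_lambda: float = 36.0
    scale_theta: float = 35.0
    n_scans: int | None = None


def _default_ts_batches() -> list[BatchSpec]:
    # one unaffected reference arm and one arm shifted by 10% of baseline,
    # the middle of the 8%-15% range reported for scanner/protocol changes
    return [
        BatchSpec(label="arm1", effect_mean=0.0),
        BatchSpec(label="arm2", effect_mean=0.10),
    ]


def _default_cc_batches() -> list[BatchSpec]:
    # six scanner models with additive effects spanning +/-10% of baseline
    gs = (-0.10, -0.06, -0.02, 0.02, 0.06, 0.10)
    return [BatchSpec(label=f"scanner{k + 1}", effect_mean=g) for k, g in enumerate(gs)]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the designs being emulated: 23 paired subjects in TS mode
    (the scan-rescan / scanner-model group size), 27 AD vs 29 CN on six
    scanner models in case-control mode, additive scanner effects of ~10% of
    baseline, and a 15% tract-restricted FD reduction in AD.
    """

    mode: str = "scanner_diff"
    grid_shape: tuple[int, int, int] = (10, 10, 5)
    fixels_per_voxel_range: tuple[int, int] = (1, 3)
    n_subjects: int = 23
    n_cases: int = 27  # AD, case_control mode
    n_controls: int = 29  # CN
    batches: list[BatchSpec] | None = None
    # biology
    baseline_range: tuple[float, float] = (0.3, 0.7)  # alpha_f (FD-like units)
    noise_sd_range: tuple[float, float] = (0.01, 0.05)  # sigma_f
    subject_sd: float = 0.04  # subject random intercept SD
    age_slope: float = -0.002  # metric units per year
    sex_effect: float = 0.01
    icv_slope: float = 1e-8  # per mm^3
    age_range: tuple[float, float] = (28.0, 36.0)
    icv_mean_sd: tuple[float, float] = (1.5e6, 1.5e5)
    # case-control structure
    effect_tract: float = 0.10  # fraction of fixels labelled "tract"
    group_effect: float = 0.15  # fractional FD reduction in AD tract fixels
    confound_strength: float = 1.0  # skew of AD assignment toward high-effect scanners
    cognitive_links: dict = field(
        default_factory=lambda: {
            # score = intercept + slope * biological tract-mean FD + N(0, noise_sd)
            "mmse": {"intercept": -13.5, "slope": 85.0, "noise_sd": 1.5},
            "moca": {"intercept": -37.0, "slope": 127.0, "noise_sd": 2.5},
        }
    )
    seed: int = 0
    structure_seed: int | None = None
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"unknown mode {self.mode!r}; one of {MODES}")
        if not 0 <= self.group_effect < 1:
            raise ValidationError("group_effect must be in [0, 1)")
        if not 0 < self.effect_tract <= 1:
            raise ValidationError("effect_tract must be in (0, 1]")
        if self.batches is None:
            self.batches = (
                _default_cc_batches() if self.mode == "case_control" else _default_ts_batches()
            )
        self.batches = [
            b if isinstance(b, BatchSpec) else BatchSpec(**b) for b in self.batches
        ]
        for b in self.batches:
            if b.effect_sd < 0:
                raise ValidationError("effect_sd must be >= 0")

    def rngs(self):
        """(structure_rng, noise_rng) derived from the configured seeds."""
        s = self.seed if self.structure_seed is None else self.structure_seed
        n = self.seed if self.noise_seed is None else self.noise_seed
        return (
            np.random.default_rng(np.random.SeedSequence([s, 1])),
            np.random.default_rng(np.random.SeedSequence([n, 2])),
        )

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("grid_shape", "fixels_per_voxel_range", "baseline_range",
                    "noise_sd_range", "age_range", "icv_mean_sd"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class GroundTruth:
    """Latent parameters of a simulated dataset (enables recovery tests).

    ``epsilon`` holds the standardized noise draws, so the batch-effect-free
    counterfactual is ``alpha + u + X beta + sigma * epsilon`` row by row.
    """

    alpha: np.ndarray  # (M,) fixel baseline (per reference group)
    beta: np.ndarray  # (p,) covariate slopes (age, sex, icv)
    sigma: np.ndarray  # (M,)
    tract_label: np.ndarray  # (M,) bool
    gamma_true: np.ndarray  # (B, M) standardized additive effects
    delta_true: np.ndarray  # (B, M) multiplicative effects (SD scale)
    subject_effect: np.ndarray  # per scan u_j
    epsilon: np.ndarray  # (N, M) standardized noise
    scan_batch: np.ndarray  # per scan batch index
    scan_group: np.ndarray | None = None  # per scan group label (case_control)

    def to_jsonable(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v is None:
                out[f.name] = None
            elif isinstance(v, np.ndarray):
                out[f.name] = v.tolist()
            else:
                out[f.name] = v
        return out


@dataclass
class SimulatedDataset:
    """A simulated scan population with its covariates and ground truth."""

    Y: FixelDataMatrix  # all scans stacked (TS: arm1 rows then arm2 rows)
    covariates: CovariateTable
    truth: GroundTruth
    config: SimulationConfig
    template: FixelTemplate

    @property
    def n_scans(self) -> int:
        return self.Y.n_scans

    # TS conveniences ---------------------------------------------------------

    @property
    def arm1(self) -> np.ndarray:
        n = self.n_scans // 2
        return self.Y.Y[:n]

    @property
    def arm2(self) -> np.ndarray:
        n = self.n_scans // 2
        return self.Y.Y[n:]

    def confound_free_Y(self) -> np.ndarray:
        """Counterfactual data with batch effects removed at the source."""
        X = self.covariates.df[["age", "sex", "icv"]].to_numpy(dtype=float)
        M = len(self.truth.alpha)
        scale = np.ones((self.n_scans, M))
        if self.truth.scan_group is not None:
            ad = np.asarray(self.truth.scan_group) == "AD"
            scale[np.ix_(ad, self.truth.tract_label)] = 1.0 - self.config.group_effect
        base = scale * self.truth.alpha[None, :]
        return (
            base
            + self.truth.subject_effect[:, None]
            + (X @ self.truth.beta)[:, None]
            + self.truth.sigma[None, :] * self.truth.epsilon
        )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def make_template(grid_shape, fixels_per_voxel_range=(1, 3), seed: int = 0) -> FixelTemplate:
    """Random fixel template: uniform per-voxel counts, isotropic directions."""
    lo, hi = fixels_per_voxel_range
    if lo < 1 or hi > 4 or lo > hi:
        raise ValidationError("fixels_per_voxel_range must lie within [1, 4]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    counts = rng.integers(lo, hi + 1, size=tuple(grid_shape)).astype(np.int64)
    m = int(counts.sum())
    flat = counts.ravel()
    offsets = np.concatenate([[0], np.cumsum(flat)[:-1]]).reshape(counts.shape)
    dirs = rng.normal(size=(m, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    affine = np.diag([1.25, 1.25, 1.25, 1.0])  # template-space voxel size in mm
    template = FixelTemplate(
        grid_shape=tuple(grid_shape),
        affine=affine,
        counts=counts,
        offsets=offsets.astype(np.int64),
        directions=dirs,
    )
    template.validate()
    return template


def _draw_fixel_params(cfg: SimulationConfig, m: int, rng):
    alpha = rng.uniform(*cfg.baseline_range, size=m)
    sigma = rng.uniform(*cfg.noise_sd_range, size=m)
    beta = np.array([cfg.age_slope, cfg.sex_effect, cfg.icv_slope])
    return alpha, beta, sigma


def _draw_batch_effects(spec: BatchSpec, alpha, sigma, rng):
    """Standardized-scale batch effects for one batch over all fixels."""
    # raw shift = effect_mean * alpha; fixels with sigma == 0 carry no
    # standardized scale, hence no batch effect either
    mean = np.divide(spec.effect_mean * alpha, sigma,
                     out=np.zeros_like(alpha), where=sigma > 0)
    gamma = mean + spec.effect_sd * rng.standard_normal(alpha.size)
    delta2 = stats.invgamma.rvs(
        a=spec.scale_lambda, scale=spec.scale_theta, size=alpha.size, random_state=rng
    )
    return gamma, np.sqrt(delta2)


def _draw_subjects(cfg: SimulationConfig, n: int, rng):
    age = rng.uniform(*cfg.age_range, size=n)
    sex = rng.integers(0, 2, size=n)
    icv = rng.normal(cfg.icv_mean_sd[0], cfg.icv_mean_sd[1], size=n)
    u = cfg.subject_sd * rng.standard_normal(n)
    return age, sex, icv, u


def simulate_travelling(template: FixelTemplate, config: SimulationConfig) -> SimulatedDataset:
    """Paired travelling-subject data: every subject scanned once per arm.

    Rows 0..n-1 are arm 1, rows n..2n-1 are arm 2, subject-aligned.  In
    ``scan_rescan`` mode both arms share a single batch (identical batch
    effects); otherwise the two configured batch specs define the arms.
    """
    if config.mode not in TS_MODES:
        raise ValidationError(f"simulate_travelling requires a TS mode, got {config.mode!r}")
    if config.n_subjects < 2:
        raise ValidationError("need at least 2 subjects")
    if config.mode != "scan_rescan" and len(config.batches) != 2:
        raise ValidationError("paired TS modes need exactly 2 batch specs")
    srng, nrng = config.rngs()
    m = template.n_fixels
    n = config.n_subjects
    alpha, beta, sigma = _draw_fixel_params(config, m, srng)
    age, sex, icv, u = _draw_subjects(config, n, srng)
    X = np.column_stack([age, sex, icv])

    if config.mode == "scan_rescan":
        g, d = _draw_batch_effects(config.batches[0], alpha, sigma, srng)
        gamma = np.stack([g, g])
        delta = np.stack([d, d])
        batch_labels = [config.batches[0].label] * (2 * n)
        scan_batch = np.zeros(2 * n, dtype=int)
    else:
        g1, d1 = _draw_batch_effects(config.batches[0], alpha, sigma, srng)
        g2, d2 = _draw_batch_effects(config.batches[1], alpha, sigma, srng)
        gamma = np.stack([g1, g2])
        delta = np.stack([d1, d2])
        batch_labels = [config.batches[0].label] * n + [config.batches[1].label] * n
        scan_batch = np.repeat([0, 1], n)

    eps = nrng.standard_normal((2 * n, m))
    loc = alpha[None, :] + u[:, None] + (X @ beta)[:, None]  # (n, M), shared biology
    Y = np.vstack(
        [
            loc + sigma[None, :] * (gamma[a][None, :] + delta[a][None, :] * eps[a * n : (a + 1) * n])
            for a in (0, 1)
        ]
    )

    subject_ids = [f"sub{j:03d}" for j in range(n)]
    rows = []
    for a in (0, 1):
        for j in range(n):
            k = a * n + j
            rows.append(
                {
                    "subject_id": subject_ids[j],
                    "batch": batch_labels[k],
                    "age": age[j],
                    "sex": int(sex[j]),
                    "icv": icv[j],
                    "datafile": f"{subject_ids[j]}_arm{a + 1}.nii.gz",
                }
            )
    covars = CovariateTable(pd.DataFrame(rows))
    truth = GroundTruth(
        alpha=alpha, beta=beta, sigma=sigma,
        tract_label=np.zeros(m, dtype=bool),
        gamma_true=gamma, delta_true=delta,
        subject_effect=np.tile(u, 2), epsilon=eps,
        scan_batch=scan_batch, scan_group=None,
    )
    Ymat = FixelDataMatrix(Y=Y, scan_ids=[r["datafile"] for r in rows], metric="FD")
    return SimulatedDataset(Y=Ymat, covariates=covars, truth=truth,
                            config=config, template=template)


def _assign_batches(group: np.ndarray, n_batches: int, confound: float, rng):
    """Scanner assignment with both groups in every batch.

    Two subjects of each group are placed in every batch first; remaining AD
    subjects are skewed toward high-index (high-effect) scanners with
    strength ``confound`` (0 = uniform), remaining CN toward low-index ones,
    emulating a group-imbalanced scanner mix.
    """
    n = group.size
    assign = np.full(n, -1, dtype=int)
    for g in np.unique(group):
        idx = np.flatnonzero(group == g)
        if idx.size < 2 * n_batches:
            raise ValidationError(
                f"group {g!r} needs at least {2 * n_batches} subjects for "
                f"{n_batches} batches"
            )
        idx = rng.permutation(idx)
        seed_block, rest = idx[: 2 * n_batches], idx[2 * n_batches :]
        assign[seed_block] = np.repeat(np.arange(n_batches), 2)
        ranks = np.linspace(-1.0, 1.0, n_batches)
        sign = 1.0 if g == "AD" else -1.0
        w = np.exp(confound * sign * ranks)
        assign[rest] = rng.choice(n_batches, size=rest.size, p=w / w.sum())
    return assign


def simulate_case_control(template: FixelTemplate, config: SimulationConfig) -> SimulatedDataset:
    """AD/CN cohort on several scanner models with a tract-restricted effect.

    A contiguous block of ``effect_tract * M`` fixels is labelled "tract"; AD
    scans have their baseline reduced by ``group_effect`` on those fixels
    only.  Cognitive scores (MMSE/MoCA) are linear in the biological (batch-
    effect-free, noise-free) tract-mean FD plus noise, rounded and truncated
    to [0, 30].
    """
    if config.mode != "case_control":
        raise ValidationError("config.mode must be 'case_control'")
    if len(config.batches) < 2:
        raise ValidationError("case-control mode needs at least 2 batches")
    srng, nrng = config.rngs()
    m = template.n_fixels
    n_ad, n_cn = config.n_cases, config.n_controls
    n = n_ad + n_cn
    alpha, beta, sigma = _draw_fixel_params(config, m, srng)
    age, sex, icv, u = _draw_subjects(config, n, srng)
    X = np.column_stack([age, sex, icv])
    group = np.array(["AD"] * n_ad + ["CN"] * n_cn)

    tract_size = max(1, int(round(config.effect_tract * m)))
    start = int(srng.integers(0, m - tract_size + 1))
    tract = np.zeros(m, dtype=bool)
    tract[start : start + tract_size] = True

    B = len(config.batches)
    assign = _assign_batches(group, B, config.confound_strength, srng)
    gamma = np.zeros((B, m))
    delta = np.ones((B, m))
    for b, spec in enumerate(config.batches):
        gamma[b], delta[b] = _draw_batch_effects(spec, alpha, sigma, srng)

    scale = np.ones((n, m))
    scale[np.ix_(group == "AD", tract)] = 1.0 - config.group_effect
    eps = nrng.standard_normal((n, m))
    loc = scale * alpha[None, :] + u[:, None] + (X @ beta)[:, None]
    Y = loc + sigma[None, :] * (gamma[assign] + delta[assign] * eps)

    bio_tract_mean = loc[:, tract].mean(axis=1)
    scores = {}
    for name, link in config.cognitive_links.items():
        raw = link["intercept"] + link["slope"] * bio_tract_mean
        raw = raw + link["noise_sd"] * nrng.standard_normal(n)
        scores[name] = np.clip(np.round(raw), 0, 30).astype(int)

    subject_ids = [f"sub{j:03d}" for j in range(n)]
    rows = []
    for j in range(n):
        row = {
            "subject_id": subject_ids[j],
            "batch": config.batches[assign[j]].label,
            "age": age[j],
            "sex": int(sex[j]),
            "icv": icv[j],
            "group": group[j],
            "datafile": f"{subject_ids[j]}.nii.gz",
        }
        row.update({k: int(v[j]) for k, v in scores.items()})
        rows.append(row)
    covars = CovariateTable(pd.DataFrame(rows))
    truth = GroundTruth(
        alpha=alpha, beta=beta, sigma=sigma, tract_label=tract,
        gamma_true=gamma, delta_true=delta,
        subject_effect=u, epsilon=eps,
        scan_batch=assign, scan_group=group,
    )
    Ymat = FixelDataMatrix(Y=Y, scan_ids=[r["datafile"] for r in rows], metric="FD")
    return SimulatedDataset(Y=Ymat, covariates=covars, truth=truth,
                            config=config, template=template)


def simulate(template: FixelTemplate, config: SimulationConfig) -> SimulatedDataset:
    """Dispatch on ``config.mode``."""
    if config.mode == "case_control":
        return simulate_case_control(template, config)
    return simulate_travelling(template, config)


def export_dataset(dataset: SimulatedDataset, out_dir, overwrite: bool = False) -> Path:
    """Write a dataset as fixel directory + covariates.csv + ground_truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fixel_dir = out_dir / "fixels"
    fixel_dir.mkdir(exist_ok=True)
    write_fixel_template(dataset.template, fixel_dir, overwrite=True)
    for k, fname in enumerate(dataset.covariates.df["datafile"]):
        write_fixel_data(dataset.template, dataset.Y.Y[k].astype(np.float32),
                         fixel_dir / fname, overwrite=overwrite)
    dataset.covariates.df.to_csv(out_dir / "covariates.csv", index=False)
    truth = dataset.truth.to_jsonable()
    truth["config"] = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in dataclasses.asdict(dataset.config).items()
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(truth))
    return out_dir
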
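"""Reading and writing the fixel directory format.

A fixel directory (the layout emitted by fixel-based-analysis pipelines)
holds the shared template geometry plus one scalar image per subject-metric:

* ``index.nii[.gz]`` — 4-D, shape ``(X, Y, Z, 2)``; volume 0 is the number of
  fixels in each voxel, volume 1 the 0-based offset of the voxel's first fixel
  in the template-wide fixel list.
* ``directions.nii[.gz]`` — shape ``(M, 1, 1, 3)``; unit direction per fixel.
* scalar data images — shape ``(M, 1, 1)``; one value per template fixel.

Only the NIfTI-1 dialect is supported here; the MRtrix-native ``.mif``
container is out of scope (``mrconvert`` converts losslessly).

Per-subject vectors are assembled into a scans × fixels matrix.  A fibre
population absent in a subject carries the value 0 at its template fixel,
preserving one-to-one fixel correspondence across participants; the reader
additionally accepts NaN as "absent" and converts it to 0 (the conversion is
counted and logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    IntegrityError,
    SchemaError,
    ShapeError,
    ValidationError,
)

logger = logging.getLogger(__name__)

METRICS = ("FD", "logFC", "FDC")

_DIRECTION_NORM_TOL = 1e-4

REQUIRED_COVARIATE_COLUMNS = ("subject_id", "batch", "age", "sex", "icv", "datafile")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class FixelTemplate:
    """Shared fixel geometry: voxel grid plus the template fixel list.

    Attributes
    ----------
    grid_shape : tuple of int
        Voxel grid dimensions ``(X, Y, Z)``.
    affine : (4, 4) ndarray
        Voxel-to-world transform in mm.
    counts : ndarray of int, shape ``grid_shape``
        Number of fixels in each voxel.
    offsets : ndarray of int, shape ``grid_shape``
        0-based index of each voxel's first fixel (meaningful where count > 0).
    directions : (M, 3) ndarray
        Unit direction vector per fixel, in fixel-list order.
    """

    grid_shape: tuple[int, int, int]
    affine: np.ndarray
    counts: np.ndarray
    offsets: np.ndarray
    directions: np.ndarray

    @property
    def n_fixels(self) -> int:
        return int(self.directions.shape[0])

    def validate(self) -> None:
        """Check all structural invariants; raise IntegrityError on violation."""
        m = self.n_fixels
        if self.counts.shape != tuple(self.grid_shape):
            raise IntegrityError("counts shape does not match grid_shape")
        if self.offsets.shape != tuple(self.grid_shape):
            raise IntegrityError("offsets shape does not match grid_shape")
        if np.any(self.counts < 0):
            raise IntegrityError("negative fixel count")
        if int(self.counts.sum()) != m:
            raise IntegrityError(
                f"counts sum to {int(self.counts.sum())} but there are {m} fixels"
            )
        norms = np.linalg.norm(self.directions, axis=1)
        if np.any(np.abs(norms - 1.0) > _DIRECTION_NORM_TOL):
            raise IntegrityError("direction vectors must have unit norm")
        # the half-open ranges [offset, offset+count) of non-empty voxels must
        # be disjoint and together cover {0, ..., M-1}
        covered = np.zeros(m, dtype=np.int64)
        for cnt, off in zip(self.counts.ravel(), self.offsets.ravel()):
            if cnt == 0:
                continue
            if off < 0 or off + cnt > m:
                raise IntegrityError(
                    f"fixel range [{off}, {off + cnt}) falls outside [0, {m})"
                )
            covered[off : off + cnt] += 1
        if np.any(covered > 1):
            raise IntegrityError("overlapping voxel fixel ranges")
        if np.any(covered == 0):
            raise IntegrityError("voxel fixel ranges do not cover the fixel list")


@dataclass
class SubjectFixelValues:
    """One scan's metric values over the template fixel list."""

    scan_id: str
    metric: str
    values: np.ndarray
    present: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        if self.values.shape != self.present.shape:
            raise ShapeError("values and present must have equal length")
        if np.any(self.values[~self.present] != 0):
            raise ValidationError("absent fixels must carry the value 0")


@dataclass
class FixelDataMatrix:
    """Scans × fixels value matrix with row-aligned scan ids and a fixel mask.

    ``mask`` marks fixels eligible for harmonisation; fixels whose values are
    constant within any batch are excluded (their residual or batch scale
    would be zero, making the location–scale adjustment singular) and pass
    through harmonisation unchanged.
    """

    Y: np.ndarray
    scan_ids: list[str]
    metric: str
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2:
            raise ShapeError("Y must be 2-D (scans x fixels)")
        if len(self.scan_ids) != self.Y.shape[0]:
            raise ShapeError("scan_ids length must equal the number of rows")
        if self.mask is None:
            self.mask = np.ones(self.Y.shape[1], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.Y.shape[1],):
            raise ShapeError("mask length must equal the number of fixels")

    @property
    def n_scans(self) -> int:
        return self.Y.shape[0]

    @property
    def n_fixels(self) -> int:
        return self.Y.shape[1]


class CovariateTable:
    """Per-scan covariates: subject, batch, age, sex, ICV, optional extras.

    Wraps a pandas DataFrame with typed, validated columns.  ``sex`` is stored
    as a 0/1 indicator (F=1, M=0); ``batch`` as a categorical in order of first
    appearance.  Every batch level must contain at least two scans, since both
    a location and a scale are estimated per batch.
    """

    def __init__(self, df: pd.DataFrame, require_datafile: bool = True):
        required = [
            c for c in REQUIRED_COVARIATE_COLUMNS if require_datafile or c != "datafile"
        ]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"covariate table missing required columns: {missing}")
        df = df.copy()
        df["subject_id"] = df["subject_id"].astype(str)
        df["sex"] = _coerce_sex(df["sex"])
        df["age"] = pd.to_numeric(df["age"], errors="raise").astype(float)
        df["icv"] = pd.to_numeric(df["icv"], errors="raise").astype(float)
        levels = list(pd.unique(df["batch"].astype(str)))
        df["batch"] = pd.Categorical(df["batch"].astype(str), categories=levels)
        for col in ("age", "sex", "icv"):
            if df[col].isna().any():
                raise ValidationError(f"missing values in required column '{col}'")
        sizes = df["batch"].value_counts()
        tiny = sizes[sizes < 2]
        if len(tiny):
            raise ValidationError(
                "every batch level needs at least 2 scans for per-batch "
                f"location and scale estimation; offending levels: {list(tiny.index)}"
            )
        self.df = df.reset_index(drop=True)

    # -- convenience accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def batch_levels(self) -> list[str]:
        return list(self.df["batch"].cat.categories)

    @property
    def batch_codes(self) -> np.ndarray:
        return self.df["batch"].cat.codes.to_numpy()

    def design_covariates(self, columns: tuple[str, ...] = ("age", "sex", "icv")):
        """Return the biological design matrix X (no intercept) and its names."""
        missing = [c for c in columns if c not in self.df.columns]
        if missing:
            raise SchemaError(f"covariate columns not in table: {missing}")
        X = self.df[list(columns)].to_numpy(dtype=float)
        return X, list(columns)

    def subset(self, row_mask: np.ndarray) -> "CovariateTable":
        sub = self.df.loc[np.asarray(row_mask, dtype=bool)].reset_index(drop=True)
        # re-derive batch categories so empty levels vanish in the subset
        sub["batch"] = sub["batch"].astype(str)
        return CovariateTable(sub, require_datafile="datafile" in sub.columns)


def _coerce_sex(col: pd.Series) -> pd.Series:
    """Accept {M, F} or {0, 1} and store as the F=1 indicator."""
    mapping = {"M": 0, "F": 1, "m": 0, "f": 1, "0": 0, "1": 1, 0: 0, 1: 1}
    try:
        out = col.map(lambda v: mapping[v if not isinstance(v, str) else v.strip()])
    except KeyError as exc:
        raise ValidationError(f"unrecognised sex code: {exc.args[0]!r}") from None
    if out.isna().any():
        raise ValidationError("unrecognised sex codes present")
    return out.astype(int)


# ---------------------------------------------------------------------------
# file operations
# ---------------------------------------------------------------------------


def _find_image(dir_path: Path, stem: str) -> Path:
    for suffix in (".nii", ".nii.gz"):
        p = dir_path / f"{stem}{suffix}"
        if p.exists():
            return p
    raise FormatError(f"no {stem}.nii[.gz] in fixel directory {dir_path}")


def read_fixel_template(dir_path) -> FixelTemplate:
    """Read ``index`` and ``directions`` images from a fixel directory."""
    dir_path = Path(dir_path)
    if not dir_path.is_dir():
        raise FormatError(f"not a directory: {dir_path}")
    index_img = nib.load(_find_image(dir_path, "index"))
    index = np.asarray(index_img.dataobj)
    if index.ndim != 4 or index.shape[-1] != 2:
        raise FormatError(
            f"index image must be 4-D with last dimension 2, got shape {index.shape}"
        )
    directions = np.asarray(nib.load(_find_image(dir_path, "directions")).dataobj)
    directions = np.squeeze(directions)
    if directions.ndim == 1:  # single fixel squeezed to (3,)
        directions = directions[None, :]
    if directions.ndim != 2 or directions.shape[1] != 3:
        raise FormatError(
            f"directions image must be M x 1 x 1 x 3, got shape {directions.shape}"
        )
    template = FixelTemplate(
        grid_shape=tuple(index.shape[:3]),
        affine=np.asarray(index_img.affine, dtype=float),
        counts=np.asarray(np.round(index[..., 0]), dtype=np.int64),
        offsets=np.asarray(np.round(index[..., 1]), dtype=np.int64),
        directions=np.asarray(directions, dtype=float),
    )
    template.validate()
    return template


def write_fixel_template(template: FixelTemplate, dir_path, overwrite: bool = True) -> None:
    """Write ``index.nii.gz`` and ``directions.nii.gz`` for a template."""
    template.validate()
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    index = np.stack([template.counts, template.offsets], axis=-1).astype(np.int32)
    index_path = dir_path / "index.nii.gz"
    dirs_path = dir_path / "directions.nii.gz"
    if not overwrite and (index_path.exists() or dirs_path.exists()):
        raise FileExistsError(f"refusing to overwrite template in {dir_path}")
    nib.save(nib.Nifti1Image(index, template.affine), index_path)
    dirs = template.directions.astype(np.float32)[:, None, None, :]
    nib.save(nib.Nifti1Image(dirs, np.eye(4)), dirs_path)


def read_fixel_data(template: FixelTemplate, file_path) -> np.ndarray:
    """Read a scalar fixel data image as a length-M vector in fixel order."""
    file_path = Path(file_path)
    if not file_path.exists():
        raise FormatError(f"fixel data file not found: {file_path}")
    data = np.asarray(nib.load(file_path).dataobj, dtype=float)
    if data.shape[0] != template.n_fixels:
        raise ShapeError(
            f"{file_path.name}: first dimension {data.shape[0]} does not match "
            f"template n_fixels={template.n_fixels}"
        )
    vec = data.reshape(data.shape[0], -1)
    if vec.shape[1] != 1:
        raise ShapeError(
            f"{file_path.name}: expected singleton trailing dimensions, got {data.shape}"
        )
    return vec[:, 0]


def write_fixel_data(template: FixelTemplate, values, file_path, overwrite: bool = False) -> None:
    """Write a length-M vector as an ``(M, 1, 1)`` float32 NIfTI image."""
    values = np.asarray(values, dtype=np.float32)
    if values.shape != (template.n_fixels,):
        raise ShapeError(
            f"values length {values.shape} does not match template "
            f"n_fixels={template.n_fixels}"
        )
    file_path = Path(file_path)
    if file_path.exists() and not overwrite:
        raise FileExistsError(f"refusing to overwrite {file_path} (pass overwrite=True)")
    img = nib.Nifti1Image(values[:, None, None], np.eye(4))
    nib.save(img, file_path)


def eligible_fixel_mask(Y: np.ndarray, batch_codes: np.ndarray) -> np.ndarray:
    """Fixels with non-zero value variance within every batch.

    A fixel constant within some batch gives a zero batch scale estimate and a
    singular adjustment; such fixels are excluded from harmonisation (they are
    copied through unchanged).
    """
    Y = np.asarray(Y, dtype=float)
    mask = np.ones(Y.shape[1], dtype=bool)
    for code in np.unique(batch_codes):
        rows = Y[batch_codes == code]
        # exact constancy, not var > 0: the variance of identical floats can
        # round to a subnormal instead of zero
        mask &= ~(rows == rows[0]).all(axis=0)
    return mask


def assemble_matrix(
    template: FixelTemplate,
    covariates: CovariateTable,
    data_dir,
    metric: str = "FD",
) -> FixelDataMatrix:
    """Stack per-scan fixel vectors into a scans × fixels matrix.

    Row k holds the scan of covariate row k.  NaNs in the data files encode
    absent fibre populations and are converted to 0 (count logged); the
    eligibility mask excludes fixels constant within any batch.
    """
    data_dir = Path(data_dir)
    files = covariates.df["datafile"].astype(str)
    if files.duplicated().any():
        dupes = sorted(files[files.duplicated()].unique())
        raise ValidationError(f"duplicate scan data files: {dupes}")
    rows = []
    n_absent = 0
    for fname in files:
        vec = read_fixel_data(template, data_dir / fname)
        nan = np.isnan(vec)
        if nan.any():
            n_absent += int(nan.sum())
            vec = np.where(nan, 0.0, vec)
        if not np.all(np.isfinite(vec)):
            raise ValidationError(f"non-finite values in {fname}")
        rows.append(vec)
    if n_absent:
        logger.info("converted %d absent (NaN) fixel values to 0", n_absent)
    Y = np.vstack(rows)
    mask = eligible_fixel_mask(Y, covariates.batch_codes)
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("excluded %d fixels constant within some batch", n_dropped)
    return FixelDataMatrix(Y=Y, scan_ids=list(files), metric=metric, mask=mask)


def read_covariates(csv_path) -> CovariateTable:
    """Read and validate a per-scan covariate CSV."""
    csv_path = Path(csv_path)
    if not csv_path.exists():
        raise FormatError(f"covariate file not found: {csv_path}")
    df = pd.read_csv(csv_path)
    return CovariateTable(df)
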
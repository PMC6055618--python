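"""Volume and cohort I/O, coordinate conventions, and pipeline configuration.

Coordinate convention used throughout the package: world coordinates are
RAS-like with ``x > 0`` the right hemisphere and the mid-sagittal plane at
``x = 0``.  Template grids have an odd number of voxels along x with the
central voxel column exactly on ``x = 0``, so the left-right flip is an exact
permutation of voxel columns (no interpolation).  Computation is performed in
64-bit floats; files are stored as float32.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GreyMatterVolume",
    "CohortTable",
    "PipelineConfig",
    "make_affine",
    "world_x_coords",
    "read_volume",
    "write_volume",
    "read_cohort",
    "write_cohort",
    "HLD_GROUPS",
    "EPILEPSY_SIDES",
    "EPILEPSY_TYPES",
    "COHORT_COLUMNS",
]

HLD_GROUPS = ("left", "right", "bilateral", "control")
EPILEPSY_SIDES = ("L", "R", "B", "U", "none")
EPILEPSY_TYPES = ("TLE", "extratemporal", "none")
COHORT_COLUMNS = [
    "id",
    "hld_group",
    "ehi",
    "sex",
    "age",
    "epilepsy_side",
    "epilepsy_type",
    "age_of_onset",
    "duration",
]


def make_affine(shape: tuple[int, int, int], voxel_size_mm: float | tuple[float, float, float]) -> np.ndarray:
    """Build a diagonal voxel-to-world affine centred on the grid.

    The centre voxel of each axis maps to world 0; along x this puts the
    central column exactly on the mid-sagittal plane (requires odd nx).
    """
    if np.isscalar(voxel_size_mm):
        voxel_size_mm = (float(voxel_size_mm),) * 3
    nx, ny, nz = shape
    if nx % 2 == 0:
        raise ValueError(f"x-dimension must be odd so the midline lies on a voxel column, got nx={nx}")
    aff = np.eye(4)
    for ax, (n, d) in enumerate(zip(shape, voxel_size_mm)):
        aff[ax, ax] = d
        aff[ax, 3] = -d * ((n - 1) / 2.0)
    return aff


def world_x_coords(shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    """World x coordinate of every voxel, broadcast to the full grid shape."""
    ii = np.arange(shape[0])
    x = affine[0, 0] * ii + affine[0, 1] * 0 + affine[0, 2] * 0 + affine[0, 3]
    return np.broadcast_to(x[:, None, None], shape)


@dataclass
class GreyMatterVolume:
    """A 3D grey-matter probability/density grid with voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray
    space_tag: str = "native"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        bad = ~np.isfinite(self.data)
        if bad.any():
            idx = tuple(int(i) for i in np.argwhere(bad)[0])
            raise ValueError(f"non-finite voxel value at index {idx}")
        if (self.data < 0).any():
            idx = tuple(int(i) for i in np.argwhere(self.data < 0)[0])
            raise ValueError(f"negative tissue value at index {idx}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def with_data(self, data: np.ndarray, space_tag: str | None = None) -> "GreyMatterVolume":
        return GreyMatterVolume(data, self.affine.copy(), space_tag or self.space_tag)

    def same_grid(self, other: "GreyMatterVolume", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)


def read_volume(path: str | Path, space_tag: str = "native") -> GreyMatterVolume:
    """Read a 3D NIfTI-1 grey-matter volume.

    Rejects missing files, non-3D images and non-finite voxels with a
    diagnostic naming the offending voxel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    return GreyMatterVolume(np.asarray(data, dtype=np.float64), np.asarray(img.affine), space_tag)


def write_volume(volume: GreyMatterVolume, path: str | Path) -> None:
    """Write a volume as float32 NIfTI-1; round-trips data to float32 precision."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    nib.save(img, str(path))


@dataclass
class CohortTable:
    """Typed subject metadata: HLD group, handedness, demographics, epilepsy."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        df = df.copy()
        df["id"] = df["id"].astype(str)
        dup = df["id"][df["id"].duplicated()].tolist()
        if dup:
            raise ValueError(f"duplicate subject ids: {sorted(set(dup))}")
        df["ehi"] = df["ehi"].astype(float)
        if ((df["ehi"] < -100) | (df["ehi"] > 100)).any():
            bad = df.loc[(df["ehi"] < -100) | (df["ehi"] > 100), "id"].tolist()
            raise ValueError(f"EHI out of [-100, 100] for subjects: {bad}")
        for col, allowed in [
            ("hld_group", HLD_GROUPS),
            ("sex", ("F", "M")),
            ("epilepsy_side", EPILEPSY_SIDES),
            ("epilepsy_type", EPILEPSY_TYPES),
        ]:
            df[col] = df[col].astype(str)
            unknown = sorted(set(df[col]) - set(allowed))
            if unknown:
                raise ValueError(f"unknown {col} value(s): {unknown}")
        ctrl_bad = df[(df["hld_group"] == "control") & (df["epilepsy_side"] != "none")]
        if len(ctrl_bad):
            raise ValueError(f"controls must have epilepsy_side='none': {ctrl_bad['id'].tolist()}")
        df["age"] = df["age"].astype(float)
        for col in ("age_of_onset", "duration"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def ids(self) -> list[str]:
        return self.frame["id"].tolist()

    def groups(self) -> pd.Series:
        return self.frame["hld_group"]

    def subset(self, group: str | list[str]) -> "CohortTable":
        groups = [group] if isinstance(group, str) else list(group)
        return CohortTable(self.frame[self.frame["hld_group"].isin(groups)].reset_index(drop=True))


def read_cohort(path: str | Path) -> CohortTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort file not found: {path}")
    df = pd.read_csv(path)
    return CohortTable(df)


def write_cohort(table: CohortTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Free parameters of one pipeline run.

    The template grid geometry is a configuration parameter (3 mm desk-scale
    default); smoothing and inference settings follow conventional
    voxel-based-morphometry practice (8 mm FWHM, cluster-forming p < 0.001,
    cluster-level FWE alpha 0.05).
    """

    grid_shape: tuple[int, int, int] = (49, 48, 48)
    voxel_size_mm: float = 3.0
    smoothing_fwhm_mm: float = 8.0
    cluster_forming_p: float = 0.001
    fwe_alpha: float = 0.05
    n_permutations: int = 1000
    master_seed: int = 1234
    gm_threshold_frac: float = 0.1
    ai_eps_frac: float = 1e-6
    connectivity: int = 26
    template_iterations: int = 1
    reg_levels: tuple[int, ...] = (4, 2, 1)
    reg_iterations: tuple[int, ...] = (60, 40, 20)
    reg_update_sigma_mm: float = 4.0
    reg_field_sigma_mm: float = 12.0
    reg_step: float = 1.0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)  # type: ignore[assignment]
        if self.smoothing_fwhm_mm < 0:
            raise ValueError("smoothing FWHM must be >= 0")
        if not (0 < self.cluster_forming_p < 1):
            raise ValueError("cluster-forming p must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100 for inference runs")
        if self.grid_shape[0] % 2 == 0:
            raise ValueError("grid x-dimension must be odd")

    def affine(self) -> np.ndarray:
        return make_affine(self.grid_shape, self.voxel_size_mm)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["reg_levels"] = list(self.reg_levels)
        d["reg_iterations"] = list(self.reg_iterations)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for key in ("grid_shape", "reg_levels", "reg_iterations"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
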
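"""Synthetic pseudo-brain grey-matter cohorts with known hemispheric asymmetries.

Generates smooth, exactly flip-symmetric base anatomies built from mirrored
ellipsoidal structures, then injects per-group left-right asymmetries and
unilateral atrophy ("lesion") analogs with closed-form ground truth, plus
inter-subject spatial jitter and smooth additive noise.

The asymmetry is injected multiplicatively: within a structure, left-side
values are scaled by (2 + delta)/2 and right-side values by (2 - delta)/2, so
the noiseless per-voxel asymmetry index (left - right) / (0.5 (left + right))
equals delta exactly, and the total left+right tissue mass of the structure is
preserved (the two factors sum to 2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .io_core import CohortTable, GreyMatterVolume, make_affine, write_cohort, write_volume

__all__ = [
    "StructureSpec",
    "AnatomyParams",
    "AsymmetrySpec",
    "LesionSpec",
    "SubjectSimConfig",
    "GroundTruth",
    "make_base_anatomy",
    "structure_mask",
    "inject_asymmetry",
    "apply_lesion",
    "simulate_subject",
    "simulate_cohort",
    "default_anatomy",
    "default_specs",
    "EHI_GROUP_PARAMS",
    "fwhm_to_sigma",
]

# Group-wise Edinburgh Handedness Inventory distributions (mean, SD), sampled
# from normals truncated to [-100, 100].  Patient-group parameters reproduce
# the cohort being emulated; controls are drawn as strongly right-handed.
EHI_GROUP_PARAMS = {
    "left": (85.4, 40.6),
    "right": (4.5, 93.7),
    "bilateral": (46.3, 83.4),
    "control": (85.0, 15.0),
}

# Age / age-of-onset / duration (mean, SD) per group, in years.
AGE_GROUP_PARAMS = {
    "left": (33.0, 9.5),
    "right": (40.0, 9.6),
    "bilateral": (33.0, 8.4),
    "control": (34.0, 10.0),
}
ONSET_GROUP_PARAMS = {"left": (11.5, 8.7), "right": (10.9, 9.0), "bilateral": (8.2, 7.1)}
DURATION_GROUP_PARAMS = {"left": (21.1, 11.1), "right": (29.1, 9.4), "bilateral": (24.7, 6.7)}
# Epilepsy side probabilities (L, R, B, U) per patient group.
SIDE_GROUP_PROBS = {
    "left": (56 / 114, 47 / 114, 2 / 114, 9 / 114),
    "right": (1.0, 0.0, 0.0, 0.0),
    "bilateral": (9 / 11, 2 / 11, 0.0, 0.0),
}


def fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class StructureSpec:
    """A mirrored ellipsoidal structure; the given centre is the right-side one
    (world x >= 0), the left homologue is implied by x -> -x."""

    name: str
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    peak: float

    def __post_init__(self) -> None:
        if not (0 < self.peak <= 1):
            raise ValueError(f"structure {self.name}: peak intensity must be in (0, 1]")
        if self.center_mm[0] < 0:
            raise ValueError(f"structure {self.name}: centre must have x >= 0")


@dataclass(frozen=True)
class AnatomyParams:
    grid_shape: tuple[int, int, int] = (49, 48, 48)
    voxel_size_mm: float = 3.0
    structures: tuple[StructureSpec, ...] = ()
    background: float = 0.0
    blur_fwhm_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.grid_shape[0] % 2 == 0:
            raise ValueError("grid x-dimension must be odd")

    def affine(self) -> np.ndarray:
        return make_affine(self.grid_shape, self.voxel_size_mm)

    def structure(self, name: str) -> StructureSpec:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(f"unknown structure: {name}")


@dataclass(frozen=True)
class AsymmetrySpec:
    """Target asymmetry index delta for one structure in the named groups.
    Positive delta = leftward asymmetry (more tissue on the left)."""

    structure: str
    delta: float
    applies_to: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (abs(self.delta) < 2):
            raise ValueError("asymmetry |delta| must be < 2")


@dataclass(frozen=True)
class LesionSpec:
    """Fractional unilateral atrophy of one structure (e.g. mesial-temporal
    volume loss) in the named groups."""

    structure: str
    side: str  # 'L' or 'R'
    fraction: float
    applies_to: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (0 <= self.fraction < 1):
            raise ValueError("lesion fraction must be in [0, 1)")
        if self.side not in ("L", "R"):
            raise ValueError("lesion side must be 'L' or 'R'")


@dataclass(frozen=True)
class SubjectSimConfig:
    noise_sd: float = 0.03
    jitter_sd_mm: float = 0.5
    jitter_rot_sd_deg: float = 0.5

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.jitter_sd_mm < 0:
            raise ValueError("jitter sd must be >= 0")


@dataclass
class GroundTruth:
    """Bookkeeping of what was injected, for recovery tests."""

    asymmetries: list[dict] = field(default_factory=list)
    lesions: list[dict] = field(default_factory=list)
    subjects: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"asymmetries": self.asymmetries, "lesions": self.lesions, "subjects": self.subjects},
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["asymmetries"], d["lesions"], d["subjects"])


def _world_grids(params: AnatomyParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    aff = params.affine()
    coords = [aff[ax, ax] * np.arange(params.grid_shape[ax]) + aff[ax, 3] for ax in range(3)]
    return np.meshgrid(*coords, indexing="ij")  # type: ignore[return-value]


def _ellipsoid(params: AnatomyParams, center: tuple[float, float, float], radii) -> np.ndarray:
    X, Y, Z = _world_grids(params)
    q = ((X - center[0]) / radii[0]) ** 2 + ((Y - center[1]) / radii[1]) ** 2 + ((Z - center[2]) / radii[2]) ** 2
    return q <= 1.0


def structure_mask(params: AnatomyParams, name: str, side: str = "both") -> np.ndarray:
    """Boolean support of a structure: the right-side ellipsoid, its mirror, or both."""
    s = params.structure(name)
    right = _ellipsoid(params, s.center_mm, s.radii_mm)
    left = right[::-1, :, :]
    if side == "R":
        return right
    if side == "L":
        return left
    return right | left


def _flip(a: np.ndarray) -> np.ndarray:
    return a[::-1, :, :]


def make_base_anatomy(params: AnatomyParams) -> GreyMatterVolume:
    """Smooth pseudo-brain grey-matter map, exactly flip-symmetric.

    Structures are composed by maximum intensity (so a structure touching the
    midline does not double with its mirror), blurred, then explicitly
    symmetrized so v == flip(v) holds bit-exactly.
    """
    shape = params.grid_shape
    vol = np.full(shape, float(params.background))
    for s in params.structures:
        m = _ellipsoid(params, s.center_mm, s.radii_mm)
        if not m.any():
            raise ValueError(f"structure {s.name} lies outside the grid")
        profile = np.where(m, s.peak, 0.0)
        vol = np.maximum(vol, profile)
        vol = np.maximum(vol, _flip(profile))
    if params.blur_fwhm_mm > 0:
        sigma_vox = fwhm_to_sigma(params.blur_fwhm_mm) / params.voxel_size_mm
        vol = ndimage.gaussian_filter(vol, sigma_vox, mode="constant")
    vol = 0.5 * (vol + _flip(vol))  # bit-exact flip symmetry
    vol = np.clip(vol, 0.0, 1.0)
    vol = 0.5 * (vol + _flip(vol))
    return GreyMatterVolume(vol, params.affine(), "native")


def inject_asymmetry(volume: GreyMatterVolume, spec: AsymmetrySpec, params: AnatomyParams) -> GreyMatterVolume:
    """Scale a structure's left side by (2+delta)/2 and right side by (2-delta)/2.

    Makes the noiseless per-voxel AI within the structure equal delta exactly
    while conserving the structure's total left+right tissue mass.
    """
    left = structure_mask(params, spec.structure, "L")
    right = structure_mask(params, spec.structure, "R")
    data = volume.data.copy()
    # x = 0 voxels belong to both sides; leave them untouched (excluded from AI).
    mid = left & right
    data[left & ~mid] *= (2.0 + spec.delta) / 2.0
    data[right & ~mid] *= (2.0 - spec.delta) / 2.0
    return volume.with_data(data)


def apply_lesion(volume: GreyMatterVolume, spec: LesionSpec, params: AnatomyParams) -> GreyMatterVolume:
    """Reduce tissue within one side of a structure by the given fraction."""
    m = structure_mask(params, spec.structure, spec.side)
    data = volume.data.copy()
    data[m] *= 1.0 - spec.fraction
    return volume.with_data(data)


def _jitter_matrix(rng: np.random.Generator, cfg: SubjectSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Small random rigid perturbation: rotation (deg sd) + translation (mm sd)."""
    angles = np.deg2rad(rng.normal(0.0, cfg.jitter_rot_sd_deg, size=3))
    shift = rng.normal(0.0, cfg.jitter_sd_mm, size=3)
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx, shift


def _apply_rigid(volume: GreyMatterVolume, R: np.ndarray, shift_mm: np.ndarray) -> GreyMatterVolume:
    """Resample through a world-space rigid map about the grid centre."""
    aff = volume.affine
    A = aff[:3, :3]
    Ainv = np.linalg.inv(A)
    # voxel -> world (centred at world 0) -> rotate+shift -> voxel
    M = Ainv @ R @ A
    offset = Ainv @ (R @ aff[:3, 3] + shift_mm - aff[:3, 3])
    out = ndimage.affine_transform(volume.data, M, offset=offset, order=1, mode="constant", cval=0.0)
    return volume.with_data(np.clip(out, 0.0, None))


def simulate_subject(
    base: GreyMatterVolume,
    specs: list,
    cfg: SubjectSimConfig,
    params: AnatomyParams,
    seed: int,
) -> GreyMatterVolume:
    """One subject's grey-matter map: asymmetries/lesions, rigid jitter, smooth noise.

    Deterministic given the per-subject seed.  ``specs`` must already be
    filtered to the subject's group.
    """
    rng = np.random.default_rng(seed)
    vol = base
    for spec in specs:
        if isinstance(spec, AsymmetrySpec):
            vol = inject_asymmetry(vol, spec, params)
        elif isinstance(spec, LesionSpec):
            vol = apply_lesion(vol, spec, params)
        else:
            raise TypeError(f"unknown spec type: {type(spec)!r}")
    if cfg.jitter_sd_mm > 0 or cfg.jitter_rot_sd_deg > 0:
        R, shift = _jitter_matrix(rng, cfg)
        vol = _apply_rigid(vol, R, shift)
    else:
        rng.normal(size=6)  # keep the stream aligned whether or not jitter is on
    if cfg.noise_sd > 0:
        white = rng.standard_normal(vol.shape)
        sigma_vox = fwhm_to_sigma(params.blur_fwhm_mm) / params.voxel_size_mm
        noise = ndimage.gaussian_filter(white, sigma_vox) if sigma_vox > 0 else white
        noise *= cfg.noise_sd / noise.std()
        # restrict noise to the tissue support (soft window): grey-matter maps
        # have near-zero background, and a clipped full-field noise floor would
        # add a spurious background pedestal
        support = (vol.data > 0.05).astype(np.float64)
        if sigma_vox > 0:
            support = ndimage.gaussian_filter(support, sigma_vox)
        vol = vol.with_data(np.clip(vol.data + noise * support, 0.0, None))
    return vol


def _sample_truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _sample_cohort_table(group_sizes: dict[str, int], rng: np.random.Generator) -> CohortTable:
    rows = []
    for group in sorted(group_sizes):
        n = group_sizes[group]
        if n < 0:
            raise ValueError("group sizes must be >= 0")
        ehi_m, ehi_s = EHI_GROUP_PARAMS[group]
        age_m, age_s = AGE_GROUP_PARAMS[group]
        ehi = _sample_truncnorm(rng, ehi_m, ehi_s, -100, 100, n)
        age = _sample_truncnorm(rng, age_m, age_s, 16, 70, n)
        if group == "control":
            onset = duration = np.full(n, np.nan)
            sides = ["none"] * n
            etypes = ["none"] * n
        else:
            on_m, on_s = ONSET_GROUP_PARAMS[group]
            onset = _sample_truncnorm(rng, on_m, on_s, 0.5, 60, n)
            duration = np.clip(age - onset, 1.0, None)
            sides = rng.choice(["L", "R", "B", "U"], size=n, p=SIDE_GROUP_PROBS[group]).tolist()
            etypes = ["TLE"] * n
        sexes = rng.choice(["F", "M"], size=n).tolist()
        for i in range(n):
            rows.append(
                {
                    "id": f"{group}_{i:03d}",
                    "hld_group": group,
                    "ehi": round(float(ehi[i]), 2),
                    "sex": sexes[i],
                    "age": round(float(age[i]), 1),
                    "epilepsy_side": sides[i],
                    "epilepsy_type": etypes[i],
                    "age_of_onset": None if group == "control" else round(float(onset[i]), 1),
                    "duration": None if group == "control" else round(float(duration[i]), 1),
                }
            )
    return CohortTable(pd.DataFrame(rows))


def simulate_cohort(
    anatomy: AnatomyParams,
    group_sizes: dict[str, int],
    specs: list,
    cfg: SubjectSimConfig,
    master_seed: int,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, GreyMatterVolume], CohortTable, GroundTruth]:
    """Generate a full cohort: per-subject volumes, cohort table, ground truth.

    Fully reproducible from ``master_seed``.  If ``out_dir`` is given, volumes
    are written as NIfTI, the table as CSV and the ground truth as JSON.
    """
    total = sum(group_sizes.values())
    if total <= 0:
        raise ValueError("cohort must contain at least one subject")
    for g in group_sizes:
        if g not in EHI_GROUP_PARAMS:
            raise ValueError(f"unknown group: {g}")
    ss = np.random.SeedSequence(master_seed)
    table_seed, *subject_seeds = ss.spawn(total + 1)
    table = _sample_cohort_table(group_sizes, np.random.default_rng(table_seed))

    base = make_base_anatomy(anatomy)
    truth = GroundTruth()
    for spec in specs:
        if isinstance(spec, AsymmetrySpec):
            truth.asymmetries.append(
                {"structure": spec.structure, "delta": spec.delta, "applies_to": list(spec.applies_to)}
            )
        elif isinstance(spec, LesionSpec):
            truth.lesions.append(
                {
                    "structure": spec.structure,
                    "side": spec.side,
                    "fraction": spec.fraction,
                    "applies_to": list(spec.applies_to),
                }
            )

    volumes: dict[str, GreyMatterVolume] = {}
    for row, sseq in zip(table.frame.itertuples(), subject_seeds):
        subj_specs = [s for s in specs if row.hld_group in s.applies_to]
        seed = int(sseq.generate_state(1)[0] % (2**31))
        vol = simulate_subject(base, subj_specs, cfg, anatomy, seed)
        volumes[row.id] = vol
        truth.subjects[row.id] = {
            "seed": seed,
            "group": row.hld_group,
            "specs": [s.structure for s in subj_specs],
        }
    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "volumes").mkdir(parents=True, exist_ok=True)
        for sid, vol in volumes.items():
            write_volume(vol, out_dir / "volumes" / f"{sid}.nii.gz")
        write_cohort(table, out_dir / "cohort.csv")
        truth.to_json(out_dir / "ground_truth.json")
    return volumes, table, truth


def default_anatomy(grid_shape=(49, 48, 48), voxel_size_mm=3.0) -> AnatomyParams:
    """Desk-scale pseudo-brain: a large cortical blob plus mirrored structures."""
    return AnatomyParams(
        grid_shape=grid_shape,
        voxel_size_mm=voxel_size_mm,
        structures=(
            StructureSpec("brain", (0.0, 0.0, 0.0), (48.0, 48.0, 45.0), 0.4),
            StructureSpec("insula", (30.0, 9.0, 0.0), (10.0, 10.0, 10.0), 0.85),
            StructureSpec("hippocampus", (24.0, -24.0, -15.0), (9.0, 12.0, 8.0), 0.85),
            StructureSpec("planum", (33.0, -33.0, 15.0), (9.0, 10.0, 8.0), 0.8),
        ),
        background=0.0,
        blur_fwhm_mm=6.0,
    )


def default_specs() -> list:
    """Default injected effects: a leftward insular asymmetry in left-HLD-pattern
    groups, rightward in right HLD, plus a left hippocampal atrophy in patients."""
    return [
        AsymmetrySpec("insula", +0.3, ("left", "bilateral", "control")),
        AsymmetrySpec("insula", -0.3, ("right",)),
        AsymmetrySpec("planum", +0.2, ("left", "right", "bilateral", "control")),
        LesionSpec("hippocampus", "L", 0.3, ("left", "right", "bilateral")),
    ]
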
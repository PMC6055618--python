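"""End-to-end orchestration: simulate -> template -> AI -> inference ->
profiling -> cohort statistics -> report, with a run manifest for provenance.

Each stage reads and writes plain files under one output directory so runs are
resumable and fully reproducible from (config, master seed).
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .asymmetry import AIImage, HemisphereMask, compute_ai, make_right_hemisphere_mask, smooth_ai
from .cohort_stats import chi_square_2x2, group_anova_posthoc, summarize_cohort
from .inference import (
    ClusterRecord,
    DesignMatrix,
    InferenceParams,
    permutation_cluster_fwe,
    within_group_asymmetry,
)
from .io_core import CohortTable, GreyMatterVolume, PipelineConfig, read_cohort, read_volume, write_volume
from .profiling import extract_cluster_profiles, hemisphere_anova, zscore_consistency
from .registration import (
    RegistrationParams,
    build_symmetric_template,
    flip_lr,
    read_field,
    warp_and_modulate,
    write_field,
)

log = logging.getLogger(__name__)

__all__ = [
    "RunManifest",
    "stage_simulate",
    "stage_template",
    "stage_ai",
    "stage_infer",
    "stage_profile",
    "stage_stats",
    "stage_report",
    "run_all",
    "load_ai_images",
]


class RunManifest:
    """Config hash, seed, stage timestamps and output checksums for one run."""

    def __init__(self, out_dir: Path, config: PipelineConfig):
        self.out_dir = Path(out_dir)
        self.path = self.out_dir / "manifest.json"
        if self.path.exists():
            with open(self.path) as fh:
                self.data = json.load(fh)
        else:
            self.data = {"config_hash": config.config_hash(), "master_seed": config.master_seed, "stages": {}, "files": {}}

    def record_stage(self, name: str, files: list[Path]) -> None:
        self.data["stages"][name] = _dt.datetime.now().isoformat(timespec="seconds")
        for f in files:
            rel = str(Path(f).relative_to(self.out_dir))
            self.data["files"][rel] = _sha256(f)
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _reg_params(config: PipelineConfig) -> RegistrationParams:
    return RegistrationParams(
        levels=config.reg_levels,
        iterations=config.reg_iterations,
        update_sigma_mm=config.reg_update_sigma_mm,
        field_sigma_mm=config.reg_field_sigma_mm,
        step=config.reg_step,
    )


def _inference_params(config: PipelineConfig, seed_offset: int = 0) -> InferenceParams:
    return InferenceParams(
        cluster_forming_p=config.cluster_forming_p,
        fwe_alpha=config.fwe_alpha,
        n_permutations=config.n_permutations,
        seed=(config.master_seed + seed_offset) % (2**31),
        connectivity=config.connectivity,
    )


def stage_simulate(
    config: PipelineConfig,
    out_dir: Path,
    group_sizes: dict[str, int] | None = None,
    anatomy: synthetic.AnatomyParams | None = None,
    specs: list | None = None,
    sim_cfg: synthetic.SubjectSimConfig | None = None,
) -> RunManifest:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    anatomy = anatomy or synthetic.default_anatomy(config.grid_shape, config.voxel_size_mm)
    specs = specs if specs is not None else synthetic.default_specs()
    sim_cfg = sim_cfg or synthetic.SubjectSimConfig()
    group_sizes = group_sizes or {"left": 20, "right": 20, "bilateral": 8, "control": 12}
    synthetic.simulate_cohort(anatomy, group_sizes, specs, sim_cfg, config.master_seed, out_dir)
    manifest = RunManifest(out_dir, config)
    files = sorted((out_dir / "volumes").glob("*.nii.gz")) + [out_dir / "cohort.csv", out_dir / "ground_truth.json"]
    manifest.record_stage("simulate", files)
    return manifest


def _load_volumes(out_dir: Path, table: CohortTable) -> dict[str, GreyMatterVolume]:
    return {sid: read_volume(out_dir / "volumes" / f"{sid}.nii.gz") for sid in table.ids}


def stage_template(config: PipelineConfig, out_dir: Path) -> RunManifest:
    out_dir = Path(out_dir)
    table = read_cohort(out_dir / "cohort.csv")
    volumes = _load_volumes(out_dir, table)
    tdir = out_dir / "template"
    (tdir / "fields").mkdir(parents=True, exist_ok=True)
    tmpl, pairs = build_symmetric_template(
        [volumes[sid] for sid in table.ids], _reg_params(config), config.template_iterations
    )
    write_volume(tmpl.template, tdir / "template.nii.gz")
    files = [tdir / "template.nii.gz"]
    for sid, (f_orig, f_flip) in zip(table.ids, pairs):
        write_field(f_orig, tdir / "fields" / f"{sid}_orig.nii.gz")
        write_field(f_flip, tdir / "fields" / f"{sid}_flip.nii.gz")
        files += [tdir / "fields" / f"{sid}_orig.nii.gz", tdir / "fields" / f"{sid}_flip.nii.gz"]
    with open(tdir / "provenance.json", "w") as fh:
        json.dump(
            {"n_iterations": tmpl.n_iterations, "symmetry_residual": tmpl.symmetry_residual},
            fh,
            indent=1,
        )
    files.append(tdir / "provenance.json")
    manifest = RunManifest(out_dir, config)
    manifest.record_stage("template", files)
    return manifest


def stage_ai(config: PipelineConfig, out_dir: Path) -> RunManifest:
    out_dir = Path(out_dir)
    table = read_cohort(out_dir / "cohort.csv")
    volumes = _load_volumes(out_dir, table)
    template = read_volume(out_dir / "template" / "template.nii.gz", space_tag="template")
    mask = make_right_hemisphere_mask(template, config.gm_threshold_frac * template.data.max())
    eps = config.ai_eps_frac * template.data.max()
    adir = out_dir / "ai"
    adir.mkdir(parents=True, exist_ok=True)
    mask_vol = GreyMatterVolume(mask.mask.astype(np.float64), mask.affine, "template")
    write_volume(mask_vol, adir / "mask.nii.gz")
    files = [adir / "mask.nii.gz"]
    fwhm = config.smoothing_fwhm_mm
    for sid in table.ids:
        f_orig = read_field(out_dir / "template" / "fields" / f"{sid}_orig.nii.gz")
        f_flip = read_field(out_dir / "template" / "fields" / f"{sid}_flip.nii.gz")
        warped = warp_and_modulate(volumes[sid], f_orig)
        warped_flip = warp_and_modulate(flip_lr(volumes[sid]), f_flip)
        ai0 = compute_ai(warped, warped_flip, mask, eps=eps, subject_id=sid)
        ai_s = smooth_ai(ai0, mask, fwhm)
        write_volume(warped, adir / f"{sid}_warped.nii.gz")
        write_volume(warped_flip, adir / f"{sid}_warped_flip.nii.gz")
        _write_signed(ai0.data, mask.affine, adir / f"{sid}_ai_s0.nii.gz")
        _write_signed(ai_s.data, mask.affine, adir / f"{sid}_ai_s{fwhm:g}.nii.gz")
        files += [
            adir / f"{sid}_warped.nii.gz",
            adir / f"{sid}_warped_flip.nii.gz",
            adir / f"{sid}_ai_s0.nii.gz",
            adir / f"{sid}_ai_s{fwhm:g}.nii.gz",
        ]
    manifest = RunManifest(out_dir, config)
    manifest.record_stage("ai", files)
    return manifest


def _write_signed(data: np.ndarray, affine: np.ndarray, path: Path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))


def _read_signed(path: Path) -> tuple[np.ndarray, np.ndarray]:
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), np.asarray(img.affine)


def load_ai_images(out_dir: Path, table: CohortTable, fwhm: float) -> dict[str, AIImage]:
    out_dir = Path(out_dir)
    mask_data, affine = _read_signed(out_dir / "ai" / "mask.nii.gz")
    mask = HemisphereMask(mask_data > 0.5, affine)
    images = {}
    for sid in table.ids:
        data, _ = _read_signed(out_dir / "ai" / f"{sid}_ai_s{fwhm:g}.nii.gz")
        data[~mask.mask] = 0.0
        images[sid] = AIImage(np.clip(data, -2, 2), mask, sid, fwhm)
    return images


def _records_frame(records: list[ClusterRecord], contrast: str) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(records):
        rows.append(
            {
                "contrast": contrast,
                "cluster_id": f"{contrast}_{i}",
                "location": r.label,
                "peak_x_mm": r.peak_coord_mm[0],
                "peak_y_mm": r.peak_coord_mm[1],
                "peak_z_mm": r.peak_coord_mm[2],
                "peak_t": r.peak_t,
                "peak_p": r.peak_p,
                "k": r.k,
                "cluster_p_fwe": r.p_fwe,
                "significant": r.significant,
                "direction": r.direction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contrast",
            "cluster_id",
            "location",
            "peak_x_mm",
            "peak_y_mm",
            "peak_z_mm",
            "peak_t",
            "peak_p",
            "k",
            "cluster_p_fwe",
            "significant",
            "direction",
        ],
    )


def stage_infer(config: PipelineConfig, out_dir: Path) -> RunManifest:
    """Within-group asymmetry maps and between-group contrasts.

    Within-group: one-sample sign-flip tests per HLD group (>= 3 subjects).
    Between-group: controls vs left HLD (two-group model, both directions) and
    a three-group model over left/right/bilateral HLD with pairwise contrasts.
    """
    out_dir = Path(out_dir)
    table = read_cohort(out_dir / "cohort.csv")
    ai = load_ai_images(out_dir, table, config.smoothing_fwhm_mm)
    idir = out_dir / "infer"
    idir.mkdir(parents=True, exist_ok=True)
    frames = []
    members_npz: dict[str, np.ndarray] = {}

    groups = table.frame.set_index("id")["hld_group"].to_dict()
    by_group: dict[str, list[str]] = {}
    for sid, g in groups.items():
        by_group.setdefault(g, []).append(sid)

    seed_offset = 0
    for g in sorted(by_group):
        ids = by_group[g]
        if len(ids) < 3:
            log.info("skipping within-group analysis for %s (n=%d < 3)", g, len(ids))
            continue
        params = _inference_params(config, seed_offset)
        seed_offset += 1
        leftward, rightward = within_group_asymmetry([ai[s] for s in ids], params)
        for name, recs in [(f"within_{g}_leftward", leftward), (f"within_{g}_rightward", rightward)]:
            frames.append(_records_frame(recs, name))
            for i, r in enumerate(recs):
                members_npz[f"{name}_{i}"] = r.members

    def _two_group(ga: str, gb: str, tag: str) -> None:
        nonlocal seed_offset
        ids = by_group.get(ga, []) + by_group.get(gb, [])
        if len(by_group.get(ga, [])) < 2 or len(by_group.get(gb, [])) < 2:
            return
        labels = [groups[s] for s in ids]
        images = [ai[s] for s in ids]
        for direction, (ca, cb) in [("gt", (1.0, -1.0)), ("lt", (-1.0, 1.0))]:
            design = DesignMatrix.group_design(labels, {ga: ca, gb: cb})
            params = _inference_params(config, seed_offset)
            seed_offset += 1
            recs = permutation_cluster_fwe(images, design, params, direction="positive")
            name = f"{tag}_{ga}_{direction}_{gb}"
            frames.append(_records_frame(recs, name))
            for i, r in enumerate(recs):
                members_npz[f"{name}_{i}"] = r.members

    _two_group("control", "left", "between")
    _two_group("left", "right", "between")
    _two_group("left", "bilateral", "between")

    clusters = pd.concat(frames, ignore_index=True) if frames else _records_frame([], "none")
    clusters.to_csv(idir / "clusters.csv", index=False)
    np.savez(idir / "cluster_members.npz", **{k: v for k, v in members_npz.items()})
    manifest = RunManifest(out_dir, config)
    manifest.record_stage("infer", [idir / "clusters.csv"])
    return manifest


def stage_profile(config: PipelineConfig, out_dir: Path) -> RunManifest:
    """Profile significant left-vs-right HLD clusters: per-subject mean AI and
    hemispheric content, per-hemisphere ANOVA, and z-score consistency."""
    out_dir = Path(out_dir)
    table = read_cohort(out_dir / "cohort.csv")
    groups = table.frame.set_index("id")["hld_group"].to_dict()
    clusters = pd.read_csv(out_dir / "infer" / "clusters.csv")
    members = np.load(out_dir / "infer" / "cluster_members.npz")
    pdir = out_dir / "profile"
    pdir.mkdir(parents=True, exist_ok=True)

    compared = ("left", "right")
    ids = [s for s in table.ids if groups[s] in compared]
    sig = clusters[
        clusters["significant"]
        & clusters["contrast"].str.startswith("between_left_")
        & clusters["contrast"].str.contains("_right")
    ]
    ai = {s: v for s, v in load_ai_images(out_dir, table, 0.0).items() if s in ids}
    warped = {s: read_volume(out_dir / "ai" / f"{s}_warped.nii.gz", "template") for s in ids}
    warped_flip = {s: read_volume(out_dir / "ai" / f"{s}_warped_flip.nii.gz", "template") for s in ids}

    profile_frames, anova_rows, cons_rows, z_rows = [], [], [], []
    for _, row in sig.iterrows():
        cid = row["cluster_id"]
        rec = ClusterRecord(
            peak_coord_mm=(row["peak_x_mm"], row["peak_y_mm"], row["peak_z_mm"]),
            peak_t=row["peak_t"],
            peak_p=row["peak_p"],
            k=int(row["k"]),
            p_fwe=row["cluster_p_fwe"],
            members=members[cid],
            direction=row["direction"],
            significant=True,
        )
        prof = extract_cluster_profiles(rec, warped, warped_flip, ai, cluster_id=cid)
        profile_frames.append(prof.to_frame())
        an = hemisphere_anova(prof, groups)
        anova_rows.append(
            {
                "cluster_id": cid,
                "lh_f": an.lh_f,
                "lh_p": an.lh_p,
                "rh_f": an.rh_f,
                "rh_p": an.rh_p,
                "df_between": an.df[0],
                "df_within": an.df[1],
            }
        )
        cons = zscore_consistency(prof, groups, compared)
        for g in compared:
            cons_rows.append(
                {
                    "cluster_id": cid,
                    "group": g,
                    "n_consistent": cons.n_consistent[g],
                    "percent_consistent": cons.percent_consistent[g],
                    "group_mean_z": cons.group_mean_z[g],
                }
            )
        for sid, z in cons.z_scores.items():
            z_rows.append({"cluster_id": cid, "subject_id": sid, "group": groups[sid], "z": z})

    (pd.concat(profile_frames, ignore_index=True) if profile_frames else pd.DataFrame(
        columns=["cluster_id", "subject_id", "mean_ai", "lh_content_mm3", "rh_content_mm3"]
    )).to_csv(pdir / "profiles.csv", index=False)
    pd.DataFrame(anova_rows, columns=["cluster_id", "lh_f", "lh_p", "rh_f", "rh_p", "df_between", "df_within"]).to_csv(
        pdir / "hemisphere_anova.csv", index=False
    )
    pd.DataFrame(
        cons_rows, columns=["cluster_id", "group", "n_consistent", "percent_consistent", "group_mean_z"]
    ).to_csv(pdir / "consistency.csv", index=False)
    pd.DataFrame(z_rows, columns=["cluster_id", "subject_id", "group", "z"]).to_csv(
        pdir / "zscores.csv", index=False
    )
    manifest = RunManifest(out_dir, config)
    manifest.record_stage(
        "profile",
        [pdir / "profiles.csv", pdir / "hemisphere_anova.csv", pdir / "consistency.csv", pdir / "zscores.csv"],
    )
    return manifest


def stage_stats(config: PipelineConfig, out_dir: Path) -> RunManifest:
    out_dir = Path(out_dir)
    table = read_cohort(out_dir / "cohort.csv")
    sdir = out_dir / "stats"
    sdir.mkdir(parents=True, exist_ok=True)
    summary = summarize_cohort(table)
    summary.group_stats.to_csv(sdir / "summary.csv")
    results: dict = {
        "total_n": summary.total_n,
        "group_n": summary.group_n,
        "group_percent": summary.group_percent,
    }
    df = table.frame
    patients = df[df["hld_group"] != "control"]

    def _side_counts(g: str) -> tuple[int, int]:
        sub = patients[patients["hld_group"] == g]
        return int((sub["epilepsy_side"] == "L").sum()), int((sub["epilepsy_side"] == "R").sum())

    have = set(patients["hld_group"])
    if {"left", "right"} <= have:
        t = [_side_counts("left"), _side_counts("right")]
        try:
            r = chi_square_2x2(t, "pearson")
            results["chi2_left_vs_right_side"] = {"statistic": r.statistic, "p": r.p, "variant": r.variant}
        except ValueError as e:
            results["chi2_left_vs_right_side"] = {"error": str(e)}
    if {"left", "bilateral"} <= have:
        t = [_side_counts("left"), _side_counts("bilateral")]
        try:
            r = chi_square_2x2(t, "yates")
            results["chi2_left_vs_bilateral_side"] = {"statistic": r.statistic, "p": r.p, "variant": r.variant}
        except ValueError as e:
            results["chi2_left_vs_bilateral_side"] = {"error": str(e)}
    if len(set(patients["hld_group"])) >= 2:
        an = group_anova_posthoc(patients["ehi"].to_numpy(), patients["hld_group"].to_numpy())
        results["ehi_anova"] = {
            "f": an.f,
            "df": list(an.df),
            "p": an.p,
            "pairwise_bonferroni": {f"{a}|{b}": p for (a, b), p in an.pairwise_p.items()},
        }
    with open(sdir / "tests.json", "w") as fh:
        json.dump(results, fh, indent=1, sort_keys=True)
    manifest = RunManifest(out_dir, config)
    manifest.record_stage("stats", [sdir / "summary.csv", sdir / "tests.json"])
    return manifest


def stage_report(config: PipelineConfig, out_dir: Path) -> RunManifest:
    """Assemble demographic, cluster and consistency tables from run outputs."""
    out_dir = Path(out_dir)
    rdir = out_dir / "report"
    required = [
        out_dir / "stats" / "summary.csv",
        out_dir / "infer" / "clusters.csv",
        out_dir / "profile" / "consistency.csv",
        out_dir / "profile" / "profiles.csv",
        out_dir / "profile" / "zscores.csv",
    ]
    missing = [str(p) for p in required if not p.exists()]
    if missing:
        raise FileNotFoundError(f"report requires upstream outputs, missing: {missing}")
    rdir.mkdir(parents=True, exist_ok=True)
    demo = pd.read_csv(required[0])
    demo.to_csv(rdir / "table_demographics.csv", index=False)
    clusters = pd.read_csv(required[1])
    clusters[clusters["significant"] == True].to_csv(rdir / "table_clusters.csv", index=False)  # noqa: E712
    pd.read_csv(required[2]).to_csv(rdir / "table_consistency.csv", index=False)
    profiles = pd.read_csv(required[3])
    profiles.to_csv(rdir / "boxplot_ai_data.csv", index=False)
    pd.read_csv(required[4]).to_csv(rdir / "zscore_series.csv", index=False)
    manifest = RunManifest(out_dir, config)
    manifest.record_stage(
        "report",
        [
            rdir / "table_demographics.csv",
            rdir / "table_clusters.csv",
            rdir / "table_consistency.csv",
            rdir / "boxplot_ai_data.csv",
            rdir / "zscore_series.csv",
        ],
    )
    return manifest


def run_all(config: PipelineConfig, out_dir: Path, **simulate_kwargs) -> RunManifest:
    stage_simulate(config, out_dir, **simulate_kwargs)
    stage_template(config, out_dir)
    stage_ai(config, out_dir)
    stage_infer(config, out_dir)
    stage_profile(config, out_dir)
    stage_stats(config, out_dir)
    return stage_report(config, out_dir)
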
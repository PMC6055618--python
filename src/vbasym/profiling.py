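"""Per-subject profiling of significant clusters.

For each significant cluster, the mean asymmetry index and the hemispheric
grey-matter content are extracted per subject: right-hemisphere content is the
sum of the modulated warped grey matter over the cluster's voxels times the
voxel volume, and left-hemisphere content is the same sum over the warped
flipped image at the same (right-hemisphere) voxels, i.e. the homologous left
tissue.  Group differences in hemispheric content are tested with one-way
ANOVAs per hemisphere, and single-subject consistency with the group-level
asymmetry pattern is quantified by standardizing individual cluster AIs to
z-scores over the two compared groups pooled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .asymmetry import AIImage
from .inference import ClusterRecord
from .io_core import GreyMatterVolume

__all__ = [
    "ClusterProfile",
    "HemisphereAnovaResult",
    "ConsistencySummary",
    "extract_cluster_profiles",
    "hemisphere_anova",
    "zscore_consistency",
    "round_half_away",
]


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (table formatting convention)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


@dataclass
class ClusterProfile:
    cluster_id: str
    subject_ids: list[str]
    mean_ai: np.ndarray  # per subject
    lh_content: np.ndarray  # mm^3-equivalent grey matter, left homologue
    rh_content: np.ndarray

    def __post_init__(self) -> None:
        self.mean_ai = np.asarray(self.mean_ai, dtype=np.float64)
        self.lh_content = np.asarray(self.lh_content, dtype=np.float64)
        self.rh_content = np.asarray(self.rh_content, dtype=np.float64)
        if (self.lh_content < 0).any() or (self.rh_content < 0).any():
            raise ValueError("hemispheric content must be >= 0")
        if (np.abs(self.mean_ai) > 2.0 + 1e-9).any():
            raise ValueError("mean AI out of [-2, 2]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster_id": self.cluster_id,
                "subject_id": self.subject_ids,
                "mean_ai": self.mean_ai,
                "lh_content_mm3": self.lh_content,
                "rh_content_mm3": self.rh_content,
            }
        )


@dataclass
class HemisphereAnovaResult:
    lh_f: float
    lh_p: float
    rh_f: float
    rh_p: float
    lh_group_means: dict[str, float]
    rh_group_means: dict[str, float]
    df: tuple[int, int]

    def __post_init__(self) -> None:
        if self.lh_f < 0 or self.rh_f < 0:
            raise ValueError("F must be >= 0")


@dataclass
class ConsistencySummary:
    cluster_id: str
    n_consistent: dict[str, int]
    percent_consistent: dict[str, float]
    z_scores: dict[str, float]  # per subject
    group_mean_z: dict[str, float]


def extract_cluster_profiles(
    cluster: ClusterRecord,
    warped: dict[str, GreyMatterVolume],
    warped_flipped: dict[str, GreyMatterVolume],
    ai: dict[str, AIImage],
    cluster_id: str = "",
) -> ClusterProfile:
    """Per-subject mean AI and left/right hemispheric grey-matter content over
    the cluster's member voxels."""
    if cluster.k < 1 or len(cluster.members) == 0:
        raise ValueError("cluster has no member voxels")
    members = tuple(cluster.members.T)
    subject_ids = sorted(ai)
    if sorted(warped) != subject_ids or sorted(warped_flipped) != subject_ids:
        raise ValueError("subject sets of warped, warped_flipped and ai must match")
    mean_ai, lh, rh = [], [], []
    for sid in subject_ids:
        vox_vol = warped[sid].voxel_volume_mm3
        mean_ai.append(float(ai[sid].data[members].mean()))
        rh.append(float(warped[sid].data[members].sum() * vox_vol))
        lh.append(float(warped_flipped[sid].data[members].sum() * vox_vol))
    return ClusterProfile(cluster_id or "cluster", subject_ids, mean_ai, lh, rh)


def hemisphere_anova(profile: ClusterProfile, groups: dict[str, str]) -> HemisphereAnovaResult:
    """One-way ANOVA on left- and right-hemisphere cluster content separately.

    ``groups`` maps subject id -> group label.  For two groups, F equals the
    square of the pooled two-sample t.
    """
    labels = np.asarray([groups[sid] for sid in profile.subject_ids])
    levels = sorted(set(labels.tolist()))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    split_lh = [profile.lh_content[labels == g] for g in levels]
    split_rh = [profile.rh_content[labels == g] for g in levels]
    for g, arr in zip(levels, split_lh):
        if len(arr) < 2:
            raise ValueError(f"group {g} has fewer than 2 subjects")
    lh_f, lh_p = stats.f_oneway(*split_lh)
    rh_f, rh_p = stats.f_oneway(*split_rh)

    def _clean(f, p):
        if not np.isfinite(f):  # identical values within groups
            return 0.0, 1.0
        return float(f), float(p)

    lh_f, lh_p = _clean(lh_f, lh_p)
    rh_f, rh_p = _clean(rh_f, rh_p)
    n = len(labels)
    return HemisphereAnovaResult(
        lh_f,
        lh_p,
        rh_f,
        rh_p,
        {g: float(a.mean()) for g, a in zip(levels, split_lh)},
        {g: float(a.mean()) for g, a in zip(levels, split_rh)},
        (len(levels) - 1, n - len(levels)),
    )


def zscore_consistency(
    profile: ClusterProfile, groups: dict[str, str], compared: tuple[str, str]
) -> ConsistencySummary:
    """Single-subject consistency with the group-level asymmetry pattern.

    Individual cluster AIs of the two compared groups pooled are standardized
    to z-scores (pooled mean 0, SD 1); a subject is consistent when the sign
    of its z matches the sign of its group's mean z.
    """
    labels = {sid: groups[sid] for sid in profile.subject_ids}
    sel = [i for i, sid in enumerate(profile.subject_ids) if labels[sid] in compared]
    if not sel:
        raise ValueError("no subjects in the compared groups")
    ids = [profile.subject_ids[i] for i in sel]
    ais = profile.mean_ai[sel]
    sd = float(ais.std(ddof=1))
    if sd <= 0:
        raise ValueError(f"zero pooled SD of AIs in cluster {profile.cluster_id}")
    z = (ais - ais.mean()) / sd
    zmap = dict(zip(ids, z))
    group_mean_z = {
        g: float(np.mean([zmap[sid] for sid in ids if labels[sid] == g])) for g in compared
    }
    n_consistent, pct = {}, {}
    for g in compared:
        members = [sid for sid in ids if labels[sid] == g]
        ref_sign = np.sign(group_mean_z[g])
        n_ok = int(sum(np.sign(zmap[sid]) == ref_sign for sid in members))
        n_consistent[g] = n_ok
        pct[g] = round_half_away(100.0 * n_ok / len(members), 1)
    return ConsistencySummary(profile.cluster_id, n_consistent, pct, {k: float(v) for k, v in zmap.items()}, group_mean_z)
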
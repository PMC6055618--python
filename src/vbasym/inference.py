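"""Voxel-wise general-linear-model t-maps and cluster-level family-wise-error
inference by permutation.

Within-group asymmetries are tested with one-sample GLMs against zero
(null distribution by sign-flipping subject AI images); group differences with
group-indicator designs and optional mean-centered covariates (null by
permuting group labels).  Family-wise error is controlled at the cluster
level with the maximum-cluster-size statistic: suprathreshold voxels at the
cluster-forming threshold are grouped into connected components, and each
observed cluster's p_FWE is the add-one permutation probability that the null
maximum cluster size reaches its size.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .asymmetry import AIImage, HemisphereMask

__all__ = [
    "DesignMatrix",
    "TMap",
    "ClusterRecord",
    "InferenceParams",
    "fit_glm",
    "threshold_clusters",
    "permutation_cluster_fwe",
    "within_group_asymmetry",
    "stack_ai_images",
]

log = logging.getLogger(__name__)

_CONNECTIVITY_STRUCT = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class DesignMatrix:
    """Subjects x regressors design with a single t-contrast.

    ``kind`` selects the permutation scheme: 'one_sample' designs are
    sign-flipped, 'group' designs have their group labels permuted (covariates
    stay attached to their subjects).
    """

    X: np.ndarray
    names: list[str]
    contrast: np.ndarray
    kind: str = "general"
    groups: np.ndarray | None = None
    n_group_cols: int = 0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.contrast = np.asarray(self.contrast, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("design matrix must be 2D")
        n, p = self.X.shape
        if len(self.contrast) != p:
            raise ValueError("contrast length must equal number of regressors")
        if np.linalg.matrix_rank(self.X) < p:
            raise ValueError("design matrix is rank deficient")
        if n - p < 2:
            raise ValueError("residual degrees of freedom must be >= 2")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def df(self) -> int:
        return self.X.shape[0] - np.linalg.matrix_rank(self.X)

    @classmethod
    def one_sample(cls, n: int) -> "DesignMatrix":
        return cls(np.ones((n, 1)), ["intercept"], np.array([1.0]), kind="one_sample")

    @classmethod
    def group_design(
        cls,
        groups,
        contrast_groups: dict[str, float],
        covariates: np.ndarray | None = None,
        covariate_names: list[str] | None = None,
    ) -> "DesignMatrix":
        """Cell-means coding (one indicator per group, no intercept) plus
        mean-centered covariates; contrast given per group name."""
        groups = np.asarray(groups)
        levels = sorted(set(groups.tolist()))
        X = np.stack([(groups == g).astype(float) for g in levels], axis=1)
        names = list(levels)
        contrast = [float(contrast_groups.get(g, 0.0)) for g in levels]
        unknown = set(contrast_groups) - set(levels)
        if unknown:
            raise ValueError(f"contrast names not in groups: {sorted(unknown)}")
        if covariates is not None:
            cov = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
            if cov.shape[0] != len(groups):
                cov = cov.T
            cov = cov - cov.mean(axis=0, keepdims=True)
            X = np.hstack([X, cov])
            names += covariate_names or [f"cov{i}" for i in range(cov.shape[1])]
            contrast += [0.0] * cov.shape[1]
        return cls(X, names, np.array(contrast), kind="group", groups=groups, n_group_cols=len(levels))


@dataclass
class TMap:
    data: np.ndarray
    df: int
    mask: HemisphereMask

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != self.mask.shape:
            raise ValueError("t-map grid does not match mask")
        if not np.isfinite(self.data[self.mask.mask]).all():
            raise ValueError("non-finite t values on the mask")

    def masked_values(self) -> np.ndarray:
        return self.data[self.mask.mask]


@dataclass
class ClusterRecord:
    peak_coord_mm: tuple[float, float, float]
    peak_t: float
    peak_p: float
    k: int
    p_fwe: float
    members: np.ndarray  # (k, 3) voxel indices
    direction: str
    significant: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("cluster must contain at least one voxel")
        if not (0.0 <= self.p_fwe <= 1.0):
            raise ValueError("p_FWE must be in [0, 1]")


@dataclass
class InferenceParams:
    cluster_forming_p: float = 0.001
    fwe_alpha: float = 0.05
    n_permutations: int = 1000
    seed: int = 0
    connectivity: int = 26

    def __post_init__(self) -> None:
        if not (0 < self.cluster_forming_p < 1):
            raise ValueError("cluster-forming p must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100 for reported p-values")
        if self.connectivity not in _CONNECTIVITY_STRUCT:
            raise ValueError("connectivity must be one of 6, 18, 26")


def stack_ai_images(ai_images: list[AIImage]) -> tuple[np.ndarray, HemisphereMask]:
    """Stack masked AI values into an (n_subjects, n_voxels) matrix."""
    if not ai_images:
        raise ValueError("no AI images")
    mask = ai_images[0].mask
    for a in ai_images[1:]:
        if a.mask.shape != mask.shape or not np.array_equal(a.mask.mask, mask.mask):
            raise ValueError("AI images must share one mask")
    Y = np.stack([a.data[mask.mask] for a in ai_images], axis=0)
    return Y, mask


def _t_from_design(X: np.ndarray, Y: np.ndarray, contrast: np.ndarray, df: int, yy: np.ndarray | None = None) -> np.ndarray:
    """Closed-form OLS t statistics for one contrast at every voxel."""
    XtX = X.T @ X
    XtY = X.T @ Y
    beta = np.linalg.solve(XtX, XtY)
    if yy is None:
        yy = np.einsum("nv,nv->v", Y, Y)
    rss = yy - np.einsum("pv,pv->v", XtY, beta)
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / df
    cvar = float(contrast @ np.linalg.solve(XtX, contrast))
    se = np.sqrt(sigma2 * cvar)
    num = contrast @ beta
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, num / np.where(se > 0, se, 1.0), 0.0)
    return t


def fit_glm(ai_images: list[AIImage], design: DesignMatrix) -> TMap:
    """Per-voxel OLS fit; voxels with zero residual variance get t = 0."""
    Y, mask = stack_ai_images(ai_images)
    if Y.shape[0] != design.n:
        raise ValueError("number of AI images must equal design rows")
    t = _t_from_design(design.X, Y, design.contrast, design.df)
    grid = np.zeros(mask.shape)
    grid[mask.mask] = t
    return TMap(grid, design.df, mask)


def _suprathreshold(tgrid: np.ndarray, t_crit: float, direction: str) -> np.ndarray:
    if direction == "positive":
        return tgrid > t_crit
    if direction == "negative":
        return tgrid < -t_crit
    if direction == "two_sided":
        return np.abs(tgrid) > t_crit
    raise ValueError(f"unknown direction: {direction}")


def _t_crit(p: float, df: int, direction: str) -> float:
    if direction == "two_sided":
        return float(stats.t.isf(p / 2.0, df))
    return float(stats.t.isf(p, df))


def threshold_clusters(
    tmap: TMap, params: InferenceParams, direction: str = "positive"
) -> list[dict]:
    """Connected components of suprathreshold voxels at the cluster-forming
    threshold; returns member indices, size and peak per cluster."""
    t_crit = _t_crit(params.cluster_forming_p, tmap.df, direction)
    sup = _suprathreshold(tmap.data, t_crit, direction) & tmap.mask.mask
    if not sup.any():
        return []
    labels, n_lab = ndimage.label(sup, structure=_CONNECTIVITY_STRUCT[params.connectivity])
    clusters = []
    for lab in range(1, n_lab + 1):
        members = np.argwhere(labels == lab)
        tvals = tmap.data[tuple(members.T)]
        signed = np.abs(tvals) if direction == "two_sided" else (tvals if direction == "positive" else -tvals)
        ipk = int(np.argmax(signed))
        clusters.append(
            {
                "members": members,
                "k": int(len(members)),
                "peak_t": float(tvals[ipk]),
                "peak_ijk": tuple(int(v) for v in members[ipk]),
            }
        )
    clusters.sort(key=lambda c: -c["k"])
    return clusters


def _max_cluster_size(sup: np.ndarray, structure: np.ndarray) -> int:
    if not sup.any():
        return 0
    idx = np.argwhere(sup)
    lo = np.maximum(idx.min(axis=0) - 1, 0)
    hi = idx.max(axis=0) + 2
    box = sup[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    labels, n_lab = ndimage.label(box, structure=structure)
    if n_lab == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def _multiset_permutations(items: list):
    """Distinct permutations of a multiset (lexicographic)."""
    items = sorted(items)
    n = len(items)
    while True:
        yield list(items)
        i = n - 2
        while i >= 0 and items[i] >= items[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while items[j] <= items[i]:
            j -= 1
        items[i], items[j] = items[j], items[i]
        items[i + 1 :] = reversed(items[i + 1 :])


def _n_distinct_permutations(design: DesignMatrix) -> float:
    if design.kind == "one_sample":
        return 2.0 ** design.n
    groups = design.groups
    counts = [int((groups == g).sum()) for g in sorted(set(groups.tolist()))]
    total = math.factorial(sum(counts))
    for c in counts:
        total //= math.factorial(c)
    return float(total)


def _permuted_designs(design: DesignMatrix, n_perm: int, rng: np.random.Generator):
    """Yield permuted design matrices under the scheme matching the design kind.

    If the number of distinct permutations does not exceed the request, all of
    them are enumerated exhaustively (logged); otherwise random draws are used.
    """
    n_distinct = _n_distinct_permutations(design)
    exhaustive = n_distinct <= n_perm
    if exhaustive:
        log.info(
            "only %d distinct permutations available (requested %d): enumerating exhaustively",
            int(n_distinct),
            n_perm,
        )
    if design.kind == "one_sample":
        if exhaustive:
            for signs in itertools.product((1.0, -1.0), repeat=design.n):
                yield np.asarray(signs)[:, None] * design.X
        else:
            for _ in range(n_perm):
                signs = rng.choice((1.0, -1.0), size=design.n)
                yield signs[:, None] * design.X
    elif design.kind == "group":
        groups = design.groups
        levels = sorted(set(groups.tolist()))

        def build(perm_groups: np.ndarray) -> np.ndarray:
            Xp = design.X.copy()
            for j, g in enumerate(levels):
                Xp[:, j] = (perm_groups == g).astype(float)
            return Xp

        if exhaustive:
            for perm in _multiset_permutations(list(groups)):
                yield build(np.asarray(perm))
        else:
            for _ in range(n_perm):
                yield build(groups[rng.permutation(design.n)])
    else:
        raise ValueError(f"no permutation scheme for design kind {design.kind!r}")


def permutation_cluster_fwe(
    ai_images: list[AIImage],
    design: DesignMatrix,
    params: InferenceParams,
    direction: str = "positive",
) -> list[ClusterRecord]:
    """Cluster-level FWE-corrected inference by the max-cluster-size permutation null.

    p_FWE = (1 + #{null max-k >= observed k}) / (1 + n_permutations); records
    with p_FWE <= alpha are flagged significant.  Deterministic given the seed.
    """
    Y, mask = stack_ai_images(ai_images)
    if Y.shape[0] != design.n:
        raise ValueError("number of AI images must equal design rows")
    tmap = fit_glm(ai_images, design)
    observed = threshold_clusters(tmap, params, direction)

    affine = mask.affine
    structure = _CONNECTIVITY_STRUCT[params.connectivity]
    t_crit = _t_crit(params.cluster_forming_p, design.df, direction)

    rng = np.random.default_rng(params.seed)
    yy = np.einsum("nv,nv->v", Y, Y)
    null_max = []
    grid = np.zeros(mask.shape)
    for Xp in _permuted_designs(design, params.n_permutations, rng):
        t = _t_from_design(Xp, Y, design.contrast, design.df, yy=yy)
        grid[mask.mask] = t
        sup = _suprathreshold(grid, t_crit, direction) & mask.mask
        null_max.append(_max_cluster_size(sup, structure))
    null_max = np.asarray(null_max)
    n_perm_used = len(null_max)

    records = []
    for c in observed:
        p_fwe = float((1 + (null_max >= c["k"]).sum()) / (1 + n_perm_used))
        ijk = np.array(c["peak_ijk"] + (1,))
        coord = tuple(float(v) for v in (affine @ ijk)[:3])
        if direction == "two_sided":
            peak_p = 2.0 * float(stats.t.sf(abs(c["peak_t"]), design.df))
        else:
            peak_p = float(stats.t.sf(abs(c["peak_t"]), design.df))
        records.append(
            ClusterRecord(
                peak_coord_mm=coord,
                peak_t=c["peak_t"],
                peak_p=peak_p,
                k=c["k"],
                p_fwe=p_fwe,
                members=c["members"],
                direction=direction,
                significant=p_fwe <= params.fwe_alpha,
            )
        )
    return records


def _negate_ai(a: AIImage) -> AIImage:
    return AIImage(-a.data, a.mask, a.subject_id, a.smoothed_fwhm_mm)


def within_group_asymmetry(
    ai_images: list[AIImage], params: InferenceParams
) -> tuple[list[ClusterRecord], list[ClusterRecord]]:
    """One-sample asymmetry maps: significant leftward (AI > 0) and rightward
    (AI < 0) clusters, each with its own sign-flip cluster-level FWE.

    The rightward analysis runs on the negated images with the same seed, so
    negating all inputs swaps the two lists exactly.
    """
    if len(ai_images) < 3:
        raise ValueError("within-group analysis needs at least 3 subjects")
    design = DesignMatrix.one_sample(len(ai_images))
    leftward = permutation_cluster_fwe(ai_images, design, params, direction="positive")
    negated = [_negate_ai(a) for a in ai_images]
    rightward = permutation_cluster_fwe(negated, design, params, direction="positive")
    for r in rightward:
        r.direction = "negative"
        r.peak_t = -r.peak_t
    return leftward, rightward
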
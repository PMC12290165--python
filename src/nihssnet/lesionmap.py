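"""Cluster lesion-density maps and one-vs-rest voxel-wise permutation tests.

Each subject contributes a binary lesion mask on a common grid.  For a
cluster ``i`` with ``n_i`` members in a cohort of ``n`` subjects, and a
voxel ``v`` lesioned ``v_i+`` times inside the cluster and ``v+`` times
overall, the two-proportion statistic with pooled variance is

    t_v = | v_i+/n_i - (v+ - v_i+)/(n - n_i) |
          / sqrt( (v+/n) (1 - v+/n) (1/n_i + 1/(n - n_i)) ).

Only voxels lesioned in at least a given fraction of the cohort are
tested.  The null distribution is built by permuting the one-vs-rest
cluster indicator; family-wise error is controlled with the Westfall-Young
step-down maxT procedure, and a Bonferroni correction across the k
one-vs-rest families yields an overall FWER level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats

from ._validate import ValidationError, check_labels

__all__ = [
    "LesionVolumeSet",
    "VoxelTestResult",
    "density_map",
    "select_voxels",
    "proportion_statistic",
    "permutation_maxt",
    "one_vs_rest_analysis",
    "lesion_volume_comparison",
]


@dataclass
class LesionVolumeSet:
    """Per-subject binary lesion masks on one common grid.

    ``masks`` is an (n, nx, ny, nz) array of {0, 1}; ``affine`` maps voxel
    indices to world (scanner/template) coordinates.
    """

    masks: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        masks = np.asarray(self.masks)
        if masks.ndim != 4:
            raise ValidationError(f"masks must be (n, nx, ny, nz), got {masks.shape}")
        if not np.isin(masks, (0, 1)).all():
            raise ValidationError("masks must be binary {0, 1}")
        self.masks = masks.astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if self.subject_ids is not None and len(self.subject_ids) != masks.shape[0]:
            raise ValidationError("subject_ids length does not match masks")

    @property
    def n(self) -> int:
        return self.masks.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.masks.shape[1:]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres, from the affine."""
        return abs(float(np.linalg.det(self.affine[:3, :3]))) / 1000.0

    def flat(self) -> np.ndarray:
        """(n, n_voxels) view of the masks."""
        return self.masks.reshape(self.n, -1)

    def volumes_ml(self) -> np.ndarray:
        """Per-subject lesion volume in mL."""
        return self.flat().sum(axis=1) * self.voxel_volume_ml

    @classmethod
    def from_manifest(cls, manifest: str | Path) -> "LesionVolumeSet":
        """Load masks from a CSV manifest with columns subject_id, path.

        NIfTI images are binarized at > 0.5; non-binary input triggers a
        warning.  All images must share grid shape and affine.
        """
        df = pd.read_csv(manifest)
        base = Path(manifest).parent
        masks, ids = [], []
        shape, affine = None, None
        for _, row in df.iterrows():
            path = Path(row["path"])
            if not path.is_absolute():
                path = base / path
            if not path.exists():
                raise ValidationError(
                    f"mask file for subject {row['subject_id']!r} not found: {path}"
                )
            img = nib.load(str(path))
            data = np.asarray(img.dataobj, dtype=float)
            if not np.isin(data, (0.0, 1.0)).all():
                warnings.warn(
                    f"mask for subject {row['subject_id']!r} is not binary; "
                    "binarizing at > 0.5",
                    stacklevel=2,
                )
            data = (data > 0.5).astype(np.uint8)
            if shape is None:
                shape, affine = data.shape, img.affine
            elif data.shape != shape or not np.allclose(img.affine, affine, atol=1e-6):
                raise ValidationError(
                    f"mask for subject {row['subject_id']!r} is not on the common grid"
                )
            masks.append(data)
            ids.append(str(row["subject_id"]))
        if not masks:
            raise ValidationError("manifest lists no masks")
        return cls(masks=np.stack(masks), affine=affine, subject_ids=ids)


@dataclass
class VoxelTestResult:
    """maxT-adjusted one-vs-rest voxel test for a single cluster."""

    cluster_id: int
    selected_voxels: np.ndarray  # flat voxel indices into the grid
    t_obs: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray
    family_alpha: float
    n_permutations: int
    grid_shape: tuple[int, int, int]

    def significance_mask(self) -> np.ndarray:
        """Binary 3-D mask of significant voxels."""
        mask = np.zeros(int(np.prod(self.grid_shape)), dtype=np.uint8)
        mask[self.selected_voxels[self.significant]] = 1
        return mask.reshape(self.grid_shape)

    def to_frame(self, affine: np.ndarray | None = None) -> pd.DataFrame:
        """Per-voxel table with grid indices, world coordinates, t and p."""
        ijk = np.column_stack(np.unravel_index(self.selected_voxels, self.grid_shape))
        df = pd.DataFrame(ijk, columns=["i", "j", "k"])
        if affine is not None:
            world = nib.affines.apply_affine(affine, ijk)
            df[["x", "y", "z"]] = world
        df["t"] = self.t_obs
        df["p_adjusted"] = self.p_adjusted
        df["significant"] = self.significant
        return df


def _cluster_indicator(labels: np.ndarray, cluster_id: int, n: int) -> np.ndarray:
    labels = check_labels(getattr(labels, "labels", labels), n)
    member = labels == cluster_id
    if member.sum() == 0:
        raise ValidationError(f"cluster {cluster_id} is empty")
    return member


def density_map(volumes: LesionVolumeSet, labels, cluster_id: int) -> np.ndarray:
    """Within-cluster lesion frequency map: the voxelwise mean of the
    cluster's binary masks, in [0, 1]."""
    member = _cluster_indicator(labels, cluster_id, volumes.n)
    return volumes.masks[member].mean(axis=0)


def select_voxels(
    volumes: LesionVolumeSet, min_fraction: float = 0.05
) -> np.ndarray:
    """Flat indices of voxels lesioned in at least ``min_fraction`` of subjects.

    The count threshold is ``floor(min_fraction * n)`` (with n = 172 and 5%
    this gives 8), promoted to 1 when it would be 0.  Selection uses pooled
    lesion counts only and never sees cluster labels.
    """
    if not 0 < min_fraction < 1:
        raise ValidationError("min_fraction must be in (0, 1)")
    threshold = max(1, math.floor(min_fraction * volumes.n + 1e-9))
    counts = volumes.flat().sum(axis=0)
    selected = np.flatnonzero(counts >= threshold)
    if selected.size == 0:
        warnings.warn(
            f"no voxel lesioned at least {threshold} times; empty selection",
            stacklevel=2,
        )
    return selected


def voxel_count_threshold(n: int, min_fraction: float = 0.05) -> int:
    """The lesion-count threshold implied by ``min_fraction`` of n subjects."""
    return max(1, math.floor(min_fraction * n + 1e-9))


def proportion_statistic(v_i_pos: int, n_i: int, v_pos: int, n: int) -> float:
    """Two-proportion statistic with pooled variance for a single voxel.

    Returns 0 (with a warning) when the pooled proportion is 0 or 1: both
    group proportions are then equal and the numerator is 0 as well.
    """
    if not 0 < n_i < n:
        raise ValidationError("need 0 < n_i < n")
    if v_i_pos > min(v_pos, n_i) or v_pos > n or v_i_pos < 0:
        raise ValidationError("inconsistent lesion counts")
    pooled = v_pos / n
    if pooled in (0.0, 1.0):
        warnings.warn(
            "pooled proportion is degenerate (0 or 1); statistic set to 0",
            stacklevel=2,
        )
        return 0.0
    num = abs(v_i_pos / n_i - (v_pos - v_i_pos) / (n - n_i))
    den = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n_i + 1.0 / (n - n_i)))
    return num / den


def _statistics_for_indicator(
    member_counts: np.ndarray, totals: np.ndarray, n_i: int, n: int
) -> np.ndarray:
    """Vectorized t_v for one or many indicator assignments.

    ``member_counts``: (..., V) lesion counts inside the cluster;
    ``totals``: (V,) pooled counts.  Degenerate pooled proportions give 0.
    """
    pooled = totals / n
    den = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n_i + 1.0 / (n - n_i)))
    num = np.abs(member_counts / n_i - (totals - member_counts) / (n - n_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return t


def permutation_maxt(
    volumes: LesionVolumeSet,
    labels,
    cluster_id: int,
    selected_voxels: np.ndarray,
    B: int = 5000,
    family_alpha: float = 0.01,
    seed: int = 0,
) -> VoxelTestResult:
    """Westfall-Young step-down maxT adjusted p-values for one cluster.

    The one-vs-rest indicator is permuted ``B`` times; voxels are ordered
    by decreasing observed statistic and each step uses the permutation
    distribution of the maximum over the not-yet-ordered voxels.  P-values
    follow the add-one convention ``(1 + #{maxT >= t_obs}) / (B + 1)`` (the
    observed labeling is not counted among the B permutations) and are
    forced non-decreasing along the ordering.  Ties in the ordering break
    by voxel index, deterministically.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    selected_voxels = np.asarray(selected_voxels, dtype=int)
    if selected_voxels.size == 0:
        raise ValidationError("selected_voxels must be nonempty")
    n = volumes.n
    member = _cluster_indicator(labels, cluster_id, n)
    n_i = int(member.sum())
    if n_i == n:
        raise ValidationError("cluster equals the whole cohort")

    M = volumes.flat()[:, selected_voxels].astype(np.float64)  # (n, V)
    totals = M.sum(axis=0)
    t_obs = _statistics_for_indicator(member @ M, totals, n_i, n)

    rng = np.random.default_rng(seed)
    # B permuted indicators as a (B, n) 0/1 matrix -> counts by one matmul
    perm = np.argsort(rng.random((B, n)), axis=1)[:, :n_i]
    indicators = np.zeros((B, n))
    np.put_along_axis(indicators, perm, 1.0, axis=1)
    t_perm = _statistics_for_indicator(indicators @ M, totals, n_i, n)  # (B, V)

    order = np.lexsort((selected_voxels, -t_obs))  # decreasing t, ties by index
    # successive maxima over the not-yet-ordered set: suffix max in sorted order
    suffix_max = np.maximum.accumulate(t_perm[:, order][:, ::-1], axis=1)[:, ::-1]
    exceed = (suffix_max >= t_obs[order][None, :] - 1e-12).sum(axis=0)
    p_sorted = (1.0 + exceed) / (B + 1.0)
    p_sorted = np.maximum.accumulate(p_sorted)  # step-down monotonicity
    p_adj = np.empty_like(p_sorted)
    p_adj[order] = p_sorted

    return VoxelTestResult(
        cluster_id=int(cluster_id),
        selected_voxels=selected_voxels,
        t_obs=t_obs,
        p_adjusted=p_adj,
        significant=p_adj <= family_alpha,
        family_alpha=family_alpha,
        n_permutations=B,
        grid_shape=volumes.grid_shape,
    )


def one_vs_rest_analysis(
    volumes: LesionVolumeSet,
    labels,
    overall_alpha: float = 0.05,
    B: int = 5000,
    seed: int = 0,
    min_fraction: float = 0.05,
) -> list[VoxelTestResult]:
    """One-vs-rest maxT analysis for every cluster, Bonferroni across families.

    Each cluster family is tested at ``overall_alpha / k`` so the overall
    FWER across the k families is controlled at ``overall_alpha``.  Voxel
    selection is shared across families (it only uses pooled counts).
    """
    labels_arr = check_labels(getattr(labels, "labels", labels), volumes.n)
    cluster_ids = np.unique(labels_arr)
    k = len(cluster_ids)
    if k < 2:
        raise ValidationError("need at least 2 clusters")
    family_alpha = overall_alpha / k
    selected = select_voxels(volumes, min_fraction)
    seeds = np.random.SeedSequence(seed).generate_state(k) % (2**31)
    return [
        permutation_maxt(
            volumes, labels_arr, int(cl), selected, B, family_alpha, int(s)
        )
        for cl, s in zip(cluster_ids, seeds)
    ]


def lesion_volume_comparison(
    volumes: LesionVolumeSet, labels, cluster_id: int
) -> tuple[float, float]:
    """Kruskal-Wallis (1 df) comparison of lesion volume, cluster vs rest.

    Volumes are in mL (voxel count times voxel volume from the affine).
    Returns ``(H, p)``; all-tied volumes give ``H = 0`` with a warning.
    """
    member = _cluster_indicator(labels, cluster_id, volumes.n)
    if member.all():
        raise ValidationError("cluster equals the whole cohort")
    vols = volumes.volumes_ml()
    inside, outside = vols[member], vols[~member]
    if np.ptp(vols) == 0:
        warnings.warn("all lesion volumes tied; H = 0", stacklevel=2)
        return 0.0, 1.0
    H, p = stats.kruskal(inside, outside)
    return float(H), float(p)


def save_volume(
    data: np.ndarray, affine: np.ndarray, path: str | Path
) -> None:
    """Write a 3-D volume as NIfTI with the given affine."""
    nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine).to_filename(str(path))
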
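"""Synthetic stroke-like cohorts: ordinal score matrices with planted
cluster structure and companion binary lesion volumes.

The default configuration emulates the structure of an acute-stroke NIHSS
cohort: 14 ordinal items with per-item maxima in {2, 3, 4}, five symptom
prototypes loosely modeled on classic syndromes (left motor, visual /
inattention, right motor, mild bilateral lacunar-like, language), and
cluster-specific ellipsoidal lesion loci on a small 3-D grid.  The
prototypes are illustrative fixtures, not clinical claims.  Ordinal noise
is a +/-1 lattice step (clipped to the item range) rather than rounded
Gaussian noise: score space is a lattice, not an interval scale.

All generators are pure functions of their configuration, including the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._validate import ValidationError
from .cohort import OrdinalScoreMatrix
from .lesionmap import LesionVolumeSet
from .rsc import ClusterAssignment

__all__ = [
    "SyntheticCohortConfig",
    "default_config",
    "generate_cohort",
    "generate_null_cohort",
    "DEFAULT_ITEM_NAMES",
    "DEFAULT_ITEM_MAX",
]

#: The 14 NIHSS-style items used after removal of the vigilance item.
DEFAULT_ITEM_NAMES: list[str] = [
    "loc_questions",
    "loc_commands",
    "best_gaze",
    "visual",
    "facial_palsy",
    "motor_arm_left",
    "motor_arm_right",
    "motor_leg_left",
    "motor_leg_right",
    "limb_ataxia",
    "sensory",
    "best_language",
    "dysarthria",
    "extinction_inattention",
]

DEFAULT_ITEM_MAX: np.ndarray = np.array([2, 2, 2, 3, 3, 4, 4, 4, 4, 2, 2, 3, 2, 2])

# Illustrative syndrome prototypes over the 14 items above.  The two
# hemispheric pairs (left motor with visual/inattention, right motor with
# language) share mild contralesional deficits, mirroring the reported
# co-occurrence structure of acute-stroke cohorts: the cohort has a coarse
# hemispheric super-structure on top of the five syndromes.
_DEFAULT_PROTOTYPES: np.ndarray = np.array(
    [
        # left motor: left arm/leg weakness, facial palsy, dysarthria, neglect
        [0, 0, 0, 0, 2, 3, 0, 3, 0, 0, 1, 0, 1, 1],
        # visual / inattention: field cut, gaze preference, neglect, left weakness
        [0, 0, 1, 2, 0, 2, 0, 2, 0, 0, 1, 0, 0, 2],
        # right motor: right arm/leg weakness, facial palsy, dysarthria
        [0, 0, 0, 0, 2, 0, 3, 0, 3, 0, 1, 0, 1, 0],
        # mild bilateral lacunar-like: facial palsy, mild bilateral arm, sensory, ataxia
        [0, 0, 0, 0, 1, 1, 1, 0, 0, 1, 1, 0, 1, 0],
        # language: aphasia, disorientation, right weakness, mild sensory, facial palsy
        [2, 1, 0, 0, 1, 0, 2, 0, 2, 0, 1, 3, 1, 0],
    ]
)

# One lesion locus per syndrome on the default 20 x 24 x 20 grid (x grows
# to the right): right deep MCA-like, posterior, left deep MCA-like,
# central deep (lacunar), left superficial temporal-like.
_DEFAULT_CENTERS: list[tuple[int, int, int]] = [
    (14, 12, 10),
    (10, 5, 9),
    (6, 12, 10),
    (10, 12, 7),
    (4, 9, 8),
]

#: Per-cluster scaling of the lesion radii; the lacunar-like cluster gets
#: distinctly smaller lesions.
_DEFAULT_RADIUS_SCALE: tuple[float, ...] = (1.0, 1.0, 1.0, 0.55, 1.0)


@dataclass
class SyntheticCohortConfig:
    """Configuration of a planted-cluster synthetic cohort.

    ``prototypes`` is a (k_true, m) integer array within the item ranges;
    ``flip_prob`` is the per-item probability of perturbing a score by one
    lattice step (clipped to [0, L_j]); ``lesion_centers`` places one
    ellipsoidal lesion locus per cluster (``None`` entries mean no
    cluster-specific locus) and ``shared_center`` optionally adds a locus
    common to every subject; ``background_rate`` is the per-voxel
    probability of spurious lesioned voxels.
    """

    k_true: int = 5
    sizes: tuple[int, ...] = (30, 30, 30, 30, 30)
    item_names: list[str] = field(default_factory=lambda: list(DEFAULT_ITEM_NAMES))
    item_max: np.ndarray = field(default_factory=lambda: DEFAULT_ITEM_MAX.copy())
    prototypes: np.ndarray = field(default_factory=lambda: _DEFAULT_PROTOTYPES.copy())
    flip_prob: float = 0.1
    grid_shape: tuple[int, int, int] = (20, 24, 20)
    lesion_centers: list[tuple[int, int, int] | None] = field(
        default_factory=lambda: list(_DEFAULT_CENTERS)
    )
    shared_center: tuple[int, int, int] | None = None
    radius_scale: tuple[float, ...] = _DEFAULT_RADIUS_SCALE
    lesion_radius_range: tuple[float, float] = (2.5, 4.5)
    center_jitter: float = 1.0
    background_rate: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        self.item_max = np.asarray(self.item_max, dtype=int)
        self.prototypes = np.asarray(self.prototypes, dtype=int)
        if self.prototypes.shape != (self.k_true, len(self.item_max)):
            raise ValidationError(
                f"prototypes must be (k_true, m) = ({self.k_true}, {len(self.item_max)})"
            )
        if np.any(self.prototypes < 0) or np.any(
            self.prototypes > self.item_max[None, :]
        ):
            raise ValidationError("prototypes out of the per-item [0, L_j] range")
        if len(self.sizes) != self.k_true or any(s < 1 for s in self.sizes):
            raise ValidationError("sizes must list >= 1 subjects per planted cluster")
        if not 0 <= self.flip_prob < 1:
            raise ValidationError("flip_prob must be in [0, 1)")
        if len(self.lesion_centers) != self.k_true:
            raise ValidationError("need one lesion center (or None) per cluster")
        if len(self.radius_scale) != self.k_true:
            raise ValidationError("need one radius scale per cluster")


def default_config(**overrides) -> SyntheticCohortConfig:
    """The default five-syndrome cohort configuration, optionally overridden."""
    return replace(SyntheticCohortConfig(), **overrides) if overrides else SyntheticCohortConfig()


def _ellipsoid_mask(
    grid_shape: tuple[int, int, int],
    center: np.ndarray,
    radii: np.ndarray,
) -> np.ndarray:
    coords = np.indices(grid_shape, dtype=float)
    dist2 = sum(
        ((coords[d] - center[d]) / max(radii[d], 1e-9)) ** 2 for d in range(3)
    )
    return (dist2 <= 1.0).astype(np.uint8)


def _noisy_scores(
    prototype: np.ndarray, item_max: np.ndarray, flip_prob: float, rng
) -> np.ndarray:
    scores = prototype.copy()
    flips = rng.random(len(scores)) < flip_prob
    steps = rng.choice((-1, 1), size=len(scores))
    scores[flips] = np.clip(scores[flips] + steps[flips], 0, item_max[flips])
    return scores


def generate_cohort(
    config: SyntheticCohortConfig | None = None, seed: int | None = None
) -> tuple[OrdinalScoreMatrix, LesionVolumeSet, ClusterAssignment]:
    """Generate scores, lesion masks and the planted labels for one cohort.

    Scores are the cluster prototype plus ordinal lattice noise.  Each
    subject's mask is an ellipsoid at the cluster's lesion locus with
    jittered center and random radii, optionally merged with a shared locus
    and sprinkled with background-rate noise voxels.
    """
    config = config or SyntheticCohortConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = int(sum(config.sizes))
    labels = np.repeat(np.arange(config.k_true), config.sizes)

    X = np.empty((n, len(config.item_max)), dtype=int)
    masks = np.zeros((n, *config.grid_shape), dtype=np.uint8)
    lo, hi = config.lesion_radius_range
    for a in range(n):
        cl = labels[a]
        X[a] = _noisy_scores(
            config.prototypes[cl], config.item_max, config.flip_prob, rng
        )
        mask = np.zeros(config.grid_shape, dtype=np.uint8)
        center = config.lesion_centers[cl]
        if center is not None:
            jitter = rng.normal(0.0, config.center_jitter, size=3)
            radii = rng.uniform(lo, hi, size=3) * config.radius_scale[cl]
            mask |= _ellipsoid_mask(
                config.grid_shape, np.asarray(center, dtype=float) + jitter, radii
            )
        if config.shared_center is not None:
            jitter = rng.normal(0.0, config.center_jitter, size=3)
            radii = rng.uniform(lo, hi, size=3)
            mask |= _ellipsoid_mask(
                config.grid_shape,
                np.asarray(config.shared_center, dtype=float) + jitter,
                radii,
            )
        if config.background_rate > 0:
            mask |= (rng.random(config.grid_shape) < config.background_rate).astype(
                np.uint8
            )
        masks[a] = mask

    subject_ids = [f"synth-{a:03d}" for a in range(n)]
    scores = OrdinalScoreMatrix(
        subject_ids=subject_ids,
        item_names=list(config.item_names),
        item_max=config.item_max,
        X=X,
    )
    volumes = LesionVolumeSet(masks=masks, affine=np.eye(4), subject_ids=subject_ids)
    planted = ClusterAssignment(labels=labels, k=config.k_true, seed_ledger=[])
    return scores, volumes, planted


def generate_null_cohort(
    n: int = 40,
    m: int = 14,
    item_max: np.ndarray | None = None,
    grid_shape: tuple[int, int, int] = (16, 16, 16),
    lesion_rate: float = 1.0,
    seed: int = 0,
) -> tuple[OrdinalScoreMatrix, LesionVolumeSet]:
    """Cohort with no symptom-lesion association, for null calibration.

    Scores are uniform over each item's range, independent of the masks.
    With probability ``lesion_rate`` a subject receives one spherical
    lesion at a jittered central position, so central voxels are lesioned
    often enough to pass the 5% selection while carrying no label signal.
    """
    if n < 4:
        raise ValidationError("need n >= 4")
    if item_max is None:
        item_max = DEFAULT_ITEM_MAX[:m]
    item_max = np.asarray(item_max, dtype=int)
    if len(item_max) != m:
        raise ValidationError("item_max length must equal m")
    rng = np.random.default_rng(seed)
    X = rng.integers(0, item_max[None, :] + 1, size=(n, m))
    # avoid all-zero degenerate profiles for downstream similarity use
    zero_rows = np.flatnonzero(X.sum(axis=1) == 0)
    for a in zero_rows:
        X[a, rng.integers(m)] = 1

    center = np.asarray(grid_shape, dtype=float) / 2.0
    masks = np.zeros((n, *grid_shape), dtype=np.uint8)
    for a in range(n):
        if rng.random() < lesion_rate:
            jitter = rng.normal(0.0, 1.5, size=3)
            radii = rng.uniform(2.0, 4.0, size=3)
            masks[a] = _ellipsoid_mask(grid_shape, center + jitter, radii)

    subject_ids = [f"null-{a:03d}" for a in range(n)]
    scores = OrdinalScoreMatrix(
        subject_ids=subject_ids,
        item_names=[f"item_{j:02d}" for j in range(m)],
        item_max=item_max,
        X=X,
    )
    volumes = LesionVolumeSet(masks=masks, affine=np.eye(4), subject_ids=subject_ids)
    return scores, volumes
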
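"""Ordinal score cohorts: loading, filtering and descriptive statistics.

The central container is :class:`OrdinalScoreMatrix`, a patient x item table
of integer ordinal scores (NIHSS-style: 0 means no deficit, per-item maxima
between 2 and 4).  The module implements the cohort filtering rules used
before any similarity computation, deficit co-occurrence counts, a
Spearman correlation network with permutation p-values and
Benjamini-Hochberg FDR, and per-cluster min/median/max profile summaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._validate import ValidationError, check_labels

logger = logging.getLogger(__name__)

__all__ = [
    "OrdinalScoreMatrix",
    "CohortMetadata",
    "CorrelationNetwork",
    "FilterResult",
    "filter_cohort",
    "cooccurrence_counts",
    "spearman_network",
    "cluster_profile_summary",
]


@dataclass
class OrdinalScoreMatrix:
    """Patient x item matrix of integer ordinal scores.

    Parameters
    ----------
    subject_ids : sequence of str
        Unique subject identifiers, one per row.
    item_names : sequence of str
        Item labels, one per column.
    item_max : sequence of int
        Per-item maximum score ``L_j`` (NIHSS items range 2-4).
    X : (n, m) array of int
        Scores ``x_aj`` with ``0 <= x_aj <= L_j``.  Missing values are not
        supported by design.
    """

    subject_ids: list[str]
    item_names: list[str]
    item_max: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.item_names = [str(s) for s in self.item_names]
        X = np.asarray(self.X)
        if X.ndim != 2:
            raise ValidationError(f"X must be 2-D, got shape {X.shape}")
        if np.any(pd.isna(X)):
            raise ValidationError("missing scores are not supported")
        if not np.all(np.equal(np.mod(X, 1), 0)):
            raise ValidationError("scores must be integers")
        self.X = X.astype(int)
        self.item_max = np.asarray(self.item_max, dtype=int)
        n, m = self.X.shape
        if n < 2:
            raise ValidationError("need at least 2 subjects")
        if m < 1:
            raise ValidationError("need at least 1 item")
        if len(self.subject_ids) != n:
            raise ValidationError("subject_ids length does not match X rows")
        if len(set(self.subject_ids)) != n:
            raise ValidationError("subject_ids must be unique")
        if len(self.item_names) != m or len(self.item_max) != m:
            raise ValidationError("item_names/item_max length does not match X columns")
        if np.any(self.X < 0) or np.any(self.X > self.item_max[None, :]):
            raise ValidationError("scores out of the per-item [0, L_j] range")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.subject_ids, columns=self.item_names)

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "subject_id"
        df.to_csv(path)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, item_max: Sequence[int] | dict[str, int] | None = None
    ) -> "OrdinalScoreMatrix":
        """Build from a DataFrame indexed by subject id.

        When ``item_max`` is omitted it is inferred from standard NIHSS item
        names where recognised, otherwise from the observed column maxima.
        """
        if isinstance(item_max, dict):
            item_max = [item_max[c] for c in df.columns]
        if item_max is None:
            item_max = [
                NIHSS_ITEM_MAXIMA.get(c, int(df[c].max())) for c in df.columns
            ]
        return cls(
            subject_ids=list(df.index.astype(str)),
            item_names=list(df.columns),
            item_max=np.asarray(item_max, dtype=int),
            X=df.to_numpy(),
        )

    @classmethod
    def from_csv(
        cls, path: str | Path, config: str | Path | None = None
    ) -> "OrdinalScoreMatrix":
        """Read a score table (first column = subject id, one column per item).

        ``config`` optionally points to a YAML sidecar with an ``item_max``
        mapping (item name -> maximum score).
        """
        df = pd.read_csv(path, index_col=0)
        item_max: dict[str, int] | None = None
        if config is not None:
            with open(config) as fh:
                cfg = yaml.safe_load(fh) or {}
            if "item_max" in cfg:
                item_max = {str(k): int(v) for k, v in cfg["item_max"].items()}
        return cls.from_frame(df, item_max=item_max)


#: Maximum scores of the standard NIHSS items (vigilance item included).
NIHSS_ITEM_MAXIMA: dict[str, int] = {
    "loc_vigilance": 3,
    "loc_questions": 2,
    "loc_commands": 2,
    "best_gaze": 2,
    "visual": 3,
    "facial_palsy": 3,
    "motor_arm_left": 4,
    "motor_arm_right": 4,
    "motor_leg_left": 4,
    "motor_leg_right": 4,
    "limb_ataxia": 2,
    "sensory": 2,
    "best_language": 3,
    "dysarthria": 2,
    "extinction_inattention": 2,
}


@dataclass
class CohortMetadata:
    """Per-subject metadata accompanying a raw score table."""

    scan_available: np.ndarray
    loc_vigilance_score: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scan_available = np.asarray(self.scan_available, dtype=bool)
        if self.loc_vigilance_score is not None:
            self.loc_vigilance_score = np.asarray(self.loc_vigilance_score, dtype=int)
            if len(self.loc_vigilance_score) != len(self.scan_available):
                raise ValidationError("metadata arrays must have equal length")

    @classmethod
    def from_csv(cls, path: str | Path, subject_ids: Sequence[str]) -> "CohortMetadata":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        missing = [s for s in subject_ids if s not in df.index]
        if missing:
            raise ValidationError(f"metadata missing subjects: {missing[:5]}")
        df = df.loc[list(subject_ids)]
        return cls(scan_available=df["scan_available"].to_numpy().astype(bool))


class FilterResult(NamedTuple):
    scores: OrdinalScoreMatrix
    drop_log: pd.DataFrame  # columns: subject_id, reason


def filter_cohort(
    raw: OrdinalScoreMatrix,
    meta: CohortMetadata,
    loc_item: str = "loc_vigilance",
) -> FilterResult:
    """Apply the cohort inclusion rules and remove the vigilance item.

    A subject is dropped when (in fixed order, though the outcome is
    order-independent): no brain scan is available; the total score over all
    items is 0; the level-of-consciousness vigilance score is positive
    (such subjects cannot be assessed on the remaining items, which would
    create missing data).  Finally the vigilance column itself is removed.

    The vigilance scores are taken from the ``loc_item`` column of ``raw``
    when present, otherwise from ``meta.loc_vigilance_score``.

    Returns
    -------
    FilterResult
        ``scores`` is the filtered matrix; ``drop_log`` records one row per
        dropped subject with the first rule that excluded it.
    """
    n = raw.n
    if len(meta.scan_available) != n:
        raise ValidationError(
            f"metadata has {len(meta.scan_available)} subjects, scores have {n}"
        )
    if loc_item in raw.item_names:
        loc_idx: int | None = raw.item_names.index(loc_item)
        loc_scores = raw.X[:, loc_idx]
    elif meta.loc_vigilance_score is not None:
        loc_idx = None
        loc_scores = meta.loc_vigilance_score
    else:
        loc_idx = None
        loc_scores = np.zeros(n, dtype=int)

    keep = np.ones(n, dtype=bool)
    reasons: dict[str, str] = {}
    for a in range(n):
        sid = raw.subject_ids[a]
        if not meta.scan_available[a]:
            keep[a] = False
            reasons[sid] = "no_scan"
        elif raw.X[a].sum() == 0:
            keep[a] = False
            reasons[sid] = "total_score_zero"
        elif loc_scores[a] > 0:
            keep[a] = False
            reasons[sid] = "loc_vigilance_positive"
    drop_log = pd.DataFrame(
        {"subject_id": list(reasons), "reason": list(reasons.values())}
    )
    for sid, reason in reasons.items():
        logger.info("dropping subject %s: %s", sid, reason)

    if keep.sum() < 2:
        raise ValidationError(
            f"fewer than 2 subjects remain after filtering ({int(keep.sum())})"
        )

    col_keep = np.ones(raw.m, dtype=bool)
    if loc_idx is not None:
        col_keep[loc_idx] = False
    filtered = OrdinalScoreMatrix(
        subject_ids=[s for s, k in zip(raw.subject_ids, keep) if k],
        item_names=[it for it, k in zip(raw.item_names, col_keep) if k],
        item_max=raw.item_max[col_keep],
        X=raw.X[np.ix_(keep, col_keep)],
    )
    return FilterResult(filtered, drop_log)


def cooccurrence_counts(scores: OrdinalScoreMatrix) -> pd.DataFrame:
    """Count patients exhibiting each pair of deficits, irrespective of severity.

    Entry (i, j) is the number of subjects with positive scores on both
    items; the diagonal holds single-deficit occurrence counts.
    """
    present = (scores.X > 0).astype(int)
    counts = present.T @ present
    return pd.DataFrame(counts, index=scores.item_names, columns=scores.item_names)


@dataclass
class CorrelationNetwork:
    """Spearman correlation network over items with permutation p-values.

    ``edges`` has one row per evaluated item pair with columns
    ``item_i, item_j, rho, p_raw, p_adjusted, significant``.  Pairs
    involving a constant item are excluded from the FDR family and listed
    in ``excluded_pairs``.
    """

    edges: pd.DataFrame
    n_permutations: int
    alpha: float
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_candidate_pairs(self) -> int:
        return len(self.edges) + len(self.excluded_pairs)

    def significant_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["significant"]].reset_index(drop=True)


def spearman_network(
    scores: OrdinalScoreMatrix,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> CorrelationNetwork:
    """Spearman rho for every item pair with two-sided permutation p-values.

    Mid-ranks handle ties.  For each pair, one column is independently
    permuted ``n_perm`` times and the two-sided p-value uses the add-one
    convention ``p = (1 + #{|rho_perm| >= |rho_obs|}) / (n_perm + 1)``.
    Benjamini-Hochberg FDR flags significance at ``alpha`` across the
    family of evaluable pairs.
    """
    if scores.n < 3:
        raise ValidationError("need at least 3 subjects for a correlation network")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    m = scores.m
    ranks = np.column_stack(
        [stats.rankdata(scores.X[:, j]) for j in range(m)]
    )
    centered = ranks - ranks.mean(axis=0)
    norms = np.linalg.norm(centered, axis=0)
    constant = norms < 1e-12
    for j in np.flatnonzero(constant):
        warnings.warn(
            f"item {scores.item_names[j]!r} is constant; its pairs are excluded "
            "from the correlation network",
            stacklevel=2,
        )

    rows = []
    excluded: list[tuple[str, str]] = []
    n = scores.n
    for i in range(m):
        for j in range(i + 1, m):
            pair = (scores.item_names[i], scores.item_names[j])
            if constant[i] or constant[j]:
                excluded.append(pair)
                continue
            rho = float(centered[:, i] @ centered[:, j] / (norms[i] * norms[j]))
            # permute column j's ranks; column i stays fixed
            perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
            permuted = centered[perm_idx, j]  # (n_perm, n)
            rho_perm = permuted @ centered[:, i] / (norms[i] * norms[j])
            p_raw = (1.0 + np.sum(np.abs(rho_perm) >= abs(rho) - 1e-12)) / (n_perm + 1.0)
            rows.append((*pair, rho, p_raw))

    edges = pd.DataFrame(rows, columns=["item_i", "item_j", "rho", "p_raw"])
    if len(edges):
        reject, p_adj, _, _ = multipletests(
            edges["p_raw"].to_numpy(), alpha=alpha, method="fdr_bh"
        )
        edges["p_adjusted"] = p_adj
        edges["significant"] = reject
    else:
        edges["p_adjusted"] = pd.Series(dtype=float)
        edges["significant"] = pd.Series(dtype=bool)
    return CorrelationNetwork(
        edges=edges, n_permutations=n_perm, alpha=alpha, excluded_pairs=excluded
    )


def _ordinal_median(sorted_vals: np.ndarray) -> int:
    """Median on the ordinal scale: lower midpoint for even-sized groups."""
    g = len(sorted_vals)
    return int(sorted_vals[(g - 1) // 2])


def cluster_profile_summary(
    scores: OrdinalScoreMatrix, labels: np.ndarray
) -> pd.DataFrame:
    """Per-cluster min / median / max score for every item.

    The median of an even-sized group is the lower of the two central order
    statistics, keeping the summary on the ordinal scale.  Means and
    standard deviations are deliberately not computed: they are not
    meaningful for ordinal scores.

    Returns a DataFrame indexed by (cluster, statistic) with one column per
    item.
    """
    labels = check_labels(getattr(labels, "labels", labels), scores.n)
    out_rows = []
    index = []
    for cl in range(int(labels.max()) + 1):
        members = scores.X[labels == cl]
        if members.shape[0] == 0:
            raise ValidationError(f"cluster {cl} is empty")
        sorted_members = np.sort(members, axis=0)
        stats_map = {
            "min": sorted_members[0],
            "median": np.array(
                [_ordinal_median(sorted_members[:, j]) for j in range(scores.m)]
            ),
            "max": sorted_members[-1],
        }
        for stat, vals in stats_map.items():
            index.append((int(cl), stat))
            out_rows.append(vals)
    return pd.DataFrame(
        np.asarray(out_rows),
        index=pd.MultiIndex.from_tuples(index, names=["cluster", "statistic"]),
        columns=scores.item_names,
    )
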
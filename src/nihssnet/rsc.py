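"""Repeated Spectral Clustering (RSC) with consensus evidence accumulation.

Spectral clustering here is the normalized-symmetric variant: embed the
nodes with the eigenvectors of the ``k`` smallest eigenvalues of
``L_sym = I - D^{-1/2} A D^{-1/2}``, normalize the embedding rows to unit
length, and run k-means in that space.  RSC repeats the k-means step ``N``
times with different centroid initializations (the embedding is a
deterministic function of the graph), accumulates the co-clustering
fractions into a consensus matrix ``C``, and then spectrally clusters
``C`` itself with the same ``k``.  The number of clusters is selected from
the Laplacian spectra: a disconnected ``W`` directly reveals its component
count (near-zero eigenvalues), and otherwise the ``k``-th eigengap of each
``C_k`` is compared against the ``k``-th eigengap of ``W`` — the candidate
with the largest increase carries the strongest evidence of a
``k``-component structure hidden in ``W``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from ._validate import ValidationError, as_square_symmetric

__all__ = [
    "SpectralProfile",
    "ConsensusMatrix",
    "ClusterAssignment",
    "sym_laplacian_spectrum",
    "spectral_embedding",
    "cluster_embedding",
    "accumulate_consensus",
    "rsc_partition",
    "select_k",
    "SelectKResult",
]


@dataclass
class SpectralProfile:
    """Ascending eigenvalues of ``L_sym`` and their consecutive gaps.

    ``gaps[i]`` is the (i+1)-th spectral gap ``lambda_{i+2} - lambda_{i+1}``
    in 1-based eigenvalue numbering, i.e. ``gap(k) = gaps[k - 1]``.
    """

    eigenvalues: np.ndarray
    gaps: np.ndarray

    def gap(self, k: int) -> float:
        """The k-th spectral gap ``lambda_{k+1} - lambda_k`` (1-based)."""
        if not 1 <= k < len(self.eigenvalues):
            raise ValidationError(f"gap index k={k} out of range")
        return float(self.gaps[k - 1])


@dataclass
class ConsensusMatrix:
    """Co-clustering fractions over N spectral clustering runs."""

    C: np.ndarray
    N: int
    k: int
    subject_ids: list[str] | None = None


@dataclass
class ClusterAssignment:
    """Hard partition into k clusters with the seeds that produced it."""

    labels: np.ndarray
    k: int
    seed_ledger: list[int]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        counts = np.bincount(self.labels, minlength=self.k)
        if len(counts) > self.k or np.any(counts == 0):
            raise ValidationError("every cluster must be nonempty")


def _as_adjacency(A) -> np.ndarray:
    A = getattr(A, "W", getattr(A, "C", A))
    A = as_square_symmetric(A, "adjacency matrix")
    if np.any(A < -1e-12):
        raise ValidationError("adjacency matrix must be nonnegative")
    return np.clip(A, 0.0, None)


def _normalized_affinity(A: np.ndarray) -> np.ndarray:
    """``D^{-1/2} A D^{-1/2}`` with a check for zero-degree nodes."""
    deg = A.sum(axis=1)
    dead = np.flatnonzero(deg <= 0)
    if dead.size:
        raise ValidationError(f"zero-degree node(s) at index {dead.tolist()}")
    inv_sqrt = 1.0 / np.sqrt(deg)
    return A * np.outer(inv_sqrt, inv_sqrt)


def sym_laplacian_spectrum(A) -> SpectralProfile:
    """Eigenvalues of the symmetric normalized Laplacian, ascending, with gaps.

    Eigenvalues are floored at 0 (they are nonnegative in exact arithmetic)
    and lie in [0, 2].
    """
    A = _as_adjacency(A)
    M = _normalized_affinity(A)
    vals = eigh(M, eigvals_only=True)  # ascending eigenvalues of M
    lam = 1.0 - vals[::-1]  # ascending eigenvalues of L_sym = I - M
    lam = np.clip(lam, 0.0, None)
    return SpectralProfile(eigenvalues=lam, gaps=np.diff(lam))


def spectral_embedding(A, k: int) -> np.ndarray:
    """Rows of the k smallest-eigenvalue eigenvectors of ``L_sym``, unit-normalized.

    Equivalently the k largest eigenvectors of the normalized affinity.
    Zero-norm rows (possible only in pathological graphs) are replaced by a
    uniform unit vector with a warning.
    """
    A = _as_adjacency(A)
    n = A.shape[0]
    if not 2 <= k < n:
        raise ValidationError(f"need 2 <= k < n, got k={k}, n={n}")
    M = _normalized_affinity(A)
    _, vecs = eigh(M, subset_by_index=[n - k, n - 1])
    U = vecs[:, ::-1]  # order by ascending L_sym eigenvalue
    norms = np.linalg.norm(U, axis=1)
    zero = norms < 1e-12
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} embedding row(s) had zero norm; replaced by a "
            "uniform unit vector",
            stacklevel=2,
        )
        U[zero] = 1.0 / np.sqrt(k)
        norms[zero] = 1.0
    return U / norms[:, None]


def _plusplus_centers(U: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Plain (non-greedy) k-means++ seeding: D^2-weighted center sampling.

    The greedy multi-trial variant is nearly deterministic on separated
    data, which would suppress the run-to-run variability the consensus
    ensemble averages over; the original single-draw scheme is used.
    """
    n = U.shape[0]
    centers = np.empty((k, U.shape[1]))
    centers[0] = U[rng.integers(n)]
    d2 = ((U - centers[0]) ** 2).sum(axis=1)
    for c in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[c] = U[rng.integers(n)]
            continue
        centers[c] = U[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((U - centers[c]) ** 2).sum(axis=1))
    return centers


def cluster_embedding(U: np.ndarray, k: int, seed: int) -> ClusterAssignment:
    """Single-initialization k-means partition of the embedding rows.

    One k-means++ initialization per call: RSC's ensemble over seeds plays
    the role of restarts.  Scikit-learn's Lloyd implementation reassigns
    empty clusters, so every cluster is nonempty by construction.
    """
    U = np.asarray(U, dtype=float)
    n_distinct = np.unique(U, axis=0).shape[0]
    if n_distinct < k:
        raise ValidationError(
            f"embedding has only {n_distinct} distinct rows, fewer than k={k}"
        )
    rng = np.random.default_rng(int(seed))
    km = KMeans(
        n_clusters=k,
        n_init=1,
        init=_plusplus_centers(U, k, rng),
        max_iter=300,
        tol=1e-6,
        algorithm="lloyd",
        random_state=int(seed) % (2**31),
    )
    labels = km.fit_predict(U)
    return ClusterAssignment(labels=labels, k=k, seed_ledger=[int(seed)])


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters in order of first appearance (stable across runs)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def _run_seeds(master_seed: int, n: int, stream: int = 0) -> list[int]:
    ss = np.random.SeedSequence([int(master_seed), stream])
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def accumulate_consensus(W, k: int, N: int, master_seed: int = 0) -> ConsensusMatrix:
    """Evidence accumulation: co-clustering fractions over N spectral runs.

    The spectral embedding of ``W`` is computed once; only the k-means
    centroid initialization varies across the N runs, each with a seed
    derived deterministically from ``master_seed``.  ``C[a, b]`` is the
    fraction of runs in which subjects a and b share a cluster.
    """
    if N < 1:
        raise ValidationError("N must be >= 1")
    subject_ids = getattr(W, "subject_ids", None)
    A = _as_adjacency(W)
    n = A.shape[0]
    U = spectral_embedding(A, k)
    counts = np.zeros((n, n))
    for seed in _run_seeds(master_seed, N, stream=0):
        labels = cluster_embedding(U, k, seed).labels
        same = labels[:, None] == labels[None, :]
        counts += same
    C = counts / float(N)
    np.fill_diagonal(C, 1.0)
    return ConsensusMatrix(C=C, N=N, k=k, subject_ids=subject_ids)


def rsc_partition(
    W, k: int, N: int = 500, master_seed: int = 0
) -> tuple[ClusterAssignment, ConsensusMatrix]:
    """Full RSC: accumulate consensus on W, then spectrally cluster C.

    The second phase uses the same normalized-symmetric spectral clustering
    with the same ``k``.  Labels are canonicalized by order of first
    appearance, so a stable consensus matrix yields byte-identical labels
    across master seeds.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    consensus = accumulate_consensus(W, k, N, master_seed)
    U_C = spectral_embedding(consensus.C, k)
    final_seed = _run_seeds(master_seed, 1, stream=1)[0]
    assignment = cluster_embedding(U_C, k, final_seed)
    labels = _canonical_labels(assignment.labels)
    return (
        ClusterAssignment(labels=labels, k=k, seed_ledger=assignment.seed_ledger),
        consensus,
    )


@dataclass
class SelectKResult:
    """Eigengap evidence table and the selected number of clusters."""

    k: int
    table: pd.DataFrame  # columns: k, gap_W, gap_C, gap_increase


#: eigenvalues below this are counted as zero when counting graph components
COMPONENT_TOL = 1e-8


def select_k(
    W, k_range, N: int = 500, master_seed: int = 0
) -> SelectKResult:
    """Select the cluster count from the spectra of W and the C_k matrices.

    The number of near-zero eigenvalues of ``L_sym`` equals the number of
    connected components, so when ``W`` itself decomposes into ``c``
    components with ``c`` inside ``k_range`` the structure is already
    plainly visible and ``c`` is returned.  Otherwise, for each candidate
    ``k`` the consensus matrix ``C_k`` is accumulated and the k-th spectral
    gap of ``C_k`` is compared to the k-th spectral gap of ``W``: the ``k``
    with the highest increase carries the greatest evidence of a
    ``k``-component structure hidden in ``W``.  Ties break toward smaller
    ``k`` (parsimony).  The full gap table is returned either way.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValidationError("k_range must be nonempty")
    A = _as_adjacency(W)
    n = A.shape[0]
    if k_range[0] < 2 or k_range[-1] >= n:
        raise ValidationError(f"k_range must lie within [2, n-1] = [2, {n - 1}]")
    profile_W = sym_laplacian_spectrum(A)
    rows = []
    for k in k_range:
        C_k = accumulate_consensus(W, k, N, master_seed)
        profile_C = sym_laplacian_spectrum(C_k.C)
        gap_W = profile_W.gap(k)
        gap_C = profile_C.gap(k)
        rows.append((k, gap_W, gap_C, gap_C - gap_W))
    table = pd.DataFrame(rows, columns=["k", "gap_W", "gap_C", "gap_increase"])
    n_components = int(np.sum(profile_W.eigenvalues < COMPONENT_TOL))
    if n_components >= 2 and n_components in k_range:
        return SelectKResult(k=n_components, table=table)
    best = int(table.loc[table["gap_increase"].idxmax(), "k"])  # idxmax: first max
    return SelectKResult(k=best, table=table)
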
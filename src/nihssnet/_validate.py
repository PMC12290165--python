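"""Shared validation helpers and exceptions."""

from __future__ import annotations

import numpy as np


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def as_square_symmetric(A: np.ndarray, name: str = "matrix", tol: float = 1e-9) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError(f"{name} must be square, got shape {A.shape}")
    if not np.allclose(A, A.T, atol=tol):
        raise ValidationError(f"{name} must be symmetric")
    return A


def check_labels(labels: np.ndarray, n: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.shape != (n,):
        raise ValidationError(
            f"labels must have one entry per subject ({n}), got shape {labels.shape}"
        )
    if labels.dtype.kind not in "iu":
        raise ValidationError("labels must be integers")
    return labels.astype(int)
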
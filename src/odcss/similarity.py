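"""Similarity measures for just-in-time neighbor selection.

All measures return a score where larger means more similar, so that one
ranking convention serves every measure.  Distance-based measures are
negated distances; degenerate inputs (zero norm for cosine, zero variance
for the Pearson coefficient) score -inf and rank last.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SIMILARITY_MEASURES", "similarity", "regularized_covariance"]

SIMILARITY_MEASURES = ("euclidean", "cosine", "covariance_weighted", "manhattan", "pearson")


def regularized_covariance(X: np.ndarray) -> np.ndarray:
    """Feature covariance of the labeled database with a trace-scaled ridge.

    The ridge (1e-6 * trace/d on the diagonal) keeps the Mahalanobis-style
    similarity defined even when the database is small or collinear.
    """
    X = np.asarray(X, dtype=float)
    d = X.shape[1]
    cov = np.cov(X, rowvar=False) if X.shape[0] > 1 else np.eye(d)
    cov = np.atleast_2d(cov)
    ridge = 1e-6 * np.trace(cov) / d
    if ridge <= 0:
        ridge = 1e-6
    return cov + ridge * np.eye(d)


def similarity(
    xq: np.ndarray,
    xi: np.ndarray,
    measure: str = "euclidean",
    cov_inv: np.ndarray | None = None,
) -> float:
    """Score how similar ``xi`` is to the query ``xq`` (larger = more similar).

    ``cov_inv`` (the inverse regularized labeled-database covariance) is
    required for the covariance-weighted measure.
    """
    xq = np.asarray(xq, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if xq.shape != xi.shape:
        raise ValueError("dimension mismatch")
    if measure == "euclidean":
        return -float(np.linalg.norm(xq - xi))
    if measure == "manhattan":
        return -float(np.abs(xq - xi).sum())
    if measure == "cosine":
        nq, ni = np.linalg.norm(xq), np.linalg.norm(xi)
        if nq == 0 or ni == 0:
            return -np.inf
        return float(xq @ xi / (nq * ni))
    if measure == "pearson":
        if xq.size < 2 or np.std(xq) == 0 or np.std(xi) == 0:
            return -np.inf
        return float(np.corrcoef(xq, xi)[0, 1])
    if measure == "covariance_weighted":
        if cov_inv is None:
            raise ValueError("covariance_weighted similarity needs cov_inv context")
        diff = xq - xi
        return -float(np.sqrt(max(diff @ cov_inv @ diff, 0.0)))
    raise ValueError(f"unknown similarity measure {measure!r}")
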
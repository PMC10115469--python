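"""Quadratic-form machinery shared by the test statistics and the calibration.

The truncated statistic keeps the ``s = ceil(eta * M)`` largest-magnitude
entries of a zero-mean Gaussian vector ``z`` with covariance ``delta`` and
decorrelates them with the matching principal submatrix:

    T(eta) = z_eta' delta_eta^{-1} z_eta.

Because the kept sets are nested across the truncation grid (the top-s sets
grow with eta), all levels can be computed from a single factorization: after
permuting ``delta`` into descending-|z| order, the leading ``s x s`` block of
its Cholesky factor is exactly the Cholesky factor of the leading ``s x s``
principal submatrix.  One triangular solve whitens the permuted vector, and
the running sum of squared whitened coordinates evaluates the quadratic form
at every truncation level simultaneously.  This reduces a grid of |Omega|
solves per draw to one factorization per draw, which is what makes
bootstrap calibration and 1e5-replication simulations tractable.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import linalg


def kept_count(eta: float, total: int) -> int:
    """Number of entries retained at truncation level ``eta`` out of ``total``.

    Defined as the ceiling of ``eta * total``; a small rounding guard keeps
    binary-float products such as 0.3 * 10 from spilling over to the next
    integer.
    """
    if not 0.0 < eta <= 1.0:
        raise ValueError(f"truncation level must lie in (0, 1], got {eta}")
    return int(math.ceil(round(eta * total, 9)))


def descending_abs_order(z: np.ndarray) -> np.ndarray:
    """Indices sorting ``z`` by descending |z|, ties broken by ascending index."""
    z = np.asarray(z)
    return np.argsort(-np.abs(z), axis=-1, kind="stable")


def quad_form(z: np.ndarray, matrix: np.ndarray) -> float:
    """Evaluate ``z' matrix^{-1} z`` through a symmetric factorization.

    Raises :class:`numpy.linalg.LinAlgError` if ``matrix`` is not positive
    definite; callers are expected to regularize estimated correlation
    matrices first.
    """
    z = np.asarray(z, dtype=float)
    c, low = linalg.cho_factor(np.asarray(matrix, dtype=float), lower=True)
    return float(z @ linalg.cho_solve((c, low), z))


def truncated_statistic(z: np.ndarray, delta: np.ndarray, eta: float) -> float:
    """Direct (per-level) evaluation of the truncated quadratic-form statistic.

    Selects the ``ceil(eta * M)`` largest |z| entries and evaluates the
    quadratic form against the corresponding principal submatrix of
    ``delta``.  This is the reference implementation; batched callers use
    :func:`truncated_statistics_batch`.
    """
    z = np.asarray(z, dtype=float).ravel()
    delta = np.asarray(delta, dtype=float)
    m_total = z.size
    if delta.shape != (m_total, m_total):
        raise ValueError(
            f"covariance shape {delta.shape} does not match vector length {m_total}"
        )
    keep = descending_abs_order(z)[: kept_count(eta, m_total)]
    sub = delta[np.ix_(keep, keep)]
    return quad_form(z[keep], sub)


def truncated_statistics_batch(
    z_batch: np.ndarray, delta: np.ndarray, counts: np.ndarray
) -> np.ndarray:
    """Truncated statistics at every kept-count in ``counts`` for a batch of draws.

    Parameters
    ----------
    z_batch
        Array of shape ``(n_draws, M)``.
    delta
        ``M x M`` positive-definite covariance (typically a Kronecker product
        of the SNP and trait correlation matrices).
    counts
        Ascending kept-counts (one per truncation level), each in ``[1, M]``.

    Returns
    -------
    Array of shape ``(n_draws, len(counts))``.
    """
    z_batch = np.atleast_2d(np.asarray(z_batch, dtype=float))
    delta = np.asarray(delta, dtype=float)
    counts = np.asarray(counts, dtype=int)
    n, m_total = z_batch.shape
    order = descending_abs_order(z_batch)
    permuted = delta[order[:, :, None], order[:, None, :]]
    try:
        chol = np.linalg.cholesky(permuted)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise np.linalg.LinAlgError(
            "Kronecker covariance is not positive definite; regularize the "
            "correlation matrices before computing truncated statistics"
        ) from exc
    z_sorted = np.take_along_axis(z_batch, order, axis=1)
    white = np.linalg.solve(chol, z_sorted[..., None])[..., 0]
    cumulative = np.cumsum(white**2, axis=1)
    return cumulative[:, counts - 1]
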
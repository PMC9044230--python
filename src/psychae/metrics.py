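"""Reconstruction-error metrics: MSE, MAE and normalized Euclidean distance.

All three compare an original matrix with its reconstruction elementwise.
NED works on sign patterns: each entry is normalized to x/|x| (so only the
sign survives; exact zeros normalize to 0), and the default mode averages
per-row Euclidean distances between the sign patterns,

    NED = (1/n) * sum_i sqrt( sum_j (sgn(xhat_ij) - sgn(x_ij))^2 ).

A ``literal`` mode evaluates the unsquared-summand variant
sqrt(sum_ij (sgn(xhat) - sgn(x))) instead; its radicand can be negative,
in which case it raises rather than returning a complex value.
"""

from __future__ import annotations

import numpy as np

__all__ = ["mse", "mae", "ned"]


def _check(original: np.ndarray, reconstructed: np.ndarray):
    x = np.asarray(original, dtype=float)
    xhat = np.asarray(reconstructed, dtype=float)
    if x.shape != xhat.shape:
        raise ValueError(
            f"shape mismatch: original {x.shape} vs reconstructed {xhat.shape}"
        )
    return x, xhat


def mse(original: np.ndarray, reconstructed: np.ndarray) -> float:
    """Mean squared error per element."""
    x, xhat = _check(original, reconstructed)
    return float(np.mean((x - xhat) ** 2))


def mae(original: np.ndarray, reconstructed: np.ndarray) -> float:
    """Mean absolute error per element."""
    x, xhat = _check(original, reconstructed)
    return float(np.mean(np.abs(xhat - x)))


def _signs(a: np.ndarray) -> np.ndarray:
    # sign of 0 is 0: zero entries contribute |0 - s| per disagreeing side
    return np.sign(a)


def ned(
    original: np.ndarray,
    reconstructed: np.ndarray,
    literal: bool = False,
) -> float:
    """Normalized Euclidean distance between sign patterns.

    Parameters
    ----------
    literal
        Evaluate the unsquared-summand formula over the whole matrix
        instead of the row-averaged squared form.  Raises ``ValueError``
        when the radicand is negative.
    """
    x, xhat = _check(original, reconstructed)
    diff = _signs(xhat) - _signs(x)
    if literal:
        radicand = float(diff.sum())
        if radicand < 0:
            raise ValueError(
                f"literal NED radicand is negative ({radicand}); "
                "use the default squared mode"
            )
        return float(np.sqrt(radicand))
    row_dist = np.sqrt((diff**2).sum(axis=1))
    return float(row_dist.mean())
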
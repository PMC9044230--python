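"""Correlated multivariate non-normal data with controlled communality.

The generator follows the classic two-stage recipe for multivariate
non-normal simulation:

1.  For each pair of variables, find the *intermediate* correlation rho
    between the underlying normals such that, after each margin passes
    through its Fleishman cubic, the observed correlation equals the
    target.  With coefficients (b, c, d) on both margins the target r
    satisfies the cubic

        r = rho*(b1 b2 + 3 b1 d2 + 3 d1 b2 + 9 d1 d2)
            + rho^2 * (2 c1 c2) + rho^3 * (6 d1 d2).

2.  Decompose the assembled intermediate matrix as F = V sqrt(Lambda)
    (principal-component factor pattern) and impose it on a panel of
    independent standard normals, X = F Z, so that X has the intermediate
    correlation; the Fleishman cubic applied per margin then yields the
    target correlation and the target marginal moments.

The three study correlation structures are 15 items in 3 blocks of 5 with
high (within 0.7 / between 0.2), wide (within 0.9..0.3 / between 0.1), and
low (within 0.5..0.3 / between 0.3) communality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fleishman import (
    SCENARIOS,
    FleishmanCoefficients,
    FleishmanInfeasibleError,
    MomentSpec,
    solve_fleishman,
)

__all__ = [
    "CorrelationStructure",
    "IntermediateMatrix",
    "FactorPattern",
    "SimulatedDataset",
    "intermediate_correlation",
    "build_intermediate_matrix",
    "factor_pattern",
    "generate",
    "study_structures",
    "STRUCTURE_LABELS",
]

STRUCTURE_LABELS = ("high", "wide", "low")


@dataclass(frozen=True)
class CorrelationStructure:
    """A named target population correlation matrix."""

    label: str
    matrix: np.ndarray
    n_blocks: int = 3
    block_size: int = 5

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(m, m.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        off = m[~np.eye(m.shape[0], dtype=bool)]
        if np.any(np.abs(off) > 1.0):
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")
        if np.linalg.eigvalsh(m).min() <= 0:
            raise ValueError(f"structure {self.label!r} is not positive definite")
        object.__setattr__(self, "matrix", m)

    @property
    def n_items(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class IntermediateMatrix:
    """Pre-transform (normal-scale) correlation matrix, possibly repaired."""

    matrix: np.ndarray
    repaired: bool = False


@dataclass(frozen=True)
class FactorPattern:
    """Principal-component factor pattern F with F F^T = intermediate matrix."""

    matrix: np.ndarray


@dataclass(frozen=True)
class SimulatedDataset:
    """An n x k response matrix plus the provenance that produced it."""

    data: np.ndarray
    structure_label: str
    scenario_id: str
    seed: int
    n: int = field(init=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] < 2:
            raise ValueError("data must be a matrix with n >= 2 rows")
        if not np.isfinite(d).all():
            raise ValueError("simulated data contains non-finite values")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "n", d.shape[0])

    def to_frame(self) -> pd.DataFrame:
        cols = [f"item{j + 1:02d}" for j in range(self.data.shape[1])]
        return pd.DataFrame(self.data, columns=cols)


def _block_matrix(within: np.ndarray, between: float, n_blocks: int) -> np.ndarray:
    k = within.shape[0] * n_blocks
    m = np.full((k, k), between)
    for b in range(n_blocks):
        s = slice(b * within.shape[0], (b + 1) * within.shape[0])
        m[s, s] = within
    return m


def study_structures() -> dict[str, CorrelationStructure]:
    """The three 15-item, 3-block target correlation matrices of the study.

    high: all within-block correlations 0.7, between-block 0.2
    wide: within-block correlations taper from 0.9 down to 0.3, between 0.1
    low:  within-block correlations 0.5 (tapering to 0.3), between 0.3
    """
    wide_block = np.array(
        [
            [1.0, 0.9, 0.8, 0.7, 0.6],
            [0.9, 1.0, 0.7, 0.6, 0.5],
            [0.8, 0.7, 1.0, 0.5, 0.4],
            [0.7, 0.6, 0.5, 1.0, 0.3],
            [0.6, 0.5, 0.4, 0.3, 1.0],
        ]
    )
    low_block = np.array(
        [
            [1.0, 0.5, 0.5, 0.5, 0.5],
            [0.5, 1.0, 0.5, 0.5, 0.5],
            [0.5, 0.5, 1.0, 0.5, 0.4],
            [0.5, 0.5, 0.5, 1.0, 0.3],
            [0.5, 0.5, 0.4, 0.3, 1.0],
        ]
    )
    high_block = np.where(np.eye(5, dtype=bool), 1.0, 0.7)
    return {
        "high": CorrelationStructure("high", _block_matrix(high_block, 0.2, 3)),
        "wide": CorrelationStructure("wide", _block_matrix(wide_block, 0.1, 3)),
        "low": CorrelationStructure("low", _block_matrix(low_block, 0.3, 3)),
    }


def _cubic_coeffs(
    c1: FleishmanCoefficients, c2: FleishmanCoefficients
) -> tuple[float, float, float]:
    linear = (
        c1.b * c2.b + 3 * c1.b * c2.d + 3 * c1.d * c2.b + 9 * c1.d * c2.d
    )
    quad = 2 * c1.c * c2.c
    cub = 6 * c1.d * c2.d
    return linear, quad, cub


def intermediate_correlation(
    r_target: float,
    c1: FleishmanCoefficients,
    c2: FleishmanCoefficients,
    tol: float = 1e-12,
) -> float:
    """Pre-transform correlation rho attaining ``r_target`` post-transform.

    Newton-Raphson on the cubic from rho = r_target, falling back to
    bisection on [-1, 1].  For normal margins the cubic reduces to
    r = rho and the target is returned unchanged.
    """
    if abs(r_target) > 1:
        raise ValueError(f"|r_target| must be <= 1, got {r_target}")
    if r_target == 0.0:
        return 0.0
    linear, quad, cub = _cubic_coeffs(c1, c2)

    def f(rho: float) -> float:
        return rho * (linear + rho * (quad + rho * cub)) - r_target

    def fprime(rho: float) -> float:
        return linear + rho * (2 * quad + 3 * rho * cub)

    rho = r_target
    for _ in range(100):
        fr = f(rho)
        if abs(fr) < tol:
            break
        deriv = fprime(rho)
        if deriv == 0:
            break
        rho -= fr / deriv
        if abs(rho) > 1.5:  # diverging; hand over to bisection
            break
    if abs(f(rho)) < tol and -1.0 <= rho <= 1.0:
        return float(rho)
    lo, hi = -1.0, 1.0
    if f(lo) * f(hi) > 0:
        raise FleishmanInfeasibleError(
            f"no intermediate correlation in [-1, 1] for target {r_target}"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    rho = 0.5 * (lo + hi)
    if abs(f(rho)) > 1e-8:
        raise FleishmanInfeasibleError(
            f"intermediate-correlation solve failed for target {r_target}"
        )
    return float(rho)


def build_intermediate_matrix(
    structure: CorrelationStructure,
    specs: list[MomentSpec] | MomentSpec,
    tol: float = 1e-12,
) -> IntermediateMatrix:
    """Assemble the elementwise intermediate correlation matrix.

    One ``MomentSpec`` may be shared by all variables (the study design) or
    supplied per variable.  If the assembled matrix is not positive
    semi-definite it is repaired by clipping eigenvalues at 1e-10 and
    rescaling to unit diagonal, with the ``repaired`` flag set.
    """
    k = structure.n_items
    if isinstance(specs, MomentSpec):
        specs = [specs] * k
    if len(specs) != k:
        raise ValueError(f"need {k} moment specs, got {len(specs)}")
    coeffs = [solve_fleishman(s) for s in specs]
    rho = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            try:
                rho[i, j] = rho[j, i] = intermediate_correlation(
                    structure.matrix[i, j], coeffs[i], coeffs[j], tol
                )
            except (FleishmanInfeasibleError, ValueError) as exc:
                raise FleishmanInfeasibleError(
                    f"intermediate correlation infeasible at entry ({i}, {j}): {exc}"
                ) from exc
    eigval = np.linalg.eigvalsh(rho)
    repaired = False
    if eigval.min() < 0:
        w, v = np.linalg.eigh(rho)
        w = np.clip(w, 1e-10, None)
        rho = (v * w) @ v.T
        scale = 1.0 / np.sqrt(np.diag(rho))
        rho = rho * np.outer(scale, scale)
        rho = 0.5 * (rho + rho.T)
        np.fill_diagonal(rho, 1.0)
        repaired = True
    return IntermediateMatrix(rho, repaired)


def factor_pattern(intermediate: IntermediateMatrix, tol: float = 1e-8) -> FactorPattern:
    """Principal-component factor pattern F = V diag(sqrt(lambda)).

    ``F @ F.T`` reproduces the input matrix to within ``tol`` elementwise.
    """
    m = np.asarray(intermediate.matrix, dtype=float)
    w, v = np.linalg.eigh(m)
    if w.min() < -tol:
        raise ValueError(
            f"intermediate matrix has negative eigenvalue {w.min():.3g}"
        )
    w = np.clip(w, 0.0, None)
    order = np.argsort(-w, kind="stable")
    f = v[:, order] * np.sqrt(w[order])
    if np.max(np.abs(f @ f.T - m)) > tol:
        raise ValueError("factor pattern does not reproduce the input matrix")
    return FactorPattern(f)


def generate(
    structure: CorrelationStructure,
    spec: MomentSpec,
    n: int,
    seed: int,
) -> SimulatedDataset:
    """Draw an n x k sample with the target correlations and marginal moments.

    Pipeline: independent standard normals -> factor-pattern mixing to the
    intermediate correlation -> per-variable Fleishman cubic -> mean/sd
    rescaling.  With a normal ``spec`` this is exact multivariate normal
    sampling from the target matrix.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    coeffs = solve_fleishman(spec)
    inter = build_intermediate_matrix(structure, spec)
    f = factor_pattern(inter).matrix
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((structure.n_items, n))
    x = f @ z
    y = coeffs.apply(x)
    y = spec.mean + spec.sd * y
    scenario = _scenario_id(spec)
    return SimulatedDataset(y.T, structure.label, scenario, seed)


def _scenario_id(spec: MomentSpec) -> str:
    for name, s in SCENARIOS.items():
        if s == spec:
            return name
    return f"custom(skew={spec.skewness},kurt={spec.kurtosis})"
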
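"""Fleishman power-method transforms for prescribed skewness and kurtosis.

A standard normal variate Z is mapped through the cubic polynomial

    Y = a + b*Z + c*Z**2 + d*Z**3,        a = -c,

whose coefficients are chosen so that Y has unit variance and prescribed
third and fourth standardized moments.  Because all moments of Z are known
in closed form, the population moments of Y are exact polynomial functions
of (a, b, c, d); the solver is a damped Newton iteration on that moment
system.

Kurtosis is the *excess* convention throughout (normal = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MomentSpec",
    "FleishmanCoefficients",
    "FleishmanInfeasibleError",
    "SCENARIOS",
    "fleishman_moments",
    "solve_fleishman",
]

# E[Z^n] for Z ~ N(0,1), n = 0..12: odd moments vanish, even are (n-1)!!
_NORMAL_MOMENTS = np.array(
    [1, 0, 1, 0, 3, 0, 15, 0, 105, 0, 945, 0, 10395], dtype=float
)


class FleishmanInfeasibleError(ValueError):
    """Raised when no cubic transform attains the requested moments."""


@dataclass(frozen=True)
class MomentSpec:
    """Target marginal moments for one simulated variable.

    ``kurtosis`` is excess kurtosis.  The three study scenarios are
    (0, 1, 0, 0), (0, 1, 1, 3) and (0, 1, 2, 20).
    """

    mean: float = 0.0
    sd: float = 1.0
    skewness: float = 0.0
    kurtosis: float = 0.0

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"sd must be positive, got {self.sd}")


#: The three non-normality scenarios of the simulation design.
SCENARIOS: dict[str, MomentSpec] = {
    "s1": MomentSpec(0.0, 1.0, 0.0, 0.0),
    "s2": MomentSpec(0.0, 1.0, 1.0, 3.0),
    "s3": MomentSpec(0.0, 1.0, 2.0, 20.0),
}


@dataclass(frozen=True)
class FleishmanCoefficients:
    """Coefficients (a, b, c, d) of the cubic transform, with a = -c."""

    a: float
    b: float
    c: float
    d: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d], dtype=float)

    @property
    def is_identity(self) -> bool:
        return self.a == 0.0 and self.b == 1.0 and self.c == 0.0 and self.d == 0.0

    def apply(self, z: np.ndarray) -> np.ndarray:
        """Evaluate a + b z + c z^2 + d z^3 elementwise."""
        return self.a + z * (self.b + z * (self.c + z * self.d))


def _raw_moments(poly: np.ndarray, upto: int = 4) -> np.ndarray:
    """Exact E[Y^k], k = 1..upto, for Y = polynomial(Z) with Z standard normal.

    ``poly`` holds coefficients in ascending degree.  Powers of the
    polynomial are formed by convolution and integrated against the normal
    moment table.
    """
    raw = np.empty(upto)
    power = np.array([1.0])
    for k in range(upto):
        power = np.convolve(power, poly)
        raw[k] = power @ _NORMAL_MOMENTS[: power.size]
    return raw


def fleishman_moments(
    coeffs: FleishmanCoefficients,
) -> tuple[float, float, float]:
    """Population (variance, skewness, excess kurtosis) of the transform.

    Exact closed form via normal-moment algebra; no sampling involved.
    """
    poly = np.array([coeffs.a, coeffs.b, coeffs.c, coeffs.d])
    m1, m2, m3, m4 = _raw_moments(poly)
    var = m2 - m1**2
    mu3 = m3 - 3 * m1 * m2 + 2 * m1**3
    mu4 = m4 - 4 * m1 * m3 + 6 * m1**2 * m2 - 3 * m1**4
    skew = mu3 / var**1.5
    exkurt = mu4 / var**2 - 3.0
    return float(var), float(skew), float(exkurt)


def _residual(bcd: np.ndarray, skew: float, exkurt: float) -> np.ndarray:
    b, c, d = bcd
    var, s, k = fleishman_moments(FleishmanCoefficients(-c, b, c, d))
    return np.array([var - 1.0, s - skew, k - exkurt])


def _jacobian(bcd: np.ndarray, skew: float, exkurt: float) -> np.ndarray:
    h = 1e-7
    jac = np.empty((3, 3))
    for j in range(3):
        step = np.zeros(3)
        step[j] = h
        jac[:, j] = (
            _residual(bcd + step, skew, exkurt)
            - _residual(bcd - step, skew, exkurt)
        ) / (2 * h)
    return jac


def solve_fleishman(
    spec: MomentSpec,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> FleishmanCoefficients:
    """Solve for the cubic coefficients matching ``spec``.

    Damped Newton iteration on the three-equation system (unit variance,
    target skewness, target excess kurtosis), initialized at
    (b, c, d) = (1, skew/6, 0).  A necessary feasibility condition is
    kurtosis >= skewness**2 - 2.

    Raises
    ------
    FleishmanInfeasibleError
        If the spec is outside the feasible region or the iteration does
        not converge.
    """
    if spec.kurtosis < spec.skewness**2 - 2:
        raise FleishmanInfeasibleError(
            f"no Fleishman transform exists for {spec}: requires "
            "kurtosis >= skewness**2 - 2"
        )
    if spec.skewness == 0.0 and spec.kurtosis == 0.0:
        return FleishmanCoefficients(0.0, 1.0, 0.0, 0.0)

    bcd = np.array([1.0, spec.skewness / 6.0, 0.0])
    res = _residual(bcd, spec.skewness, spec.kurtosis)
    for _ in range(max_iter):
        norm = np.max(np.abs(res))
        if norm < tol:
            break
        try:
            step = np.linalg.solve(
                _jacobian(bcd, spec.skewness, spec.kurtosis), res
            )
        except np.linalg.LinAlgError as exc:  # singular Jacobian
            raise FleishmanInfeasibleError(
                f"Fleishman solver failed for {spec}: singular Jacobian"
            ) from exc
        # damp: halve the step until the residual does not get worse
        scale = 1.0
        for _ in range(30):
            trial = bcd - scale * step
            trial_res = _residual(trial, spec.skewness, spec.kurtosis)
            if np.max(np.abs(trial_res)) < norm or scale < 1e-6:
                break
            scale *= 0.5
        bcd, res = trial, trial_res
    else:
        raise FleishmanInfeasibleError(
            f"Fleishman solver did not converge for {spec} "
            f"after {max_iter} iterations (residual {np.max(np.abs(res)):.3g})"
        )
    b, c, d = (float(v) for v in bcd)
    if not all(map(math.isfinite, (b, c, d))):
        raise FleishmanInfeasibleError(
            f"Fleishman solver diverged for {spec}"
        )
    return FleishmanCoefficients(-c, b, c, d)
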
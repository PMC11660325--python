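"""Restricted cubic spline bases on log time and on age.

The flexible parametric survival model places a restricted cubic spline
(a natural cubic spline, linear beyond its boundary knots) in log time on
the log cumulative hazard scale; the same basis family models the age
effect.  With ``m`` knots the basis has ``m - 1`` columns: the identity
``v1(u) = u`` plus ``m - 2`` truncated-cubic combinations

    v_j(u) = (u - k_j)_+^3 - lam_j (u - k_1)_+^3 - (1 - lam_j) (u - k_m)_+^3,
    lam_j = (k_m - k_j) / (k_m - k_1),

which makes every column twice continuously differentiable and linear
outside ``[k_1, k_m]``.  No intercept column is included; models add their
own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray


@dataclass(frozen=True)
class SplineSpec:
    """Knot locations on the transformed scale (log months, or years of age)."""

    knots: tuple[float, ...]
    scale_label: str = "log_time"

    def __post_init__(self) -> None:
        knots = tuple(float(k) for k in self.knots)
        object.__setattr__(self, "knots", knots)
        if len(knots) < 3:
            raise ValueError(f"need at least 3 knots, got {len(knots)}")
        if not all(a < b for a, b in zip(knots, knots[1:])):
            raise ValueError(f"knots must be strictly increasing: {knots}")

    @property
    def n_knots(self) -> int:
        return len(self.knots)

    @property
    def n_basis(self) -> int:
        """Number of basis columns (degrees of freedom excluding intercept)."""
        return len(self.knots) - 1

    def to_dict(self) -> dict:
        return {"knots": list(self.knots), "scale_label": self.scale_label}

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(knots=tuple(d["knots"]), scale_label=d.get("scale_label", "log_time"))


def knots_from_quantiles(
    values: ArrayLike, m: int, scale_label: str = "log_time"
) -> SplineSpec:
    """Place ``m`` knots: boundary at min/max, internal at equally spaced
    quantiles (linear-interpolation definition).

    ``m = 4`` puts internal knots at the 33.3/66.7th percentiles; ``m = 6``
    at 20/40/60/80.  Raises if the values cannot support ``m`` distinct knots.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot place knots on an empty sample")
    if m < 3:
        raise ValueError(f"need m >= 3 knots, got {m}")
    qs = np.linspace(0.0, 1.0, m)
    knots = np.quantile(values, qs, method="linear")
    if np.unique(knots).size < m:
        raise ValueError(
            f"too few distinct values to place {m} distinct knots (got {knots})"
        )
    return SplineSpec(knots=tuple(knots), scale_label=scale_label)


def _plus_cubed(x: NDArray) -> NDArray:
    return np.where(x > 0.0, x, 0.0) ** 3


def rcs_basis(u: ArrayLike, spec: SplineSpec) -> NDArray:
    """Evaluate the restricted cubic spline basis.

    Returns shape ``(..., m - 1)``; the first column is ``u`` itself.
    """
    u = np.asarray(u, dtype=float)
    k = np.asarray(spec.knots)
    k1, km = k[0], k[-1]
    out = np.empty(u.shape + (spec.n_basis,))
    out[..., 0] = u
    for j in range(1, spec.n_basis):
        kj = k[j]
        lam = (km - kj) / (km - k1)
        out[..., j] = (
            _plus_cubed(u - kj)
            - lam * _plus_cubed(u - k1)
            - (1.0 - lam) * _plus_cubed(u - km)
        )
    return out


def rcs_derivative(u: ArrayLike, spec: SplineSpec) -> NDArray:
    """Termwise analytic derivative of :func:`rcs_basis` with respect to ``u``."""
    u = np.asarray(u, dtype=float)
    k = np.asarray(spec.knots)
    k1, km = k[0], k[-1]

    def plus_sq(x: NDArray) -> NDArray:
        return np.where(x > 0.0, x, 0.0) ** 2

    out = np.empty(u.shape + (spec.n_basis,))
    out[..., 0] = 1.0
    for j in range(1, spec.n_basis):
        kj = k[j]
        lam = (km - kj) / (km - k1)
        out[..., j] = 3.0 * (
            plus_sq(u - kj) - lam * plus_sq(u - k1) - (1.0 - lam) * plus_sq(u - km)
        )
    return out
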
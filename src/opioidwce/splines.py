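"""B-spline bases used for nonlinear covariate effects, time-dependent effects and
recency-weight functions.

All bases are clamped (open knot vector) B-splines built on scipy's ``BSpline``; on the
interior of the boundary interval the basis functions form a partition of unity, which is
what makes the nesting arguments in the model hierarchy (linear ⊂ nonlinear,
proportional-hazards ⊂ time-dependent) exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineBasis", "make_basis"]


@dataclass(frozen=True)
class SplineBasis:
    """A clamped B-spline basis on [lo, hi] with the given interior knots."""

    degree: int
    interior_knots: tuple[float, ...]
    boundary: tuple[float, float]

    @property
    def knot_vector(self) -> np.ndarray:
        lo, hi = self.boundary
        return np.r_[
            np.full(self.degree + 1, lo), self.interior_knots, np.full(self.degree + 1, hi)
        ]

    @property
    def n_basis(self) -> int:
        return len(self.interior_knots) + self.degree + 1

    def design(self, x: np.ndarray) -> np.ndarray:
        """Evaluate all basis functions at x (shape: len(x) × n_basis).

        Values outside [lo, hi] raise: the model never extrapolates beyond the
        boundary knots.
        """
        x = np.asarray(x, dtype=float)
        lo, hi = self.boundary
        if x.size and (x.min() < lo or x.max() > hi):
            raise ValueError(
                f"spline evaluated outside boundary knots [{lo}, {hi}]: "
                f"range [{x.min()}, {x.max()}]"
            )
        return BSpline.design_matrix(x, self.knot_vector, self.degree).toarray()


def make_basis(
    degree: int,
    n_interior: int,
    boundary: tuple[float, float],
    interior: np.ndarray | None = None,
    x_for_quantile_knots: np.ndarray | None = None,
) -> SplineBasis:
    """Build a basis with explicit interior knots, quantile-placed knots, or
    equally spaced knots over the boundary interval.

    Knot placement priority: explicit ``interior`` > quantiles of
    ``x_for_quantile_knots`` > equally spaced. Knots must end up strictly inside the
    boundary and strictly increasing.
    """
    lo, hi = float(boundary[0]), float(boundary[1])
    if not hi > lo:
        raise ValueError(f"degenerate boundary [{lo}, {hi}]")
    if interior is not None:
        knots = np.asarray(interior, dtype=float)
    elif n_interior == 0:
        knots = np.array([])
    elif x_for_quantile_knots is not None:
        q = np.linspace(0, 1, n_interior + 2)[1:-1]
        knots = np.quantile(np.asarray(x_for_quantile_knots, dtype=float), q)
        # zero-inflated or heavily tied covariates can push quantile knots onto the
        # boundary or each other; fall back to equal spacing
        if np.any(np.diff(knots) <= 0) or knots.min() <= lo or knots.max() >= hi:
            knots = np.linspace(lo, hi, n_interior + 2)[1:-1]
    else:
        knots = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.asarray(knots, dtype=float)
    if knots.size and (np.any(np.diff(knots) <= 0) or knots.min() <= lo or knots.max() >= hi):
        raise ValueError(f"interior knots {knots} must be strictly increasing inside ({lo}, {hi})")
    return SplineBasis(degree=degree, interior_knots=tuple(knots), boundary=(lo, hi))
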
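"""Computed ABC (cABC) analysis: ABC curves and computed set boundaries.

ABC analysis partitions a set of non-negative item values ``x_i`` (feature
importances, eigenvalues, inventory values ...) into subsets "A" (the
important few), "B" (intermediate) and "C" (the trivial many).  The ABC
curve plots the cumulative normalized yield

    Y_i = sum(x_(1..i)) / sum(x_(1..n)),   values sorted descending,

against the effort fraction ``E_i = i / n``.  It is the reversed-order
counterpart of the Lorenz curve.  Computed ABC analysis replaces heuristic
cut-offs (80/20 and friends) with two boundaries computed from the curve:

* the **Juran point** — the curve point closest to the ideal "Pareto"
  point (0, 1), marking the A|B boundary;
* the **break-even point** — the first point where the curve slope
  dY/dE falls to 1 (marginal yield equals marginal effort), marking the
  B|C boundary.

Both are located on a continuous interpolant through the curve knots, by
default a shape-preserving monotone piecewise cubic (PCHIP); an
unconstrained cubic spline is available for concordance experiments but
can overshoot and violate monotonicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator
from scipy.optimize import brentq, minimize_scalar

from .errors import (
    DegenerateInputError,
    NegativeValueError,
    NonMonotoneInterpolantError,
    TooFewItemsError,
)

__all__ = [
    "ItemSet",
    "ABCCurve",
    "ABCPartition",
    "BreakEvenPoint",
    "compute_abc_curve",
    "find_juran_point",
    "find_break_even",
    "partition",
]

#: number of points in the coarse grid used to bracket boundary searches
_GRID = 4096
#: x-tolerance of the refined boundary locations
_XTOL = 1e-9


@dataclass(frozen=True)
class ItemSet:
    """A universe of labelled non-negative item values.

    Parameters
    ----------
    labels
        Unique item identifiers.
    values
        Non-negative importance values, one per label.  At least one value
        must be strictly positive and ``n >= 3``.
    """

    labels: tuple
    values: np.ndarray

    def __init__(self, labels: Sequence, values: Iterable[float]):
        labels = tuple(labels)
        values = np.asarray(list(values) if not isinstance(values, np.ndarray)
                            else values, dtype=float)
        if values.ndim != 1 or len(labels) != values.size:
            raise ValueError("labels and values must be 1-D and of equal length")
        if len(set(labels)) != len(labels):
            raise ValueError("item labels must be unique")
        if values.size == 0:
            raise ValueError("item set must not be empty")
        if np.any(np.isnan(values)):
            raise ValueError("item values must not contain NaN")
        neg = np.flatnonzero(values < 0)
        if neg.size:
            raise NegativeValueError(labels[neg[0]], values[neg[0]])
        if not np.any(values > 0):
            raise DegenerateInputError("all item values are zero")
        values.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return self.values.size

    @classmethod
    def from_dict(cls, mapping: Mapping) -> "ItemSet":
        return cls(tuple(mapping.keys()), list(mapping.values()))

    @classmethod
    def from_values(cls, values: Iterable[float], prefix: str = "item") -> "ItemSet":
        values = np.asarray(list(values), dtype=float)
        width = len(str(values.size))
        labels = tuple(f"{prefix}{i + 1:0{width}d}" for i in range(values.size))
        return cls(labels, values)

    def subset(self, labels: Sequence) -> "ItemSet":
        """Restrict the set to ``labels``, preserving this set's order."""
        wanted = set(labels)
        keep = [i for i, lab in enumerate(self.labels) if lab in wanted]
        if len(keep) != len(wanted):
            missing = wanted - set(self.labels)
            raise KeyError(f"labels not in item set: {sorted(missing)!r}")
        return ItemSet(tuple(self.labels[i] for i in keep), self.values[keep])

    def to_dict(self) -> dict:
        return dict(zip(self.labels, self.values.tolist()))


@dataclass(frozen=True)
class ABCCurve:
    """Normalized effort/yield knots plus a continuous interpolant.

    ``efforts`` and ``yields`` hold the n+1 knots (0, 0), (i/n, Y_i); the
    interpolant maps an effort fraction p in [0, 1] to the interpolated
    yield Y(p), with the first derivative available via :meth:`slope`.
    """

    efforts: np.ndarray
    yields: np.ndarray
    kind: str
    n: int
    _interp: object = field(repr=False)

    def __call__(self, p):
        return self._interp(p)

    def slope(self, p):
        """First derivative dY/dp of the interpolant."""
        return self._interp.derivative()(p)

    def is_monotone(self, tol: float = 1e-9) -> bool:
        """True if the interpolated yield is nondecreasing on [0, 1]."""
        grid = np.linspace(0.0, 1.0, _GRID + 1)
        return bool(np.min(self.slope(grid)) >= -tol)


class BreakEvenPoint(NamedTuple):
    x: float
    y: float
    degenerate: bool  # slope never crosses 1 (identity-like curve)


@dataclass(frozen=True)
class ABCPartition:
    """A/B/C membership with the computed boundary points.

    ``set_a``/``set_b``/``set_c`` are label tuples ordered by decreasing
    value; ``juran`` and ``break_even`` are (x, y) points on the ABC curve.
    """

    juran: tuple
    break_even: tuple
    degenerate_flat: bool
    set_a: tuple
    set_b: tuple
    set_c: tuple
    a_fraction: float
    n: int

    @property
    def counts(self) -> tuple:
        return (len(self.set_a), len(self.set_b), len(self.set_c))

    def to_dict(self) -> dict:
        return {
            "juran": [float(self.juran[0]), float(self.juran[1])],
            "break_even": [float(self.break_even[0]), float(self.break_even[1])],
            "degenerate_flat": self.degenerate_flat,
            "a": list(self.set_a),
            "b": list(self.set_b),
            "c": list(self.set_c),
            "a_fraction": float(self.a_fraction),
            "n": self.n,
        }


def _descending_order(values: np.ndarray) -> np.ndarray:
    # stable sort: ties keep input order
    return np.argsort(-values, kind="stable")


def compute_abc_curve(items: ItemSet, *, interpolation: str = "pchip",
                      min_to_zero: bool = False) -> ABCCurve:
    """Build the ABC curve of an item set.

    Values are sorted in decreasing order; knot i is
    ``(i/n, cumsum_desc(i)/total)`` with (0, 0) prepended.

    Parameters
    ----------
    interpolation
        ``"pchip"`` (default) fits a shape-preserving monotone piecewise
        cubic; ``"cubic"`` fits an unconstrained cubic spline, which can
        overshoot on strongly skewed data.
    min_to_zero
        Shift all values so the minimum becomes zero before constructing
        the curve (ABC analysis is scale- but not translation-invariant).
    """
    values = items.values.astype(float)
    if min_to_zero:
        values = values - values.min()
    total = values.sum()
    if total <= 0:
        raise DegenerateInputError(
            "total item value is zero after normalization; no ABC curve exists")
    n = values.size
    if n < 3:
        raise TooFewItemsError(
            f"need at least 3 items to build an ABC curve, got {n}")
    srt = np.sort(values)[::-1]
    efforts = np.arange(0, n + 1, dtype=float) / n
    yields = np.concatenate([[0.0], np.cumsum(srt) / total])
    # numeric guard: force the exact endpoint
    yields[-1] = 1.0
    if interpolation == "pchip":
        interp = PchipInterpolator(efforts, yields)
    elif interpolation == "cubic":
        interp = CubicSpline(efforts, yields)
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    return ABCCurve(efforts=efforts, yields=yields, kind=interpolation,
                    n=n, _interp=interp)


def _check_monotone(curve: ABCCurve) -> None:
    if not curve.is_monotone():
        raise NonMonotoneInterpolantError(
            "interpolated ABC curve is not monotone (spline overshoot); "
            "use shape-preserving interpolation (interpolation='pchip')")


def find_juran_point(curve: ABCCurve) -> tuple:
    """Locate the Juran point: the curve point nearest the Pareto point (0, 1).

    A 4096-point coarse grid brackets the minimum of the squared Euclidean
    distance ``p**2 + (1 - Y(p))**2``; bounded scalar minimization then
    refines it to an x-tolerance well below 1e-6.
    """
    _check_monotone(curve)

    def sqdist(p):
        return p * p + (1.0 - curve(p)) ** 2

    grid = np.linspace(0.0, 1.0, _GRID + 1)
    i = int(np.argmin(sqdist(grid)))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, _GRID)]
    if hi - lo < _XTOL:
        jx = grid[i]
    else:
        res = minimize_scalar(sqdist, bounds=(lo, hi), method="bounded",
                              options={"xatol": _XTOL})
        jx = float(res.x)
    return (jx, float(curve(jx)))


def find_break_even(curve: ABCCurve, from_x: float = 0.0) -> BreakEvenPoint:
    """Locate the break-even point: the smallest ``p >= from_x`` with slope 1.

    The slope of a descending-sorted ABC curve starts at or above 1 and ends
    at or below 1; the first sign change of ``slope - 1`` on a coarse grid
    is refined by bracketed root finding.  If the slope never drops below 1
    (identity-like data) the boundary ``p = 1`` is returned with
    ``degenerate=True``.
    """
    _check_monotone(curve)
    from_x = float(from_x)
    if not 0.0 <= from_x < 1.0:
        raise ValueError("from_x must lie in [0, 1)")

    def excess(p):
        return curve.slope(p) - 1.0

    grid = np.linspace(from_x, 1.0, _GRID + 1)
    ex = excess(grid)
    below = np.flatnonzero(ex < -1e-9)
    if below.size == 0:
        # slope ~ 1 (or above) everywhere: flat/identity-like curve
        return BreakEvenPoint(1.0, float(curve(1.0)), True)
    k = int(below[0])
    if k == 0:
        bx = from_x
    else:
        bx = float(brentq(excess, grid[k - 1], grid[k], xtol=_XTOL))
    return BreakEvenPoint(bx, float(curve(bx)), False)


def _rank_counts(jx: float, bx: float, n: int) -> tuple:
    n_a = max(1, int(round(jx * n)))
    n_ab = min(n, max(n_a, int(round(bx * n))))
    return n_a, n_ab


def partition(items: ItemSet, *, interpolation: str = "pchip",
              bc_method: str = "slope", keep_ties_together: bool = False,
              min_to_zero: bool = False, force: bool = False) -> ABCPartition:
    """Run computed ABC analysis: partition items into subsets A, B and C.

    The A|B boundary is the Juran point; the count of "A" items is
    ``max(1, round(J_x * n))``.  The B|C boundary is located with
    ``bc_method``:

    * ``"slope"`` (default) — first point right of the Juran point where
      the curve slope equals 1;
    * ``"juran_subcurve"`` — a Juran-style nearest-to-Pareto search on the
      ABC sub-curve built from the items right of the A|B boundary.

    Items are ranked by descending value (ties broken by input order) and
    boundaries cut by rank; ``keep_ties_together=True`` widens A (and A+B)
    to include neighbors of equal value.  The partition is invariant to
    multiplying all values by any positive constant.

    Fewer than three items cannot support a curve; with ``force=True`` such
    input yields the trivial all-"A" partition instead of an error.
    """
    n = items.n
    if n < 3:
        if not force:
            raise TooFewItemsError(
                f"cannot partition {n} items; pass force=True for the trivial "
                "all-A answer")
        return ABCPartition(juran=(1.0, 1.0), break_even=(1.0, 1.0),
                            degenerate_flat=True, set_a=tuple(items.labels),
                            set_b=(), set_c=(), a_fraction=1.0, n=n)

    curve = compute_abc_curve(items, interpolation=interpolation,
                              min_to_zero=min_to_zero)
    jx, jy = find_juran_point(curve)

    values = items.values.astype(float)
    if min_to_zero:
        values = values - values.min()
    order = _descending_order(values)
    srt = values[order]

    n_a = max(1, int(round(jx * n)))
    degenerate = False
    if bc_method == "slope":
        be = find_break_even(curve, from_x=jx)
        degenerate = be.degenerate
        bx, by = be.x, be.y
        n_a, n_ab = _rank_counts(jx, bx, n)
    elif bc_method == "juran_subcurve":
        rest = srt[n_a:]
        if rest.size >= 3 and rest.sum() > 0:
            sub = compute_abc_curve(ItemSet.from_values(rest, prefix="r"),
                                    interpolation=interpolation)
            sub_jx, _ = find_juran_point(sub)
            n_b = max(1, int(round(sub_jx * rest.size)))
            n_ab = min(n, n_a + n_b)
        else:
            # too few residual items for a sub-curve; fall back to slope search
            be = find_break_even(curve, from_x=jx)
            degenerate = be.degenerate
            n_a, n_ab = _rank_counts(jx, be.x, n)
        bx = n_ab / n
        by = float(curve(bx))
    else:
        raise ValueError(f"unknown bc_method {bc_method!r}")

    if keep_ties_together:
        while n_a < n and srt[n_a] == srt[n_a - 1]:
            n_a += 1
        n_ab = max(n_ab, n_a)
        while n_ab < n and srt[n_ab] == srt[n_ab - 1]:
            n_ab += 1

    labels = items.labels
    set_a = tuple(labels[i] for i in order[:n_a])
    set_b = tuple(labels[i] for i in order[n_a:n_ab])
    set_c = tuple(labels[i] for i in order[n_ab:])
    return ABCPartition(juran=(float(jx), float(jy)),
                        break_even=(float(bx), float(by)),
                        degenerate_flat=degenerate,
                        set_a=set_a, set_b=set_b, set_c=set_c,
                        a_fraction=n_a / n, n=n)
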
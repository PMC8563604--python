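"""Two-iteration fractional spherical central-composite design engine.

The optimizer screens three factors — feed flowrate (mL/min), temperature
(degC) and dilution ratio (solvent:substrate pump flow) — in two zoom-in
rounds:

1. a centered subregion spanning 70% of each axis of the design space is
   screened with a fractional spherical CCD: 1 center + 2k axial points
   (coded +-1 per axis) + a half-fraction of the cube corners, 11 runs for
   k = 3;
2. the best run (highest space-time yield) becomes the center of a second
   subregion spanning 40% of the first, screened with the same design minus
   the center (already measured), 10 more runs — 21 in total.

All non-center points sit on the unit sphere in coded units: the axial
points at coded +-1 on one axis, the corner points at +-alpha/k = +-1/sqrt(k)
on every axis, where alpha = sqrt(k) is the corner distance expressed in
per-axis sign units.  With fractions (0.7, 0.4) the scheme can reach 98% of
each factor range while guaranteeing every run stays inside the user bounds.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "DEFAULT_BOUNDS",
    "DesignSpace",
    "Subregion",
    "DesignPoint",
    "CampaignPlan",
    "alpha",
    "half_fraction_corners",
    "coded_to_real",
    "real_to_coded",
    "generate_ccd",
    "subregion_first",
    "subregion_second",
    "coverage_fraction",
    "select_best",
    "plan_campaign",
]

#: Default factor bounds: flowrate mL/min, temperature degC, dilution ratio.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "flowrate": (0.2, 2.0),
    "temperature": (25.0, 35.0),
    "dilution": (4.0, 40.0),
}


@dataclass(frozen=True)
class DesignSpace:
    """Axis-aligned box of factor bounds, ordered by factor name insertion."""

    bounds: tuple[tuple[str, float, float], ...] = tuple(
        (name, lo, hi) for name, (lo, hi) in DEFAULT_BOUNDS.items()
    )

    def __post_init__(self):
        if not self.bounds:
            raise ValidationError("design space needs at least one factor")
        names = [b[0] for b in self.bounds]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate factor names")
        for name, lo, hi in self.bounds:
            if not lo < hi:
                raise ValidationError(f"factor {name!r}: lower bound must be < upper")

    @classmethod
    def from_mapping(cls, bounds: Mapping[str, Sequence[float]]) -> "DesignSpace":
        return cls(tuple((name, float(lo), float(hi)) for name, (lo, hi) in bounds.items()))

    @classmethod
    def default(cls) -> "DesignSpace":
        return cls()

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bounds)

    @property
    def k(self) -> int:
        return len(self.bounds)

    @property
    def lower(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])

    @property
    def upper(self) -> np.ndarray:
        return np.array([b[2] for b in self.bounds])

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)

    def contains(self, real: Sequence[float], tol: float = 1e-9) -> bool:
        real = np.asarray(real, dtype=float)
        return bool(
            np.all(real >= self.lower - tol) and np.all(real <= self.upper + tol)
        )


@dataclass(frozen=True)
class Subregion:
    """A centered sub-box of a design space, the arena of one CCD iteration."""

    space: DesignSpace
    center: tuple[float, ...]
    half_span: tuple[float, ...]

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        h = np.asarray(self.half_span, dtype=float)
        if c.shape != (self.space.k,) or h.shape != (self.space.k,):
            raise ValidationError("center/half_span must match the factor count")
        if np.any(h <= 0):
            raise ValidationError("half spans must be positive")
        tol = 1e-9 * np.maximum(1.0, self.space.span)
        if np.any(c - h < self.space.lower - tol) or np.any(
            c + h > self.space.upper + tol
        ):
            raise ValidationError("subregion extends outside its design space")

    @property
    def lower(self) -> np.ndarray:
        return np.asarray(self.center) - np.asarray(self.half_span)

    @property
    def upper(self) -> np.ndarray:
        return np.asarray(self.center) + np.asarray(self.half_span)

    def contains(self, real: Sequence[float], tol: float = 1e-9) -> bool:
        real = np.asarray(real, dtype=float)
        t = tol * np.maximum(1.0, self.space.span)
        return bool(np.all(real >= self.lower - t) and np.all(real <= self.upper + t))


@dataclass(frozen=True)
class DesignPoint:
    """One planned run: coded coordinates, engineering values, bookkeeping."""

    factors: tuple[str, ...]
    coded: tuple[float, ...]
    real: tuple[float, ...]
    role: str  # "center" | "axial" | "factorial"
    iteration: int
    run_index: int

    def __post_init__(self):
        if self.role not in ("center", "axial", "factorial"):
            raise ValidationError(f"unknown role {self.role!r}")
        if not (len(self.factors) == len(self.coded) == len(self.real)):
            raise ValidationError("factors/coded/real length mismatch")
        if self.iteration not in (1, 2):
            raise ValidationError("iteration must be 1 or 2")

    def value(self, name: str) -> float:
        return self.real[self.factors.index(name)]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.factors, self.real))


def alpha(k: int) -> float:
    """Corner distance in coded sign units: sqrt(k)."""
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ValueError("k must be an integer >= 1")
    return math.sqrt(k)


def half_fraction_corners(k: int = 3) -> list[tuple[int, ...]]:
    """The 2^(k-1) cube-corner sign vectors with component product +1.

    For k = 3: (+,+,+), (+,-,-), (-,+,-), (-,-,+).  The defining relation
    (product of signs = +1) picks one half-fraction of the full factorial.
    """
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ValueError("k must be an integer >= 1")
    return [
        signs
        for signs in itertools.product((1, -1), repeat=int(k))
        if math.prod(signs) == 1
    ]


def coded_to_real(coded: Sequence[float], subregion: Subregion) -> np.ndarray:
    """Affine map per axis: real = center + coded * half_span."""
    return np.asarray(subregion.center) + np.asarray(coded, dtype=float) * np.asarray(
        subregion.half_span
    )


def real_to_coded(real: Sequence[float], subregion: Subregion) -> np.ndarray:
    """Exact inverse of :func:`coded_to_real`."""
    return (np.asarray(real, dtype=float) - np.asarray(subregion.center)) / np.asarray(
        subregion.half_span
    )


def generate_ccd(
    subregion: Subregion,
    include_center: bool = True,
    *,
    iteration: int = 1,
    start_index: int = 0,
) -> list[DesignPoint]:
    """Spherical fractional CCD points for one subregion.

    1 center (optional) + 2k axial points at coded +-1 on a single axis +
    ``half_fraction_corners(k)`` corners scaled to +-1/sqrt(k) per axis, so
    every non-center point lies at unit coded radius.  11 points for k = 3
    with the center, 10 without.
    """
    k = subregion.space.k
    coded_points: list[tuple[tuple[float, ...], str]] = []
    if include_center:
        coded_points.append((tuple(0.0 for _ in range(k)), "center"))
    for axis in range(k):
        for sign in (-1.0, 1.0):
            coded = [0.0] * k
            coded[axis] = sign
            coded_points.append((tuple(coded), "axial"))
    scale = alpha(k) / k  # = 1/sqrt(k): puts corners on the unit coded sphere
    for signs in half_fraction_corners(k):
        coded_points.append((tuple(scale * s for s in signs), "factorial"))

    points = []
    for offset, (coded, role) in enumerate(coded_points):
        real = coded_to_real(coded, subregion)
        points.append(
            DesignPoint(
                factors=subregion.space.names,
                coded=coded,
                real=tuple(float(v) for v in real),
                role=role,
                iteration=iteration,
                run_index=start_index + offset,
            )
        )
    return points


def subregion_first(space: DesignSpace, fraction: float = 0.7) -> Subregion:
    """Centered subregion whose per-axis span is ``fraction`` of the parent's."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return Subregion(
        space=space,
        center=tuple(space.center),
        half_span=tuple(fraction * space.span / 2.0),
    )


def subregion_second(
    space: DesignSpace,
    first: Subregion,
    best: DesignPoint | Sequence[float],
    fraction: float = 0.4,
) -> Subregion:
    """Zoomed subregion for iteration 2, centered at the iteration-1 best.

    The span is ``fraction`` of the first subregion's span.  If the box would
    protrude beyond the design space (possible only with non-default
    fractions) it is translated inward with its span preserved, keeping the
    CCD geometry intact.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    real = np.asarray(best.real if isinstance(best, DesignPoint) else best, dtype=float)
    if not first.contains(real):
        raise ValidationError("best point must lie inside the first subregion")
    half = fraction * np.asarray(first.half_span)
    if np.any(2 * half > space.span):
        raise ValidationError("second subregion larger than the design space")
    center = np.clip(real, space.lower + half, space.upper - half)
    return Subregion(space=space, center=tuple(center), half_span=tuple(half))


def coverage_fraction(f1: float, f2: float) -> float:
    """Per-axis fraction of the full range reachable by the two iterations.

    The centered first region spans ``f1``; centering the second region at a
    first-region boundary point extends the reach by ``f2*f1/2`` on each
    side, so the reachable fraction is ``min(1, f1 + f2*f1)``.
    """
    if not (0 < f1 <= 1 and 0 < f2 <= 1):
        raise ValueError("fractions must be in (0, 1]")
    return min(1.0, f1 + f2 * f1)


def select_best(results: Iterable) -> object:
    """Argmax of space-time yield; ties broken by earliest run index.

    Accepts any objects exposing ``.sty`` and ``.point.run_index``.
    """
    ordered = sorted(results, key=lambda r: r.point.run_index)
    if not ordered:
        raise ValueError("no results to select from")
    best = ordered[0]
    for r in ordered[1:]:
        if r.sty > best.sty:
            best = r
    return best


@dataclass
class CampaignPlan:
    """The 21-run schedule: iteration 1 up front, iteration 2 once the best
    first-round point is known (it is reused as the new center, not re-run)."""

    space: DesignSpace
    first_fraction: float
    second_fraction: float
    subregion_1: Subregion
    points: list[DesignPoint]
    subregion_2: Subregion | None = None
    alpha: float = field(init=False)

    def __post_init__(self):
        self.alpha = alpha(self.space.k)

    @property
    def iteration1(self) -> list[DesignPoint]:
        return [p for p in self.points if p.iteration == 1]

    @property
    def iteration2(self) -> list[DesignPoint]:
        return [p for p in self.points if p.iteration == 2]

    @property
    def complete(self) -> bool:
        return self.subregion_2 is not None

    def complete_second(self, best: DesignPoint | Sequence[float]) -> list[DesignPoint]:
        """Fix the second subregion around the iteration-1 best and append
        the 10 second-round points; returns the new points."""
        if self.complete:
            raise ValidationError("second iteration already planned")
        self.subregion_2 = subregion_second(
            self.space, self.subregion_1, best, self.second_fraction
        )
        new_points = generate_ccd(
            self.subregion_2,
            include_center=False,
            iteration=2,
            start_index=len(self.points),
        )
        self.points.extend(new_points)
        return new_points


def plan_campaign(config) -> CampaignPlan:
    """Build the iteration-1 plan from a campaign configuration.

    ``config`` must expose ``design_space``, ``first_fraction`` and
    ``second_fraction`` (see :class:`flowbed.io_formats.CampaignConfig`).
    The second iteration is added later via ``CampaignPlan.complete_second``.
    """
    space = config.design_space
    first = subregion_first(space, config.first_fraction)
    points = generate_ccd(first, include_center=True, iteration=1, start_index=0)
    return CampaignPlan(
        space=space,
        first_fraction=config.first_fraction,
        second_fraction=config.second_fraction,
        subregion_1=first,
        points=points,
    )
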
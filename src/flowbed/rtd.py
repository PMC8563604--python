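"""Residence-time-distribution analysis for structured-bed flow reactors.

Step-tracer experiments record the detector signal at the inlet and the
outlet of a column holding a 3D-printed insert (honeycomb or cubic lattice).
This module turns those two raw signals into

* a cumulative distribution ``F`` (normalized step response),
* an exit-age density ``E = dF/dt``,
* mean residence time and variance of ``E`` (trapezoidal quadrature),
* inlet-corrected moments via Levenspiel's additivity rule
  (moments of devices in series add, so subtracting the inlet-capillary
  moments isolates the column itself),
* the Bodenstein number ``Bo = u * L_char / D_ax`` from the open-open
  axial-dispersion model, whose dimensionless variance obeys

  .. math:: \\sigma_\\theta^2 = 2/Bo + 8/Bo^2

  with the closed-form inverse ``Bo = (1 + sqrt(1 + 8 s)) / s``,
* the Reynolds number ``Re = rho * u * d_H / mu`` based on the hydraulic
  diameter ``d_H = 4 A / P`` of the channel cross-section.

Interface units are the bench units (mm, mm^2, mm^3, mL/min, s); conversion
to SI happens internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .exceptions import DataInconsistencyError, SignalQualityError, ValidationError

__all__ = [
    "FluidProperties",
    "InsertGeometry",
    "StepCurves",
    "RTDResult",
    "ETHANOL",
    "WATER",
    "builtin_inserts",
    "hydraulic_diameter",
    "reynolds",
    "normalize_step",
    "f_to_e",
    "moments",
    "correct_moments",
    "sigma_theta_from_bodenstein",
    "bodenstein_from_variance",
    "bodenstein_from_moments",
    "analyze_rtd",
]


@dataclass(frozen=True)
class FluidProperties:
    """Bulk fluid properties used for the Reynolds number.

    density: kg/m^3, dynamic_viscosity: Pa*s.
    """

    density: float
    dynamic_viscosity: float

    def __post_init__(self):
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("density and dynamic_viscosity must be positive")


#: Ethanol at ~20 degC, the carrier solvent of the methylene-blue tracer runs.
ETHANOL = FluidProperties(density=789.0, dynamic_viscosity=1.2e-3)
#: Water at ~20 degC, for reference calculations.
WATER = FluidProperties(density=998.0, dynamic_viscosity=1.0e-3)


@dataclass(frozen=True)
class InsertGeometry:
    """Geometry of one structured insert (all lengths in mm).

    ``hydraulic_diameter`` is the per-channel 4A/P value; ``length`` is the
    characteristic length used for Bo -> D_ax back-calculation.  The open
    cross-section used for the superficial velocity is ``cross_section_area``
    when provided, else ``internal_volume / length``.
    """

    name: str
    family: str  # "HC" (honeycomb) or "CL" (cubic lattice)
    hydraulic_diameter: float  # mm
    internal_volume: float  # mm^3
    length: float  # mm
    internal_area: float | None = None  # mm^2
    area_to_volume: float | None = None  # mm^2/mm^3, as declared by CAD
    cross_section_area: float | None = None  # mm^2, open flow area
    wetted_perimeter: float | None = None  # mm

    def __post_init__(self):
        if self.family not in ("HC", "CL"):
            raise ValidationError(f"unknown insert family {self.family!r}")
        for attr in ("hydraulic_diameter", "internal_volume", "length"):
            if getattr(self, attr) <= 0:
                raise ValidationError(f"{attr} must be positive")
        for attr in ("internal_area", "area_to_volume", "cross_section_area",
                     "wetted_perimeter"):
            v = getattr(self, attr)
            if v is not None and v <= 0:
                raise ValidationError(f"{attr} must be positive when given")
        if self.internal_area is not None and self.area_to_volume is not None:
            ratio = self.internal_area / self.internal_volume
            # declared ratios are typically quoted to one decimal, so accept
            # either 1% or half a print unit, whichever is looser
            tol = max(0.01 * self.area_to_volume, 0.05)
            if abs(ratio - self.area_to_volume) > tol:
                raise ValidationError(
                    "internal_area / internal_volume deviates from the "
                    f"declared area-to-volume ratio by more than 1% "
                    f"({ratio:.3f} vs {self.area_to_volume:.3f})"
                )

    @property
    def flow_area(self) -> float:
        """Open cross-section in mm^2 seen by the superficial velocity."""
        if self.cross_section_area is not None:
            return self.cross_section_area
        return self.internal_volume / self.length


def builtin_inserts() -> dict[str, InsertGeometry]:
    """The six CAD-characterized inserts (honeycomb HC1-3, cubic lattice
    CL1-3), all 39.8 mm long."""
    rows = [
        ("HC1", "HC", 0.757, 351.71, 1857.3, 5.3),
        ("HC2", "HC", 0.521, 314.86, 2416.1, 7.7),
        ("HC3", "HC", 0.263, 234.65, 3572.2, 15.2),
        ("CL1", "CL", 1.564, 1044.78, 2671.3, 2.6),
        ("CL2", "CL", 0.930, 842.98, 3627.2, 4.3),
        ("CL3", "CL", 0.433, 467.12, 4319.5, 9.2),
    ]
    return {
        name: InsertGeometry(
            name=name,
            family=family,
            hydraulic_diameter=dh,
            internal_volume=vol,
            length=39.8,
            internal_area=area,
            area_to_volume=av,
        )
        for name, family, dh, vol, area, av in rows
    }


@dataclass
class StepCurves:
    """Processed step-response curves for one experiment."""

    time: np.ndarray  # s
    f_inlet: np.ndarray
    f_outlet: np.ndarray
    e_inlet: np.ndarray  # 1/s
    e_outlet: np.ndarray  # 1/s


@dataclass
class RTDResult:
    """Corrected RTD moments and derived dimensionless numbers.

    ``above_range`` flags experiments whose corrected variance is too small
    to resolve (near-ideal plug flow or identical inlet/outlet signals); the
    Bodenstein number is then ``inf`` and ``axial_dispersion`` 0.
    """

    mean_residence_time: float  # s
    variance: float  # s^2
    dimensionless_variance: float
    bodenstein: float
    axial_dispersion: float  # m^2/s
    reynolds: float
    superficial_velocity: float  # m/s
    flowrate: float  # mL/min
    above_range: bool = False
    curves: StepCurves | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# dimensionless numbers


def hydraulic_diameter(cross_section_area: float, wetted_perimeter: float) -> float:
    """d_H = 4*A/P for a non-circular channel (mm^2, mm -> mm)."""
    if cross_section_area <= 0 or wetted_perimeter <= 0:
        raise ValueError("cross-section area and wetted perimeter must be positive")
    return 4.0 * cross_section_area / wetted_perimeter


def reynolds(fluid: FluidProperties, velocity: float, d_h: float) -> float:
    """Re = rho*u*d_H/mu with u in m/s and d_H in m."""
    if velocity <= 0 or d_h <= 0:
        raise ValueError("velocity and hydraulic diameter must be positive")
    return fluid.density * velocity * d_h / fluid.dynamic_viscosity


# ---------------------------------------------------------------------------
# step-signal processing


def normalize_step(
    signal,
    light_reference: float | None = None,
    dark_reference: float | None = None,
    *,
    step_down: bool = False,
    edge_fraction: float = 0.1,
    min_snr: float = 3.0,
    clip: bool = True,
) -> np.ndarray:
    """Normalize a raw step signal to a cumulative F-curve in [0, 1].

    The baseline is the median of the pre-step samples (everything before the
    smoothed signal first crosses 10% of its span), the plateau the median of
    the trailing ``edge_fraction`` window;
    ``F = (s - baseline)/(plateau - baseline)`` clipped to [0, 1].
    ``light_reference``/``dark_reference`` (the solvent flush references) may
    be supplied to pre-scale the raw detector counts; the normalization
    itself is affine-invariant so they only matter for sanity checking.
    Step-down recordings are flipped to step-up first.
    """
    s = np.asarray(signal, dtype=float)
    if s.ndim != 1 or s.size < 3:
        raise ValidationError("signal must be 1-D with at least 3 samples")
    if not np.all(np.isfinite(s)):
        raise ValidationError("signal contains non-finite values")
    if light_reference is not None or dark_reference is not None:
        if light_reference is None or dark_reference is None:
            raise ValidationError("provide both light and dark references or neither")
        if light_reference == dark_reference:
            raise ValidationError("light and dark references must differ")
        s = (s - dark_reference) / (light_reference - dark_reference)
    if step_down:
        s = -s
    k = max(1, int(round(edge_fraction * s.size)))
    smooth = uniform_filter1d(s, size=min(5, s.size), mode="nearest")
    lo, hi = np.percentile(smooth, [1.0, 99.0])
    rough_span = hi - lo
    if rough_span <= 0:
        raise SignalQualityError("signal is constant; no step to normalize")
    rise = np.nonzero(smooth >= lo + 0.1 * rough_span)[0]
    i_rise = int(rise[0]) if rise.size else 0
    base_win = s[:i_rise] if i_rise >= 2 else s[:1]
    baseline = float(np.median(base_win))
    plateau = float(np.median(s[-k:]))
    base_noise = float(np.std(base_win)) if base_win.size >= 5 else 0.0
    noise = max(base_noise, float(np.std(s[-k:])))
    span = plateau - baseline
    if span == 0.0 or abs(span) <= min_snr * noise:
        raise SignalQualityError(
            "step height indistinguishable from noise "
            f"(span={span:.3g}, noise={noise:.3g})"
        )
    f = (s - baseline) / span
    if clip:
        # the exposed F-curve contract; moment estimation works on the
        # unclipped curve because one-sided clipping rectifies plateau noise
        f = np.clip(f, 0.0, 1.0)
    return f


def f_to_e(f, time, smooth_window: int = 5) -> np.ndarray:
    """Differentiate an F-curve into the exit-age density E (1/s).

    A centered moving average of ``smooth_window`` samples is applied before
    central-difference differentiation and E is renormalized to unit area.
    Small negative noise lobes are deliberately retained: clipping them
    would rectify zero-mean detector noise into spurious positive exit-age
    mass and bias the variance upward.
    """
    f = np.asarray(f, dtype=float)
    t = np.asarray(time, dtype=float)
    if f.size != t.size:
        raise ValidationError("F and time must have equal length")
    if f.size < 5:
        raise ValidationError("need at least 5 samples to differentiate")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("time must be strictly increasing")
    if smooth_window and smooth_window > 1:
        f = uniform_filter1d(f, size=int(smooth_window), mode="nearest")
    e = np.gradient(f, t)
    area = float(np.trapezoid(e, t))
    if area <= 0:
        raise SignalQualityError("F-curve carries no rise; cannot form E")
    return e / area


def moments(e, time) -> tuple[float, float]:
    """Mean residence time and variance of an exit-age density.

    ``t_mean = int t E dt`` and ``sigma^2 = int (t - t_mean)^2 E dt`` by
    trapezoidal quadrature; E is renormalized defensively first.
    """
    e = np.asarray(e, dtype=float)
    t = np.asarray(time, dtype=float)
    area = float(np.trapezoid(e, t))
    if area <= 0:
        raise ValidationError("E must have positive area")
    e = e / area
    t_mean = float(np.trapezoid(t * e, t))
    var = float(np.trapezoid((t - t_mean) ** 2 * e, t))
    return t_mean, var


def correct_moments(
    outlet: tuple[float, float], inlet: tuple[float, float]
) -> tuple[float, float]:
    """Remove the feed-system contribution by moment additivity.

    For devices in series both the mean and the variance add, so the column's
    own moments are the element-wise outlet-minus-inlet differences.
    """
    dt_mean = outlet[0] - inlet[0]
    dvar = outlet[1] - inlet[1]
    if dt_mean < 0 or dvar < 0:
        raise DataInconsistencyError(
            "outlet moments smaller than inlet moments "
            f"(dt_mean={dt_mean:.4g}, dvar={dvar:.4g})"
        )
    return dt_mean, dvar


# ---------------------------------------------------------------------------
# open-open dispersion model


def sigma_theta_from_bodenstein(bo: float) -> float:
    """Dimensionless variance of the open-open model: 2/Bo + 8/Bo^2."""
    if bo <= 0:
        raise ValueError("Bo must be positive")
    return 2.0 / bo + 8.0 / bo**2


def bodenstein_from_variance(sigma_theta_sq: float) -> float:
    """Closed-form inverse of ``sigma_theta_from_bodenstein``.

    The unique positive root of ``s = 2/Bo + 8/Bo^2`` is
    ``Bo = (1 + sqrt(1 + 8 s)) / s``.
    """
    if sigma_theta_sq <= 0:
        raise ValueError("dimensionless variance must be positive")
    s = sigma_theta_sq
    return (1.0 + math.sqrt(1.0 + 8.0 * s)) / s


def bodenstein_from_moments(t_mean: float, variance: float) -> float:
    """Bodenstein number from *measured* open-open moments.

    In an open-open vessel the measured mean overshoots the space time,
    ``t_mean = tau * (1 + 2/Bo)``, while ``sigma^2 = tau^2 * (2/Bo + 8/Bo^2)``.
    Eliminating tau gives, with ``r = sigma^2 / t_mean^2`` and ``x = 1/Bo``,

        (4r - 8) x^2 + (4r - 2) x + r = 0,

    whose admissible root is ``x = (2 - 4r - 2*sqrt(4r + 1)) / (8r - 16)``.
    ``r`` approaches 2 from below as Bo -> 0, so r >= 2 is out of range.
    """
    if t_mean <= 0 or variance <= 0:
        raise ValueError("t_mean and variance must be positive")
    r = variance / t_mean**2
    if r >= 2.0:
        raise ValueError(
            f"measured sigma^2/t_mean^2 = {r:.3g} exceeds the open-open limit of 2"
        )
    x = (2.0 - 4.0 * r - 2.0 * math.sqrt(4.0 * r + 1.0)) / (8.0 * r - 16.0)
    return 1.0 / x


# ---------------------------------------------------------------------------
# full pipeline


def _moment_window(f: np.ndarray, t: np.ndarray, tail_factor: float) -> np.ndarray:
    """Boolean mask restricting moment integrals to the step transition.

    Detector noise far from the transition is amplified by the (t - t_mean)^2
    weight of the variance integral, so E is integrated only from just before
    the first 1% crossing of F to ``tail_factor`` transition-widths past the
    99% crossing.  For noise-free curves the excluded region carries no mass,
    so the window is bias-free to well below quadrature accuracy.
    """
    # heavy smoothing for crossing detection only, so single noise spikes
    # cannot trigger the 99% crossing early (the last sample still below the
    # threshold marks the true end of the transition)
    fs = uniform_filter1d(f, size=min(25, f.size), mode="nearest")
    above_lo = np.nonzero(fs >= 0.01)[0]
    below_hi = np.nonzero(fs < 0.99)[0]
    if above_lo.size == 0 or below_hi.size == 0 or below_hi[-1] + 1 >= f.size:
        return np.ones_like(f, dtype=bool)
    t_lo = t[above_lo[0]]
    t_hi = t[below_hi[-1] + 1]
    width = max(t_hi - t_lo, t[1] - t[0])
    lo = t_lo - 0.25 * width
    hi = t_hi + tail_factor * width
    return (t >= lo) & (t <= hi)


def _taper(t: np.ndarray, lo: float, hi: float, width: float) -> np.ndarray:
    """Smooth window: 1 on [lo, hi], cosine rolloff of ``width`` outside.

    A hard cutoff would inject the F-noise of the two edge samples into the
    variance integral with weight (t_edge - t_mean)^2; the taper spreads the
    edge over many samples so that noise averages out.
    """
    w = np.zeros_like(t)
    core = (t >= lo) & (t <= hi)
    w[core] = 1.0
    left = (t >= lo - width) & (t < lo)
    w[left] = 0.5 * (1.0 + np.cos(np.pi * (lo - t[left]) / width))
    right = (t > hi) & (t <= hi + width)
    w[right] = 0.5 * (1.0 + np.cos(np.pi * (t[right] - hi) / width))
    return w


def _series_moments(
    f: np.ndarray, t: np.ndarray, smooth_window: int, tail_factor: float
) -> tuple[float, float]:
    """Moments of one series with noise-robust windowing.

    Starting from the F-crossing window, the moment window is refined twice
    around the current estimates (4 sigma below to ``tail_factor`` + 4 sigma
    above the mean, 1-sigma cosine taper) so that far-plateau detector noise,
    whose contribution to the variance integral grows as (t - t_mean)^2,
    is excluded without biasing the skewed open-open tail.
    """
    e = f_to_e(f, t, smooth_window=smooth_window)
    mask = _moment_window(f, t, tail_factor)
    tm, var = moments(np.where(mask, e, 0.0), t)
    for _ in range(2):
        sig = math.sqrt(max(var, (t[1] - t[0]) ** 2))
        w = _taper(t, tm - 4.0 * sig, tm + (tail_factor + 4.0) * sig, sig)
        ew = e * w
        area = float(np.trapezoid(ew, t))
        if area <= 0:
            raise SignalQualityError("moment window rejected all exit-age mass")
        tm, var = moments(ew / area, t)
    return tm, var


def analyze_rtd(
    time,
    inlet_signal,
    outlet_signal,
    geometry: InsertGeometry,
    fluid: FluidProperties,
    flowrate: float,
    *,
    step_down: bool = False,
    smooth_window: int = 5,
    tail_factor: float = 2.0,
    bo_max: float = 1e6,
    keep_curves: bool = True,
) -> RTDResult:
    """Full dual-point RTD pipeline for one insert at one flowrate.

    normalize -> differentiate -> moments (inlet and outlet) -> inlet
    correction -> Bo from the measured-moment open-open relation
    (:func:`bodenstein_from_moments`, which accounts for the open-vessel
    mean overshoot) -> ``D_ax = u*L_char/Bo``, with ``u = FR / A_open`` and
    Re from the channel hydraulic diameter.  ``flowrate`` is in mL/min.

    Corrected variances that would imply ``Bo > bo_max`` cannot be resolved
    by the moment method and are flagged ``above_range`` (Bo = inf).
    """
    if flowrate <= 0:
        raise ValueError("flowrate must be positive")
    t = np.asarray(time, dtype=float)
    f_in = normalize_step(inlet_signal, step_down=step_down, clip=False)
    f_out = normalize_step(outlet_signal, step_down=step_down, clip=False)
    tm_in, var_in = _series_moments(f_in, t, smooth_window, tail_factor)
    tm_out, var_out = _series_moments(f_out, t, smooth_window, tail_factor)
    f_in = np.clip(f_in, 0.0, 1.0)
    f_out = np.clip(f_out, 0.0, 1.0)
    tm, var = correct_moments((tm_out, var_out), (tm_in, var_in))
    if tm <= 0:
        # identical inlet/outlet signals: nothing measurable happened in the
        # column, which is the extreme above-range (plug-flow-like) case
        if var > 1e-9 * max(tm_out, 1.0) ** 2:
            raise DataInconsistencyError(
                "corrected mean residence time is not positive"
            )
        sigma_theta_sq = 0.0
    else:
        sigma_theta_sq = var / tm**2

    # SI conversions: mL/min -> m^3/s, mm^2 -> m^2, mm -> m
    volumetric = flowrate * 1e-6 / 60.0
    u = volumetric / (geometry.flow_area * 1e-6)
    length_m = geometry.length * 1e-3

    floor = sigma_theta_from_bodenstein(bo_max)
    if sigma_theta_sq <= floor:
        bo, d_ax, above = math.inf, 0.0, True
    else:
        bo = bodenstein_from_moments(tm, var)
        d_ax = u * length_m / bo
        above = False

    curves = None
    if keep_curves:
        curves = StepCurves(
            time=t,
            f_inlet=f_in,
            f_outlet=f_out,
            e_inlet=f_to_e(f_in, t, smooth_window=smooth_window),
            e_outlet=f_to_e(f_out, t, smooth_window=smooth_window),
        )
    return RTDResult(
        mean_residence_time=tm,
        variance=var,
        dimensionless_variance=sigma_theta_sq,
        bodenstein=bo,
        axial_dispersion=d_ax,
        reynolds=reynolds(fluid, u, geometry.hydraulic_diameter * 1e-3),
        superficial_velocity=u,
        flowrate=flowrate,
        above_range=above,
        curves=curves,
    )
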
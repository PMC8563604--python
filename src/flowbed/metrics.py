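"""Scalar process formulas for the continuous decarboxylation platform.

Covers dosing (dilution-ratio pump splitting), inline UV-Vis quantification
(Beer-Lambert window means), conversion/yield, residence time, space-time
yield, immobilization yield, enzymatic activity units and steady-state
detection.  The model reaction is the 1:1 decarboxylation of coumaric acid
to 4-vinylphenol by immobilized bsPAD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .doe import DesignPoint
from .exceptions import ValidationError
from .rtd import InsertGeometry

__all__ = [
    "VINYLPHENOL_MW",
    "SpectraCalibration",
    "SteadyStateSettings",
    "ImmobilizationRecord",
    "ActivityAssay",
    "ExperimentResult",
    "dilution_to_concentration",
    "pump_split",
    "absorbance_to_concentration",
    "conversion_and_yield",
    "residence_time",
    "sty",
    "immobilization_yield",
    "activity_units",
    "steady_state_detect",
    "evaluate_run",
]

#: Molar mass of 4-vinylphenol, g/mol, for mM -> g/L conversion.
VINYLPHENOL_MW = 120.15


@dataclass(frozen=True)
class SpectraCalibration:
    """Beer-Lambert quantification windows and calibration slopes.

    The product (4-vinylphenol) absorbs at 263-269 nm, the substrate
    (coumaric acid) at 325-328 nm where the product does not absorb; slopes
    are AU per mM from calibration curves at the 1.5 mm flow-cell path.
    """

    product_window: tuple[float, float] = (263.0, 269.0)
    substrate_window: tuple[float, float] = (325.0, 328.0)
    slopes: dict[str, float] = field(
        default_factory=lambda: {"product": 0.8, "substrate": 0.3}
    )
    path_length: float = 1.5  # mm

    def __post_init__(self):
        for name, (lo, hi) in (
            ("product_window", self.product_window),
            ("substrate_window", self.substrate_window),
        ):
            if not lo < hi:
                raise ValidationError(f"{name} must be an increasing interval")
        lo1, hi1 = self.product_window
        lo2, hi2 = self.substrate_window
        if max(lo1, lo2) < min(hi1, hi2):
            raise ValidationError("quantification windows must not overlap")
        for species, slope in self.slopes.items():
            if slope <= 0:
                raise ValidationError(f"slope for {species!r} must be positive")
        if self.path_length <= 0:
            raise ValidationError("path length must be positive")

    def window(self, species: str) -> tuple[float, float]:
        if species == "product":
            return self.product_window
        if species == "substrate":
            return self.substrate_window
        raise ValidationError(f"unknown species {species!r}")


@dataclass(frozen=True)
class SteadyStateSettings:
    """Sliding-window plateau criterion for inline concentration traces."""

    window: int = 10
    rel_tol: float = 0.02

    def __post_init__(self):
        if self.window < 3:
            raise ValidationError("window must cover at least 3 samples")
        if self.rel_tol <= 0:
            raise ValidationError("rel_tol must be positive")


@dataclass(frozen=True)
class ImmobilizationRecord:
    """Solution activity before/after immobilization and the implied yield."""

    activity_before: float  # U
    activity_after: float  # U
    yield_percent: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self,
            "yield_percent",
            immobilization_yield(self.activity_before, self.activity_after),
        )


@dataclass(frozen=True)
class ActivityAssay:
    """A 30-min batch assay: coumaric acid consumed per minute (units U)."""

    c_start: float  # umol/L
    c_end: float  # umol/L
    volume: float  # L
    duration: float = 30.0  # min
    units: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self,
            "units",
            activity_units(self.c_start, self.c_end, self.volume, self.duration),
        )


@dataclass(frozen=True)
class ExperimentResult:
    """Steady-state outcome of one run: concentrations, X, Y, tau, STY."""

    point: DesignPoint
    c0: float  # mM
    c_substrate: float  # mM
    c_prod: float  # mM
    c_prod_g_l: float  # g/L
    conversion: float  # fraction
    yield_frac: float  # fraction
    residence_time_s: float
    sty: float  # g/(L*h)

    def __post_init__(self):
        if not (-1e-9 <= self.conversion <= 1 + 1e-9):
            raise ValidationError("conversion must lie in [0, 1]")
        if not (-1e-9 <= self.yield_frac <= 1 + 1e-9):
            raise ValidationError("yield must lie in [0, 1]")
        if self.yield_frac > self.conversion + 1e-9:
            raise ValidationError("yield cannot exceed conversion (1:1 stoichiometry)")
        if self.sty < 0:
            raise ValidationError("STY must be non-negative")


# ---------------------------------------------------------------------------
# dosing


def dilution_to_concentration(stock: float, dilution: float) -> float:
    """Feed concentration from the solvent:substrate flow ratio D.

    c0 = stock / (1 + D): at D = 4.36 a 10 mM stock gives 1.87 mM.
    """
    if stock <= 0:
        raise ValueError("stock concentration must be positive")
    if dilution < 0:
        raise ValueError("dilution ratio must be non-negative")
    return stock / (1.0 + dilution)


def pump_split(total_flowrate: float, dilution: float) -> tuple[float, float]:
    """Split a total flowrate into (substrate, solvent) pump setpoints.

    substrate = total/(1+D), solvent = total*D/(1+D); the sum is exact.
    """
    if total_flowrate <= 0:
        raise ValueError("total flowrate must be positive")
    if dilution < 0:
        raise ValueError("dilution ratio must be non-negative")
    substrate = total_flowrate / (1.0 + dilution)
    return substrate, total_flowrate - substrate


# ---------------------------------------------------------------------------
# quantification


def absorbance_to_concentration(
    wavelengths,
    absorbance_row,
    calibration: SpectraCalibration,
    species: str,
) -> float:
    """Window-mean absorbance divided by the species slope (linear
    Beer-Lambert model); negative results are clipped to 0 with a warning."""
    w = np.asarray(wavelengths, dtype=float)
    a = np.asarray(absorbance_row, dtype=float)
    if w.shape != a.shape:
        raise ValidationError("wavelength and absorbance rows differ in length")
    lo, hi = calibration.window(species)
    if lo < w[0] or hi > w[-1]:
        raise ValidationError(
            f"{species} window {lo}-{hi} nm outside the measured axis "
            f"{w[0]}-{w[-1]} nm"
        )
    mask = (w >= lo) & (w <= hi)
    if not np.any(mask):
        raise ValidationError("no wavelength samples inside the window")
    conc = float(np.mean(a[mask])) / calibration.slopes[species]
    if conc < 0:
        warnings.warn(
            f"negative {species} concentration ({conc:.3g} mM) clipped to 0",
            stacklevel=2,
        )
        conc = 0.0
    return conc


def conversion_and_yield(
    c0: float, c_substrate: float, c_prod: float
) -> tuple[float, float]:
    """Mole-basis conversion X = (c0 - c_s)/c0 and yield Y = c_p/c0."""
    if c0 <= 0:
        raise ValueError("feed concentration must be positive")
    return (c0 - c_substrate) / c0, c_prod / c0


# ---------------------------------------------------------------------------
# reactor-scale metrics


def residence_time(internal_volume: float, flowrate: float) -> float:
    """Hydraulic residence time in s from V_i (mm^3) and FR (mL/min)."""
    if internal_volume <= 0 or flowrate <= 0:
        raise ValueError("volume and flowrate must be positive")
    return internal_volume / 1000.0 / flowrate * 60.0


def sty(c_prod_g_l: float, flowrate: float, internal_volume: float) -> float:
    """Space-time yield in g/(L*h): c_prod (g/L) * FR (L/h) / V_i (L)."""
    if flowrate <= 0 or internal_volume <= 0:
        raise ValueError("flowrate and volume must be positive")
    if c_prod_g_l < 0:
        raise ValueError("product concentration must be non-negative")
    return c_prod_g_l * (flowrate * 0.06) / (internal_volume * 1e-6)


def immobilization_yield(activity_before: float, activity_after: float) -> float:
    """Yi = (A_b - A_a)/A_b * 100, the % of solution activity transferred
    to the support."""
    if activity_before <= 0:
        raise ValueError("activity before immobilization must be positive")
    if not 0 <= activity_after <= activity_before:
        raise ValidationError("activity after must lie in [0, activity_before]")
    return (activity_before - activity_after) / activity_before * 100.0


def activity_units(
    c_start: float, c_end: float, volume: float, duration: float
) -> float:
    """U = (C_0 - C_t) * V_assay / t in umol/min (C in umol/L, V in L)."""
    if duration <= 0:
        raise ValueError("assay duration must be positive")
    if volume <= 0:
        raise ValueError("assay volume must be positive")
    if c_end > c_start:
        raise ValidationError("substrate concentration cannot increase in the assay")
    return (c_start - c_end) * volume / duration


def steady_state_detect(
    values, window: int = 10, rel_tol: float = 0.02
) -> float | None:
    """Earliest sliding window whose relative range is within ``rel_tol``.

    Returns the mean of that window, or ``None`` when no window qualifies
    (e.g. a still-ramping trace).
    """
    if window < 3:
        raise ValueError("window must cover at least 3 samples")
    v = np.asarray(values, dtype=float)
    if v.size < window:
        return None
    for i in range(v.size - window + 1):
        chunk = v[i : i + window]
        mean = float(np.mean(chunk))
        rng = float(np.max(chunk) - np.min(chunk))
        if rng <= rel_tol * abs(mean) or (mean == 0.0 and rng == 0.0):
            return mean
    return None


# ---------------------------------------------------------------------------
# assembling one run's result


def evaluate_run(
    point: DesignPoint,
    geometry: InsertGeometry,
    stock: float,
    c_substrate: float,
    c_prod: float,
    *,
    molar_mass: float = VINYLPHENOL_MW,
    clip: bool = True,
) -> ExperimentResult:
    """Derive every reported metric for one run from measured steady-state
    substrate and product concentrations (mM).

    With ``clip`` (default) measured concentrations are clipped to the mass
    balance (0 <= c_s <= c0, 0 <= c_p <= c0 - c_s), absorbing small detector
    noise that would otherwise make the yield exceed the conversion.
    """
    dilution = point.value("dilution")
    flowrate = point.value("flowrate")
    c0 = dilution_to_concentration(stock, dilution)
    if clip:
        c_substrate = float(np.clip(c_substrate, 0.0, c0))
        c_prod = float(np.clip(c_prod, 0.0, c0 - c_substrate))
    conversion, yield_frac = conversion_and_yield(c0, c_substrate, c_prod)
    tau = residence_time(geometry.internal_volume, flowrate)
    c_prod_g_l = c_prod * molar_mass / 1000.0
    return ExperimentResult(
        point=point,
        c0=c0,
        c_substrate=c_substrate,
        c_prod=c_prod,
        c_prod_g_l=c_prod_g_l,
        conversion=conversion,
        yield_frac=yield_frac,
        residence_time_s=tau,
        sty=sty(c_prod_g_l, flowrate, geometry.internal_volume),
    )
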
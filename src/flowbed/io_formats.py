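"""Readers and writers for every external artifact of the platform.

* tracer logs — the comma-separated ``t,v_in,v_out`` dialect of the serial
  terminal capture, ``#`` for comments, times in seconds, UTF-8, "." decimal;
* spectra frames — CSV with wavelengths (nm) across the first row and
  timestamps (s) down the first column;
* design and results tables — CSV, one row per run;
* campaign configurations — YAML.

Readers never reorder records, and every reader/writer pair round-trips.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

from .doe import DesignPoint, DesignSpace
from .exceptions import ParseError, ValidationError
from .metrics import ExperimentResult, SteadyStateSettings
from .rtd import InsertGeometry

__all__ = [
    "TracerLogRecord",
    "SpectraFrame",
    "CampaignConfig",
    "read_tracer_log",
    "write_tracer_log",
    "tracer_arrays",
    "read_spectra_frame",
    "write_spectra_frame",
    "read_design_table",
    "write_design_table",
    "write_results_table",
    "read_results_table",
    "load_campaign_config",
    "dump_campaign_config",
]


class TracerLogRecord(NamedTuple):
    """One logged sample of the dual-photometer tracer rig."""

    elapsed_time: float  # s
    signal_inlet: float
    signal_outlet: float


@dataclass
class SpectraFrame:
    """UV-Vis absorbance frames: time x wavelength matrix."""

    timestamps: np.ndarray  # s
    wavelengths: np.ndarray  # nm, strictly increasing
    absorbance: np.ndarray  # AU, shape (n_times, n_wavelengths)

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.shape != (self.timestamps.size, self.wavelengths.size):
            raise ValidationError(
                "absorbance matrix shape does not match the time/wavelength axes"
            )
        if self.wavelengths.size == 0 or self.timestamps.size == 0:
            raise ValidationError("spectra frame must not be empty")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValidationError("absorbance contains non-finite values")

    def row(self, index: int) -> np.ndarray:
        return self.absorbance[index]


def _as_text_handle(source, mode: str = "r"):
    """(handle, should_close) for a path or an already-open text stream."""
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8"), True
    return source, False


# ---------------------------------------------------------------------------
# tracer logs


def read_tracer_log(source) -> list[TracerLogRecord]:
    """Parse a ``t,v_in,v_out`` tracer log (path or text stream).

    ``#`` lines and blank lines are skipped; time must be strictly
    increasing and all values finite.
    """
    handle, close = _as_text_handle(source)
    records: list[TracerLogRecord] = []
    prev_t = -math.inf
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ParseError(
                    f"expected 3 comma-separated fields, got {len(parts)}", lineno
                )
            try:
                t, v_in, v_out = (float(p) for p in parts)
            except ValueError as exc:
                raise ParseError(f"non-numeric field in {line!r}", lineno) from exc
            if not all(map(math.isfinite, (t, v_in, v_out))):
                raise ParseError("non-finite value", lineno)
            if t < 0:
                raise ValidationError(f"line {lineno}: negative elapsed time {t}")
            if t <= prev_t:
                raise ValidationError(
                    f"line {lineno}: elapsed time not strictly increasing "
                    f"({t} after {prev_t})"
                )
            prev_t = t
            records.append(TracerLogRecord(t, v_in, v_out))
    finally:
        if close:
            handle.close()
    return records


def write_tracer_log(records: Iterable[TracerLogRecord], sink) -> None:
    handle, close = _as_text_handle(sink, "w")
    try:
        handle.write("# elapsed_time_s,signal_inlet,signal_outlet\n")
        for r in records:
            handle.write(f"{r.elapsed_time!r},{r.signal_inlet!r},{r.signal_outlet!r}\n")
    finally:
        if close:
            handle.close()


def tracer_arrays(
    records: Sequence[TracerLogRecord],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(time, inlet, outlet) arrays in file order."""
    if not records:
        raise ValidationError("empty tracer log")
    arr = np.asarray(records, dtype=float)
    return arr[:, 0], arr[:, 1], arr[:, 2]


# ---------------------------------------------------------------------------
# spectra frames


def read_spectra_frame(source) -> SpectraFrame:
    """CSV with wavelengths across the header row and timestamps down the
    first column."""
    handle, close = _as_text_handle(source)
    try:
        lines = [
            (n, line.strip())
            for n, line in enumerate(handle, start=1)
            if line.strip()
        ]
    finally:
        if close:
            handle.close()
    if not lines:
        raise ParseError("empty spectra file")
    header_no, header = lines[0]
    fields = header.split(",")
    if len(fields) < 2:
        raise ParseError("header must list at least one wavelength", header_no)
    try:
        wavelengths = [float(f) for f in fields[1:]]
    except ValueError as exc:
        raise ParseError("non-numeric wavelength in header", header_no) from exc
    if len(lines) == 1:
        raise ParseError("spectra file has a header but no data rows")
    timestamps, rows = [], []
    for lineno, line in lines[1:]:
        parts = line.split(",")
        if len(parts) != len(fields):
            raise ParseError(
                f"row has {len(parts)} fields, header has {len(fields)}", lineno
            )
        try:
            timestamps.append(float(parts[0]))
            rows.append([float(p) for p in parts[1:]])
        except ValueError as exc:
            raise ParseError("non-numeric value", lineno) from exc
    return SpectraFrame(
        timestamps=np.array(timestamps),
        wavelengths=np.array(wavelengths),
        absorbance=np.array(rows),
    )


def write_spectra_frame(frame: SpectraFrame, sink) -> None:
    handle, close = _as_text_handle(sink, "w")
    try:
        handle.write("time," + ",".join(repr(float(w)) for w in frame.wavelengths) + "\n")
        for t, row in zip(frame.timestamps, frame.absorbance):
            handle.write(repr(float(t)) + "," + ",".join(repr(float(v)) for v in row) + "\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# design and results tables


def write_design_table(points: Sequence[DesignPoint], sink) -> None:
    """CSV with iteration, run index, role, coded and real coordinates."""
    if not points:
        handle, close = _as_text_handle(sink, "w")
        try:
            handle.write("iteration,run_index,role\n")
        finally:
            if close:
                handle.close()
        return
    factors = points[0].factors
    rows = []
    for p in points:
        row: dict[str, object] = {
            "iteration": p.iteration,
            "run_index": p.run_index,
            "role": p.role,
        }
        row.update({f"coded_{n}": c for n, c in zip(factors, p.coded)})
        row.update({n: v for n, v in zip(factors, p.real)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(sink, index=False)


def read_design_table(source) -> list[DesignPoint]:
    df = pd.read_csv(source)
    required = {"iteration", "run_index", "role"}
    if not required.issubset(df.columns):
        raise ParseError(f"design table missing columns {required - set(df.columns)}")
    factors = tuple(
        c[len("coded_"):] for c in df.columns if c.startswith("coded_")
    )
    points = []
    for _, row in df.iterrows():
        points.append(
            DesignPoint(
                factors=factors,
                coded=tuple(float(row[f"coded_{n}"]) for n in factors),
                real=tuple(float(row[n]) for n in factors),
                role=str(row["role"]),
                iteration=int(row["iteration"]),
                run_index=int(row["run_index"]),
            )
        )
    return points


_RESULT_COLUMNS = [
    "c0_mM",
    "c_substrate_mM",
    "c_prod_mM",
    "c_prod_g_L",
    "conversion",
    "yield",
    "residence_time_s",
    "sty_g_L_h",
]


def write_results_table(results: Sequence[ExperimentResult], sink) -> None:
    """One row per run in the semantics of the campaign summary table:
    operating point, feed and outlet concentrations, X, Y, tau, STY."""
    rows = []
    for r in results:
        row: dict[str, object] = {
            "iteration": r.point.iteration,
            "run_index": r.point.run_index,
            "role": r.point.role,
        }
        row.update(r.point.as_dict())
        row.update(
            dict(
                zip(
                    _RESULT_COLUMNS,
                    [
                        r.c0,
                        r.c_substrate,
                        r.c_prod,
                        r.c_prod_g_l,
                        r.conversion,
                        r.yield_frac,
                        r.residence_time_s,
                        r.sty,
                    ],
                )
            )
        )
        rows.append(row)
    pd.DataFrame(rows, columns=(
        ["iteration", "run_index", "role"]
        + (list(results[0].point.factors) if results else [])
        + _RESULT_COLUMNS
    )).to_csv(sink, index=False)


def read_results_table(source) -> pd.DataFrame:
    return pd.read_csv(source)


# ---------------------------------------------------------------------------
# campaign configuration


@dataclass
class CampaignConfig:
    """Everything a campaign needs: bounds, dosing stock, insert, schedule."""

    design_space: DesignSpace
    stock_concentration: float  # mM
    insert: InsertGeometry
    first_fraction: float = 0.7
    second_fraction: float = 0.4
    steady_state: SteadyStateSettings = field(default_factory=SteadyStateSettings)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.first_fraction <= 1:
            raise ValidationError("first_fraction must be in (0, 1]")
        if not 0 < self.second_fraction <= 1:
            raise ValidationError("second_fraction must be in (0, 1]")
        if self.stock_concentration <= 0:
            raise ValidationError("stock concentration must be positive")


def load_campaign_config(source) -> CampaignConfig:
    """Load a campaign configuration from YAML (path or stream)."""
    handle, close = _as_text_handle(source)
    try:
        data = yaml.safe_load(handle)
    finally:
        if close:
            handle.close()
    if not isinstance(data, dict):
        raise ParseError("campaign config must be a YAML mapping")
    try:
        space = DesignSpace.from_mapping(data["design_space"])
        insert = InsertGeometry(**data["insert"])
        steady = SteadyStateSettings(**data.get("steady_state", {}))
        return CampaignConfig(
            design_space=space,
            stock_concentration=float(data["stock_concentration"]),
            insert=insert,
            first_fraction=float(data.get("first_fraction", 0.7)),
            second_fraction=float(data.get("second_fraction", 0.4)),
            steady_state=steady,
            seed=int(data.get("seed", 0)),
        )
    except KeyError as exc:
        raise ParseError(f"campaign config missing key {exc}") from exc
    except TypeError as exc:
        raise ParseError(f"malformed campaign config: {exc}") from exc


def dump_campaign_config(config: CampaignConfig, sink) -> None:
    data = {
        "design_space": {
            name: [lo, hi] for name, lo, hi in config.design_space.bounds
        },
        "stock_concentration": config.stock_concentration,
        "first_fraction": config.first_fraction,
        "second_fraction": config.second_fraction,
        "seed": config.seed,
        "insert": {
            k: v for k, v in asdict(config.insert).items() if v is not None
        },
        "steady_state": asdict(config.steady_state),
    }
    handle, close = _as_text_handle(sink, "w")
    try:
        yaml.safe_dump(data, handle, sort_keys=False)
    finally:
        if close:
            handle.close()
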
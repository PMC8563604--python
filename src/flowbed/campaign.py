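"""Orchestration of the two-iteration self-optimization campaign.

The campaign engine is provider-agnostic: anything implementing
:class:`ExperimentProvider` — the bundled virtual reactor, or a future
hardware adapter driving pumps, valve and spectrometer — can serve the 21
runs.  The engine plans iteration 1 (11 runs), picks the best point by
space-time yield, zooms, runs iteration 2 (10 runs, the center inherited
without re-running), and reports the overall optimum.  Failed runs are
excluded from selection; the campaign aborts once more than a configurable
fraction of runs has failed.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import pandas as pd

from . import doe, metrics
from .doe import CampaignPlan, DesignPoint
from .io_formats import CampaignConfig, write_results_table
from .metrics import ExperimentResult
from .simulate import VirtualReactor, measure_concentrations

__all__ = [
    "ExperimentProvider",
    "SimulatorProvider",
    "FailedRun",
    "CampaignResult",
    "run_campaign",
    "report",
]


@runtime_checkable
class ExperimentProvider(Protocol):
    """Contract for an experiment backend.

    ``run`` must return measured steady-state (substrate, product)
    concentrations in mM for the requested design point, stateless across
    calls except for per-run seeding.
    """

    def run(self, point: DesignPoint) -> tuple[float, float]:  # pragma: no cover
        ...


@dataclass
class SimulatorProvider:
    """Experiment provider backed by the virtual reactor.

    Same point + same seed gives the same result; each run index draws an
    independent noise stream.
    """

    reactor: VirtualReactor
    noise_rel: float | None = None
    seed: int | None = None

    def run(self, point: DesignPoint) -> tuple[float, float]:
        return measure_concentrations(
            point, self.reactor, noise_rel=self.noise_rel, seed=self.seed
        )


@dataclass(frozen=True)
class FailedRun:
    point: DesignPoint
    error: str
    timestamp: str


@dataclass
class CampaignResult:
    """Everything a finished (or aborted) campaign produced."""

    plan: CampaignPlan
    results: list[ExperimentResult]
    failures: list[FailedRun]
    best_iteration1: ExperimentResult | None
    best_final: ExperimentResult | None
    log: list[dict] = field(default_factory=list)
    aborted: bool = False
    abort_reason: str | None = None

    def iteration_results(self, iteration: int) -> list[ExperimentResult]:
        return [r for r in self.results if r.point.iteration == iteration]


def _now() -> str:
    return _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")


def _log_row(point: DesignPoint, status: str, result: ExperimentResult | None,
             error: str | None) -> dict:
    row = {
        "timestamp": _now(),
        "run_index": point.run_index,
        "iteration": point.iteration,
        "role": point.role,
        "status": status,
        **point.as_dict(),
    }
    if result is not None:
        row.update(
            c0_mM=result.c0,
            c_substrate_mM=result.c_substrate,
            c_prod_mM=result.c_prod,
            conversion=result.conversion,
            **{"yield": result.yield_frac},
            sty_g_L_h=result.sty,
        )
    if error is not None:
        row["error"] = error
    return row


def run_campaign(
    provider: ExperimentProvider,
    config: CampaignConfig,
    *,
    max_failure_fraction: float = 0.2,
) -> CampaignResult:
    """Execute the full two-iteration campaign against a provider.

    Provider exceptions mark the run failed and exclude it from selection;
    once failures exceed ``max_failure_fraction`` of the 21 planned runs the
    campaign stops with ``aborted=True`` and a partial log.
    """
    plan = doe.plan_campaign(config)
    geometry, stock = config.insert, config.stock_concentration
    total_planned = len(plan.points) + 10  # iteration 2 is planned lazily
    max_failures = max_failure_fraction * total_planned

    results: list[ExperimentResult] = []
    failures: list[FailedRun] = []
    log: list[dict] = []

    def aborted(reason: str) -> CampaignResult:
        best = doe.select_best(results) if results else None
        return CampaignResult(
            plan=plan,
            results=results,
            failures=failures,
            best_iteration1=best,
            best_final=best,
            log=log,
            aborted=True,
            abort_reason=reason,
        )

    def run_points(points: list[DesignPoint]) -> str | None:
        for point in points:
            try:
                c_sub, c_prod = provider.run(point)
                result = metrics.evaluate_run(point, geometry, stock, c_sub, c_prod)
            except Exception as exc:  # noqa: BLE001 - provider contract
                failures.append(FailedRun(point, repr(exc), _now()))
                log.append(_log_row(point, "failed", None, repr(exc)))
                if len(failures) > max_failures:
                    return (
                        f"{len(failures)} of {total_planned} runs failed "
                        f"(> {max_failure_fraction:.0%})"
                    )
            else:
                results.append(result)
                log.append(_log_row(point, "ok", result, None))
        return None

    reason = run_points(plan.iteration1)
    if reason:
        return aborted(reason)
    iter1 = [r for r in results if r.point.iteration == 1]
    if not iter1:
        return aborted("no successful first-iteration run")
    best1 = doe.select_best(iter1)

    second_points = plan.complete_second(best1.point)
    reason = run_points(second_points)
    if reason:
        result = aborted(reason)
        result.best_iteration1 = best1
        return result

    best_final = doe.select_best(results)
    return CampaignResult(
        plan=plan,
        results=results,
        failures=failures,
        best_iteration1=best1,
        best_final=best_final,
        log=log,
    )


def _best_summary(result: ExperimentResult | None) -> dict | None:
    if result is None:
        return None
    return {
        "run_index": result.point.run_index,
        "iteration": result.point.iteration,
        **result.point.as_dict(),
        "c0_mM": result.c0,
        "conversion": result.conversion,
        "yield": result.yield_frac,
        "residence_time_s": result.residence_time_s,
        "sty_g_L_h": result.sty,
    }


def report(result: CampaignResult, sink) -> dict[str, Path]:
    """Write the campaign artifacts to a directory.

    ``runs.csv`` (full run log incl. failures), ``results.csv`` (successful
    runs with derived metrics), ``summary.json`` (bests, counts, abort
    reason) and ``iteration_summary.csv`` — per-iteration best yield [%],
    STY [g/(L*h)] and residence time [s], the shape of the published
    campaign summary tables.
    """
    out = Path(sink)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "runs": out / "runs.csv",
        "results": out / "results.csv",
        "summary": out / "summary.json",
        "iterations": out / "iteration_summary.csv",
    }
    pd.DataFrame(result.log).to_csv(paths["runs"], index=False)
    write_results_table(result.results, paths["results"])

    rows = []
    for iteration in (1, 2):
        sub = result.iteration_results(iteration)
        if not sub:
            continue
        best = doe.select_best(sub)
        rows.append(
            {
                "iteration": iteration,
                "yield_percent": 100.0 * best.yield_frac,
                "sty_g_L_h": best.sty,
                "residence_time_s": best.residence_time_s,
            }
        )
    pd.DataFrame(
        rows, columns=["iteration", "yield_percent", "sty_g_L_h", "residence_time_s"]
    ).to_csv(paths["iterations"], index=False)

    summary = {
        "aborted": result.aborted,
        "abort_reason": result.abort_reason,
        "n_planned": len(result.plan.points),
        "n_successful": len(result.results),
        "n_failed": len(result.failures),
        "best_iteration1": _best_summary(result.best_iteration1),
        "best_final": _best_summary(result.best_final),
    }
    paths["summary"].write_text(json.dumps(summary, indent=2))
    return paths
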
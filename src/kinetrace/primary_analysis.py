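"""Per-ROI (primary) analysis: descriptive statistics and linear regression.

The respirometry specialization is the linear module: an ordinary
least-squares fit of the O2 trace inside a ROI whose slope, negated and
converted from per-second to per-minute, is the respiration rate in
nmol O2 ml^-1 min^-1 (chamber O2 is in uM, i.e. nmol/ml, and time in
seconds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, RegistryError
from .io_import import SECONDS_PER_MINUTE
from .roi_engine import ROI
from .store import Store
from .trace_model import Data, TraceSegment

__all__ = [
    "PrimaryResult",
    "roi_stats",
    "roi_linear",
    "analyze_primary",
    "PRIMARY_MODULES",
]


@dataclass(frozen=True)
class PrimaryResult:
    """Named scalar results of one ROI; keys absent when undefined."""

    analysis_id: str
    stats: dict[str, float]
    units: dict[str, str] = field(default_factory=dict)
    roi_id: int | None = None
    status: str = "ok"


def roi_stats(segment: TraceSegment) -> PrimaryResult:
    """Mean, median and sample (n-1) standard deviation of the segment values.

    sd is omitted for a single sample rather than reported as 0.
    """
    values = np.asarray(segment.values, dtype=float)
    if values.size == 0:
        raise InsufficientDataError("empty segment: no samples to summarize")
    out = {"mean": float(np.mean(values)), "median": float(np.median(values))}
    if values.size >= 2:
        out["sd"] = float(np.std(values, ddof=1))
    unit = segment.unit
    return PrimaryResult(
        "roi_stats", out, units={k: unit for k in out}
    )


def roi_linear(segment: TraceSegment) -> PrimaryResult:
    """OLS fit of values vs argument: slope, intercept, r^2 and, for
    time-argument segments, the respiration rate = -slope * 60.

    r^2 is omitted (not forced to 0 or 1) when the values have zero variance,
    where the coefficient of determination is meaningless.
    """
    x = np.asarray(segment.argument, dtype=float)
    y = np.asarray(segment.values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("linear fit needs at least 2 samples")
    if np.ptp(x) == 0:
        raise InsufficientDataError(
            "degenerate design: all argument values are equal"
        )
    if np.ptp(y) == 0:
        slope, intercept = 0.0, float(y[0])
        out = {"slope": slope, "intercept": intercept}
    else:
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
        out = {"slope": slope, "intercept": intercept, "r2": float(fit.rvalue**2)}

    units = {"slope": f"{segment.unit}/s", "intercept": segment.unit, "r2": ""}
    if segment.argument_kind == "time":
        out["rate"] = -slope * SECONDS_PER_MINUTE
        units["rate"] = "nmol/ml/min" if segment.unit == "uM" else f"{segment.unit}/min"
    return PrimaryResult("roi_linear", out, units={k: units.get(k, "") for k in out})


#: registered primary analyzers, dispatched by ROI.analysis_id
PRIMARY_MODULES = {"roi_stats": roi_stats, "roi_linear": roi_linear}

_RESULT_COLUMNS = {
    "roi_stats": ("mean", "median", "sd"),
    "roi_linear": ("slope", "intercept", "r2", "rate"),
}


def analyze_primary(
    data: Data, rois: list[ROI], store: Store | None = None, modules=None
) -> list[PrimaryResult]:
    """Run each ROI's bound analyzer on its trace segment.

    Results are written to the analyzer's own table keyed by roi_id
    (replace-on-rerun). A ROI whose fit fails is recorded with a failed
    status; the remaining ROIs are still analyzed. ``modules`` overrides the
    default analyzer dispatch table (used by the plugin registry).
    """
    modules = PRIMARY_MODULES if modules is None else modules
    results: list[PrimaryResult] = []
    for roi in rois:
        if roi.analysis_id not in modules:
            raise RegistryError(
                f"no primary analysis module named {roi.analysis_id!r}; "
                f"registered: {sorted(modules)}"
            )
        module = modules[roi.analysis_id]
        trace_names = (
            list(data.traces) if roi.trace_name == "all" else [roi.trace_name]
        )
        # the shipped analyzers are single-channel; "all" means every trace,
        # and respirometry experiments carry exactly one (O2)
        for tname in trace_names:
            segment = data.slice(roi.lo, roi.hi, tname)
            try:
                result = module(segment)
                result = PrimaryResult(
                    result.analysis_id, result.stats, result.units, roi_id=roi.roi_id
                )
            except InsufficientDataError as exc:
                result = PrimaryResult(
                    roi.analysis_id, {}, roi_id=roi.roi_id, status=f"failed: {exc}"
                )
            results.append(result)
            table_cols = _RESULT_COLUMNS.get(roi.analysis_id)
            if store is not None and roi.roi_id is not None and table_cols:
                columns = {c: result.stats.get(c) for c in table_cols}
                columns["status"] = result.status
                store.write_result(roi.analysis_id, "roi_id", roi.roi_id, columns)
    return results
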
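"""Region-of-interest creation, editing and protocol-driven splitting.

A ROI is a half-open slice ``[lo, hi)`` of an experiment's argument axis —
half-open so that adjacent regions never share a sample. Manual ROIs are
unconstrained (overlaps allowed); the automatic splitter derives disjoint
regions from the experiment's protocol events, one per titration step,
optionally skipping a settling window after each addition while the chamber
mixes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .errors import TraceLookupError, ValidationError
from .store import Store
from .trace_model import Data

log = logging.getLogger(__name__)

__all__ = ["ROI", "create_roi", "update_roi", "auto_split", "save_rois"]

#: default settling delay after a titration event before the slope is steady
DEFAULT_SETTLE = 30.0
#: default minimum usable window width
DEFAULT_MIN_WIDTH = 60.0


@dataclass(frozen=True)
class ROI:
    roi_id: int | None
    experiment_id: str
    lo: float
    hi: float
    trace_name: str = "all"
    event_name: str | None = None
    event_value: float | None = None
    analysis_id: str = "roi_linear"

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValidationError(f"degenerate ROI range [{self.lo}, {self.hi})")


def _check_range(data: Data, lo: float, hi: float, trace_name: str) -> None:
    if trace_name != "all" and trace_name not in data.traces:
        raise TraceLookupError(
            f"unknown trace {trace_name!r}; available: {sorted(data.traces)}"
        )
    dlo, dhi = data.argument_range
    if hi <= dlo or lo > dhi:
        raise ValidationError(
            f"ROI [{lo}, {hi}) does not intersect the experiment range [{dlo}, {dhi}]"
        )


def create_roi(
    data: Data,
    lo: float,
    hi: float,
    trace_name: str = "all",
    analysis_id: str = "roi_linear",
    store: Store | None = None,
) -> ROI:
    """Create a manual ROI (overlap with existing ROIs is permitted).

    When a store is given the ROI is persisted and carries its roi_id.
    """
    if not lo < hi:
        raise ValidationError(f"degenerate ROI range [{lo}, {hi})")
    _check_range(data, lo, hi, trace_name)
    roi = ROI(
        roi_id=None,
        experiment_id=data.experiment_id,
        lo=float(lo),
        hi=float(hi),
        trace_name=trace_name,
        analysis_id=analysis_id,
    )
    if store is not None:
        roi = replace(roi, roi_id=_persist(store, roi))
    return roi


def update_roi(store: Store, roi_id: int, lo: float, hi: float) -> None:
    """Move/resize a persisted ROI; stale downstream results are deleted and
    recomputed on the next analysis run."""
    store.update_roi_bounds(roi_id, float(lo), float(hi))


def auto_split(
    data: Data,
    settle: float = DEFAULT_SETTLE,
    min_width: float = DEFAULT_MIN_WIDTH,
    trace_name: str = "all",
    analysis_id: str = "roi_linear",
) -> list[ROI]:
    """Split a trace into one ROI per protocol event.

    Event i at t_i yields ROI ``[t_i + settle, t_{i+1})`` (trace end for the
    last event), labeled with the event's parsed agent name and concentration.
    Windows narrower than ``min_width`` are skipped with a warning. Without
    events the whole trace becomes a single unlabeled ROI.
    """
    if settle < 0:
        raise ValidationError("settle must be >= 0")
    if min_width <= 0:
        raise ValidationError("min_width must be > 0")
    dlo, dhi = data.argument_range
    if not data.events:
        return [
            ROI(None, data.experiment_id, dlo, dhi, trace_name, analysis_id=analysis_id)
        ]

    rois: list[ROI] = []
    events = list(data.events)
    for ev, nxt in zip(events, events[1:] + [None]):
        lo = ev.at + settle
        hi = nxt.at if nxt is not None else dhi
        if hi - lo < min_width:
            log.warning(
                "skipping window [%g, %g) after event %r: narrower than %g s",
                lo, hi, ev.text, min_width,
            )
            continue
        rois.append(
            ROI(
                roi_id=None,
                experiment_id=data.experiment_id,
                lo=float(lo),
                hi=float(hi),
                trace_name=trace_name,
                event_name=ev.name,
                event_value=ev.concentration,
                analysis_id=analysis_id,
            )
        )
    return rois


def save_rois(store: Store, rois: list[ROI]) -> list[ROI]:
    """Persist ROIs; idempotent (keyed by experiment, bounds and trace)."""
    return [replace(r, roi_id=_persist(store, r)) for r in rois]


def _persist(store: Store, roi: ROI) -> int:
    return store.insert_roi(
        roi.experiment_id,
        roi.lo,
        roi.hi,
        trace_name=roi.trace_name,
        event_name=roi.event_name,
        event_value=roi.event_value,
        analysis_id=roi.analysis_id,
    )
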
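"""In-memory experiment representation.

An experiment is a :class:`Data` object: a deterministic content-hash
experiment ID, one or more named :class:`Trace` channels sharing the same
argument type (time, in seconds, for every analysis shipped here), an ordered
list of protocol :class:`Event` annotations, and free-form config metadata.
This object is what import readers produce and what every analysis stage
consumes.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import TraceLookupError, ValidationError

__all__ = [
    "Trace",
    "Event",
    "Data",
    "generate_experiment_id",
    "build_data",
    "parse_event_text",
]

#: annotation grammar: "<agent name> <number> [unit]", unit defaults to mM
_EVENT_RE = re.compile(
    r"^\s*(?P<name>.*?)\s+(?P<num>[+-]?\d+(?:\.\d*)?(?:[eE][+-]?\d+)?)"
    r"\s*(?P<unit>uM|mM)?\s*$"
)


@dataclass(frozen=True)
class Trace:
    """One measured channel: paired argument/value arrays with a unit.

    Arguments are monotone non-decreasing (time in seconds for all shipped
    analyses); values are the measurement (e.g. chamber O2 in uM).
    """

    name: str
    argument: np.ndarray
    values: np.ndarray
    unit: str = ""
    argument_kind: str = "time"  # "time" or "space"

    def __post_init__(self):
        arg = np.asarray(self.argument, dtype=float)
        val = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "argument", arg)
        object.__setattr__(self, "values", val)
        if arg.ndim != 1 or val.ndim != 1:
            raise ValidationError(f"trace {self.name!r}: arrays must be 1-D")
        if arg.size != val.size:
            raise ValidationError(
                f"trace {self.name!r}: argument and values differ in length "
                f"({arg.size} vs {val.size})"
            )
        if arg.size < 2:
            raise ValidationError(f"trace {self.name!r}: needs at least 2 samples")
        if np.any(np.diff(arg) < 0):
            raise ValidationError(f"trace {self.name!r}: argument must be sorted")
        if self.argument_kind not in ("time", "space"):
            raise ValidationError(
                f"trace {self.name!r}: unknown argument kind {self.argument_kind!r}"
            )

    def __len__(self) -> int:
        return int(self.argument.size)

    def slice(self, lo: float, hi: float) -> "Trace | TraceSegment":
        """Sub-trace with argument in the half-open interval [lo, hi)."""
        if not lo < hi:
            raise ValidationError(f"degenerate slice range [{lo}, {hi})")
        mask = (self.argument >= lo) & (self.argument < hi)
        return TraceSegment(
            name=self.name,
            argument=self.argument[mask],
            values=self.values[mask],
            unit=self.unit,
            argument_kind=self.argument_kind,
        )


@dataclass(frozen=True)
class TraceSegment:
    """A (possibly empty) slice of a trace; same fields, no length invariant."""

    name: str
    argument: np.ndarray
    values: np.ndarray
    unit: str = ""
    argument_kind: str = "time"

    def __len__(self) -> int:
        return int(np.asarray(self.argument).size)


@dataclass(frozen=True, order=True)
class Event:
    """Timestamped protocol annotation, e.g. a titration step.

    ``name``/``concentration`` are parsed from the free-text annotation;
    concentration is stored in mM when present.
    """

    at: float
    text: str = field(compare=False)
    name: str = field(compare=False)
    concentration: float | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.concentration is not None and self.concentration < 0:
            raise ValidationError(
                f"event {self.text!r}: negative concentration {self.concentration}"
            )


def parse_event_text(at: float, text: str) -> Event:
    """Parse a raw annotation into an Event.

    Recognized form: ``"<name> <number> [uM|mM]"`` (unit defaults to mM, uM is
    converted to mM). Anything else keeps the full text as the name with no
    concentration, so unconventional comments are never lost.
    """
    m = _EVENT_RE.match(text)
    if m and m.group("name"):
        conc = float(m.group("num"))
        if m.group("unit") == "uM":
            conc /= 1000.0
        if conc >= 0:
            return Event(at=at, text=text, name=m.group("name").strip(), concentration=conc)
    return Event(at=at, text=text, name=text.strip(), concentration=None)


@dataclass(frozen=True)
class Data:
    """One experiment: ID, traces, ordered events, import metadata."""

    experiment_id: str
    kind: str
    traces: dict[str, Trace]
    events: tuple[Event, ...] = ()
    config: dict[str, object] = field(default_factory=dict)

    @property
    def argument_range(self) -> tuple[float, float]:
        lo = min(float(t.argument[0]) for t in self.traces.values())
        hi = max(float(t.argument[-1]) for t in self.traces.values())
        return lo, hi

    def trace(self, name: str) -> Trace:
        try:
            return self.traces[name]
        except KeyError:
            raise TraceLookupError(
                f"unknown trace {name!r}; available: {sorted(self.traces)}"
            ) from None

    def slice(self, lo: float, hi: float, trace_name: str) -> TraceSegment:
        """Half-open [lo, hi) segment of the named trace."""
        return self.trace(trace_name).slice(lo, hi)

    def with_experiment_id(self, experiment_id: str) -> "Data":
        return replace(self, experiment_id=experiment_id)


def generate_experiment_id(raw_bytes: bytes) -> str:
    """Deterministic experiment ID: SHA-256 hex digest of the raw file bytes.

    Identical raw files always map to the same ID, which is what makes import
    deduplication work; any byte difference yields a different ID.
    """
    return hashlib.sha256(raw_bytes).hexdigest()


def build_data(
    traces,
    events=(),
    config=None,
    *,
    kind: str = "respirometry",
    experiment_id: str = "",
) -> Data:
    """Validate and assemble a Data object.

    Traces may be a dict or an iterable of Trace; events may be Event objects
    or ``(at, text)`` pairs (parsed here). Events are sorted by time and must
    lie within the experiment's argument range.
    """
    if not isinstance(traces, dict):
        traces = {t.name: t for t in traces}
    if not traces:
        raise ValidationError("an experiment needs at least one trace")
    kinds = {t.argument_kind for t in traces.values()}
    if len(kinds) > 1:
        raise ValidationError(f"mixed argument types in one experiment: {sorted(kinds)}")

    parsed: list[Event] = []
    for ev in events:
        if not isinstance(ev, Event):
            at, text = ev
            ev = parse_event_text(float(at), str(text))
        parsed.append(ev)
    parsed.sort(key=lambda e: e.at)

    lo = min(float(t.argument[0]) for t in traces.values())
    hi = max(float(t.argument[-1]) for t in traces.values())
    for ev in parsed:
        if not (lo <= ev.at <= hi):
            raise ValidationError(
                f"event {ev.text!r} at {ev.at} s outside argument range [{lo}, {hi}] s"
            )

    return Data(
        experiment_id=experiment_id,
        kind=kind,
        traces=dict(traces),
        events=tuple(parsed),
        config=dict(config or {}),
    )
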
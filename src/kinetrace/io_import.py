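"""Raw-trace text I/O and the synthetic respirometry generator.

The on-disk dialect is a hardware-agnostic UTF-8 text format:

* header lines ``key: value`` (``unit:<trace>`` and ``argkind:<trace>`` carry
  per-channel metadata);
* a ``# events`` section of ``time_s<TAB>text`` lines;
* a ``# data`` section whose header row names columns ``<trace>:arg`` /
  ``<trace>:value``; traces recorded on different sample grids occupy separate
  column pairs, with missing cells left empty.

Floats are written with ``repr`` so a write/read round trip is bit exact.

The synthetic generator emulates an oxygraph titration experiment: chamber O2
declines piecewise linearly, the slope of each step following a
Michaelis-Menten response v(c) = v0 + vmax*c/(km + c) to the titrant
concentration, with optional Gaussian measurement noise on the O2 readings.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import ParseError, ValidationError
from .trace_model import Data, Event, Trace, build_data, generate_experiment_id

__all__ = [
    "SyntheticProtocol",
    "read_raw",
    "write_raw",
    "serialize_raw",
    "simulate_respirometry",
]

_MAGIC = "# kinetrace raw v1"

#: conversion between an O2 slope in uM/s and a respiration rate in
#: nmol O2 * ml^-1 * min^-1 (1 uM == 1 nmol/ml)
SECONDS_PER_MINUTE = 60.0


@dataclass(frozen=True)
class SyntheticProtocol:
    """Ground-truth description of a simulated titration experiment.

    Rates are in nmol O2*ml^-1*min^-1, concentrations in mM, times in
    seconds, O2 in uM. ``concentrations`` must be strictly increasing with the
    first entry 0 (the baseline step before any titrant is added).
    """

    v0: float = 10.0
    vmax: float = 90.0
    km: float = 0.3
    concentrations: tuple[float, ...] = (0.0, 0.05, 0.1, 0.3, 1.0, 2.0)
    step_duration: float = 300.0
    o2_start: float = 1800.0
    noise_sd: float = 0.0
    sample_interval: float = 1.0
    seed: int = 0
    agent: str = "ADP"
    chamber_volume_ml: float = 2.0

    def __post_init__(self):
        if self.km <= 0:
            raise ValidationError("km must be > 0")
        if self.vmax < 0 or self.v0 < 0:
            raise ValidationError("rates must be >= 0")
        if self.step_duration <= 0 or self.sample_interval <= 0:
            raise ValidationError("durations must be > 0")
        c = np.asarray(self.concentrations, dtype=float)
        if c.size == 0 or np.any(np.diff(c) <= 0):
            raise ValidationError("concentrations must be strictly increasing")

    def rate(self, c: float) -> float:
        """True rate at titrant concentration c (Michaelis-Menten)."""
        return self.v0 + self.vmax * c / (self.km + c)


def _fmt(x: float) -> str:
    return repr(float(x))


def serialize_raw(data: Data) -> str:
    """Render a Data object in the raw-trace dialect (the exact file content)."""
    lines = [_MAGIC, f"kind: {data.kind}"]
    for key, value in sorted(data.config.items()):
        if key == "filename":  # local path, not part of the dataset identity
            continue
        lines.append(f"{key}: {value}")
    for name in sorted(data.traces):
        tr = data.traces[name]
        lines.append(f"unit:{name}: {tr.unit}")
        lines.append(f"argkind:{name}: {tr.argument_kind}")
    lines.append("# events")
    for ev in data.events:
        lines.append(f"{_fmt(ev.at)}\t{ev.text}")
    lines.append("# data")
    names = sorted(data.traces)
    header = []
    for name in names:
        header += [f"{name}:arg", f"{name}:value"]
    lines.append("\t".join(header))
    nrows = max(len(data.traces[n]) for n in names)
    for i in range(nrows):
        cells = []
        for name in names:
            tr = data.traces[name]
            if i < len(tr):
                cells += [_fmt(tr.argument[i]), _fmt(tr.values[i])]
            else:
                cells += ["", ""]
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def write_raw(data: Data, path) -> Path:
    """Write the raw-trace file; ``read_raw`` of the result reproduces the
    arrays bit exactly and, for generator output, the experiment ID."""
    path = Path(path)
    path.write_text(serialize_raw(data), encoding="utf-8")
    return path


def _parse_scalar(text: str):
    try:
        return float(text)
    except ValueError:
        return text


def read_raw(path) -> Data:
    """Parse a raw-trace file into a validated Data object.

    The experiment ID is the SHA-256 digest of the file bytes, so re-reading
    the same file always yields the same ID (import deduplication).
    """
    path = Path(path)
    raw = path.read_bytes()
    lines = raw.decode("utf-8").splitlines()
    if not lines or lines[0].strip() != _MAGIC:
        raise ParseError(f"not a kinetrace raw file (missing {_MAGIC!r} header)", line=1)

    config: dict[str, object] = {}
    units: dict[str, str] = {}
    argkinds: dict[str, str] = {}
    kind = "respirometry"
    events: list[tuple[float, str]] = []
    section = "header"
    header_cols: list[str] | None = None
    columns: list[list[float]] = []

    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        if line.strip() == "# events":
            section = "events"
            continue
        if line.strip() == "# data":
            section = "data"
            continue
        if section == "header":
            if ":" not in line:
                raise ParseError(f"malformed header line {line!r}", line=lineno)
            key, _, value = line.partition(":")
            key, value = key.strip(), value.strip()
            if key == "kind":
                kind = value
            elif key == "unit":
                name, _, unit = value.partition(":")
                units[name.strip()] = unit.strip()
            elif key == "argkind":
                name, _, ak = value.partition(":")
                argkinds[name.strip()] = ak.strip()
            else:
                config[key] = _parse_scalar(value)
        elif section == "events":
            at_text, _, text = line.partition("\t")
            try:
                at = float(at_text)
            except ValueError:
                raise ParseError(f"non-numeric event time {at_text!r}", line=lineno)
            events.append((at, text))
        else:  # data
            if header_cols is None:
                header_cols = line.split("\t")
                columns = [[] for _ in header_cols]
                continue
            cells = line.split("\t")
            if len(cells) != len(header_cols):
                raise ParseError(
                    f"expected {len(header_cols)} columns, got {len(cells)}", line=lineno
                )
            for col, cell in zip(columns, cells):
                if cell != "":
                    try:
                        col.append(float(cell))
                    except ValueError:
                        raise ParseError(f"non-numeric sample {cell!r}", line=lineno)

    if header_cols is None or not columns or not columns[0]:
        raise ParseError("no data rows found")

    # reassemble (arg, value) column pairs into traces
    by_trace: dict[str, dict[str, list[float]]] = {}
    for colname, col in zip(header_cols, columns):
        tname, _, role = colname.rpartition(":")
        if role not in ("arg", "value") or not tname:
            raise ParseError(f"bad data column name {colname!r}")
        by_trace.setdefault(tname, {})[role] = col
    traces = {}
    for tname, cols in by_trace.items():
        if "arg" not in cols or "value" not in cols:
            raise ParseError(f"trace {tname!r} missing arg or value column")
        traces[tname] = Trace(
            name=tname,
            argument=np.array(cols["arg"], dtype=float),
            values=np.array(cols["value"], dtype=float),
            unit=units.get(tname, ""),
            argument_kind=argkinds.get(tname, "time"),
        )

    config["filename"] = path.name
    return build_data(
        traces,
        events=events,
        config=config,
        kind=kind,
        experiment_id=generate_experiment_id(raw),
    )


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually put into a synthetic experiment."""

    v0: float
    vmax: float
    km: float
    concentrations: tuple[float, ...]
    rates: tuple[float, ...]
    step_starts: tuple[float, ...]
    noise_sd: float
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def simulate_respirometry(protocol: SyntheticProtocol) -> tuple[Data, GroundTruth]:
    """Generate a synthetic titration experiment with known kinetics.

    For each concentration step the O2 trace declines linearly with slope
    -v(c)/60 uM/s (rates are per minute, time in seconds), continuous across
    step boundaries, with i.i.d. Gaussian noise of sd ``noise_sd`` added to
    the O2 samples. One event marks each step start ("baseline" for c=0,
    otherwise "<agent> <c>"). Deterministic for a given seed.
    """
    p = protocol
    conc = np.asarray(p.concentrations, dtype=float)
    rates = np.array([p.rate(c) for c in conc])
    nsteps = conc.size
    step_starts = np.arange(nsteps) * p.step_duration
    total = nsteps * p.step_duration

    # O2 at the step breakpoints (cumulative linear consumption)
    o2_break = p.o2_start - np.concatenate(
        ([0.0], np.cumsum(rates * p.step_duration / SECONDS_PER_MINUTE))
    )
    if o2_break[-1] < 0:
        raise ValidationError(
            "O2 would drop below zero before the protocol ends; use shorter "
            "steps, fewer concentrations, or a higher o2_start"
        )

    t = np.arange(0.0, total + p.sample_interval / 2, p.sample_interval)
    idx = np.minimum((t // p.step_duration).astype(int), nsteps - 1)
    o2 = o2_break[idx] - rates[idx] / SECONDS_PER_MINUTE * (t - step_starts[idx])
    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        o2 = o2 + rng.normal(0.0, p.noise_sd, size=o2.shape)

    events = []
    for c, t0 in zip(conc, step_starts):
        text = "baseline" if c == 0 else f"{p.agent} {c:g}"
        events.append((float(t0), text))

    data = build_data(
        {"O2": Trace(name="O2", argument=t, values=o2, unit="uM")},
        events=events,
        config={"chamber_volume_ml": p.chamber_volume_ml, "hardware": "synthetic"},
        kind="respirometry",
    )
    # the content hash of the serialized file *is* the experiment identity,
    # so writing this Data out and re-importing it deduplicates correctly
    data = data.with_experiment_id(
        generate_experiment_id(serialize_raw(data).encode("utf-8"))
    )
    truth = GroundTruth(
        v0=p.v0,
        vmax=p.vmax,
        km=p.km,
        concentrations=tuple(float(c) for c in conc),
        rates=tuple(float(r) for r in rates),
        step_starts=tuple(float(s) for s in step_starts),
        noise_sd=p.noise_sd,
        seed=p.seed,
    )
    return data, truth
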
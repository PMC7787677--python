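"""Plugin discovery and the analysis pipeline.

Modules come in four types, dispatched by the application according to their
task: ``args`` (extra CLI options), ``database`` (schema setup), ``reader``
(data import) and ``analyzer`` (primary, per ROI, or secondary, per
experiment). Built-in modules ship in :mod:`kinetrace.modules`; users can
point ``--module-dir`` at folders of additional Python files, each exposing a
``SPECS`` list. A user module with the same name as a built-in overrides it;
a module that fails to load is skipped with a diagnostic, never fatally.

The pipeline runs database -> reader -> split -> primary -> secondary, and
every stage reads its inputs from the store (the only shared state beyond
the in-memory Data object), which is what makes re-running any stage in a
separate process equivalent to a single run.
"""

from __future__ import annotations

import importlib
import importlib.util
import logging
import pkgutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

from . import modules as _builtin_pkg
from .errors import KinetraceError, RegistryError
from .io_import import read_raw
from .primary_analysis import analyze_primary
from .roi_engine import ROI, auto_split, save_rois
from .store import Store

log = logging.getLogger(__name__)

__all__ = ["ModuleSpec", "Registry", "discover", "run_pipeline", "PipelineReport"]

MODULE_TYPES = ("args", "database", "reader", "analyzer")


@dataclass(frozen=True)
class ModuleSpec:
    """Declaration record a plugin module exposes in its ``SPECS`` list."""

    name: str
    mtype: str
    entry: Callable
    stage: str | None = None  # analyzers: "primary" | "secondary"
    kinds: tuple[str, ...] = ()

    def __post_init__(self):
        if self.mtype not in MODULE_TYPES:
            raise RegistryError(
                f"module {self.name!r}: unknown type {self.mtype!r} "
                f"(must be one of {MODULE_TYPES})"
            )
        if self.mtype == "analyzer" and self.stage not in ("primary", "secondary"):
            raise RegistryError(
                f"analyzer module {self.name!r} must declare stage primary|secondary"
            )


@dataclass
class Registry:
    specs: dict[str, ModuleSpec] = field(default_factory=dict)

    def add(self, spec: ModuleSpec, override: bool = False) -> None:
        if spec.name in self.specs and not override:
            raise RegistryError(f"duplicate module name {spec.name!r}")
        self.specs[spec.name] = spec

    def by_type(self, mtype: str, stage: str | None = None) -> list[ModuleSpec]:
        out = [s for s in self.specs.values() if s.mtype == mtype]
        if stage is not None:
            out = [s for s in out if s.stage == stage]
        return sorted(out, key=lambda s: s.name)

    def reader_for(self, kind: str) -> ModuleSpec:
        readers = self.by_type("reader")
        for spec in readers:
            if kind in spec.kinds:
                return spec
        available = sorted({k for s in readers for k in s.kinds})
        raise RegistryError(
            f"no reader module claims experiment kind {kind!r}; "
            f"available kinds: {available}"
        )

    def primary_dispatch(self) -> dict[str, Callable]:
        return {s.name: s.entry for s in self.by_type("analyzer", "primary")}


def _load_specs(module, registry: Registry, override: bool, origin: str) -> None:
    specs = getattr(module, "SPECS", None)
    if not specs:
        log.warning("module %s defines no SPECS list; skipped", origin)
        return
    for spec in specs:
        if not isinstance(spec, ModuleSpec):
            log.warning("module %s: SPECS entry %r is not a ModuleSpec; skipped",
                        origin, spec)
            continue
        registry.add(spec, override=override)


def discover(paths: tuple[str | Path, ...] = ()) -> Registry:
    """Build the module registry: built-ins plus user-provided folders.

    Deterministic for the same filesystem contents (files loaded in sorted
    order). Invalid user modules are skipped with a logged diagnostic.
    """
    registry = Registry()
    for info in sorted(pkgutil.iter_modules(_builtin_pkg.__path__), key=lambda i: i.name):
        module = importlib.import_module(f"{_builtin_pkg.__name__}.{info.name}")
        _load_specs(module, registry, override=False, origin=info.name)

    for path in paths:
        for pyfile in sorted(Path(path).glob("*.py")):
            try:
                spec = importlib.util.spec_from_file_location(
                    f"kinetrace_user_{pyfile.stem}", pyfile
                )
                module = importlib.util.module_from_spec(spec)
                spec.loader.exec_module(module)
            except Exception as exc:  # user code: isolate failures
                log.warning("skipping user module %s: %s", pyfile, exc)
                continue
            _load_specs(module, registry, override=True, origin=str(pyfile))
    return registry


@dataclass
class PipelineReport:
    experiment_id: str | None = None
    stages: dict[str, dict] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return all(s.get("status") == "ok" for s in self.stages.values())

    def record(self, stage: str, status: str, **info) -> None:
        self.stages[stage] = {"status": status, **info}


def _rois_from_store(store: Store, experiment_id: str) -> list[ROI]:
    return [
        ROI(
            roi_id=row["roi_id"],
            experiment_id=row["experiment_id"],
            lo=row["lo"],
            hi=row["hi"],
            trace_name=row["trace_name"],
            event_name=row["event_name"],
            event_value=row["event_value"],
            analysis_id=row["analysis_id"],
        )
        for row in store.get_rois(experiment_id)
    ]


def run_pipeline(
    source: str | Path,
    store: Store,
    registry: Registry | None = None,
    *,
    no_split: bool = False,
    settle: float = 30.0,
    min_width: float = 60.0,
    basal: bool = True,
) -> PipelineReport:
    """Run the full analysis for one experiment.

    ``source`` is either a raw-trace file path (imported, deduplicated by
    content hash) or the experiment ID of an already-imported experiment
    (re-loaded from the store). Stages: database modules (schema), reader,
    event-based split (skipped when ROIs already exist or ``no_split``),
    primary analyzers, secondary analyzers. Per-stage failures are recorded
    in the report; later stages that depend on a failed one are not run.
    """
    registry = registry if registry is not None else discover()
    report = PipelineReport()

    try:
        for spec in registry.by_type("database"):
            spec.entry(store)
        report.record("database", "ok", modules=len(registry.by_type("database")))
    except KinetraceError as exc:
        report.record("database", f"failed: {exc}")
        return report

    try:
        path = Path(source)
        if path.exists():
            data = read_raw(path)  # generic dialect; kind from the header
            reader = registry.reader_for(data.kind)
            data, record = reader.entry(path, store)
            report.record(
                "import", "ok", experiment_id=data.experiment_id,
                duplicate=record.duplicate, count=1,
            )
        else:
            experiment_id = str(source)
            if not store.has_experiment(experiment_id):
                raise LookupError(
                    f"{source!r} is neither an existing file nor a known experiment ID"
                )
            data = store.load_data(experiment_id)
            report.record("import", "ok", experiment_id=data.experiment_id,
                          duplicate=True, count=1)
    except (KinetraceError, LookupError, OSError) as exc:
        report.record("import", f"failed: {exc}")
        return report
    report.experiment_id = data.experiment_id

    try:
        rois = _rois_from_store(store, data.experiment_id)
        if not rois and not no_split:
            rois = save_rois(
                store, auto_split(data, settle=settle, min_width=min_width)
            )
        report.record("split", "ok", count=len(rois))
    except KinetraceError as exc:
        report.record("split", f"failed: {exc}")
        return report

    try:
        results = analyze_primary(
            data, rois, store=store, modules=registry.primary_dispatch() or None
        )
        failed = sum(1 for r in results if r.status != "ok")
        report.record("primary", "ok", count=len(results), failed=failed)
    except KinetraceError as exc:
        report.record("primary", f"failed: {exc}")
        return report

    try:
        count = 0
        for spec in registry.by_type("analyzer", "secondary"):
            if data.kind in spec.kinds or not spec.kinds:
                spec.entry(data.experiment_id, store, basal=basal)
                count += 1
        report.record("secondary", "ok", count=count)
    except KinetraceError as exc:
        report.record("secondary", f"failed: {exc}")
    return report
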
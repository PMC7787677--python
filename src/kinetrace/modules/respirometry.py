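"""Respirometry module set: reader, primary analyzers, kinetics analyzer.

The reader imports a raw oxygraph trace (generic text dialect) and stores it;
the primary analyzers compute per-ROI statistics and the O2-slope respiration
rate; the secondary analyzer fits rate vs titrant concentration with the
Michaelis-Menten relationship and derives the rate summary.
"""

from ..io_import import read_raw
from ..primary_analysis import roi_linear, roi_stats
from ..registry import ModuleSpec
from ..secondary_analysis import analyze_secondary


def import_raw(path, store):
    """Read a raw-trace file and persist it; returns (Data, ExperimentRecord)."""
    data = read_raw(path)
    record = store.import_experiment(data)
    return data, record


def cli_options():
    """Extra CLI option defaults contributed by this module (args type)."""
    return {"settle": 30.0, "min_width": 60.0, "basal": True}


SPECS = [
    ModuleSpec(
        name="respirometry_reader",
        mtype="reader",
        entry=import_raw,
        kinds=("respirometry",),
    ),
    ModuleSpec(
        name="roi_stats", mtype="analyzer", stage="primary", entry=roi_stats,
        kinds=("respirometry",),
    ),
    ModuleSpec(
        name="roi_linear", mtype="analyzer", stage="primary", entry=roi_linear,
        kinds=("respirometry",),
    ),
    ModuleSpec(
        name="mm_kinetics", mtype="analyzer", stage="secondary",
        entry=analyze_secondary, kinds=("respirometry",),
    ),
    ModuleSpec(name="respirometry_args", mtype="args", entry=cli_options),
]
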
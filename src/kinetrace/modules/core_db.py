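"""Database module: creates the core tables and views when missing."""

from ..registry import ModuleSpec


def setup(store):
    return store.init_schema()


SPECS = [ModuleSpec(name="core_schema", mtype="database", entry=setup)]
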
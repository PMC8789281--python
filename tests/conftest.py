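"""Shared fixtures: tiny synthetic panels generated at test time."""

from __future__ import annotations

import pytest

from stopgc import pipeline
from stopgc.synthetic import PanelSpec, generate_panel


@pytest.fixture(scope="session")
def small_panel_dir(tmp_path_factory):
    """A 12-species desk panel spanning GC 0.25-0.65, written to disk."""
    out = tmp_path_factory.mktemp("panel")
    spec = PanelSpec(
        n_species=12,
        genes_per_species=80,
        gc_grid=(0.25, 0.65),
        asc_rate=0.5,
        seed=11,
    )
    generate_panel(spec, out)
    return out


@pytest.fixture(scope="session")
def small_panel(small_panel_dir):
    """(metas, records_by_species) loaded from the small panel."""
    return pipeline.load_panel(small_panel_dir)
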
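"""Shared fixtures: the hand-checkable tiny study and the default simulation.

Both are generated programmatically; the default-fixture pipeline products
are computed once per session because the model stage (two cluster sweeps
plus the VAE architecture search) takes a few seconds.
"""

from __future__ import annotations

import numpy as np
import pytest

import prevcommon as pc


@pytest.fixture(scope="session")
def tiny_study(tmp_path_factory):
    """The 2-area, 1-species fixture with hand-computed feature values."""
    d = tmp_path_factory.mktemp("tiny")
    paths = pc.make_fixture("tiny", d)
    rs = pc.read_occurrences(paths["occurrences"])
    cfg = pc.load_config(paths["config"])
    cfg.datasets = pc.read_polygons(paths["areas"])
    return {"paths": paths, "records": rs, "config": cfg,
            "species": "Ardea tinyensis"}


@pytest.fixture(scope="session")
def default_sim():
    """Default simulation draw (150 species, 3 tiers, seed 42) + study config."""
    sim = pc.SimulationConfig(seed=42)
    rs, truth = pc.generate(sim)
    cfg = pc.study_config_for(sim)
    rs = pc.assign_context(pc.deduplicate(rs), cfg)
    return {"sim": sim, "records": rs, "truth": truth, "config": cfg}


@pytest.fixture(scope="session")
def default_table(default_sim):
    """Standardized species-data table of the default simulation."""
    return pc.build_species_table(default_sim["records"],
                                  list(default_sim["truth"]["species"]),
                                  default_sim["config"])


@pytest.fixture(scope="session")
def default_models(default_sim, default_table):
    """All model columns (clusterings, VAE, classes, ensemble) at seed 42."""
    cols = pc.model_columns(default_table, default_sim["config"])
    truth = default_sim["truth"].set_index("species")["tier"]
    ref = np.asarray([truth[s] for s in default_table.species], dtype=object)
    return {"cols": cols, "reference": ref}
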
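import datetime as dt

import numpy as np
import pandas as pd
import pytest

from catscape.pipeline import PipelineConfig, run_pipeline
from catscape.simulate import SimConfig, simulate_population
from catscape.tracks import Track

T0 = dt.datetime(2021, 5, 1, 8, 0, 0)


def make_track(
    offsets_s,
    xy=None,
    elevation=50.0,
    ehpe=3.0,
    cat_id="cat",
    start=T0,
    tz_offset_hours=0.0,
    **track_kwargs,
):
    """Build a Track from second offsets and optional per-fix columns."""
    offsets_s = list(offsets_s)
    n = len(offsets_s)
    if xy is None:
        xy = np.zeros((n, 2))
    xy = np.asarray(xy, dtype=float)
    elev = np.broadcast_to(np.asarray(elevation, dtype=float), n)
    ehp = np.broadcast_to(np.asarray(ehpe, dtype=float), n)
    fixes = pd.DataFrame(
        {
            "timestamp": [start + dt.timedelta(seconds=float(s)) for s in offsets_s],
            "x": xy[:, 0],
            "y": xy[:, 1],
            "elevation": elev,
            "ehpe": ehp,
        }
    )
    return Track(
        cat_id=cat_id, fixes=fixes, tz_offset_hours=tz_offset_hours, **track_kwargs
    )


@pytest.fixture(scope="session")
def sim_pop():
    """The default 12-cat synthetic population, seed 1."""
    return simulate_population(SimConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(sim_pop):
    """Full pipeline on the default synthetic population (default config)."""
    return run_pipeline(
        sim_pop.tracks,
        sim_pop.cats,
        landcover=sim_pop.landcover,
        config=PipelineConfig(),
    )
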
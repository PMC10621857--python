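import warnings

import numpy as np
import pandas as pd
import pytest

from terratactics import pipeline, simdata

warnings.filterwarnings("ignore", message=".*outside the UD lattice.*")


@pytest.fixture(scope="session")
def small_world():
    """A 16-day two-group simulation with landscape + events extracted once."""
    cfg = simdata.SimConfig(seed=11, days=16)
    bundle = simdata.gen_tracklogs(cfg)
    land = pipeline.extract_landscape(bundle.fixes)
    ev = pipeline.extract_events(bundle.fixes, bundle.party_obs,
                                 bundle.minutes, land)
    return {"cfg": cfg, "bundle": bundle, "land": land, "ev": ev}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def make_fixes(xs, ys, elevs, group="west", follow="f0",
               start="2014-01-06 07:00"):
    """Minimal fix table at 1-min cadence."""
    n = len(xs)
    return pd.DataFrame({
        "time": pd.date_range(start, periods=n, freq="min"),
        "x": np.asarray(xs, float), "y": np.asarray(ys, float),
        "elev": np.asarray(elevs, float),
        "group": group, "follow_id": follow,
    })
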
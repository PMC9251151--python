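import numpy as np
import pandas as pd
import pytest

from gp96tme.quantify import CoreCellTable


def make_core(core_id="C0", area_mm2=1.0, **marker_counts):
    """Build a core from phenotype counts, e.g. make_core(gp96=50, none=150).

    Each keyword is a '_'-joined list of positive markers ('none' for
    marker-negative cells); coordinates are placed deterministically on a
    grid so geometry-free operations see varied but fixed positions.
    """
    rows = []
    i = 0
    for key, n in marker_counts.items():
        positive = [] if key == "none" else key.split("_")
        for _ in range(n):
            rows.append({
                "x_um": float(17 * i % 500), "y_um": float(23 * i % 500),
                **{m: int(m in positive) for m in ("GFAP", "gp96", "CD4", "CD8", "PD1")},
            })
            i += 1
    return CoreCellTable(core_id=core_id, area_mm2=area_mm2,
                         cells=pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def null_survival(rng):
    """Survival sample independent of any marker (exponential, light censoring)."""
    n = 60
    t = rng.exponential(12.0, n)
    c = rng.uniform(0, 40, n)
    times = np.minimum(t, c)
    events = (t <= c).astype(int)
    marker = rng.normal(size=n)
    return marker, times, events
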
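import numpy as np
import pandas as pd
import pytest

from flowdisp.core import EventTable
from flowdisp.gating import run_gating
from flowdisp.simulate import SimCohortConfig, simulate_cohort


def make_table(
    n: int,
    rng: np.random.Generator,
    fl=None,
    fsc=None,
    ssc=None,
    fsc_w=None,
    dapi=None,
    **meta,
) -> EventTable:
    """Ad-hoc event table with plausible defaults for unspecified channels."""
    data = pd.DataFrame(
        {
            "FSC-A": fsc if fsc is not None else rng.lognormal(10.0, 0.2, n),
            "SSC-A": ssc if ssc is not None else rng.lognormal(9.0, 0.2, n),
            "FSC-W": fsc_w if fsc_w is not None else rng.normal(70.0, 3.0, n),
            "DAPI": dapi if dapi is not None else rng.normal(100.0, 5.0, n),
            "FL": fl if fl is not None else rng.normal(5.0, 0.5, n),
        }
    )
    meta.setdefault("sample_id", "s0")
    return EventTable(data, **meta)


@pytest.fixture(scope="session")
def cohort():
    """Small full-event cohort: 6 lines x 3 replicates x 10k events."""
    cfg = SimCohortConfig(
        n_lines=6, n_replicates=3, n_events=10000, n_null_snps=20, seed=11
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def gated_cohort(cohort):
    _, tables, _ = cohort
    return run_gating(tables)
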
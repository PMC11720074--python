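import numpy as np
import pytest

from cenoblock import io as cio
from cenoblock import ord_model
from cenoblock.cable import CableConfig, measure_cv, run_cable
from cenoblock.myocyte import prepaced_state


@pytest.fixture(scope="session")
def docking_df():
    return cio.load_docking_table()


@pytest.fixture(scope="session")
def mmpbsa_df():
    return cio.load_mmpbsa_table()


@pytest.fixture(scope="session")
def rest_state():
    """Briefly pre-paced single-cell state shared across simulation tests."""
    return prepaced_state(n_beats=5)


@pytest.fixture(scope="session")
def cable_cv(rest_state):
    """Memoized strand runs: (gj, b_eq) -> CvResult for beat 2.

    Uses equilibrium-mode block so the blocked fraction is an exact input,
    and a short pre-pace; each combination is simulated once per session.
    """
    cache: dict = {}

    def run(gj: float, b_eq: float = 0.0):
        key = (gj, b_eq)
        if key not in cache:
            drug = ord_model.pack_drug(mode=2, b_eq=b_eq) if b_eq > 0 else None
            trace = run_cable(
                CableConfig(gj_ps_per_pf=gj, prepace_beats=5),
                drug=drug, y0_cell=rest_state,
            )
            cache[key] = measure_cv(trace, beat_index=1)
        return cache[key]

    return run


@pytest.fixture(scope="session")
def study_matrix():
    """The full experiment matrix at the study conditions (17 µM, docking Kd,
    kinetic block, default pacing, 50-beat pre-pace)."""
    from cenoblock.pipeline import run_matrix

    return run_matrix(cio.RunConfig())
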
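import numpy as np
import pytest

from retmap.substrate import KnockinSpec, assign_gradients, place_cells
from retmap.tk import EnergyParams, run_tk2011


@pytest.fixture(scope="session")
def small_sheets():
    """A 400+400 cell pair with wild-type gradients."""
    ret = place_cells(400, "circle", seed=11)
    col = place_cells(400, "hemi-ellipse", seed=12)
    assign_gradients(ret, KnockinSpec(DR=0.0, seed=13))
    assign_gradients(col)
    return ret, col


@pytest.fixture(scope="session")
def wt_sim(small_sheets):
    """A converged small wild-type development run, shared across tests."""
    ret, col = small_sheets
    return run_tk2011(ret, col, EnergyParams(), iterations=3_000_000, seed=1)


@pytest.fixture(scope="session")
def synthetic_baseline():
    """WT fluctuation baseline for synthetic maps at the default noise level."""
    from retmap.filtering import filter_phase_map
    from retmap.synthetic import generate_phase_map

    pm, _ = generate_phase_map("single", noise_sd=2.0, seed=99)
    mask = filter_phase_map(pm, self_baseline=True)
    return float(mask.meta["wt_baseline_sd"])
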
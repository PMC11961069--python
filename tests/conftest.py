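"""Shared fixtures: scaled-down assay designs and a fitted calibration.

The reduced designs are 1/10 (and 1/100) linear scale-downs of the
reference geometry that preserve both the bead loading λ = n_beads/n_droplets
and the concentration→molecules-per-bead transfer (sample_volume/n_beads is
held fixed), so all closed-form expectations carry over unchanged.
"""

import pytest
from hypothesis import settings

import ddelisa as dd
from ddelisa.pipeline import calibrate

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

DROPLET_VOL_50UM = 65.44984694978736  # sphere volume of a 50 um droplet, pl


@pytest.fixture(scope="session")
def opn():
    return dd.DEFAULT_PANEL["OPN"]


@pytest.fixture(scope="session")
def panel_targets():
    return {k: dd.DEFAULT_PANEL[k] for k in ("OPN", "IL-10", "IL-6")}


@pytest.fixture(scope="session")
def noise():
    return dd.NoiseModel()


@pytest.fixture(scope="session")
def small_design():
    """1/10-scale reference run: λ = 0.789, full transfer curve."""
    return dd.DropletDesign(50.0, DROPLET_VOL_50UM, 76_000, 60_000, 5.0, 0.422)


@pytest.fixture(scope="session")
def tiny_design():
    """1/100-scale run for cheap smoke tests."""
    return dd.DropletDesign(50.0, DROPLET_VOL_50UM, 7_600, 6_000, 0.5, 0.422)


@pytest.fixture(scope="session")
def small_calibration(small_design, opn, noise):
    """Standard curve fitted on the 1/10-scale ladder (3 reps + 3 blanks)."""
    ladder = [0.0] * 3 + [0.01, 0.1, 1.0, 10.0, 100.0, 1000.0]
    run = dd.simulate_calibration_run(small_design, opn, ladder, 3, noise, seed=7)
    return calibrate(run, {"OPN": opn}), run
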
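"""Shared hand-built fixtures used across test modules."""

import math

import numpy as np
import pandas as pd

import ddelisa as dd
from ddelisa.quantify import AEBValue

#: fixed thresholds matching the default noise model's populations
FIXED_THRESHOLDS = dd.Thresholds(
    bead_gate_cutoff=1000.0,
    positive_cutoff={"green": 130.0, "blue": 130.0, "red": 130.0},
    single_bead_mode=2000.0,
)


def silent_noise():
    """No background spread, no false positives: the silent-assay limit."""
    return dd.NoiseModel(
        bead_gate_cv=0.0,
        gate_background_sd=0.0,
        background_sd=0.0,
        signal_cv=0.0,
        false_positive_rate=0.0,
    )


def clean_noise():
    """Clean-calling regime: no false positives, near-noiseless background,
    so positive calling reflects encapsulation statistics alone."""
    return dd.NoiseModel(false_positive_rate=0.0, background_sd=2.0)


def manual_table(gate, green, well_id="fixture"):
    """Hand-built droplet table for spreadsheet-style oracles."""
    n = len(gate)
    return dd.DropletTable(
        data=pd.DataFrame(
            {
                "droplet_id": np.arange(n),
                "well_id": well_id,
                "bead_gate": np.asarray(gate, dtype=float),
                "ch_green": np.asarray(green, dtype=float),
                "ch_blue": np.zeros(n),
                "ch_red": np.zeros(n),
            }
        ),
        well_id=well_id,
    )


def aeb_value(aeb, n_beads=1000, saturated=False):
    f_on = 1 - math.exp(-aeb)
    return AEBValue(
        aeb=aeb, mode="poisson_corrected", f_on=f_on, n_beads=n_beads,
        saturated=saturated,
    )
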
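"""High-level orchestration: simulate → gate → call → AEB → calibrate →
quantify → panel.

These helpers tie the stage modules together with one shared convention
(thresholds fitted on the run's blanks, Poisson-corrected AEB with saturation
flooring so the standard curve can see and exclude saturated ladder tops)
and are what the CLI, the examples, and the acceptance checks drive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .assay_model import DropletDesign, MolecularTarget
from .quantify import (
    AEBValue,
    CalibrationCurve,
    compute_aeb,
    concentration_from_aeb,
    convert_units,
    fit_calibration,
)
from .readout import DigitalCounts, Thresholds, call_positives, estimate_thresholds, gate_beads
from .synthetic import DropletTable, NoiseModel, simulate_calibration_run

logger = logging.getLogger("ddelisa")

__all__ = ["calibrate", "quantify_sample", "CalibrationResult"]


@dataclass
class CalibrationResult:
    thresholds: Thresholds
    curves: dict[str, CalibrationCurve]  # analyte name → curve


def table_aeb(
    table: DropletTable,
    thresholds: Thresholds,
    channel: str,
    mode: str = "poisson_corrected",
    on_saturation: str = "floor",
) -> AEBValue:
    """Gate, call and reduce one table to its AEB on one channel."""
    counts = call_positives(gate_beads(table, thresholds), thresholds)
    return compute_aeb(counts, channel, mode=mode, on_saturation=on_saturation)


def calibrate(
    run: list[tuple[float, DropletTable]],
    targets: dict[str, MolecularTarget],
    k_sd: float = 3.0,
    mode: str = "poisson_corrected",
) -> CalibrationResult:
    """Fit thresholds and per-analyte standard curves from a calibration run.

    ``run`` pairs each table with its ladder concentration; entries at
    0 pg/mL are the blanks, used both for threshold estimation and for the
    blank-AEB statistics of the LOD rule.
    """
    blanks = [t for c, t in run if c == 0]
    if len(blanks) == 0:
        raise ValueError("calibration run contains no blank (0 pg/mL) wells")
    thresholds = estimate_thresholds(blanks, k_sd=k_sd)
    curves = {}
    for name, target in targets.items():
        ch = target.channel
        points = [
            (c, table_aeb(t, thresholds, ch, mode=mode)) for c, t in run if c > 0
        ]
        blank_aebs = [table_aeb(t, thresholds, ch, mode=mode) for t in blanks]
        curve = fit_calibration(points, blank_aebs, k_sd=k_sd)
        logger.info(
            "calibrated %s: slope=%.3f r2=%.4f LOD=%.4g pg/ml range=%s",
            name,
            curve.slope,
            curve.r_squared,
            curve.lod_concentration,
            curve.dynamic_range,
        )
        curves[name] = curve
    return CalibrationResult(thresholds=thresholds, curves=curves)


def quantify_sample(
    table: DropletTable,
    calibration: CalibrationResult,
    targets: dict[str, MolecularTarget],
    mode: str = "poisson_corrected",
) -> dict[str, dict]:
    """Quantify every panel analyte of one sample table.

    Returns analyte → {f_on, aeb, concentration_pg_ml, concentration_fM,
    flag}.
    """
    gated = gate_beads(table, calibration.thresholds)
    counts = call_positives(gated, calibration.thresholds)
    out = {}
    for name, target in targets.items():
        aeb = compute_aeb(counts, target.channel, mode=mode, on_saturation="floor")
        conc, flag = concentration_from_aeb(calibration.curves[name], aeb)
        out[name] = {
            "f_on": aeb.f_on,
            "aeb": aeb.aeb,
            "aeb_mode": aeb.mode,
            "concentration_pg_ml": conc,
            "concentration_fM": convert_units(conc, target),
            "flag": flag,
        }
    logger.info(
        "quantified well %s: beads=%d, %s",
        table.well_id,
        counts.n_beads,
        {k: round(v["concentration_pg_ml"], 4) for k, v in out.items()},
    )
    return out
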
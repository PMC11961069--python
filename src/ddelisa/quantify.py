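"""AEB statistic, log-log calibration, LOD, back-calculation, dilution linearity.

The digital statistic is AEB, average enzymes per bead.  From on/off bead
counts the Poisson-corrected estimator is AEB = −ln(1 − f_on): if per-bead
enzyme counts are Poisson(μ_eff), the off fraction is e^{−μ_eff}, so the
corrected AEB is a consistent estimator of μ_eff.  The naive mode AEB = f_on
is retained for sensitivity analysis; the two agree to first order for
f_on ≲ 0.1.

Calibration is ordinary least squares of log10(AEB) on log10(concentration)
over a detected dynamic range; the limit of detection is the blank AEB mean
plus three blank SDs, inverted through the fitted line.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import units
from .assay_model import MolecularTarget
from .readout import DigitalCounts

__all__ = [
    "AEBValue",
    "CalibrationCurve",
    "DilutionReport",
    "compute_aeb",
    "fit_calibration",
    "compute_lod",
    "concentration_from_aeb",
    "convert_units",
    "dilution_linearity",
]

#: log10 residual beyond which a ladder point is outside the linear range
DYNAMIC_RANGE_RESIDUAL = 0.15


@dataclass(frozen=True)
class AEBValue:
    """Average enzymes per bead for one well/channel."""

    aeb: float
    mode: str  # "poisson_corrected" | "naive"
    f_on: float
    n_beads: int
    saturated: bool = False


class SaturationError(ValueError):
    """Every bead is positive; the digital count carries no information."""


def compute_aeb(
    counts: DigitalCounts,
    channel: str,
    mode: str = "poisson_corrected",
    on_saturation: str = "raise",
) -> AEBValue:
    """AEB from digital counts.

    ``poisson_corrected`` (default): AEB = −ln(1 − f_on).  ``naive``:
    AEB = f_on.  A well with zero positive beads reports AEB = 0 (blank
    wells get a Jeffreys-style floor later, inside :func:`fit_calibration`);
    a fully saturated well (f_on = 1) raises :class:`SaturationError` with
    dilution advice unless ``on_saturation="floor"``, which caps
    f_on at 1 − 0.5/n_beads and flags the value ``saturated``.
    """
    if mode not in ("poisson_corrected", "naive"):
        raise ValueError(f"unknown AEB mode {mode!r}")
    if counts.n_beads == 0:
        raise ValueError(f"AEB undefined: well {counts.well_id!r} has no beads")
    n = counts.n_beads
    f_on = counts.f_on(channel)
    saturated = False
    if f_on >= 1.0:
        if mode == "poisson_corrected" and on_saturation != "floor":
            raise SaturationError(
                f"f_on = 1 on channel {channel!r} of well {counts.well_id!r}: "
                "assay saturated; dilute the sample and re-run"
            )
        f_on = 1.0 - 0.5 / n
        saturated = True
    aeb = -math.log1p(-f_on) if mode == "poisson_corrected" else f_on
    return AEBValue(aeb=aeb, mode=mode, f_on=f_on, n_beads=n, saturated=saturated)


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted log-log standard curve with LOD and dynamic range.

    ``slope``/``intercept`` are for log10(AEB) = slope·log10(c) + intercept
    with c in pg/mL.  ``lod_aeb`` = blank AEB mean + 3·SD; the concentration
    LOD is the curve inverse of ``lod_aeb``.
    """

    slope: float
    intercept: float
    r_squared: float
    dynamic_range: tuple[float, float]
    blank_aeb_mean: float
    blank_aeb_sd: float
    lod_aeb: float
    lod_concentration: float
    n_points: int
    provenance: dict = field(default_factory=dict)

    def predict_aeb(self, concentration: float) -> float:
        return 10 ** (self.slope * math.log10(concentration) + self.intercept)

    def to_json_dict(self) -> dict:
        d = {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "dynamic_range": list(self.dynamic_range),
            "blank_aeb_mean": self.blank_aeb_mean,
            "blank_aeb_sd": self.blank_aeb_sd,
            "lod_aeb": self.lod_aeb,
            "lod_concentration": self.lod_concentration,
            "n_points": self.n_points,
            "provenance": self.provenance,
        }
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "CalibrationCurve":
        d = dict(d)
        d["dynamic_range"] = tuple(d["dynamic_range"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationCurve":
        return cls.from_json_dict(json.loads(Path(path).read_text()))


def _floored_blank_aeb(v: AEBValue) -> float:
    """Blank AEB with the zero floor f_on ← 0.5/n_beads applied.

    A blank with no positive beads would report AEB = 0 and make the 3-SD
    LOD degenerate; the Jeffreys-style floor keeps it finite with finite
    bead counts.
    """
    if v.aeb > 0:
        return v.aeb
    f_floor = 0.5 / v.n_beads
    return -math.log1p(-f_floor) if v.mode == "poisson_corrected" else f_floor


def _ols_loglog(concs: np.ndarray, aebs: np.ndarray):
    res = stats.linregress(np.log10(concs), np.log10(aebs))
    return res.slope, res.intercept, res.rvalue**2


def fit_calibration(
    points: list[tuple[float, AEBValue]],
    blanks: list[AEBValue],
    k_sd: float = 3.0,
    residual_tol: float = DYNAMIC_RANGE_RESIDUAL,
) -> CalibrationCurve:
    """Fit the log-log standard curve and detect its dynamic range.

    ``points`` are (concentration pg/mL, AEB) replicates at non-zero
    concentrations; ``blanks`` are AEB values of blank wells (>= 2; three per
    the standard background rule).

    The dynamic range is the maximal contiguous run of ladder levels whose
    mean AEB exceeds ``lod_aeb`` and whose pointwise log10 residual against
    the current fit stays below ``residual_tol``; saturated points never
    enter.  Levels outside the run are excluded and the final OLS uses all
    replicate points inside it.
    """
    if len(blanks) < 2:
        raise ValueError("need >= 2 blank AEB values for the background rule")
    concs = sorted({c for c, _ in points if c > 0})
    if len(concs) < 3:
        raise ValueError("need >= 3 non-blank concentrations")

    blank_vals = np.array([_floored_blank_aeb(b) for b in blanks])
    blank_mean, blank_sd = float(blank_vals.mean()), float(blank_vals.std(ddof=1))
    lod_aeb = blank_mean + k_sd * blank_sd

    # per-level mean log10 AEB, saturation-aware
    level_aeb = {}
    saturated_levels = set()
    for c, v in points:
        if c <= 0:
            continue
        level_aeb.setdefault(c, []).append(_floored_blank_aeb(v))
        if v.saturated:
            saturated_levels.add(c)
    mean_log = {
        c: float(np.mean(np.log10(vals))) for c, vals in level_aeb.items()
    }

    usable = [
        c
        for c in concs
        if c not in saturated_levels and 10 ** mean_log[c] > lod_aeb
    ]
    if len(usable) == 0:
        raise ValueError("no ladder level rises above the LOD: no signal")
    # iteratively trim the worst out-of-tolerance level
    while len(usable) >= 3:
        x = np.log10(np.array(usable))
        y = np.array([mean_log[c] for c in usable])
        slope, intercept, _ = _ols_loglog(np.array(usable), 10**y)
        resid = np.abs(y - (slope * x + intercept))
        worst = int(np.argmax(resid))
        if resid[worst] < residual_tol:
            break
        usable.pop(worst)
    if len(usable) < 3:
        raise ValueError(
            f"fewer than 3 usable ladder levels above LOD/within tolerance: {usable}"
        )
    # maximal contiguous run of usable levels in ladder order
    runs, current = [], []
    for c in concs:
        if c in usable:
            current.append(c)
        else:
            if current:
                runs.append(current)
            current = []
    if current:
        runs.append(current)
    best = max(runs, key=len)
    if len(best) < 3:
        raise ValueError("no contiguous dynamic range of >= 3 levels")

    fit_concs = np.array([c for c, v in points if c in best])
    fit_aebs = np.array([_floored_blank_aeb(v) for c, v in points if c in best])
    slope, intercept, r2 = _ols_loglog(fit_concs, fit_aebs)
    if slope <= 0:
        raise ValueError(f"non-identifiable calibration: slope {slope} <= 0")
    lod_conc = 10 ** ((math.log10(lod_aeb) - intercept) / slope) if lod_aeb > 0 else 0.0
    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        dynamic_range=(min(best), max(best)),
        blank_aeb_mean=blank_mean,
        blank_aeb_sd=blank_sd,
        lod_aeb=lod_aeb,
        lod_concentration=lod_conc,
        n_points=len(fit_concs),
        provenance={"ladder": concs, "n_blanks": len(blanks), "k_sd": k_sd},
    )


def compute_lod(
    curve: CalibrationCurve, target: MolecularTarget | None = None
) -> dict[str, float]:
    """LOD in pg/mL (and fM when a target with molecular weight is given).

    lod_concentration = 10^((log10 lod_aeb − intercept)/slope).
    """
    if curve.slope <= 0:
        raise ValueError("non-identifiable curve: slope <= 0")
    out = {"lod_pg_ml": curve.lod_concentration, "lod_aeb": curve.lod_aeb}
    if target is not None:
        out["lod_fM"] = convert_units(curve.lod_concentration, target)
    return out


def concentration_from_aeb(
    curve: CalibrationCurve, aeb: AEBValue
) -> tuple[float, str]:
    """Back-calculate concentration from AEB with a range flag.

    Flags: ``below_LOD`` (reported, never censored to zero), ``in_range``,
    ``above_range``.  AEB of exactly 0 maps to concentration 0 with the
    below-LOD flag.
    """
    if aeb.aeb <= 0:
        return 0.0, "below_LOD"
    conc = 10 ** ((math.log10(aeb.aeb) - curve.intercept) / curve.slope)
    if aeb.aeb < curve.lod_aeb:
        return conc, "below_LOD"
    if aeb.saturated or conc > curve.dynamic_range[1]:
        return conc, "above_range"
    return conc, "in_range"


def convert_units(concentration_pg_ml: float, target: MolecularTarget) -> float:
    """pg/mL → fM using the target's molecular weight (kDa)."""
    return units.pg_per_ml_to_fm(concentration_pg_ml, target.molecular_weight)


@dataclass(frozen=True)
class DilutionReport:
    """Dilution-linearity assessment of one analyte."""

    levels: pd.DataFrame  # dilution, measured, back_corrected, recovery_pct
    neat_concentration: float
    linear_range_bound: float
    r_squared: float


def dilution_linearity(
    series: list[tuple[float, float]],
    recovery_tol: float = 0.20,
) -> DilutionReport:
    """Assess linearity of a serial-dilution series.

    ``series`` holds (dilution factor, measured pg/mL) with factor 1 = neat.
    Each level's back-corrected concentration is measured × dilution; the
    linear-range bound is the largest dilution up to which every level's
    recovery against neat stays within ±``recovery_tol``; r² is for measured
    signal vs 1/dilution.
    """
    if any(d <= 0 for d, _ in series):
        raise ValueError("dilution factors must be > 0")
    if len(series) < 3:
        raise ValueError("need >= 3 dilution levels including neat")
    df = pd.DataFrame(sorted(series), columns=["dilution", "measured"])
    if df["dilution"].iloc[0] != 1:
        raise ValueError("series must include the neat sample (dilution factor 1)")
    df["back_corrected"] = df["measured"] * df["dilution"]
    neat = float(df.loc[df["dilution"] == 1, "back_corrected"].mean())
    df["recovery_pct"] = 100.0 * df["back_corrected"] / neat
    bound = 0.0
    for _, row in df.iterrows():
        if abs(row["back_corrected"] / neat - 1.0) <= recovery_tol:
            bound = float(row["dilution"])
        else:
            break
    res = stats.linregress(1.0 / df["dilution"], df["measured"])
    return DilutionReport(
        levels=df,
        neat_concentration=neat,
        linear_range_bound=bound,
        r_squared=float(res.rvalue**2),
    )
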
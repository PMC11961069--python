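"""Centralized unit conversions and rounding helpers.

All public operations in this package take and return the units stated in
their signatures; every conversion factor lives here so there is exactly one
place where, e.g., the cubic-micron/femtolitre identity is written down.

Identities used:

* 1 μm³ = 1e-18 m³ = 1e-15 L = 1 fL, hence 10³ μm³ = 1 pL.
* 1 μL = 1e6 pL.
* 1 pg/mL = 1e-9 g/L; dividing by a molar mass in kDa (1 kDa = 10³ g/mol)
  gives mol/L in units of 1e-12 M, i.e. pg/mL ÷ kDa × 10³ = fM.
"""

from __future__ import annotations

import math

AVOGADRO = 6.02214076e23  # molecules per mol (exact, SI)

UM3_PER_FL = 1.0
UM3_PER_PL = 1.0e3
PL_PER_UL = 1.0e6
ML_PER_UL = 1.0e-3
G_PER_PG = 1.0e-12
G_PER_MOL_PER_KDA = 1.0e3

#: floors on physically-counted quantities tolerate this much float slack
_COUNT_EPS = 1e-9


def um3_to_pl(v_um3: float) -> float:
    """Convert a volume in cubic microns to picolitres."""
    return v_um3 / UM3_PER_PL


def ul_to_pl(v_ul: float) -> float:
    """Convert microlitres to picolitres."""
    return v_ul * PL_PER_UL


def pl_to_ul(v_pl: float) -> float:
    """Convert picolitres to microlitres."""
    return v_pl / PL_PER_UL


def ul_to_ml(v_ul: float) -> float:
    """Convert microlitres to millilitres."""
    return v_ul * ML_PER_UL


def pg_per_ml_to_fm(c_pg_ml: float, molecular_weight_kda: float) -> float:
    """Convert a mass concentration (pg/mL) to femtomolar.

    fM = pg/mL ÷ kDa × 10³ (dimensional identity: 1 pg/mL = 1e-9 g/L).
    """
    if molecular_weight_kda <= 0:
        raise ValueError(f"molecular_weight_kda must be > 0, got {molecular_weight_kda}")
    return c_pg_ml / molecular_weight_kda * 1.0e3


def fm_to_pg_per_ml(c_fm: float, molecular_weight_kda: float) -> float:
    """Inverse of :func:`pg_per_ml_to_fm`."""
    if molecular_weight_kda <= 0:
        raise ValueError(f"molecular_weight_kda must be > 0, got {molecular_weight_kda}")
    return c_fm * molecular_weight_kda / 1.0e3


def floor_count(x: float) -> int:
    """Floor a real quantity to an integer count, tolerating float slack.

    Physical counts (beads, droplets) are discrete; a ratio that is 1.0 up to
    representation error must floor to 1, not 0.
    """
    return int(math.floor(x + _COUNT_EPS))


def round_sig(x: float, n_sig: int) -> float:
    """Round ``x`` to ``n_sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -exponent + n_sig - 1)


def sci_notation(x: float, n_sig: int = 2) -> str:
    """Format ``x`` in the ``m × 10^e`` scientific form used in reports.

    >>> sci_notation(763942)
    '7.6 × 10^5'
    """
    if x == 0:
        return "0"
    exponent = math.floor(math.log10(abs(x)))
    mantissa = round_sig(x / 10**exponent, n_sig)
    if abs(mantissa) >= 10:  # rounding pushed the mantissa over a decade
        mantissa /= 10
        exponent += 1
    mantissa_str = f"{mantissa:.{max(n_sig - 1, 0)}f}"
    return f"{mantissa_str} × 10^{exponent}"
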
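"""Closed-form encapsulation statistics and assay geometry.

A digital droplet immunoassay disperses antibody-coated silica beads and
analyte molecules into monodisperse water-in-oil droplets.  Two independent
Poisson processes govern the assay ("double Poisson"): beads are distributed
over droplets with mean occupancy λ = n_beads / n_droplets, and captured,
enzyme-labeled molecules are distributed over beads with mean load μ that is
proportional to analyte concentration.  Everything in this module is
deterministic closed form; the stochastic counterpart lives in
:mod:`ddelisa.synthetic`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

from scipy import stats

from . import units

__all__ = [
    "DropletDesign",
    "MolecularTarget",
    "OccupancySummary",
    "DEFAULT_PANEL",
    "bead_loading_lambda",
    "occupancy_summary",
    "occupancy_pmf",
    "droplet_volume_from_diameter",
    "droplet_count",
    "beads_for_singlet_fraction",
    "mean_molecules_per_bead",
]


def droplet_volume_from_diameter(diameter_um: float) -> float:
    """Sphere volume of a droplet, μm diameter in, picolitres out.

    A 50 μm droplet computes to 65.45 pL, which rounds to the conventional
    65 pL quoted for this geometry.
    """
    if diameter_um <= 0:
        raise ValueError(f"diameter_um must be > 0, got {diameter_um}")
    return units.um3_to_pl(math.pi * diameter_um**3 / 6.0)


def droplet_count(sample_volume_ul: float, droplet_volume_pl: float) -> int:
    """Number of whole droplets a sample volume partitions into.

    50 μL at 65.45 pL per droplet yields 763,942 droplets — reported at two
    significant figures as 7.6 × 10^5.
    """
    if sample_volume_ul <= 0:
        raise ValueError(f"sample_volume_ul must be > 0, got {sample_volume_ul}")
    if droplet_volume_pl <= 0:
        raise ValueError(f"droplet_volume_pl must be > 0, got {droplet_volume_pl}")
    return units.floor_count(units.ul_to_pl(sample_volume_ul) / droplet_volume_pl)


def bead_loading_lambda(n_beads: int, n_droplets: int) -> float:
    """Mean beads per droplet λ for a given loading."""
    if n_droplets < 1:
        raise ValueError(f"n_droplets must be >= 1, got {n_droplets}")
    if n_beads < 0:
        raise ValueError(f"n_beads must be >= 0, got {n_beads}")
    return n_beads / n_droplets


@dataclass(frozen=True)
class OccupancySummary:
    """Poisson bead-occupancy summary at loading λ.

    ``singlet_bead_fraction`` is the probability that a given bead shares its
    droplet with no other bead; for Poisson loading this equals e^{−λ}, the
    same as the empty-droplet fraction (a classical Poisson identity).
    ``singlet_droplet_fraction`` is the fraction of droplets holding exactly
    one bead, λe^{−λ}.
    """

    lam: float
    p_empty: float
    p_occupied: float
    singlet_droplet_fraction: float
    singlet_bead_fraction: float


def occupancy_summary(lam: float) -> OccupancySummary:
    """Closed-form occupancy summary for Poisson loading with mean ``lam``.

    At λ = 0 the singlet-bead fraction is taken as 1 by limit (every one of
    zero beads is trivially alone).
    """
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    p_empty = math.exp(-lam)
    return OccupancySummary(
        lam=lam,
        p_empty=p_empty,
        p_occupied=1.0 - p_empty,
        singlet_droplet_fraction=lam * p_empty,
        singlet_bead_fraction=p_empty,
    )


def occupancy_pmf(lam: float, k_max: int) -> tuple[list[float], float]:
    """Poisson pmf over bead counts k = 0..k_max, plus truncation remainder.

    Returns ``(pmf, remainder)`` where ``remainder`` is the probability mass
    above ``k_max``.
    """
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    if k_max < 0:
        raise ValueError(f"k_max must be >= 0, got {k_max}")
    ks = range(k_max + 1)
    pmf = [float(stats.poisson.pmf(k, lam)) for k in ks]
    remainder = float(stats.poisson.sf(k_max, lam))
    return pmf, remainder


def beads_for_singlet_fraction(target_fraction: float, n_droplets: int) -> int:
    """Largest bead count whose singlet-bead fraction still meets a target.

    Since the singlet-bead fraction e^{−n/D} decreases with the bead count n,
    the loading that meets ``singlet_bead_fraction >= target_fraction`` most
    densely is n = floor(−ln(target) · n_droplets).
    """
    if not (0.0 < target_fraction < 1.0):
        raise ValueError(f"target_fraction must be in (0, 1), got {target_fraction}")
    if n_droplets < 1:
        raise ValueError(f"n_droplets must be >= 1, got {n_droplets}")
    return units.floor_count(-math.log(target_fraction) * n_droplets)


@dataclass(frozen=True)
class MolecularTarget:
    """One analyte of the panel: identity, enzyme label, readout channel.

    The enzyme↔channel pairing encodes the multiplexing scheme: each enzyme
    turns over a substrate fluorescing in its own channel, so one droplet can
    report several analytes at once.  ``molecular_weight`` (kDa) is only used
    for the pg/mL ↔ fM conversion and is configurable.
    """

    name: str
    enzyme_label: str
    channel: str
    molecular_weight: float

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError(
                f"molecular_weight must be > 0, got {self.molecular_weight}"
            )


#: Conventional 3-plex inflammatory panel plus the specificity-control
#: analyte.  Molecular weights are standard literature values (monomer);
#: they parameterize unit conversion only.
DEFAULT_PANEL: dict[str, MolecularTarget] = {
    "OPN": MolecularTarget("OPN", "HRP", "green", 33.0),
    "IL-10": MolecularTarget("IL-10", "AKP", "blue", 18.6),
    "IL-6": MolecularTarget("IL-6", "PDE", "red", 21.0),
    "TNF-a": MolecularTarget("TNF-a", "HRP", "green", 17.4),
}


@dataclass(frozen=True)
class DropletDesign:
    """Geometry and loading of one assay run.

    Attributes
    ----------
    droplet_diameter : float
        Droplet diameter, μm.
    droplet_volume : float
        Droplet volume, pL.  When built with :meth:`from_diameter` this is
        the sphere volume of the diameter.
    n_droplets : int
        Droplets generated from the sample volume.
    n_beads : int
        Beads loaded into the run.
    sample_volume : float
        Reaction volume partitioned into droplets, μL.
    capture_efficiency : float
        Fraction of analyte molecules bound by bead-immobilized capture
        antibody; the assay characterized here reaches at most 0.422.
    """

    droplet_diameter: float
    droplet_volume: float
    n_droplets: int
    n_beads: int
    sample_volume: float
    capture_efficiency: float = 0.422

    def __post_init__(self) -> None:
        if self.droplet_volume <= 0:
            raise ValueError(f"droplet_volume must be > 0, got {self.droplet_volume}")
        if self.n_droplets < 1:
            raise ValueError(f"n_droplets must be >= 1, got {self.n_droplets}")
        if self.n_beads < 0:
            raise ValueError(f"n_beads must be >= 0, got {self.n_beads}")
        if not (0.0 <= self.capture_efficiency <= 1.0):
            raise ValueError(
                f"capture_efficiency must be in [0, 1], got {self.capture_efficiency}"
            )
        expected = droplet_volume_from_diameter(self.droplet_diameter)
        if abs(self.droplet_volume - expected) > 0.01 * expected:
            raise ValueError(
                f"droplet_volume {self.droplet_volume} pL deviates >1% from the "
                f"sphere volume {expected:.4g} pL of a {self.droplet_diameter} μm droplet"
            )
        if self.n_droplets * self.droplet_volume > units.ul_to_pl(self.sample_volume) * (
            1 + units._COUNT_EPS
        ):
            raise ValueError(
                "n_droplets × droplet_volume exceeds sample_volume: "
                f"{self.n_droplets} × {self.droplet_volume} pL > {self.sample_volume} μL"
            )

    @classmethod
    def from_diameter(
        cls,
        diameter_um: float,
        sample_volume_ul: float,
        n_beads: int,
        capture_efficiency: float = 0.422,
    ) -> "DropletDesign":
        """Build a design from droplet diameter and sample volume alone."""
        volume_pl = droplet_volume_from_diameter(diameter_um)
        return cls(
            droplet_diameter=diameter_um,
            droplet_volume=volume_pl,
            n_droplets=droplet_count(sample_volume_ul, volume_pl),
            n_beads=n_beads,
            sample_volume=sample_volume_ul,
            capture_efficiency=capture_efficiency,
        )

    @property
    def bead_lambda(self) -> float:
        return bead_loading_lambda(self.n_beads, self.n_droplets)

    def occupancy(self) -> OccupancySummary:
        return occupancy_summary(self.bead_lambda)

    # -- JSON run-config block -------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "diameter_um": self.droplet_diameter,
            "volume_pl": self.droplet_volume,
            "n_droplets": self.n_droplets,
            "n_beads": self.n_beads,
            "sample_volume_ul": self.sample_volume,
            "capture_efficiency": self.capture_efficiency,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "DropletDesign":
        return cls(
            droplet_diameter=d["diameter_um"],
            droplet_volume=d["volume_pl"],
            n_droplets=d["n_droplets"],
            n_beads=d["n_beads"],
            sample_volume=d["sample_volume_ul"],
            capture_efficiency=d["capture_efficiency"],
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "DropletDesign":
        return cls.from_json_dict(json.loads(Path(path).read_text()))


def mean_molecules_per_bead(
    concentration_pg_ml: float,
    target: MolecularTarget,
    design: DropletDesign,
) -> float:
    """Mean captured molecules per bead μ at a given analyte concentration.

    μ = c · V / M · N_A · η / n_beads with c the concentration (pg/mL),
    V the sample volume, M the molar mass, η the capture efficiency.  This
    is the second Poisson mean of the double-Poisson model: each bead's
    captured count is Poisson(μ).
    """
    if concentration_pg_ml < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration_pg_ml}")
    if design.n_beads == 0:
        raise ValueError("mean_molecules_per_bead undefined for a design with n_beads = 0")
    mass_g = concentration_pg_ml * units.G_PER_PG * units.ul_to_ml(design.sample_volume)
    moles = mass_g / (target.molecular_weight * units.G_PER_MOL_PER_KDA)
    molecules = moles * units.AVOGADRO
    return molecules * design.capture_efficiency / design.n_beads
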
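"""File-format plumbing: droplet CSVs, threshold/curve JSON, run configs.

Formats are deliberately plain: JSON for configuration and fitted objects,
CSV for tabular data, multi-page 16-bit TIFF for images.  Droplet CSVs may
carry a leading ``#`` comment line with provenance (config hash, seed);
readers skip comments.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .assay_model import DropletDesign, MolecularTarget
from .synthetic import CHANNELS, CohortSpec, DropletTable, NoiseModel

__all__ = [
    "RunConfig",
    "read_droplet_csv",
    "write_droplet_csv",
    "config_hash",
]

MANDATORY_COLUMNS = ["droplet_id", "well_id", "bead_gate"] + [
    f"ch_{ch}" for ch in CHANNELS
]
_KNOWN_EXTRA = {
    "true_n_beads",
    "has_bead",
    "multi_bead",
    "est_n_beads",
    "centroid_row",
    "centroid_col",
} | {f"true_molecules_{ch}" for ch in CHANNELS}


def write_droplet_csv(
    table: DropletTable, path: str | Path, provenance: str | None = None
) -> None:
    """Write a droplet table to CSV, optionally with a ``#`` provenance line."""
    path = Path(path)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        table.data.to_csv(fh, index=False)


def read_droplet_csv(path: str | Path) -> DropletTable:
    """Read a droplet CSV, validating the schema.

    Missing mandatory columns raise a schema error naming them; unknown
    extra columns are accepted with a warning and preserved.  Ragged rows
    raise with the offending line number.
    """
    path = Path(path)
    try:
        data = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as e:
        raise ValueError(f"malformed droplet CSV {path}: {e}") from e
    missing = [c for c in MANDATORY_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"droplet CSV {path} missing mandatory column(s): {missing}")
    unknown = [
        c for c in data.columns if c not in MANDATORY_COLUMNS and c not in _KNOWN_EXTRA
    ]
    if unknown:
        warnings.warn(f"droplet CSV {path} has unknown column(s) {unknown}; preserved")
    well_ids = data["well_id"].unique()
    well_id = str(well_ids[0]) if len(well_ids) == 1 else "multi-well"
    return DropletTable(data=data, channels=CHANNELS, well_id=well_id)


class TargetConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    enzyme_label: str
    channel: str
    molecular_weight: float = Field(gt=0)

    def to_target(self) -> MolecularTarget:
        return MolecularTarget(
            self.name, self.enzyme_label, self.channel, self.molecular_weight
        )


class DesignConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    diameter_um: float = 50.0
    sample_volume_ul: float = 50.0
    n_beads: int = 600_000
    capture_efficiency: float = 0.422

    def to_design(self) -> DropletDesign:
        return DropletDesign.from_diameter(
            self.diameter_um,
            self.sample_volume_ul,
            self.n_beads,
            self.capture_efficiency,
        )


class NoiseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    bead_gate_mean: float = 2000.0
    bead_gate_cv: float = 0.1
    gate_background_mean: float = 100.0
    gate_background_sd: float = 10.0
    background_mean: float = 100.0
    background_sd: float = 10.0
    per_enzyme_amplitude: float = 50.0
    signal_cv: float = 0.1
    false_positive_rate: float = 2.0e-4
    label_efficiency: float = 0.5

    def to_noise(self) -> NoiseModel:
        return NoiseModel(
            bead_gate_mean=self.bead_gate_mean,
            bead_gate_cv=self.bead_gate_cv,
            gate_background_mean=self.gate_background_mean,
            gate_background_sd=self.gate_background_sd,
            background_mean=self.background_mean,
            background_sd=self.background_sd,
            per_enzyme_amplitude=self.per_enzyme_amplitude,
            signal_cv=self.signal_cv,
            false_positive_rate=self.false_positive_rate,
            label_efficiency=self.label_efficiency,
        )


class CohortGroupConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    label: str
    n_samples: int = Field(ge=1)
    fold_change: dict[str, float] = Field(default_factory=dict)


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    groups: list[CohortGroupConfig]
    baseline: dict[str, float]
    between_sample_cv: float = 0.1

    def to_spec(self) -> CohortSpec:
        return CohortSpec(
            groups=tuple((g.label, g.n_samples) for g in self.groups),
            baseline=dict(self.baseline),
            fold_change={g.label: dict(g.fold_change) for g in self.groups},
            between_sample_cv=self.between_sample_cv,
        )


class RunConfig(BaseModel):
    """Validated end-to-end run configuration (JSON-serializable).

    Unknown keys are rejected; ``seed`` is mandatory for any simulation.
    """

    model_config = ConfigDict(extra="forbid")
    design: DesignConfig = Field(default_factory=DesignConfig)
    targets: list[TargetConfig] = Field(
        default_factory=lambda: [
            TargetConfig(name="OPN", enzyme_label="HRP", channel="green", molecular_weight=33.0)
        ]
    )
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    ladder: list[float] = Field(
        default_factory=lambda: [0.01, 0.1, 1.0, 10.0, 100.0, 1000.0]
    )
    n_blanks: int = 3
    replicates: int = 3
    seed: int
    cohort: CohortConfig | None = None
    output_dir: str = "ddelisa-out"

    @field_validator("ladder")
    @classmethod
    def _ladder_nonneg(cls, v):
        if any(c < 0 for c in v):
            raise ValueError("ladder concentrations must be >= 0")
        return v

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def target_map(self) -> dict[str, MolecularTarget]:
        targets = {t.name: t.to_target() for t in self.targets}
        channels = [t.channel for t in targets.values()]
        if len(set(channels)) != len(channels):
            raise ValueError(f"targets share readout channels: {channels}")
        return targets


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the canonical config JSON, for provenance."""
    canonical = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
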
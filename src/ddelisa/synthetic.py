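"""Seeded stochastic generator of droplet-level digital ELISA data.

The generator realizes the double-Poisson assay model: bead counts per
droplet are Poisson(λ) with λ = n_beads/n_droplets, and enzyme-labeled
molecules per bead per channel are Poisson(μ·label_efficiency) with μ from
:func:`ddelisa.assay_model.mean_molecules_per_bead`.  Binomial thinning of a
Poisson count by the label efficiency keeps the per-bead count Poisson, so
the effective per-bead mean is exactly μ_eff = μ·label_efficiency — the
quantity the Poisson-corrected AEB statistic estimates.

Multi-bead droplets pool their enzymes into a single droplet intensity
(physically, all beads in a droplet share one substrate pool).  Signal noise
is multiplicative lognormal with unit mean so bright droplets have
proportional spread; blanks are governed by the additive Gaussian background
alone.

All randomness flows from one integer seed through a counter-based
``numpy.random.SeedSequence`` scheme: sub-stream k of run seed s is
``SeedSequence(s, spawn_key=(k,))``, so adding a replicate or ladder level
never perturbs the draws of earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assay_model import DropletDesign, MolecularTarget, mean_molecules_per_bead

__all__ = [
    "CHANNELS",
    "NoiseModel",
    "DropletTable",
    "CohortSpec",
    "ImageConfig",
    "simulate_droplet_table",
    "simulate_calibration_run",
    "simulate_cohort",
    "render_droplet_image",
]

CHANNELS = ("green", "blue", "red")


def _per_channel(value, channels=CHANNELS) -> dict[str, float]:
    """Broadcast a scalar to all channels, or validate a dict."""
    if isinstance(value, dict):
        return {ch: float(value.get(ch, 0.0)) for ch in channels}
    return {ch: float(value) for ch in channels}


@dataclass(frozen=True)
class NoiseModel:
    """Instrument/assay noise description.

    The defaults are synthetic fixture values chosen to behave like a clean
    fluorescence readout (bright, well-separated bead gate; ~10 a.u.
    background noise; ~50 a.u. per enzyme); they are NOT measured constants
    of any particular instrument.

    Parameters
    ----------
    bead_gate_mean : float
        Mean FITC gate intensity contributed per bead, a.u.
    bead_gate_cv : float
        CV of the lognormal per-droplet gate signal spread.
    gate_background_mean, gate_background_sd : float
        Gaussian background of the gate channel, a.u.
    background_mean, background_sd : dict channel → a.u.
        Gaussian background of each analyte channel.
    per_enzyme_amplitude : dict channel → a.u.
        Fluorescence per enzyme molecule in a droplet.
    signal_cv : float
        CV of the multiplicative lognormal signal noise.
    false_positive_rate : dict channel → fraction
        Probability that a bead-containing, enzyme-free droplet nonetheless
        fluoresces like a single-enzyme droplet (nonspecific binding).
    label_efficiency : float
        Fraction of captured molecules that end up enzyme-labeled; thins the
        per-bead Poisson mean μ to μ_eff = μ·label_efficiency.
    """

    bead_gate_mean: float = 2000.0
    bead_gate_cv: float = 0.1
    gate_background_mean: float = 100.0
    gate_background_sd: float = 10.0
    background_mean: dict[str, float] = field(
        default_factory=lambda: _per_channel(100.0)
    )
    background_sd: dict[str, float] = field(default_factory=lambda: _per_channel(10.0))
    per_enzyme_amplitude: dict[str, float] = field(
        default_factory=lambda: _per_channel(50.0)
    )
    signal_cv: float = 0.1
    false_positive_rate: dict[str, float] = field(
        default_factory=lambda: _per_channel(2.0e-4)
    )
    label_efficiency: float = 0.5

    def __post_init__(self) -> None:
        for name in ("bead_gate_cv", "gate_background_sd", "signal_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.label_efficiency <= 1.0):
            raise ValueError(f"label_efficiency must be in [0, 1], got {self.label_efficiency}")
        object.__setattr__(self, "background_mean", _per_channel(self.background_mean))
        object.__setattr__(self, "background_sd", _per_channel(self.background_sd))
        object.__setattr__(
            self, "per_enzyme_amplitude", _per_channel(self.per_enzyme_amplitude)
        )
        object.__setattr__(
            self, "false_positive_rate", _per_channel(self.false_positive_rate)
        )
        for ch in CHANNELS:
            if self.background_sd[ch] < 0:
                raise ValueError(f"background_sd[{ch}] must be >= 0")
            if not (0.0 <= self.false_positive_rate[ch] <= 1.0):
                raise ValueError(f"false_positive_rate[{ch}] must be in [0, 1]")


@dataclass
class DropletTable:
    """Per-droplet events of one well: gate intensity, channel intensities,
    and (for simulated data) the latent truth columns.

    ``data`` columns: ``droplet_id``, ``well_id``, ``bead_gate``,
    ``ch_<channel>``..., and when simulated ``true_n_beads`` and
    ``true_molecules_<channel>``.
    """

    data: pd.DataFrame
    channels: tuple[str, ...] = CHANNELS
    well_id: str = "well-0"
    true_concentrations: dict[str, float] | None = None

    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_truth(self) -> bool:
        return "true_n_beads" in self.data.columns


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Lognormal draws with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _sub_rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-based sub-stream: stable under adding later keys."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def simulate_droplet_table(
    design: DropletDesign,
    concentrations: dict[str, float],
    targets: dict[str, MolecularTarget],
    noise: NoiseModel,
    seed: int,
    well_id: str = "well-0",
) -> DropletTable:
    """Simulate one well of droplet events under the double-Poisson model.

    Parameters
    ----------
    concentrations : dict analyte name → pg/mL
        True analyte concentrations in the sample.
    targets : dict analyte name → MolecularTarget
        Panel definition; each named analyte must be present and map to a
        distinct channel.

    Returns
    -------
    DropletTable with ``design.n_droplets`` rows, truth columns included.
    """
    for name, c in concentrations.items():
        if c < 0:
            raise ValueError(f"concentration of {name} must be >= 0, got {c}")
        if name not in targets:
            raise KeyError(f"analyte {name!r} not in the configured panel")
    channel_of = {name: targets[name].channel for name in concentrations}
    if len(set(channel_of.values())) != len(channel_of):
        raise ValueError(f"analytes share a readout channel: {channel_of}")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = design.n_droplets
    n_beads_true = rng.poisson(design.bead_lambda, size=n)
    has_bead = n_beads_true > 0

    # FITC bead gate: background plus a per-bead contribution
    gate = rng.normal(noise.gate_background_mean, noise.gate_background_sd, size=n)
    gate = gate + noise.bead_gate_mean * n_beads_true * _lognormal_unit_mean(
        rng, noise.bead_gate_cv, n
    )

    cols: dict[str, np.ndarray] = {
        "droplet_id": np.arange(n),
        "well_id": np.repeat(well_id, n),
        "bead_gate": np.clip(gate, 0.0, None),
        "true_n_beads": n_beads_true,
    }

    channel_to_analyte = {ch: name for name, ch in channel_of.items()}
    for ch in CHANNELS:
        name = channel_to_analyte.get(ch)
        if name is None or concentrations[name] == 0:
            molecules = np.zeros(n, dtype=np.int64)
        else:
            mu = mean_molecules_per_bead(concentrations[name], targets[name], design)
            mu_eff = mu * noise.label_efficiency
            # sum of per-bead Poisson(mu_eff) counts pooled per droplet
            molecules = rng.poisson(mu_eff * n_beads_true)
        fp = noise.false_positive_rate[ch]
        if fp > 0:
            flip = has_bead & (molecules == 0) & (rng.random(n) < fp)
            molecules = molecules + flip.astype(np.int64)
        intensity = rng.normal(
            noise.background_mean[ch], noise.background_sd[ch], size=n
        ) + noise.per_enzyme_amplitude[ch] * molecules * _lognormal_unit_mean(
            rng, noise.signal_cv, n
        )
        cols[f"ch_{ch}"] = np.clip(intensity, 0.0, None)
        cols[f"true_molecules_{ch}"] = molecules

    return DropletTable(
        data=pd.DataFrame(cols),
        channels=CHANNELS,
        well_id=well_id,
        true_concentrations=dict(concentrations),
    )


def simulate_calibration_run(
    design: DropletDesign,
    target: MolecularTarget,
    ladder: list[float],
    n_replicates: int,
    noise: NoiseModel,
    seed: int,
) -> list[tuple[float, DropletTable]]:
    """Simulate a calibration ladder: one well per (concentration, replicate).

    Sub-seeds are derived by the counter scheme ``(level_index,
    replicate_index)`` so extending the ladder or adding replicates never
    changes earlier wells.  Blanks are ladder entries of 0 pg/mL.
    """
    if len(ladder) == 0:
        raise ValueError("ladder must contain at least one concentration")
    if any(c < 0 for c in ladder):
        raise ValueError("ladder concentrations must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    out: list[tuple[float, DropletTable]] = []
    for i, conc in enumerate(ladder):
        for r in range(n_replicates):
            sub_seed_seq = np.random.SeedSequence(seed, spawn_key=(i, r))
            # materialize a plain integer seed for simulate_droplet_table
            sub_seed = int(sub_seed_seq.generate_state(1, np.uint32)[0])
            table = simulate_droplet_table(
                design,
                {target.name: conc},
                {target.name: target},
                noise,
                seed=sub_seed,
                well_id=f"cal-{conc:g}-rep{r}",
            )
            out.append((conc, table))
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Group-structured cohort: per-group sample counts and per-analyte
    concentration scales.

    ``fold_change[group][analyte]`` multiplies ``baseline[analyte]``; true
    per-sample concentrations are lognormal around the group mean with the
    given between-sample CV.
    """

    groups: tuple[tuple[str, int], ...]
    baseline: dict[str, float]
    fold_change: dict[str, dict[str, float]]
    between_sample_cv: float = 0.1

    def __post_init__(self) -> None:
        for label, n in self.groups:
            if n < 1:
                raise ValueError(f"group {label!r} must have n_samples >= 1")
            for analyte, fold in self.fold_change.get(label, {}).items():
                if fold <= 0:
                    raise ValueError(f"fold_change[{label}][{analyte}] must be > 0")
        if self.between_sample_cv < 0:
            raise ValueError("between_sample_cv must be >= 0")


def simulate_cohort(
    design: DropletDesign,
    spec: CohortSpec,
    targets: dict[str, MolecularTarget],
    noise: NoiseModel,
    seed: int,
) -> list[tuple[str, str, DropletTable]]:
    """Simulate labeled cohort samples.

    Returns a list of ``(sample_id, group_label, DropletTable)``; each
    table's ``true_concentrations`` records the per-sample ground truth for
    recovery testing.
    """
    out = []
    for g, (label, n_samples) in enumerate(spec.groups):
        folds = spec.fold_change.get(label, {})
        for s in range(n_samples):
            rng = _sub_rng(seed, g, s)
            concs = {}
            for analyte, base in spec.baseline.items():
                mean_c = base * folds.get(analyte, 1.0)
                concs[analyte] = float(
                    mean_c * _lognormal_unit_mean(rng, spec.between_sample_cv, 1)[0]
                )
            sub_seed = int(
                np.random.SeedSequence(seed, spawn_key=(g, s, 1)).generate_state(
                    1, np.uint32
                )[0]
            )
            sample_id = f"{label}-{s}"
            table = simulate_droplet_table(
                design, concs, targets, noise, seed=sub_seed, well_id=sample_id
            )
            out.append((sample_id, label, table))
    return out


@dataclass(frozen=True)
class ImageConfig:
    """Canvas geometry for rendering a droplet monolayer.

    Droplets sit on a square grid with per-droplet jitter; ``intensity_scale``
    maps a.u. to 16-bit grey levels (default 1.0, clipped at 65535).
    """

    width: int = 512
    height: int = 512
    droplet_radius_px: int = 6
    jitter_px: int = 1
    intensity_scale: float = 1.0

    @property
    def cell_px(self) -> int:
        # one grid cell per droplet; jitter bounded so discs never overlap
        return 2 * (self.droplet_radius_px + self.jitter_px) + 2

    @property
    def capacity(self) -> int:
        return (self.width // self.cell_px) * (self.height // self.cell_px)


def render_droplet_image(
    table: DropletTable,
    config: ImageConfig = ImageConfig(),
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a droplet table as a multi-channel 16-bit monolayer image.

    Returns ``(image, truth)``: image has shape ``(1 + n_channels, H, W)``
    (gate channel first) and dtype uint16; ``truth`` lists droplet_id, row,
    col and radius of every rendered disc.  The canvas background is 0 so
    every droplet (whose interior carries its fluorescence background) is
    segmentable in any channel.
    """
    from skimage.draw import disk

    n = len(table)
    if n > config.capacity:
        min_side = config.cell_px * int(np.ceil(np.sqrt(n)))
        raise ValueError(
            f"canvas {config.width}x{config.height} holds {config.capacity} droplets, "
            f"got {n}; need at least {min_side}x{min_side} px at this radius"
        )
    n_ch = 1 + len(table.channels)
    img = np.zeros((n_ch, config.height, config.width), dtype=np.uint16)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    cols_per_row = config.width // config.cell_px

    rows = []
    intens = np.column_stack(
        [table.data["bead_gate"].to_numpy()]
        + [table.data[f"ch_{ch}"].to_numpy() for ch in table.channels]
    )
    for i in range(n):
        gr, gc = divmod(i, cols_per_row)
        cy = gr * config.cell_px + config.cell_px // 2
        cx = gc * config.cell_px + config.cell_px // 2
        if config.jitter_px:
            cy += int(rng.integers(-config.jitter_px, config.jitter_px + 1))
            cx += int(rng.integers(-config.jitter_px, config.jitter_px + 1))
        rr, cc = disk((cy, cx), config.droplet_radius_px, shape=img.shape[1:])
        for c in range(n_ch):
            img[c, rr, cc] = np.uint16(
                np.clip(round(intens[i, c] * config.intensity_scale), 0, 65535)
            )
        rows.append(
            {
                "droplet_id": int(table.data["droplet_id"].iloc[i]),
                "row": cy,
                "col": cx,
                "radius": config.droplet_radius_px,
            }
        )
    truth = pd.DataFrame(rows, columns=["droplet_id", "row", "col", "radius"])
    return img, truth
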
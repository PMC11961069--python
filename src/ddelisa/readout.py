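"""Digital calling: bead gating, per-channel positive calls, image detection.

The digital readout reduces each well to per-channel counts: how many
droplets contain a bead (FITC gate), and how many of those exceed the
analyte-channel positive cutoff.  Cutoffs follow the blank-based rule:
positive_cutoff = blank mean + k·SD (k = 3 by default), with the blank
statistics taken over bead-containing droplets of the blank wells.

Ties at a cutoff are called positive (>= rule) so integer fixtures are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import CHANNELS, DropletTable

__all__ = [
    "Thresholds",
    "DigitalCounts",
    "estimate_thresholds",
    "gate_beads",
    "call_positives",
    "detect_droplets",
]


@dataclass(frozen=True)
class Thresholds:
    """Gating and positive-call cutoffs with their blank provenance.

    ``positive_cutoff[ch]`` is recomputable as
    ``blank_mean[ch] + k_sd * blank_sd[ch]``; the blank well ids are kept so
    any downstream counts object can be audited back to its blanks.
    """

    bead_gate_cutoff: float
    positive_cutoff: dict[str, float]
    k_sd: float = 3.0
    blank_mean: dict[str, float] = field(default_factory=dict)
    blank_sd: dict[str, float] = field(default_factory=dict)
    blank_wells: tuple[str, ...] = ()
    single_bead_mode: float = float("nan")

    def to_json_dict(self) -> dict:
        return {
            "bead_gate_cutoff": self.bead_gate_cutoff,
            "positive_cutoff": dict(self.positive_cutoff),
            "k_sd": self.k_sd,
            "blank_mean": dict(self.blank_mean),
            "blank_sd": dict(self.blank_sd),
            "blank_wells": list(self.blank_wells),
            "single_bead_mode": self.single_bead_mode,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "Thresholds":
        return cls(
            bead_gate_cutoff=d["bead_gate_cutoff"],
            positive_cutoff=dict(d["positive_cutoff"]),
            k_sd=d["k_sd"],
            blank_mean=dict(d.get("blank_mean", {})),
            blank_sd=dict(d.get("blank_sd", {})),
            blank_wells=tuple(d.get("blank_wells", ())),
            single_bead_mode=d.get("single_bead_mode", float("nan")),
        )


@dataclass(frozen=True)
class DigitalCounts:
    """Per-channel digital counts of one well: the inputs of the AEB
    statistic."""

    n_droplets_total: int
    n_beads: int
    n_multibead: int
    n_on: dict[str, int]
    well_id: str = "well-0"

    def f_on(self, channel: str) -> float:
        if self.n_beads == 0:
            return 0.0
        return self.n_on[channel] / self.n_beads


def _gate_split(gate: np.ndarray) -> tuple[float, float, float]:
    """Split gate intensities into background/bead populations.

    Returns (background_mode, single_bead_mode, cutoff).  The cutoff is the
    documented rule: midpoint of the two empirical modes.  The Otsu split is
    taken on log intensity (fluorescence populations span decades, and the
    multi-bead tail would otherwise dominate the between-class variance);
    the background mode is the median of the lower class and the single-bead
    mode is the histogram peak of the upper class, which is robust to the
    multi-bead tail.
    """
    from skimage.filters import threshold_otsu

    lo, hi = float(np.min(gate)), float(np.max(gate))
    if hi - lo < 1e-9:  # degenerate: a single population
        return lo, hi, hi
    log_gate = np.log10(gate + 1.0)
    t = 10 ** float(threshold_otsu(log_gate, nbins=512)) - 1.0
    below, above = gate[gate < t], gate[gate >= t]
    if len(below) == 0 or len(above) == 0:
        return lo, hi, t
    bg_mode = float(np.median(below))
    hist, edges = np.histogram(above, bins=100)
    peak = int(np.argmax(hist))
    bead_mode = float(0.5 * (edges[peak] + edges[peak + 1]))
    return bg_mode, bead_mode, 0.5 * (bg_mode + bead_mode)


def estimate_thresholds(
    blank_tables: list[DropletTable],
    k_sd: float = 3.0,
) -> Thresholds:
    """Fit gating and positive cutoffs from blank wells.

    Per analyte channel, the blank mean and SD are computed over the
    bead-containing droplets of all blanks pooled, and the positive cutoff
    is mean + k_sd·SD.  The bead-gate cutoff is the midpoint between the
    empirical background and single-bead gate modes.
    """
    if len(blank_tables) == 0:
        raise ValueError("at least one blank table is required")
    channels = blank_tables[0].channels
    gate_all = np.concatenate([t.data["bead_gate"].to_numpy() for t in blank_tables])
    _, bead_mode, gate_cutoff = _gate_split(gate_all)
    beaded = gate_all >= gate_cutoff
    if not beaded.any():
        raise ValueError("no bead-containing droplets found in the blank wells")
    blank_mean, blank_sd, cutoff = {}, {}, {}
    for ch in channels:
        vals = np.concatenate(
            [t.data[f"ch_{ch}"].to_numpy() for t in blank_tables]
        )[beaded]
        m, s = float(np.mean(vals)), float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        blank_mean[ch], blank_sd[ch] = m, s
        cutoff[ch] = m + k_sd * s
    return Thresholds(
        bead_gate_cutoff=gate_cutoff,
        positive_cutoff=cutoff,
        k_sd=k_sd,
        blank_mean=blank_mean,
        blank_sd=blank_sd,
        blank_wells=tuple(t.well_id for t in blank_tables),
        single_bead_mode=bead_mode,
    )


def gate_beads(table: DropletTable, thresholds: Thresholds) -> DropletTable:
    """Flag bead-containing droplets on the FITC gate.

    Every flagged droplet is counted as one bead (the single-bead operating
    assumption of the monodisperse design); droplets whose gate intensity
    exceeds 1.5× the single-bead mode are additionally flagged multi-bead.
    """
    data = table.data.copy()
    gate = data["bead_gate"].to_numpy()
    has_bead = gate >= thresholds.bead_gate_cutoff
    data["has_bead"] = has_bead
    multi_cut = 1.5 * thresholds.single_bead_mode
    data["multi_bead"] = has_bead & (gate > multi_cut) if np.isfinite(multi_cut) else False
    data["est_n_beads"] = has_bead.astype(int)
    return DropletTable(
        data=data,
        channels=table.channels,
        well_id=table.well_id,
        true_concentrations=table.true_concentrations,
    )


def call_positives(gated: DropletTable, thresholds: Thresholds) -> DigitalCounts:
    """Count analyte-positive beads per channel.

    Only bead-containing droplets can contribute to ``n_on`` or ``n_beads``;
    a droplet is positive on a channel iff its intensity >= that channel's
    cutoff.
    """
    if "has_bead" not in gated.data.columns:
        raise ValueError("table is not gated; run gate_beads first")
    has_bead = gated.data["has_bead"].to_numpy()
    n_beads = int(has_bead.sum())
    n_on = {}
    for ch in gated.channels:
        if ch not in thresholds.positive_cutoff:
            raise KeyError(f"channel {ch!r} absent from thresholds")
        vals = gated.data[f"ch_{ch}"].to_numpy()
        n_on[ch] = int((has_bead & (vals >= thresholds.positive_cutoff[ch])).sum())
    return DigitalCounts(
        n_droplets_total=len(gated),
        n_beads=n_beads,
        n_multibead=int(gated.data["multi_bead"].sum()),
        n_on=n_on,
        well_id=gated.well_id,
    )


def counts_to_frame(counts_list: list[DigitalCounts]) -> pd.DataFrame:
    """Tidy per-well summary (well_id, channel, n_droplets, n_beads, n_on, f_on)."""
    rows = []
    for c in counts_list:
        for ch, n_on in c.n_on.items():
            rows.append(
                {
                    "well_id": c.well_id,
                    "channel": ch,
                    "n_droplets": c.n_droplets_total,
                    "n_beads": c.n_beads,
                    "n_on": n_on,
                    "f_on": c.f_on(ch),
                }
            )
    return pd.DataFrame(rows)


def detect_droplets(
    image: np.ndarray,
    droplet_radius_px: int = 6,
    intensity_scale: float = 1.0,
    min_foreground: float = 25.0,
    well_id: str = "image-0",
) -> DropletTable:
    """Locate droplets in a rendered monolayer image and extract intensities.

    Segmentation is per-pixel background thresholding on the channel sum,
    connected components, then size ([0.5, 2]× the nominal disc area) and
    circularity (>= 0.7) filters.  Per-droplet channel intensity is the mean
    over the component interior, mapped back to a.u. via ``intensity_scale``.

    An image with no detectable droplets yields an empty table, not an error.
    """
    from skimage.measure import label, regionprops

    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = img[None, ...]
    mask = img.sum(axis=0) > min_foreground * intensity_scale
    labels = label(mask)
    nominal_area = np.pi * droplet_radius_px**2
    rows = []
    centers = []
    for region in regionprops(labels):
        if not (0.5 * nominal_area <= region.area <= 2.0 * nominal_area):
            continue
        circularity = 4 * np.pi * region.area / max(region.perimeter, 1e-9) ** 2
        if circularity < 0.7:
            continue
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        means = img[:, rr, cc].mean(axis=1) / intensity_scale
        row = {"droplet_id": len(rows), "well_id": well_id, "bead_gate": means[0]}
        for i, ch in enumerate(CHANNELS):
            row[f"ch_{ch}"] = means[1 + i] if 1 + i < img.shape[0] else 0.0
        rows.append(row)
        centers.append(region.centroid)
    columns = ["droplet_id", "well_id", "bead_gate"] + [f"ch_{ch}" for ch in CHANNELS]
    data = pd.DataFrame(rows, columns=columns)
    data["centroid_row"] = [c[0] for c in centers]
    data["centroid_col"] = [c[1] for c in centers]
    return DropletTable(data=data, channels=CHANNELS, well_id=well_id)
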
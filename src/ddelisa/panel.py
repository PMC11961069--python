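"""Cohort-level assembly and comparison of multiplex panel results.

Per-sample concentration estimates are assembled into a tidy long-format
table with group labels, then compared between groups: fold change of group
means, Welch's two-sample t-test on log-concentrations (immunoassay errors
are multiplicative), and Benjamini-Hochberg adjustment across the analytes
of each comparison pair.  Below-LOD samples are excluded from testing with
their counts reported, not imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["PanelResult", "assemble_panel", "compare_groups"]

SAMPLE_COLUMNS = [
    "sample_id",
    "group",
    "analyte",
    "concentration_pg_ml",
    "flag",
]


@dataclass
class PanelResult:
    """Long-format per-sample panel with recomputable group summaries."""

    samples: pd.DataFrame  # SAMPLE_COLUMNS

    def summary(self) -> pd.DataFrame:
        """Per group × analyte mean, sd, n over quantifiable samples."""
        ok = self.samples[self.samples["flag"] != "below_LOD"]
        return (
            ok.groupby(["group", "analyte"])["concentration_pg_ml"]
            .agg(mean="mean", sd="std", n="count")
            .reset_index()
        )

    @property
    def analytes(self) -> list[str]:
        return sorted(self.samples["analyte"].unique())


def assemble_panel(results: list[dict]) -> PanelResult:
    """Assemble per-sample quantification outputs into one panel.

    Each element of ``results`` describes one sample:
    ``{"sample_id": ..., "group": ..., "concentrations": {analyte: (pg/mL,
    flag)}}``.  All samples must carry the same analyte set; duplicate
    sample ids are rejected.
    """
    if len(results) == 0:
        raise ValueError("no samples to assemble")
    ids = [r["sample_id"] for r in results]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicated sample_id(s): {sorted(dupes)}")
    analyte_sets = {frozenset(r["concentrations"]) for r in results}
    if len(analyte_sets) > 1:
        sets = [sorted(s) for s in analyte_sets]
        raise ValueError(f"mismatched analyte sets across samples: {sets}")
    rows = []
    for r in results:
        for analyte, (conc, flag) in r["concentrations"].items():
            rows.append(
                {
                    "sample_id": r["sample_id"],
                    "group": r["group"],
                    "analyte": analyte,
                    "concentration_pg_ml": conc,
                    "flag": flag,
                }
            )
    return PanelResult(samples=pd.DataFrame(rows, columns=SAMPLE_COLUMNS))


def compare_groups(
    panel: PanelResult,
    pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Per-analyte group comparison for each (reference, test) pair.

    Returns a frame with columns pair, analyte, fold (test mean / reference
    mean), p (Welch t on log10 concentration), q (BH across analytes within
    the pair), n_ref, n_test, n_excluded_below_lod.  Fold change alone is
    reported (p = NaN) when either group has n < 2.
    """
    known = set(panel.samples["group"].unique())
    rows = []
    for ref, test in pairs:
        for g in (ref, test):
            if g not in known:
                raise KeyError(f"group {g!r} not present in the panel")
        pvals, pair_rows = [], []
        for analyte in panel.analytes:
            sub = panel.samples[panel.samples["analyte"] == analyte]
            excl = int(
                ((sub["flag"] == "below_LOD") & sub["group"].isin([ref, test])).sum()
            )
            sub = sub[sub["flag"] != "below_LOD"]
            x_ref = sub.loc[sub["group"] == ref, "concentration_pg_ml"].to_numpy()
            x_test = sub.loc[sub["group"] == test, "concentration_pg_ml"].to_numpy()
            ref_mean = float(x_ref.mean()) if len(x_ref) else float("nan")
            if len(x_ref) and ref_mean == 0:
                raise ValueError(
                    f"reference group {ref!r} has zero mean for {analyte!r}: "
                    "fold change undefined"
                )
            fold = float(x_test.mean()) / ref_mean if len(x_test) and len(x_ref) else float("nan")
            if len(x_ref) >= 2 and len(x_test) >= 2:
                p = float(
                    stats.ttest_ind(
                        np.log10(x_test), np.log10(x_ref), equal_var=False
                    ).pvalue
                )
            else:
                p = float("nan")
            pvals.append(p)
            pair_rows.append(
                {
                    "pair": f"{ref} vs {test}",
                    "analyte": analyte,
                    "fold": fold,
                    "p": p,
                    "n_ref": len(x_ref),
                    "n_test": len(x_test),
                    "n_excluded_below_lod": excl,
                }
            )
        finite = [not math.isnan(p) for p in pvals]
        qvals = [float("nan")] * len(pvals)
        if any(finite):
            adj = multipletests(
                [p for p, f in zip(pvals, finite) if f], method="fdr_bh"
            )[1]
            it = iter(adj)
            qvals = [float(next(it)) if f else float("nan") for f in finite]
        for row, q in zip(pair_rows, qvals):
            row["q"] = q
        rows.extend(pair_rows)
    return pd.DataFrame(
        rows,
        columns=[
            "pair",
            "analyte",
            "fold",
            "p",
            "q",
            "n_ref",
            "n_test",
            "n_excluded_below_lod",
        ],
    )
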
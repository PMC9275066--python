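"""Scan-rescan reproducibility of the GS statistic.

Two consecutive scans of the same anatomy are processed independently (no
registration: GS needs no superimposition) and their GS tables are joined
on (tooth_label, roi_kind, measure, diameter).  The mean absolute GS
difference per group is the methodological error; alongside the cohort GS
mean and sd it forms the signal-to-noise style summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .measures import MEASURES

log = logging.getLogger(__name__)

__all__ = ["ReproReport", "match_pairs", "method_error", "signal_noise_chart"]

_KEYS = ["tooth_label", "roi_kind", "measure", "diameter_mm"]


@dataclass
class ReproReport:
    """Per-(roi_kind, measure, diameter) error and cohort GS summary."""

    pairs: pd.DataFrame  # matched rows with gs_scan / gs_rescan
    summary: pd.DataFrame  # roi_kind, measure, diameter_mm, mean_abs_diff, cohort_gs_mean, cohort_gs_sd, n_pairs


def match_pairs(scan_table: pd.DataFrame, rescan_table: pd.DataFrame) -> pd.DataFrame:
    """Inner-join the two GS tables on the grouping keys.

    Unmatched rows on either side are reported via logging; zero matches is
    an error (the tables describe different anatomy).
    """
    for name, df in (("scan", scan_table), ("rescan", rescan_table)):
        missing = [k for k in _KEYS + ["gs"] if k not in df.columns]
        if missing:
            raise ValueError(f"{name} table lacks columns {missing}")
    merged = scan_table.merge(
        rescan_table, on=_KEYS, how="outer", suffixes=("_scan", "_rescan"), indicator=True
    )
    unmatched = int((merged["_merge"] != "both").sum())
    if unmatched:
        log.warning("match_pairs: %d unmatched row(s) dropped", unmatched)
    pairs = merged[merged["_merge"] == "both"].drop(columns="_merge").reset_index(drop=True)
    if len(pairs) == 0:
        raise ValueError("no matching (tooth, roi, measure, diameter) rows between the tables")
    pairs.attrs["n_unmatched"] = unmatched
    return pairs


def method_error(pairs: pd.DataFrame, agg: str = "mean") -> ReproReport:
    """Mean (or median) absolute GS difference per (roi_kind, measure, diameter).

    The cohort GS mean/sd pool the scan and rescan values, mirroring the
    signal (cohort shape) against which the error (noise) is judged.
    """
    if agg not in ("mean", "median"):
        raise ValueError("agg must be 'mean' or 'median'")
    df = pairs.copy()
    df["abs_diff"] = (df["gs_scan"] - df["gs_rescan"]).abs()
    rows = []
    for (kind, measure, d), grp in df.groupby(["roi_kind", "measure", "diameter_mm"], sort=True):
        pooled = np.concatenate([grp["gs_scan"].to_numpy(), grp["gs_rescan"].to_numpy()])
        err = grp["abs_diff"].mean() if agg == "mean" else grp["abs_diff"].median()
        rows.append(
            {
                "roi_kind": kind,
                "measure": measure,
                "diameter_mm": d,
                "mean_abs_diff": float(err),
                "cohort_gs_mean": float(pooled.mean()),
                "cohort_gs_sd": float(pooled.std(ddof=1)) if len(pooled) > 1 else 0.0,
                "n_pairs": len(grp),
            }
        )
    return ReproReport(pairs=df, summary=pd.DataFrame(rows))


def signal_noise_chart(report: ReproReport, path: str | Path) -> None:
    """Grouped bar chart: cohort GS mean±sd (light grey) vs method error
    (dark grey) across diameters, one panel per measure and ROI kind row."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = report.summary
    if len(summary) == 0:
        raise ValueError("empty report")
    kinds = sorted(summary["roi_kind"].unique())
    measures = [m.value for m in MEASURES if m.value in set(summary["measure"])]
    ncols = len(measures)
    fig, axes = plt.subplots(
        len(kinds), ncols, figsize=(2.6 * ncols, 2.8 * len(kinds)), squeeze=False
    )
    for r, kind in enumerate(kinds):
        for c, measure in enumerate(measures):
            ax = axes[r][c]
            grp = summary[(summary["roi_kind"] == kind) & (summary["measure"] == measure)]
            grp = grp.sort_values("diameter_mm")
            if len(grp) == 0:
                log.warning("signal_noise_chart: no data for %s/%s, panel omitted", kind, measure)
                ax.set_visible(False)
                continue
            x = np.arange(len(grp))
            ax.bar(
                x - 0.2,
                grp["cohort_gs_mean"],
                0.4,
                yerr=grp["cohort_gs_sd"],
                color="0.8",
                edgecolor="0.4",
                capsize=2,
                label="GS mean±sd",
            )
            ax.bar(
                x + 0.2,
                grp["mean_abs_diff"],
                0.4,
                color="0.35",
                label="method error",
            )
            ax.set_xticks(x)
            ax.set_xticklabels([f"{d:g}" for d in grp["diameter_mm"]])
            ax.set_title(f"{kind} / {measure}", fontsize=9)
            if c == 0:
                ax.set_ylabel("value")
            ax.set_xlabel("diameter (mm)")
    handles, labels = axes[0][0].get_legend_handles_labels()
    if handles:
        fig.legend(handles, labels, loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)
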
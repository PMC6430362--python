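"""Per-code aggregation and QC report data.

The end product of a multiplexed bead assay is binding statistics per
analyte, i.e. per code.  This module groups the kept rows of the bead table
by assigned code and computes summary statistics of the background-subtracted
fluorescence signal, joins optional analyte names, and assembles the data
behind the standard QC views: bead-diameter histogram, beads-per-code
histogram, fluorescence-vs-ratio cross-talk correlations, ratio-level
histograms with companion 2-D scatters, and per-code box-and-whiskers
statistics (Q1/median/Q3 with 1.5 x IQR whiskers).  Everything is returned
as plain tables; rendering is left to the caller.
"""

from __future__ import annotations

import logging
import time

import numpy as np
import pandas as pd

from .beadfind import BeadMaskSet
from .imageio import ImageSet

logger = logging.getLogger(__name__)

__all__ = ["per_code_stats", "qc_report_data", "per_bead_report"]


def _signal_column(table: pd.DataFrame, channel: str) -> str:
    col = f"{channel}_median_bg_subtracted"
    if col not in table.columns:
        col = f"{channel}_median_ring"
    if col not in table.columns:
        raise KeyError(f"no extracted signal column found for channel {channel!r}")
    return col


def _kept(table: pd.DataFrame) -> pd.DataFrame:
    if "kept" in table.columns:
        return table[table["kept"]]
    return table


def per_code_stats(
    table: pd.DataFrame,
    channel: str,
    analyte_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-code summary of the bg-subtracted signal for one fluorescence channel.

    Returns one row per code that received at least one kept bead, with
    ``n_beads``, mean, median, sample SD, and quartiles.  *analyte_map*
    (columns ``code``, ``analyte``) joins human-readable analyte names;
    unknown codes in the map produce a warning and are ignored.
    """
    if "code" not in table.columns:
        raise KeyError("table has no 'code' column; run decode first")
    col = _signal_column(table, channel)
    kept = _kept(table)
    kept = kept[kept["code"] >= 0]
    g = kept.groupby("code")[col]
    out = pd.DataFrame(
        {
            "n_beads": g.size(),
            "mean": g.mean(),
            "median": g.median(),
            "sd": g.std(ddof=1),
            "q1": g.quantile(0.25),
            "q3": g.quantile(0.75),
        }
    ).reset_index()
    if analyte_map is not None:
        extra = set(analyte_map["code"]) - set(out["code"])
        if extra:
            logger.warning("analyte map codes with no beads or unknown: %s",
                           sorted(extra))
        out = out.merge(analyte_map[["code", "analyte"]], on="code", how="left")
    return out


def qc_report_data(
    table: pd.DataFrame,
    hist_channel: str | None = None,
    fluor_channel: str | None = None,
    ratio_columns: list[str] | None = None,
    n_bins: int = 50,
) -> dict:
    """Assemble the QC report tables.

    Always includes the bead-diameter histogram.  When the table carries
    decode results, adds per-code counts and box-and-whiskers statistics;
    when *fluor_channel* and *ratio_columns* are given, adds
    fluorescence-vs-ratio pairs with Pearson correlations (cross-talk QC);
    when *hist_channel* (a ratio column) is given, adds its binned level
    histogram plus the companion scatter of the other ratio dimensions.
    """
    kept = _kept(table)
    report: dict = {}

    counts, edges = np.histogram(kept["diameter"].dropna(), bins="auto")
    report["diameter_hist"] = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )

    has_codes = "code" in kept.columns
    if has_codes:
        coded = kept[kept["code"] >= 0]
        report["code_counts"] = (
            coded.groupby("code").size().rename("count").reset_index()
        )

    if fluor_channel is not None and ratio_columns:
        col = _signal_column(kept, fluor_channel)
        pairs = {}
        corr_rows = []
        for rc in ratio_columns:
            ratio_col = f"{rc}_median_core"
            sub = kept[[col, ratio_col]].dropna()
            pairs[rc] = sub.rename(
                columns={col: "fluorescence", ratio_col: "ratio"}
            )
            r = sub[col].corr(sub[ratio_col]) if len(sub) > 1 else np.nan
            corr_rows.append({"ratio": rc, "pearson_r": r})
        report["crosstalk_pairs"] = pairs
        report["crosstalk_corr"] = pd.DataFrame(corr_rows)

    if hist_channel is not None:
        ratio_col = f"{hist_channel}_median_core"
        if ratio_col not in kept.columns:
            raise KeyError(f"no ratio column {ratio_col!r} in table")
        vals = kept[ratio_col].dropna()
        counts, edges = np.histogram(vals, bins=n_bins)
        report["level_hist"] = pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        )
        if ratio_columns:
            others = [c for c in ratio_columns if c != hist_channel]
            cols = [f"{c}_median_core" for c in others]
            scatter = kept[[ratio_col] + cols].dropna().copy()
            scatter["bin"] = np.clip(
                np.digitize(scatter[ratio_col], edges) - 1, 0, n_bins - 1
            )
            report["level_scatter"] = scatter

    if has_codes:
        col_candidates = [
            c for c in kept.columns if c.endswith("_median_bg_subtracted")
        ]
        if col_candidates:
            col = col_candidates[0]
            rows = []
            for code, grp in kept[kept["code"] >= 0].groupby("code"):
                q1, med, q3 = grp[col].quantile([0.25, 0.5, 0.75])
                iqr = q3 - q1
                lo = grp[col][grp[col] >= q1 - 1.5 * iqr].min()
                hi = grp[col][grp[col] <= q3 + 1.5 * iqr].max()
                rows.append(
                    {"code": code, "q1": q1, "median": med, "q3": q3,
                     "whisker_low": lo, "whisker_high": hi,
                     "n_beads": len(grp)}
                )
            report["box_stats"] = pd.DataFrame(rows)
    return report


def per_bead_report(
    table: pd.DataFrame,
    images: ImageSet,
    masks_per_file: dict[tuple[str, int], BeadMaskSet],
    channels: list[str],
    selection: str = "all",
    code: int | None = None,
    file_index: int | None = None,
    pad: int = 3,
) -> dict:
    """Per-bead inspection bundle: cropped tiles plus the quantitative row.

    ``selection`` is ``"all"`` (file order), ``"code"`` (requires *code*) or
    ``"file"`` (requires *file_index*).  Each entry holds the bead key, one
    tile per requested channel cropped to the bead bounding box padded by
    *pad* pixels, the four region-mask tiles, and the bead's table row.  The
    bundle records an estimated generation time (measured on the first
    entry) before building the rest.
    """
    kept = _kept(table)
    if selection == "all":
        rows = kept
    elif selection == "code":
        if code is None:
            raise ValueError("selection='code' requires a code")
        if "code" not in kept.columns:
            raise KeyError("table has no 'code' column; run decode first")
        rows = kept[kept["code"] == code]
    elif selection == "file":
        if file_index is None:
            raise ValueError("selection='file' requires a file_index")
        rows = kept[kept["file"] == file_index]
    else:
        raise ValueError(f"unknown selection {selection!r}")
    rows = rows.sort_values(["set", "file", "label"])
    if rows.empty:
        logger.warning("per-bead report selection matched no beads")
        return {"entries": [], "estimated_seconds": 0.0}

    def _build(row) -> dict:
        key = (row["set"], int(row["file"]))
        masks = masks_per_file[key]
        where = masks.whole == int(row["label"])
        rr, cc = np.nonzero(where)
        r0 = max(rr.min() - pad, 0)
        r1 = min(rr.max() + 1 + pad, masks.whole.shape[0])
        c0 = max(cc.min() - pad, 0)
        c1 = min(cc.max() + 1 + pad, masks.whole.shape[1])
        win = (slice(r0, r1), slice(c0, c1))
        tiles = {
            ch: images[row["set"], int(row["file"]), ch][win] for ch in channels
        }
        mask_tiles = {
            name: masks.region(name)[win]
            for name in ("whole", "core", "ring", "background")
        }
        return {
            "key": (row["set"], int(row["file"]), int(row["label"])),
            "window": (r0, c0, r1 - r0, c1 - c0),
            "tiles": tiles,
            "masks": mask_tiles,
            "values": row.to_dict(),
        }

    t0 = time.perf_counter()
    first = _build(rows.iloc[0])
    per_entry = time.perf_counter() - t0
    estimate = per_entry * len(rows)
    logger.info(
        "per-bead report: %d entries, estimated %.1f s", len(rows), estimate
    )
    entries = [first] + [_build(row) for _, row in rows.iloc[1:].iterrows()]
    return {"entries": entries, "estimated_seconds": estimate}
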
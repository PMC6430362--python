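"""Per-bead statistics: region medians, local background subtraction, non-bead filtering.

The bead table holds one row per bead key ``(set, file, label)``.  Columns
follow a flat naming scheme:

* morphology: ``centroid_row``, ``centroid_col``, ``area``, ``diameter``,
  ``eccentricity``;
* per fluorescence channel ``ch``: ``{ch}_median_ring``,
  ``{ch}_median_background``, ``{ch}_median_bg_subtracted``,
  ``{ch}_total_ring``, ``{ch}_total_per_diameter``;
* per unmixed reference or ratio channel ``name``: ``{name}_median_core``;
* bookkeeping: ``kept`` (bool), ``removal_reason``.

Medians are used as the primary signal because they are robust to hot pixels
and to the partial-pixel edges of the region masks.  Background subtraction
is local (per bead, from that bead's own background annulus), so spatial
illumination or reflection gradients do not bias weak signals; negative
background-subtracted values are preserved, not clipped, so that per-code
averages of non-binders stay centred on zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .beadfind import BeadMaskSet

logger = logging.getLogger(__name__)

__all__ = [
    "region_stats",
    "extract_medians",
    "add_channel_stats",
    "background_subtract",
    "filter_nonbeads",
]

KEY_COLUMNS = ["set", "file", "label"]


def region_stats(
    masks: BeadMaskSet, image: np.ndarray, region: str
) -> pd.DataFrame:
    """Median, total and pixel count per bead label over one region mask.

    Labels present in the mask set but empty in the chosen region get NaN
    statistics (logged).  Index: bead label.
    """
    label_grid = masks.region(region)
    image = np.asarray(image)
    if label_grid.shape != image.shape:
        raise ValueError(
            f"mask shape {label_grid.shape} != image shape {image.shape}"
        )
    sel = label_grid > 0
    df = pd.DataFrame({"label": label_grid[sel], "value": image[sel].astype(float)})
    grouped = df.groupby("label")["value"].agg(
        median="median", total="sum", count="count"
    )
    all_labels = masks.labels
    grouped = grouped.reindex(all_labels)
    missing = grouped.index[grouped["count"].isna()]
    if len(missing):
        logger.warning(
            "region %r empty for label(s) %s; statistics set missing",
            region, list(missing),
        )
    return grouped


def extract_medians(
    masks: BeadMaskSet, image: np.ndarray, region: str
) -> dict[int, float]:
    """Per-label median over one region; missing regions map to NaN."""
    stats = region_stats(masks, image, region)
    return {int(k): float(v) for k, v in stats["median"].items()}


def add_channel_stats(
    table: pd.DataFrame,
    masks: BeadMaskSet,
    image: np.ndarray,
    channel: str,
    set_name: str,
    file_index: int,
    regions: tuple[str, ...] = ("ring", "background"),
    core_only: bool = False,
) -> pd.DataFrame:
    """Merge per-bead statistics of one image into the bead table in place.

    With ``core_only=True`` only ``{channel}_median_core`` is added (used for
    unmixed weight and ratio images); otherwise ring/background medians and
    ring totals are added for a fluorescence channel.
    """
    sel = (table["set"] == set_name) & (table["file"] == file_index)
    labels = table.loc[sel, "label"].to_numpy()
    if core_only:
        stats = region_stats(masks, image, "core")
        table.loc[sel, f"{channel}_median_core"] = (
            stats["median"].reindex(labels).to_numpy()
        )
        return table
    for region in regions:
        stats = region_stats(masks, image, region)
        table.loc[sel, f"{channel}_median_{region}"] = (
            stats["median"].reindex(labels).to_numpy()
        )
        if region == "ring":
            table.loc[sel, f"{channel}_total_ring"] = (
                stats["total"].reindex(labels).to_numpy()
            )
    if f"{channel}_total_ring" in table.columns and "diameter" in table.columns:
        table.loc[sel, f"{channel}_total_per_diameter"] = (
            table.loc[sel, f"{channel}_total_ring"] / table.loc[sel, "diameter"]
        )
    return table


def background_subtract(table: pd.DataFrame, channel: str) -> pd.DataFrame:
    """Add ``{channel}_median_bg_subtracted = median_ring - median_background``.

    Applied per bead (each bead's own background annulus), never per image.
    Negative results are preserved.  Beads lacking a background median get a
    missing value and are flagged.
    """
    ring = f"{channel}_median_ring"
    bg = f"{channel}_median_background"
    if ring not in table.columns or bg not in table.columns:
        raise KeyError(f"table lacks {ring!r}/{bg!r}; extract the channel first")
    table[f"{channel}_median_bg_subtracted"] = table[ring] - table[bg]
    missing = table[bg].isna()
    if missing.any():
        logger.warning(
            "%d bead(s) lack a background median for channel %r", missing.sum(), channel
        )
        _flag(table, missing, f"no background region ({channel})")
    return table


def _flag(table: pd.DataFrame, mask: pd.Series, reason: str) -> None:
    if "removal_reason" not in table.columns:
        table["removal_reason"] = ""
    existing = table.loc[mask, "removal_reason"]
    table.loc[mask, "removal_reason"] = np.where(
        existing == "", reason, existing + "; " + reason
    )


def filter_nonbeads(
    table: pd.DataFrame,
    invariant_lnp: str,
    background_ref: str = "background",
    n_sd: float = 2.0,
    per_file: bool = False,
    max_removed_fraction: float = 0.5,
) -> pd.DataFrame:
    """Flag objects whose invariant-species or background core levels are outliers.

    Bead-like objects that are not real encoded beads (air bubbles, dust)
    carry no embedded luminescence: their unmixed invariant-species weight
    sits at the background level, far from the bead population.  A single
    pass computes the mean and sample SD (ddof=1) of the invariant-species
    and unmixed-background core medians over all objects and removes those
    deviating by more than *n_sd* SD in either quantity.

    Statistics are pooled over the whole experiment by default; with
    ``per_file=True`` they are computed within each (set, file) group.  With
    fewer than 3 objects the filter is skipped with a warning.  Removing more
    than *max_removed_fraction* of objects trips a hard warning (degenerate
    SD guard) but still applies the filter.
    """
    inv_col = f"{invariant_lnp}_median_core"
    bg_col = f"{background_ref}_median_core"
    for col in (inv_col, bg_col):
        if col not in table.columns:
            raise KeyError(f"table lacks column {col!r}; run unmixed extraction first")
    if "kept" not in table.columns:
        table["kept"] = True
    if "removal_reason" not in table.columns:
        table["removal_reason"] = ""
    if len(table) < 3:
        logger.warning("fewer than 3 objects; non-bead filter skipped")
        return table

    def _zscores(df: pd.DataFrame, col: str) -> pd.Series:
        sd = df[col].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            return pd.Series(0.0, index=df.index)
        return (df[col] - df[col].mean()).abs() / sd

    groups = table.groupby(["set", "file"]).groups.values() if per_file else [table.index]
    removed = pd.Series(False, index=table.index)
    for idx in groups:
        sub = table.loc[idx]
        z_inv = _zscores(sub, inv_col)
        z_bg = _zscores(sub, bg_col)
        bad_inv = z_inv > n_sd
        bad_bg = z_bg > n_sd
        _flag(table, bad_inv.reindex(table.index, fill_value=False),
              f"{invariant_lnp} level > {n_sd} SD from mean")
        _flag(table, bad_bg.reindex(table.index, fill_value=False),
              f"unmixed background > {n_sd} SD from mean")
        removed |= (bad_inv | bad_bg).reindex(table.index, fill_value=False)

    frac = removed.mean()
    if frac > max_removed_fraction:
        logger.warning(
            "non-bead filter removed %.1f%% of objects (> %.0f%% guard); "
            "check invariant-channel statistics",
            100 * frac, 100 * max_removed_fraction,
        )
    table.loc[removed, "kept"] = False
    logger.info(
        "non-bead filter: removed %d of %d objects", int(removed.sum()), len(table)
    )
    return table
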
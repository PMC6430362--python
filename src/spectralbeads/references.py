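"""Reference emission spectra for linear unmixing.

Decoding ratiometric spectral codes requires a reference spectrum per
luminescent species: the relative intensity each species contributes to every
emission channel.  Spectra are measured from dedicated reference beads that
carry the maximum amount of a single species (median core-pixel intensity per
channel), plus one "background" spectrum measured from a bead-free image
region that captures slide autofluorescence and bleed-through.  Stacked as
columns they form the channels x references matrix ``A`` of the linear
unmixing system ``A @ X = B``; with 9 emission channels and 4 species plus
background this is a 9 x 5 matrix.

Columns are normalized to unit sum.  Absolute spectrum scale is arbitrary
(it trades off against the unmixed weights), and unit-sum columns make
weights comparable across species while leaving the ratiometric code
coordinates — ratios of weights — unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import beadfind
from .imageio import ImageSet

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceMatrix",
    "spectrum_from_reference_beads",
    "background_spectrum",
    "assemble",
    "load_reference_csv",
    "save_reference_csv",
]

BACKGROUND_NAME = "background"


@dataclass
class ReferenceMatrix:
    """Channels x references spectrum matrix with unit-sum columns.

    ``A[i, j]`` is the fraction of reference ``j``'s emission appearing in
    channel ``i``.  The system must be square or overdetermined
    (``len(channels) >= len(names)``).
    """

    channels: list[str]
    names: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (len(self.channels), len(self.names)):
            raise ValueError(
                f"matrix shape {self.A.shape} does not match "
                f"{len(self.channels)} channels x {len(self.names)} references"
            )
        if len(self.channels) < len(self.names):
            raise ValueError(
                "underdetermined system: need at least as many channels as references"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("reference names must be unique")
        if (self.A < 0).any():
            raise ValueError("spectrum entries must be non-negative")
        sums = self.A.sum(axis=0)
        if np.any(sums <= 0):
            bad = [n for n, s in zip(self.names, sums) if s <= 0]
            raise ValueError(f"zero spectrum column(s): {bad}")
        self.A = self.A / sums

    def column(self, name: str) -> np.ndarray:
        return self.A[:, self.names.index(name)]

    @property
    def lnp_names(self) -> list[str]:
        """Reference names excluding the background column."""
        return [n for n in self.names if n != BACKGROUND_NAME]


def spectrum_from_reference_beads(
    images: ImageSet,
    channel_names: list[str],
    bright_field: str = "Bright-field",
    find_config: dict | None = None,
) -> np.ndarray:
    """Measure one species' spectrum from its reference-bead image set.

    Beads are found and segmented on the bright-field channel of every file;
    the spectrum entry for each emission channel is the median over the
    pooled core pixels of all found beads.  Returned un-normalized.
    """
    find_config = dict(find_config or {})
    threshold_keys = {"block_size", "offset", "dark_objects"}
    thr_cfg = {k: v for k, v in find_config.items() if k in threshold_keys}
    seg_cfg = {k: v for k, v in find_config.items() if k not in threshold_keys}

    core_pixels: dict[str, list[np.ndarray]] = {ch: [] for ch in channel_names}
    n_beads = 0
    for set_name in images.set_names:
        for i in range(images.n_files(set_name)):
            bf = images[set_name, i, bright_field]
            mask = beadfind.adaptive_threshold(bf, **thr_cfg)
            masks, morph = beadfind.segment_beads(mask, **seg_cfg)
            n_beads += len(morph)
            core = masks.core > 0
            if not core.any():
                continue
            for ch in channel_names:
                core_pixels[ch].append(images[set_name, i, ch][core])
    if n_beads == 0:
        raise ValueError(
            f"no beads found in reference image set(s) {images.set_names}"
        )
    return np.array(
        [np.median(np.concatenate(core_pixels[ch])) for ch in channel_names]
    )


def background_spectrum(
    images: ImageSet,
    roi: tuple[int, int, int, int],
    channel_names: list[str],
    bead_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-channel median over a bead-free rectangular region.

    *roi* is ``(row0, col0, height, width)``, 0-based half-open.  Pixels are
    pooled across all files of all sets.  When a *bead_mask* (any nonzero =
    bead) is supplied and the region overlaps it, a warning is logged but the
    spectrum is still computed.
    """
    row0, col0, height, width = roi
    if height <= 0 or width <= 0:
        raise ValueError(f"empty background region: {roi}")
    if bead_mask is not None and np.any(
        np.asarray(bead_mask)[row0 : row0 + height, col0 : col0 + width]
    ):
        logger.warning("background region %s overlaps identified beads", roi)
    values: dict[str, list[np.ndarray]] = {ch: [] for ch in channel_names}
    for set_name in images.set_names:
        for i in range(images.n_files(set_name)):
            for ch in channel_names:
                grid = images[set_name, i, ch]
                if row0 + height > grid.shape[0] or col0 + width > grid.shape[1]:
                    raise ValueError(
                        f"roi {roi} out of bounds for image shape {grid.shape}"
                    )
                values[ch].append(
                    grid[row0 : row0 + height, col0 : col0 + width].ravel()
                )
    return np.array(
        [np.median(np.concatenate(values[ch])) for ch in channel_names]
    )


def assemble(
    spectra: dict[str, np.ndarray],
    background: np.ndarray,
    channels: list[str],
) -> ReferenceMatrix:
    """Stack named species spectra plus the background spectrum into a matrix.

    Column order follows the insertion order of *spectra*, with background
    last; each column is normalized to unit sum.
    """
    names = list(spectra)
    cols = [np.asarray(spectra[n], dtype=float) for n in names]
    cols.append(np.asarray(background, dtype=float))
    names.append(BACKGROUND_NAME)
    for name, col in zip(names, cols):
        if col.shape != (len(channels),):
            raise ValueError(
                f"spectrum {name!r} has length {col.shape}, expected {len(channels)}"
            )
    return ReferenceMatrix(channels=list(channels), names=names, A=np.column_stack(cols))


def save_reference_csv(matrix: ReferenceMatrix, path: str | Path) -> Path:
    """Write the matrix as CSV: first column ``channel``, one column per reference."""
    path = Path(path)
    df = pd.DataFrame(matrix.A, columns=matrix.names)
    df.insert(0, "channel", matrix.channels)
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def load_reference_csv(path: str | Path) -> ReferenceMatrix:
    """Load a reference matrix from the CSV dialect written by :func:`save_reference_csv`."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc
    if "channel" not in df.columns:
        raise ValueError(f"{path}: missing required header column 'channel'")
    names = [c for c in df.columns if c != "channel"]
    values = df[names]
    numeric = values.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        rows, cols = np.nonzero(numeric.isna().to_numpy())
        raise ValueError(
            f"{path}: non-numeric value at data row {rows[0] + 1}, "
            f"column {names[cols[0]]!r}"
        )
    return ReferenceMatrix(
        channels=[str(c) for c in df["channel"]],
        names=names,
        A=numeric.to_numpy(dtype=float),
    )
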
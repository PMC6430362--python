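"""Loading, indexing, cropping and illumination-correcting multi-channel image sets.

Bead assays are imaged at many stage positions, each position yielding one
multi-channel file: a bright-field image for bead finding, several narrow-band
emission channels for decoding the embedded spectral code, and one or more
fluorescence channels for quantifying bound probe.  :class:`ImageSet` is the
in-memory container for such data, addressed by ``(set name, file index,
channel name)``.

Conventions used throughout the package:

* pixel coordinates are ``(row, col)``, 0-based;
* rectangles are ``(row0, col0, height, width)``, half-open;
* intensities are finite and non-negative after loading.
"""

from __future__ import annotations

import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "ImageSet",
    "CorrectionImages",
    "load_image_folder",
    "from_arrays",
    "crop_roi",
    "flat_field_correct",
    "build_flat_field",
    "write_ome_tiff",
]


class ImageSet:
    """Keyed collection of 2-D intensity images.

    Data are organised as named *sets* (e.g. one per assay condition), each
    holding an ordered list of *files* (stage positions), each file a mapping
    of channel name to a 2-D array.  Lookup uses tuple indexing::

        images["Set A", 0, "Bright-field"]     # explicit set
        images[0, "Bright-field"]              # allowed when only one set

    All channels within one file share the same height and width, and channel
    names are unique within a file.
    """

    def __init__(self) -> None:
        self._sets: dict[str, list[dict[str, np.ndarray]]] = {}
        self._meta: dict[str, list[dict]] = {}

    # -- construction -----------------------------------------------------

    def add_file(
        self,
        set_name: str,
        channels: dict[str, np.ndarray],
        meta: dict | None = None,
    ) -> None:
        """Append one multi-channel file to a set, validating the invariants."""
        if not channels:
            raise ValueError("a file must contain at least one channel")
        shapes = {np.asarray(g).shape for g in channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels of one file must share a shape, got {shapes}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError(f"channels must be 2-D, got shape {shape}")
        clean: dict[str, np.ndarray] = {}
        for name, grid in channels.items():
            arr = np.asarray(grid)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if np.issubdtype(arr.dtype, np.floating) and (arr < 0).any():
                logger.warning("channel %r has negative pixels; clipping to 0", name)
                arr = np.clip(arr, 0, None)
            clean[name] = arr
        self._sets.setdefault(set_name, []).append(clean)
        self._meta.setdefault(set_name, []).append(dict(meta or {}))

    # -- introspection ----------------------------------------------------

    @property
    def set_names(self) -> list[str]:
        return list(self._sets)

    def n_files(self, set_name: str | None = None) -> int:
        return len(self._sets[self._resolve_set(set_name)])

    def channel_names(self, set_name: str | None = None, index: int = 0) -> list[str]:
        return list(self._sets[self._resolve_set(set_name)][index])

    def file_meta(self, set_name: str | None, index: int) -> dict:
        return self._meta[self._resolve_set(set_name)][index]

    def files(self, set_name: str | None = None) -> list[dict[str, np.ndarray]]:
        return self._sets[self._resolve_set(set_name)]

    def _resolve_set(self, set_name: str | None) -> str:
        if set_name is not None:
            if set_name not in self._sets:
                raise KeyError(f"unknown set {set_name!r}")
            return set_name
        if len(self._sets) != 1:
            raise KeyError(
                "set name required when the ImageSet holds multiple sets: "
                f"{sorted(self._sets)}"
            )
        return next(iter(self._sets))

    # -- addressing -------------------------------------------------------

    def __getitem__(self, key):
        if not isinstance(key, tuple):
            raise KeyError("use (set, index, channel), (index, channel) or (set, index)")
        if len(key) == 3:
            set_name, index, channel = key
        elif len(key) == 2 and isinstance(key[0], (int, np.integer)):
            set_name, (index, channel) = None, key
        elif len(key) == 2:
            set_name, index = key
            return dict(self._sets[self._resolve_set(set_name)][index])
        else:
            raise KeyError(f"bad key {key!r}")
        file = self._sets[self._resolve_set(set_name)][index]
        if channel not in file:
            raise KeyError(
                f"unknown channel {channel!r}; available: {sorted(file)}"
            )
        return file[channel]

    def __contains__(self, set_name: str) -> bool:
        return set_name in self._sets

    def __len__(self) -> int:
        return sum(len(v) for v in self._sets.values())

    def map(self, fn, channels: set[str] | None = None) -> "ImageSet":
        """Return a new ImageSet with ``fn(grid)`` applied per channel.

        When *channels* is given, only those channels are transformed; other
        channels are carried over untouched (same array objects).
        """
        out = ImageSet()
        for set_name, files in self._sets.items():
            for i, file in enumerate(files):
                new = {
                    ch: (fn(g) if channels is None or ch in channels else g)
                    for ch, g in file.items()
                }
                out.add_file(set_name, new, self._meta[set_name][i])
        return out


@dataclass
class CorrectionImages:
    """Flat-field and dark-field correction images.

    ``flat_field`` is normalized to unit mean and strictly positive, so that
    division corrects spatial illumination heterogeneity while preserving the
    average intensity scale.  ``dark_field`` is the mean camera offset image
    subtracted before division.
    """

    flat_field: np.ndarray
    dark_field: np.ndarray

    def __post_init__(self) -> None:
        self.flat_field = np.asarray(self.flat_field, dtype=float)
        self.dark_field = np.asarray(self.dark_field, dtype=float)
        if self.flat_field.shape != self.dark_field.shape:
            raise ValueError("flat_field and dark_field shapes differ")
        if (self.flat_field <= 0).any():
            raise ValueError("flat_field must be strictly positive after normalization")
        if (self.dark_field < 0).any():
            raise ValueError("dark_field must be non-negative")


# ---------------------------------------------------------------------------
# loading


def _ome_channel_names(tif: tifffile.TiffFile) -> list[str] | None:
    """Channel names from OME-XML metadata, if present."""
    xml = tif.ome_metadata
    if not xml:
        return None
    try:
        root = ET.fromstring(xml)
    except ET.ParseError:
        return None
    names = [
        el.get("Name")
        for el in root.iter()
        if el.tag.endswith("Channel") and el.get("Name")
    ]
    return names or None


def _read_stack(path: Path) -> np.ndarray:
    """Read a TIFF as a (channels, height, width) stack."""
    with tifffile.TiffFile(path) as tif:
        arr = tif.series[0].asarray()
    arr = np.squeeze(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected 2-D or 3-D image data, got {arr.shape}")
    return arr


def load_image_folder(
    folder: str | Path,
    file_pattern: str,
    channel_names: list[str] | None = None,
    set_name: str = "set",
) -> ImageSet:
    """Load all TIFF files in *folder* whose name matches *file_pattern*.

    The pattern is a regular expression; its first capture group, when
    present, is the integer file (stage position) index used to order files.
    Channel names are taken from embedded OME metadata when available,
    otherwise from *channel_names*, otherwise ``ch0..chN``.  On a conflict
    between OME metadata and *channel_names* the metadata wins with a logged
    warning.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise FileNotFoundError(f"folder does not exist: {folder}")
    regex = re.compile(file_pattern)
    matched: list[tuple[int, Path]] = []
    for i, path in enumerate(sorted(folder.iterdir())):
        m = regex.search(path.name)
        if m is None:
            continue
        index = int(m.group(1)) if m.groups() else i
        matched.append((index, path))
    if not matched:
        raise FileNotFoundError(
            f"empty set: no file in {folder} matches pattern {file_pattern!r}"
        )
    matched.sort(key=lambda t: t[0])

    images = ImageSet()
    for _, path in matched:
        stack = _read_stack(path)
        n = stack.shape[0]
        with tifffile.TiffFile(path) as tif:
            ome_names = _ome_channel_names(tif)
        if ome_names is not None and len(ome_names) == n:
            names = ome_names
            if channel_names is not None and list(channel_names) != names:
                logger.warning(
                    "%s: OME channel names %s override provided names %s",
                    path.name, names, list(channel_names),
                )
        elif channel_names is not None:
            if len(channel_names) != n:
                raise ValueError(
                    f"{path.name}: {n} channels in file but "
                    f"{len(channel_names)} channel names provided"
                )
            names = list(channel_names)
        else:
            names = [f"ch{i}" for i in range(n)]
        images.add_file(
            set_name,
            {name: stack[i] for i, name in enumerate(names)},
            meta={"source": str(path)},
        )
    return images


def from_arrays(
    stacks: dict[str, list[np.ndarray] | np.ndarray],
    channel_names: list[str],
) -> ImageSet:
    """Build an ImageSet from in-memory arrays.

    *stacks* maps set name to either a single ``(c, h, w)`` array (one file)
    or a sequence of such arrays (one per file); the leading axis must equal
    ``len(channel_names)``.
    """
    images = ImageSet()
    for set_name, entry in stacks.items():
        arr = np.asarray(entry) if not isinstance(entry, (list, tuple)) else entry
        files = [arr] if isinstance(arr, np.ndarray) and arr.ndim == 3 else list(arr)
        for stack in files:
            stack = np.asarray(stack)
            if stack.ndim != 3 or stack.shape[0] != len(channel_names):
                raise ValueError(
                    f"set {set_name!r}: stack shape {stack.shape} does not match "
                    f"{len(channel_names)} channel names"
                )
            images.add_file(
                set_name, {n: stack[i] for i, n in enumerate(channel_names)}
            )
    return images


# ---------------------------------------------------------------------------
# cropping and correction


def crop_roi(images: ImageSet, rect: tuple[int, int, int, int]) -> ImageSet:
    """Crop every channel of every file to ``rect = (row0, col0, height, width)``.

    The rectangle is 0-based and half-open; it must lie fully within bounds.
    """
    row0, col0, height, width = rect
    if min(row0, col0, height, width) < 0:
        raise ValueError(f"rect values must be non-negative, got {rect}")

    def _crop(grid: np.ndarray) -> np.ndarray:
        if row0 + height > grid.shape[0] or col0 + width > grid.shape[1]:
            raise ValueError(
                f"rect {rect} out of bounds for image of shape {grid.shape}"
            )
        return grid[row0 : row0 + height, col0 : col0 + width]

    return images.map(_crop)


def flat_field_correct(
    images: ImageSet, channel: str, corr: CorrectionImages
) -> ImageSet:
    """Apply ``(raw - dark_field) / flat_field`` to one channel, clipped at 0.

    Other channels are passed through untouched.  The flat field must already
    be unit-mean normalized (see :func:`build_flat_field`).
    """

    def _correct(grid: np.ndarray) -> np.ndarray:
        if grid.shape != corr.flat_field.shape:
            raise ValueError(
                f"correction shape {corr.flat_field.shape} does not match "
                f"image shape {grid.shape}"
            )
        out = (np.asarray(grid, dtype=float) - corr.dark_field) / corr.flat_field
        return np.clip(out, 0, None)

    return images.map(_correct, channels={channel})


def build_flat_field(
    tile_images: list[np.ndarray],
    dark_images: list[np.ndarray] | None = None,
) -> CorrectionImages:
    """Construct correction images from dye-tile and dark-camera exposures.

    The flat field is the per-pixel median of the tile images minus the
    per-pixel mean of the dark images, normalized to unit mean; the dark
    field is the per-pixel mean of the dark images (zero when none given).
    """
    if not tile_images:
        raise ValueError("at least one tile image is required")
    tiles = np.asarray([np.asarray(t, dtype=float) for t in tile_images])
    if dark_images:
        dark = np.mean([np.asarray(d, dtype=float) for d in dark_images], axis=0)
    else:
        dark = np.zeros(tiles.shape[1:])
    if dark.shape != tiles.shape[1:]:
        raise ValueError("dark image shape does not match tile image shape")
    flat = np.median(tiles, axis=0) - dark
    mean = flat.mean()
    if mean <= 0 or (flat <= 0).any():
        raise ValueError(
            "flat field is not strictly positive after dark subtraction; "
            "check tile/dark image pairing"
        )
    return CorrectionImages(flat_field=flat / mean, dark_field=dark)


# ---------------------------------------------------------------------------
# writing


def write_ome_tiff(
    path: str | Path,
    channels: dict[str, np.ndarray],
    dtype=None,
) -> Path:
    """Write one multi-channel file as OME-TIFF with channel names in metadata."""
    path = Path(path)
    names = list(channels)
    stack = np.stack([np.asarray(channels[n]) for n in names])
    if dtype is not None:
        stack = stack.astype(dtype)
    tifffile.imwrite(
        path,
        stack,
        ome=True,
        metadata={"axes": "CYX", "Channel": {"Name": names}},
    )
    return path
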
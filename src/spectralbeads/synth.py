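"""Seeded generator of synthetic encoded-bead scenes with ground truth.

The generator renders the imaging model the pipeline is built for, so the
whole analysis chain can be exercised and scored without microscope data:

* **bright-field** — bright background with a dark ring at each bead edge
  (and a slightly darkened core), the appearance hydrogel beads have in
  transmitted light;
* **emission channels** — each bead-core pixel carries the linear mixture
  ``A @ w`` of the reference spectra, where the weight vector ``w`` is the
  bead's code ratios times a per-bead draw of the invariant-species level,
  on top of a constant background-spectrum term and Gaussian read noise;
* **fluorescence channel** — a thin bright ring at each bead perimeter
  (bound probe) over a background, both modulated by a smooth illumination
  gradient;
* **artifacts** — bead-like objects (air bubbles) that look like beads in
  bright-field but contain no embedded luminescence, for exercising the
  non-bead filter.

Per-bead code noise is drawn per ratio dimension with SD expressed as a
fraction of the nearest-level spacing of the target table, optionally grown
linearly with the ratio level (Poisson-like encapsulation noise).  Every
rendered object is recorded in a ground-truth manifest.  All randomness
flows from the single seed in the scene spec; the same spec renders
bit-identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .decode import TargetCodeTable
from .imageio import ImageSet, write_ome_tiff
from .references import BACKGROUND_NAME, ReferenceMatrix

__all__ = [
    "SceneSpec",
    "default_reference_matrix",
    "default_target_table",
    "generate_scene",
    "generate_reference_set",
    "write_scene",
    "match_to_manifest",
]

DEFAULT_CHANNELS = [
    "435nm", "474nm", "536nm", "546nm", "572nm", "620nm", "630nm", "650nm", "780nm",
]


def default_reference_matrix(
    channels: list[str] | None = None,
    lnps: tuple[str, ...] = ("Dy", "Sm", "Tm", "Eu"),
) -> ReferenceMatrix:
    """Synthetic but realistic reference spectra: one narrow emission bump per
    species at a distinct channel, a broad flat background column."""
    channels = list(channels or DEFAULT_CHANNELS)
    c = len(channels)
    idx = np.arange(c)
    peaks = np.linspace(0.5, c - 1.5, num=len(lnps))
    cols = []
    for peak in peaks:
        col = np.exp(-0.5 * ((idx - peak) / 0.9) ** 2) + 0.02
        cols.append(col)
    background = np.full(c, 1.0)
    A = np.column_stack(cols + [background])
    return ReferenceMatrix(
        channels=channels, names=list(lnps) + [BACKGROUND_NAME], A=A
    )


def default_target_table() -> TargetCodeTable:
    """48-code design: 4 Dy x 4 Sm x 3 Tm ratio levels against the Eu reference."""
    return TargetCodeTable.from_levels(
        {
            "Dy.Eu": [0.0, 0.3, 0.6, 0.9],
            "Sm.Eu": [0.0, 0.3, 0.6, 0.9],
            "Tm.Eu": [0.0, 0.45, 0.9],
        }
    )


@dataclass
class SceneSpec:
    """Study conditions for one synthetic scene set.

    ``beads_per_code`` spreads each code over the files round-robin;
    alternatively set ``n_beads`` for code-agnostic scenes.  Distances are
    pixels, intensities camera counts.
    """

    image_shape: tuple[int, int] = (512, 512)
    n_files: int = 1
    bead_diameter_px: int = 14
    ring_width_px: int = 2
    min_separation_px: int = 2
    targets: TargetCodeTable = field(default_factory=default_target_table)
    reference: ReferenceMatrix = field(default_factory=default_reference_matrix)
    beads_per_code: int | None = None
    n_beads: int | None = 20
    n_artifacts: int = 0
    invariant_lnp: str = "Eu"
    eu_level_mean: float = 1000.0
    eu_level_sd: float = 50.0
    background_level: float = 100.0
    ratio_noise_frac: float = 0.10  # x nearest-level spacing, per dimension
    level_noise_slope: float = 0.0  # extra SD per unit ratio level
    read_noise_sd: float = 2.0
    bf_background: float = 200.0
    bf_ring: float = 50.0
    bf_core: float = 190.0
    fluor_background: float = 50.0
    fluor_signal: float = 500.0
    fluor_signal_sd: float = 20.0
    illumination_gradient: float = 0.15
    bright_field_name: str = "Bright-field"
    fluor_name: str = "Cy5"
    seed: int = 0


def _place_centers(
    rng: np.random.Generator, spec: SceneSpec, n_objects: int
) -> np.ndarray:
    """Non-overlapping integer centers on a jittered grid, margin-safe.

    Cells are sized so that even adjacent jittered beads keep the minimum
    separation; requesting more objects than cells is an error.
    """
    h, w = spec.image_shape
    margin = spec.bead_diameter_px // 2 + spec.min_separation_px + 2
    cell = spec.bead_diameter_px + spec.min_separation_px + 2
    rows = (h - 2 * margin) // cell
    cols = (w - 2 * margin) // cell
    if rows * cols < n_objects:
        raise ValueError(
            f"cannot place {n_objects} objects of diameter {spec.bead_diameter_px} px "
            f"in a {h}x{w} image without overlap; reduce the count or enlarge the image"
        )
    cells = [(r, c) for r in range(rows) for c in range(cols)]
    chosen = rng.permutation(len(cells))[:n_objects]
    jitter_max = 1  # cell size leaves 2 px of slack; +-1 px keeps separation
    centers = []
    for k in chosen:
        r, c = cells[k]
        jr, jc = rng.integers(-jitter_max, jitter_max + 1, size=2)
        centers.append(
            (margin + r * cell + cell // 2 + jr, margin + c * cell + cell // 2 + jc)
        )
    return np.array(centers, dtype=int)


def _disk_masks(spec: SceneSpec, center: tuple[int, int], shape: tuple[int, int]):
    """Boolean core and ring index windows for one bead."""
    radius = spec.bead_diameter_px / 2.0
    r0, c0 = center
    size = int(np.ceil(radius)) + 1
    rr = np.arange(max(r0 - size, 0), min(r0 + size + 1, shape[0]))
    cc = np.arange(max(c0 - size, 0), min(c0 + size + 1, shape[1]))
    dist = np.hypot(rr[:, None] - r0, cc[None, :] - c0)
    inside = dist <= radius
    ring = inside & (dist > radius - spec.ring_width_px)
    core = inside & ~ring
    window = np.ix_(rr, cc)
    return window, core, ring


def _noisy_ratios(
    rng: np.random.Generator, spec: SceneSpec, code_row: np.ndarray
) -> np.ndarray:
    # single-level dimensions have no spacing: no spacing-scaled noise there
    spacing = np.nan_to_num(spec.targets.level_spacing(), nan=0.0)
    sd = spec.ratio_noise_frac * spacing + spec.level_noise_slope * code_row
    return code_row + rng.normal(0.0, 1.0, size=len(code_row)) * sd


def generate_scene(spec: SceneSpec) -> tuple[ImageSet, pd.DataFrame]:
    """Render a scene set and its ground-truth manifest.

    Returns an :class:`ImageSet` (one set, ``spec.n_files`` files, channels =
    bright-field + emission channels + fluorescence) and a manifest with one
    row per rendered object: file, center, diameter, code (-1 for
    artifacts), true ratios, invariant-species level, true fluorescence
    signal, and the artifact flag.
    """
    rng = np.random.default_rng(spec.seed)
    ref = spec.reference
    dims = spec.targets.dimensions
    lnp_names = ref.lnp_names
    variable = [d.split(".")[0] for d in dims]
    if spec.invariant_lnp not in lnp_names:
        raise ValueError(f"invariant species {spec.invariant_lnp!r} not in reference")
    A_lnp = np.column_stack([ref.column(n) for n in lnp_names])
    A_bg = ref.column(BACKGROUND_NAME)

    if spec.beads_per_code is not None:
        codes = np.repeat(np.arange(spec.targets.n_codes), spec.beads_per_code)
        codes = rng.permutation(codes)
    else:
        if spec.n_beads is None:
            raise ValueError("set either beads_per_code or n_beads")
        codes = rng.integers(0, spec.targets.n_codes, size=spec.n_beads)
    n_beads = len(codes)
    n_total = n_beads + spec.n_artifacts

    per_file = np.array_split(np.arange(n_total), spec.n_files)
    is_artifact = np.zeros(n_total, dtype=bool)
    is_artifact[n_beads:] = True
    order = rng.permutation(n_total)
    is_artifact = is_artifact[order]
    code_of = np.full(n_total, -1, dtype=int)
    code_of[~is_artifact] = codes

    images = ImageSet()
    records: list[dict] = []
    h, w = spec.image_shape
    gy, gx = np.mgrid[0:h, 0:w]
    illum = 1.0 + spec.illumination_gradient * (
        (gy + gx) / (h + w) - 0.5
    )

    obj_id = 0
    for file_index, obj_idx in enumerate(per_file):
        n_objects = len(obj_idx)
        centers = _place_centers(rng, spec, n_objects)
        bf = np.full((h, w), spec.bf_background)
        emission = np.einsum(
            "c,hw->chw", A_bg * spec.background_level, np.ones((h, w))
        )
        fluor = spec.fluor_background * illum

        for j, global_j in enumerate(obj_idx):
            center = tuple(centers[j])
            window, core, ring = _disk_masks(spec, center, (h, w))
            bf_win = bf[window]
            bf_win[core] = spec.bf_core
            bf_win[ring] = spec.bf_ring
            bf[window] = bf_win

            artifact = bool(is_artifact[global_j])
            code = int(code_of[global_j])
            eu_level = float(
                max(rng.normal(spec.eu_level_mean, spec.eu_level_sd), 1.0)
            )
            if artifact:
                true_ratios = np.full(len(dims), np.nan)
                fl_signal = 0.0
            else:
                true_ratios = _noisy_ratios(rng, spec, spec.targets.ratios[code])
                weights = np.zeros(len(lnp_names))
                for name, ratio in zip(variable, true_ratios):
                    weights[lnp_names.index(name)] = max(ratio, 0.0) * eu_level
                weights[lnp_names.index(spec.invariant_lnp)] = eu_level
                bead_spectrum = A_lnp @ weights  # counts per channel
                em_win = emission[(slice(None),) + window]
                em_win[:, core] += bead_spectrum[:, None]
                emission[(slice(None),) + window] = em_win
                fl_signal = float(
                    max(rng.normal(spec.fluor_signal, spec.fluor_signal_sd), 0.0)
                )
                fl_win = fluor[window]
                fl_win[ring] += fl_signal * illum[window][ring]
                fluor[window] = fl_win

            records.append(
                {
                    "object_id": obj_id,
                    "file": file_index,
                    "center_row": center[0],
                    "center_col": center[1],
                    "diameter": spec.bead_diameter_px,
                    "code": code,
                    **{f"true_{d}": r for d, r in zip(dims, true_ratios)},
                    "eu_level": eu_level if not artifact else np.nan,
                    "true_fluor": fl_signal,
                    "is_artifact": artifact,
                }
            )
            obj_id += 1

        if spec.read_noise_sd > 0:
            bf = bf + rng.normal(0, spec.read_noise_sd, bf.shape)
            emission = emission + rng.normal(0, spec.read_noise_sd, emission.shape)
            fluor = fluor + rng.normal(0, spec.read_noise_sd, fluor.shape)
        channels = {spec.bright_field_name: np.clip(bf, 0, None)}
        for ci, ch in enumerate(ref.channels):
            channels[ch] = np.clip(emission[ci], 0, None)
        channels[spec.fluor_name] = np.clip(fluor, 0, None)
        images.add_file("synthetic", channels, meta={"file_index": file_index})

    manifest = pd.DataFrame.from_records(records)
    return images, manifest


def generate_reference_set(spec: SceneSpec, lnp: str) -> ImageSet:
    """Scene whose beads carry the named species alone at maximum loading.

    The rendered emission of every bead core is ``eu_level x`` the species'
    spectrum column plus the scene background, matching how real reference
    beads are synthesized for spectrum measurement.
    """
    if lnp not in spec.reference.lnp_names:
        raise ValueError(
            f"unknown species {lnp!r}; reference has {spec.reference.lnp_names}"
        )
    rng = np.random.default_rng(spec.seed)
    ref = spec.reference
    n_beads = spec.n_beads or 20
    h, w = spec.image_shape
    images = ImageSet()
    for file_index in range(spec.n_files):
        centers = _place_centers(rng, spec, n_beads)
        bf = np.full((h, w), spec.bf_background)
        emission = np.einsum(
            "c,hw->chw", ref.column(BACKGROUND_NAME) * spec.background_level,
            np.ones((h, w)),
        )
        for j in range(n_beads):
            window, core, ring = _disk_masks(spec, tuple(centers[j]), (h, w))
            bf_win = bf[window]
            bf_win[core] = spec.bf_core
            bf_win[ring] = spec.bf_ring
            bf[window] = bf_win
            eu_level = float(
                max(rng.normal(spec.eu_level_mean, spec.eu_level_sd), 1.0)
            )
            em_win = emission[(slice(None),) + window]
            em_win[:, core] += (ref.column(lnp) * eu_level)[:, None]
            emission[(slice(None),) + window] = em_win
        if spec.read_noise_sd > 0:
            bf = bf + rng.normal(0, spec.read_noise_sd, bf.shape)
            emission = emission + rng.normal(0, spec.read_noise_sd, emission.shape)
        channels = {spec.bright_field_name: np.clip(bf, 0, None)}
        for ci, ch in enumerate(ref.channels):
            channels[ch] = np.clip(emission[ci], 0, None)
        images.add_file(f"ref_{lnp}", channels, meta={"file_index": file_index})
    return images


def write_scene(
    images: ImageSet, folder: str | Path, prefix: str = "scene"
) -> list[Path]:
    """Write every file of a scene as float32 OME-TIFF (``{prefix}_{index}.ome.tif``)."""
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    paths = []
    for set_name in images.set_names:
        for i in range(images.n_files(set_name)):
            path = folder / f"{prefix}_{i:03d}.ome.tif"
            write_ome_tiff(path, images[set_name, i], dtype=np.float32)
            paths.append(path)
    return paths


def match_to_manifest(
    table: pd.DataFrame, manifest: pd.DataFrame, max_dist: float | None = None
) -> pd.DataFrame:
    """Join detected beads to ground-truth objects by nearest centroid per file.

    Adds the matched manifest columns (prefixed ``true_`` where needed) to a
    copy of *table*; detections farther than *max_dist* (default: one bead
    radius) from any ground-truth object get no match (NaN columns).
    """
    if max_dist is None:
        max_dist = manifest["diameter"].iloc[0] / 2.0
    out = table.copy()
    matched_cols = ["object_id", "code", "is_artifact", "true_fluor"]
    for col in matched_cols:
        out["gt_" + col] = np.nan
    for file_index, grp in out.groupby("file"):
        truth = manifest[manifest["file"] == file_index]
        if truth.empty:
            continue
        tc = truth[["center_row", "center_col"]].to_numpy(float)
        dc = grp[["centroid_row", "centroid_col"]].to_numpy(float)
        d2 = ((dc[:, None, :] - tc[None, :, :]) ** 2).sum(axis=2)
        nearest = d2.argmin(axis=1)
        dist = np.sqrt(d2[np.arange(len(grp)), nearest])
        ok = dist <= max_dist
        for col in matched_cols:
            vals = truth[col].to_numpy()[nearest].astype(float)
            vals[~ok] = np.nan
            out.loc[grp.index, "gt_" + col] = vals
    out["gt_is_artifact"] = out["gt_is_artifact"].astype("boolean")
    return out
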
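"""Per-pixel linear spectral unmixing and ratiometric images.

Each pixel's vector of emission-channel intensities ``b`` is modelled as a
linear mixture of the reference spectra: ``A @ x = b`` where ``A`` is the
channels x references matrix and ``x`` the per-species weights.  Flattening
the image to a channels x pixels matrix ``B``, the ordinary least-squares
solution ``X = argmin ||A X - B||_2`` is computed with one shared QR
factorization of ``A`` reused for every pixel, then each row of ``X`` is
reshaped back into a "pseudo-intensity" image per species.

Weights are unconstrained: with noise they may dip slightly negative, and
that is preserved for QC.  Ratio images divide each variable species' weight
image by the invariant reference species' weight image (code coordinates are
ratios, insensitive to overall intensity); pixels whose reference weight does
not exceed a small floor are flagged missing (NaN) rather than producing
infinities.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import linalg

from .imageio import ImageSet
from .references import BACKGROUND_NAME, ReferenceMatrix

logger = logging.getLogger(__name__)

__all__ = ["unmix", "ratio_images", "unmix_imageset", "ratio_name"]


def ratio_name(variable: str, reference: str) -> str:
    """Channel name used for the *variable*/*reference* ratio image."""
    return f"{variable}.{reference}"


def _check_rank(ref: ReferenceMatrix) -> None:
    """Raise for a rank-deficient reference matrix, naming collinear columns."""
    _, R, piv = linalg.qr(ref.A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(ref.A.shape) * np.finfo(float).eps
    deficient = diag <= tol
    if deficient.any():
        bad = [ref.names[piv[i]] for i in np.nonzero(deficient)[0]]
        raise ValueError(
            f"reference matrix is rank-deficient; collinear column(s): {bad}"
        )


def unmix(ref: ReferenceMatrix, channels: np.ndarray) -> dict[str, np.ndarray]:
    """Solve the least-squares mixture per pixel.

    *channels* is a ``(c, h, w)`` stack (or ``(c, p)`` matrix) whose leading
    axis matches ``ref.channels``.  Returns one weight grid per reference
    name, each with the spatial shape of the input.
    """
    stack = np.asarray(channels, dtype=float)
    if stack.shape[0] != len(ref.channels):
        raise ValueError(
            f"{stack.shape[0]} channel images but reference matrix has "
            f"{len(ref.channels)} channels"
        )
    _check_rank(ref)
    spatial = stack.shape[1:]
    B = stack.reshape(stack.shape[0], -1)
    # one shared factorization of A for all pixels/files
    Q, R = linalg.qr(ref.A, mode="economic")
    X = linalg.solve_triangular(R, Q.T @ B)
    return {
        name: X[j].reshape(spatial) for j, name in enumerate(ref.names)
    }


def ratio_images(
    weights: dict[str, np.ndarray],
    reference_lnp: str,
    floor: float | None = None,
) -> dict[str, np.ndarray]:
    """Divide each variable species' weights by the invariant reference's.

    Pixels where the reference weight is not above *floor* (default
    ``1e-12 x max reference weight``) are NaN.  The background column is
    never ratioed.
    """
    if reference_lnp not in weights:
        raise ValueError(
            f"reference species {reference_lnp!r} not among {sorted(weights)}"
        )
    if reference_lnp == BACKGROUND_NAME:
        raise ValueError("the background column cannot serve as ratio reference")
    w_ref = np.asarray(weights[reference_lnp], dtype=float)
    if floor is None:
        floor = 1e-12 * max(w_ref.max(), 0.0)
    defined = w_ref > floor
    out: dict[str, np.ndarray] = {}
    for name, grid in weights.items():
        if name in (reference_lnp, BACKGROUND_NAME):
            continue
        ratio = np.full(w_ref.shape, np.nan)
        np.divide(np.asarray(grid, dtype=float), w_ref, out=ratio, where=defined)
        out[ratio_name(name, reference_lnp)] = ratio
    return out


def unmix_imageset(
    ref: ReferenceMatrix,
    images: ImageSet,
    reference_lnp: str | None = None,
    floor: float | None = None,
) -> ImageSet:
    """Unmix every file of an ImageSet; optionally append ratio channels.

    The output ImageSet mirrors the input's set/file structure with one
    channel per reference name (weight images) and, when *reference_lnp* is
    given, one ``variable.reference`` channel per variable species.
    """
    out = ImageSet()
    for set_name in images.set_names:
        for i in range(images.n_files(set_name)):
            stack = np.stack([images[set_name, i, ch] for ch in ref.channels])
            weights = unmix(ref, stack)
            channels = dict(weights)
            if reference_lnp is not None:
                channels.update(ratio_images(weights, reference_lnp, floor=floor))
            # bypass add_file validation: weight grids may be slightly
            # negative and ratio grids carry NaN missing-flags by design
            out._sets.setdefault(set_name, []).append(channels)
            out._meta.setdefault(set_name, []).append(
                dict(images.file_meta(set_name, i))
            )
    return out
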
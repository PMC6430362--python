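"""Code assignment: ICP registration of ratio clusters onto designed targets, GMM classification.

A bead library is designed on a grid of target ratio coordinates (one
d-dimensional point per code, e.g. Dy/Eu, Sm/Eu, Tm/Eu).  Measured per-bead
ratios reproduce this pattern up to an affine distortion — scaling when the
reference beads carried different species loadings than the assay beads,
offsets from buffer or background shifts.  Decoding therefore proceeds in
two stages:

1. **Trimmed iterative closest point (ICP).**  Beads are matched to their
   nearest targets, the top percentile of worst-matched beads is trimmed,
   and a full affine transform (d x d matrix ``T`` plus offset ``o``, row
   vectors, data -> target direction) is re-estimated by least squares.
   Iteration stops when the relative change of the transform

       delta = (sum((T_new - T_old)^2) + sum((o_new - o_old)^2))
               / (sum(T_new^2) + sum(o_new^2))

   falls below a tolerance.  The initial transform is a diagonal scaling of
   per-dimension SD ratios with a mean-matching offset, which is robust to
   outliers and to codes missing at the edge of the code space.

2. **Supervised Gaussian mixture.**  One full-covariance component per code,
   means initialized at the target coordinates, equal initial weights, and a
   small isotropic initial covariance (sigma0, default 1e-5).  Because the
   means start on the targets, the component index *is* the code index; each
   bead receives the code of its maximum-responsibility component together
   with that responsibility (probability) and its log.

Quality metrics: ICP iteration count, number of clusters found, the list of
designed codes with no assigned beads, per-cluster confidence ellipses from
the covariance eigendecomposition, and the mean silhouette coefficient of
the assignment (1 for point-like clusters, near 0 for unclustered data).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

__all__ = [
    "TargetCodeTable",
    "IcpResult",
    "DecodeResult",
    "initial_transform",
    "icp_align",
    "gmm_classify",
    "confidence_ellipse",
    "cluster_quality",
    "decode",
]


@dataclass
class TargetCodeTable:
    """Designed ratio coordinates per code.

    ``ratios`` has one row per code, ordered by code index 0..N-1;
    ``dimensions`` names the ratio axes (e.g. ``["Dy.Eu", "Sm.Eu", "Tm.Eu"]``).
    """

    ratios: np.ndarray
    dimensions: list[str]

    def __post_init__(self) -> None:
        self.ratios = np.atleast_2d(np.asarray(self.ratios, dtype=float))
        if self.ratios.shape[1] != len(self.dimensions):
            raise ValueError("ratio width does not match number of dimensions")
        uniq = np.unique(self.ratios, axis=0)
        if len(uniq) != len(self.ratios):
            raise ValueError("target code coordinates must be pairwise distinct")

    @property
    def n_codes(self) -> int:
        return len(self.ratios)

    @classmethod
    def from_levels(cls, levels: dict[str, list[float]]) -> "TargetCodeTable":
        """Full factorial grid over per-dimension level lists (N = product of level counts)."""
        dims = list(levels)
        grids = np.meshgrid(*[np.asarray(levels[d], float) for d in dims], indexing="ij")
        ratios = np.column_stack([g.ravel() for g in grids])
        return cls(ratios=ratios, dimensions=dims)

    @classmethod
    def read_csv(cls, path: str | Path) -> "TargetCodeTable":
        df = pd.read_csv(path)
        if "code" not in df.columns:
            raise ValueError(f"{path}: missing 'code' column")
        df = df.sort_values("code")
        dims = [c for c in df.columns if c != "code"]
        return cls(ratios=df[dims].to_numpy(float), dimensions=dims)

    def to_csv(self, path: str | Path) -> Path:
        df = pd.DataFrame(self.ratios, columns=self.dimensions)
        df.insert(0, "code", np.arange(self.n_codes))
        df.to_csv(path, index=False)
        return Path(path)

    def level_spacing(self) -> np.ndarray:
        """Smallest gap between distinct levels, per dimension."""
        out = []
        for j in range(self.ratios.shape[1]):
            lv = np.unique(self.ratios[:, j])
            out.append(np.diff(lv).min() if len(lv) > 1 else np.nan)
        return np.array(out)


@dataclass
class IcpResult:
    """Affine registration result: ``transformed = raw @ T + o``."""

    T: np.ndarray
    o: np.ndarray
    n_iterations: int
    converged: bool
    transformed: np.ndarray
    delta_history: list[float] = field(default_factory=list)
    trimmed_fraction: list[float] = field(default_factory=list)


@dataclass
class DecodeResult:
    """Full decode output: per-bead assignments plus per-code and global QC."""

    beads: pd.DataFrame  # code, log_prob, prob per bead (input order)
    means: np.ndarray  # n_codes x d fitted cluster means
    covariances: np.ndarray  # n_codes x d x d
    counts: np.ndarray  # beads per code
    ellipses: list[dict]  # axis lengths + orientation per code
    clusters_found: int
    missing_codes: list[int]
    silhouette: float | None
    icp: IcpResult | None = None


def initial_transform(
    ratios: np.ndarray,
    targets: TargetCodeTable,
    direction: str = "data_to_target",
) -> tuple[np.ndarray, np.ndarray]:
    """Outlier-robust diagonal initialization for ICP.

    Per dimension, the scale is the ratio of target-level spread (SD) to
    observed-ratio spread (SD, ddof=0), so that ``ratios @ T0 + o0`` matches
    the targets' spread and mean.  ``direction="target_to_data"`` returns the
    reciprocal convention instead.
    """
    X = np.atleast_2d(np.asarray(ratios, dtype=float))
    if len(X) < 2:
        raise ValueError("at least 2 beads are required for the initial transform")
    sd_data = X.std(axis=0)
    sd_target = targets.ratios.std(axis=0)
    for name, sds in (("data", sd_data), ("targets", sd_target)):
        if np.any(sds == 0):
            dim = targets.dimensions[int(np.argmin(sds))]
            raise ValueError(f"zero spread in {name} along dimension {dim!r}")
    if direction == "data_to_target":
        scale = sd_target / sd_data
        T0 = np.diag(scale)
        o0 = targets.ratios.mean(axis=0) - X.mean(axis=0) @ T0
    elif direction == "target_to_data":
        scale = sd_data / sd_target
        T0 = np.diag(scale)
        o0 = X.mean(axis=0) - targets.ratios.mean(axis=0) @ T0
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return T0, o0


def _transform_cost(
    T_new: np.ndarray, T_old: np.ndarray, o_new: np.ndarray, o_old: np.ndarray
) -> float:
    """Relative change of the affine transform between two ICP iterations."""
    num = np.sum((T_new - T_old) ** 2) + np.sum((o_new - o_old) ** 2)
    den = np.sum(T_new**2) + np.sum(o_new**2)
    return float(num / den)


def icp_align(
    ratios: np.ndarray,
    targets: TargetCodeTable,
    trim_pct: float = 1.0,
    tol: float = 1e-4,
    max_iter: int = 100,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> IcpResult:
    """Register observed ratios onto target codes by trimmed ICP.

    Each iteration: (a) transform the raw ratios with the current (T, o) and
    match every bead to its nearest target by Euclidean distance (ties to
    the lower code index); (b) drop the *trim_pct* percent of beads with the
    largest matched distance (recomputed fresh each iteration); (c) re-solve
    the augmented least-squares system mapping surviving **raw** ratios to
    their matched targets; (d) stop when the transform-change cost drops to
    *tol* or *max_iter* is reached.
    """
    X = np.atleast_2d(np.asarray(ratios, dtype=float))
    n, d = X.shape
    if n < targets.n_codes:
        logger.warning(
            "only %d beads for %d target codes; registration may be unstable",
            n, targets.n_codes,
        )
    if not 0 <= trim_pct < 100:
        raise ValueError(f"trim_pct must be in [0, 100), got {trim_pct}")
    if init is not None:
        T, o = init
    else:
        # the initial scaling must not be driven by gross outliers: estimate
        # it on the beads closest to the data's median centre, excluding the
        # same top percentile that ICP trims each iteration
        drop = max(trim_pct, 1.0)
        center_dist = np.linalg.norm(X - np.median(X, axis=0), axis=1)
        robust = X[center_dist <= np.percentile(center_dist, 100 - drop)]
        T, o = initial_transform(robust if len(robust) >= 2 else X, targets)
    T = np.asarray(T, dtype=float)
    o = np.asarray(o, dtype=float)

    aug = np.column_stack([X, np.ones(n)])
    deltas: list[float] = []
    trimmed: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        moved = X @ T + o
        dists = cdist(moved, targets.ratios)
        nearest = np.argmin(dists, axis=1)  # argmin takes the first (lowest) index on ties
        d_near = dists[np.arange(n), nearest]
        if trim_pct > 0:
            cutoff = np.percentile(d_near, 100 - trim_pct)
            keep = d_near <= cutoff
        else:
            keep = np.ones(n, dtype=bool)
        trimmed.append(1.0 - keep.mean())
        M, *_ = np.linalg.lstsq(aug[keep], targets.ratios[nearest[keep]], rcond=None)
        T_new, o_new = M[:d], M[d]
        delta = _transform_cost(T_new, T, o_new, o)
        if not np.isfinite(delta):
            raise FloatingPointError(
                f"ICP diverged at iteration {it}; delta history: {deltas}"
            )
        deltas.append(delta)
        T, o = T_new, o_new
        if delta <= tol:
            converged = True
            break
    if not converged:
        logger.warning("ICP did not converge within %d iterations", max_iter)
    return IcpResult(
        T=T,
        o=o,
        n_iterations=it,
        converged=converged,
        transformed=X @ T + o,
        delta_history=deltas,
        trimmed_fraction=trimmed,
    )


class _FixedWeightGMM(GaussianMixture):
    """GaussianMixture whose component weights stay frozen at their initial values."""

    def _m_step(self, X, log_resp):
        super()._m_step(X, log_resp)
        self.weights_ = np.full(self.n_components, 1.0 / self.n_components)


def gmm_classify(
    transformed: np.ndarray,
    targets: TargetCodeTable,
    sigma0: float = 1e-5,
    seed: int = 0,
    max_iter: int = 100,
    freeze_weights: bool = False,
) -> tuple[pd.DataFrame, GaussianMixture]:
    """Assign each bead a code with a supervised full-covariance Gaussian mixture.

    One component per code; means initialized at the target coordinates,
    weights equal, covariances at ``sigma0 * I``.  EM then refines means,
    covariances and (unless frozen) weights.  Returns a per-bead frame with
    ``code``, ``prob`` (the assigned component's responsibility, normalized
    over codes by log-sum-exp) and ``log_prob``, plus the fitted mixture.
    """
    X = np.atleast_2d(np.asarray(transformed, dtype=float))
    if len(X) == 0:
        raise ValueError("no beads to classify")
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")
    n_codes, d = targets.ratios.shape
    cls = _FixedWeightGMM if freeze_weights else GaussianMixture
    gmm = cls(
        n_components=n_codes,
        covariance_type="full",
        weights_init=np.full(n_codes, 1.0 / n_codes),
        means_init=targets.ratios,
        precisions_init=np.repeat(np.eye(d)[None] / sigma0, n_codes, axis=0),
        random_state=seed,
        max_iter=max_iter,
    )
    gmm.fit(X)
    if not (np.all(np.isfinite(gmm.means_)) and np.all(np.isfinite(gmm.covariances_))):
        raise FloatingPointError(
            "mixture component collapsed (non-finite parameters); "
            "try a larger sigma0"
        )
    resp = gmm.predict_proba(X)
    code = resp.argmax(axis=1)
    prob = resp[np.arange(len(X)), code]
    with np.errstate(divide="ignore"):
        log_prob = np.log(prob)
    beads = pd.DataFrame({"code": code, "prob": prob, "log_prob": log_prob})
    return beads, gmm


def confidence_ellipse(
    covariance: np.ndarray, level: float = 0.95
) -> dict:
    """Principal-axis description of a cluster confidence ellipse.

    Axis length per principal direction is ``2 * z * sqrt(eigenvalue)``
    where ``z`` is the two-sided normal quantile of *level* (1.96 at 95%).
    Returns axis lengths (descending), the eigenvector matrix (columns), and
    for 2-D input the major-axis angle in degrees.
    """
    cov = np.asarray(covariance, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be a square matrix")
    if not np.allclose(cov, cov.T, atol=1e-10 * max(1.0, np.abs(cov).max())):
        raise ValueError("covariance must be symmetric")
    z = sps.norm.ppf(0.5 + level / 2.0)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals = np.clip(eigvals, 0, None)
    lengths = 2.0 * z * np.sqrt(eigvals)
    out = {"axis_lengths": lengths, "axes": eigvecs, "level": level}
    if cov.shape[0] == 2:
        out["angle_deg"] = float(
            np.degrees(np.arctan2(eigvecs[1, 0], eigvecs[0, 0]))
        )
    return out


def cluster_quality(
    transformed: np.ndarray,
    assignments: np.ndarray,
    targets: TargetCodeTable,
) -> tuple[int, list[int], float | None]:
    """Clusters found, missing designed codes, and mean silhouette coefficient.

    The silhouette is computed on the transformed ratios with the assigned
    labels; it is ``None`` (undefined) when fewer than 2 distinct codes are
    present.  For well-separated clustered data it lies in (0, 1], reaching
    exactly 1 when every cluster is a single point.
    """
    X = np.atleast_2d(np.asarray(transformed, dtype=float))
    labels = np.asarray(assignments)
    present = np.unique(labels)
    clusters_found = len(present)
    missing = sorted(set(range(targets.n_codes)) - set(int(c) for c in present))
    if clusters_found < 2 or len(X) <= clusters_found:
        logger.warning("silhouette undefined: %d cluster(s), %d beads",
                       clusters_found, len(X))
        return clusters_found, missing, None
    sil = float(silhouette_score(X, labels))
    return clusters_found, missing, sil


def decode(
    ratios: np.ndarray,
    targets: TargetCodeTable,
    trim_pct: float = 1.0,
    tol: float = 1e-4,
    max_iter: int = 100,
    sigma0: float = 1e-5,
    seed: int = 0,
    freeze_weights: bool = False,
    min_prob: float | None = None,
) -> DecodeResult:
    """Full decode: ICP registration, GMM classification, QC metrics.

    *min_prob*, when set, post-filters ambiguously classified beads by
    assigning code -1 to beads whose assignment probability falls below it
    (disabled by default).
    """
    icp = icp_align(ratios, targets, trim_pct=trim_pct, tol=tol, max_iter=max_iter)
    beads, gmm = gmm_classify(
        icp.transformed, targets, sigma0=sigma0, seed=seed,
        freeze_weights=freeze_weights,
    )
    if min_prob is not None:
        low = beads["prob"] < min_prob
        if low.any():
            logger.info("%d bead(s) below probability %.3g set to code -1",
                        int(low.sum()), min_prob)
        beads.loc[low, "code"] = -1
    assigned = beads.loc[beads["code"] >= 0, "code"].to_numpy()
    kept = beads["code"] >= 0
    clusters_found, missing, silhouette = cluster_quality(
        icp.transformed[kept.to_numpy()], assigned, targets
    )
    counts = np.bincount(assigned, minlength=targets.n_codes)
    ellipses = [confidence_ellipse(cov) for cov in gmm.covariances_]
    return DecodeResult(
        beads=beads,
        means=gmm.means_,
        covariances=gmm.covariances_,
        counts=counts,
        ellipses=ellipses,
        clusters_found=clusters_found,
        missing_codes=missing,
        silhouette=silhouette,
        icp=icp,
    )
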
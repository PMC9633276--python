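"""Phase one of PVS detection: per-voxel intensity scoring and thresholding.

PVS are hypointense against white matter on T1w images, so each voxel is
compared with its local neighborhood on the normalized [0, 1] intensity
scale. Two complementary contrast scores are computed over a cubic window
(default radius 2, i.e. 5x5x5 with the center excluded), both signed so
that dark-in-bright voxels score positive:

* median score  = median(neighbor intensities) − voxel intensity
* difference score = mean(neighbor intensities) − voxel intensity

Scores are computed for (and are zero outside) the search domain.
Neighborhoods are restricted to the brain mask rather than to the
parenchymal search domain: the contrast operator runs on the brain image
itself, so dark CSF neighbors legitimately suppress partial-volume rim
voxels at tissue–CSF boundaries that would otherwise mimic PVS. Voxels
with no in-brain neighbors score 0.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .maskprep import SearchDomain
from .volume_io import Mask, Volume, check_same_geometry

logger = logging.getLogger(__name__)

DEFAULT_RADIUS = 2

#: Threshold grids swept during optimization, in sweep order.
DEFAULT_GRIDS: dict[str, list[float]] = {
    "difference_thr": [0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.09, 0.1, 0.15],
    "median_thr": [0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.09, 0.1, 0.15],
    "cluster_thr": [3, 4, 5, 6, 7, 8, 9, 10],
    "linearity_thr": [0.64, 0.65, 0.66, 0.67, 0.68, 0.69, 0.7, 0.72, 0.75, 0.77, 0.8, 0.82, 0.85, 0.87, 0.9],
}


@dataclass(frozen=True)
class ThresholdSet:
    """The four tunable detection thresholds plus the fixed width limit.

    difference_thr, median_thr : float
        Minimum contrast scores on the normalized intensity scale.
    cluster_thr : int
        Minimum accepted cluster size in voxels.
    linearity_thr : float
        Minimum fraction of coordinate variance on the first principal
        component (tube-vs-blob discriminator).
    width_thr : float
        Maximum extent perpendicular to the first principal axis, voxels.
    """

    difference_thr: float = 0.05
    median_thr: float = 0.1
    cluster_thr: int = 5
    linearity_thr: float = 0.8
    width_thr: float = 15.0

    def __post_init__(self) -> None:
        if not (0 < self.linearity_thr <= 1):
            raise ValueError("linearity_thr must be in (0, 1]")
        if self.cluster_thr < 1:
            raise ValueError("cluster_thr must be >= 1 voxel")
        if self.width_thr <= 0:
            raise ValueError("width_thr must be positive")


#: Thresholds reported as optimal for motion-degraded clinical T1w data.
CLINICAL_OPTIMAL = ThresholdSet(difference_thr=0.05, median_thr=0.06, cluster_thr=5, linearity_thr=0.68)


@dataclass
class ScoreMaps:
    """Median and difference score grids over a search domain."""

    median_score: np.ndarray
    difference_score: np.ndarray
    neighborhood_radius: int
    domain: SearchDomain

    def __post_init__(self) -> None:
        for name in ("median_score", "difference_score"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            if np.any(arr[~self.domain.search.data] != 0):
                raise ValueError(f"{name} is nonzero outside the search domain")


def _neighbor_offsets(radius: int) -> np.ndarray:
    """All offsets in the cubic window of ``radius``, center excluded."""
    rng = range(-radius, radius + 1)
    offs = [o for o in itertools.product(rng, rng, rng) if o != (0, 0, 0)]
    return np.asarray(offs, dtype=np.intp)


def _neighborhood_scores(
    vol: Volume, domain: SearchDomain, radius: int
) -> tuple[np.ndarray, np.ndarray]:
    """Compute (median, mean) neighbor scores for all in-domain voxels.

    Neighbor intensities are gathered into an (N_voxels, N_offsets) table;
    interior voxels (full in-brain neighborhoods) take a plain median/mean,
    boundary voxels mask out-of-brain neighbors. Returns full grids that
    are zero outside the search domain.
    """
    if radius < 1:
        raise ValueError("neighborhood radius must be >= 1")
    dom = domain.search.data
    nbr_mask = domain.brain.data if domain.brain is not None else dom
    data = np.asarray(vol.data, dtype=np.float64)
    offsets = _neighbor_offsets(radius)
    coords = np.argwhere(dom)
    n = len(coords)
    med = np.zeros(dom.shape)
    mean = np.zeros(dom.shape)
    if n == 0:
        return med, mean

    pv = np.pad(data, radius, mode="constant")
    pd = np.pad(nbr_mask, radius, mode="constant")
    ci, cj, ck = (coords + radius).T

    vals = np.empty((n, len(offsets)), dtype=np.float64)
    inmask = np.empty((n, len(offsets)), dtype=bool)
    for k, (di, dj, dk) in enumerate(offsets):
        vals[:, k] = pv[ci + di, cj + dj, ck + dk]
        inmask[:, k] = pd[ci + di, cj + dj, ck + dk]

    counts = inmask.sum(axis=1)
    center = data[dom]
    med_v = np.zeros(n)
    mean_v = np.zeros(n)

    full = counts == len(offsets)
    if full.any():
        med_v[full] = np.median(vals[full], axis=1)
        mean_v[full] = vals[full].mean(axis=1, dtype=np.float64)
    partial = (~full) & (counts > 0)
    if partial.any():
        masked = np.where(inmask[partial], vals[partial], np.nan)
        med_v[partial] = np.nanmedian(masked, axis=1)
        mean_v[partial] = np.nansum(masked, axis=1, dtype=np.float64) / counts[partial]
    isolated = counts == 0
    if isolated.any():
        logger.info("%d in-domain voxels have no in-domain neighbors; scored 0", int(isolated.sum()))
        med_v[isolated] = center[isolated]  # yields score 0 below
        mean_v[isolated] = center[isolated]

    med[dom] = med_v - center
    mean[dom] = mean_v - center
    return med, mean


def compute_scores(vol: Volume, domain: SearchDomain, radius: int = DEFAULT_RADIUS) -> ScoreMaps:
    """Compute both intensity scores in one pass over the neighborhood table."""
    check_same_geometry(vol, domain.search)
    med, mean = _neighborhood_scores(vol, domain, radius)
    return ScoreMaps(median_score=med, difference_score=mean, neighborhood_radius=radius, domain=domain)


def median_score(vol: Volume, domain: SearchDomain, radius: int = DEFAULT_RADIUS) -> np.ndarray:
    """Median neighbor intensity minus voxel intensity, in-domain only."""
    return compute_scores(vol, domain, radius).median_score


def difference_score(vol: Volume, domain: SearchDomain, radius: int = DEFAULT_RADIUS) -> np.ndarray:
    """Mean neighbor intensity minus voxel intensity, in-domain only."""
    return compute_scores(vol, domain, radius).difference_score


def threshold_candidates(scores: ScoreMaps, thr: ThresholdSet, combine: str = "and") -> Mask:
    """Select candidate voxels passing the intensity thresholds.

    A voxel is a candidate iff it lies in the search domain and its median
    score >= ``thr.median_thr`` and its difference score >=
    ``thr.difference_thr``. ``combine="or"`` (either score suffices) is
    provided for sensitivity analysis only.
    """
    dom = scores.domain.search
    med_pass = scores.median_score >= thr.median_thr
    diff_pass = scores.difference_score >= thr.difference_thr
    if combine == "and":
        cand = med_pass & diff_pass
    elif combine == "or":
        cand = med_pass | diff_pass
    else:
        raise ValueError("combine must be 'and' or 'or'")
    cand &= dom.data
    return Mask(cand, voxel_size=dom.voxel_size, affine=dom.affine, label="PVS_auto")
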
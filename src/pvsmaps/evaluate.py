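"""Threshold optimization against manual masks and validation metrics.

The optimizer sweeps the four detection thresholds against manual
reference segmentations, scoring each combination by the mean Dice
overlap across scans. Because the intensity scores do not depend on the
thresholds, they are computed once per scan; connected-component
labeling is cached per (difference, median) pair and the cluster-level
size/linearity/width filters are evaluated vectorized, which makes the
exhaustive sweep of the full default grids (12 000 combinations)
tractable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .detect import DEFAULT_GRIDS, DEFAULT_RADIUS, ThresholdSet, compute_scores, threshold_candidates
from .maskprep import SearchDomain
from .morphology import Segmentation, label_components
from .volume_io import Mask, Volume, check_same_geometry, normalize_intensity

logger = logging.getLogger(__name__)

SWEEP_ORDER = ("difference_thr", "median_thr", "cluster_thr", "linearity_thr")


def dice(a: Mask, b: Mask) -> float:
    """Dice overlap 2|a∩b| / (|a|+|b|).

    Two empty masks agree perfectly (1.0, logged); exactly one empty
    gives 0.0.
    """
    check_same_geometry(a, b)
    na, nb = a.count, b.count
    if na == 0 and nb == 0:
        logger.info("dice of two empty masks: 1.0 by convention")
        return 1.0
    inter = int(np.count_nonzero(a.data & b.data))
    return 2.0 * inter / (na + nb)


def count_clusters_in_slice(seg: Segmentation, axis: int, index: int) -> int:
    """Number of accepted clusters with at least one voxel in a slice."""
    if not 0 <= axis <= 2:
        raise ValueError("axis must be 0, 1 or 2")
    if not 0 <= index < seg.mask.shape[axis]:
        raise IndexError(f"slice {index} out of range for axis {axis}")
    return sum(1 for c in seg.clusters if np.any(c.voxels[:, axis] == index))


def correlate_counts(manual: list[float], automated: list[float]) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between paired PVS counts."""
    manual = np.asarray(manual, dtype=float)
    automated = np.asarray(automated, dtype=float)
    if manual.shape != automated.shape:
        raise ValueError("count lists must have equal length")
    if len(manual) < 3:
        raise ValueError("need at least 3 paired counts")
    if np.std(manual) == 0 or np.std(automated) == 0:
        raise ValueError("zero variance in a count list")
    res = stats.pearsonr(manual, automated)
    return float(res.statistic), float(res.pvalue)


def match_clusters(
    auto: Segmentation, manual: Mask, min_overlap: int = 1
) -> tuple[int, int]:
    """Cluster-level (false positives, false negatives) vs a manual mask.

    The manual mask is itself component-labeled (26-connectivity). An
    automated cluster is matched if it shares >= ``min_overlap`` voxels
    with the manual mask; a manual cluster is missed (FN) if no
    automated voxel falls on it.
    """
    check_same_geometry(auto.mask, manual)
    manual_clusters = label_components(manual, connectivity=26)
    fp = sum(
        1
        for c in auto.clusters
        if int(np.count_nonzero(manual.data[tuple(c.voxels.T)])) < min_overlap
    )
    fn = sum(
        1
        for m in manual_clusters
        if int(np.count_nonzero(auto.mask.data[tuple(m.voxels.T)])) < min_overlap
    )
    return fp, fn


@dataclass
class ValidationReport:
    """Per-scan validation against manual references."""

    scans: pd.DataFrame  # columns: scan, manual_count, automated_count, fp, fn, dice
    pearson_r: float
    pearson_p: float


def validate(
    pairs: list[tuple[Segmentation, Mask]], ids: list[str] | None = None
) -> ValidationReport:
    """Validate segmentations against manual masks: counts, FP/FN, Dice,
    and the Pearson correlation between manual and automated counts."""
    if not pairs:
        raise ValueError("no (segmentation, manual mask) pairs supplied")
    ids = ids or [f"scan{i + 1}" for i in range(len(pairs))]
    rows = []
    for scan_id, (seg, manual) in zip(ids, pairs):
        fp, fn = match_clusters(seg, manual)
        manual_count = len(label_components(manual, connectivity=26))
        rows.append(
            {
                "scan": scan_id,
                "manual_count": manual_count,
                "automated_count": seg.cluster_count,
                "fp": fp,
                "fn": fn,
                "dice": dice(seg.mask, manual),
            }
        )
    df = pd.DataFrame(rows)
    if len(df) >= 3 and df["manual_count"].std() > 0 and df["automated_count"].std() > 0:
        r, p = correlate_counts(df["manual_count"].tolist(), df["automated_count"].tolist())
    else:
        r, p = float("nan"), float("nan")
    return ValidationReport(scans=df, pearson_r=r, pearson_p=p)


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

@dataclass
class GridSearchResult:
    trials: list[tuple[ThresholdSet, float, list[float]]]
    best: ThresholdSet
    strategy: str
    grids: dict[str, list] = field(default_factory=dict)

    @property
    def best_dice(self) -> float:
        key = self.best
        for thr, mean_dice, _ in self.trials:
            if thr == key:
                return mean_dice
        raise KeyError("best threshold set missing from trials")

    def trial_table(self) -> pd.DataFrame:
        rows = [
            {**thr.__dict__, "mean_dice": md, **{f"dice_{i}": d for i, d in enumerate(per)}}
            for thr, md, per in self.trials
        ]
        return pd.DataFrame(rows)


class _ScanCache:
    """Per-scan precomputation for the threshold sweep."""

    def __init__(
        self,
        vol: Volume,
        domain: SearchDomain,
        manual: Mask,
        radius: int,
        connectivity: int,
        normalize: bool,
    ):
        check_same_geometry(vol, manual)
        work = normalize_intensity(vol, domain.brain or domain.search) if normalize else vol
        self.scores = compute_scores(work, domain, radius)
        self.manual = manual
        self.manual_count = manual.count
        self.connectivity = connectivity
        self._by_intensity: dict[tuple[float, float], tuple] = {}

    def _cluster_stats(self, diff_thr: float, med_thr: float):
        key = (diff_thr, med_thr)
        if key not in self._by_intensity:
            probe = ThresholdSet(difference_thr=diff_thr, median_thr=med_thr,
                                 cluster_thr=1, linearity_thr=0.01)
            cand = threshold_candidates(self.scores, probe)
            clusters = label_components(cand, self.connectivity)
            size = np.array([c.size for c in clusters], dtype=float)
            lin = np.array([c.linearity for c in clusters], dtype=float)
            width = np.array([c.width for c in clusters], dtype=float)
            overlap = np.array(
                [int(np.count_nonzero(self.manual.data[tuple(c.voxels.T)])) for c in clusters],
                dtype=float,
            )
            self._by_intensity[key] = (size, lin, width, overlap)
        return self._by_intensity[key]

    def dice_at(self, thr: ThresholdSet) -> float:
        size, lin, width, overlap = self._cluster_stats(thr.difference_thr, thr.median_thr)
        if len(size) == 0:
            return 1.0 if self.manual_count == 0 else 0.0
        acc = (size >= thr.cluster_thr) & (lin >= thr.linearity_thr) & (width <= thr.width_thr)
        auto_n = size[acc].sum()
        inter = overlap[acc].sum()
        if auto_n == 0 and self.manual_count == 0:
            return 1.0
        if auto_n + self.manual_count == 0:
            return 1.0
        return float(2.0 * inter / (auto_n + self.manual_count))


def _tie_key(thr: ThresholdSet, defaults: ThresholdSet):
    """Sort key implementing 'prefer default, then smaller' per parameter
    in sweep order (used only among equal-dice trials)."""
    key = []
    for name in SWEEP_ORDER:
        v, d = getattr(thr, name), getattr(defaults, name)
        key.append((0 if v == d else 1, v))
    return tuple(key)


def optimize_thresholds(
    scans: list[tuple[Volume, SearchDomain, Mask]],
    grids: dict[str, list] | None = None,
    strategy: str = "sequential",
    defaults: ThresholdSet | None = None,
    radius: int = DEFAULT_RADIUS,
    connectivity: int = 26,
    normalize: bool = True,
    passes: int = 1,
) -> GridSearchResult:
    """Find the threshold combination maximizing mean Dice across scans.

    ``sequential`` sweeps the parameters in the order difference, median,
    cluster, linearity, fixing each at its best value before sweeping the
    next (parameters not yet swept stay at their defaults); ``passes > 1``
    repeats the sweep until convergence or the pass budget is exhausted.
    ``exhaustive`` evaluates the full Cartesian product. Ties are broken
    toward the default value, then the smaller value.
    """
    if not scans:
        raise ValueError("at least one scan with a manual mask is required")
    grids = {**DEFAULT_GRIDS, **(grids or {})}
    for name in SWEEP_ORDER:
        if not grids.get(name):
            raise ValueError(f"empty grid for {name}")
    defaults = defaults or ThresholdSet()
    if strategy not in ("sequential", "exhaustive"):
        raise ValueError("strategy must be 'sequential' or 'exhaustive'")

    caches = [
        _ScanCache(vol, domain, manual, radius, connectivity, normalize)
        for vol, domain, manual in scans
    ]

    trials: list[tuple[ThresholdSet, float, list[float]]] = []
    seen: dict[ThresholdSet, float] = {}

    def evaluate_thr(thr: ThresholdSet) -> float:
        if thr in seen:
            return seen[thr]
        per = [c.dice_at(thr) for c in caches]
        mean = float(np.mean(per))
        trials.append((thr, mean, per))
        seen[thr] = mean
        return mean

    def pick(cands: list[ThresholdSet]) -> ThresholdSet:
        scored = [(evaluate_thr(t), t) for t in cands]
        best_score = max(s for s, _ in scored)
        tied = [t for s, t in scored if s == best_score]
        return min(tied, key=lambda t: _tie_key(t, defaults))

    if strategy == "sequential":
        current = defaults
        for _ in range(max(1, passes)):
            previous = current
            for name in SWEEP_ORDER:
                cands = [
                    ThresholdSet(**{**current.__dict__, name: v}) for v in grids[name]
                ]
                current = pick(cands)
            if current == previous:
                break
        best = current
    else:
        combos = [
            ThresholdSet(difference_thr=d, median_thr=m, cluster_thr=c, linearity_thr=l)
            for d, m, c, l in itertools.product(
                grids["difference_thr"], grids["median_thr"],
                grids["cluster_thr"], grids["linearity_thr"],
            )
        ]
        best = pick(combos)

    return GridSearchResult(trials=trials, best=best, strategy=strategy, grids=grids)
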
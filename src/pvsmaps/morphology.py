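"""Phase two of PVS detection: cluster morphology filtering.

Candidate voxels are grouped into connected components (default
26-connectivity) and each cluster is kept only if it looks like a
perivascular space: big enough to be real (size >= cluster threshold),
elongated (linearity — the fraction of coordinate variance carried by the
first principal component — above the linearity threshold), and thin
(extent perpendicular to the first principal axis at most the width
limit). Rejected clusters are retained with the first failing rule, in
the fixed order size -> linearity -> width, so reports are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .detect import DEFAULT_RADIUS, ThresholdSet, compute_scores, threshold_candidates
from .maskprep import SearchDomain
from .volume_io import Mask, Volume, check_same_geometry, normalize_intensity

_CONNECTIVITY_STRUCTURE = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class Cluster:
    """A connected set of supra-threshold voxels and its shape metrics."""

    id: int
    voxels: np.ndarray  # (n, 3) int voxel indices, 0-based
    size: int = 0
    centroid: np.ndarray = field(default_factory=lambda: np.zeros(3))
    eigenvalues: np.ndarray = field(default_factory=lambda: np.zeros(3))
    linearity: float = 1.0
    width: float = 0.0
    passed: bool = True
    reject_reason: str | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.intp).reshape(-1, 3)
        self.size = len(self.voxels)
        if self.size == 0:
            raise ValueError("a cluster must contain at least one voxel")
        self.centroid = self.voxels.mean(axis=0)


def _principal_axes(voxels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and eigenvectors (columns) of the
    population covariance of voxel coordinates."""
    x = voxels - voxels.mean(axis=0)
    cov = (x.T @ x) / len(x)  # population normalization (divide by N)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    return evals, evecs[:, order]


def compute_linearity(cluster: Cluster) -> float:
    """Fraction of coordinate variance on the first principal component.

    Clusters of one or two voxels are trivially collinear and return 1.0.
    For size >= 3 the value lies in [1/3, 1]: 1 for a perfect line, 1/3
    for an isotropic blob.
    """
    if cluster.size <= 2:
        cluster.eigenvalues = np.zeros(3)
        if cluster.size == 2:
            d = cluster.voxels[1] - cluster.voxels[0]
            cluster.eigenvalues[0] = float(d @ d) / 4.0
        cluster.linearity = 1.0
        return 1.0
    evals, _ = _principal_axes(cluster.voxels)
    cluster.eigenvalues = evals
    total = evals.sum()
    cluster.linearity = 1.0 if total == 0 else float(evals[0] / total)
    return cluster.linearity


def compute_width(cluster: Cluster) -> float:
    """Maximal extent perpendicular to the first principal axis, voxels.

    Coordinates are projected onto the second and third principal axes;
    the width is the larger of the two peak-to-peak projection ranges
    (the stricter reading of "extent perpendicular to PC1"). A single
    voxel or a collinear cluster has width 0.
    """
    if cluster.size == 1:
        cluster.width = 0.0
        return 0.0
    _, evecs = _principal_axes(cluster.voxels)
    x = cluster.voxels - cluster.voxels.mean(axis=0)
    proj = x @ evecs[:, 1:]  # PC2 and PC3
    cluster.width = float((proj.max(axis=0) - proj.min(axis=0)).max())
    return cluster.width


def label_components(candidates: Mask, connectivity: int = 26) -> list[Cluster]:
    """Partition a binary mask into maximal connected components.

    Clusters are ordered lexicographically by their minimum voxel index,
    so numbering is deterministic, and shape metrics are filled in.
    """
    if connectivity not in _CONNECTIVITY_STRUCTURE:
        raise ValueError("connectivity must be 6, 18 or 26")
    labeled, n = ndimage.label(candidates.data, structure=_CONNECTIVITY_STRUCTURE[connectivity])
    if n == 0:
        return []
    coords = np.argwhere(labeled > 0)
    labels = labeled[tuple(coords.T)]
    flat = np.ravel_multi_index(tuple(coords.T), candidates.shape)
    # order components by their lexicographically smallest voxel
    first_flat = ndimage.minimum(flat, labels=labels, index=np.arange(1, n + 1))
    order = np.argsort(first_flat, kind="stable")
    clusters = []
    for new_id, lab in enumerate(np.arange(1, n + 1)[order], start=1):
        c = Cluster(id=new_id, voxels=coords[labels == lab])
        compute_linearity(c)
        compute_width(c)
        clusters.append(c)
    return clusters


def filter_clusters(
    clusters: list[Cluster], thr: ThresholdSet
) -> tuple[list[Cluster], list[Cluster]]:
    """Apply the size, linearity and width criteria.

    A cluster is accepted iff size >= cluster_thr AND linearity >=
    linearity_thr AND width <= width_thr. Rejected clusters carry the
    first failing rule in the fixed order size, linearity, width.
    """
    accepted, rejected = [], []
    for c in clusters:
        if c.size < thr.cluster_thr:
            reason = "size"
        elif c.linearity < thr.linearity_thr:
            reason = "linearity"
        elif c.width > thr.width_thr:
            reason = "width"
        else:
            reason = None
        c.passed = reason is None
        c.reject_reason = reason
        (accepted if c.passed else rejected).append(c)
    return accepted, rejected


@dataclass
class Segmentation:
    """Final PVS segmentation: mask, accepted/rejected clusters, provenance."""

    mask: Mask
    clusters: list[Cluster]
    rejected: list[Cluster]
    thresholds: ThresholdSet
    source_id: str = ""
    edit_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        expect = np.zeros(self.mask.shape, dtype=bool)
        for c in self.clusters:
            expect[tuple(c.voxels.T)] = True
        if not np.array_equal(expect, self.mask.data):
            raise ValueError("segmentation mask is not the union of accepted clusters")

    @property
    def cluster_count(self) -> int:
        return len(self.clusters)

    @property
    def pvs_volume_voxels(self) -> int:
        return int(sum(c.size for c in self.clusters))

    def cluster_table(self) -> pd.DataFrame:
        """Per-cluster metrics (accepted and rejected) as a DataFrame."""
        rows = []
        for c in self.clusters + self.rejected:
            rows.append(
                {
                    "id": c.id,
                    "size": c.size,
                    "centroid_i": c.centroid[0],
                    "centroid_j": c.centroid[1],
                    "centroid_k": c.centroid[2],
                    "linearity": c.linearity,
                    "width": c.width,
                    "accepted": c.passed,
                    "reject_reason": c.reject_reason or "",
                }
            )
        return pd.DataFrame(rows).sort_values("id").reset_index(drop=True)

    def save(self, directory: str | Path, stem: str = "pvs") -> dict[str, Path]:
        """Write mask (NIfTI), cluster table (CSV) and provenance (JSON)."""
        from .volume_io import write_nifti

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "mask": directory / f"{stem}_mask.nii.gz",
            "clusters": directory / f"{stem}_clusters.csv",
            "provenance": directory / f"{stem}_provenance.json",
        }
        write_nifti(self.mask, paths["mask"])
        self.cluster_table().to_csv(paths["clusters"], index=False)
        prov = {
            "source_id": self.source_id,
            "thresholds": self.thresholds.__dict__,
            "cluster_count": self.cluster_count,
            "pvs_volume_voxels": self.pvs_volume_voxels,
            "edit_log": self.edit_log,
        }
        paths["provenance"].write_text(json.dumps(prov, indent=2))
        return paths


def _mask_from_clusters(clusters: list[Cluster], like: Mask) -> Mask:
    data = np.zeros(like.shape, dtype=bool)
    for c in clusters:
        data[tuple(c.voxels.T)] = True
    return Mask(data, voxel_size=like.voxel_size, affine=like.affine, label="PVS_auto")


def segment(
    vol: Volume,
    domain: SearchDomain,
    thr: ThresholdSet | None = None,
    radius: int = DEFAULT_RADIUS,
    connectivity: int = 26,
    normalize: bool = True,
) -> Segmentation:
    """Run the full two-phase pipeline on one volume.

    Intensities are normalized to [0, 1] within the search domain (1st and
    99th percentiles) unless ``normalize=False`` (input already on the
    normalized scale), then scored, thresholded, labeled and filtered.
    Deterministic for fixed inputs.
    """
    thr = thr or ThresholdSet()
    check_same_geometry(vol, domain.search)
    if domain.search.count == 0:
        empty = Mask(np.zeros(vol.shape, dtype=bool), voxel_size=domain.search.voxel_size,
                     affine=domain.search.affine, label="PVS_auto")
        return Segmentation(mask=empty, clusters=[], rejected=[], thresholds=thr, source_id=vol.id)
    work = normalize_intensity(vol, domain.brain or domain.search) if normalize else vol
    scores = compute_scores(work, domain, radius)
    candidates = threshold_candidates(scores, thr)
    clusters = label_components(candidates, connectivity)
    accepted, rejected = filter_clusters(clusters, thr)
    return Segmentation(
        mask=_mask_from_clusters(accepted, candidates),
        clusters=accepted,
        rejected=rejected,
        thresholds=thr,
        source_id=vol.id,
    )


def edit_segmentation(
    seg: Segmentation, add: Mask | None = None, remove: list[int] | None = None
) -> Segmentation:
    """Apply a batch visual-inspection edit: remove false positives by
    cluster id and/or add manually segmented voxels as new clusters.

    Removed clusters move to the rejected list with reason "manual";
    added voxels are connected-component labeled and appended. The edit
    is recorded in the segmentation's edit log.
    """
    remove = remove or []
    known = {c.id for c in seg.clusters}
    unknown = [i for i in remove if i not in known]
    if unknown:
        raise KeyError(f"unknown cluster ids: {unknown}")
    kept = [c for c in seg.clusters if c.id not in remove]
    newly_rejected = []
    for c in seg.clusters:
        if c.id in remove:
            c.passed = False
            c.reject_reason = "manual"
            newly_rejected.append(c)

    added: list[Cluster] = []
    if add is not None and add.count > 0:
        check_same_geometry(seg.mask, add)
        next_id = max([c.id for c in seg.clusters + seg.rejected], default=0) + 1
        for c in label_components(add):
            c.id = next_id
            next_id += 1
            added.append(c)
    accepted = kept + added
    log_entry = {"removed": list(remove), "added_clusters": len(added),
                 "added_voxels": int(add.count) if add is not None else 0}
    return Segmentation(
        mask=_mask_from_clusters(accepted, seg.mask),
        clusters=accepted,
        rejected=seg.rejected + newly_rejected,
        thresholds=seg.thresholds,
        source_id=seg.source_id,
        edit_log=seg.edit_log + [log_entry],
    )
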
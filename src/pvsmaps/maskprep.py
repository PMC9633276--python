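"""Construction of the search domain in which PVS detection runs.

The detector scores voxels only inside a search domain built from the
skull-stripped brain mask and the tissue segmentation: the brain mask is
dilated by two voxels to reinstate gray matter removed by stripping, the
result is restricted to parenchymal tissue (cortical GM, deep GM and WM),
and an expanded ventricular mask — the ventricles dilated by three voxels
and intersected with the CSF mask — is carved out so that ventricle walls
and choroid plexus do not masquerade as PVS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .volume_io import Mask, check_same_geometry, dilate, intersect, subtract, union

VENTRICLE_DILATION = 3
BRAIN_DILATION = 2


@dataclass
class SearchDomain:
    """Where PVS scoring runs, plus the masks needed downstream.

    ``brain``, when present, is the mask within which intensity
    normalization percentiles are taken (the full brain spans the whole
    CSF-to-WM intensity range; the search parenchyma alone does not).
    """

    search: Mask
    wm: Mask
    excluded_ventricles: Mask
    brain: Mask | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        check_same_geometry(self.search, self.wm)
        check_same_geometry(self.search, self.excluded_ventricles)
        if np.any(self.search.data & self.excluded_ventricles.data):
            raise ValueError("search domain overlaps the excluded ventricular region")


def expand_ventricles(ventricles: Mask, csf: Mask) -> Mask:
    """Expanded ventricular exclusion: dilate(ventricles, 3) ∩ CSF.

    Restricting the dilation to the CSF mask keeps the exclusion from
    eating into periventricular white matter, where PVS are common.
    """
    expanded = dilate(ventricles, VENTRICLE_DILATION)
    return intersect(expanded, csf, label="ventricles")


def build_search_domain(
    brain: Mask,
    tissue: dict[str, Mask],
    ventricles_expanded: Mask,
    include_infratentorial: bool = False,
) -> SearchDomain:
    """Assemble the search domain from brain and tissue masks.

    ``tissue`` maps labels to masks; ``"WM"`` is required, ``"GM"`` and
    ``"deep_GM"`` are included in the searched parenchyma when present.
    Brainstem and cerebellum masks, when provided, are excluded by default
    (PVS burden is conventionally reported for the cerebrum); pass
    ``include_infratentorial=True`` to keep them.
    """
    if "WM" not in tissue:
        raise ValueError("tissue set must contain a 'WM' mask")
    wm = tissue["WM"]
    check_same_geometry(brain, wm)
    check_same_geometry(brain, ventricles_expanded)

    parenchyma = replace(wm, label="search")
    for key in ("GM", "deep_GM"):
        if key in tissue:
            parenchyma = union(parenchyma, tissue[key], label="search")

    search = intersect(dilate(brain, BRAIN_DILATION), parenchyma, label="search")
    search = subtract(search, ventricles_expanded, label="search")
    if not include_infratentorial:
        for key in ("brainstem", "cerebellum"):
            if key in tissue:
                search = subtract(search, tissue[key], label="search")
    if search.count == 0:
        raise ValueError("search domain is empty after exclusions")
    return SearchDomain(
        search=search,
        wm=wm,
        excluded_ventricles=ventricles_expanded,
        brain=brain,
        provenance={
            "brain_dilation": BRAIN_DILATION,
            "ventricle_dilation": VENTRICLE_DILATION,
            "include_infratentorial": include_infratentorial,
            "tissues": sorted(tissue),
        },
    )
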
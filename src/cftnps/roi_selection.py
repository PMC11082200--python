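"""Atlas ROI retention against an omnibus significance mask.

An atlas parcel is retained for pattern analysis when it (1) contains at
least ``min_voxels`` voxels (default 100) and (2) has at least
``min_overlap`` (default 25%) of its voxels inside the omnibus mask of
condition-sensitive voxels. Both boundaries are inclusive. Label 0 is
background and never an ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ROISpec", "select_rois", "roi_table"]


@dataclass
class ROISpec:
    label: int
    name: str
    voxel_indices: np.ndarray = field(repr=False)  # flat indices into the grid
    n_voxels: int = 0
    overlap_fraction: float = 0.0
    retained: bool = False


def select_rois(
    atlas: np.ndarray,
    omnibus_mask: np.ndarray,
    min_voxels: int = 100,
    min_overlap: float = 0.25,
    names: dict | None = None,
) -> list[ROISpec]:
    """One ROISpec per positive atlas label, ordered by label.

    ``overlap_fraction`` = |ROI and mask| / |ROI|; retained iff
    ``n_voxels >= min_voxels`` and ``overlap_fraction >= min_overlap``.
    """
    atlas = np.asarray(atlas)
    mask = np.asarray(omnibus_mask).astype(bool)
    if atlas.shape != mask.shape:
        raise ValueError(f"grid mismatch: atlas {atlas.shape} vs mask {mask.shape}")
    flat_atlas = atlas.reshape(-1)
    flat_mask = mask.reshape(-1)
    labels = np.unique(flat_atlas)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError("empty atlas: no positive labels")

    rois = []
    for label in labels:
        vox = np.flatnonzero(flat_atlas == label)
        n = int(vox.size)
        overlap = float(flat_mask[vox].sum()) / n
        retained = (n >= min_voxels) and (overlap >= min_overlap)
        name = (names or {}).get(int(label), f"roi_{int(label)}")
        rois.append(
            ROISpec(
                label=int(label),
                name=name,
                voxel_indices=vox,
                n_voxels=n,
                overlap_fraction=overlap,
                retained=retained,
            )
        )
    return rois


def roi_table(rois: list[ROISpec]) -> pd.DataFrame:
    """Tabular view (label, name, n_voxels, overlap_fraction, retained)."""
    return pd.DataFrame(
        {
            "label": [r.label for r in rois],
            "name": [r.name for r in rois],
            "n_voxels": [r.n_voxels for r in rois],
            "overlap_fraction": [r.overlap_fraction for r in rois],
            "retained": [r.retained for r in rois],
        }
    )
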
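"""Localisation of voxel sets against probabilistic atlases."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ProbAtlas", "assignment_quotient", "volume_fractions"]


@dataclass
class ProbAtlas:
    """Per-area probability volumes stacked along the first axis."""

    probs: np.ndarray
    area_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 4:
            raise ValueError("probs must be (n_areas, nx, ny, nz)")
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if not self.area_labels:
            self.area_labels = [f"area{i + 1}" for i in range(self.probs.shape[0])]
        if len(self.area_labels) != self.probs.shape[0]:
            raise ValueError("area_labels length must match the number of areas")

    def area(self, label: str) -> np.ndarray:
        return self.probs[self.area_labels.index(label)]


def assignment_quotient(
    cluster_mask: np.ndarray,
    atlas: ProbAtlas,
    area: str,
    min_probability: float = 0.0,
) -> float | None:
    """Distribution-based cluster assignment quotient.

    Mean area probability over the cluster voxels divided by the mean over
    all voxels where the area is observed (probability above
    ``min_probability``).  > 1 indicates a central location of the cluster
    within the area.  Returns None when the area has no support.
    """
    mask = np.asarray(cluster_mask, dtype=bool)
    if not mask.any():
        raise ValueError("cluster mask is empty")
    p = atlas.area(area)
    if p.shape != mask.shape:
        raise ValueError("cluster mask and atlas are on different grids")
    support = p > min_probability
    if not support.any():
        return None
    return float(p[mask].mean() / p[support].mean())


def volume_fractions(
    label_masks: dict[str, np.ndarray],
    structure_masks: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Percentage of each structure's volume covered by each label.

    Rows are structures, columns labels; entry = 100 * |label & structure|
    / |structure|.
    """
    rows = {}
    for sname, smask in structure_masks.items():
        smask = np.asarray(smask, dtype=bool)
        total = smask.sum()
        if total == 0:
            raise ValueError(f"structure mask {sname!r} is empty")
        rows[sname] = {
            lname: 100.0 * np.sum(np.asarray(lmask, bool) & smask) / total
            for lname, lmask in label_masks.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index")
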
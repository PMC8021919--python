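"""Parcellation atlas container shared by the phantom generator and feature
extraction."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ParcelAtlas:
    """Integer label volume defining regions of interest.

    Label 0 is reserved for background; ``label_ids`` lists the nonzero labels
    in strictly increasing order (ascending-label order is the feature order
    everywhere downstream).
    """

    labels: np.ndarray  # 3D int array
    label_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D integer volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integer-valued")
        if self.label_ids is None:
            ids = np.unique(self.labels)
            self.label_ids = ids[ids > 0]
        else:
            self.label_ids = np.asarray(self.label_ids)
            if np.any(np.diff(self.label_ids) <= 0):
                raise ValueError("label_ids must be strictly increasing")
            if np.any(self.label_ids <= 0):
                raise ValueError("label 0 is reserved for background")

    @property
    def n_parcels(self) -> int:
        return int(len(self.label_ids))

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(self.labels.shape)
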
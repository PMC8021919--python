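"""Feature extraction for the conventional ML brain-age baselines.

Two strategies:

* **Parcel-wise**: the mean value of each atlas region, per channel.  With a
  442-region atlas and two channels (volume + density) this yields the classic
  884-feature morphometry table.
* **Spatial ICA**: the training cohort's (subjects x voxels) matrix for one
  channel is decomposed into K spatially independent component maps (FastICA
  after PCA whitening); each subject — training or held out — is then
  summarized by the beta weights of one joint multiple regression of their
  masked voxel vector on all K maps ("integrity scores", the dual-regression
  convention).  Four channels at K=400 give the 1,600-score table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .atlas import ParcelAtlas
from .synthetic import SubjectVolume


class EmptyParcelError(ValueError):
    """An atlas label has no voxels in the volume grid."""


class CollinearComponentsError(np.linalg.LinAlgError):
    """The spatial-regression design matrix is rank deficient."""


@dataclass
class FeatureTable:
    """Subjects x features matrix with aligned names and subject ids."""

    matrix: np.ndarray
    feature_names: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValueError("matrix shape must be (n_subjects, n_features)")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=self.subject_ids, columns=self.feature_names
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureTable":
        return cls(
            matrix=frame.to_numpy(dtype=float),
            feature_names=list(frame.columns),
            subject_ids=[str(i) for i in frame.index],
        )


@dataclass
class ComponentBasis:
    """K unthresholded spatial component maps over a brain mask.

    ``maps`` has shape (K, n_mask_voxels): row k holds component k restricted
    to the ``mask`` voxels (C-order).  ``converged`` records whether the ICA
    iteration reached its tolerance; a non-converged basis is still usable
    (best iterate) but flagged.
    """

    maps: np.ndarray
    mask: np.ndarray
    converged: bool = True
    channel: str = ""

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.maps.ndim != 2:
            raise ValueError("maps must be (K, n_voxels)")
        if self.maps.shape[1] != int(self.mask.sum()):
            raise ValueError("maps width must equal the number of mask voxels")

    @property
    def K(self) -> int:
        return int(self.maps.shape[0])

    def map_volume(self, k: int) -> np.ndarray:
        """Component k unflattened to the full 3D grid (zeros off-mask)."""
        vol = np.zeros(self.mask.shape)
        vol[self.mask] = self.maps[k]
        return vol


def parcel_means(volume: np.ndarray, atlas: ParcelAtlas) -> np.ndarray:
    """Mean voxel value of each atlas region, in ascending-label order."""
    volume = np.asarray(volume, dtype=float)
    if volume.shape != atlas.shape:
        raise ValueError(
            f"volume grid {volume.shape} does not match atlas grid {atlas.shape}"
        )
    labels = atlas.labels.ravel()
    counts = np.bincount(labels, minlength=int(atlas.label_ids[-1]) + 1)
    if np.any(counts[atlas.label_ids] == 0):
        empty = atlas.label_ids[counts[atlas.label_ids] == 0]
        raise EmptyParcelError(f"atlas labels with no voxels: {empty.tolist()}")
    sums = np.bincount(labels, weights=volume.ravel(), minlength=len(counts))
    return sums[atlas.label_ids] / counts[atlas.label_ids]


def build_parcel_table(
    volumes: Sequence[SubjectVolume],
    atlas: ParcelAtlas,
    channels: Sequence[str],
) -> FeatureTable:
    """Parcel-mean features for each subject, channels concatenated.

    Column count is ``n_parcels * len(channels)``; names are
    ``{channel}_parcel{label}``.
    """
    names = [
        f"{ch}_parcel{int(label)}" for ch in channels for label in atlas.label_ids
    ]
    rows = []
    for vol in volumes:
        feats = [parcel_means(vol.channels[ch], atlas) for ch in channels]
        rows.append(np.concatenate(feats))
    return FeatureTable(
        matrix=np.asarray(rows),
        feature_names=names,
        subject_ids=[v.subject_id for v in volumes],
    )


def cohort_mask(
    volumes: Sequence[SubjectVolume], channel: str, frac: float = 0.95
) -> np.ndarray:
    """Voxels nonzero in at least ``frac`` of the training subjects."""
    nonzero = sum((v.channels[channel] != 0).astype(int) for v in volumes)
    return np.asarray(nonzero >= frac * len(volumes))


def fit_spatial_ica(
    data: np.ndarray,
    mask: np.ndarray,
    K: int,
    seed: int = 0,
    max_iter: int = 500,
    channel: str = "",
) -> ComponentBasis:
    """Spatial ICA of a (subjects x masked-voxels) matrix into K components.

    PCA-whitens to K dimensions then runs FastICA; the independent directions
    live in voxel space (rows of the returned basis).  Non-convergence is
    reported with a warning and flagged on the result rather than raised: the
    best iterate is still a usable basis.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be (n_subjects, n_voxels)")
    n_subjects = data.shape[0]
    if K > n_subjects:
        raise ValueError(f"K={K} exceeds the {n_subjects} subjects available")
    if int(np.sum(mask)) != data.shape[1]:
        raise ValueError("mask voxel count must match data columns")
    ica = FastICA(
        n_components=K,
        whiten="unit-variance",
        random_state=int(seed),
        max_iter=max_iter,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        # samples = voxels, features = subjects -> sources are spatial maps
        sources = ica.fit_transform(data.T)  # (n_voxels, K)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            warnings.warn(
                "spatial ICA did not converge; returning best iterate",
                ConvergenceWarning,
                stacklevel=2,
            )
    return ComponentBasis(
        maps=sources.T, mask=np.asarray(mask, dtype=bool), converged=converged,
        channel=channel,
    )


def integrity_scores(subject_map: np.ndarray, basis: ComponentBasis) -> np.ndarray:
    """Beta weights of one joint OLS regression of a subject on all K maps.

    The design matrix is (n_voxels, K + 1) — every component map plus an
    intercept — and the response is the subject's masked voxel vector.  The
    returned vector holds the K component betas (intercept dropped).
    """
    y = np.asarray(subject_map, dtype=float)
    if y.ndim == 3:
        if y.shape != basis.mask.shape:
            raise ValueError("subject map grid does not match basis mask grid")
        y = y[basis.mask]
    if y.shape[0] != basis.maps.shape[1]:
        raise ValueError("subject vector length does not match basis voxel count")
    X = np.column_stack([np.ones(y.shape[0]), basis.maps.T])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending components via the null space of X
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        null = vt[s < s.max() * max(X.shape) * np.finfo(float).eps]
        involved = sorted(
            {int(j) - 1 for row in null for j in np.nonzero(np.abs(row) > 1e-8)[0] if j > 0}
        )
        raise CollinearComponentsError(
            f"spatial-regression design is rank deficient; collinear components: {involved}"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta[1:]


def build_sica_table(
    volumes: Sequence[SubjectVolume],
    bases: Mapping[str, ComponentBasis],
    K: int | None = None,
) -> FeatureTable:
    """Integrity-score features: K betas per channel basis, concatenated.

    Column names ``{channel}_ic{k}`` parse back to (feature set, component)
    uniquely.  All bases must share one mask grid.
    """
    shapes = {b.mask.shape for b in bases.values()}
    if len(shapes) > 1:
        raise ValueError(f"bases use inconsistent mask grids: {shapes}")
    for name, b in bases.items():
        if K is not None and b.K != K:
            raise ValueError(f"basis {name!r} has K={b.K}, expected {K}")
    names = [f"{ch}_ic{k}" for ch in bases for k in range(bases[ch].K)]
    rows = []
    for vol in volumes:
        feats = [
            integrity_scores(vol.channels[ch], basis) for ch, basis in bases.items()
        ]
        rows.append(np.concatenate(feats))
    return FeatureTable(
        matrix=np.asarray(rows),
        feature_names=names,
        subject_ids=[v.subject_id for v in volumes],
    )
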
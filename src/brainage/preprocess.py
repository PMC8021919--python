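"""Volume I/O, intensity rescaling, grid conforming, and 4D channel stacking.

Network inputs follow the convention of rescaling every channel to [0, 1] by
dividing by the maximum value over the *training* cohort, then stacking the
selected channels into a single (channel, x, y, z) array per subject.  The
stored training divisor is reused for validation/test subjects so no statistic
leaks across the split; out-of-range values there are clipped back to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .synthetic import SubjectVolume


class DegenerateInputError(ValueError):
    """A channel is identically zero over the training cohort."""


class ChannelConfigurationError(KeyError):
    """A requested channel is missing from a subject."""


@dataclass
class StackedInput:
    """4D network input for one subject: (channel, x, y, z), values in [0, 1]."""

    data: np.ndarray
    channel_names: tuple[str, ...]
    subject_id: str = ""


def _affine(voxel_size: Sequence[float]) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0]).astype(float)
    return aff


def save_subject(volume: SubjectVolume, outdir: str | Path) -> Path:
    """Write one subject as a 4D NIfTI (last axis = channel) plus channel list."""
    outdir = Path(outdir)
    data = np.stack([volume.channels[c] for c in volume.channels], axis=-1)
    img = nib.Nifti1Image(data.astype(np.float32), _affine(volume.voxel_size))
    img.header.set_data_dtype(np.float32)
    path = outdir / f"{volume.subject_id}.nii"
    nib.save(img, path)
    (outdir / f"{volume.subject_id}.channels.txt").write_text(
        "\n".join(volume.channels) + "\n"
    )
    return path


def load_subject(path: str | Path) -> SubjectVolume:
    """Read a subject written by :func:`save_subject`."""
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float32)
    names = (
        path.with_suffix("").with_suffix("")  # strip .nii
        .parent
        / (path.name.replace(".nii", "") + ".channels.txt")
    ).read_text().split()
    voxel = tuple(float(v) for v in img.header.get_zooms()[:3])
    channels = {name: data[..., i] for i, name in enumerate(names)}
    return SubjectVolume(subject_id=path.name.replace(".nii", ""), channels=channels, voxel_size=voxel)


class CohortRescaler:
    """Per-channel max-division rescaler fitted on training subjects only.

    ``fit`` records, for each channel, the maximum voxel value across the whole
    training cohort; ``transform`` divides by that stored maximum and (for
    subjects outside the training set, whose values may exceed it) clips to
    [0, 1].
    """

    def __init__(self, clip_out_of_range: bool = True) -> None:
        self.clip_out_of_range = clip_out_of_range
        self.channel_max_: dict[str, float] | None = None

    def fit(self, train_volumes: Iterable[SubjectVolume]) -> "CohortRescaler":
        maxima: dict[str, float] = {}
        n = 0
        for vol in train_volumes:
            n += 1
            for name, arr in vol.channels.items():
                m = float(arr.max())
                maxima[name] = max(maxima.get(name, -np.inf), m)
        if n == 0:
            raise ValueError("need at least one training subject")
        for name, m in maxima.items():
            if m <= 0:
                raise DegenerateInputError(
                    f"channel {name!r} has non-positive maximum over the training cohort"
                )
        self.channel_max_ = maxima
        return self

    def transform(self, volume: SubjectVolume) -> SubjectVolume:
        if self.channel_max_ is None:
            raise RuntimeError("rescaler not fitted")
        channels = {}
        for name, arr in volume.channels.items():
            if name not in self.channel_max_:
                raise ChannelConfigurationError(
                    f"channel {name!r} was not present at fit time"
                )
            out = arr / self.channel_max_[name]
            if self.clip_out_of_range:
                out = np.clip(out, 0.0, 1.0)
            channels[name] = out.astype(arr.dtype)
        return SubjectVolume(
            subject_id=volume.subject_id, channels=channels, voxel_size=volume.voxel_size
        )

    def fit_transform(self, train_volumes: Sequence[SubjectVolume]) -> list[SubjectVolume]:
        self.fit(train_volumes)
        return [self.transform(v) for v in train_volumes]


def conform_grid(
    volume: np.ndarray,
    source_voxel_mm: Sequence[float],
    target_dims: Sequence[int],
    target_voxel_mm: Sequence[float],
) -> np.ndarray:
    """Trilinearly resample a 3D volume onto a target grid, zero-padded.

    Voxel centers are aligned so that the physical field of view is mapped
    proportionally: output voxel i samples the input at
    ``(i + 0.5) * (target_mm / source_mm) - 0.5`` along each axis.  Points
    falling outside the source grid read as zero.
    """
    target_dims = tuple(int(d) for d in target_dims)
    if any(d <= 0 for d in target_dims):
        raise ValueError("target dims must be positive")
    if tuple(volume.shape) == target_dims and tuple(source_voxel_mm) == tuple(
        target_voxel_mm
    ):
        return volume.copy()
    scales = [t / s for t, s in zip(target_voxel_mm, source_voxel_mm)]
    grids = [
        (np.arange(target_dims[a]) + 0.5) * scales[a] - 0.5 for a in range(3)
    ]
    coords = np.stack(np.meshgrid(*grids, indexing="ij"), axis=0)
    return ndimage.map_coordinates(
        volume.astype(float), coords, order=1, mode="constant", cval=0.0
    )


def conform_subject(
    volume: SubjectVolume, target_dims: Sequence[int]
) -> SubjectVolume:
    """Resample every channel onto ``target_dims``, preserving the field of view.

    The target voxel size is chosen per axis so the physical extent is kept:
    ``target_mm = source_mm * source_dim / target_dim``.
    """
    target_dims = tuple(int(d) for d in target_dims)
    shape = volume.shape
    tvox = tuple(
        volume.voxel_size[a] * shape[a] / target_dims[a] for a in range(3)
    )
    channels = {
        name: conform_grid(arr, volume.voxel_size, target_dims, tvox).astype(
            arr.dtype
        )
        for name, arr in volume.channels.items()
    }
    return SubjectVolume(
        subject_id=volume.subject_id, channels=channels, voxel_size=tvox
    )


def stack_channels(
    subject: SubjectVolume, channel_names: Sequence[str]
) -> StackedInput:
    """Concatenate the named channels into a (C, x, y, z) input, in order."""
    missing = [c for c in channel_names if c not in subject.channels]
    if missing:
        raise ChannelConfigurationError(
            f"subject {subject.subject_id!r} is missing channels {missing}"
        )
    data = np.stack([subject.channels[c] for c in channel_names], axis=0)
    return StackedInput(
        data=data, channel_names=tuple(channel_names), subject_id=subject.subject_id
    )
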
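"""Age-structured multichannel brain phantoms.

The generator emulates a morphometry-style training cohort: a right-skewed
adult age distribution (mean ~36.4 y, SD ~16.4 y, support 17-90 y) and, per
subject, a set of coregistered 3D channel maps (pseudo-T1, gray/white-matter
volume- and density-like maps, plus an age-independent stub channel standing in
for a synthesized FLAIR contrast).  Regional signal in each channel varies
linearly with age on top of a per-parcel baseline, with additive Gaussian
voxel noise.  Every stage downstream of raw-image preprocessing is therefore
testable without any imaging download.

Determinism: the cohort is a pure function of ``PhantomConfig``.  Each subject
draws from an independent RNG stream keyed by ``(seed, subject_id)`` via
SHA-256, so cohorts are order-independent and individual subjects can be
re-rendered in isolation.
"""

from __future__ import annotations

import hashlib
from functools import lru_cache
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import ParcelAtlas

#: Channel order used throughout: pseudo-T1, volume-like maps, density-like
#: maps, and the age-independent stub contrast.
DEFAULT_CHANNELS = ("t1", "gmv", "wmv", "gmd", "wmd", "flair_stub")


class ConfigurationError(ValueError):
    """Raised when a phantom configuration is internally inconsistent."""


@dataclass
class PhantomConfig:
    """Study-design knobs for the phantom cohort.

    Ages are in years.  ``effect_slopes`` maps channel name -> {parcel label:
    signal change per year}; when ``None``, slopes are drawn once per cohort
    (density channels get larger-magnitude slopes than volume channels, so the
    density-informative ordering seen in morphometry data can be emulated).
    ``noise_sd`` is the per-voxel Gaussian noise SD in signal units.
    """

    n_subjects: int = 200
    grid: tuple[int, int, int] = (24, 28, 24)
    n_parcels: int = 60
    age_mean: float = 36.41
    age_sd: float = 16.37
    age_min: float = 17.0
    age_max: float = 90.0
    effect_slopes: dict[str, dict[int, float]] | None = None
    noise_sd: float = 0.1
    seed: int = 0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)

    def __post_init__(self) -> None:
        if not self.age_min < self.age_max:
            raise ConfigurationError("age_min must be strictly below age_max")
        if self.n_parcels < 2:
            raise ConfigurationError("need at least 2 parcels")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if len(self.grid) != 3 or any(g < 4 for g in self.grid):
            raise ConfigurationError("grid must be 3 axes of at least 4 voxels")
        if self.n_subjects < 0:
            raise ConfigurationError("n_subjects must be non-negative")


@dataclass
class SubjectRecord:
    """One row of the cohort table: identity, chronological age, sex."""

    subject_id: str
    age: float
    sex: int  # 0 / 1


@dataclass
class SubjectVolume:
    """Multichannel 3D image for one subject.

    ``channels`` is an ordered mapping channel-name -> 3D float array; all
    channels share one grid shape and contain no non-finite values.
    """

    subject_id: str
    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one grid shape")
        for name, ch in self.channels.items():
            if not np.all(np.isfinite(ch)):
                raise ValueError(f"channel {name!r} contains non-finite values")

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(next(iter(self.channels.values())).shape)


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    """Independent, order-invariant RNG stream for one subject."""
    digest = hashlib.sha256(f"{seed}:{subject_id}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def _named_rng(seed: int, tag: str) -> np.random.Generator:
    return _subject_rng(seed, f"__{tag}__")


@lru_cache(maxsize=32)
def _truncated_lognormal_params(
    target_mean: float, target_sd: float, upper: float
) -> tuple[float, float]:
    """(mu, sigma) of a log-normal whose [0, upper]-truncation has the target
    mean and SD.

    Uses the closed-form truncated moments
    ``E[X^k | X <= U] = exp(k mu + k^2 s^2 / 2) *
    Phi((ln U - mu - k s^2)/s) / Phi((ln U - mu)/s)`` and a root solve,
    started from the untruncated moment match.
    """
    from scipy import optimize, stats

    cv2 = (target_sd / target_mean) ** 2
    s0 = float(np.sqrt(np.log1p(cv2)))
    mu0 = float(np.log(target_mean)) - s0**2 / 2

    def truncated_moments(mu: float, s: float) -> tuple[float, float]:
        z = (np.log(upper) - mu) / s
        denom = stats.norm.cdf(z)
        m1 = np.exp(mu + s**2 / 2) * stats.norm.cdf(z - s) / denom
        m2 = np.exp(2 * mu + 2 * s**2) * stats.norm.cdf(z - 2 * s) / denom
        return float(m1), float(m2 - m1**2)

    def equations(params):
        mu, s = params
        if s <= 0:
            return [1e6, 1e6]
        m1, var = truncated_moments(mu, s)
        return [m1 - target_mean, var - target_sd**2]

    sol, info, ier, _ = optimize.fsolve(
        equations, x0=[mu0, s0], full_output=True
    )
    if ier != 1:
        raise ConfigurationError(
            f"cannot match age mean {target_mean} / SD {target_sd} on [0, {upper}]"
        )
    return float(sol[0]), float(sol[1])


def sample_ages(
    n: int, config: PhantomConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``n`` chronological ages from a truncated shifted log-normal.

    The log-normal parameters are moment-matched numerically so that the
    *truncated* distribution (support ``[age_min, age_max]``) has mean
    ``age_mean`` and SD ``age_sd``; sampling is by rejection, keeping the
    right skew characteristic of young-adult-heavy imaging cohorts.
    """
    if n < 0:
        raise ConfigurationError("n must be non-negative")
    if rng is None:
        rng = _named_rng(config.seed, "ages")
    if n == 0:
        return np.empty(0)
    if config.age_mean <= config.age_min:
        raise ConfigurationError("age_mean must exceed age_min")
    mu, sigma = _truncated_lognormal_params(
        config.age_mean - config.age_min,
        config.age_sd,
        config.age_max - config.age_min,
    )
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = config.age_min + rng.lognormal(mu, sigma, size=n - filled)
        keep = draw[draw <= config.age_max]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return np.clip(out, config.age_min, config.age_max)


def make_atlas(
    grid: tuple[int, int, int], n_parcels: int, seed: int = 0
) -> ParcelAtlas:
    """Tile an interior ellipsoidal brain mask with ``n_parcels`` parcels.

    Parcel centroids are sampled uniformly from the mask and every mask voxel
    is assigned to its nearest centroid, so labels 1..n_parcels are contiguous
    blobs and each contains at least its own centroid voxel.  Label 0 is
    background.
    """
    grid = tuple(int(g) for g in grid)
    idx = np.indices(grid, dtype=float)
    center = [(g - 1) / 2 for g in grid]
    semi = [0.45 * g for g in grid]
    r2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    mask = r2 <= 1.0
    coords = np.argwhere(mask)
    if n_parcels > len(coords):
        raise ConfigurationError(
            f"{n_parcels} parcels requested but mask has only {len(coords)} voxels"
        )
    rng = np.random.default_rng(seed)
    centroid_idx = rng.choice(len(coords), size=n_parcels, replace=False)
    centroids = coords[centroid_idx].astype(float)
    # nearest-centroid assignment; centroid voxels are at distance 0 from
    # themselves so every label is nonempty
    d2 = ((coords[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    assignment = np.argmin(d2, axis=1) + 1
    labels = np.zeros(grid, dtype=np.int32)
    labels[tuple(coords.T)] = assignment
    return ParcelAtlas(labels=labels)


def channel_effect_params(
    config: PhantomConfig, atlas: ParcelAtlas
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-channel baseline and slope vectors (one entry per parcel).

    Drawn once per cohort from a seed-keyed stream, or taken from
    ``config.effect_slopes`` where given.  Density-like channels get a larger
    slope scale than volume-like channels; the stub channel carries no age
    effect at all.
    """
    rng = _named_rng(config.seed, "effects")
    scale = {"t1": 0.003, "gmv": 0.004, "wmv": 0.004, "gmd": 0.008, "wmd": 0.008}
    baselines: dict[str, np.ndarray] = {}
    slopes: dict[str, np.ndarray] = {}
    for name in config.channels:
        baselines[name] = rng.uniform(0.5, 1.5, size=atlas.n_parcels)
        s = scale.get(name, 0.0)
        sl = rng.uniform(-s, s, size=atlas.n_parcels) if s > 0 else np.zeros(atlas.n_parcels)
        if config.effect_slopes is not None and name in config.effect_slopes:
            for label, value in config.effect_slopes[name].items():
                pos = int(np.searchsorted(atlas.label_ids, label))
                if pos >= atlas.n_parcels or atlas.label_ids[pos] != label:
                    raise ConfigurationError(f"unknown parcel label {label}")
                sl[pos] = value
        slopes[name] = sl
    return baselines, slopes


def render_subject(
    record: SubjectRecord,
    atlas: ParcelAtlas,
    config: PhantomConfig,
    params: tuple[dict[str, np.ndarray], dict[str, np.ndarray]] | None = None,
) -> SubjectVolume:
    """Render one subject's multichannel volume.

    Voxels in parcel p of channel c take value
    ``baseline[c][p] + slope[c][p] * (age - age_mean) + N(0, noise_sd)``;
    background voxels are exactly zero.  Deterministic given
    ``(config.seed, subject_id)``.
    """
    if atlas.shape != tuple(config.grid):
        raise ConfigurationError(
            f"atlas grid {atlas.shape} does not match config grid {tuple(config.grid)}"
        )
    if params is None:
        params = channel_effect_params(config, atlas)
    baselines, slopes = params
    rng = _subject_rng(config.seed, record.subject_id)
    labels = atlas.labels
    inside = labels > 0
    # lookup table indexed by label value (position 0 unused)
    channels: dict[str, np.ndarray] = {}
    for name in config.channels:
        lut = np.zeros(int(atlas.label_ids[-1]) + 1)
        lut[atlas.label_ids] = baselines[name] + slopes[name] * (
            record.age - config.age_mean
        )
        vol = lut[labels]
        if config.noise_sd > 0:
            vol = vol + rng.normal(0.0, config.noise_sd, size=vol.shape) * inside
        vol[~inside] = 0.0
        channels[name] = vol.astype(np.float32)
    return SubjectVolume(
        subject_id=record.subject_id, channels=channels, voxel_size=config.voxel_size
    )


def make_cohort(
    config: PhantomConfig,
    atlas: ParcelAtlas | None = None,
    outdir: str | Path | None = None,
) -> tuple[list[SubjectVolume], pd.DataFrame]:
    """Generate the full phantom cohort (volumes + subject table).

    When ``outdir`` is given, each subject is written as one 4D NIfTI file and
    the table as ``cohort.csv`` with columns subject_id, age, sex.
    """
    if atlas is None:
        atlas = make_atlas(config.grid, config.n_parcels, seed=config.seed)
    ages = sample_ages(config.n_subjects, config)
    sex_rng = _named_rng(config.seed, "sex")
    sexes = sex_rng.integers(0, 2, size=config.n_subjects)
    records = [
        SubjectRecord(subject_id=f"sub-{i + 1:04d}", age=float(a), sex=int(s))
        for i, (a, s) in enumerate(zip(ages, sexes))
    ]
    params = channel_effect_params(config, atlas)
    volumes = [render_subject(rec, atlas, config, params=params) for rec in records]
    table = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
        }
    )
    if outdir is not None:
        from .preprocess import save_subject  # local import avoids cycle at import time

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        try:
            for vol in volumes:
                save_subject(vol, outdir)
            table.to_csv(outdir / "cohort.csv", index=False)
        except OSError as err:
            raise OSError(f"failed writing cohort under {outdir}: {err}") from err
    return volumes, table
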
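"""Run configuration: one YAML document driving the whole pipeline.

A single global seed fans out deterministically to per-stage seeds (simulate,
CV, each network) so two runs from one config are numerically identical.
Desk-scale defaults are active (small grid, few components, quarter-width
network, short training); the full-scale values used on real morphometry data
(121 x 145 x 121 grid at 1.5 mm, K = 400 components, 442-parcel atlas,
full-width network, 300 epochs) are documented in ``docs/methods.md`` and can
be set from the same YAML keys.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .ml import CVConfig
from .nn.resnet import ResNet26Spec
from .nn.train import TrainConfig
from .synthetic import PhantomConfig


@dataclass
class FeatureConfig:
    parcel_channels: tuple[str, ...] = ("gmv", "gmd")
    sica_channels: tuple[str, ...] = ("gmv", "gmd", "wmv", "wmd")
    n_components: int = 20  # K; 400 at full scale
    mask_frac: float = 0.95


@dataclass
class DLConfig:
    """Which Objective-1 members to train and with what schedule."""

    members: tuple[str, ...] = ("model1-1", "model1-4")
    grid: tuple[int, int, int] = (16, 16, 16)  # 121x145x121 at full scale
    spec: ResNet26Spec = field(default_factory=lambda: ResNet26Spec.desk())
    train: TrainConfig = field(default_factory=lambda: TrainConfig(epochs=10))


@dataclass
class RunConfig:
    stages: tuple[str, ...] = (
        "simulate",
        "preprocess",
        "features",
        "train_ml",
        "train_dl",
        "ensemble",
        "evaluate",
    )
    seed: int = 0
    outdir: str = "runs"
    val_fraction: float = 0.2
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    dl: DLConfig = field(default_factory=DLConfig)
    ensemble_objective: int = 1

    def __post_init__(self) -> None:
        # one global seed fans out to stage seeds
        self.phantom = dataclasses.replace(self.phantom, seed=self._stage_seed("simulate"))
        self.cv = dataclasses.replace(self.cv, seed=self._stage_seed("ml"))
        self.dl.train = dataclasses.replace(self.dl.train, seed=self._stage_seed("dl"))

    def _stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "little") % (2**31)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(_as_jsonable(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    return obj


def _build(cls, data: dict):
    """Construct a dataclass from a plain dict, coercing lists to tuples."""
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if dataclasses.is_dataclass(f.type) and isinstance(value, dict):
            value = _build(f.type, value)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


_NESTED = {
    "phantom": PhantomConfig,
    "cv": CVConfig,
    "features": FeatureConfig,
}


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file (missing keys take defaults)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key, value in data.items():
        if key in _NESTED and isinstance(value, dict):
            kwargs[key] = _build(_NESTED[key], value)
        elif key == "dl" and isinstance(value, dict):
            dl_kwargs = {}
            if "members" in value:
                dl_kwargs["members"] = tuple(value["members"])
            if "spec" in value:
                dl_kwargs["spec"] = _build(ResNet26Spec, value["spec"])
            if "train" in value:
                dl_kwargs["train"] = _build(TrainConfig, value["train"])
            kwargs[key] = DLConfig(**dl_kwargs)
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)
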
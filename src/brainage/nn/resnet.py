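"""The 26-layer 3D residual age regressor.

The network is a stem 3x3x3 convolution followed by 12 residual blocks, global
average pooling and a single linear output unit — 26 weighted layers on the
main path (1 stem conv + 24 block convs + 1 linear).  Each block is
conv-BN-ReLU-dropout-conv-BN with a shortcut add and a trailing ReLU; blocks
flagged stride-2 halve each spatial dimension with a stride-2 first conv and a
1x1 stride-2 convolution (plus BN) on the shortcut.  Optionally a binary sex
covariate is concatenated to the pooled feature vector before the linear head.

Channel widths are not dictated by the architecture sketch; the defaults here
start at 16 and double at each of the three stride-2 stages (16-32-64-128).
A quarter-width "desk" variant is provided for CPU-scale experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import BatchNorm3d, Conv3d, Dropout, GlobalAvgPool3d, Linear, ReLU


@dataclass
class ResNet26Spec:
    """Architecture hyperparameters.

    ``stage_widths`` has one entry per resolution stage (the first stage runs
    at full resolution); ``stride2_block_indices`` are the blocks that open
    stages 1..len-1 by downsampling.
    """

    in_channels: int = 3
    stem_width: int = 16
    stage_widths: tuple[int, ...] = (16, 32, 64, 128)
    n_blocks: int = 12
    stride2_block_indices: tuple[int, ...] = (3, 6, 9)
    dropout_rate: float = 0.1
    sex_input: bool = False

    def __post_init__(self) -> None:
        if self.n_blocks != 12:
            raise ValueError("the architecture is fixed at 12 residual blocks")
        if len(self.stage_widths) != len(self.stride2_block_indices) + 1:
            raise ValueError("need one stage width per resolution stage")
        if any(i <= 0 or i >= self.n_blocks for i in self.stride2_block_indices):
            raise ValueError("stride-2 blocks must be interior block indices")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    def block_width(self, i: int) -> int:
        stage = sum(1 for s in self.stride2_block_indices if s <= i)
        return self.stage_widths[stage]

    @classmethod
    def desk(cls, in_channels: int = 3, **kw) -> "ResNet26Spec":
        """Quarter-width variant for CPU-scale runs."""
        return cls(
            in_channels=in_channels,
            stem_width=4,
            stage_widths=(4, 8, 16, 32),
            **kw,
        )


class ResidualBlock:
    def __init__(
        self,
        in_width: int,
        out_width: int,
        stride: int,
        dropout_rate: float,
        rng: np.random.Generator,
        dropout_rng: np.random.Generator,
    ) -> None:
        self.conv1 = Conv3d(in_width, out_width, 3, stride=stride, rng=rng)
        self.bn1 = BatchNorm3d(out_width)
        self.relu1 = ReLU()
        self.drop = Dropout(dropout_rate, rng=dropout_rng)
        self.conv2 = Conv3d(out_width, out_width, 3, stride=1, rng=rng)
        self.bn2 = BatchNorm3d(out_width)
        self.relu_out = ReLU()
        self.downsample = stride != 1 or in_width != out_width
        if self.downsample:
            self.conv_sc = Conv3d(in_width, out_width, 1, stride=stride, padding=0, rng=rng)
            self.bn_sc = BatchNorm3d(out_width)

    def layers(self) -> list:
        base = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.downsample:
            base += [self.conv_sc, self.bn_sc]
        return base

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = self.conv1.forward(x, training)
        out = self.bn1.forward(out, training)
        out = self.relu1.forward(out, training)
        out = self.drop.forward(out, training)
        out = self.conv2.forward(out, training)
        out = self.bn2.forward(out, training)
        if self.downsample:
            sc = self.bn_sc.forward(self.conv_sc.forward(x, training), training)
        else:
            sc = x
        return self.relu_out.forward(out + sc, training)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dout)
        dsc = d
        dmain = self.bn2.backward(d)
        dmain = self.conv2.backward(dmain)
        dmain = self.drop.backward(dmain)
        dmain = self.relu1.backward(dmain)
        dmain = self.bn1.backward(dmain)
        dx = self.conv1.backward(dmain)
        if self.downsample:
            dx = dx + self.conv_sc.backward(self.bn_sc.backward(dsc))
        else:
            dx = dx + dsc
        return dx


class ResNet26:
    """Maps (N, C, D, H, W) inputs (plus optional sex) to (N,) predicted ages."""

    def __init__(self, spec: ResNet26Spec, seed: int = 0) -> None:
        self.spec = spec
        init_rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        self.dropout_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        self.stem = Conv3d(spec.in_channels, spec.stem_width, 3, rng=init_rng)
        self.stem_bn = BatchNorm3d(spec.stem_width)
        self.stem_relu = ReLU()
        self.blocks: list[ResidualBlock] = []
        in_w = spec.stem_width
        for i in range(spec.n_blocks):
            out_w = spec.block_width(i)
            stride = 2 if i in spec.stride2_block_indices else 1
            self.blocks.append(
                ResidualBlock(in_w, out_w, stride, spec.dropout_rate, init_rng, self.dropout_rng)
            )
            in_w = out_w
        self.pool = GlobalAvgPool3d()
        head_in = in_w + (1 if spec.sex_input else 0)
        self.head = Linear(head_in, 1, rng=init_rng)
        self._sex_used: bool = False

    # -- introspection ------------------------------------------------------
    @property
    def n_residual_blocks(self) -> int:
        return len(self.blocks)

    def main_path_weighted_layers(self) -> int:
        """Stem conv + two convs per block + the linear head (shortcuts excluded)."""
        return 1 + 2 * len(self.blocks) + 1

    def parameter_layers(self) -> list:
        layers = [self.stem, self.stem_bn]
        for b in self.blocks:
            layers.extend(b.layers())
        layers.append(self.head)
        return layers

    def parameters(self) -> list[tuple[str, dict, dict]]:
        out = []
        for i, layer in enumerate(self.parameter_layers()):
            out.append((f"layer{i}", layer.params, layer.grads))
        return out

    def n_parameters(self) -> int:
        return sum(p.size for _, params, _ in self.parameters() for p in params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, params, _ in self.parameters():
            for k, v in params.items():
                state[f"{name}.{k}"] = v.copy()
        for i, layer in enumerate(self.parameter_layers()):
            if isinstance(layer, BatchNorm3d):
                state[f"layer{i}.running_mean"] = layer.running_mean.copy()
                state[f"layer{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, params, _ in self.parameters():
            for k in params:
                params[k][...] = state[f"{name}.{k}"]
        for i, layer in enumerate(self.parameter_layers()):
            if isinstance(layer, BatchNorm3d):
                layer.running_mean[...] = state[f"layer{i}.running_mean"]
                layer.running_var[...] = state[f"layer{i}.running_var"]

    def zero_grad(self) -> None:
        for layer in self.parameter_layers():
            layer.zero_grad()

    # -- passes -------------------------------------------------------------
    def _check_grid(self, spatial: tuple[int, ...]) -> None:
        halvings = len(self.spec.stride2_block_indices)
        for d in spatial:
            if d % (2**halvings) != 0:
                raise ValueError(
                    f"grid {spatial} not divisible by 2^{halvings} for the "
                    "stride-2 stages"
                )

    def forward(
        self, x: np.ndarray, sex: np.ndarray | None = None, training: bool = True
    ) -> np.ndarray:
        if x.ndim != 5 or x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected (N, {self.spec.in_channels}, D, H, W) input, got {x.shape}"
            )
        self._check_grid(x.shape[2:])
        if self.spec.sex_input and sex is None:
            raise ValueError("this model requires a sex covariate")
        h = self.stem.forward(x, training)
        h = self.stem_bn.forward(h, training)
        h = self.stem_relu.forward(h, training)
        for block in self.blocks:
            h = block.forward(h, training)
        pooled = self.pool.forward(h, training)
        if self.spec.sex_input:
            pooled = np.concatenate(
                [pooled, np.asarray(sex, dtype=float).reshape(-1, 1)], axis=1
            )
            self._sex_used = True
        else:
            self._sex_used = False
        return self.head.forward(pooled, training)[:, 0]

    def backward(self, dpred: np.ndarray) -> None:
        d = self.head.backward(np.asarray(dpred).reshape(-1, 1))
        if self._sex_used:
            d = d[:, :-1]  # gradient w.r.t. the sex scalar is discarded
        d = self.pool.backward(d)
        for block in reversed(self.blocks):
            d = block.backward(d)
        d = self.stem_relu.backward(d)
        d = self.stem_bn.backward(d)
        self.stem.backward(d)

    def predict(
        self, x: np.ndarray, sex: np.ndarray | None = None, batch_size: int = 8
    ) -> np.ndarray:
        """Eval-mode predictions (running BN stats, no dropout)."""
        preds = []
        for i in range(0, x.shape[0], batch_size):
            s = None if sex is None else sex[i : i + batch_size]
            preds.append(self.forward(x[i : i + batch_size], sex=s, training=False))
        return np.concatenate(preds) if preds else np.empty(0)


def build_model(spec: ResNet26Spec, seed: int = 0) -> ResNet26:
    """Construct a deterministic network from its spec and seed."""
    return ResNet26(spec, seed=seed)
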
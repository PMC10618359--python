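"""D-VGG: a compact residual VGG-style grading network with channel attention.

The backbone is five "stack" blocks of two 3×3 convolutions each, with widths
32→64→128→256→512 (a 32-wide stack prepended to, and the deepest 512 group
removed from, the VGG16 plan).  Each stack carries batch normalization after
every convolution and a 1×1 batch-normalized shortcut added before the final
activation.  Every block is followed by a squeeze-and-excitation attention
module (squeeze = midpoint of global average and global max pooling,
excitation = linear→ReLU6→linear→sigmoid) and a 2×2 max pool.  A global
average pooling head replaces fully connected layers: 224×224 input reaches
the head as 7×7×512, is pooled to a 512-vector and mapped by a single linear
layer to softmax class probabilities.

Ablation variants are plain flags on :class:`DVGGConfig`: ``use_residual`` /
``use_batchnorm`` off reproduces the residual+BN ablation, ``use_se`` off the
attention ablation.  Convolutions followed by BN carry no bias; when BN is
ablated the biases come back.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import Layer, Param

__all__ = [
    "StackSpec",
    "SEBlockSpec",
    "DVGGConfig",
    "Stack",
    "DVGG",
    "se_squeeze",
    "se_excite",
    "se_rescale",
    "build_stack",
    "build_dvgg",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# declarative specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StackSpec:
    """One residual conv stack: two 3×3 convolutions plus a 1×1 shortcut."""

    in_channels: int
    out_channels: int
    conv_kernel: int = 3
    shortcut_kernel: int = 1
    use_batchnorm: bool = True
    use_residual: bool = True


@dataclass(frozen=True)
class SEBlockSpec:
    """Squeeze-and-excitation geometry: C channels reduced by ratio r."""

    channels: int
    reduction: int = 16

    def __post_init__(self) -> None:
        if self.channels % self.reduction:
            raise ValueError(
                f"channels {self.channels} not divisible by reduction {self.reduction}"
            )


@dataclass(frozen=True)
class DVGGConfig:
    """Declarative description of the full network and its ablations.

    ``stack_widths`` fixes both the depth (number of blocks) and channel
    widths; the default five-block 32→512 plan expects a 224×224 input and
    hands a 7×7×512 map to global average pooling.  ``input_size`` must be
    divisible by 2^len(stack_widths).
    """

    stack_widths: tuple[int, ...] = (32, 64, 128, 256, 512)
    num_classes: int = 6
    se_ratio: int = 16
    input_size: int = 224
    use_residual: bool = True
    use_batchnorm: bool = True
    use_se: bool = True
    use_gap_head: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_size % (2 ** len(self.stack_widths)):
            raise ValueError(
                f"input size {self.input_size} not divisible through "
                f"{len(self.stack_widths)} 2×2 pools"
            )

    @property
    def gap_spatial(self) -> int:
        return self.input_size // (2 ** len(self.stack_widths))


# ---------------------------------------------------------------------------
# functional squeeze-and-excitation (channel-last, single feature map)
# ---------------------------------------------------------------------------

def se_squeeze(feature_map: np.ndarray) -> np.ndarray:
    """Per-channel squeeze of an H×W×C map: midpoint of mean and max.

    z_c = GMP_c + (GAP_c − GMP_c)/2 = (mean_c + max_c)/2.
    """
    fm = np.asarray(feature_map, dtype=np.float64)
    if fm.ndim != 3:
        raise ValueError(f"expected an H×W×C feature map, got shape {fm.shape}")
    flat = fm.reshape(-1, fm.shape[2])
    return (flat.mean(axis=0) + flat.max(axis=0)) / 2.0


def se_excite(
    z: np.ndarray,
    w1: np.ndarray,
    b1: np.ndarray,
    w2: np.ndarray,
    b2: np.ndarray,
) -> np.ndarray:
    """Excitation s = Sigmoid(L2(ReLU6(L1(z)))); every weight lies in (0, 1)."""
    z = np.asarray(z, dtype=np.float64)
    if w1.shape[1] != z.shape[0] or w2.shape[1] != w1.shape[0]:
        raise ValueError("excitation weight dimensions do not match the squeeze vector")
    return nn.sigmoid(nn.relu6(w1 @ z + b1) @ w2.T + b2)


def se_rescale(feature_map: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Channel-wise rescale U_c = u_c · s_c of an H×W×C map."""
    fm = np.asarray(feature_map, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    if s.shape != (fm.shape[2],):
        raise ValueError("weight vector length must equal the channel count")
    return fm * s[None, None, :]


# ---------------------------------------------------------------------------
# network modules
# ---------------------------------------------------------------------------

class Stack(Layer):
    """Two 3×3 conv layers with optional BN and a 1×1 residual shortcut.

    Residual form: out = ReLU(conv→BN→ReLU→conv→BN  +  1×1 conv→BN).
    Plain form (no residual): [conv→(BN)→ReLU] × 2.
    The addition happens before the final ReLU; the shortcut carries its own
    BN and no activation.
    """

    def __init__(self, spec: StackSpec, rng: np.random.Generator) -> None:
        self.spec = spec
        bias = not spec.use_batchnorm
        cin, cout = spec.in_channels, spec.out_channels
        self.conv1 = nn.Conv2d(cin, cout, spec.conv_kernel, bias=bias, rng=rng)
        self.bn1 = nn.BatchNorm2d(cout) if spec.use_batchnorm else None
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(cout, cout, spec.conv_kernel, bias=bias, rng=rng)
        self.bn2 = nn.BatchNorm2d(cout) if spec.use_batchnorm else None
        self.relu2 = nn.ReLU()
        if spec.use_residual:
            self.shortcut = nn.Conv2d(cin, cout, spec.shortcut_kernel, bias=bias, rng=rng)
            self.bn_sc = nn.BatchNorm2d(cout) if spec.use_batchnorm else None
        else:
            self.shortcut = None
            self.bn_sc = None

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in (self.conv1, self.bn1, self.conv2, self.bn2, self.shortcut, self.bn_sc):
            if layer is not None:
                out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.conv1.forward(x, train)
        if self.bn1 is not None:
            h = self.bn1.forward(h, train)
        h = self.relu1.forward(h, train)
        h = self.conv2.forward(h, train)
        if self.bn2 is not None:
            h = self.bn2.forward(h, train)
        if self.shortcut is not None:
            sc = self.shortcut.forward(x, train)
            if self.bn_sc is not None:
                sc = self.bn_sc.forward(sc, train)
            return self.relu2.forward(h + sc, train)
        return self.relu2.forward(h, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu2.backward(dout)
        dx = np.zeros(0)
        if self.shortcut is not None:
            dsc = d
            if self.bn_sc is not None:
                dsc = self.bn_sc.backward(dsc)
            dx = self.shortcut.backward(dsc)
        dh = d
        if self.bn2 is not None:
            dh = self.bn2.backward(dh)
        dh = self.conv2.backward(dh)
        dh = self.relu1.backward(dh)
        if self.bn1 is not None:
            dh = self.bn1.backward(dh)
        dh = self.conv1.backward(dh)
        return dh + dx if self.shortcut is not None else dh


class DVGG(Layer):
    """The assembled network: blocks of [stack, attention, pool] plus the head."""

    def __init__(self, config: DVGGConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        widths = config.stack_widths
        layers: list[Layer] = []
        cin = 3
        for width in widths:
            layers.append(
                Stack(
                    StackSpec(
                        cin,
                        width,
                        use_batchnorm=config.use_batchnorm,
                        use_residual=config.use_residual,
                    ),
                    rng,
                )
            )
            if config.use_se:
                layers.append(nn.SEBlock(width, config.se_ratio, rng=rng))
            layers.append(nn.MaxPool2d())
            cin = width
        self.features = nn.Sequential(*layers)
        if config.use_gap_head:
            self.head_pool: Layer = nn.GlobalAvgPool()
            head_in = widths[-1]
        else:
            self.head_pool = nn.Flatten()
            head_in = widths[-1] * config.gap_spatial**2
        self.classifier = nn.Linear(head_in, config.num_classes, rng=rng)

    def params(self) -> list[Param]:
        return self.features.params() + self.classifier.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch of NCHW images."""
        h = self.features.forward(np.asarray(x, dtype=np.float64), train)
        self._gap_input_shape = h.shape  # (N, C, s, s) entering the head
        h = self.head_pool.forward(h, train)
        return self.classifier.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.classifier.backward(dlogits)
        d = self.head_pool.backward(d)
        return self.features.backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities in eval mode (running BN statistics)."""
        return nn.softmax(self.forward(x, train=False), axis=1)

    # -- (de)serialization ---------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        j = 0
        for layer in self._bn_layers():
            state[f"bn_{j}_mean"] = layer.running_mean
            state[f"bn_{j}_var"] = layer.running_var
            j += 1
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value = np.array(state[f"param_{i}"], dtype=np.float64)
            p.grad = np.zeros_like(p.value)
        for j, layer in enumerate(self._bn_layers()):
            layer.running_mean = np.array(state[f"bn_{j}_mean"], dtype=np.float64)
            layer.running_var = np.array(state[f"bn_{j}_var"], dtype=np.float64)

    def _bn_layers(self) -> list[nn.BatchNorm2d]:
        out = []
        for layer in self.features.layers:
            if isinstance(layer, Stack):
                out.extend(b for b in (layer.bn1, layer.bn2, layer.bn_sc) if b is not None)
        return out


def build_stack(spec: StackSpec, seed: int = 0) -> Stack:
    """Construct a single stack block from its spec."""
    return Stack(spec, np.random.default_rng(seed))


def build_dvgg(config: DVGGConfig | None = None) -> DVGG:
    """Construct the network (default: the full five-block grading model)."""
    return DVGG(config or DVGGConfig())


def count_parameters(model: Layer) -> int:
    """Number of trainable scalars (conv/linear weights+biases, BN γ/β).

    BN running statistics are buffers, not parameters, and are excluded.
    """
    return int(sum(p.value.size for p in model.params()))


def save_checkpoint(model: DVGG, path: str | Path) -> None:
    """Weights as .npz plus a JSON sidecar serializing the config."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_arrays())
    sidecar = asdict(model.config)
    sidecar["stack_widths"] = list(model.config.stack_widths)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> DVGG:
    path = Path(path)
    cfg = json.loads(path.with_suffix(".json").read_text())
    cfg["stack_widths"] = tuple(cfg["stack_widths"])
    model = DVGG(DVGGConfig(**cfg))
    with np.load(path.with_suffix(".npz")) as state:
        model.load_state_arrays(dict(state))
    return model
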
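"""Network architectures: side-branch attention blocks, channel attention,
scaled dot-product attention, the attention-enhanced classifier and a
residual (ResNet-style) baseline.

The attention-enhanced net keeps the feature map at full spatial resolution
through a stack of shape-preserving *side-branch blocks*: each block runs the
feature map through a main convolution and, in parallel, through two side
branches that reduce resolution/channels by strided convolution and restore
them by transposed convolution, then fuses everything back (element-wise
addition by default, a sigmoid gate optionally) under a residual skip. A
global average pool and a linear head produce the two class logits
(pneumonia vs normal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import (
    AdamW,  # noqa: F401  (re-exported for convenience)
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    GlobalAvgPool,
    Layer,
    Linear,
    MaxPool2d,
    Param,
    ReLU,
    Sequential,
    sigmoid,
    softmax,
)

__all__ = [
    "AttentionQKV",
    "NetworkConfig",
    "scaled_dot_product_attention",
    "SideBranchBlock",
    "ChannelAttention",
    "side_branch_block",
    "channel_attention",
    "build_attention_net",
    "build_resnet_baseline",
    "resnet_shape_walk",
    "ImageClassifier",
    "PAPER_CONFIG",
    "DESK_CONFIG",
]


class ConfigError(ValueError):
    """A network configuration violates one of its invariants."""


# ---------------------------------------------------------------------------
# scaled dot-product attention
# ---------------------------------------------------------------------------

@dataclass
class AttentionQKV:
    """Query/key/value matrices for Attention(Q,K,V) = softmax(QKᵀ/√d_k)V."""

    q: np.ndarray
    k: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.q.ndim != 2 or self.k.ndim != 2 or self.v.ndim != 2:
            raise ConfigError("Q, K, V must be 2-D matrices")
        if self.q.shape[1] != self.k.shape[1]:
            raise ConfigError(
                f"Q has d_k={self.q.shape[1]} but K has d_k={self.k.shape[1]}")
        if self.k.shape[0] != self.v.shape[0]:
            raise ConfigError(
                f"K has {self.k.shape[0]} rows but V has {self.v.shape[0]}")

    @property
    def d_k(self) -> int:
        return self.q.shape[1]


def scaled_dot_product_attention(qkv: AttentionQKV,
                                 return_weights: bool = False):
    """softmax(QKᵀ/√d_k)V; each output row is a convex combination of V's rows."""
    scores = qkv.q @ qkv.k.T / np.sqrt(qkv.d_k)
    weights = softmax(scores, axis=-1)
    out = weights @ qkv.v
    if return_weights:
        return out, weights
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    input_size is (H, W, channels). ``branch_reduction`` r divides the channel
    count in the side branches (C -> C/r); ``branch_stride`` s is their spatial
    down/up-sampling factor. ``fusion_mode`` selects additive fusion (the
    default) or a sigmoid gate on the branch sum multiplying the main path.
    """

    input_size: tuple[int, int, int] = (512, 512, 3)
    stem_channels: int = 64
    n_blocks: int = 8
    branch_reduction: int = 4
    branch_stride: int = 2
    fusion_mode: str = "additive"
    use_channel_attention: bool = False
    n_classes: int = 2

    def validate(self) -> None:
        h, w, c = self.input_size
        problems = []
        if h < 1 or w < 1 or c not in (1, 3):
            problems.append(f"input_size {self.input_size} (channels must be 1 or 3)")
        if self.stem_channels < 1:
            problems.append(f"stem_channels {self.stem_channels} < 1")
        if self.n_blocks < 1:
            problems.append(f"n_blocks {self.n_blocks} < 1")
        if self.branch_reduction < 1 or self.stem_channels % self.branch_reduction:
            problems.append(
                f"branch_reduction {self.branch_reduction} must divide stem_channels")
        if self.branch_stride < 1 or h % self.branch_stride or w % self.branch_stride:
            problems.append(
                f"H and W must be divisible by branch_stride {self.branch_stride}")
        if self.fusion_mode not in ("additive", "gated"):
            problems.append(f"fusion_mode {self.fusion_mode!r}")
        if self.n_classes < 2:
            problems.append(f"n_classes {self.n_classes} < 2")
        if problems:
            raise ConfigError("invalid NetworkConfig: " + "; ".join(problems))


PAPER_CONFIG = NetworkConfig()
#: reduced preset for CPU-scale experiments on the synthetic phantoms
DESK_CONFIG = NetworkConfig(input_size=(64, 64, 1), stem_channels=8, n_blocks=2)


# ---------------------------------------------------------------------------
# side-branch attention block
# ---------------------------------------------------------------------------

class SideBranchBlock(Layer):
    """Shape-preserving block: main conv + two reduce/upsample side branches.

    ``out = F + fuse(MainConv(F), Σ_branches Upsample(ReduceConv(F)))`` with
    additive fusion ``main + branch_sum`` or gated fusion
    ``sigmoid(branch_sum) * main``. The residual skip and the per-conv batch
    normalization can be disabled for analytic tests.
    """

    def __init__(self, channels: int, reduction: int = 4, stride: int = 2,
                 reduce_ksize: int = 3, up_ksize: int | None = None,
                 fusion_mode: str = "additive", use_skip: bool = True,
                 use_norm: bool = True, n_branches: int = 2,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        if up_ksize is None:
            up_ksize = 2 * stride if stride > 1 else 3
        up_pad = (up_ksize - stride) // 2
        if up_ksize - 2 * up_pad != stride:
            raise ConfigError(
                f"up_ksize {up_ksize} incompatible with stride {stride}: "
                "transposed conv cannot restore the input size")
        if channels % reduction:
            raise ConfigError(f"reduction {reduction} must divide channels {channels}")
        if fusion_mode not in ("additive", "gated"):
            raise ConfigError(f"unknown fusion_mode {fusion_mode!r}")
        cmid = channels // reduction
        self.channels = channels
        self.stride = stride
        self.fusion_mode = fusion_mode
        self.use_skip = use_skip
        self.use_norm = use_norm

        def norm():
            return BatchNorm2d(channels, dtype=dtype) if use_norm else None

        self.main = Conv2d(channels, channels, 3, stride=1, pad=1, rng=rng, dtype=dtype)
        self.main_norm = norm()
        self.branches = []
        for _ in range(n_branches):
            reduce = Conv2d(channels, cmid, reduce_ksize, stride=stride,
                            pad=reduce_ksize // 2, rng=rng, dtype=dtype)
            rnorm = BatchNorm2d(cmid, dtype=dtype) if use_norm else None
            relu = ReLU()
            up = ConvTranspose2d(cmid, channels, up_ksize, stride=stride,
                                 pad=up_pad, rng=rng, dtype=dtype)
            unorm = norm()
            self.branches.append((reduce, rnorm, relu, up, unorm))

    def forward(self, x, training=False):
        c, h, w = x.shape[1], x.shape[2], x.shape[3]
        if c != self.channels:
            raise ConfigError(f"expected {self.channels} channels, got {c}")
        if h % self.stride or w % self.stride:
            raise ConfigError(
                f"spatial dims ({h},{w}) not divisible by branch stride {self.stride}")
        main = self.main.forward(x, training)
        if self.main_norm is not None:
            main = self.main_norm.forward(main, training)
        branch_sum = None
        for reduce, rnorm, relu, up, unorm in self.branches:
            b = reduce.forward(x, training)
            if rnorm is not None:
                b = rnorm.forward(b, training)
            b = relu.forward(b, training)
            b = up.forward(b, training)
            if unorm is not None:
                b = unorm.forward(b, training)
            branch_sum = b if branch_sum is None else branch_sum + b
        if self.fusion_mode == "additive":
            fused = main + branch_sum
            self._gate = None
        else:
            gate = sigmoid(branch_sum)
            fused = gate * main
            self._gate = gate
            self._main_out = main
            self._branch_sum_pre = branch_sum
        return x + fused if self.use_skip else fused

    def backward(self, dy):
        if self.fusion_mode == "additive":
            dmain = dy
            dbranch = dy
        else:
            gate = self._gate
            dmain = dy * gate
            dbranch = dy * self._main_out * gate * (1.0 - gate)
        if self.main_norm is not None:
            dmain = self.main_norm.backward(dmain)
        dx = self.main.backward(dmain)
        for reduce, rnorm, relu, up, unorm in self.branches:
            db = dbranch
            if unorm is not None:
                db = unorm.backward(db)
            db = up.backward(db)
            db = relu.backward(db)
            if rnorm is not None:
                db = rnorm.backward(db)
            dx = dx + reduce.backward(db)
        if self.use_skip:
            dx = dx + dy
        return dx

    def params(self):
        out = self.main.params()
        if self.main_norm is not None:
            out += self.main_norm.params()
        for reduce, rnorm, relu, up, unorm in self.branches:
            out += reduce.params()
            if rnorm is not None:
                out += rnorm.params()
            out += up.params()
            if unorm is not None:
                out += unorm.params()
        return out

    def out_shape(self, shape):
        return shape


class ChannelAttention(Layer):
    """Squeeze-and-gate channel attention.

    Global average pooling yields a per-channel descriptor; a two-layer
    bottleneck (reduction r, ReLU) maps it back to C gates through a sigmoid,
    and the feature map is rescaled channel-wise. Gates lie strictly in (0,1).
    """

    def __init__(self, channels: int, reduction: int = 4,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        cmid = max(1, channels // reduction)
        self.fc1 = Linear(channels, cmid, rng=rng, dtype=dtype)
        self.fc2 = Linear(cmid, channels, rng=rng, dtype=dtype)

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        d = x.mean(axis=(2, 3))
        hmid = self.fc1.forward(d, training)
        self._hmask = hmid > 0
        hact = hmid * self._hmask
        z = self.fc2.forward(hact, training)
        g = sigmoid(z)
        self._cache = (x, g)
        return x * g[:, :, None, None]

    def backward(self, dy):
        x, g = self._cache
        n, c, h, w = x.shape
        dx = dy * g[:, :, None, None]
        dg = (dy * x).sum(axis=(2, 3))
        dz = dg * g * (1.0 - g)
        dh = self.fc2.backward(dz)
        dh = dh * self._hmask
        dd = self.fc1.backward(dh)
        dx = dx + (dd / (h * w))[:, :, None, None]
        return dx

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def out_shape(self, shape):
        return shape

    def gates(self, x: np.ndarray) -> np.ndarray:
        """Return the per-sample channel gates for inspection."""
        d = x.mean(axis=(2, 3))
        hmid = np.maximum(self.fc1.forward(d), 0.0)
        return sigmoid(hmid @ self.fc2.w.data.T + self.fc2.b.data)


def side_branch_block(f_map: np.ndarray, block: SideBranchBlock,
                      training: bool = False) -> np.ndarray:
    """Functional wrapper: apply a side-branch block to an NCHW feature map."""
    return block.forward(f_map, training=training)


def channel_attention(f_map: np.ndarray, module: ChannelAttention,
                      training: bool = False) -> np.ndarray:
    """Functional wrapper: apply channel attention to an NCHW feature map."""
    return module.forward(f_map, training=training)


# ---------------------------------------------------------------------------
# full classifiers
# ---------------------------------------------------------------------------

@dataclass
class _WalkEntry:
    name: str
    shape: tuple


class ImageClassifier:
    """A sequential classifier with named stages and a shape walk.

    ``forward`` takes an NCHW float batch and returns (N, n_classes) logits.
    """

    def __init__(self, stages: list[tuple[str, Layer]], config: NetworkConfig):
        self.stages = stages
        self.net = Sequential([layer for _, layer in stages])
        self.config = config

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x)
        h, w, c = self.config.input_size
        if x.ndim != 4 or x.shape[1] != c:
            raise ConfigError(
                f"expected batch of shape (N,{c},H,W), got {x.shape}")
        return self.net.forward(x, training=training)

    __call__ = forward

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.net.backward(dlogits)

    def params(self) -> list[Param]:
        return self.net.params()

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Argmax class per sample (0 = normal, 1 = pneumonia)."""
        return self.forward(x, training=False).argmax(axis=1)

    def shape_walk(self) -> list[_WalkEntry]:
        """Named (stage, shape) trace, spatial shapes reported as (H, W, C)."""
        h, w, c = self.config.input_size
        shape = (c, h, w)
        walk = [_WalkEntry("input", (h, w, c))]
        for name, layer in self.stages:
            shape = layer.out_shape(shape)
            pretty = (shape[1], shape[2], shape[0]) if len(shape) == 3 else shape
            walk.append(_WalkEntry(name, pretty))
        return walk

    def n_params(self) -> int:
        return sum(p.data.size for p in self.params())


def build_attention_net(config: NetworkConfig = DESK_CONFIG,
                        seed: int = 0) -> ImageClassifier:
    """Stem conv -> n_blocks side-branch blocks (optional channel attention)
    -> global average pool -> linear head."""
    config.validate()
    rng = np.random.default_rng(seed)
    h, w, c_in = config.input_size
    c = config.stem_channels
    stages: list[tuple[str, Layer]] = [
        ("stem", Sequential([
            Conv2d(c_in, c, 3, stride=1, pad=1, rng=rng),
            BatchNorm2d(c),
            ReLU(),
        ])),
    ]
    for i in range(config.n_blocks):
        block_layers: list[Layer] = [SideBranchBlock(
            c, reduction=config.branch_reduction, stride=config.branch_stride,
            fusion_mode=config.fusion_mode, rng=rng)]
        if config.use_channel_attention:
            block_layers.append(ChannelAttention(c, reduction=config.branch_reduction,
                                                 rng=rng))
        stages.append((f"block{i + 1}", Sequential(block_layers)))
    stages.append(("pool", GlobalAvgPool()))
    stages.append(("head", Linear(c, config.n_classes, rng=rng)))
    return ImageClassifier(stages, config)


class _ResidualBlock(Layer):
    """Basic two-conv residual block with a projection skip when needed."""

    def __init__(self, cin: int, cout: int, stride: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, pad=1, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(cout, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, stride=1, pad=1, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(cout, dtype=dtype)
        self.relu_out = ReLU()
        if stride != 1 or cin != cout:
            self.proj = Conv2d(cin, cout, 1, stride=stride, pad=0, bias=False,
                               rng=rng, dtype=dtype)
            self.proj_bn = BatchNorm2d(cout, dtype=dtype)
        else:
            self.proj = None

    def forward(self, x, training=False):
        y = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, training), training))
        y = self.bn2.forward(self.conv2.forward(y, training), training)
        if self.proj is not None:
            skip = self.proj_bn.forward(self.proj.forward(x, training), training)
        else:
            skip = x
        return self.relu_out.forward(y + skip, training)

    def backward(self, dy):
        dy = self.relu_out.backward(dy)
        dmain = self.bn2.backward(dy)
        dmain = self.conv2.backward(dmain)
        dmain = self.relu1.backward(dmain)
        dmain = self.bn1.backward(dmain)
        dx = self.conv1.backward(dmain)
        if self.proj is not None:
            dx = dx + self.proj.backward(self.proj_bn.backward(dy))
        else:
            dx = dx + dy
        return dx

    def params(self):
        out = (self.conv1.params() + self.bn1.params()
               + self.conv2.params() + self.bn2.params())
        if self.proj is not None:
            out += self.proj.params() + self.proj_bn.params()
        return out

    def out_shape(self, shape):
        shape = self.conv1.out_shape(shape)
        return shape


#: ResNet-50 stage output channels after each bottleneck stage
_RESNET50_STAGE_CHANNELS = (256, 512, 1024, 2048)


def resnet_shape_walk(input_size: int) -> list[tuple[int, int, int]]:
    """Stage output shapes (H, W, C) of the ResNet-50 front end.

    For a square ``input_size`` the walk is: 7x7/2 stem conv with 64 filters,
    3x3/2 max pool, then four bottleneck stages (conv2_x..conv5_x) ending at
    2048 channels; conv2_x keeps the pooled resolution, each later stage
    halves it.
    """
    if input_size < 32:
        raise ConfigError(
            f"input_size {input_size} too small for 5 downsamplings (needs >= 32)")
    h = -(-input_size // 2)          # stem conv, stride 2, pad 3 (ceil)
    walk = [(h, h, 64)]
    h = -(-h // 2)                   # 3x3 max pool, stride 2
    walk.append((h, h, 64))
    for i, c in enumerate(_RESNET50_STAGE_CHANNELS):
        if i > 0:
            h = -(-h // 2)
        walk.append((h, h, c))
    return walk


def build_resnet_baseline(config: NetworkConfig = DESK_CONFIG,
                          seed: int = 0) -> ImageClassifier:
    """Depth-reduced residual baseline honoring the ResNet shape walk.

    Stem 7x7/2 conv + 3x3/2 max pool, then ``config.n_blocks`` basic residual
    stages each halving resolution and doubling channels from
    ``stem_channels``, then global average pool and a linear head.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    h, w, c_in = config.input_size
    if min(h, w) < 16:
        raise ConfigError(f"input {h}x{w} too small for the residual baseline")
    c = config.stem_channels
    stages: list[tuple[str, Layer]] = [
        ("stem", Sequential([
            Conv2d(c_in, c, 7, stride=2, pad=3, rng=rng),
            BatchNorm2d(c),
            ReLU(),
            MaxPool2d(3, 2, 1),
        ])),
    ]
    cin = c
    for i in range(config.n_blocks):
        cout = c * (2 ** (i + 1))
        stages.append((f"conv{i + 2}_x", _ResidualBlock(cin, cout, stride=2, rng=rng)))
        cin = cout
    stages.append(("pool", GlobalAvgPool()))
    stages.append(("head", Linear(cin, config.n_classes, rng=rng)))
    return ImageClassifier(stages, config)
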
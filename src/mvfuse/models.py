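"""Two-view fusion classifier and its comparator architectures.

The primary model classifies a weakly-labelled artery segment from a pair of
orthogonal grayscale views:

1. each view is passed through one *shared* (Siamese) residual backbone,
   yielding a spatial grid of L feature vectors ``q_i`` of dimension D;
2. a shared linear map projects every vector to dimension M < D and the two
   grids are stacked into a 2L x M instance matrix ``Q~``;
3. a content-attention module scores every instance,
   ``s_k = w^T tanh(V q~_k)`` (optionally gated by ``sigmoid(U q~_k)``),
   normalises the scores with a softmax into weights ``a`` and forms the
   segment representation ``z = sum_k a_k q~_k`` — a convex combination, which
   is what makes the attention weights interpretable as instance importance;
4. a fully-connected head maps ``z`` to a culprit probability via a sigmoid.

Comparators:

* ``ChannelsModel`` — the two views stacked as input channels of a single
  backbone (no Siamese branch, no cross-view instance pooling);
* ``ConcatModel`` — per-view global max-pooled backbone features concatenated
  and classified by a fully-connected head.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import Parameter, Tensor, concat, conv2d, maximum

__all__ = [
    "ModelConfig",
    "Backbone",
    "FusionModel",
    "ChannelsModel",
    "ConcatModel",
    "build_model",
    "extract_features",
    "project_stack",
    "attention_pool",
    "classify",
    "fusion_forward",
    "channels_forward",
    "concat_forward",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The default layer plan is a reduced residual network: a strided stem
    convolution followed by four stages of basic blocks (two 3x3 convolutions
    each, identity or 1x1-projected shortcut).  With ``blocks=(1, 2, 2, 1)``
    that is 1 + 12 = 13 convolutions plus the classifier head — 14 weighted
    layers, the smallest conventional plan consistent with a depth-14
    residual net.  Total stride 16, so a 96 px input yields a 6x6 grid of
    L = 36 feature vectors per view.
    """

    input_size: int = 96
    in_channels: int = 1
    widths: tuple[int, ...] = (16, 32, 64, 128)
    blocks: tuple[int, ...] = (1, 2, 2, 1)
    strides: tuple[int, ...] = (1, 2, 2, 2)
    stem_stride: int = 2
    projection_dim: int = 64
    attention_hidden: int = 64
    gated_attention: bool = False
    classifier_hidden: tuple[int, ...] = ()
    dropout: float = 0.0          # on projected instance vectors, training only
    relu_slope: float = 0.05      # leaky backbone activations: no dead units
    init_seed: int = 0

    @property
    def feature_dim(self) -> int:
        return self.widths[-1]

    @property
    def total_stride(self) -> int:
        return self.stem_stride * int(np.prod(self.strides))

    @property
    def grid_size(self) -> int:
        return self.input_size // self.total_stride

    def __post_init__(self):
        if self.input_size < 32:
            raise ValueError("input_size must be >= 32")
        if not (0 < self.projection_dim <= self.feature_dim):
            raise ValueError("projection_dim must satisfy 0 < M <= D")
        if len(self.widths) != len(self.blocks) or len(self.widths) != len(self.strides):
            raise ValueError("widths, blocks and strides must have equal length")
        if self.grid_size < 1 or self.grid_size >= self.input_size:
            raise ValueError("feature grid must be non-empty and coarser than the input")

    @staticmethod
    def small(input_size: int = 48, **kw) -> "ModelConfig":
        """A desk-scale backbone: 3 stages, moderate width, CPU-trainable."""
        return ModelConfig(input_size=input_size, widths=(16, 32, 48), blocks=(1, 1, 1),
                           strides=(1, 2, 2), projection_dim=24, attention_hidden=24, **kw)

    @staticmethod
    def tiny(input_size: int = 32, **kw) -> "ModelConfig":
        """The smallest usable backbone, for tests and CPU-bound protocols."""
        return ModelConfig(input_size=input_size, widths=(8, 16, 32), blocks=(1, 1, 1),
                           strides=(1, 2, 2), projection_dim=16, attention_hidden=16, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        d = dict(d)
        for k in ("widths", "blocks", "strides", "classifier_hidden"):
            if k in d:
                d[k] = tuple(d[k])
        return ModelConfig(**d)


def _he(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(np.float32)


class _Conv:
    def __init__(self, rng, cin, cout, k=3, stride=1):
        self.w = Parameter(_he(rng, (cout, cin, k, k), cin * k * k))
        self.b = Parameter(np.zeros(cout, dtype=np.float32))
        self.stride = stride
        self.pad = k // 2

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)

    def params(self):
        return [self.w, self.b]


class _Linear:
    def __init__(self, rng, din, dout, scale=None):
        s = math.sqrt((2.0 if scale is None else scale) / din)
        self.w = Parameter((rng.standard_normal((din, dout)) * s).astype(np.float32))
        self.b = Parameter(np.zeros(dout, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def params(self):
        return [self.w, self.b]


class _Norm:
    """Per-sample layer normalisation over (C, H, W) with a channel affine.

    Batch-independent (the same segment always normalises the same way), so
    evaluation is deterministic and the Siamese view-swap symmetry is exact.
    """

    def __init__(self, channels: int):
        self.g = Parameter(np.ones((1, channels, 1, 1), dtype=np.float32))
        self.b = Parameter(np.zeros((1, channels, 1, 1), dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(1, 2, 3), keepdims=True)
        return xc * ((var + 1e-5) ** -0.5) * self.g + self.b

    def params(self):
        return [self.g, self.b]


class _BasicBlock:
    """Residual basic block: conv-norm-relu-conv-norm, additive shortcut."""

    def __init__(self, rng, cin, cout, stride, slope=0.0):
        self.conv1 = _Conv(rng, cin, cout, stride=stride)
        self.norm1 = _Norm(cout)
        self.conv2 = _Conv(rng, cout, cout)
        self.norm2 = _Norm(cout)
        self.proj = _Conv(rng, cin, cout, k=1, stride=stride) if (stride != 1 or cin != cout) else None
        self.slope = slope

    def __call__(self, x: Tensor) -> Tensor:
        h = self.norm2(self.conv2(self.norm1(self.conv1(x)).relu(self.slope)))
        sc = self.proj(x) if self.proj is not None else x
        return (h + sc).relu(self.slope)

    def params(self):
        out = (self.conv1.params() + self.norm1.params()
               + self.conv2.params() + self.norm2.params())
        if self.proj is not None:
            out += self.proj.params()
        return out


class Backbone:
    """Shared convolutional feature extractor.

    Maps an ``(N, C, H, W)`` image batch to an ``(N, L, D)`` grid of feature
    vectors (row-major over the spatial grid).  One instance of this class is
    used for *both* views of a pair — the Siamese weight-sharing contract is
    object identity, not weight copying.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        self.stem = _Conv(rng, config.in_channels, config.widths[0], stride=config.stem_stride)
        self.stem_norm = _Norm(config.widths[0])
        self.stages: list[_BasicBlock] = []
        cin = config.widths[0]
        for width, n_blocks, stride in zip(config.widths, config.blocks, config.strides):
            for i in range(n_blocks):
                self.stages.append(_BasicBlock(rng, cin, width, stride if i == 0 else 1,
                                               slope=config.relu_slope))
                cin = width

    def __call__(self, x: Tensor) -> Tensor:
        h = self.stem_norm(self.stem(x)).relu(self.config.relu_slope)
        for block in self.stages:
            h = block(h)
        n, d, gh, gw = h.shape
        return h.reshape(n, d, gh * gw).transpose(0, 2, 1)  # (N, L, D), row-major

    def params(self):
        out = self.stem.params() + self.stem_norm.params()
        for b in self.stages:
            out += b.params()
        return out


class _AttentionPool:
    """Content attention over instance vectors (tanh gate, optional sigmoid gate)."""

    def __init__(self, rng, dim, hidden, gated):
        self.V = _Linear(rng, dim, hidden, scale=1.0)
        self.U = _Linear(rng, dim, hidden, scale=1.0) if gated else None
        self.w = _Linear(rng, hidden, 1, scale=1.0)

    def scores(self, q: Tensor) -> Tensor:
        h = self.V(q).tanh()
        if self.U is not None:
            h = h * self.U(q).sigmoid()
        return self.w(h).reshape(q.shape[0], q.shape[1])  # (N, K)

    def __call__(self, q: Tensor) -> tuple[Tensor, Tensor]:
        a = self.scores(q).softmax(axis=-1)                       # (N, K)
        z = (q * a.reshape(a.shape[0], a.shape[1], 1)).sum(axis=1)  # (N, dim)
        return z, a

    def params(self):
        out = self.V.params() + self.w.params()
        if self.U is not None:
            out += self.U.params()
        return out


class _Head:
    """Fully-connected classifier ending in a single sigmoid logit."""

    def __init__(self, rng, din, hidden: tuple[int, ...]):
        self.layers: list[_Linear] = []
        for h in hidden:
            self.layers.append(_Linear(rng, din, h))
            din = h
        self.out = _Linear(rng, din, 1, scale=1.0)

    def logit(self, z: Tensor) -> Tensor:
        for layer in self.layers:
            z = layer(z).relu()
        return self.out(z).reshape(z.shape[0])

    def __call__(self, z: Tensor) -> Tensor:
        return self.logit(z).sigmoid()

    def params(self):
        out = []
        for layer in self.layers:
            out += layer.params()
        return out + self.out.params()


class _ModelBase:
    """Shared training-mode / dropout plumbing."""

    training: bool = False
    _drop_rng: np.random.Generator | None = None

    def set_training(self, training: bool, rng: np.random.Generator | None = None) -> None:
        self.training = bool(training)
        self._drop_rng = rng

    def _dropout(self, t: Tensor) -> Tensor:
        p = self.config.dropout
        if not self.training or p <= 0.0:
            return t
        keep = (self._drop_rng.random(t.shape) >= p).astype(np.float32) / (1.0 - p)
        return t * Tensor(keep)


class FusionModel(_ModelBase):
    """Learned two-view fusion: Siamese backbone -> shared projection ->
    instance stacking -> content-attention pooling -> sigmoid head."""

    arch = "fusion"

    def __init__(self, config: ModelConfig):
        rng = np.random.default_rng(config.init_seed)
        self.config = config
        self.backbone = Backbone(config, rng)
        self.projection = _Linear(rng, config.feature_dim, config.projection_dim, scale=1.0)
        self.attention = _AttentionPool(rng, config.projection_dim,
                                        config.attention_hidden, config.gated_attention)
        self.head = _Head(rng, config.projection_dim, config.classifier_hidden)

    def forward(self, x1: Tensor, x2: Tensor) -> tuple[Tensor, Tensor]:
        # Mathematically this is attention pooling over the stacked 2L
        # instances; it is computed from per-view partial sums joined only by
        # commutative ops (+, elementwise max), so swapping the two views
        # gives the bit-identical score.
        q1 = self._dropout(self.projection(self.backbone(x1)))
        q2 = self._dropout(self.projection(self.backbone(x2)))  # same backbone object: Siamese contract
        s1 = self.attention.scores(q1)                # (N, L)
        s2 = self.attention.scores(q2)
        m = maximum(s1.max(axis=1, keepdims=True), s2.max(axis=1, keepdims=True))
        e1, e2 = (s1 - m).exp(), (s2 - m).exp()
        denom = e1.sum(axis=1, keepdims=True) + e2.sum(axis=1, keepdims=True)
        inv = denom ** -1.0
        part1 = (q1 * e1.reshape(e1.shape[0], e1.shape[1], 1)).sum(axis=1)
        part2 = (q2 * e2.reshape(e2.shape[0], e2.shape[1], 1)).sum(axis=1)
        z = (part1 + part2) * inv
        a = concat([e1, e2], axis=1) * inv
        return self.head(z), a

    def __call__(self, x1: Tensor, x2: Tensor) -> Tensor:
        return self.forward(x1, x2)[0]

    def params(self):
        return (self.backbone.params() + self.projection.params()
                + self.attention.params() + self.head.params())

    def param_groups(self) -> dict[str, list[Parameter]]:
        return {"backbone": self.backbone.params(), "projection": self.projection.params(),
                "attention": self.attention.params(), "head": self.head.params()}


class ChannelsModel(_ModelBase):
    """Views-as-channels comparator: one backbone over a 2-channel input."""

    arch = "channels"

    def __init__(self, config: ModelConfig):
        if config.in_channels != 2:
            config = ModelConfig.from_dict({**config.to_dict(), "in_channels": 2})
        rng = np.random.default_rng(config.init_seed)
        self.config = config
        self.backbone = Backbone(config, rng)
        self.projection = _Linear(rng, config.feature_dim, config.projection_dim, scale=1.0)
        self.attention = _AttentionPool(rng, config.projection_dim,
                                        config.attention_hidden, config.gated_attention)
        self.head = _Head(rng, config.projection_dim, config.classifier_hidden)

    def __call__(self, x1: Tensor, x2: Tensor) -> Tensor:
        x = concat([x1, x2], axis=1)                  # channel stacking: order matters
        z, _ = self.attention(self._dropout(self.projection(self.backbone(x))))
        return self.head(z)

    def params(self):
        return (self.backbone.params() + self.projection.params()
                + self.attention.params() + self.head.params())


class ConcatModel(_ModelBase):
    """Feature-concatenation comparator: per-view global max-pooled backbone
    features, concatenated and classified by a fully-connected head."""

    arch = "concat"

    def __init__(self, config: ModelConfig):
        rng = np.random.default_rng(config.init_seed)
        self.config = config
        self.backbone = Backbone(config, rng)
        self.head = _Head(rng, 2 * config.feature_dim, config.classifier_hidden)

    def __call__(self, x1: Tensor, x2: Tensor) -> Tensor:
        p1 = self._dropout(self.backbone(x1).max(axis=1))   # (N, D) global max pool
        p2 = self._dropout(self.backbone(x2).max(axis=1))
        return self.head(concat([p1, p2], axis=1))

    def params(self):
        return self.backbone.params() + self.head.params()


_ARCHS = {"fusion": FusionModel, "channels": ChannelsModel, "concat": ConcatModel}


def build_model(arch: str, config: ModelConfig):
    if arch not in _ARCHS:
        raise ValueError(f"unknown architecture {arch!r}; expected one of {sorted(_ARCHS)}")
    return _ARCHS[arch](config)


# ---------------------------------------------------------------------------
# Functional stage API (numpy in / numpy out), mirroring the pipeline stages.
# ---------------------------------------------------------------------------

def _as_batch(view: np.ndarray) -> Tensor:
    """Accept (H, W), (C, H, W) or (N, C, H, W) and return a 4-D tensor."""
    a = np.asarray(view, dtype=np.float32)
    if a.ndim == 2:
        a = a[None, None]
    elif a.ndim == 3:
        a = a[None]
    return Tensor(a)


def extract_features(view: np.ndarray, backbone: Backbone) -> np.ndarray:
    """Run one view through the shared backbone; returns the (L, D) grid."""
    a = np.asarray(view)
    expected = backbone.config.input_size
    if a.shape[-1] != expected or a.shape[-2] != expected:
        raise ValueError(f"view is {a.shape[-2]}x{a.shape[-1]}, backbone expects "
                         f"{expected}x{expected}")
    out = backbone(_as_batch(view)).numpy()
    return out[0] if a.ndim == 2 else out


def project_stack(fg1: np.ndarray, fg2: np.ndarray, projection: _Linear) -> np.ndarray:
    """Project both feature grids with the shared map and stack to (2L, M)."""
    fg1, fg2 = np.asarray(fg1, np.float32), np.asarray(fg2, np.float32)
    if fg1.shape[-1] != fg2.shape[-1]:
        raise ValueError("feature grids disagree on D")
    q = concat([projection(Tensor(fg1[None])), projection(Tensor(fg2[None]))], axis=1)
    return q.numpy()[0]


def attention_pool(stack: np.ndarray, attention: _AttentionPool) -> tuple[np.ndarray, np.ndarray]:
    """Pool an instance stack to (z, a); a is non-negative and sums to 1."""
    stack = np.asarray(stack, np.float32)
    if stack.size == 0:
        raise ValueError("attention_pool: empty instance stack")
    z, a = attention(Tensor(stack[None]))
    return z.numpy()[0], a.numpy()[0]


def classify(z: np.ndarray, head: _Head) -> float | np.ndarray:
    """Map a segment representation to a culprit probability in [0, 1]."""
    z = np.asarray(z, np.float32)
    out = head(Tensor(z[None] if z.ndim == 1 else z)).numpy()
    return float(out[0]) if z.ndim == 1 else out


def fusion_forward(x1: np.ndarray, x2: np.ndarray, model: FusionModel) -> tuple[np.ndarray, np.ndarray]:
    """Full fusion path; returns (scores, attention weights)."""
    s, a = model.forward(_as_batch(x1), _as_batch(x2))
    squeeze = np.asarray(x1).ndim == 2
    return ((float(s.numpy()[0]), a.numpy()[0]) if squeeze else (s.numpy(), a.numpy()))


def channels_forward(x1: np.ndarray, x2: np.ndarray, model: ChannelsModel) -> float | np.ndarray:
    out = model(_as_batch(x1), _as_batch(x2)).numpy()
    return float(out[0]) if np.asarray(x1).ndim == 2 else out


def concat_forward(x1: np.ndarray, x2: np.ndarray, model: ConcatModel) -> float | np.ndarray:
    out = model(_as_batch(x1), _as_batch(x2)).numpy()
    return float(out[0]) if np.asarray(x1).ndim == 2 else out
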
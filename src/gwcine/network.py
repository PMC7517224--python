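"""Convolutional registration network: a reduced U-net in pure NumPy.

The network maps a (frame, template) pair — stacked on the channel axis —
to a dense 2-component displacement field at input resolution.  It is an
encoder-decoder with skip connections that concatenate encoder feature maps
into the decoder, 3x3 convolutions, LeakyReLU activations, 2x max-pooling
and nearest-neighbor upsampling, and a final 1x1 convolution initialized
near zero so the untrained network outputs (almost) the identity transform.

The implementation is deliberately self-contained: each layer provides an
explicit ``forward``/``backward`` pair, and the whole network is trained
with the bundled Adam optimizer.  Backpropagation is validated against
finite differences in the test suite.  Default capacity is small (about
19k parameters with ``depth=3`` and filters 8/16/16): cine motion is
dominated by smooth, low-frequency displacement, so a small network both
trains quickly on a CPU and regularizes implicitly.

Tensors flow through the network channels-last, shape (B, H, W, C), the
same memory layout as the displacement fields (N, H, W, 2), so no data
reordering happens anywhere in the training loop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import CineSequence, DeformationSequence
from .template import TemplateImage

__all__ = [
    "NetConfig",
    "GWNet",
    "Adam",
    "build_network",
    "predict_fields",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = "gwcine-net-1"


@dataclass
class NetConfig:
    depth: int = 3
    base_filters: int = 8
    filters_per_level: tuple[int, ...] | None = None
    activation: str = "leaky_relu"
    leaky_slope: float = 0.2
    use_skip_connections: bool = True
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        if self.activation not in ("leaky_relu", "relu"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.filters_per_level is not None:
            self.filters_per_level = tuple(int(f) for f in self.filters_per_level)
            if len(self.filters_per_level) != self.depth:
                raise ValueError("filters_per_level must have one entry per level")
            if any(f < 1 for f in self.filters_per_level):
                raise ValueError("all channel counts must be >= 1")

    @property
    def filters(self) -> tuple[int, ...]:
        if self.filters_per_level is not None:
            return self.filters_per_level
        # double once, then constant: (8, 16, 16) at the defaults
        return tuple(
            self.base_filters * (2 if i >= 1 else 1) for i in range(self.depth)
        )

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)

    def validate_image_size(self, h: int, w: int) -> None:
        div = 2 ** (self.depth - 1)
        if h % div or w % div:
            raise ValueError(
                f"image size {h}x{w} not divisible by 2^(depth-1)={div}; "
                f"pad to {-(-h // div) * div}x{-(-w // div) * div}"
            )


# ---------------------------------------------------------------------------
# layers (channels-last)
# ---------------------------------------------------------------------------

class Conv2D:
    """Same-padded KxK convolution, im2col in channels-last layout.

    Weights are stored as (K, K, Cin, Cout) so the im2col matrix multiplies
    them without any transposition.
    """

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator,
                 dtype=np.float32, weight_scale: float | None = None):
        self.cin, self.cout, self.k = cin, cout, ksize
        std = weight_scale if weight_scale is not None else np.sqrt(
            2.0 / (cin * ksize * ksize)
        )
        self.weight = rng.normal(0.0, std, size=(ksize, ksize, cin, cout)).astype(dtype)
        self.bias = np.zeros(cout, dtype=dtype)
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)
        self._cols: np.ndarray | None = None
        self._in_shape: tuple | None = None

    @property
    def params(self):
        return [(self.weight, self.grad_weight), (self.bias, self.grad_bias)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # (B, H, W, C, k, k) -> want index order (k, k, C): move window axes first
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(b * h * w, k * k * c)
        return np.ascontiguousarray(cols)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, h, w, c = x.shape
        if self.k == 1:
            cols = x.reshape(b * h * w, c)
        else:
            cols = self._im2col(x)
        wmat = self.weight.reshape(-1, self.cout)
        out = cols @ wmat + self.bias
        if train:
            self._cols = cols
            self._in_shape = x.shape
        return out.reshape(b, h, w, self.cout)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        b, h, w, c = self._in_shape
        k = self.k
        g = gout.reshape(b * h * w, self.cout)
        self.grad_weight += (self._cols.T @ g).reshape(self.grad_weight.shape)
        self.grad_bias += g.sum(axis=0)
        self._cols = None
        if k == 1:
            return (g @ self.weight.reshape(c, self.cout).T).reshape(b, h, w, c)
        # input gradient = convolution of gout with the flipped, transposed
        # kernel: reuse the same im2col machinery
        wflip = self.weight[::-1, ::-1].transpose(0, 1, 3, 2)  # (k,k,Cout,Cin)
        p = k // 2
        gp = np.pad(gout, ((0, 0), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(gp, (k, k), axis=(1, 2))
        gcols = np.ascontiguousarray(
            win.transpose(0, 1, 2, 4, 5, 3).reshape(b * h * w, k * k * self.cout)
        )
        gin = gcols @ wflip.reshape(-1, c)
        return gin.reshape(b, h, w, c)


class LeakyReLU:
    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._mask: np.ndarray | None = None

    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = np.where(self._mask, gout, self.slope * gout)
        self._mask = None
        return g


class MaxPool2:
    """2x2 max pooling as two 1D max steps (rows then columns)."""

    def __init__(self):
        self._i1 = self._i2 = None
        self._shape: tuple | None = None

    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, h, w, c = x.shape
        xr = x.reshape(b, h // 2, 2, w, c)
        i1 = xr.argmax(axis=2)
        m = np.take_along_axis(xr, i1[:, :, None], axis=2)[:, :, 0]
        mr = m.reshape(b, h // 2, w // 2, 2, c)
        i2 = mr.argmax(axis=3)
        out = np.take_along_axis(mr, i2[:, :, :, None], axis=3)[:, :, :, 0]
        if train:
            self._i1, self._i2, self._shape = i1, i2, x.shape
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        gm = np.zeros((b, h // 2, w // 2, 2, c), dtype=gout.dtype)
        np.put_along_axis(gm, self._i2[:, :, :, None], gout[:, :, :, None], axis=3)
        gm = gm.reshape(b, h // 2, w, c)
        gx = np.zeros((b, h // 2, 2, w, c), dtype=gout.dtype)
        np.put_along_axis(gx, self._i1[:, :, None], gm[:, :, None], axis=2)
        self._i1 = self._i2 = None
        return gx.reshape(b, h, w, c)


class UpsampleNearest2:
    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        b, h, w, c = gout.shape
        return gout.reshape(b, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class _ConvBlock:
    """conv -> act -> conv -> act"""

    def __init__(self, cin: int, cout: int, cfg: NetConfig, rng):
        slope = cfg.leaky_slope if cfg.activation == "leaky_relu" else 0.0
        dt = cfg.np_dtype
        self.layers = [
            Conv2D(cin, cout, 3, rng, dtype=dt),
            LeakyReLU(slope),
            Conv2D(cout, cout, 3, rng, dtype=dt),
            LeakyReLU(slope),
        ]

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    @property
    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out


class GWNet:
    """Reduced U-net mapping (frame, template) to a displacement field."""

    def __init__(self, cfg: NetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        filters = cfg.filters
        self.enc_blocks = []
        self.pools = []
        cin = 2
        for lvl in range(cfg.depth - 1):
            self.enc_blocks.append(_ConvBlock(cin, filters[lvl], cfg, rng))
            self.pools.append(MaxPool2())
            cin = filters[lvl]
        self.bottleneck = _ConvBlock(cin, filters[-1], cfg, rng)
        self.ups = []
        self.dec_blocks = []
        cin = filters[-1]
        for lvl in range(cfg.depth - 2, -1, -1):
            self.ups.append(UpsampleNearest2())
            skip = filters[lvl] if cfg.use_skip_connections else 0
            self.dec_blocks.append(_ConvBlock(cin + skip, filters[lvl], cfg, rng))
            cin = filters[lvl]
        # near-zero final 1x1 conv: untrained net ~ identity transform
        self.head = Conv2D(cin, 2, 1, rng, dtype=cfg.np_dtype, weight_scale=1e-5)

    # -- parameter access ---------------------------------------------------
    @property
    def params(self):
        out = []
        for blk in self.enc_blocks:
            out.extend(blk.params)
        out.extend(self.bottleneck.params)
        for blk in self.dec_blocks:
            out.extend(blk.params)
        out.extend(self.head.params)
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.params))

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x: (B, H, W, 2) channels-last -> (B, H, W, 2) displacement."""
        x = np.ascontiguousarray(x, dtype=self.cfg.np_dtype)
        if x.ndim != 4 or x.shape[-1] != 2:
            raise ValueError(f"expected input (B, H, W, 2); got {x.shape}")
        self.cfg.validate_image_size(x.shape[1], x.shape[2])
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            x = blk.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        for up, blk, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            x = up.forward(x, train)
            if self.cfg.use_skip_connections:
                x = np.concatenate([x, skip], axis=-1)
            x = blk.forward(x, train)
        out = self.head.forward(x, train)
        if train:
            self._n_skip_channels = [s.shape[-1] for s in skips]
        return out

    def backward(self, gout: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(output)."""
        g = np.ascontiguousarray(gout, dtype=self.cfg.np_dtype)
        g = self.head.backward(g)
        gskips = [None] * len(self.enc_blocks)
        n_levels = len(self.dec_blocks)
        for i in range(n_levels - 1, -1, -1):
            g = self.dec_blocks[i].backward(g)
            skip_level = len(self.enc_blocks) - 1 - i
            if self.cfg.use_skip_connections:
                nch = self._n_skip_channels[skip_level]
                gskips[skip_level] = g[..., -nch:]
                g = g[..., :-nch]
            g = self.ups[i].backward(g)
        g = self.bottleneck.backward(g)
        for lvl in range(len(self.enc_blocks) - 1, -1, -1):
            g = self.pools[lvl].backward(g)
            if gskips[lvl] is not None:
                g = g + gskips[lvl]
            g = self.enc_blocks[lvl].backward(g)


class Adam:
    """Adam optimizer over a network's (param, grad) pairs."""

    def __init__(self, net: GWNet, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in net.params]
        self.v = [np.zeros_like(p) for p, _ in net.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for (p, g), m, v in zip(self.net.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def build_network(cfg: NetConfig | None = None) -> GWNet:
    """Build a seeded, reproducibly initialized registration network."""
    return GWNet(cfg or NetConfig())


def _input_batch(seq: CineSequence, template: TemplateImage | np.ndarray,
                 dtype) -> np.ndarray:
    tpl = template.image if isinstance(template, TemplateImage) else np.asarray(template)
    if tpl.shape != seq.frame_shape:
        raise ValueError(
            f"template shape {tpl.shape} does not match frames {seq.frame_shape}"
        )
    n = seq.n_frames
    x = np.empty((n, *seq.frame_shape, 2), dtype=dtype)
    x[..., 0] = seq.frames
    x[..., 1] = tpl
    return x


def predict_fields(
    net: GWNet, seq: CineSequence, template: TemplateImage | np.ndarray,
    train: bool = False,
) -> DeformationSequence:
    """Apply the network to every frame against a fixed template.

    The whole sequence is one batch (the batch size used in training).
    Inference is deterministic: no dropout or batch statistics.
    """
    x = _input_batch(seq, template, net.cfg.np_dtype)
    out = net.forward(x, train=train)  # (N, H, W, 2)
    return DeformationSequence(out.astype(np.float64))


def save_checkpoint(net: GWNet, path) -> None:
    """Serialize weights plus the embedded NetConfig to one NPZ file."""
    path = Path(path)
    cfg = net.cfg
    meta = json.dumps(
        {
            "version": CHECKPOINT_VERSION,
            "depth": cfg.depth,
            "base_filters": cfg.base_filters,
            "filters_per_level": list(cfg.filters_per_level) if cfg.filters_per_level else None,
            "activation": cfg.activation,
            "leaky_slope": cfg.leaky_slope,
            "use_skip_connections": cfg.use_skip_connections,
            "seed": cfg.seed,
            "dtype": cfg.dtype,
        }
    )
    arrays = {f"param_{i}": p for i, (p, _) in enumerate(net.params)}
    np.savez(path, config=meta, **arrays)


def load_checkpoint(path) -> GWNet:
    path = Path(path)
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["config"]))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')!r}")
        cfg = NetConfig(
            depth=meta["depth"],
            base_filters=meta["base_filters"],
            filters_per_level=tuple(meta["filters_per_level"])
            if meta["filters_per_level"]
            else None,
            activation=meta["activation"],
            leaky_slope=meta["leaky_slope"],
            use_skip_connections=meta["use_skip_connections"],
            seed=meta["seed"],
            dtype=meta.get("dtype", "float32"),
        )
        net = GWNet(cfg)
        for i, (p, _) in enumerate(net.params):
            p[...] = archive[f"param_{i}"]
    return net
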
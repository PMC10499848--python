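"""Configurable 2D/3D V-Net style encoder-decoder segmentation networks.

The architecture follows the V-Net pattern: per encoder level a stack of
convolution blocks (with a residual add where input and output channel
counts match), 2x downsampling by strided convolution with channel doubling,
a bottleneck stack, and a symmetric decoder whose upsampling (transposed)
convolutions halve the channel count and whose inputs are concatenated with
the matching encoder skip connection.  A final 1-voxel convolution and a
sigmoid produce a per-voxel foreground probability (the background
probability is its complement, so per-voxel class probabilities sum to 1).

Reference configurations (both trained here with the negative-log-dice
loss):

========  ========  ========
field     2D        3D
========  ========  ========
channels  16        12
levels    2         4
convs     [4, 4]    [1, 3, 4, 3]
bottom    2         4
l.r.      0.0005    0.00001
========  ========  ========

Implementation notes.  Convolutions are evaluated spectrally: kernels are
embedded in the field grid and both operands are transformed with a real
FFT, so a convolution of any kernel size costs a fixed number of
transforms, and every adjoint needed for backpropagation (gradient with
respect to input and kernel) is an exact conjugate multiply in the same
basis.  Boundary handling is therefore circular; inputs are reflect-padded
to a multiple of ``2**n_levels`` before inference which keeps wrap-around
effects at the rim of the padding.  Activations are leaky rectifiers
(slope 0.1); elementwise dropout with the configured keep probability is
applied at the end of every block during training only.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import scipy.fft as sfft
import yaml

from .imaging import ProbMap, Volume

__all__ = [
    "VNetConfig",
    "VNet",
    "build_model",
    "predict",
    "predict_slices",
    "save_model",
    "load_model",
    "VIEW_AXES",
]

#: slice axis for per-view 2D models under the (row, column, slice) = axial
#: acquisition convention
VIEW_AXES = {"axial": 2, "coronal": 0, "sagittal": 1}


@dataclass(frozen=True)
class VNetConfig:
    """Architecture and optimizer hyper-parameters for one network."""

    dims: int
    n_channels: int
    n_levels: int
    convs_per_level: tuple[int, ...]
    bottom_convs: int
    learning_rate: float
    dropout_keep_prob: float = 0.95
    kernel_size: int = 5
    in_channels: int = 1
    negative_slope: float = 0.1

    def __post_init__(self):
        object.__setattr__(
            self, "convs_per_level", tuple(int(c) for c in self.convs_per_level)
        )
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if len(self.convs_per_level) != self.n_levels:
            raise ValueError(
                f"convs_per_level has length {len(self.convs_per_level)}, "
                f"expected n_levels = {self.n_levels}"
            )
        if min(self.convs_per_level, default=0) < 1 or self.bottom_convs < 1:
            raise ValueError("all convolution counts must be >= 1")
        if not 0.0 < self.dropout_keep_prob <= 1.0:
            raise ValueError("dropout_keep_prob must lie in (0, 1]")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 1")

    @classmethod
    def default_2d(cls, **overrides) -> "VNetConfig":
        """The reference 2D configuration (16 channels, 2 levels)."""
        kw = dict(dims=2, n_channels=16, n_levels=2, convs_per_level=(4, 4),
                  bottom_convs=2, learning_rate=5e-4)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def default_3d(cls, **overrides) -> "VNetConfig":
        """The reference 3D configuration (12 channels, 4 levels)."""
        kw = dict(dims=3, n_channels=12, n_levels=4,
                  convs_per_level=(1, 3, 4, 3), bottom_convs=4,
                  learning_rate=1e-5)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def tiny(cls, dims: int = 3, **overrides) -> "VNetConfig":
        """A small configuration for phantoms and sanity runs."""
        kw = dict(dims=dims, n_channels=4, n_levels=2, convs_per_level=(1, 1),
                  bottom_convs=1, learning_rate=3e-3, kernel_size=3)
        kw.update(overrides)
        return cls(**kw)


# ---------------------------------------------------------------------------
# primitive layers


class _Conv:
    """One convolution, evaluated as a circular convolution via real FFTs.

    ``mode`` is 'same' (stride 1), 'down' (stride-2 subsample of the full
    convolution) or 'up' (zero-stuffed transposed convolution, 2x upsample).
    """

    def __init__(self, name, c_in, c_out, rank, kernel_size, mode, rng,
                 dtype=np.float32):
        self.name = name
        self.c_in = c_in
        self.c_out = c_out
        self.rank = rank
        self.mode = mode
        k = (kernel_size,) * rank
        std = np.sqrt(2.0 / (c_in * np.prod(k)))
        self.W = (rng.standard_normal((c_out, c_in, *k)) * std).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    # -- helpers ----------------------------------------------------------
    @property
    def _pointwise(self) -> bool:
        return self.W.shape[2] == 1 and self.mode == "same"

    def _flat_index(self, spatial):
        """Flat field index of each kernel tap, centred and wrapped
        (circular convolution; fields smaller than the kernel fold over)."""
        k = self.W.shape[2:]
        grids = np.meshgrid(
            *[(np.arange(n) - n // 2) % s for n, s in zip(k, spatial)],
            indexing="ij",
        )
        return np.ravel_multi_index(grids, spatial).ravel()

    def _kernel_fft(self, spatial):
        fidx = self._flat_index(spatial)
        K = np.zeros((self.c_out, self.c_in, int(np.prod(spatial))),
                     dtype=self.W.dtype)
        np.add.at(K, (slice(None), slice(None), fidx),
                  self.W.reshape(self.c_out, self.c_in, -1))
        K = K.reshape(self.c_out, self.c_in, *spatial)
        return sfft.rfftn(K, axes=tuple(range(2, K.ndim)))

    def _stride_slices(self):
        return (slice(None), *([slice(None, None, 2)] * self.rank))

    # -- forward / backward ----------------------------------------------
    def forward(self, x):
        if self._pointwise:
            w = self.W.reshape(self.c_out, self.c_in)
            y = np.einsum("oi,i...->o...", w, x)
            y += self.b.reshape((-1,) + (1,) * self.rank)
            self._cache = ("pw", x)
            return y
        if self.mode == "up":
            big = tuple(2 * n for n in x.shape[1:])
            xin = np.zeros((self.c_in, *big), dtype=x.dtype)
            xin[self._stride_slices()] = x
        else:
            xin = x
        spatial = xin.shape[1:]
        axes = tuple(range(1, 1 + self.rank))
        xhat = sfft.rfftn(xin, axes=axes)
        what = self._kernel_fft(spatial)
        yhat = np.einsum("oi...,i...->o...", what, xhat)
        y = sfft.irfftn(yhat, s=spatial, axes=axes)
        y += self.b.reshape((-1,) + (1,) * self.rank)
        if self.mode == "down":
            y = y[self._stride_slices()]
        self._cache = ("fft", xhat, what, spatial)
        return np.ascontiguousarray(y)

    def backward(self, g):
        if self._cache[0] == "pw":
            _, x = self._cache
            w = self.W.reshape(self.c_out, self.c_in)
            sp_axes = tuple(range(1, 1 + self.rank))
            self.gW += np.tensordot(g, x, axes=(sp_axes, sp_axes)).reshape(
                self.W.shape
            )
            self.gb += g.sum(axis=sp_axes)
            return np.einsum("oi,o...->i...", w, g)
        _, xhat, what, spatial = self._cache
        axes = tuple(range(1, 1 + self.rank))
        if self.mode == "down":
            gfull = np.zeros((self.c_out, *spatial), dtype=g.dtype)
            gfull[self._stride_slices()] = g
            g = gfull
        self.gb += g.sum(axis=axes)
        ghat = sfft.rfftn(g, axes=axes)
        gx = sfft.irfftn(
            np.einsum("oi...,o...->i...", np.conj(what), ghat),
            s=spatial, axes=axes,
        )
        gk_hat = np.einsum("o...,i...->oi...", ghat, np.conj(xhat))
        gk = sfft.irfftn(gk_hat, s=spatial, axes=tuple(range(2, 2 + self.rank)))
        fidx = self._flat_index(spatial)
        self.gW += gk.reshape(self.c_out, self.c_in, -1)[:, :, fidx].reshape(
            self.W.shape
        )
        if self.mode == "up":
            gx = np.ascontiguousarray(gx[self._stride_slices()])
        return gx

    def zero_grad(self):
        self.gW[...] = 0
        self.gb[...] = 0


class _LeakyReLU:
    def __init__(self, slope):
        self.slope = slope
        self._pos = None

    def forward(self, x):
        self._pos = x > 0
        return np.where(self._pos, x, self.slope * x)

    def backward(self, g):
        return np.where(self._pos, g, self.slope * g)


class _Block:
    """A stack of conv+activation layers with an optional residual add and
    training-time dropout."""

    def __init__(self, name, c_in, c_out, n_convs, rank, kernel_size,
                 keep_prob, slope, rng, dtype):
        self.convs = []
        self.acts = []
        for j in range(n_convs):
            ci = c_in if j == 0 else c_out
            self.convs.append(
                _Conv(f"{name}.conv{j}", ci, c_out, rank, kernel_size,
                      "same", rng, dtype)
            )
            self.acts.append(_LeakyReLU(slope))
        self.residual = c_in == c_out
        self.keep_prob = keep_prob
        self._drop = None

    def forward(self, x, train, rng):
        h = x
        for conv, act in zip(self.convs, self.acts):
            h = act.forward(conv.forward(h))
        if self.residual:
            h = h + x
        if train and self.keep_prob < 1.0:
            self._drop = (rng.random(h.shape) < self.keep_prob).astype(h.dtype)
            h = h * self._drop / self.keep_prob
        else:
            self._drop = None
        return h

    def backward(self, g):
        if self._drop is not None:
            g = g * self._drop / self.keep_prob
        g_res = g if self.residual else None
        for conv, act in zip(reversed(self.convs), reversed(self.acts)):
            g = conv.backward(act.backward(g))
        if g_res is not None:
            g = g + g_res
        return g


class _Unit:
    """A single strided (down) or transposed (up) conv with activation."""

    def __init__(self, name, c_in, c_out, rank, kernel_size, mode, slope,
                 rng, dtype):
        self.conv = _Conv(name, c_in, c_out, rank, kernel_size, mode, rng,
                          dtype)
        self.act = _LeakyReLU(slope)

    def forward(self, x):
        return self.act.forward(self.conv.forward(x))

    def backward(self, g):
        return self.conv.backward(self.act.backward(g))


# ---------------------------------------------------------------------------
# the network


class VNet:
    """An encoder-decoder segmentation network; see the module docstring.

    ``forward`` maps an array of shape ``(in_channels, *spatial)`` to a
    foreground-probability array of the same spatial shape (leading channel
    axis dropped).  Spatial sizes must be divisible by ``2**n_levels``; use
    :func:`predict` for automatic padding.
    """

    def __init__(self, config: VNetConfig, rng=None, dtype=np.float32):
        if rng is None:
            rng = np.random.default_rng(0)
        self.config = config
        self.dtype = dtype
        c = config
        rank = c.dims
        chans = [c.n_channels * 2 ** i for i in range(c.n_levels + 1)]
        self._chans = chans
        args = dict(rank=rank, kernel_size=c.kernel_size,
                    slope=c.negative_slope, rng=rng, dtype=dtype)
        blk = dict(args, keep_prob=c.dropout_keep_prob)
        self.enc = [
            _Block(f"enc{i}", c.in_channels if i == 0 else chans[i], chans[i],
                   c.convs_per_level[i], **blk)
            for i in range(c.n_levels)
        ]
        self.down = [
            _Unit(f"down{i}", chans[i], chans[i + 1], mode="down", **args)
            for i in range(c.n_levels)
        ]
        self.bottom = _Block("bottom", chans[-1], chans[-1], c.bottom_convs,
                             **blk)
        self.up = [
            _Unit(f"up{i}", chans[i + 1], chans[i], mode="up", **args)
            for i in range(c.n_levels)
        ]
        self.dec = [
            _Block(f"dec{i}", 2 * chans[i], chans[i], c.convs_per_level[i],
                   **blk)
            for i in range(c.n_levels)
        ]
        self.out = _Conv("out", chans[0], 1, rank, 1, "same", rng, dtype)
        self._p = None

    # -- bookkeeping -------------------------------------------------------
    def _all_convs(self):
        for block in (*self.enc, self.bottom, *self.dec):
            yield from block.convs
        for unit in (*self.down, *self.up):
            yield unit.conv
        yield self.out

    def parameters(self):
        """Yield (name, weight array, gradient array) triples."""
        for conv in self._all_convs():
            yield f"{conv.name}.W", conv.W, conv.gW
            yield f"{conv.name}.b", conv.b, conv.gb

    @property
    def n_parameters(self) -> int:
        return sum(w.size for _, w, _ in self.parameters())

    def zero_grad(self):
        for conv in self._all_convs():
            conv.zero_grad()

    def state_dict(self):
        return {name: w.copy() for name, w, _ in self.parameters()}

    def load_state_dict(self, state):
        for name, w, _ in self.parameters():
            w[...] = state[name]

    # -- forward / backward -------------------------------------------------
    def forward(self, x, train: bool = False, rng=None):
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == self.config.dims:
            x = x[None]
        if x.ndim != self.config.dims + 1:
            raise ValueError(
                f"expected ({self.config.in_channels}, *spatial) input, "
                f"got shape {x.shape}"
            )
        div = 2 ** self.config.n_levels
        if any(n % div for n in x.shape[1:]):
            raise ValueError(
                f"spatial shape {x.shape[1:]} is not divisible by "
                f"2**n_levels = {div}; pad the input (predict() does)"
            )
        if train and rng is None:
            rng = np.random.default_rng(0)
        skips = []
        h = x
        for i in range(self.config.n_levels):
            h = self.enc[i].forward(h, train, rng)
            skips.append(h)
            h = self.down[i].forward(h)
        h = self.bottom.forward(h, train, rng)
        for i in reversed(range(self.config.n_levels)):
            u = self.up[i].forward(h)
            h = np.concatenate([u, skips[i]], axis=0)
            h = self.dec[i].forward(h, train, rng)
        logits = self.out.forward(h)[0]
        # numerically stable sigmoid
        p = np.empty_like(logits)
        pos = logits >= 0
        p[pos] = 1.0 / (1.0 + np.exp(-logits[pos]))
        ez = np.exp(logits[~pos])
        p[~pos] = ez / (1.0 + ez)
        self._p = p
        return p

    def backward(self, dLdp):
        """Backpropagate a gradient w.r.t. the output probability map."""
        p = self._p
        g = (dLdp * p * (1.0 - p))[None].astype(self.dtype)
        g = self.out.backward(g)
        skip_grads = [None] * self.config.n_levels
        for i in range(self.config.n_levels):
            g = self.dec[i].backward(g)
            c = self._chans[i]
            g_up, skip_grads[i] = g[:c], g[c:]
            g = self.up[i].backward(g_up)
        g = self.bottom.backward(g)
        for i in reversed(range(self.config.n_levels)):
            g = self.down[i].backward(g)
            g = g + skip_grads[i]
            g = self.enc[i].backward(g)
        return g


def build_model(config: VNetConfig, seed: int = 0,
                dtype=np.float32) -> VNet:
    """Construct a :class:`VNet` with seeded weight initialization."""
    return VNet(config, rng=np.random.default_rng(seed), dtype=dtype)


# ---------------------------------------------------------------------------
# inference helpers


def _pad_to_multiple(data: np.ndarray, mult: int):
    pads = []
    for n in data.shape:
        extra = (-n) % mult
        pads.append((0, extra))
    padded = np.pad(data, pads, mode="reflect") if any(
        p[1] for p in pads) else data
    crops = tuple(slice(0, n) for n in data.shape)
    return padded, crops


def predict(model: VNet, v: Volume) -> ProbMap:
    """Run a 3D model on a volume (deterministic; dropout disabled).

    The input is reflect-padded to the nearest multiple of
    ``2**n_levels`` per axis and the output cropped back.
    """
    if model.config.dims != 3:
        raise ValueError("predict() requires a 3D model; see predict_slices")
    padded, crops = _pad_to_multiple(v.data, 2 ** model.config.n_levels)
    p = model.forward(padded, train=False)
    return ProbMap(np.clip(p[crops], 0.0, 1.0), v.spacing)


def predict_slices(model: VNet, v: Volume, view: str = "axial") -> ProbMap:
    """Run a 2D model slice-wise along a view axis and stack the maps."""
    if model.config.dims != 2:
        raise ValueError("predict_slices() requires a 2D model")
    axis = VIEW_AXES[view]
    out = np.empty(v.shape, dtype=np.float32)
    mult = 2 ** model.config.n_levels
    for k in range(v.shape[axis]):
        sl = [slice(None)] * 3
        sl[axis] = k
        plane = v.data[tuple(sl)]
        padded, crops = _pad_to_multiple(plane, mult)
        p = model.forward(padded, train=False)
        out[tuple(sl)] = p[crops]
    return ProbMap(np.clip(out, 0.0, 1.0), v.spacing)


# ---------------------------------------------------------------------------
# checkpoints


def save_model(model: VNet, path) -> None:
    """Save weights plus the embedded configuration to a single file."""
    arrays = {name: w for name, w, _ in model.parameters()}
    cfg = yaml.safe_dump(asdict(model.config))
    np.savez(path, __config__=np.array(cfg), **arrays)


def load_model(path) -> VNet:
    """Rebuild a model from :func:`save_model` output."""
    with np.load(path, allow_pickle=False) as archive:
        cfg = yaml.safe_load(str(archive["__config__"]))
        cfg["convs_per_level"] = tuple(cfg["convs_per_level"])
        model = VNet(VNetConfig(**cfg))
        for name, w, _ in model.parameters():
            w[...] = archive[name]
    return model
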
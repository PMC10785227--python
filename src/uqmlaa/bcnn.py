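"""Dropout-equipped encoder-decoder pseudo-CT regressor.

Maps three pseudo-Dixon MR channels (in-phase, fat fraction, water
fraction) to a CT image in Hounsfield units.  Dropout follows every
convolution (except the output convolution) and stays active at
inference, so repeated stochastic forward passes ("Monte Carlo
dropout") sample the predictive distribution: their per-voxel mean is
the pseudo-CT and their biased (1/N) sample variance is the predictive
uncertainty in HU^2.  Regions unlike anything in the training set —
e.g. the MR signal void of a metal implant inside the body — produce
disagreeing samples and hence high variance, which downstream modules
convert into a weak attenuation prior there.

The network, its backpropagation, and the Adam optimizer are written
directly on numpy arrays (im2col convolutions); the whole model is a
few hundred thousand parameters and trains on a CPU in minutes at the
2-D patch sizes used here.

The training loss combines an L1 term with gradient-difference (GDL)
and Laplacian-difference (LDL) penalties::

    loss = mean|y - yhat|
         + lambda_gdl * sum_axes mean((grad_a y - grad_a yhat)^2)
         + lambda_ldl * mean((lap y - lap yhat)^2)

with forward differences (trailing zero) for the gradient and an
edge-replicate 2*ndim-point stencil for the Laplacian, so that a
constant offset contributes exactly |offset| and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .phantom import PhantomCase

__all__ = ["NetConfig", "TrainConfig", "MCConfig", "ModelState",
           "composite_loss", "composite_loss_grad", "train",
           "mc_dropout_infer"]

_DTYPE = np.float32


# ---------------------------------------------------------------------------
# composite loss (finite differences are shared by loss and tests)

def _fdiff(x: np.ndarray, axis: int) -> np.ndarray:
    """Forward difference with a trailing zero (same shape as x)."""
    d = np.diff(x, axis=axis)
    pad = [(0, 0)] * x.ndim
    pad[axis] = (0, 1)
    return np.pad(d, pad)


def _fdiff_adj(v: np.ndarray, axis: int) -> np.ndarray:
    """Adjoint of :func:`_fdiff`."""
    out = np.zeros_like(v)
    sl_i = [slice(None)] * v.ndim
    sl_im1 = [slice(None)] * v.ndim
    sl_i[axis] = slice(1, None)
    sl_im1[axis] = slice(None, -1)
    out[tuple(sl_i)] += v[tuple(sl_im1)]
    sl_head = [slice(None)] * v.ndim
    sl_head[axis] = slice(None, -1)
    out[tuple(sl_head)] -= v[tuple(sl_head)]
    return out


def _laplacian(x: np.ndarray) -> np.ndarray:
    """2*ndim-point Laplacian with edge-replicate (Neumann) boundaries;
    self-adjoint, and annihilates constants."""
    out = np.zeros_like(x, dtype=np.float64)
    for axis in range(x.ndim):
        up = np.concatenate([x.take([0], axis=axis), x], axis=axis)
        up = up.take(range(x.shape[axis]), axis=axis)
        dn = np.concatenate([x, x.take([-1], axis=axis)], axis=axis)
        dn = dn.take(range(1, x.shape[axis] + 1), axis=axis)
        out += up + dn - 2.0 * x
    return out


def composite_loss(y, yhat, lambda_gdl: float = 0.01,
                   lambda_ldl: float = 0.01) -> float:
    """L1 + GDL + LDL training loss between HU patches (voxel-mean
    reduction per term)."""
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError("patch shapes differ")
    loss = np.abs(y - yhat).mean()
    for axis in range(y.ndim):
        loss += lambda_gdl * ((_fdiff(y, axis) - _fdiff(yhat, axis)) ** 2).mean()
    loss += lambda_ldl * ((_laplacian(y) - _laplacian(yhat)) ** 2).mean()
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite loss")
    return float(loss)


def composite_loss_grad(y, yhat, lambda_gdl: float = 0.01,
                        lambda_ldl: float = 0.01) -> np.ndarray:
    """d(composite_loss)/d(yhat)."""
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    n = y.size
    g = np.sign(yhat - y) / n
    for axis in range(y.ndim):
        diff = _fdiff(yhat, axis) - _fdiff(y, axis)
        g += lambda_gdl * 2.0 / n * _fdiff_adj(diff, axis)
    ldiff = _laplacian(yhat) - _laplacian(y)
    g += lambda_ldl * 2.0 / n * _laplacian(ldiff)  # Laplacian is self-adjoint
    return g


# ---------------------------------------------------------------------------
# configs

@dataclass(frozen=True)
class NetConfig:
    """Encoder-decoder topology.  ``depth`` resolution levels (depth-1
    2x poolings), ``base_channels`` at full resolution doubling per
    level, 3x3 convolutions, dropout after every convolution except the
    output head.  ``hu_scale`` converts the O(1) network output to HU."""

    depth: int = 3
    base_channels: int = 16
    dropout: float = 0.2
    patch_size: tuple[int, int] = (64, 64)
    in_channels: int = 3
    out_channels: int = 1
    hu_scale: float = 1000.0
    #: fixed centring of the [0,1] MR channels.  Keeps first-layer units
    #: active in signal voids (an all-zero input would silence the ReLU
    #: feature maps and with them the dropout variance).
    input_offset: float = 0.5
    #: leaky-ReLU negative slope.  A strictly positive slope keeps every
    #: unit responsive in low-signal regions, so the dropout variance
    #: never collapses to zero just because a region is feature-dead.
    relu_slope: float = 0.1

    def __post_init__(self):
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        div = 2 ** (self.depth - 1)
        if self.patch_size[0] % div or self.patch_size[1] % div:
            raise ValueError("patch size must be divisible by 2**(depth-1)")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.  The Adam moment/epsilon constants, the L2
    weight decay, the loss weights and the minibatch of four follow the
    method's published recipe; the learning rate and iteration count are
    desk-scale defaults for runs of a few minutes."""

    lambda_gdl: float = 0.01
    lambda_ldl: float = 0.01
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    weight_decay: float = 1e-5
    batch_size: int = 4
    iterations: int = 1500
    seed: int = 0

    def __post_init__(self):
        if self.lambda_gdl < 0 or self.lambda_ldl < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo dropout inference settings.  The method's reference
    sample count is 243; tests use fewer."""

    n_samples: int = 243
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("need at least 2 Monte Carlo samples for a variance")


@dataclass
class ModelState:
    """Serializable checkpoint: parameters plus provenance."""

    params: list[np.ndarray]
    net_cfg: NetConfig
    seed: int = 0
    iterations: int = 0
    loss_history: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def final_loss(self) -> float:
        return float(self.loss_history[-1]) if self.loss_history.size else np.nan


# ---------------------------------------------------------------------------
# layers (explicit tape: each layer stores what backward needs)

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    b, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))          # (b,c,h,w,k,k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)
                                ).reshape(b, h * w, c * k * k)


def _col2im(dcols: np.ndarray, xshape, k: int) -> np.ndarray:
    b, c, h, w = xshape
    p = k // 2
    d = dcols.reshape(b, h, w, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + h, j:j + w] += d[:, :, i, j]
    return dxp[:, :, p:p + h, p:p + w] if p else dxp


class _Conv:
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(cout, cin, k, k)).astype(_DTYPE)
        self.b = np.zeros(cout, dtype=_DTYPE)
        self.k = k
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x):
        self._xshape = x.shape
        self._cols = _im2col(x, self.k)
        wm = self.W.reshape(self.W.shape[0], -1)
        y = self._cols @ wm.T + self.b
        b, hw, cout = y.shape
        h, w = self._xshape[2], self._xshape[3]
        return y.transpose(0, 2, 1).reshape(b, cout, h, w)

    def backward(self, dy):
        b, cout, h, w = dy.shape
        dym = dy.reshape(b, cout, h * w).transpose(0, 2, 1)      # (b,hw,cout)
        wm = self.W.reshape(cout, -1)
        flat_dy = dym.reshape(-1, cout)
        flat_cols = self._cols.reshape(-1, self._cols.shape[-1])
        self.gW = (flat_dy.T @ flat_cols).reshape(self.W.shape)
        self.gb = flat_dy.sum(axis=0)
        dcols = dym @ wm
        self._cols = None
        return _col2im(dcols, self._xshape, self.k)


class _LeakyReLU:
    params: list = []
    grads: list = []

    def __init__(self, slope: float):
        self.slope = slope

    def forward(self, x):
        self._scale = np.where(x > 0, np.asarray(1.0, x.dtype),
                               np.asarray(self.slope, x.dtype))
        return x * self._scale

    def backward(self, dy):
        return dy * self._scale


class _Dropout:
    """Inverted dropout, active in training and in MC inference."""

    params: list = []
    grads: list = []

    def __init__(self, p: float):
        self.p = p

    def forward(self, x, rng: np.random.Generator | None):
        if self.p == 0.0 or rng is None:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class _AvgPool2:
    params: list = []
    grads: list = []

    def forward(self, x):
        b, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dy):
        b, c, h, w = self._shape
        return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) * np.asarray(
            0.25, dtype=dy.dtype)


class _Upsample2:
    params: list = []
    grads: list = []

    def forward(self, x):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy):
        b, c, h, w = dy.shape
        return dy.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class _UNet:
    """Depth-``d`` encoder-decoder with skip concatenations.  Two
    conv+ReLU+dropout blocks per level, average-pool down, nearest
    upsample + skip concat on the way up, 1x1 linear output head."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        self.cfg = cfg
        ch = [cfg.base_channels * (2 ** i) for i in range(cfg.depth)]
        self.enc_blocks = []
        cin = cfg.in_channels
        for lv in range(cfg.depth):
            blk = [self._cbr(cin, ch[lv], rng), self._cbr(ch[lv], ch[lv], rng)]
            self.enc_blocks.append(blk)
            cin = ch[lv]
        self.dec_blocks = []
        for lv in range(cfg.depth - 2, -1, -1):
            cin_dec = ch[lv + 1] + ch[lv]  # upsampled + skip
            blk = [self._cbr(cin_dec, ch[lv], rng), self._cbr(ch[lv], ch[lv], rng)]
            self.dec_blocks.append(blk)
        self.head = _Conv(ch[0], cfg.out_channels, 1, rng)
        self.pools = [_AvgPool2() for _ in range(cfg.depth - 1)]
        self.ups = [_Upsample2() for _ in range(cfg.depth - 1)]

    def _cbr(self, cin, cout, rng):
        return (_Conv(cin, cout, 3, rng), _LeakyReLU(self.cfg.relu_slope),
                _Dropout(self.cfg.dropout))

    # ---- parameter plumbing

    def conv_layers(self):
        for blk in self.enc_blocks + self.dec_blocks:
            for conv, _, _ in blk:
                yield conv
        yield self.head

    def params(self):
        out = []
        for conv in self.conv_layers():
            out.extend(conv.params)
        return out

    def grads(self):
        out = []
        for conv in self.conv_layers():
            out.extend(conv.grads)
        return out

    def set_params(self, params: list[np.ndarray]):
        it = iter(params)
        for conv in self.conv_layers():
            conv.W = np.asarray(next(it), dtype=_DTYPE)
            conv.b = np.asarray(next(it), dtype=_DTYPE)

    # ---- forward/backward

    def _run_block(self, blk, x, rng):
        for conv, relu, drop in blk:
            x = drop.forward(relu.forward(conv.forward(x)), rng)
        return x

    def _back_block(self, blk, dy):
        for conv, relu, drop in reversed(blk):
            dy = conv.backward(relu.backward(drop.backward(dy)))
        return dy

    def forward(self, x: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
        """x: (B, in_channels, H, W) -> (B, H, W) in HU.  ``rng=None``
        disables dropout (deterministic pass)."""
        x = np.asarray(x, dtype=_DTYPE) - _DTYPE(self.cfg.input_offset)
        feats = []
        for lv, blk in enumerate(self.enc_blocks):
            x = self._run_block(blk, x, rng)
            if lv < self.cfg.depth - 1:
                feats.append(x)
                x = self.pools[lv].forward(x)
        self._skip_channels = []
        for i, blk in enumerate(self.dec_blocks):
            skip = feats[-(i + 1)]
            x = self.ups[i].forward(x)
            self._skip_channels.append((skip.shape[1], x.shape[1]))
            x = np.concatenate([x, skip], axis=1)
            x = self._run_block(blk, x, rng)
        y = self.head.forward(x)
        return y[:, 0] * self.cfg.hu_scale

    def backward(self, dy: np.ndarray) -> None:
        """Accumulate parameter gradients for dLoss/d(output in HU)."""
        dy = (np.asarray(dy) * self.cfg.hu_scale).astype(_DTYPE)
        d = self.head.backward(dy[:, None])
        dskips = []
        for i in range(len(self.dec_blocks) - 1, -1, -1):
            d = self._back_block(self.dec_blocks[i], d)
            n_skip, n_up = self._skip_channels[i]
            dskips.append(d[:, n_up:])
            d = self.ups[i].backward(d[:, :n_up])
        dskips.reverse()  # dskips[i] pairs with enc level depth-2-i
        for lv in range(self.cfg.depth - 1, -1, -1):
            if lv < self.cfg.depth - 1:
                d = self.pools[lv].backward(d)
                d = d + dskips[-(lv + 1)]
            d = self._back_block(self.enc_blocks[lv], d)


def _build_net(state: ModelState) -> _UNet:
    net = _UNet(state.net_cfg, np.random.default_rng(0))
    net.set_params(state.params)
    return net


# ---------------------------------------------------------------------------
# training

class _Adam:
    def __init__(self, params, cfg: TrainConfig):
        self.cfg = cfg
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.beta1 ** self.t
        bc2 = 1.0 - c.beta2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            g = g + c.weight_decay * p  # L2 regularization
            m *= c.beta1
            m += (1.0 - c.beta1) * g
            v *= c.beta2
            v += (1.0 - c.beta2) * g * g
            p -= c.learning_rate * (m / bc1) / (np.sqrt(v / bc2) + c.eps)


def _sample_patch(case: PhantomCase, rng: np.random.Generator,
                  patch: tuple[int, int]):
    s = int(rng.integers(case.grid_shape[0]))
    ph, pw = patch
    h, w = case.grid_shape[1], case.grid_shape[2]
    if ph > h or pw > w:
        raise ValueError("patch does not fit the case grid")
    r = int(rng.integers(h - ph + 1))
    c = int(rng.integers(w - pw + 1))
    x = case.mr[:, s, r:r + ph, c:c + pw]
    y = case.ct[s, r:r + ph, c:c + pw]
    return x, y


def train(dataset, net_cfg: NetConfig | None = None,
          train_cfg: TrainConfig | None = None,
          allow_implants: bool = False,
          progress: bool = False) -> ModelState:
    """Train the regressor on a list of phantom cases (or a
    ``PhantomDataset``, in which case its training split is used).

    By default refuses cases containing implant voxels: the network must
    only ever see implant-free anatomy so that implants remain
    out-of-distribution and show up in the predictive uncertainty.
    """
    net_cfg = net_cfg or NetConfig()
    train_cfg = train_cfg or TrainConfig()
    cases = dataset.train if hasattr(dataset, "train") else list(dataset)
    if not cases:
        raise ValueError("empty training dataset")
    if not allow_implants:
        for c in cases:
            if c.implant_mask.any():
                raise ValueError(
                    "training case contains an implant; the training policy "
                    "requires implant-free cases (pass allow_implants=True "
                    "to override)")

    ss = np.random.SeedSequence([int(train_cfg.seed), 0xB0])
    init_rng, patch_rng, drop_rng = [np.random.default_rng(s) for s in ss.spawn(3)]
    net = _UNet(net_cfg, init_rng)
    opt = _Adam(net.params(), train_cfg)

    iterator = range(train_cfg.iterations)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="train")

    history = np.empty(train_cfg.iterations)
    for it in iterator:
        xs, ys = [], []
        for _ in range(train_cfg.batch_size):
            ci = int(patch_rng.integers(len(cases)))
            x, y = _sample_patch(cases[ci], patch_rng, net_cfg.patch_size)
            xs.append(x)
            ys.append(y)
        xb = np.stack(xs)
        yb = np.stack(ys)
        pred = net.forward(xb, drop_rng)
        loss = composite_loss(yb, pred, train_cfg.lambda_gdl, train_cfg.lambda_ldl)
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged at iteration {it}: loss={loss}")
        history[it] = loss
        dball = composite_loss_grad(yb, pred, train_cfg.lambda_gdl,
                                    train_cfg.lambda_ldl)
        net.backward(dball)
        opt.step(net.params(), net.grads())

    return ModelState(params=[p.copy() for p in net.params()], net_cfg=net_cfg,
                      seed=train_cfg.seed, iterations=train_cfg.iterations,
                      loss_history=history)


# ---------------------------------------------------------------------------
# Monte Carlo dropout inference

def _tile_positions(n: int, p: int) -> list[int]:
    stride = max(p // 2, 1)
    pos = list(range(0, max(n - p, 0) + 1, stride))
    if pos[-1] != n - p:
        pos.append(n - p)
    return sorted(set(pos))


def _predict_slice(net: _UNet, mr_slice: np.ndarray,
                   rng: np.random.Generator | None) -> np.ndarray:
    """One stochastic full-slice prediction, assembled from overlapping
    patches averaged with uniform weights (stride = half patch)."""
    ph, pw = net.cfg.patch_size
    _, h, w = mr_slice.shape
    out = np.zeros((h, w))
    cover = np.zeros((h, w))
    for r in _tile_positions(h, ph):
        for c in _tile_positions(w, pw):
            pred = net.forward(mr_slice[None, :, r:r + ph, c:c + pw], rng)[0]
            out[r:r + ph, c:c + pw] += pred
            cover[r:r + ph, c:c + pw] += 1.0
    return out / cover


def mc_dropout_infer(model: ModelState, mr: np.ndarray,
                     mc: MCConfig | None = None,
                     return_samples: bool = False):
    """Monte Carlo dropout inference.

    Runs ``mc.n_samples`` stochastic forward passes over the full volume
    and returns ``(pct, variance)``: the per-voxel sample mean (pseudo-CT,
    HU) and the biased 1/N sample variance (HU^2).  With dropout rate 0
    the variance is identically zero.  Bit-reproducible for a fixed model
    and MC seed.  ``return_samples=True`` additionally returns the full
    (N, ...) sample stack the statistics were computed from.
    """
    mc = mc or MCConfig()
    mr = np.asarray(mr, dtype=np.float64)
    if mr.ndim == 3:            # (3, H, W)
        stack = mr[:, None]
        squeeze = True
    elif mr.ndim == 4:          # (3, S, H, W)
        stack = mr
        squeeze = False
    else:
        raise ValueError("mr must be (3, H, W) or (3, S, H, W)")

    net = _build_net(model)
    use_dropout = model.net_cfg.dropout > 0.0
    rng = np.random.default_rng(
        np.random.SeedSequence([int(mc.seed), 0x3C])) if use_dropout else None

    n_slices = stack.shape[1]
    samples = np.empty((mc.n_samples, n_slices) + stack.shape[2:])
    for i in range(mc.n_samples):
        for s in range(n_slices):
            samples[i, s] = _predict_slice(net, stack[:, s], rng)

    pct = samples.mean(axis=0)
    variance = ((samples - pct) ** 2).mean(axis=0)
    if squeeze:
        pct, variance, samples = pct[0], variance[0], samples[:, 0]
    if return_samples:
        return pct, variance, samples
    return pct, variance
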
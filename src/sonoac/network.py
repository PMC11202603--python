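"""B-mode-guided attenuation-coefficient regression network.

Architecture: five per-angle 1-D convolutional encoders (independent
weights, residual blocks) extract time-varying intensity features from the
envelope-detected frames E_1..E_5; their outputs are concatenated
channel-wise; the fused features are standardized per time slice and then
re-scaled/shifted with parameter vectors gamma_t and beta_t derived from the
B-mode image (B-mode-guided adaptive denormalization, BGN):

    X_t = gamma_t * (x_t - mu) / sigma + beta_t

where mu and sigma are the per-slice mean and (population) standard
deviation of the encoded slice x_t.  gamma_t and beta_t come from 4 shared
convolutional layers over the B-mode followed by 4 separate fully connected
layers per parameter.  A 2-D convolutional trunk with batch normalization
and a fully connected head regress the scalar attenuation coefficient,
bounded to a physical range by a scaled sigmoid.

The ablation variant (``use_bmode=False``) keeps the plain per-slice
standardization (gamma = 1, beta = 0) and drops the B-mode branch.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import InputError

__all__ = [
    "NetworkConfig",
    "BGNParams",
    "ACRegressionNet",
    "Adam",
    "bgn_denormalize",
    "slice_moments",
    "reduced_network_config",
    "save_checkpoint",
    "load_checkpoint",
]

logger = logging.getLogger(__name__)


@dataclass
class NetworkConfig:
    """Hyperparameters; defaults are the desk-scale reference architecture."""

    input_shape: tuple[int, int, int] = (5, 64, 128)  # (angles, channels, time)
    bmode_shape: tuple[int, int] = (32, 32)
    encoder_widths: tuple[int, ...] = (16, 32, 64)
    encoder_kernel: int = 7
    encoder_stride: int = 2
    residual: bool = True
    bgn_conv_layers: int = 4  # shared conv layers in the B-mode branch
    bgn_fc_layers: int = 4  # separate FC layers per parameter vector
    bgn_conv_channels: int = 8
    bgn_fc_hidden: int = 64
    gamma_vector_mode: bool = False  # per-slice-and-channel gamma/beta if True
    trunk_widths: tuple[int, ...] = (64, 128)
    trunk_kernel: int = 3
    head_fc_layers: int = 2
    head_hidden: int = 64
    use_bmode: bool = True
    ac_range: tuple[float, float] = (0.0, 1.2)  # dB/cm/MHz output bounds
    eps: float = 1e-5
    seed: int = 0


def reduced_network_config(**overrides) -> NetworkConfig:
    """Compact variant sized for CPU-scale experiments."""
    base = dict(
        input_shape=(5, 32, 128),
        bmode_shape=(32, 32),
        encoder_widths=(8, 12, 16),
        bgn_conv_channels=6,
        bgn_fc_hidden=32,
        trunk_widths=(12, 16),
        head_hidden=32,
    )
    base.update(overrides)
    return NetworkConfig(**base)


# -- parameter containers ---------------------------------------------------

def _he(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    return Tensor(rng.standard_normal(shape) * np.sqrt(2.0 / fan_in), requires_grad=True)


class _Linear:
    def __init__(self, rng, n_in, n_out):
        self.w = _he(rng, (n_in, n_out), n_in)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def params(self):
        return [self.w, self.b]


class _Conv1d:
    def __init__(self, rng, c_in, c_out, k, stride=1, pad=0):
        self.w = _he(rng, (c_out, c_in, k), c_in * k)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv1d(x, self.w, self.b, stride=self.stride, pad=self.pad)

    def params(self):
        return [self.w, self.b]


class _Conv2d:
    def __init__(self, rng, c_in, c_out, k, stride=1, pad=0):
        self.w = _he(rng, (c_out, c_in, k, k), c_in * k * k)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)

    def params(self):
        return [self.w, self.b]


class _BatchNorm2d:
    """Standard batch normalization with running statistics for inference."""

    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mu) / (var + self.eps).sqrt()
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)

    def params(self):
        return [self.gamma, self.beta]


class _EncoderPath:
    """1-D conv encoder over time with residual blocks (independent weights)."""

    def __init__(self, rng, c_in, widths, k, stride, residual):
        pad = k // 2
        self.residual = residual
        self.stem = _Conv1d(rng, c_in, widths[0], k, stride=stride, pad=pad)
        self.blocks = []
        prev = widths[0]
        for w in widths[1:]:
            main1 = _Conv1d(rng, prev, w, k, stride=stride, pad=pad)
            main2 = _Conv1d(rng, w, w, k, stride=1, pad=pad)
            short = _Conv1d(rng, prev, w, 1, stride=stride, pad=0)
            self.blocks.append((main1, main2, short))
            prev = w

    def __call__(self, x: Tensor) -> Tensor:
        h = ad.relu(self.stem(x))
        for main1, main2, short in self.blocks:
            y = main2(ad.relu(main1(h)))
            h = ad.relu(y + short(h)) if self.residual else ad.relu(y)
        return h

    def params(self):
        ps = self.stem.params()
        for m1, m2, s in self.blocks:
            ps += m1.params() + m2.params() + s.params()
        return ps


# -- BGN functional core ----------------------------------------------------

@dataclass
class BGNParams:
    """The four quantities entering the BGN affine transform.

    ``gamma``/``beta`` are B-mode-derived modulation vectors (one entry per
    normalized time slice, or per slice-and-channel in vector mode);
    ``mu``/``sigma`` are the per-slice moments of the encoded features.
    """

    gamma: np.ndarray
    beta: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray


def slice_moments(x: Tensor, eps: float = 1e-5) -> tuple[Tensor, Tensor]:
    """Per-time-slice mean/std of (B, C, T) features, across the channel axis.

    Population standard deviation, epsilon-stabilized.  A slice variance
    below eps is flagged at debug level and clamped.
    """
    mu = x.mean(axis=1, keepdims=True)
    var = ((x - mu) * (x - mu)).mean(axis=1, keepdims=True)
    n_low = int(np.count_nonzero(var.data < eps))
    if n_low:
        logger.debug("BGN: %d time slices with variance < %.1e (eps-stabilized)", n_low, eps)
    sigma = (var + eps).sqrt()
    return mu, sigma


def bgn_denormalize(x: Tensor | np.ndarray, gamma, beta, eps: float = 1e-5) -> Tensor:
    """X_t = gamma_t * (x_t - mu) / sigma + beta_t over (B, C, T) features.

    ``gamma``/``beta`` broadcast against (B, 1, T) (scalar per slice) or
    (B, C, T) (vector mode).
    """
    x = x if isinstance(x, Tensor) else Tensor(x)
    gamma = gamma if isinstance(gamma, Tensor) else Tensor(gamma)
    beta = beta if isinstance(beta, Tensor) else Tensor(beta)
    mu, sigma = slice_moments(x, eps)
    return gamma * ((x - mu) / sigma) + beta


# -- full model -------------------------------------------------------------

class ACRegressionNet:
    """Five-encoder, BGN-conditioned attenuation regressor."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        n_ang, c_in, t_in = config.input_shape
        self.encoders = [
            _EncoderPath(rng, c_in, config.encoder_widths, config.encoder_kernel,
                         config.encoder_stride, config.residual)
            for _ in range(n_ang)
        ]
        n_stages = len(config.encoder_widths)
        self.t_feat = t_in
        for _ in range(n_stages):
            self.t_feat = (self.t_feat + 2 * (config.encoder_kernel // 2)
                           - config.encoder_kernel) // config.encoder_stride + 1
        self.c_fused = n_ang * config.encoder_widths[-1]

        if config.use_bmode:
            cc = config.bgn_conv_channels
            h, w = config.bmode_shape
            self.bgn_convs = []
            prev = 1
            for _ in range(config.bgn_conv_layers):
                self.bgn_convs.append(_Conv2d(rng, prev, cc, 3, stride=2, pad=1))
                prev = cc
                h, w = (h + 1) // 2, (w + 1) // 2
            flat = cc * h * w
            out_dim = self.t_feat * (self.c_fused if config.gamma_vector_mode else 1)
            self.gamma_fcs, self.beta_fcs = [], []
            for stack in (self.gamma_fcs, self.beta_fcs):
                dims = [flat] + [config.bgn_fc_hidden] * (config.bgn_fc_layers - 1) + [out_dim]
                for a, b in zip(dims[:-1], dims[1:]):
                    stack.append(_Linear(rng, a, b))
            # Zero-init the output layers so BGN starts as plain
            # standardization (gamma=1, beta=0) and learns modulation.
            self.gamma_fcs[-1].w.data[:] = 0.0
            self.gamma_fcs[-1].b.data[:] = 1.0
            self.beta_fcs[-1].w.data[:] = 0.0

        self.trunk, self.trunk_bns = [], []
        prev = 1
        ch, cw = self.c_fused, self.t_feat
        for w in config.trunk_widths:
            self.trunk.append(_Conv2d(rng, prev, w, config.trunk_kernel, stride=2,
                                      pad=config.trunk_kernel // 2))
            self.trunk_bns.append(_BatchNorm2d(w))
            prev = w
            ch = (ch + 2 * (config.trunk_kernel // 2) - config.trunk_kernel) // 2 + 1
            cw = (cw + 2 * (config.trunk_kernel // 2) - config.trunk_kernel) // 2 + 1
        flat = prev * ch * cw
        dims = [flat] + [config.head_hidden] * (config.head_fc_layers - 1) + [1]
        self.head = [_Linear(rng, a, b) for a, b in zip(dims[:-1], dims[1:])]
        self.training = False

    # -- sub-computations --------------------------------------------------
    def encode(self, envelopes: Tensor) -> Tensor:
        """Fuse the five per-angle frames channel-wise: (B,5,C,T) -> (B,C_f,T')."""
        n_ang = self.config.input_shape[0]
        if envelopes.shape[1] != n_ang:
            raise InputError(
                f"expected {n_ang} angle frames, got {envelopes.shape[1]}")
        feats = [self.encoders[i](envelopes[:, i]) for i in range(n_ang)]
        return ad.concatenate(feats, axis=1)

    def bgn_params(self, bmode: Tensor) -> tuple[Tensor, Tensor]:
        """gamma_t, beta_t from the B-mode image (shared convs, separate FCs)."""
        h = bmode
        for conv in self.bgn_convs:
            h = ad.relu(conv(h))
        b = h.shape[0]
        h = h.reshape(b, -1)
        outs = []
        for stack in (self.gamma_fcs, self.beta_fcs):
            y = h
            for i, fc in enumerate(stack):
                y = fc(y)
                if i < len(stack) - 1:
                    y = ad.relu(y)
            if self.config.gamma_vector_mode:
                outs.append(y.reshape(b, self.c_fused, self.t_feat))
            else:
                outs.append(y.reshape(b, 1, self.t_feat))
        return outs[0], outs[1]

    def bgn_parameters(self, x: Tensor, bmode: Tensor) -> BGNParams:
        """Materialize (gamma, beta, mu, sigma) for inspection/debugging."""
        gamma, beta = self.bgn_params(bmode)
        mu, sigma = slice_moments(x, self.config.eps)
        return BGNParams(gamma=gamma.data.copy(), beta=beta.data.copy(),
                         mu=mu.data.copy(), sigma=sigma.data.copy())

    def bgn(self, x: Tensor, bmode: Tensor | None) -> Tensor:
        """Adaptive denormalization of encoded features, Eq.-style affine."""
        if self.config.use_bmode:
            if bmode is None:
                raise InputError("B-mode conditioning image required")
            gamma, beta = self.bgn_params(bmode)
            return bgn_denormalize(x, gamma, beta, self.config.eps)
        mu, sigma = slice_moments(x, self.config.eps)
        return (x - mu) / sigma

    def forward(self, envelopes: Tensor, bmode: Tensor | None) -> Tensor:
        """(B,5,C,T), (B,1,H,W) -> (B,) attenuation in dB/cm/MHz."""
        n_ang, c_in, t_in = self.config.input_shape
        if envelopes.shape[1:] != (n_ang, c_in, t_in):
            raise InputError(
                f"envelope shape {envelopes.shape[1:]} != expected {(n_ang, c_in, t_in)}")
        fused = self.encode(envelopes)
        x = self.bgn(fused, bmode)
        b = x.shape[0]
        h = x.reshape(b, 1, self.c_fused, self.t_feat)
        for conv, bn in zip(self.trunk, self.trunk_bns):
            h = ad.relu(bn(conv(h), self.training))
        h = h.reshape(b, -1)
        for i, fc in enumerate(self.head):
            h = fc(h)
            if i < len(self.head) - 1:
                h = ad.relu(h)
        lo, hi = self.config.ac_range
        return (ad.sigmoid(h) * (hi - lo) + lo).reshape(b)

    def predict(self, envelopes: np.ndarray, bmode: np.ndarray | None) -> np.ndarray:
        """Inference on numpy batches; returns finite scalars per item."""
        self.training = False
        env = np.asarray(envelopes, dtype=np.float64)
        if env.ndim == 3:
            env = env[None]
        bm = None
        if bmode is not None:
            bm = np.asarray(bmode, dtype=np.float64)
            if bm.ndim == 2:
                bm = bm[None, None]
            elif bm.ndim == 3:
                bm = bm[None]
        out = self.forward(Tensor(env), Tensor(bm) if bm is not None else None)
        return out.data.copy()

    # -- bookkeeping --------------------------------------------------------
    def params(self) -> list[Tensor]:
        ps = []
        for enc in self.encoders:
            ps += enc.params()
        if self.config.use_bmode:
            for conv in self.bgn_convs:
                ps += conv.params()
            for stack in (self.gamma_fcs, self.beta_fcs):
                for fc in stack:
                    ps += fc.params()
        for conv, bn in zip(self.trunk, self.trunk_bns):
            ps += conv.params() + bn.params()
        for fc in self.head:
            ps += fc.params()
        return ps

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def state_dict(self) -> list[np.ndarray]:
        state = [p.data.copy() for p in self.params()]
        for bn in self.trunk_bns:
            state.append(bn.running_mean.copy())
            state.append(bn.running_var.copy())
        return state

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        ps = self.params()
        for p, s in zip(ps, state[: len(ps)]):
            p.data = s.copy()
        rest = state[len(ps):]
        for i, bn in enumerate(self.trunk_bns):
            bn.running_mean = rest[2 * i].copy()
            bn.running_var = rest[2 * i + 1].copy()

    def clone(self) -> "ACRegressionNet":
        other = ACRegressionNet(copy.deepcopy(self.config))
        other.load_state_dict(self.state_dict())
        return other


def save_checkpoint(model: ACRegressionNet, path, **meta) -> None:
    """Serialize weights + config (json) + metadata to an .npz file."""
    import dataclasses
    import json

    state = model.state_dict()
    cfg = json.dumps(dataclasses.asdict(model.config))
    np.savez_compressed(path, __config__=np.array(cfg),
                        __meta__=np.array(json.dumps(meta)),
                        **{f"state_{i}": s for i, s in enumerate(state)})


def load_checkpoint(path) -> tuple[ACRegressionNet, dict]:
    """Rebuild a model from :func:`save_checkpoint` output."""
    import json

    with np.load(path, allow_pickle=False) as f:
        cfg_dict = json.loads(str(f["__config__"]))
        meta = json.loads(str(f["__meta__"]))
        n = sum(1 for k in f.files if k.startswith("state_"))
        state = [f[f"state_{i}"] for i in range(n)]
    for key in ("input_shape", "bmode_shape", "encoder_widths", "trunk_widths",
                "ac_range"):
        cfg_dict[key] = tuple(cfg_dict[key])
    model = ACRegressionNet(NetworkConfig(**cfg_dict))
    model.load_state_dict(state)
    return model, meta


class Adam:
    """Adam with (coupled) L2 regularization added to the gradients."""

    def __init__(self, params: list[Tensor], lr: float = 5e-6, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
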
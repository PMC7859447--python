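"""The edge-aware pyramidal registration network.

One forward pass takes a preprocessed fixed/moving volume pair, builds the
two dual-channel inputs (intensity + Sobel edge map), encodes both through a
*shared* four-level convolutional encoder, estimates a global 12-DOF affine
transform from the coarsest feature pair, and then refines the deformation
coarse-to-fine with three deformable blocks that each predict a residual
displacement field.  Grids compose additively: ``G_i = up2(G_{i+1}) + φ_i``.

The affine and deformable output layers are zero-initialized, so a freshly
constructed network is exactly the identity map — a property the tests and
the training loop rely on as an anchor.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .edge import make_dual_input
from .transform import (affine_grid, aggregate_field, compose_grid,
                        identity_grid, resize_field, upsample_grid, warp)

__all__ = ["NetworkConfig", "EPRegNet", "ForwardResult"]


@dataclasses.dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    enc_channels : feature channels of the four encoder levels
    head_channels : width of the affine/deformable head residual blocks
    aspp_rates : dilation rates of the coarsest-level ASPP branches
    use_edges : include the Sobel edge map as a second input channel
        (disable for the intensity-only ablation)
    norm : "instance", "batch", or "none" (with one pair per step instance
        and batch normalization coincide)
    dtype : compute precision of the network
    """

    enc_channels: tuple[int, int, int, int] = (16, 32, 32, 64)
    head_channels: int = 32
    aspp_rates: tuple[int, ...] = (1, 2, 4)
    use_edges: bool = True
    norm: str = "instance"
    dtype: str = "float32"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["enc_channels"] = list(self.enc_channels)
        d["aspp_rates"] = list(self.aspp_rates)
        return d

    @staticmethod
    def from_dict(d: dict) -> "NetworkConfig":
        d = dict(d)
        d["enc_channels"] = tuple(d["enc_channels"])
        d["aspp_rates"] = tuple(d["aspp_rates"])
        return NetworkConfig(**d)


@dataclasses.dataclass
class ForwardResult:
    """Outputs of one registration pass."""

    phis: dict          # level -> residual field (level 4: dense affine residual)
    grids: dict         # level -> deformation grid G_i
    affine: Tensor      # 3x4 affine matrix
    warped: Tensor      # moving volume warped by up2(G_1)
    full_grid: Tensor   # full-resolution sampling grid used for the warp
    aggregate: Tensor   # full-resolution aggregated displacement field


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv3d:
    def __init__(self, rng, cin, cout, k=3, stride=1, dilation=1,
                 zero_init=False, dtype=np.float32):
        fan_in = cin * k**3
        scale = 0.0 if zero_init else np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            (rng.standard_normal((cout, cin, k, k, k)) * scale).astype(dtype),
            requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True)
        self.stride = stride
        self.dilation = dilation

    def __call__(self, x):
        return ad.conv3d(x, self.weight, self.bias, stride=self.stride,
                         dilation=self.dilation)

    def params(self):
        return [self.weight, self.bias]


class Norm3d:
    """Per-channel spatial normalization with affine parameters.

    In training mode statistics come from the current activation (for one
    sample this is instance normalization, identical to batch normalization
    at batch size 1) and exponential running statistics are tracked; eval
    mode uses the running statistics.  ``mode="none"`` is a pass-through.
    """

    def __init__(self, channels, mode="instance", momentum=0.1,
                 dtype=np.float32):
        self.mode = mode
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum = momentum
        self.training = True
        self.eps = 1e-5

    def __call__(self, x):
        if self.mode == "none":
            return x
        c = x.shape[0]
        sh = (c, 1, 1, 1)
        if self.training:
            mu = x.mean(axis=(1, 2, 3), keepdims=True)
            xc = x - mu
            var = ad.mul(xc, xc).mean(axis=(1, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (
                mu.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (
                var.data.reshape(-1) - self.running_var)
            xhat = ad.div(xc, ad.sqrt(var + self.eps))
        else:
            dt = x.dtype
            xc = x - Tensor(self.running_mean.reshape(sh).astype(dt))
            xhat = ad.div(xc, Tensor(
                np.sqrt(self.running_var.reshape(sh) + self.eps).astype(dt)))
        return xhat * self.gamma.reshape(sh) + self.beta.reshape(sh)

    def params(self):
        return [] if self.mode == "none" else [self.gamma, self.beta]


class ResBlock:
    """Two 3x3x3 convs with normalization, ReLU, and an identity skip."""

    def __init__(self, rng, channels, norm="instance", dtype=np.float32):
        self.conv1 = Conv3d(rng, channels, channels, dtype=dtype)
        self.norm1 = Norm3d(channels, norm, dtype=dtype)
        self.conv2 = Conv3d(rng, channels, channels, dtype=dtype)
        self.norm2 = Norm3d(channels, norm, dtype=dtype)

    def __call__(self, x):
        h = ad.relu(self.norm1(self.conv1(x)))
        h = self.norm2(self.conv2(h))
        return ad.relu(h + x)

    def params(self):
        return (self.conv1.params() + self.norm1.params()
                + self.conv2.params() + self.norm2.params())

    def norms(self):
        return [self.norm1, self.norm2]


class ASPP:
    """Atrous spatial pyramid pooling: parallel dilated convs, fused 1x1x1."""

    def __init__(self, rng, channels, rates=(1, 2, 4), norm="instance",
                 dtype=np.float32):
        self.branches = [Conv3d(rng, channels, channels, dilation=r,
                                dtype=dtype) for r in rates]
        self.bnorms = [Norm3d(channels, norm, dtype=dtype) for _ in rates]
        self.fuse = Conv3d(rng, channels * len(rates), channels, k=1,
                           dtype=dtype)
        self.fnorm = Norm3d(channels, norm, dtype=dtype)

    def __call__(self, x):
        outs = [ad.relu(n(b(x))) for b, n in zip(self.branches, self.bnorms)]
        return ad.relu(self.fnorm(self.fuse(ad.concat(outs, axis=0))))

    def params(self):
        p = []
        for b, n in zip(self.branches, self.bnorms):
            p += b.params() + n.params()
        return p + self.fuse.params() + self.fnorm.params()

    def norms(self):
        return list(self.bnorms) + [self.fnorm]


class EPRegNet:
    """Shared-encoder pyramid network with affine and deformable heads."""

    def __init__(self, config: NetworkConfig | None = None):
        self.config = config or NetworkConfig()
        cfg = self.config
        dtype = np.float32 if cfg.dtype == "float32" else np.float64
        rng = np.random.default_rng(cfg.seed)
        c = cfg.enc_channels
        in_ch = 2 if cfg.use_edges else 1
        nm = cfg.norm

        # encoder: four stride-2 blocks (shared between the two streams)
        self.enc_conv = [
            Conv3d(rng, in_ch, c[0], stride=2, dtype=dtype),
            Conv3d(rng, c[0], c[1], stride=2, dtype=dtype),
            Conv3d(rng, c[1], c[2], stride=2, dtype=dtype),
            Conv3d(rng, c[2], c[3], stride=2, dtype=dtype),
        ]
        self.enc_norm = [Norm3d(ch, nm, dtype=dtype) for ch in c]
        self.enc_res = {
            2: [ResBlock(rng, c[1], nm, dtype), ResBlock(rng, c[1], nm, dtype)],
            3: [ResBlock(rng, c[2], nm, dtype), ResBlock(rng, c[2], nm, dtype)],
        }
        self.aspp = ASPP(rng, c[3], cfg.aspp_rates, nm, dtype)

        # affine head: residual block on F4||M4, 1x1x1 conv to 12, GAP;
        # the final conv is zero-initialized so the raw output is [I|0]
        hw = cfg.head_channels
        self.aff_proj = Conv3d(rng, 2 * c[3], hw, k=1, dtype=dtype)
        self.aff_res = ResBlock(rng, hw, nm, dtype)
        self.aff_out = Conv3d(rng, hw, 12, k=1, zero_init=True, dtype=dtype)

        # deformable heads for levels 3, 2, 1; zero-initialized outputs
        self.def_proj = {}
        self.def_res = {}
        self.def_out = {}
        for i in (3, 2, 1):
            ci, cc = c[i - 1], c[i]  # this level's and the coarser channels
            cin = 2 * ci + 2 * cc + 3
            self.def_proj[i] = Conv3d(rng, cin, hw, k=1, dtype=dtype)
            self.def_res[i] = [ResBlock(rng, hw, nm, dtype),
                               ResBlock(rng, hw, nm, dtype)]
            self.def_out[i] = Conv3d(rng, hw, 3, k=1, zero_init=True,
                                     dtype=dtype)

    # -- parameter plumbing ------------------------------------------------
    def params(self) -> list[Tensor]:
        p = []
        for conv, norm in zip(self.enc_conv, self.enc_norm):
            p += conv.params() + norm.params()
        for blocks in self.enc_res.values():
            for b in blocks:
                p += b.params()
        p += self.aspp.params()
        p += self.aff_proj.params() + self.aff_res.params() + self.aff_out.params()
        for i in (3, 2, 1):
            p += self.def_proj[i].params() + self.def_out[i].params()
            for b in self.def_res[i]:
                p += b.params()
        return p

    def _norm_layers(self):
        layers = list(self.enc_norm)
        for blocks in self.enc_res.values():
            for b in blocks:
                layers += b.norms()
        layers += self.aspp.norms() + self.aff_res.norms()
        for i in (3, 2, 1):
            for b in self.def_res[i]:
                layers += b.norms()
        return layers

    def train_mode(self, flag: bool = True):
        for n in self._norm_layers():
            n.training = flag
        return self

    # -- forward -----------------------------------------------------------
    def encode(self, dual_input) -> dict:
        """Feature pyramid of one stream: level i at stride 2^i."""
        x = dual_input if isinstance(dual_input, Tensor) else Tensor(
            np.asarray(dual_input))
        if x.ndim != 4:
            raise ValueError("encoder expects a (C, D, H, W) input")
        for n in x.shape[1:]:
            if n % 16 != 0:
                raise ValueError(
                    f"input axes must be divisible by 16, got {tuple(x.shape[1:])}")
        feats = {}
        for i in range(1, 5):
            x = ad.relu(self.enc_norm[i - 1](self.enc_conv[i - 1](x)))
            if i in (2, 3):
                for block in self.enc_res[i]:
                    x = block(x)
            if i == 4:
                x = self.aspp(x)
            feats[i] = x
        return feats

    def affine_head(self, f4, m4) -> Tensor:
        """12-DOF affine matrix from the coarsest feature pair."""
        if tuple(f4.shape) != tuple(m4.shape):
            raise ValueError("F4/M4 shape mismatch")
        h = self.aff_proj(ad.concat([f4, m4], axis=0))
        h = self.aff_res(h)
        h = self.aff_out(h)
        vals = h.mean(axis=(1, 2, 3))  # global average pooling -> 12 values
        ident = np.concatenate([np.eye(3), np.zeros((3, 1))], axis=1)
        return vals.reshape((3, 4)) + Tensor(ident.astype(vals.dtype))

    def deformable_head(self, i, f_i, m_i_warped, f_coarse, m_coarse_warped,
                        phi_coarse) -> Tensor:
        """Residual displacement at level i from this level's pair, the
        upsampled coarser pair, and the upsampled coarser field."""
        parts = [f_i, m_i_warped,
                 upsample_grid(f_coarse, 2), upsample_grid(m_coarse_warped, 2),
                 upsample_grid(phi_coarse, 2)]
        sp = tuple(f_i.shape[1:])
        for p in parts:
            if tuple(p.shape[1:]) != sp:
                raise ValueError(
                    f"deformable head {i}: operand at wrong level "
                    f"({tuple(p.shape[1:])} != {sp})")
        h = self.def_proj[i](ad.concat(parts, axis=0))
        for block in self.def_res[i]:
            h = block(h)
        return self.def_out[i](h)

    def forward(self, fixed: np.ndarray, moving: np.ndarray) -> ForwardResult:
        """Register one preprocessed pair in a single pass."""
        fixed = np.asarray(fixed, dtype=np.float64)
        moving = np.asarray(moving, dtype=np.float64)
        if fixed.shape != moving.shape:
            raise ValueError(
                f"fixed {fixed.shape} and moving {moving.shape} shapes differ")
        dtype = np.float32 if self.config.dtype == "float32" else np.float64
        if self.config.use_edges:
            in_f = make_dual_input(fixed).astype(dtype)
            in_m = make_dual_input(moving).astype(dtype)
        else:
            in_f = fixed[None].astype(dtype)
            in_m = moving[None].astype(dtype)

        feats_f = self.encode(in_f)
        feats_m = self.encode(in_m)

        shape = fixed.shape
        lvl_shape = {i: tuple(s // 2**i for s in shape) for i in range(1, 5)}

        affine = self.affine_head(feats_f[4], feats_m[4])
        g4 = affine_grid(affine, lvl_shape[4])
        phi4 = g4 - Tensor(identity_grid(lvl_shape[4], dtype=g4.dtype))

        grids = {4: g4}
        phis = {4: phi4}
        for i in (3, 2, 1):
            up_g = upsample_grid(grids[i + 1], 2)
            m_i_w = warp(feats_m[i], up_g)
            m_c_w = warp(feats_m[i + 1], grids[i + 1])
            phi_i = self.deformable_head(i, feats_f[i], m_i_w,
                                         feats_f[i + 1], m_c_w, phis[i + 1])
            phis[i] = phi_i
            grids[i] = compose_grid(grids[i + 1], phi_i)

        full_grid = upsample_grid(grids[1], 2)
        warped = warp(Tensor(moving), full_grid)
        agg = aggregate_field(phis, shape)
        return ForwardResult(phis=phis, grids=grids, affine=affine,
                             warped=warped, full_grid=full_grid, aggregate=agg)

    # -- checkpointing -----------------------------------------------------
    def state_arrays(self) -> dict:
        state = {f"param_{k}": p.data for k, p in enumerate(self.params())}
        for k, n in enumerate(self._norm_layers()):
            state[f"rmean_{k}"] = n.running_mean
            state[f"rvar_{k}"] = n.running_var
        return state

    def save(self, path) -> None:
        """Self-describing checkpoint: weights + architecture config."""
        state = self.state_arrays()
        state["config_json"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8)
        np.savez(path, **state)

    @staticmethod
    def load(path) -> "EPRegNet":
        with np.load(path) as data:
            cfg = NetworkConfig.from_dict(
                json.loads(bytes(data["config_json"]).decode()))
            net = EPRegNet(cfg)
            for k, p in enumerate(net.params()):
                arr = data[f"param_{k}"]
                if arr.shape != p.data.shape:
                    raise ValueError(
                        "checkpoint/architecture mismatch at parameter "
                        f"{k}: {arr.shape} vs {p.data.shape}")
                p.data = arr
            for k, n in enumerate(net._norm_layers()):
                n.running_mean = data[f"rmean_{k}"]
                n.running_var = data[f"rvar_{k}"]
        return net
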
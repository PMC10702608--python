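"""The MFA-UNet architecture.

A residual U-shaped encoder-decoder for vessel probability maps with three
optional modules, each individually toggleable for ablations:

* **MSAM** (multi-scale fusion self-attention): fuses the three deepest
  encoder scales at the middle resolution, applies channel self-attention
  (learned channel embeddings as queries), spatial self-attention and a
  token MLP, then redistributes the refined feature to the skip paths.
* **PAM** (parallel attention): CBAM-style channel and spatial attention
  computed in parallel after each decoder block and summed.
* **MBDM** (multi-branch decoder): a deep-supervised head with a 7x7
  BCE-trained branch (macrovessels), a 9x9 Dice-trained branch
  (microvessels) and a 3x3/1x1 fusion branch producing the final logits.

The encoder downsamples with depthwise large-kernel strided convolutions
followed by pointwise channel expansion; the decoder upsamples bilinearly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import _autodiff as ad
from .layers import (BatchNorm2d, Conv2d, ConvBNRelu, Linear, Module,
                     Parameter)


@dataclass
class ModelConfig:
    """Architectural hyperparameters of MFA-UNet.

    The defaults are the reference configuration whose trainable-parameter
    count sits at ~2.39 M with all modules enabled and ~1.92 M with all of
    them off.  ``msam_token_dim`` defaults to the fused channel width
    (``encoder_channels[2]``).
    """

    encoder_channels: tuple[int, ...] = (64, 128, 256, 512)
    msam_token_dim: int | None = None
    msam_mlp_ratio: float = 0.125
    msam_ssa_dim: int | None = None
    msam_token_cap: int = 4096
    pam_reduction: int = 8
    mbdm_branch_channels: int = 3
    head_channels: int = 16
    downsample_kernel: int = 5
    use_msam: bool = True
    use_pam: bool = True
    use_mbdm: bool = True
    seed: int = 0

    def __post_init__(self):
        ch = tuple(self.encoder_channels)
        if len(ch) != 4 or any(b <= a for a, b in zip(ch, ch[1:])):
            raise ValueError("encoder_channels must be 4 strictly increasing widths")
        self.encoder_channels = ch
        if self.downsample_kernel % 2 == 0:
            raise ValueError("downsample_kernel must be odd")

    @property
    def token_dim(self) -> int:
        return self.msam_token_dim or self.encoder_channels[2]

    @property
    def ssa_dim(self) -> int:
        return self.msam_ssa_dim or max(1, self.token_dim // 4)

    def as_dict(self) -> dict:
        return asdict(self)


def slim_config(seed: int = 0, **overrides) -> ModelConfig:
    """A narrow configuration for CPU-scale experiments and tests."""
    kw = dict(encoder_channels=(8, 16, 32, 64), msam_mlp_ratio=0.5,
              pam_reduction=4, mbdm_branch_channels=4, head_channels=8,
              seed=seed)
    kw.update(overrides)
    return ModelConfig(**kw)


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class BasicBlock(Module):
    """Residual double 3x3 convolution at constant width."""

    def __init__(self, c, rng):
        super().__init__()
        self.c1 = Conv2d(c, c, 3, rng, bias=False)
        self.b1 = BatchNorm2d(c)
        self.c2 = Conv2d(c, c, 3, rng, bias=False)
        self.b2 = BatchNorm2d(c)

    def forward(self, x):
        h = ad.relu(self.b1(self.c1(x)))
        return ad.relu(self.b2(self.c2(h)) + x)


class Bottleneck(Module):
    """Residual 1x1 -> 3x3 -> 1x1 block with mid width ``c // 2``."""

    def __init__(self, c, rng):
        super().__init__()
        m = max(1, c // 2)
        self.c1 = Conv2d(c, m, 1, rng, bias=False)
        self.b1 = BatchNorm2d(m)
        self.c2 = Conv2d(m, m, 3, rng, bias=False)
        self.b2 = BatchNorm2d(m)
        self.c3 = Conv2d(m, c, 1, rng, bias=False)
        self.b3 = BatchNorm2d(c)

    def forward(self, x):
        h = ad.relu(self.b1(self.c1(x)))
        h = ad.relu(self.b2(self.c2(h)))
        return ad.relu(self.b3(self.c3(h)) + x)


class Downsample(Module):
    """Strided depthwise large-kernel conv + pointwise channel expansion."""

    def __init__(self, cin, cout, k, rng):
        super().__init__()
        self.dw = Conv2d(cin, cin, k, rng, stride=2, groups=cin, bias=False)
        self.b1 = BatchNorm2d(cin)
        self.pw = Conv2d(cin, cout, 1, rng, bias=False)
        self.b2 = BatchNorm2d(cout)

    def forward(self, x):
        return ad.relu(self.b2(self.pw(self.b1(self.dw(x)))))


class DecoderBlock(Module):
    """Bottleneck-style fusion of concatenated decoder + skip features."""

    def __init__(self, cin, cout, rng):
        super().__init__()
        m = max(1, cout // 2)
        self.c1 = Conv2d(cin, m, 1, rng, bias=False)
        self.b1 = BatchNorm2d(m)
        self.c2 = Conv2d(m, m, 3, rng, bias=False)
        self.b2 = BatchNorm2d(m)
        self.c3 = Conv2d(m, cout, 1, rng, bias=False)
        self.b3 = BatchNorm2d(cout)

    def forward(self, x):
        h = ad.relu(self.b1(self.c1(x)))
        h = ad.relu(self.b2(self.c2(h)))
        return ad.relu(self.b3(self.c3(h)))


class GroupedConvBN(Module):
    """Grouped 3x3 conv + BN used by MSAM to move between channel widths.

    Initialised as a centre-tap channel duplication/average, so at build
    time the layer resamples channels without scrambling spatial content;
    training is free to move away from that.
    """

    def __init__(self, cin, cout, rng):
        super().__init__()
        g = int(np.gcd(cin, cout))
        self.conv = Conv2d(cin, cout, 3, rng, groups=g, bias=False)
        self.bn = BatchNorm2d(cout)
        w = np.zeros_like(self.conv.weight.data)
        w[:, :, 1, 1] = 1.0 / w.shape[1]
        self.conv.weight.data = w

    def forward(self, x):
        return self.bn(self.conv(x))


class MSAM(Module):
    """Multi-scale fusion self-attention on the skip paths.

    The 1/2, 1/4 and 1/8 scale encoder features are resampled to the 1/4
    scale, projected to a common width ``D`` and summed into a fused map.
    Channel self-attention uses a trainable channel-embedding matrix as
    queries against the fused tokens; a sigmoid read-out of the attended
    embeddings gates the token channels.  Spatial self-attention and a
    residual MLP follow, and the refined map is redistributed to the three
    input scales.
    """

    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        c1, c2, c3 = cfg.encoder_channels[1:]
        d = cfg.token_dim
        if d != c2:
            raise ValueError("msam_token_dim must equal the fused channel width")
        self.token_cap = cfg.msam_token_cap
        self.in1 = GroupedConvBN(c1, c2, rng)
        self.in3 = GroupedConvBN(c3, c2, rng)
        self.token_proj = Conv2d(c2, d, 1, rng)
        self.ch_embed = Parameter(rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, d)))
        self.wq = Linear(d, d, rng, bias=False)
        self.wk = Linear(d, d, rng, bias=False)
        self.wv = Linear(d, d, rng, bias=False)
        self.gate = Linear(d, 1, rng)
        s = cfg.ssa_dim
        self.sq = Linear(d, s, rng, bias=False)
        self.sk = Linear(d, s, rng, bias=False)
        self.sv = Linear(d, s, rng, bias=False)
        self.so = Linear(s, d, rng)
        hidden = max(1, int(round(d * cfg.msam_mlp_ratio)))
        self.mlp1 = Linear(d, hidden, rng)
        self.mlp2 = Linear(hidden, d, rng)
        self.out1 = GroupedConvBN(c2, c1, rng)
        self.out3 = GroupedConvBN(c2, c3, rng)
        self._d, self._s = d, s
        self.last_csa_attn = None
        self.last_ssa_attn = None
        # near-passthrough start: the module initially forwards the fused
        # multi-scale feature unchanged (identity tokens, neutral gate,
        # zero attention/MLP residuals) so the skip paths keep carrying
        # encoder detail while the attention weights are still random
        self.token_proj.weight.data = np.eye(d).reshape(d, d, 1, 1)
        self.token_proj.bias.data[...] = 0.0
        self.gate.weight.data[...] = 0.0
        self.gate.bias.data[...] = 0.0
        self.so.weight.data[...] = 0.0
        self.mlp2.weight.data[...] = 0.0

    def forward(self, f1, f2, f3):
        n, c2, h2, w2 = f2.shape
        if h2 * w2 > self.token_cap:
            raise ValueError(
                f"MSAM token count {h2 * w2} exceeds cap {self.token_cap}")
        fa = (self.in1(ad.resize2d(f1, h2, w2)) + f2
              + self.in3(ad.resize2d(f3, h2, w2)))
        d = self._d
        z = ad.transpose(ad.reshape(self.token_proj(fa), (n, d, h2 * w2)),
                         (0, 2, 1))                              # (N, T, D)
        # channel self-attention: embeddings query the tokens
        q = self.wq(self.ch_embed)                               # (C, D)
        k = self.wk(z)                                           # (N, T, D)
        v = self.wv(z)
        attn = ad.softmax(ad.matmul(q, ad.transpose(k, (0, 2, 1)))
                          * (1.0 / np.sqrt(d)), axis=-1)         # (N, C, T)
        self.last_csa_attn = attn.data
        f_ch = self.ch_embed + ad.matmul(attn, v)                # (N, C, D)
        gate = ad.sigmoid(self.gate(f_ch))                       # (N, C, 1)
        s_ch = z * ad.transpose(gate, (0, 2, 1))                 # gate channels
        # spatial self-attention with residual
        sq, sk, sv = self.sq(s_ch), self.sk(s_ch), self.sv(s_ch)
        sattn = ad.softmax(ad.matmul(sq, ad.transpose(sk, (0, 2, 1)))
                           * (1.0 / np.sqrt(self._s)), axis=-1)  # (N, T, T)
        self.last_ssa_attn = sattn.data
        s_sp = s_ch + self.so(ad.matmul(sattn, sv))
        # token-wise MLP with residual
        s = s_sp + self.mlp2(ad.gelu(self.mlp1(s_sp)))
        smap = ad.reshape(ad.transpose(s, (0, 2, 1)), (n, d, h2, w2))
        s1 = ad.resize2d(self.out1(smap), f1.shape[2], f1.shape[3])
        s3 = ad.resize2d(self.out3(smap), f3.shape[2], f3.shape[3])
        return s1, smap, s3


class PAM(Module):
    """Parallel channel + spatial attention (summed CBAM branches)."""

    def __init__(self, c, reduction, rng):
        super().__init__()
        m = max(1, c // reduction)
        self.fc0 = Linear(c, m, rng)
        self.fc1 = Linear(m, c, rng)
        self.spatial = Conv2d(2, 1, 7, rng)

    def _mlp(self, x):
        return self.fc1(ad.relu(self.fc0(x)))

    def forward(self, x):
        n, c = x.shape[0], x.shape[1]
        avg = ad.tmean(x, axis=(2, 3))                           # (N, C)
        mx = ad.tmax(ad.tmax(x, axis=3), axis=2)                 # (N, C)
        mc = ad.sigmoid(self._mlp(avg) + self._mlp(mx))          # (N, C)
        mc = ad.reshape(mc, (n, c, 1, 1))
        cat = ad.concat([ad.tmean(x, axis=1, keepdims=True),
                         ad.tmax(x, axis=1, keepdims=True)], axis=1)
        ms = ad.sigmoid(self.spatial(cat))                       # (N, 1, H, W)
        return x * mc + x * ms


class MBDM(Module):
    """Deep-supervised multi-branch output head.

    Branch 1 (7x7 receptive field) is BCE-supervised and favours
    macrovessels; branch 2 (9x9) is Dice-supervised and favours
    microvessels; the fusion branch refines the concatenated branch
    probabilities with 3x3 and 1x1 convolutions into the final logits.
    """

    def __init__(self, cin, h, rng):
        super().__init__()
        self.b1a = ConvBNRelu(cin, h, 7, rng)
        self.b1b = Conv2d(h, 1, 1, rng)
        self.b2a = ConvBNRelu(cin, h, 9, rng)
        self.b2b = Conv2d(h, 1, 1, rng)
        hf = max(4, h)
        self.fa = ConvBNRelu(2, hf, 3, rng)
        self.fb = Conv2d(hf, 1, 1, rng)

    def forward(self, x):
        l1 = self.b1b(self.b1a(x))
        l2 = self.b2b(self.b2a(x))
        cat = ad.concat([ad.sigmoid(l1), ad.sigmoid(l2)], axis=1)
        lf = self.fb(self.fa(cat))
        return l1, l2, lf


class SingleHead(Module):
    """Plain output head used when the multi-branch decoder is disabled."""

    def __init__(self, cin, h, rng):
        super().__init__()
        self.a = ConvBNRelu(cin, h, 3, rng)
        self.b = Conv2d(h, 1, 1, rng)

    def forward(self, x):
        return (self.b(self.a(x)),)


# ---------------------------------------------------------------------------
# the full model
# ---------------------------------------------------------------------------

class MFAUNet(Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c0, c1, c2, c3 = cfg.encoder_channels
        k = cfg.downsample_kernel
        self.stem = ConvBNRelu(1, c0, 3, rng)
        self.stem2 = ConvBNRelu(c0, c0, 3, rng)
        self.enc0 = BasicBlock(c0, rng)
        self.down1 = Downsample(c0, c1, k, rng)
        self.enc1 = Bottleneck(c1, rng)
        self.down2 = Downsample(c1, c2, k, rng)
        self.enc2 = Bottleneck(c2, rng)
        self.down3 = Downsample(c2, c3, k, rng)
        self.enc3 = Bottleneck(c3, rng)
        self.msam = MSAM(cfg, rng) if cfg.use_msam else None
        self.up1 = ConvBNRelu(c3, c2, 1, rng)
        self.dec1 = DecoderBlock(2 * c2, c2, rng)
        self.up2 = ConvBNRelu(c2, c1, 1, rng)
        self.dec2 = DecoderBlock(2 * c1, c1, rng)
        self.up3 = ConvBNRelu(c1, c0, 1, rng)
        self.dec3 = DecoderBlock(2 * c0, c0, rng)
        if cfg.use_pam:
            r = cfg.pam_reduction
            self.pam1 = PAM(c2, r, rng)
            self.pam2 = PAM(c1, r, rng)
            self.pam3 = PAM(c0, r, rng)
        else:
            self.pam1 = self.pam2 = self.pam3 = None
        if cfg.use_mbdm:
            self.head = MBDM(c0, cfg.mbdm_branch_channels, rng)
        else:
            self.head = SingleHead(c0, cfg.head_channels, rng)

    def forward(self, x):
        """Return the tuple of branch logits (length 3 with MBDM, else 1)."""
        x = ad.astensor(x)
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("expected input of shape (N, 1, H, W)")
        if x.shape[2] % 8 or x.shape[3] % 8:
            raise ValueError("input spatial dims must be divisible by 8")
        s0 = self.enc0(self.stem2(self.stem(x)))
        f1 = self.enc1(self.down1(s0))
        f2 = self.enc2(self.down2(f1))
        f3 = self.enc3(self.down3(f2))
        if self.msam is not None:
            f1, f2, f3 = self.msam(f1, f2, f3)

        d = self.up1(ad.resize2d(f3, f2.shape[2], f2.shape[3]))
        d = self.dec1(ad.concat([d, f2], axis=1))
        if self.pam1 is not None:
            d = self.pam1(d)
        d = self.up2(ad.resize2d(d, f1.shape[2], f1.shape[3]))
        d = self.dec2(ad.concat([d, f1], axis=1))
        if self.pam2 is not None:
            d = self.pam2(d)
        d = self.up3(ad.resize2d(d, s0.shape[2], s0.shape[3]))
        d = self.dec3(ad.concat([d, s0], axis=1))
        if self.pam3 is not None:
            d = self.pam3(d)
        return self.head(d)

    def predict_logits(self, x):
        """Fusion-branch (or single-head) logits."""
        return self.forward(x)[-1]

    def predict_proba(self, x) -> np.ndarray:
        """Vessel probabilities for a batch, no gradient bookkeeping."""
        return np.asarray(ad.sigmoid(self.predict_logits(x)).data)


def build_model(cfg: ModelConfig | None = None) -> MFAUNet:
    return MFAUNet(cfg or ModelConfig())


def count_parameters(model: Module) -> int:
    """Number of trainable scalars in the model."""
    return model.count_parameters()
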
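"""Dual-decoder U-Net for imbalanced binary segmentation.

Architecture, end to end:

* **Encoder with two contraction paths.**  Path one is a classic U-Net
  contraction (3x3 conv, 1x1 conv, each with batch norm + ReLU, then 2x2 max
  pool).  Path two runs in parallel at the same cadence; at every level the
  corresponding path-one features are added in before a further 3x3
  conv/norm/ReLU block.  The bottleneck doubles the last width (so the
  default 256x256 input yields a 1024-channel 32x32 map after three
  downsamplings).
* **BiFPN fusion.**  The per-level combined features form a pyramid that a
  bidirectional feature pyramid refines: every merge is a fast-normalized
  weighted sum ``U = sum_p relu(w_p) / (eps + sum_q relu(w_q)) * I_p`` with
  ``eps = 1e-4``, followed by a depthwise-separable convolution with batch
  norm and a Swish activation.  Upsampling between tiers uses a learned
  deconvolution, downsampling a max pool.  A feature-optimization gate
  (1x1 conv -> norm -> sigmoid multiplier -> dropout) follows the last pass.
* **Masked coarse-to-fine attention.**  Candidate embeddings first predict a
  coarse mask by a sigmoid-ed inner product with the coarsest tier's pixel
  embeddings, then refine themselves with cross-attention confined (by an
  additive 0 / -1e9 mask) to their currently predicted foreground; a linear
  head classifies each candidate.
* **Dual decoders + fusion.**  Two structurally identical expansion paths
  (nearest-neighbour upsample + 3x3 conv, pooling-integration skip fusion,
  3x3 refine) emit a foreground score map ``M_F`` and a background score map
  ``M_B``; the final map combines them, by default as
  ``(sigmoid(M_F) + 1 - sigmoid(M_B)) / 2`` (the published form
  ``1 - (sigmoid(M_F) + sigmoid(M_B)) / 2`` is kept as ``verbatim`` mode,
  although it degenerates to 0.5 for perfectly complementary decoders).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .nn import (
    BatchNorm2d, Conv2d, ConvBNAct, ConvTranspose2x, Dropout, Module,
    Parameter, Tensor, softmax,
)
from .nn import functional as F
from .nn.modules import xavier_uniform

FUSION_EPS = 1e-4
MASK_NEG = -1e9


@dataclass
class ModelConfig:
    input_size: int = 256
    encoder_channels: tuple[int, ...] = (128, 256, 512)
    bifpn_channels: int = 64
    bifpn_passes: int = 1
    eam_iterations: int = 1
    n_candidates: int = 2
    embed_dim: int = 256
    n_classes: int = 2
    dropout: float = 0.1
    fusion_mode: str = "complement"
    eam_gate_bottleneck: bool = False
    seed: int = 0

    @property
    def n_downsamples(self) -> int:
        return len(self.encoder_channels)

    @property
    def bottleneck_channels(self) -> int:
        return 2 * self.encoder_channels[-1]

    def __post_init__(self):
        if self.input_size % (2 ** self.n_downsamples):
            raise ValueError(
                f"input_size {self.input_size} must be divisible by "
                f"2^{self.n_downsamples}")
        if self.fusion_mode not in ("complement", "verbatim"):
            raise ValueError(f"unknown fusion_mode {self.fusion_mode!r}")
        if self.n_candidates < 1 or self.eam_iterations < 0:
            raise ValueError("n_candidates >= 1 and eam_iterations >= 0 required")

    @classmethod
    def tiny(cls, input_size: int = 64, **kw) -> "ModelConfig":
        """Reduced-width configuration for CPU-scale experiments."""
        kw.setdefault("encoder_channels", (4, 8, 16))
        kw.setdefault("bifpn_channels", 8)
        kw.setdefault("embed_dim", 16)
        kw.setdefault("dropout", 0.0)
        return cls(input_size=input_size, **kw)

    @classmethod
    def small(cls, input_size: int = 64, **kw) -> "ModelConfig":
        kw.setdefault("encoder_channels", (8, 16, 32))
        kw.setdefault("bifpn_channels", 16)
        kw.setdefault("embed_dim", 32)
        kw.setdefault("dropout", 0.0)
        return cls(input_size=input_size, **kw)


@dataclass
class DecoderOutputs:
    """Pre-sigmoid foreground/background score maps and the fused map."""

    M_F: Tensor
    M_B: Tensor
    O_Final: Tensor
    eam: Optional[dict] = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# functional pieces (used by the modules, unit-testable in isolation)
# ---------------------------------------------------------------------------

def fast_normalized_fusion(inputs: list[Tensor], weights: Tensor,
                           eps: float = FUSION_EPS) -> Tensor:
    """Weighted fusion ``sum_p relu(w_p)/(eps + sum_q relu(w_q)) * I_p``."""
    if len(inputs) != weights.shape[0]:
        raise ValueError("one weight per fused input required")
    shape0 = inputs[0].shape
    for t in inputs[1:]:
        if t.shape != shape0:
            raise ValueError(f"fusion input shapes differ: {t.shape} vs {shape0}")
    wr = weights.relu()
    denom = wr.sum() + eps
    out = inputs[0] * (wr[0] / denom)
    for i in range(1, len(inputs)):
        out = out + inputs[i] * (wr[i] / denom)
    return out


def _swap_last(x: Tensor) -> Tensor:
    axes = list(range(x.ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return x.transpose(*axes)


def eam_initial_mask(T_o: Tensor, Q: Tensor) -> Tensor:
    """Coarse prediction ``sigmoid(T_o x Q^T)``; ``T_o`` is [A, D] (or
    batched), ``Q`` is [P, D] (or [N, P, D]) -> [.., A, P] in (0, 1)."""
    T_o, Q = Tensor.as_tensor(T_o), Tensor.as_tensor(Q)
    if T_o.shape[-1] != Q.shape[-1]:
        raise ValueError(
            f"embedding dims differ: {T_o.shape[-1]} vs {Q.shape[-1]}")
    return (T_o @ _swap_last(Q)).sigmoid()


def attention_mask_from_coarse(a, neg: float = MASK_NEG) -> np.ndarray:
    """Additive attention mask: 0 where the coarse mask predicts foreground
    (>= 0.5), ``neg`` elsewhere.  A candidate whose mask is entirely empty
    falls back to unmasked attention."""
    a = np.asarray(a.data if isinstance(a, Tensor) else a, dtype=np.float64)
    fg = a >= 0.5
    add = np.where(fg, 0.0, neg)
    empty = ~fg.any(axis=-1)
    if empty.any():
        add[empty] = 0.0
    return add


def eam_refine(T: Tensor, Q: Tensor, a, Mq: Tensor, Mk: Tensor, Mv: Tensor,
               neg: float = MASK_NEG) -> Tensor:
    """One masked cross-attention refinement:
    ``T + softmax((T Mq)(Q Mk)^T + f(a)) (Q Mv)``."""
    T, Q = Tensor.as_tensor(T), Tensor.as_tensor(Q)
    scores = (T @ Mq) @ _swap_last(Q @ Mk)
    add = attention_mask_from_coarse(a, neg)
    attn = softmax(scores, axis=-1, additive_mask=add)
    return T + attn @ (Q @ Mv)


def eam_classify(T: Tensor, M_fc: Tensor):
    """Linear class logits per candidate and their argmax labels
    (ties resolve to the lowest class index)."""
    L = Tensor.as_tensor(T) @ M_fc
    R_hat = np.argmax(L.data, axis=-1)
    return L, R_hat


def fuse_outputs(M_F: Tensor, M_B: Tensor, mode: str = "complement") -> Tensor:
    """Merge the two decoder score maps into the final probability map."""
    M_F, M_B = Tensor.as_tensor(M_F), Tensor.as_tensor(M_B)
    if M_F.shape != M_B.shape:
        raise ValueError(f"decoder map shapes differ: {M_F.shape} vs {M_B.shape}")
    sF, sB = M_F.sigmoid(), M_B.sigmoid()
    if mode == "verbatim":
        return 1.0 - (sF + sB) * 0.5
    if mode == "complement":
        return (sF + (1.0 - sB)) * 0.5
    raise ValueError(f"unknown fusion mode {mode!r}")


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Encoder(Module):
    """Two contraction paths; the second consumes the first's features."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, cin: int = 1):
        super().__init__()
        self.n = cfg.n_downsamples
        self.p1_a, self.p1_b, self.p2_pre, self.p2_post = [], [], [], []
        c_prev = cin
        for c in cfg.encoder_channels:
            self.p1_a.append(ConvBNAct(c_prev, c, 3, rng))
            self.p1_b.append(ConvBNAct(c, c, 1, rng))
            self.p2_pre.append(ConvBNAct(c_prev, c, 3, rng))
            self.p2_post.append(ConvBNAct(c, c, 3, rng))
            c_prev = c
        self.bottleneck = ConvBNAct(c_prev, cfg.bottleneck_channels, 3, rng)

    def __call__(self, x: Tensor):
        H, W = x.shape[-2:]
        if H % (2 ** self.n) or W % (2 ** self.n):
            raise ValueError(
                f"spatial size {H}x{W} not divisible by 2^{self.n}")
        p1 = p2 = x
        pyramid: dict[int, Tensor] = {}
        for i in range(self.n):
            p1 = self.p1_b[i](self.p1_a[i](p1))
            p2 = self.p2_post[i](self.p2_pre[i](p2) + p1)
            pyramid[i] = p2
            p1 = F.maxpool2x(p1)
            p2 = F.maxpool2x(p2)
        bott = self.bottleneck(p2)
        pyramid[self.n] = bott
        return pyramid, bott


class SeparableConvBlock(Module):
    """Depthwise 3x3 -> norm -> pointwise 1x1 -> norm, Swish-activated."""

    def __init__(self, c: int, rng: np.random.Generator):
        super().__init__()
        from .nn.modules import he_normal
        self.dw_weight = Parameter(he_normal(rng, (c, 1, 3, 3), 9))
        self.bn1 = BatchNorm2d(c)
        self.pw = Conv2d(c, c, 1, rng)
        self.bn2 = BatchNorm2d(c)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.bn1(F.conv2d(x, self.dw_weight, None, 1, 1, depthwise=True))
        return self.bn2(self.pw(x)).swish()


class BiFPNPass(Module):
    """One top-down + bottom-up sweep over ``n_tiers`` equal-width tiers."""

    def __init__(self, n_tiers: int, c: int, rng: np.random.Generator):
        super().__init__()
        self.n = n_tiers
        self.up = [ConvTranspose2x(c, c, rng) for _ in range(n_tiers - 1)]
        self.td_conv = [SeparableConvBlock(c, rng) for _ in range(n_tiers - 1)]
        self.bu_conv = [SeparableConvBlock(c, rng) for _ in range(n_tiers - 1)]
        self.w_td = [Parameter(np.ones(2)) for _ in range(n_tiers - 1)]
        # interior bottom-up nodes fuse (input, top-down, lower output)
        self.w_bu = [Parameter(np.ones(3 if 0 < i < n_tiers - 1 else 2))
                     for i in range(1, n_tiers)]

    def __call__(self, tiers: list[Tensor]) -> list[Tensor]:
        n = self.n
        td = [None] * n
        td[n - 1] = tiers[n - 1]
        for i in range(n - 2, -1, -1):
            upped = self.up[i](td[i + 1])
            fused = fast_normalized_fusion([tiers[i], upped], self.w_td[i])
            td[i] = self.td_conv[i](fused)
        out = [None] * n
        out[0] = td[0]
        for i in range(1, n):
            down = F.maxpool2x(out[i - 1])
            ins = [tiers[i], down] if i == n - 1 else [tiers[i], td[i], down]
            fused = fast_normalized_fusion(ins, self.w_bu[i - 1])
            out[i] = self.bu_conv[i - 1](fused)
        return out


class FeatureGate(Module):
    """Feature optimization: x * sigmoid(1x1 conv(norm(x))), then dropout."""

    def __init__(self, c: int, dropout: float, rng, drop_rng):
        super().__init__()
        self.bn = BatchNorm2d(c)
        self.conv = Conv2d(c, c, 1, rng)
        self.drop = Dropout(dropout, drop_rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.drop(x * self.conv(self.bn(x)).sigmoid())


class BiFPN(Module):
    def __init__(self, cfg: ModelConfig, rng, drop_rng, in_channels: list[int]):
        super().__init__()
        c = cfg.bifpn_channels
        self.lateral = [ConvBNAct(ci, c, 1, rng) for ci in in_channels]
        self.passes = [BiFPNPass(len(in_channels), c, rng)
                       for _ in range(cfg.bifpn_passes)]
        self.gates = [FeatureGate(c, cfg.dropout, rng, drop_rng)
                      for _ in in_channels]

    def __call__(self, tiers: list[Tensor]) -> list[Tensor]:
        tiers = [lat(t) for lat, t in zip(self.lateral, tiers)]
        for p in self.passes:
            tiers = p(tiers)
        return [g(t) for g, t in zip(self.gates, tiers)]


class EAM(Module):
    """Coarse-to-fine masked attention over the coarsest tier."""

    def __init__(self, cfg: ModelConfig, cin: int, rng: np.random.Generator):
        super().__init__()
        A, D = cfg.n_candidates, cfg.embed_dim
        self.iters = cfg.eam_iterations
        self.q_proj = Conv2d(cin, D, 1, rng)
        self.T_o = Parameter(xavier_uniform(rng, (A, D)))
        self.Mq = Parameter(xavier_uniform(rng, (D, D)))
        self.Mk = Parameter(xavier_uniform(rng, (D, D)))
        self.Mv = Parameter(xavier_uniform(rng, (D, D)))
        self.M_fc = Parameter(xavier_uniform(rng, (D, cfg.n_classes)))

    def __call__(self, feature: Tensor) -> dict:
        N, _, h, w = feature.shape
        D = self.T_o.shape[1]
        Q = self.q_proj(feature).reshape(N, D, h * w)
        Q = Q.transpose(0, 2, 1)  # [N, P, D]
        T = self.T_o
        masks = [eam_initial_mask(T, Q)]  # [N, A, P]
        for _ in range(self.iters):
            T = eam_refine(T, Q, masks[-1].data, self.Mq, self.Mk, self.Mv)
            masks.append(eam_initial_mask(T, Q))
        L, R_hat = eam_classify(T, self.M_fc)  # [N, A, R] or [A, R]
        if L.ndim == 2:  # iters == 0 keeps T unbatched
            R_hat = np.broadcast_to(R_hat, (N, R_hat.shape[0]))
        final = masks[-1]
        # assemble the fused coarse map: elementwise max over candidates
        # classified as foreground (class 1); none -> all-zero map
        sel = (R_hat == 1).astype(np.float64)[..., None]  # [N, A, 1]
        weighted = final * Tensor(np.broadcast_to(sel, final.shape).copy()) \
            if final.ndim == 3 else final * Tensor(sel[0])
        cur = weighted[:, 0] if weighted.ndim == 3 else weighted[0].reshape(1, -1)
        A = final.shape[-2]
        for a in range(1, A):
            nxt = weighted[:, a] if weighted.ndim == 3 else weighted[a].reshape(1, -1)
            cur = cur + (nxt - cur).relu()
        fg_map = cur.reshape(N, 1, h, w) if weighted.ndim == 3 else cur.reshape(1, 1, h, w)
        return {
            "masks": masks, "candidate_masks": final, "logits": L,
            "labels": R_hat, "fg_map": fg_map, "spatial": (h, w),
        }


class PoolingIntegration(Module):
    """Smooth high-level features with a 3x3 average pool, add the low-level
    features, refine with 1x1 conv + norm + ReLU."""

    def __init__(self, c: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(c, c, 1, rng)
        self.bn = BatchNorm2d(c)

    def __call__(self, low: Tensor, high: Tensor) -> Tensor:
        if low.shape != high.shape:
            raise ValueError(
                f"pooling-integration shape mismatch: {low.shape} vs {high.shape}")
        return self.bn(self.conv(F.avgpool2d(high) + low)).relu()


class Decoder(Module):
    """U-Net style expansion path with pooling-integration skip fusion."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        c = cfg.bifpn_channels
        n = cfg.n_downsamples
        self.up_convs = [ConvBNAct(c, c, 3, rng) for _ in range(n)]
        self.pils = [PoolingIntegration(c, rng) for _ in range(n)]
        self.refines = [ConvBNAct(c, c, 3, rng) for _ in range(n)]
        self.head = ConvBNAct(c, c, 3, rng)
        self.out_conv = Conv2d(c, 1, 1, rng)

    def __call__(self, tiers: list[Tensor]) -> Tensor:
        n = len(tiers) - 1
        x = tiers[-1]
        for step, level in enumerate(range(n - 1, -1, -1)):
            x = self.up_convs[step](F.upsample_nearest2x(x))
            x = self.pils[step](tiers[level], x)
            x = self.refines[step](x)
        return self.out_conv(self.head(x))


class DualDecoderUNet(Module):
    """The full network: encoder -> BiFPN -> attention -> dual decoders ->
    output fusion.  Deterministic given ``config.seed`` and the input."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 71]))
        drop_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 72]))
        chans = list(config.encoder_channels) + [config.bottleneck_channels]
        self.encoder = Encoder(config, rng)
        self.bifpn = BiFPN(config, rng, drop_rng, chans)
        self.eam = EAM(config, config.bifpn_channels, rng)
        self.decoder_fg = Decoder(config, rng)
        self.decoder_bg = Decoder(config, rng)

    @staticmethod
    def _as_input(x) -> Tensor:
        if isinstance(x, Tensor):
            t = x
        else:
            arr = np.asarray(x, dtype=np.float64)
            if arr.ndim == 2:
                arr = arr[None, None]
            elif arr.ndim == 3:
                arr = arr[:, None]
            t = Tensor(arr)
        if t.ndim != 4:
            raise ValueError(f"expected [N,C,H,W] input, got shape {t.shape}")
        return t

    def __call__(self, x) -> DecoderOutputs:
        x = self._as_input(x)
        pyramid, _ = self.encoder(x)
        tiers = self.bifpn([pyramid[i] for i in sorted(pyramid)])
        eam_out = self.eam(tiers[-1])
        if self.config.eam_gate_bottleneck:
            tiers = list(tiers)
            tiers[-1] = tiers[-1] * eam_out["fg_map"]
        M_F = self.decoder_fg(tiers)
        M_B = self.decoder_bg(tiers)
        O = fuse_outputs(M_F, M_B, self.config.fusion_mode)
        return DecoderOutputs(M_F=M_F, M_B=M_B, O_Final=O, eam=eam_out)
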
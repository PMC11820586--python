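"""W-shaped recurrent-residual attention network for fetal ECG extraction.

Two five-level attention U-Nets over 1-D signals are joined in a W shape:
the *maternal* branch (kernel size 5) reconstructs the maternal ECG from the
abdominal mixture; the *fetal* branch (kernel size 3) encodes the same
mixture, subtracts the maternal encoder's feature maps level by level
(passed through tanh), and decodes the difference into the fetal ECG.

Building blocks:

* **RRC block** — recurrent residual convolution: a forward convolution
  whose activation is refined for ``T`` recurrence steps by a second
  convolution fed back on itself, wrapped in a residual connection
  (identity, or a 1x1 projection when channel counts differ).
* **Attention gate** — additive attention replacing the plain skip
  connection: ``alpha = sigmoid(psi(relu(W_u u + W_g g + b_g)) + b_psi)``
  with the decoder-side gating signal ``g``; the encoder features are
  reweighted per sample position by ``alpha`` in [0, 1].

All convolutions are stride-1 zero-padded; max pooling and linear
upsampling provide every length change, so the network is fully
convolutional in time: any input length divisible by ``2**(depth-1)``
works.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn.autograd import Tensor, concat, conv1d, maxpool2, upsample_linear2
from .nn.layers import ACTIVATIONS, Conv1d, Module

__all__ = [
    "NetworkConfig", "RRCBlock", "AttentionGate", "Encoder", "Decoder",
    "AttentionR2WNet", "fuse_subtract_tanh", "count_parameters",
    "save_checkpoint", "load_checkpoint",
]

BLOCK_TYPES = ("forward", "residual", "recurrent", "rrc")


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``channels`` defaults to the doubling schedule 64·2^l scaled by
    ``width_multiplier`` (so the full-scale depth-5 network is
    64, 128, 256, 512, 1024 and the desk-scale 1/8 variant 8, 16, 32, 64,
    128).  ``fusion_levels`` of ``None`` fuses at every encoder level.
    """

    depth: int = 5
    width_multiplier: float = 1.0
    channels: tuple[int, ...] | None = None
    kernel_maternal: int = 5
    kernel_fetal: int = 3
    recurrence_T: int = 2
    pool_factor: int = 2
    fusion_levels: tuple[int, ...] | None = None
    activation: str = "leaky_relu"
    block_type: str = "rrc"
    fusion_feeds_encoder: bool = False

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.kernel_maternal % 2 == 0 or self.kernel_fetal % 2 == 0:
            raise ValueError("kernel sizes must be odd")
        if self.recurrence_T < 1:
            raise ValueError("recurrence_T must be >= 1")
        if self.block_type not in BLOCK_TYPES:
            raise ValueError(f"block_type must be one of {BLOCK_TYPES}")
        ch = self.resolved_channels()
        if any(b <= a for a, b in zip(ch, ch[1:])):
            raise ValueError(f"channels must be strictly increasing, got {ch}")

    def resolved_channels(self) -> tuple[int, ...]:
        if self.channels is not None:
            return tuple(self.channels)
        return tuple(max(1, int(round(64 * (2 ** l) * self.width_multiplier)))
                     for l in range(self.depth))

    def resolved_fusion_levels(self) -> tuple[int, ...]:
        if self.fusion_levels is None:
            return tuple(range(self.depth))
        return tuple(self.fusion_levels)


# ---------------------------------------------------------------------------
# blocks

class RRCBlock(Module):
    """Recurrent residual convolution block (and its ablation variants).

    * ``rrc``       — y(0) = act(conv_f(x)); y(t) = act(conv_f(x) +
      conv_r(y(t-1))), t = 1..T; output = x' + y(T) with x' a 1x1
      projection of x when channel counts differ.
    * ``recurrent`` — the same recurrence without the residual term.
    * ``residual``  — two plain convolutions with a residual connection.
    * ``forward``   — two plain convolutions only.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, T: int,
                 rng: np.random.Generator, activation: str = "leaky_relu",
                 block_type: str = "rrc"):
        if block_type not in BLOCK_TYPES:
            raise ValueError(f"unknown block type {block_type!r}")
        self.conv_f = Conv1d(in_ch, out_ch, kernel, rng)
        self.conv_r = Conv1d(out_ch, out_ch, kernel, rng)
        self.proj = Conv1d(in_ch, out_ch, 1, rng) if in_ch != out_ch else None
        self.T = T
        self.block_type = block_type
        self.act = ACTIVATIONS(activation)

    def _residual_input(self, x: Tensor) -> Tensor:
        return self.proj(x) if self.proj is not None else x

    def __call__(self, x: Tensor, T: int | None = None) -> Tensor:
        T = self.T if T is None else T
        if self.block_type in ("forward", "residual"):
            y = self.act(self.conv_r(self.act(self.conv_f(x))))
            return self._residual_input(x) + y if self.block_type == "residual" else y
        z = self.conv_f(x)
        y = self.act(z)
        for _ in range(T):
            y = self.act(z + self.conv_r(y))
        if self.block_type == "recurrent":
            return y
        return self._residual_input(x) + y


def rrc_block(x: Tensor, block: RRCBlock, T: int | None = None) -> Tensor:
    """Functional alias: apply an RRC block with an explicit unroll count."""
    return block(x, T=T)


class AttentionGate(Module):
    """Additive attention gate reweighting encoder features.

    The internal channel width is half the gated feature width.  The gating
    signal must already share the encoder features' temporal length (the
    decoder upsamples before gating); a mismatch raises a shape error.
    """

    def __init__(self, u_ch: int, g_ch: int, rng: np.random.Generator):
        inter = max(1, u_ch // 2)
        self.w_u = Conv1d(u_ch, inter, 1, rng, bias=False)
        self.w_g = Conv1d(g_ch, inter, 1, rng, bias=True)   # bias b_g
        self.psi = Conv1d(inter, 1, 1, rng, bias=True)      # bias b_phi

    def __call__(self, u: Tensor, g: Tensor) -> Tensor:
        if u.shape[-1] != g.shape[-1]:
            raise ValueError(
                f"gate inputs disagree in length: u {u.shape} vs g {g.shape}"
            )
        q = self.psi((self.w_u(u) + self.w_g(g)).relu())
        alpha = q.sigmoid()          # (B, 1, L), broadcast over channels
        return alpha * u

    def coefficients(self, u: Tensor, g: Tensor) -> np.ndarray:
        """Attention coefficients alpha in [0, 1] (diagnostic)."""
        q = self.psi((self.w_u(u) + self.w_g(g)).relu())
        return q.sigmoid().data


def attention_gate(u: Tensor, g: Tensor, gate: AttentionGate) -> Tensor:
    """Functional alias for applying an attention gate."""
    return gate(u, g)


def fuse_subtract_tanh(fetal_feats: list[Tensor], maternal_feats: list[Tensor],
                       fusion_levels) -> list[Tensor]:
    """Cross-branch fusion: ``tanh(fetal - maternal)`` at the given levels.

    Non-fused levels pass through unchanged.  Fused activations are bounded
    to (-1, 1) by construction.
    """
    fused = []
    levels = set(fusion_levels)
    for l, f in enumerate(fetal_feats):
        if l in levels:
            m = maternal_feats[l]
            if f.shape != m.shape:
                raise ValueError(
                    f"fusion shape mismatch at level {l}: {f.shape} vs {m.shape}"
                )
            fused.append((f - m).tanh())
        else:
            fused.append(f)
    return fused


# ---------------------------------------------------------------------------
# encoder / decoder

class Encoder(Module):
    """Stack of RRC blocks with max pooling between levels.

    Level ``l`` output has ``channels[l]`` channels and length ``L / 2**l``.
    """

    def __init__(self, config: NetworkConfig, kernel: int,
                 rng: np.random.Generator):
        ch = config.resolved_channels()
        self.blocks = [
            RRCBlock(1 if l == 0 else ch[l - 1], ch[l], kernel,
                     config.recurrence_T, rng, config.activation,
                     config.block_type)
            for l in range(config.depth)
        ]

    def __call__(self, x: Tensor,
                 fuse_with: list[Tensor] | None = None,
                 fusion_levels=()) -> list[Tensor]:
        """Return per-level feature maps; optionally fuse in-stream.

        When ``fuse_with`` is given, the subtraction-tanh fusion replaces
        this encoder's stream at each fusion level before pooling.
        """
        feats = []
        levels = set(fusion_levels)
        for l, block in enumerate(self.blocks):
            x = block(x)
            if fuse_with is not None and l in levels:
                x = (x - fuse_with[l]).tanh()
            feats.append(x)
            if l < len(self.blocks) - 1:
                x = maxpool2(x)
        return feats


class Decoder(Module):
    """Mirror of the encoder: upsample, gate the skip, concatenate, refine."""

    def __init__(self, config: NetworkConfig, kernel: int,
                 rng: np.random.Generator):
        ch = config.resolved_channels()
        d = config.depth
        self.reduce = [Conv1d(ch[l + 1], ch[l], 1, rng) for l in range(d - 1)]
        self.gates = [AttentionGate(ch[l], ch[l], rng) for l in range(d - 1)]
        self.blocks = [
            RRCBlock(2 * ch[l], ch[l], kernel, config.recurrence_T, rng,
                     config.activation, config.block_type)
            for l in range(d - 1)
        ]
        # linear output head, initialized small so the untrained network
        # predicts near zero (Z-scored targets are O(1); starting the
        # regression from ~0 keeps early optimization stable)
        self.head = Conv1d(ch[0], 1, 1, rng)
        self.head.weight.data *= 0.01

    def __call__(self, feats: list[Tensor]) -> Tensor:
        d = feats[-1]
        for l in range(len(feats) - 2, -1, -1):
            up = self.reduce[l](upsample_linear2(d))
            gated = self.gates[l](feats[l], up)
            d = self.blocks[l](concat([gated, up], axis=1))
        return self.head(d)


# ---------------------------------------------------------------------------
# the W-shaped model

class AttentionR2WNet(Module):
    """Dual attention R2U-Net: maternal reconstruction + fetal extraction.

    The two branches share no weights.  By default the fused
    (subtract-tanh) feature maps only feed the fetal decoder's attention
    gates; with ``config.fusion_feeds_encoder`` they also replace the fetal
    encoder's stream for subsequent levels.
    """

    def __init__(self, config: NetworkConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.enc_maternal = Encoder(config, config.kernel_maternal, rng)
        self.dec_maternal = Decoder(config, config.kernel_maternal, rng)
        self.enc_fetal = Encoder(config, config.kernel_fetal, rng)
        self.dec_fetal = Decoder(config, config.kernel_fetal, rng)

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, None, :]
        elif x.ndim == 2:
            x = x[:, None, :]
        if x.ndim != 3 or x.shape[1] != 1:
            raise ValueError(f"expected (batch, 1, length) input, got {x.shape}")
        div = self.config.pool_factor ** (self.config.depth - 1)
        if x.shape[2] % div:
            raise ValueError(
                f"input length {x.shape[2]} not divisible by {div} "
                f"(depth {self.config.depth})"
            )
        return x

    def forward(self, x) -> tuple[Tensor, Tensor]:
        """Run both branches; returns ``(fecg_pred, mecg_pred)`` tensors."""
        xt = x if isinstance(x, Tensor) else Tensor(self._check_input(x))
        cfg = self.config
        fusion = cfg.resolved_fusion_levels()
        m_feats = self.enc_maternal(xt)
        mecg = self.dec_maternal(m_feats)
        if cfg.fusion_feeds_encoder:
            fused = self.enc_fetal(xt, fuse_with=m_feats, fusion_levels=fusion)
        else:
            f_feats = self.enc_fetal(xt)
            fused = fuse_subtract_tanh(f_feats, m_feats, fusion)
        fecg = self.dec_fetal(fused)
        return fecg, mecg

    __call__ = forward

    def predict(self, segments: np.ndarray, batch_size: int = 32
                ) -> tuple[np.ndarray, np.ndarray]:
        """Inference without graph bookkeeping; returns (fecg, mecg) arrays
        of shape ``(n_segments, length)``."""
        segs = np.atleast_2d(np.asarray(segments, dtype=float))
        params = self.parameters()
        flags = [p.requires_grad for p in params]
        for p in params:
            p.requires_grad = False
        try:
            f_out, m_out = [], []
            for i in range(0, segs.shape[0], batch_size):
                f, m = self.forward(segs[i:i + batch_size])
                f_out.append(f.data[:, 0, :])
                m_out.append(m.data[:, 0, :])
        finally:
            for p, fl in zip(params, flags):
                p.requires_grad = fl
        return np.concatenate(f_out), np.concatenate(m_out)


def count_parameters(model: Module) -> int:
    """Total number of trainable scalar parameters."""
    return int(sum(p.data.size for p in model.parameters()))


# ---------------------------------------------------------------------------
# checkpoints: weights file + JSON config sidecar

def save_checkpoint(model: AttentionR2WNet, directory) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savez(d / "weights.npz", **model.state_dict())
    (d / "config.json").write_text(json.dumps(asdict(model.config), indent=2))
    return d


def load_checkpoint(directory) -> AttentionR2WNet:
    d = Path(directory)
    cfg_path, w_path = d / "config.json", d / "weights.npz"
    if not cfg_path.exists() or not w_path.exists():
        raise FileNotFoundError(f"no checkpoint (config.json + weights.npz) in {d}")
    raw = json.loads(cfg_path.read_text())
    for key in ("channels", "fusion_levels"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    config = NetworkConfig(**raw)
    model = AttentionR2WNet(config)
    with np.load(w_path) as npz:
        state = {k: npz[k] for k in npz.files}
    try:
        model.load_state_dict(state)
    except ValueError as exc:
        raise ValueError(f"checkpoint/config architecture mismatch: {exc}") from exc
    return model
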
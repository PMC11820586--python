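"""Joint training of the maternal and fetal branches.

Both decoders are supervised at once: the loss is a weighted sum of the
per-branch reconstruction errors (MAE by default, MSE available for the
loss ablation), computed on Z-scored 1024-sample windows.  Optimization is
Adam; all shuffling and initialization flow through the run seed, so a
(seed, dataset) pair reproduces its history exactly.

Two presets are provided: ``paper`` (learning rate 1e-4, batch 32,
30 epochs — the full-scale configuration) and ``desk`` (width 1/8 network,
learning rate 1e-3, batch 8, up to 10 epochs) sized so a run finishes in
minutes on one CPU core.

The train/validation split is by record, never by segment, so overlapping
windows cannot leak across the split.  On synthetic records the maternal
target is the clean maternal component; when a record carries no maternal
truth (real abdominal data) the abdominal mixture itself stands in, fetal
energy being a small residual by comparison.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .nn.autograd import Tensor
from .nn.layers import Adam
from .preprocess import SEGMENT_LEN, bandpass_3_100, resample_to_250, segment, zscore
from .r2wnet import AttentionR2WNet, NetworkConfig, count_parameters, save_checkpoint
from .signal_io import Record, read_record

__all__ = ["TrainConfig", "TrainHistory", "joint_loss", "train", "ablate",
           "load_training_arrays", "desk_network_config"]

logger = logging.getLogger("fecgnet.training")

ABLATION_AXES = {
    "loss": ("mae", "mse"),
    "depth": (4, 5, 6),
    "block_type": ("forward", "residual", "recurrent", "rrc"),
}


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults follow the full-scale configuration."""

    loss: str = "mae"
    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 30
    loss_weights: tuple[float, float] = (1.0, 1.0)  # (fetal, maternal)
    seed: int = 0
    device: str = "cpu"
    preset: str = "paper"
    val_fraction: float = 0.1
    clip_norm: float = 5.0
    max_segments: int | None = None

    def __post_init__(self):
        if self.loss not in ("mae", "mse"):
            raise ValueError("loss must be 'mae' or 'mse'")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        wf, wm = self.loss_weights
        if wf < 0 or wm < 0 or (wf == 0 and wm == 0):
            raise ValueError("loss weights must be >= 0 and not both zero")

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        base = dict(learning_rate=1e-3, batch_size=8, epochs=10, preset="desk",
                    max_segments=500)
        base.update(overrides)
        return cls(**base)


def desk_network_config(**overrides) -> NetworkConfig:
    """Desk-scale architecture: 1/8 width, otherwise the full design."""
    kw = dict(width_multiplier=1 / 8)
    kw.update(overrides)
    return NetworkConfig(**kw)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    epoch_seconds: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# loss

def joint_loss(fecg_pred: Tensor, fecg_true: np.ndarray, mecg_pred: Tensor,
               mecg_true: np.ndarray, weights: tuple[float, float] = (1.0, 1.0),
               kind: str = "mae") -> Tensor:
    """Weighted two-branch reconstruction loss.

    ``weights[0] * err(fetal) + weights[1] * err(maternal)`` where ``err``
    is the mean absolute error (default) or mean squared error.
    """
    f_t, m_t = np.asarray(fecg_true, float), np.asarray(mecg_true, float)
    if fecg_pred.shape != f_t.shape or mecg_pred.shape != m_t.shape:
        raise ValueError(
            f"prediction/target shape mismatch: {fecg_pred.shape} vs {f_t.shape}, "
            f"{mecg_pred.shape} vs {m_t.shape}"
        )

    def err(pred, true):
        d = pred - Tensor(true)
        return d.abs().mean() if kind == "mae" else (d * d).mean()

    wf, wm = weights
    if wm == 0:
        return wf * err(fecg_pred, f_t)
    if wf == 0:
        return wm * err(mecg_pred, m_t)
    return wf * err(fecg_pred, f_t) + wm * err(mecg_pred, m_t)


# ---------------------------------------------------------------------------
# data pipeline

def record_to_training_windows(record: Record) -> dict:
    """Condition one record into aligned (mixture, fetal, maternal) windows.

    The mixture is band-passed, resampled to 250 Hz, windowed and Z-scored;
    the supervision targets are cut at the same offsets and scaled by the
    mixture window's standard deviation so prediction and target live on
    one scale.
    """
    proc = replace(
        record,
        signals=np.stack([bandpass_3_100(ch, record.fs)
                          for ch in record.signals]),
    )
    proc = resample_to_250(proc)
    mix = proc.channel("abdominal_mixture")
    sset = zscore(segment(mix, proc.fs))
    if proc.has_channel("fetal_truth"):
        fetal = proc.channel("fetal_truth")
    elif proc.has_channel("fetal_scalp_reference"):
        fetal = proc.channel("fetal_scalp_reference")
    else:
        raise ValueError("record provides neither fetal truth nor reference")
    maternal = (proc.channel("maternal_truth")
                if proc.has_channel("maternal_truth") else mix)
    mean, sd = sset.norm_state[:, 0], sset.norm_state[:, 1]
    offs = sset.offsets
    yf = np.stack([fetal[o:o + SEGMENT_LEN] for o in offs]) / sd[:, None]
    ym = (np.stack([maternal[o:o + SEGMENT_LEN] for o in offs])
          - mean[:, None]) / sd[:, None]
    return {"x": sset.segments, "yf": yf, "ym": ym}


def load_training_arrays(manifest_path) -> list[dict]:
    """Load every record in a manifest as training windows (one dict each)."""
    manifest = Path(manifest_path)
    if not manifest.exists():
        raise ValueError(f"manifest not found: {manifest}")
    lines = manifest.read_text().strip().splitlines()
    if len(lines) < 2:
        raise ValueError(f"empty manifest: {manifest}")
    out = []
    for line in lines[1:]:
        rel = line.split("\t")[0]
        rec = read_record(manifest.parent / rel)
        item = record_to_training_windows(rec)
        item["path"] = rel
        out.append(item)
    return out


def _split_records(items: list[dict], val_fraction: float, seed: int):
    """Record-level split; with a single record it serves both roles."""
    if len(items) == 1:
        return items, items
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    n_val = max(1, int(round(val_fraction * len(items))))
    val_idx = set(order[:n_val].tolist())
    train = [it for i, it in enumerate(items) if i not in val_idx]
    val = [it for i, it in enumerate(items) if i in val_idx]
    return train, val


def _stack(items: list[dict], max_segments: int | None, rng):
    x = np.concatenate([it["x"] for it in items])
    yf = np.concatenate([it["yf"] for it in items])
    ym = np.concatenate([it["ym"] for it in items])
    if max_segments is not None and x.shape[0] > max_segments:
        keep = rng.choice(x.shape[0], size=max_segments, replace=False)
        keep.sort()
        x, yf, ym = x[keep], yf[keep], ym[keep]
    return x, yf, ym


def _np_loss(model, x, yf, ym, weights, kind):
    f, m = model.predict(x)
    def err(p, t):
        d = p - t
        return float(np.abs(d).mean()) if kind == "mae" else float((d * d).mean())
    return weights[0] * err(f, yf) + weights[1] * err(m, ym)


# ---------------------------------------------------------------------------
# training loop

def train(model: AttentionR2WNet, dataset_manifest, config: TrainConfig,
          checkpoint_dir=None) -> tuple[AttentionR2WNet, TrainHistory]:
    """Train both branches jointly; returns the best-validation model.

    Deterministic given ``config.seed``.  Raises on an empty manifest and
    aborts with a diagnostic if the loss turns non-finite.
    """
    items = load_training_arrays(dataset_manifest)
    rng = np.random.default_rng(config.seed)
    train_items, val_items = _split_records(items, config.val_fraction,
                                            config.seed)
    x, yf, ym = _stack(train_items, config.max_segments, rng)
    xv, yfv, ymv = _stack(val_items, None, rng)
    logger.info("training on %d segments (%d records), validating on %d",
                x.shape[0], len(train_items), xv.shape[0])

    opt = Adam(model.parameters(), lr=config.learning_rate,
               clip_norm=config.clip_norm)
    history = TrainHistory()
    best_val, best_state = np.inf, model.state_dict()
    n = x.shape[0]
    for epoch in range(config.epochs):
        t0 = time.time()
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            model.zero_grad()
            f_pred, m_pred = model.forward(x[idx])
            loss = joint_loss(f_pred, yf[idx][:, None, :], m_pred,
                              ym[idx][:, None, :], config.loss_weights,
                              config.loss)
            lv = loss.item()
            if not np.isfinite(lv):
                raise RuntimeError(
                    f"non-finite loss {lv} at epoch {epoch}, batch {n_batches}"
                )
            loss.backward()
            opt.step()
            epoch_loss += lv
            n_batches += 1
        val_loss = _np_loss(model, xv, yfv, ymv, config.loss_weights,
                            config.loss)
        history.train_loss.append(epoch_loss / max(n_batches, 1))
        history.val_loss.append(val_loss)
        history.epoch_seconds.append(time.time() - t0)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            history.best_epoch = epoch
        logger.info("epoch %d: train %.4f  val %.4f  (%.1fs)", epoch,
                    history.train_loss[-1], val_loss,
                    history.epoch_seconds[-1])
    model.load_state_dict(best_state)

    if checkpoint_dir is not None:
        d = save_checkpoint(model, checkpoint_dir)
        (d / "history.json").write_text(json.dumps(history.as_dict(), indent=2))
        digest = hashlib.sha256(
            Path(dataset_manifest).read_bytes()).hexdigest()
        (d / "train_config.json").write_text(json.dumps(
            {**asdict(config), "manifest_sha256": digest}, indent=2))
    return model, history


# ---------------------------------------------------------------------------
# ablation harness

def ablate(dataset_manifest, axis: str, values: list,
           network_config: NetworkConfig | None = None,
           train_config: TrainConfig | None = None):
    """Train one desk-preset model per value of one design axis.

    Supported axes: ``loss`` (mae/mse), ``depth`` (4/5/6) and ``block_type``
    (forward/residual/recurrent/rrc).  All runs share the seed and the
    record split, so rows are directly comparable.  Returns a
    ``pandas.DataFrame`` with one row per value: final/best losses,
    validation signal errors, and the parameter count.
    """
    import pandas as pd

    if axis not in ABLATION_AXES:
        raise ValueError(f"axis must be one of {sorted(ABLATION_AXES)}")
    for v in values:
        if v not in ABLATION_AXES[axis]:
            raise ValueError(f"unsupported value {v!r} for axis {axis!r}")
    net_cfg = network_config or desk_network_config()
    tr_cfg = train_config or TrainConfig.desk()
    rows = []
    for v in values:
        n_cfg, t_cfg = net_cfg, tr_cfg
        if axis == "loss":
            t_cfg = replace(tr_cfg, loss=v)
        elif axis == "depth":
            n_cfg = replace(net_cfg, depth=v, channels=None)
        elif axis == "block_type":
            n_cfg = replace(net_cfg, block_type=v)
        model = AttentionR2WNet(n_cfg, seed=t_cfg.seed)
        model, hist = train(model, dataset_manifest, t_cfg)
        items = load_training_arrays(dataset_manifest)
        _, val_items = _split_records(items, t_cfg.val_fraction, t_cfg.seed)
        xv, yfv, ymv = _stack(val_items, None, np.random.default_rng(t_cfg.seed))
        f, _m = model.predict(xv)
        resid = f - yfv
        rows.append({
            axis: v,
            "final_train_loss": hist.train_loss[-1],
            "best_val_loss": min(hist.val_loss),
            "val_fetal_mse": float((resid ** 2).mean()),
            "val_fetal_mae": float(np.abs(resid).mean()),
            "n_parameters": count_parameters(model),
        })
    return pd.DataFrame(rows)
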
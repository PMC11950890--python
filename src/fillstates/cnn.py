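"""Control-free fill-state estimation with a compact 3D CNN.

Fill states are defined relative to a control cohort, which limits their
use where no normative sample exists. This module trains a small 3D
convolutional regression network to map an SUVR volume directly to its
fill state (fraction of abnormal meta-ROI voxels), so that inference needs
only the image. The network: 4 strided conv blocks with ReLU, global
average pooling, one dense head, sigmoid output in [0, 1] (scaled x100 for
percentage points). Loss is mean absolute error. Estimates are clipped to
[0, 100] and clipping is logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import Adam, Conv3d, Dense, GlobalAvgPool, ReLU, Sequential, Sigmoid, mae_loss
from .volume import VolumeGrid

logger = logging.getLogger(__name__)


@dataclass
class EstimatorConfig:
    input_shape: tuple = (32, 32, 32)
    channels: tuple = (8, 16, 32, 32)
    lr: float = 3e-3
    batch_size: int = 16
    epochs: int = 40
    loss: str = "mae"
    val_fraction: float = 0.3
    seed: int = 0
    #: fixed affine input standardization (SUVR ~ 1.2 +- 0.3)
    input_center: float = 1.2
    input_scale: float = 0.3
    bounded_output: bool = True  # sigmoid head; False = unbounded linear head

    def __post_init__(self):
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")


def _build_net(config: EstimatorConfig) -> Sequential:
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 11])
    layers = []
    c_prev = 1
    for c in config.channels:
        layers += [Conv3d(c_prev, c, k=3, stride=2, pad=1, rng=rng), ReLU()]
        c_prev = c
    layers += [GlobalAvgPool(), Dense(c_prev, 1, rng=rng)]
    if config.bounded_output:
        layers.append(Sigmoid())
    return Sequential(layers)


class FillStateEstimator:
    """Trained estimator mapping one SUVR volume to a fill state in %."""

    def __init__(self, config: EstimatorConfig, net: Sequential | None = None):
        self.config = config
        self.net = net or _build_net(config)
        self.history: dict = {}

    def _prep(self, arrays: list[np.ndarray]) -> np.ndarray:
        x = np.stack(arrays).astype(float)[:, None]  # (n, 1, d, h, w)
        return (x - self.config.input_center) / self.config.input_scale

    def estimate_batch(self, volumes) -> np.ndarray:
        arrays = [v.values if isinstance(v, VolumeGrid) else np.asarray(v) for v in volumes]
        for a in arrays:
            if a.shape != tuple(self.config.input_shape):
                raise ValueError(
                    f"volume shape {a.shape} != estimator input {tuple(self.config.input_shape)}"
                )
        raw = self.net.forward(self._prep(arrays), train=False).ravel() * 100.0
        n_clip = int(((raw < 0) | (raw > 100)).sum())
        if n_clip:
            logger.info("clipped %d estimates to [0, 100]", n_clip)
        return np.clip(raw, 0.0, 100.0)

    def estimate(self, volume) -> float:
        """Fill state (%) for one volume; no control model needed."""
        return float(self.estimate_batch([volume])[0])

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), *self.net.state())
        sidecar = {"config": asdict(self.config), "history": self.history}
        sidecar["config"]["input_shape"] = list(self.config.input_shape)
        sidecar["config"]["channels"] = list(self.config.channels)
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "FillStateEstimator":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg = sidecar["config"]
        cfg["input_shape"] = tuple(cfg["input_shape"])
        cfg["channels"] = tuple(cfg["channels"])
        config = EstimatorConfig(**cfg)
        est = cls(config)
        with np.load(path.with_suffix(".npz")) as z:
            est.net.load_state([z[k] for k in z.files])
        est.history = sidecar.get("history", {})
        return est


def split_train_val(n: int, val_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, seed-reproducible train/validation index split."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 17])
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    return perm[n_val:], perm[:n_val]


def train_estimator(
    volumes, fill_states_pct, config: EstimatorConfig | None = None
) -> FillStateEstimator:
    """Train an estimator on labeled volumes (labels in percentage points).

    Deterministic for a fixed config seed (weight init, split, batch order).
    Records per-epoch train loss and validation MAE in ``history``.
    """
    config = config or EstimatorConfig()
    labels = np.asarray(fill_states_pct, dtype=float)
    if labels.min() < 0 or labels.max() > 100:
        raise ValueError("fill-state labels must lie in [0, 100]")
    if len(volumes) < 50:
        raise ValueError(f"need >= 50 labeled volumes, got {len(volumes)}")

    est = FillStateEstimator(config)
    arrays = [v.values if isinstance(v, VolumeGrid) else np.asarray(v) for v in volumes]
    x = est._prep(arrays)
    y = labels[:, None] / 100.0

    tr, va = split_train_val(len(arrays), config.val_fraction, config.seed)
    opt = Adam(est.net.params, est.net.grads, lr=config.lr)
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 23])

    train_losses, val_maes = [], []
    for epoch in range(config.epochs):
        order = rng.permutation(tr)
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            pred = est.net.forward(x[idx], train=True)
            loss, dpred = mae_loss(pred, y[idx])
            est.net.backward(dpred)
            opt.step()
            epoch_loss += loss * len(idx)
        train_losses.append(epoch_loss / len(order))
        val_pred = est.net.forward(x[va], train=False).ravel()
        val_maes.append(float(np.abs(val_pred * 100.0 - labels[va]).mean()))
    est.history = {
        "train_loss": train_losses,
        "val_mae_pct": val_maes,
        "n_train": int(len(tr)),
        "n_val": int(len(va)),
        "train_idx": tr.tolist(),
        "val_idx": va.tolist(),
    }
    return est


@dataclass
class EvalReport:
    mae_pct: float
    r2: float
    pairs: pd.DataFrame = field(repr=False)

    def to_json(self) -> str:
        return json.dumps({"mae_pct": self.mae_pct, "r2": self.r2, "n": len(self.pairs)})


def evaluate(estimator: FillStateEstimator, volumes, truth_pct, subject_ids=None) -> EvalReport:
    """MAE (percentage points) and r^2 = 1 - SS_res/SS_tot on a test set."""
    truth = np.asarray(truth_pct, dtype=float)
    if len(volumes) == 0:
        raise ValueError("empty test set")
    est = estimator.estimate_batch(volumes)
    mae = float(np.abs(est - truth).mean())
    ss_res = float(((est - truth) ** 2).sum())
    ss_tot = float(((truth - truth.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    ids = subject_ids if subject_ids is not None else list(range(len(truth)))
    pairs = pd.DataFrame({"subject_id": ids, "truth": truth, "estimate": est})
    return EvalReport(mae, r2, pairs)
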
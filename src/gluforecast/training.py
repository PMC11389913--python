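"""Seeded, early-stopped gradient training of any model kind.

Loss is MSE in scaled units for conditioning; predictions are inverted to
mmol/L before any reported error so evaluation happens on the clinical
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, SGD, Tensor
from .dataset import Scaler, SupervisedWindows, invert_scaler, validation_split
from .errors import ContractError, DivergenceError, ParameterError
from .evaluation import ForecastResult
from .models import _ForecasterBase


@dataclass
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 15
    val_frac: float = 0.2
    seed: int = 0
    optimizer: str = "adam"

    def __post_init__(self):
        if self.lr < 0:
            raise ParameterError("lr must be nonnegative")
        if self.max_epochs < 1:
            raise ParameterError("max_epochs must be >= 1")
        if not 0.0 < self.val_frac < 1.0:
            raise ParameterError("val_frac must be in (0, 1)")
        if self.optimizer not in ("adam", "sgd"):
            raise ParameterError("optimizer must be 'adam' or 'sgd'")


@dataclass
class TrainLog:
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_early: bool = False

    @property
    def epochs_run(self) -> int:
        return len(self.train_losses)


def _batch_loss(model: _ForecasterBase, x: np.ndarray, y: np.ndarray) -> Tensor:
    pred = model(Tensor(x))
    diff = pred - Tensor(y)
    return (diff * diff).mean()


def train(
    model: _ForecasterBase,
    windows: SupervisedWindows,
    cfg: TrainConfig,
) -> tuple[_ForecasterBase, TrainLog]:
    """Minimize scaled-unit MSE with early stopping on a chronological
    validation split; restores the best-validation parameters.  Fully
    reproducible given ``cfg.seed`` (shuffling, dropout)."""
    if not windows.scaled:
        raise ContractError("train expects scaled windows; apply a Scaler first")
    if len(windows) < 2:
        raise ParameterError("need at least 2 windows")
    if len(windows) < cfg.batch_size:
        raise ParameterError("fewer windows than batch_size")

    tr, val = validation_split(windows, cfg.val_frac)
    rng = np.random.default_rng(cfg.seed)
    model.train()
    model.set_dropout_rng(rng)

    params = model.parameters()
    opt = Adam(params, lr=cfg.lr) if cfg.optimizer == "adam" else SGD(params, lr=cfg.lr)

    log = TrainLog()
    best_val = np.inf
    best_state = model.state()
    bad_epochs = 0
    n = len(tr)

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            loss = _batch_loss(model, tr.inputs[idx], tr.targets[idx])
            if not np.isfinite(loss.item()):
                raise DivergenceError(epoch)
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item() * len(idx))
        train_loss = float(np.sum(epoch_losses) / n)

        val_pred = model.predict_batch(val.inputs)
        val_loss = float(np.mean((val_pred - val.targets) ** 2))
        if not np.isfinite(val_loss):
            raise DivergenceError(epoch)

        log.train_losses.append(train_loss)
        log.val_losses.append(val_loss)

        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state()
            log.best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                log.stopped_early = True
                break

    model.load_state(best_state)
    model.eval()
    model.set_dropout_rng(None)
    return model, log


def predict(
    model: _ForecasterBase,
    windows: SupervisedWindows,
    scaler: Scaler,
) -> ForecastResult:
    """Evaluation-mode forecasts inverted to mmol/L, aligned by target time."""
    if not windows.scaled:
        raise ContractError("predict expects scaled windows")
    if windows.spec.lookback_steps != model.cfg.lookback:
        raise ParameterError("window lookback does not match model lookback")
    pred_scaled = model.predict_batch(windows.inputs)
    return ForecastResult(
        horizon_min=windows.spec.horizon_min,
        predictions=invert_scaler(pred_scaled, scaler),
        actuals=invert_scaler(windows.targets, scaler),
        target_times=windows.target_times.copy(),
    )
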
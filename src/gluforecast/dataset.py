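"""Sliding-window supervised learning sets with leak-free chronological
splits and reversible z-scaling.

A window of ``L`` consecutive samples predicts the value ``H`` steps after
the window's last sample (direct multi-horizon forecasting: one model per
horizon).  Windows never span regularized-segment boundaries, so signal-loss
gaps cannot leak into an input window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cgm_io import GlucoseSeries
from .errors import (
    ConstantDataError,
    EmptyInputError,
    ParameterError,
)


@dataclass(frozen=True)
class WindowSpec:
    lookback_steps: int = 12
    horizon_steps: int = 3
    interval_min: int = 5

    def __post_init__(self):
        if self.lookback_steps < 1 or self.horizon_steps < 1:
            raise ParameterError("lookback and horizon must be >= 1")
        if self.interval_min < 1:
            raise ParameterError("interval_min must be >= 1")

    @property
    def horizon_min(self) -> int:
        return self.horizon_steps * self.interval_min


@dataclass
class SupervisedWindows:
    inputs: np.ndarray        # (n_windows, L)
    targets: np.ndarray       # (n_windows,)
    target_times: np.ndarray  # (n_windows,) datetime64[s]
    spec: WindowSpec
    scaled: bool = False

    def __post_init__(self):
        self.inputs = np.asarray(self.inputs, dtype=np.float64)
        self.targets = np.asarray(self.targets, dtype=np.float64)
        self.target_times = np.asarray(self.target_times, dtype="datetime64[s]")
        n = len(self.targets)
        if self.inputs.shape != (n, self.spec.lookback_steps):
            raise ParameterError("inputs shape inconsistent with spec")
        if len(self.target_times) != n:
            raise ParameterError("target_times length mismatch")

    def __len__(self) -> int:
        return len(self.targets)


@dataclass(frozen=True)
class Scaler:
    mean: float
    sd: float

    def __post_init__(self):
        if not self.sd > 0:
            raise ConstantDataError("scaler sd must be positive")


def make_windows(
    segments: list[GlucoseSeries] | GlucoseSeries, spec: WindowSpec
) -> SupervisedWindows:
    """Enumerate every (history window, horizon target) pair per segment.

    Each segment of length ``n`` yields ``max(0, n - L - H + 1)`` windows:
    window ``i`` covers steps ``[i, i+L)`` and its target is the value at
    step ``i + L + H - 1``.
    """
    if isinstance(segments, GlucoseSeries):
        segments = [segments]
    L, H = spec.lookback_steps, spec.horizon_steps
    step = np.timedelta64(spec.interval_min * 60, "s")

    inputs, targets, times = [], [], []
    for seg in segments:
        n = len(seg)
        if n < L + H:
            continue
        diffs = np.diff(seg.timestamps)
        if len(diffs) and not np.all(diffs == step):
            raise ParameterError(
                f"segment not regular at {spec.interval_min} min; run regularize() first"
            )
        n_win = n - L - H + 1
        sliding = np.lib.stride_tricks.sliding_window_view(seg.glucose, L)[:n_win]
        inputs.append(sliding.copy())
        targets.append(seg.glucose[L + H - 1:])
        times.append(seg.timestamps[L + H - 1:])
    if not inputs:
        raise EmptyInputError(
            f"no segment long enough for L={L}, H={H} windows"
        )
    return SupervisedWindows(
        inputs=np.concatenate(inputs),
        targets=np.concatenate(targets),
        target_times=np.concatenate(times),
        spec=spec,
        scaled=False,
    )


def chronological_split(
    w: SupervisedWindows, train_frac: float = 0.8
) -> tuple[SupervisedWindows, SupervisedWindows]:
    """Split by target time: earliest ``floor(train_frac * n)`` windows train."""
    if not 0.0 < train_frac < 1.0:
        raise ParameterError("train_frac must be in (0, 1)")
    n = len(w)
    if n < 2:
        raise ParameterError("need at least 2 windows to split")
    n_train = int(np.floor(train_frac * n))
    if n_train == 0 or n_train == n:
        raise ParameterError(
            f"train_frac={train_frac} leaves an empty side for n={n}"
        )
    order = np.argsort(w.target_times, kind="stable")

    def take(idx: np.ndarray) -> SupervisedWindows:
        return SupervisedWindows(
            w.inputs[idx], w.targets[idx], w.target_times[idx], w.spec, w.scaled
        )

    return take(order[:n_train]), take(order[n_train:])


def fit_scaler(train: SupervisedWindows) -> Scaler:
    """Mean/SD over all *training input* entries (targets excluded so the
    scaler never sees a future value)."""
    flat = train.inputs.ravel()
    sd = float(np.std(flat))
    if sd == 0.0:
        raise ConstantDataError("training inputs are constant; cannot scale")
    return Scaler(mean=float(np.mean(flat)), sd=sd)


def apply_scaler(w: SupervisedWindows, s: Scaler) -> SupervisedWindows:
    return SupervisedWindows(
        (w.inputs - s.mean) / s.sd,
        (w.targets - s.mean) / s.sd,
        w.target_times,
        w.spec,
        scaled=True,
    )


def invert_scaler(values: np.ndarray, s: Scaler) -> np.ndarray:
    return np.asarray(values, dtype=np.float64) * s.sd + s.mean


def unscale_windows(w: SupervisedWindows, s: Scaler) -> SupervisedWindows:
    return SupervisedWindows(
        invert_scaler(w.inputs, s),
        invert_scaler(w.targets, s),
        w.target_times,
        w.spec,
        scaled=False,
    )


def validation_split(
    w: SupervisedWindows, val_frac: float
) -> tuple[SupervisedWindows, SupervisedWindows]:
    """Chronologically last ``val_frac`` of windows as validation."""
    return chronological_split(w, 1.0 - val_frac)


def concat_windows(parts: list[SupervisedWindows]) -> SupervisedWindows:
    if not parts:
        raise EmptyInputError("nothing to concatenate")
    spec = parts[0].spec
    scaled = parts[0].scaled
    for p in parts[1:]:
        if p.spec != spec or p.scaled != scaled:
            raise ParameterError("window sets differ in spec or scaling")
    return SupervisedWindows(
        np.concatenate([p.inputs for p in parts]),
        np.concatenate([p.targets for p in parts]),
        np.concatenate([p.target_times for p in parts]),
        spec,
        scaled,
    )
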
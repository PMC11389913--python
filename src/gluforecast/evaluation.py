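"""Forecast evaluation: MSE on the mmol/L scale, the six-model x
three-horizon comparison protocol, residual normality diagnostics, and the
persistence sanity baseline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cgm_io import GlucoseSeries, regularize
from .dataset import (
    SupervisedWindows,
    WindowSpec,
    apply_scaler,
    chronological_split,
    concat_windows,
    fit_scaler,
)
from .errors import (
    ConstantDataError,
    ContractError,
    InsufficientDataError,
    ParameterError,
)


@dataclass
class ForecastResult:
    """Paired forecasts y_hat(t | t - PH) and truths y(t) at one horizon."""

    horizon_min: int
    predictions: np.ndarray
    actuals: np.ndarray
    target_times: np.ndarray

    def __post_init__(self):
        self.predictions = np.asarray(self.predictions, dtype=np.float64)
        self.actuals = np.asarray(self.actuals, dtype=np.float64)
        if len(self.predictions) != len(self.actuals):
            raise ParameterError("predictions and actuals must align")
        if len(self.predictions) == 0:
            raise ParameterError("empty forecast result")

    def __len__(self) -> int:
        return len(self.predictions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target_time": np.datetime_as_string(
                    np.asarray(self.target_times, dtype="datetime64[s]"), unit="s"
                ),
                "actual_mmol_l": self.actuals,
                "predicted_mmol_l": self.predictions,
            }
        )


def mse(result: ForecastResult) -> float:
    """Mean squared error (1/N) * sum (y_hat - y)^2, in (mmol/L)^2."""
    d = result.predictions - result.actuals
    return float(np.mean(d * d))


def persistence_forecast(windows: SupervisedWindows) -> ForecastResult:
    """Naive baseline: repeat the last observed value of each window."""
    if windows.scaled:
        raise ContractError("persistence baseline expects unscaled windows")
    return ForecastResult(
        horizon_min=windows.spec.horizon_min,
        predictions=windows.inputs[:, -1].copy(),
        actuals=windows.targets.copy(),
        target_times=windows.target_times.copy(),
    )


@dataclass
class QQReport:
    theoretical_quantiles: np.ndarray
    sample_quantiles: np.ndarray
    r: float
    n: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": self.n,
                "r": self.r,
                "theoretical_quantiles": list(self.theoretical_quantiles),
                "sample_quantiles": list(self.sample_quantiles),
            }
        )


def qq_normality(result: ForecastResult) -> QQReport:
    """Standardized residual order statistics against standard normal
    quantiles at Hazen probability points (i - 0.5) / N."""
    e = result.predictions - result.actuals
    n = len(e)
    if n < 3:
        raise InsufficientDataError("need at least 3 residuals for a Q-Q report")
    sd = np.std(e, ddof=1)
    if sd == 0:
        raise ConstantDataError("zero-variance residuals")
    z = np.sort((e - np.mean(e)) / sd)
    probs = (np.arange(1, n + 1) - 0.5) / n
    theo = stats.norm.ppf(probs)
    r = float(np.corrcoef(theo, z)[0, 1])
    return QQReport(theoretical_quantiles=theo, sample_quantiles=z, r=r, n=n)


@dataclass
class ComparisonTable:
    """Test MSE per (model kind, horizon), in (mmol/L)^2."""

    kinds: list[str]
    horizons_min: list[int]
    values: np.ndarray  # (n_kinds, n_horizons); NaN marks a failed cell
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.kinds), len(self.horizons_min)):
            raise ParameterError("values grid inconsistent with labels")

    @property
    def n_failed(self) -> int:
        return int(np.isnan(self.values).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.kinds, name="model"),
            columns=[f"mse_{h}min" for h in self.horizons_min],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ComparisonTable":
        df = pd.read_csv(path, index_col=0)
        horizons = [int(c.removeprefix("mse_").removesuffix("min")) for c in df.columns]
        return cls(list(df.index), horizons, df.to_numpy())

    def to_json(self) -> str:
        return json.dumps(
            {
                "kinds": self.kinds,
                "horizons_min": self.horizons_min,
                "values": [
                    [None if np.isnan(v) else v for v in row] for row in self.values
                ],
                "metadata": self.metadata,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ComparisonTable":
        raw = json.loads(text)
        values = np.array(
            [[np.nan if v is None else v for v in row] for row in raw["values"]]
        )
        return cls(raw["kinds"], raw["horizons_min"], values, raw.get("metadata", {}))


def _config_digest(*objs) -> str:
    return hashlib.sha256(repr(objs).encode()).hexdigest()[:12]


def prepare_splits(
    cohort: list[GlucoseSeries],
    spec: WindowSpec,
    train_frac: float = 0.8,
    max_gap_min: int = 15,
):
    """Regularize each patient, window, split chronologically *per patient*,
    pool, and scale with a train-only scaler.  Returns
    (train_scaled, test_scaled, test_unscaled, scaler)."""
    trains, tests = [], []
    for series in cohort:
        segments = regularize(series, spec.interval_min, max_gap_min)
        w = make_windows_safe(segments, spec)
        if w is None or len(w) < 2:
            continue
        tr, te = chronological_split(w, train_frac)
        trains.append(tr)
        tests.append(te)
    if not trains:
        raise ParameterError("no patient produced enough windows")
    train = concat_windows(trains)
    test = concat_windows(tests)
    scaler = fit_scaler(train)
    return apply_scaler(train, scaler), apply_scaler(test, scaler), test, scaler


def make_windows_safe(segments, spec: WindowSpec):
    from .dataset import make_windows
    from .errors import EmptyInputError

    try:
        return make_windows(segments, spec)
    except EmptyInputError:
        return None


def evaluate_horizons(
    cohort: list[GlucoseSeries],
    kinds: list[str],
    horizons_min: list[int] = [15, 30, 45],
    model_cfg=None,
    train_cfg=None,
    interval_min: int = 5,
    lookback_steps: int = 12,
    train_frac: float = 0.8,
    seed: int = 0,
) -> ComparisonTable:
    """Train and score every (kind, horizon) cell.

    A cell whose training diverges is recorded as NaN and the run
    continues; callers (e.g. the CLI) translate NaN cells into a nonzero
    exit status.
    """
    from dataclasses import replace

    from .errors import DivergenceError
    from .models import HybridConfig, build_model
    from .training import TrainConfig, predict, train as train_model

    model_cfg = model_cfg or HybridConfig(lookback=lookback_steps)
    train_cfg = train_cfg or TrainConfig(seed=seed)
    values = np.full((len(kinds), len(horizons_min)), np.nan)
    meta: dict = {
        "seed": seed,
        "config_digest": _config_digest(model_cfg, train_cfg, horizons_min, kinds),
        "cells": {},
    }
    forecasts: dict[tuple[str, int], ForecastResult] = {}

    for j, horizon in enumerate(horizons_min):
        if horizon % interval_min != 0:
            raise ParameterError(
                f"horizon {horizon} not divisible by interval {interval_min}"
            )
        spec = WindowSpec(lookback_steps, horizon // interval_min, interval_min)
        train_s, test_s, _, scaler = prepare_splits(cohort, spec, train_frac)
        for i, kind in enumerate(kinds):
            cfg_k = replace(model_cfg, lookback=lookback_steps)
            model = build_model(kind, cfg_k, seed=seed)
            cell = f"{kind}@{horizon}min"
            try:
                model, log = train_model(model, train_s, replace(train_cfg, seed=seed))
                result = predict(model, test_s, scaler)
                values[i, j] = mse(result)
                forecasts[(kind, horizon)] = result
                meta["cells"][cell] = {
                    "epochs": log.epochs_run,
                    "best_epoch": log.best_epoch,
                }
            except DivergenceError as exc:
                meta["cells"][cell] = {"failed": str(exc)}

    table = ComparisonTable(list(kinds), list(horizons_min), values, meta)
    table.forecasts = forecasts  # per-cell results for artifact dumping
    return table
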
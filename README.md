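# gluforecast

Forecasting of continuous glucose monitoring (CGM) traces with a hybrid
Transformer-LSTM model, compared against five recurrent baselines (RNN,
GRU, LSTM, stacked LSTM, bidirectional LSTM) at 15/30/45-minute horizons.

The package covers the full pipeline:

- **`cgm_io`** — read/write CGM traces in a canonical CSV dialect
  (`patient_id,timestamp,glucose_mmol_l,calibration_bg_mmol_l`), snap them
  to an exact 5-minute grid (short gaps interpolated, long signal-loss
  gaps split into segments), and summarize them.
- **`synthetic_cgm`** — a seeded cohort generator (baseline + circadian
  sinusoid + meal-excursion kernels + AR(1) noise, clamped to 2.2–22.2
  mmol/L) whose packaged defaults are calibrated to pooled moments of
  ~8.32 mmol/L mean and ~3.51 mmol/L SD over 8 patients × 14 days
  (>32,000 samples), so every downstream stage is testable without
  clinical data.
- **`dataset`** — sliding-window supervised sets (lookback `L` steps →
  target `H` steps ahead), leak-free chronological train/test splits, and
  reversible z-scaling fit on training inputs only.
- **`models`** — the hybrid forecaster (linear embedding → sinusoidal
  positional encoding → post-norm transformer encoder → parallel pooled
  encoder output and LSTM final state → concatenation → linear head) plus
  the five baselines, all built on a small numpy reverse-mode autodiff
  engine (`autodiff`) since no deep-learning framework is assumed.
  Functional numpy primitives (`lstm_cell_step`, `lstm_forward`,
  `positional_encoding`) double as oracles for the trainable layers.
- **`training`** — seeded Adam/SGD training with chronological validation
  split, early stopping, and best-epoch restoration; losses in scaled
  units, all reported errors in mmol/L.
- **`evaluation`** — MSE, the 6-model × 3-horizon comparison grid,
  persistence (last-value) baseline, and residual normal Q-Q diagnostics.
- **`hyperopt`** — genetic hyperparameter search (tournament selection,
  uniform crossover, resampling mutation, elitism) with validation-MSE
  fitness; elitism makes the best-so-far fitness curve nonincreasing.

## CLI

```sh
gluforecast simulate --patients 8 --days 14 --seed 1 --out out/sim
gluforecast train    --kind transformer_lstm --horizon 15 --seed 1 --out out/train
gluforecast compare  --patients 2 --days 4 --horizons 15,30,45 --out out/cmp
gluforecast optimize --pop-size 6 --iterations 5 --out out/opt
```

Each command accepts `--config <yaml>` (generator settings) and `--seed`;
reruns with the same seed are byte-identical. `compare` writes
`comparison_table.csv`/`.json`, per-cell `forecast_<kind>_<H>min.csv`
files (`target_time,actual_mmol_l,predicted_mmol_l`), and
`qq_report.json`; add `--plot` for PNG figures.

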
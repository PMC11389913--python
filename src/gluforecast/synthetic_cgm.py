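"""Synthetic CGM cohort generator.

Signal model per patient: baseline + 24-h circadian sinusoid + meal
excursion kernels + stationary AR(1) noise, clamped to a physiological
range.  The packaged default configuration is calibrated so the pooled
cohort moments match the study-data descriptive statistics
(mean ~= 8.32 mmol/L, SD ~= 3.51 mmol/L over 8 patients x 14 days).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .cgm_io import GlucoseSeries
from .errors import ParameterError

DEFAULT_START = np.datetime64("2022-03-01T00:00:00", "s")


@dataclass
class PatientProfile:
    basal_mmol_l: float
    circadian_amp_mmol_l: float
    meal_times_h: list[float]
    meal_amp_mmol_l: list[float]
    meal_rise_min: float
    meal_decay_min: float
    ar_coef: float
    noise_sd_mmol_l: float
    seed: int

    def __post_init__(self):
        if self.basal_mmol_l <= 0:
            raise ParameterError("basal must be positive")
        if not 0.0 <= self.ar_coef < 1.0:
            raise ParameterError("ar_coef must be in [0, 1)")
        if self.noise_sd_mmol_l < 0:
            raise ParameterError("noise_sd must be nonnegative")
        if len(self.meal_times_h) != len(self.meal_amp_mmol_l):
            raise ParameterError("meal time and amplitude lists must match")


@dataclass
class ProfileSampler:
    """Uniform ranges from which per-patient profiles are drawn."""

    # defaults frozen after a coarse numeric calibration of the default
    # 8-patient x 14-day cohort against pooled mean 8.32 / SD 3.51 mmol/L
    basal_range: tuple[float, float] = (3.57, 7.97)
    circadian_amp_range: tuple[float, float] = (0.6, 1.4)
    meal_times_h: tuple[float, ...] = (7.5, 12.5, 18.5)
    meal_time_jitter_h: float = 0.75
    meal_amp_range: tuple[float, float] = (4.5, 9.5)
    meal_rise_range: tuple[float, float] = (35.0, 55.0)
    meal_decay_range: tuple[float, float] = (60.0, 110.0)
    ar_range: tuple[float, float] = (0.88, 0.95)
    noise_sd_range: tuple[float, float] = (0.45, 0.70)

    def sample(
        self,
        rng: np.random.Generator,
        seed: int,
        basal_u: float | None = None,
        meal_u: float | None = None,
        decay_u: float | None = None,
    ) -> PatientProfile:
        """Draw one profile.  ``basal_u``/``meal_u`` in [0,1] pin the draw to
        a quantile of its range — the cohort generator stratifies these
        across patients so pooled moments are stable across master seeds
        while between-patient variability is preserved."""

        def draw(lo_hi: tuple[float, float], u: float | None) -> float:
            lo, hi = lo_hi
            if u is None:
                return float(rng.uniform(lo, hi))
            return float(lo + (hi - lo) * u)

        times = [
            float(t + rng.uniform(-self.meal_time_jitter_h, self.meal_time_jitter_h))
            for t in self.meal_times_h
        ]
        amps = []
        for _ in times:
            u = (
                None
                if meal_u is None
                else float(np.clip(meal_u + rng.uniform(-0.12, 0.12), 0.0, 1.0))
            )
            amps.append(draw(self.meal_amp_range, u))
        return PatientProfile(
            basal_mmol_l=draw(self.basal_range, basal_u),
            circadian_amp_mmol_l=float(rng.uniform(*self.circadian_amp_range)),
            meal_times_h=times,
            meal_amp_mmol_l=amps,
            meal_rise_min=float(rng.uniform(*self.meal_rise_range)),
            meal_decay_min=draw(self.meal_decay_range, decay_u),
            ar_coef=float(rng.uniform(*self.ar_range)),
            noise_sd_mmol_l=float(rng.uniform(*self.noise_sd_range)),
            seed=seed,
        )


@dataclass
class GeneratorConfig:
    n_patients: int = 8
    days_per_patient: int = 14
    interval_min: int = 5
    clamp_mmol_l: tuple[float, float] = (2.2, 22.2)
    calibration_rate_per_day: float = 1.1
    gap_rate_per_day: float = 0.5
    gap_len_min: tuple[float, float] = (20.0, 90.0)
    profile_sampler: ProfileSampler = field(default_factory=ProfileSampler)

    def __post_init__(self):
        lo, hi = self.clamp_mmol_l
        if lo >= hi:
            raise ParameterError("clamp low must be < high")
        if self.calibration_rate_per_day < 0 or self.gap_rate_per_day < 0:
            raise ParameterError("rates must be nonnegative")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "GeneratorConfig":
        raw = yaml.safe_load(text)
        sampler_raw = raw.pop("profile_sampler", {})
        sampler = ProfileSampler(
            **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in sampler_raw.items()
            }
        )
        for key in ("clamp_mmol_l", "gap_len_min"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(profile_sampler=sampler, **raw)


def meal_kernel(
    t_since_meal_min, amp: float, rise_min: float, decay_min: float
):
    """Gamma-shaped meal excursion: zero at t=0, peak ``amp`` at t=rise,
    then an exponential tail with asymptotic time constant ``decay_min``.

    For t <= rise the shape is amp*(t/rise)*exp(1 - t/rise); beyond the
    peak the same curve is raised to the power rise/decay, which stretches
    (or compresses) the tail to the requested decay constant while keeping
    the function C1-continuous at the peak.
    """
    if rise_min <= 0 or decay_min <= 0:
        raise ParameterError("rise and decay constants must be positive")
    t = np.asarray(t_since_meal_min, dtype=np.float64)
    if np.any(t < 0):
        raise ParameterError("time since meal must be nonnegative")
    x = t / rise_min
    base = x * np.exp(1.0 - x)
    out = np.where(t <= rise_min, base, base ** (rise_min / decay_min))
    result = amp * out
    return float(result) if np.isscalar(t_since_meal_min) else result


def simulate_patient(
    profile: PatientProfile,
    days: int,
    interval_min: int = 5,
    seed: int | None = None,
    clamp: tuple[float, float] = (2.2, 22.2),
    start: np.datetime64 = DEFAULT_START,
) -> GlucoseSeries:
    """Simulate one patient's regular CGM trace.

    Length is exactly ``days * 1440 / interval_min`` samples; identical
    seeds give bit-identical output.
    """
    if days < 1:
        raise ParameterError("days must be >= 1")
    if interval_min <= 0 or 1440 % interval_min != 0:
        raise ParameterError("interval_min must divide 1440")
    rng = np.random.default_rng(profile.seed if seed is None else seed)

    per_day = 1440 // interval_min
    n = days * per_day
    minutes = np.arange(n, dtype=np.float64) * interval_min
    hours = minutes / 60.0

    # circadian: trough at ~03:00, peak at ~15:00
    circadian = profile.circadian_amp_mmol_l * np.sin(
        2.0 * np.pi * (hours - 9.0) / 24.0
    )

    meals = np.zeros(n)
    horizon_min = 8 * 60.0  # kernel support considered per meal
    for day in range(days):
        for meal_h, amp in zip(profile.meal_times_h, profile.meal_amp_mmol_l):
            t_meal = day * 1440.0 + meal_h * 60.0
            # mild day-to-day variation in timing and size
            t_meal += rng.uniform(-15.0, 15.0)
            amp_day = amp * rng.uniform(0.85, 1.15)
            lo = int(np.ceil(max(t_meal, 0.0) / interval_min))
            hi = int(min(np.floor((t_meal + horizon_min) / interval_min), n - 1))
            if lo > hi:
                continue
            dt = minutes[lo : hi + 1] - t_meal
            meals[lo : hi + 1] += meal_kernel(
                dt, amp_day, profile.meal_rise_min, profile.meal_decay_min
            )

    noise = np.zeros(n)
    if profile.noise_sd_mmol_l > 0:
        stationary_sd = profile.noise_sd_mmol_l / np.sqrt(1.0 - profile.ar_coef**2)
        noise[0] = rng.normal(0.0, stationary_sd)
        eps = rng.normal(0.0, profile.noise_sd_mmol_l, size=n)
        for k in range(1, n):
            noise[k] = profile.ar_coef * noise[k - 1] + eps[k]

    values = np.clip(
        profile.basal_mmol_l + circadian + meals + noise, clamp[0], clamp[1]
    )
    step = np.timedelta64(interval_min * 60, "s")
    timestamps = start + np.arange(n) * step
    return GlucoseSeries(f"P{profile.seed:03d}", timestamps, values)


def simulate_cohort(
    config: GeneratorConfig, seed: int = 0
) -> list[GlucoseSeries]:
    """Generate a cohort; per-patient seeds derive from the master seed.

    Signal-loss gaps are realized by *deleting* samples so that downstream
    regularization exercises its splitting path; calibration entries are
    sparse non-NaN values in the calibration column.
    """
    master = np.random.SeedSequence(seed)
    *children, cohort_child = master.spawn(config.n_patients + 1)
    cohort_rng = np.random.default_rng(cohort_child)
    n_pat = config.n_patients
    # stratified quantiles: independent permutations for the draws that
    # dominate the pooled mean (basal level, meal size, meal decay), so the
    # cohort mean is stable across master seeds
    def strata() -> np.ndarray:
        return (
            cohort_rng.permutation(n_pat) + cohort_rng.uniform(0.4, 0.6, n_pat)
        ) / n_pat

    basal_strata, meal_strata, decay_strata = strata(), strata(), strata()
    cohort: list[GlucoseSeries] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        profile = config.profile_sampler.sample(
            rng,
            seed=i + 1,
            basal_u=basal_strata[i],
            meal_u=meal_strata[i],
            decay_u=decay_strata[i],
        )
        series = simulate_patient(
            profile,
            config.days_per_patient,
            config.interval_min,
            seed=int(rng.integers(2**31)),
            clamp=config.clamp_mmol_l,
            start=DEFAULT_START + np.timedelta64(i, "D").astype("timedelta64[s]"),
        )
        n = len(series)
        ts, glucose = series.timestamps, series.glucose
        cal = np.full(n, np.nan)

        n_cal = rng.poisson(config.calibration_rate_per_day * config.days_per_patient)
        if n_cal > 0:
            idx = rng.choice(n, size=min(n_cal, n), replace=False)
            cal[idx] = np.clip(
                glucose[idx] + rng.normal(0.0, 0.35, size=len(idx)), 1.0, None
            )

        keep = np.ones(n, dtype=bool)
        n_gaps = rng.poisson(config.gap_rate_per_day * config.days_per_patient)
        for _ in range(n_gaps):
            gap_len = rng.uniform(*config.gap_len_min)
            width = max(int(round(gap_len / config.interval_min)), 1)
            start_idx = int(rng.integers(0, max(n - width, 1)))
            keep[start_idx : start_idx + width] = False

        cohort.append(
            GlucoseSeries(f"P{i + 1:03d}", ts[keep], glucose[keep], cal[keep])
        )
    return cohort


def default_cohort_config() -> GeneratorConfig:
    """Packaged configuration calibrated to the study cohort's pooled
    moments (mean ~8.32 mmol/L, SD ~3.51 mmol/L, clamp 2.2-22.2)."""
    return GeneratorConfig()
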
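"""Synthetic EMA studies with a known generative model.

The generator emulates the qualitative features of wrist-accelerometer epoch
counts — nonnegative, positively skewed (gamma marginal), with a sinusoidal
diurnal profile and occasional multiplicative bursts — together with an EMA
prompt schedule (jittered anchors through waking hours, independent prompt
missingness) and affect scores drawn from the univariate random-intercept
model used by the window scan:

    affect_tj = γ00 + γ10 (X_tj − X̄_j) + ζ0j + ε_tj,

where X_tj is the configured local statistic of activity in a *planted*
window around each prompt.  Because the truth (parameters, random effects,
noise draws) is recorded, every downstream estimate can be checked against
it.

All randomness flows from a single seed through spawned per-subject
generators, so subject j's data do not depend on how many subjects follow.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import EmaObservation, EpochSeries
from .local_stats import LocalStatConfig, WindowSpec, compute_local_stat

__all__ = [
    "SyntheticConfig",
    "SyntheticStudy",
    "simulate_activity",
    "simulate_ema_schedule",
    "simulate_affect",
    "simulate_study",
]


@dataclass
class SyntheticConfig:
    """The stated world of a simulated study.

    Defaults mirror a small intensive-sampling cohort: 9 subjects wearing the
    device for a week of 1-min epochs, 6 prompts/day through waking hours
    (08:00–22:00) with ±30 min jitter and 20% prompt missingness.  Activity is
    gamma with shape < 1 (right-skewed, occasional zero epochs after
    rounding), a 50% diurnal modulation peaking at 14:00, and ~0.5 bursts/h
    of 5× activity lasting 5 min.  Affect (e.g. a 0–6 depressive-mood rating)
    responds to the centered 60-min local mean of activity ending at the
    prompt's −60 min mark with slope −0.5.
    """

    seed: int
    n_subjects: int = 9
    n_days: int = 7
    epoch_length: float = 1.0
    start_date: str = "2024-01-01"
    # EMA schedule
    prompts_per_day: int = 6
    prompt_jitter: float = 30.0
    missing_prompt_prob: float = 0.2
    waking_start_minute: float = 480.0   # 08:00
    waking_end_minute: float = 1320.0    # 22:00
    # activity model
    gamma_shape: float = 0.8
    base_scale: float = 200.0
    diurnal_amplitude: float = 0.5
    diurnal_peak_minute: float = 840.0   # 14:00
    burst_rate_per_hour: float = 0.5
    burst_magnitude: float = 5.0
    burst_duration: float = 5.0
    # generative affect model
    gamma00: float = 3.0
    gamma10: float = -0.5
    var_zeta0: float = 0.25
    var_zeta1: float = 0.0
    var_eps: float = 0.5
    center_predictor: bool = True
    # planted window
    planted_location: float = -60.0
    planted_size: float = 60.0
    planted_statistic: str = "mean"
    planted_detrend_order: Optional[int] = None
    min_coverage: float = 0.8

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        for name in ("var_zeta0", "var_zeta1", "var_eps"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0 <= self.missing_prompt_prob <= 1):
            raise ValidationError("missing_prompt_prob must be in [0, 1]")
        if self.gamma_shape <= 0 or self.base_scale <= 0:
            raise ValidationError("gamma shape and scale must be positive")
        if not (0 <= self.diurnal_amplitude < 1):
            raise ValidationError("diurnal_amplitude must be in [0, 1)")
        if self.burst_rate_per_hour < 0 or self.burst_magnitude < 1:
            raise ValidationError("burst rate must be >= 0 and magnitude >= 1")

    @property
    def planted_window(self) -> WindowSpec:
        return WindowSpec(location=self.planted_location, size=self.planted_size)

    @property
    def planted_config(self) -> LocalStatConfig:
        return LocalStatConfig(
            statistic=self.planted_statistic,
            detrend_order=self.planted_detrend_order,
            min_coverage=self.min_coverage,
        )


@dataclass
class SyntheticStudy:
    """A complete simulated study plus its generating truth."""

    activity: dict[str, EpochSeries]
    ema: list[EmaObservation]
    truth: dict
    config: SyntheticConfig = None

    def to_csv(self, outdir) -> None:
        """Write activity.csv, ema.csv and truth.json under ``outdir``."""
        os.makedirs(outdir, exist_ok=True)
        rows = []
        for sid, series in self.activity.items():
            times = series.start_time + pd.to_timedelta(
                np.arange(len(series)) * series.epoch_length, unit="m"
            )
            rows.append(
                pd.DataFrame(
                    {
                        "subject": sid,
                        "timestamp": times,
                        "counts": series.counts,
                        "wear": series.wear.astype(int),
                    }
                )
            )
        act = pd.concat(rows, ignore_index=True).dropna(subset=["counts"])
        act.to_csv(os.path.join(outdir, "activity.csv"), index=False)

        pd.DataFrame(
            {
                "subject": [o.subject_id for o in self.ema],
                "day": [o.day_index for o in self.ema],
                "timestamp": [o.prompt_time for o in self.ema],
                "affect": [o.affect for o in self.ema],
            }
        ).to_csv(os.path.join(outdir, "ema.csv"), index=False)

        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(self.truth, fh, indent=2, default=float)


def _subject_ids(n: int) -> list[str]:
    return [f"S{j + 1:03d}" for j in range(n)]


def _stream_rngs(config: SyntheticConfig):
    """Per-subject generator triples (activity, schedule, affect).

    One spawned child per subject, split again per stream, so any stream for
    subject j is reproducible regardless of subject count or of which other
    streams were consumed.
    """
    ids = _subject_ids(config.n_subjects)
    children = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    act, sch, aff = {}, {}, {}
    for sid, child in zip(ids, children):
        a, s, f = child.spawn(3)
        act[sid] = np.random.default_rng(a)
        sch[sid] = np.random.default_rng(s)
        aff[sid] = np.random.default_rng(f)
    return act, sch, aff


def _simulate_one_activity(
    config: SyntheticConfig, rng: np.random.Generator, subject_id: str
) -> EpochSeries:
    n = int(round(config.n_days * 1440 / config.epoch_length))
    tod = (np.arange(n) * config.epoch_length) % 1440.0
    scale = config.base_scale * (
        1.0
        + config.diurnal_amplitude
        * np.cos(2 * np.pi * (tod - config.diurnal_peak_minute) / 1440.0)
    )
    mult = np.ones(n)
    if config.burst_rate_per_hour > 0:
        total_hours = n * config.epoch_length / 60.0
        n_bursts = rng.poisson(config.burst_rate_per_hour * total_hours)
        starts = rng.integers(0, n, size=n_bursts)
        width = max(1, int(round(config.burst_duration / config.epoch_length)))
        for s in starts:
            mult[s : s + width] = config.burst_magnitude
    counts = np.round(rng.gamma(config.gamma_shape, scale * mult))
    return EpochSeries(
        subject_id=subject_id,
        start_time=pd.Timestamp(config.start_date),
        epoch_length=config.epoch_length,
        counts=counts,
        wear=np.ones(n, dtype=bool),
    )


def simulate_activity(config: SyntheticConfig) -> dict[str, EpochSeries]:
    """Gamma epoch counts with diurnal modulation and multiplicative bursts."""
    act_rngs, _, _ = _stream_rngs(config)
    return {
        sid: _simulate_one_activity(config, act_rngs[sid], sid)
        for sid in _subject_ids(config.n_subjects)
    }


def _schedule_one(
    config: SyntheticConfig, rng: np.random.Generator
) -> list[list[pd.Timestamp]]:
    k = config.prompts_per_day
    if k < 1:
        raise ValidationError("prompts_per_day must be >= 1")
    span = config.waking_end_minute - config.waking_start_minute
    spacing = span / k
    if 2 * config.prompt_jitter > spacing:
        raise ValidationError(
            f"prompt_jitter {config.prompt_jitter} can reorder anchors spaced {spacing:g} min"
        )
    anchors = config.waking_start_minute + (np.arange(k) + 0.5) * spacing
    start = pd.Timestamp(config.start_date)
    days = []
    for d in range(config.n_days):
        jit = rng.uniform(-config.prompt_jitter, config.prompt_jitter, size=k)
        keep = rng.uniform(size=k) >= config.missing_prompt_prob
        minutes = np.floor(anchors + jit)[keep]
        minutes = np.unique(minutes)  # guard against floor collisions
        days.append(
            [start + pd.Timedelta(days=d, minutes=float(m)) for m in minutes]
        )
    return days


def simulate_ema_schedule(config: SyntheticConfig) -> dict[str, list[list[pd.Timestamp]]]:
    """Jittered, thinned prompt times per subject, grouped by day (1-based order)."""
    _, sch_rngs, _ = _stream_rngs(config)
    out = {
        sid: _schedule_one(config, sch_rngs[sid])
        for sid in _subject_ids(config.n_subjects)
    }
    if all(not any(days) for days in out.values()):
        warnings.warn("all prompts dropped (missing_prompt_prob too high?)")
    return out


def simulate_affect(
    activity: dict[str, EpochSeries],
    schedule: dict[str, list[list[pd.Timestamp]]],
    config: SyntheticConfig,
    rngs: Optional[dict[str, np.random.Generator]] = None,
) -> tuple[list[EmaObservation], dict]:
    """Affect scores from the planted-window random-intercept model.

    Prompts whose planted window fails the coverage rule are dropped (they
    would carry no defined predictor).  Returns the observations and a truth
    record holding every parameter and random draw.
    """
    if rngs is None:
        _, _, rngs = _stream_rngs(config)
    spec = config.planted_window
    stat_config = config.planted_config

    ema: list[EmaObservation] = []
    truth: dict = {
        "gamma00": config.gamma00,
        "gamma10": config.gamma10,
        "var_zeta0": config.var_zeta0,
        "var_zeta1": config.var_zeta1,
        "var_eps": config.var_eps,
        "planted_location": config.planted_location,
        "planted_size": config.planted_size,
        "planted_statistic": config.planted_statistic,
        "seed": config.seed,
        "zeta0": {},
        "zeta1": {},
        "observations": [],
    }
    n_usable = 0
    for sid, series in activity.items():
        rng = rngs[sid]
        zeta0 = rng.normal(0.0, np.sqrt(config.var_zeta0))
        zeta1 = rng.normal(0.0, np.sqrt(config.var_zeta1)) if config.var_zeta1 > 0 else 0.0
        truth["zeta0"][sid] = zeta0
        truth["zeta1"][sid] = zeta1

        prompts, xs, days = [], [], []
        for d, day_prompts in enumerate(schedule.get(sid, []), start=1):
            for t in day_prompts:
                obs = EmaObservation(
                    subject_id=sid, day_index=d, prompt_time=t, affect=0.0
                )
                v = compute_local_stat(series, obs, spec, stat_config)
                if v.is_missing:
                    continue
                prompts.append(t)
                xs.append(v.value)
                days.append(d)
        if not prompts:
            continue
        x = np.asarray(xs)
        xc = x - x.mean() if config.center_predictor else x
        eps = rng.normal(0.0, np.sqrt(config.var_eps), size=len(x))
        affect = (
            config.gamma00 + (config.gamma10 + zeta1) * xc + zeta0 + eps
        )
        n_usable += len(x)
        for t, d, xi, xci, ei, yi in zip(prompts, days, x, xc, eps, affect):
            ema.append(
                EmaObservation(
                    subject_id=sid, day_index=d, prompt_time=t, affect=float(yi)
                )
            )
            truth["observations"].append(
                {
                    "subject": sid,
                    "prompt_time": str(t),
                    "day": d,
                    "x": float(xi),
                    "x_centered": float(xci),
                    "eps": float(ei),
                    "affect": float(yi),
                }
            )
    if n_usable == 0:
        raise ValidationError("no prompt has a computable planted-window statistic")
    ema.sort(key=lambda o: (o.subject_id, o.prompt_time))
    return ema, truth


def simulate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Compose activity, schedule and affect generation under one seed."""
    ids = _subject_ids(config.n_subjects)
    act_rngs, sch_rngs, aff_rngs = _stream_rngs(config)
    activity = {
        sid: _simulate_one_activity(config, act_rngs[sid], sid) for sid in ids
    }
    schedule = {sid: _schedule_one(config, sch_rngs[sid]) for sid in ids}
    ema, truth = simulate_affect(activity, schedule, config, rngs=aff_rngs)
    return SyntheticStudy(activity=activity, ema=ema, truth=truth, config=config)
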
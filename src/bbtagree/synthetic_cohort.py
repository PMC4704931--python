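"""Synthetic biphasic-cycle and wearable-stream generator.

Produces daily oral basal-body-temperature (BBT) series and minute-level
overnight armband skin-temperature streams with the statistical structure the
device-comparison analysis assumes, together with ground truth (ovulatory
status, ovulation day).

The cycle model is a two-plateau step function: a follicular baseline, an
optional single-day nadir, then a sustained post-ovulatory shift of
0.2-0.5 degC lasting the luteal phase (>= 11 days for ovulatory cycles, so
that cycles satisfy the visual criteria by construction).  Anovulatory
(including oral-contraceptive "control") cycles are flat.  Fever days add a
fixed offset and carry an illness flag; missing days are marked missing, not
imputed.

The armband model is an affine transform of the day's true temperature: at
the reference temperature (36.4 degC, the oral grand mean) the armband reads
``bias_at_reference`` lower (-1.78 by default, set jointly with the range
clipping so the post-clip cohort mean difference is ~1.8), and the
oral-minus-armband
difference grows at lower temperatures (``prop_bias_slope`` < 0).  On top of
this sit a per-night environmental level shift (``night_effect_sd``, the
dominant source of the armband's ~1.2 degC spread), per-minute sensor noise,
a warm-up ramp over the first ``stabilization_minutes`` of wear, and hard
clipping to the sensor's recordable range (29.7-36.7 degC by default).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .temperature_io import (
    CycleSeries,
    MinuteStream,
    write_daily_csv,
    write_minute_csv,
)

#: device skin-temperature quantisation, degC
TEMP_RESOLUTION = 0.01

DEFAULT_WAKE_HOUR = 7.0  # nominal wake time, local clock hours


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class CycleParams:
    """Parameters of one simulated menstrual cycle.

    ``ovulation_day`` (the nadir day; the sustained rise starts the day
    after) is derived as ``cycle_length - luteal_length`` for ovulatory
    cycles and is absent for anovulatory ones.
    """

    cycle_length: int = 28
    ovulatory: bool = True
    luteal_length: int = 14
    follicular_mean: float = 36.29
    shift_magnitude: float = 0.35
    nadir_depth: float = 0.2
    daily_noise_sd: float = 0.2
    missing_prob: float = 0.05
    fever_days: frozenset = frozenset()
    fever_delta: float = 0.8

    def __post_init__(self) -> None:
        if self.cycle_length < 1:
            raise ValueError("cycle_length must be positive")
        if self.ovulatory and self.luteal_length >= self.cycle_length:
            raise ValueError("luteal_length must be < cycle_length")
        if self.ovulatory and self.luteal_length < 1:
            raise ValueError("luteal_length must be >= 1 for ovulatory cycles")
        if self.daily_noise_sd < 0:
            raise ValueError("daily_noise_sd must be >= 0")
        if not 0 <= self.missing_prob < 1:
            raise ValueError("missing_prob must be in [0, 1)")
        if self.nadir_depth < 0 or self.fever_delta < 0:
            raise ValueError("nadir_depth and fever_delta must be >= 0")
        if any(not 1 <= d <= self.cycle_length for d in self.fever_days):
            raise ValueError("fever_days must be valid cycle days")

    @property
    def ovulation_day(self) -> int | None:
        if not self.ovulatory:
            return None
        return self.cycle_length - self.luteal_length


@dataclass(frozen=True)
class DeviceModel:
    """Affine + noise model of the armband skin-temperature sensor.

    ``prop_bias_slope`` is the change of the (oral - armband) difference per
    degC of underlying temperature; a negative value makes the negative bias
    larger at lower temperatures.  ``night_effect_sd`` is the SD of a
    per-night level shift capturing bedding/room/wear variation, the main
    driver of the armband's between-night spread.
    """

    reference_temp: float = 36.4
    bias_at_reference: float = -1.78
    prop_bias_slope: float = -0.2
    stream_noise_sd: float = 0.15
    night_effect_sd: float = 1.15
    stabilization_minutes: int = 40
    clip_low: float = 29.7
    clip_high: float = 36.7

    def __post_init__(self) -> None:
        if self.clip_low >= self.clip_high:
            raise ValueError("clip_low must be < clip_high")
        if self.stabilization_minutes <= 20:
            raise ValueError("stabilization_minutes must exceed 20")
        if self.stream_noise_sd < 0 or self.night_effect_sd < 0:
            raise ValueError("noise SDs must be >= 0")

    def level(self, true_temp_c: float) -> float:
        """Noise-free armband level for a given underlying temperature.

        The oral-minus-armband difference is
        ``-bias_at_reference + prop_bias_slope * (true - reference)``, so the
        level is ``true - difference``.
        """
        diff = -self.bias_at_reference + self.prop_bias_slope * (
            true_temp_c - self.reference_temp
        )
        return true_temp_c - diff


@dataclass(frozen=True)
class CycleDistribution:
    """Sampling ranges for per-participant cycle parameters.

    Integer ranges are inclusive; float ranges are uniform.  The follicular
    baseline range is centred so the cycle-wide oral mean reproduces the
    36.4 degC oral grand mean once the ovulatory shift is averaged in.
    """

    cycle_length: tuple[int, int] = (26, 32)
    luteal_length: tuple[int, int] = (12, 16)
    follicular_mean: tuple[float, float] = (36.13, 36.43)
    shift_magnitude: tuple[float, float] = (0.2, 0.5)
    nadir_depth: tuple[float, float] = (0.1, 0.3)
    daily_noise_sd: float = 0.2
    missing_prob: float = 0.05
    fever_prob: float = 0.15  # per-cycle probability of a 2-day fever episode
    fever_delta: float = 0.8

    def sample(self, ovulatory: bool, rng: np.random.Generator) -> CycleParams:
        length = int(rng.integers(self.cycle_length[0], self.cycle_length[1] + 1))
        luteal = int(rng.integers(self.luteal_length[0], self.luteal_length[1] + 1))
        fever: frozenset = frozenset()
        if rng.random() < self.fever_prob:
            start = int(rng.integers(1, length))
            fever = frozenset({start, min(start + 1, length)})
        return CycleParams(
            cycle_length=length,
            ovulatory=ovulatory,
            luteal_length=luteal,
            follicular_mean=float(rng.uniform(*self.follicular_mean)),
            shift_magnitude=float(rng.uniform(*self.shift_magnitude)),
            nadir_depth=float(rng.uniform(*self.nadir_depth)),
            daily_noise_sd=self.daily_noise_sd,
            missing_prob=self.missing_prob,
            fever_days=fever,
            fever_delta=self.fever_delta,
        )


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level configuration.

    Each participant is a flat-cycle control with probability
    ``fraction_control`` (emulating oral-contraceptive users); otherwise she
    is ovulatory with probability ``fraction_ovulatory``.
    """

    n_participants: int = 15
    fraction_ovulatory: float = 0.85
    fraction_control: float = 0.2
    cycles: CycleDistribution = field(default_factory=CycleDistribution)
    device: DeviceModel = field(default_factory=DeviceModel)
    window_minutes: int = 480
    wake_jitter_minutes: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for p in (self.fraction_ovulatory, self.fraction_control):
            if not 0 <= p <= 1:
                raise ValueError("fractions must be in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), default=_json_default, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _json_default(obj):
    if isinstance(obj, frozenset):
        return sorted(obj)
    raise TypeError(f"not JSON-serialisable: {obj!r}")


@dataclass
class CycleGroundTruth:
    """What the generator knows that the analysis must recover."""

    participant_id: str
    ovulatory: bool
    ovulation_day: int | None  # nadir day; sustained rise starts the next day
    shift_day: int | None  # first elevated day
    shift_magnitude: float
    luteal_length: int | None
    is_control: bool
    true_temps: np.ndarray | None = None  # noise-free profile incl. nadir/fever


@dataclass
class ParticipantData:
    participant_id: str
    params: CycleParams
    series: CycleSeries  # oral daily log
    truth: CycleGroundTruth
    streams: list[MinuteStream]


@dataclass
class Cohort:
    config: CohortConfig
    participants: list[ParticipantData]

    def ground_truth_table(self) -> pd.DataFrame:
        rows = [
            {
                "participant_id": p.participant_id,
                "ovulatory": p.truth.ovulatory,
                "ovulation_day": p.truth.ovulation_day,
                "is_control": p.truth.is_control,
            }
            for p in self.participants
        ]
        return pd.DataFrame(rows)

    def oral_series(self) -> list[CycleSeries]:
        return [p.series for p in self.participants]

    def all_streams(self) -> list[MinuteStream]:
        return [s for p in self.participants for s in p.streams]


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def true_profile(params: CycleParams) -> np.ndarray:
    """Noise-free daily temperature profile, including nadir and fever days."""
    temps = np.full(params.cycle_length, params.follicular_mean)
    if params.ovulatory:
        od = params.ovulation_day  # 1-based nadir day
        temps[od:] = params.follicular_mean + params.shift_magnitude
        temps[od - 1] = params.follicular_mean - params.nadir_depth
    for d in params.fever_days:
        temps[d - 1] += params.fever_delta
    return temps


def generate_cycle(
    params: CycleParams,
    seed,
    participant_id: str = "P000",
    start_date: dt.date = dt.date(2015, 6, 1),
) -> tuple[CycleSeries, CycleGroundTruth]:
    """Generate one cycle's daily oral-thermometer series plus ground truth.

    Oral readings are the true profile plus i.i.d. Gaussian noise, quantised
    to the thermometer's 0.01 degC resolution.  Missing days are NaN.
    """
    rng = _rng(seed)
    truth_temps = true_profile(params)
    n = params.cycle_length
    oral = truth_temps + rng.normal(0.0, params.daily_noise_sd, size=n)
    oral = np.round(oral / TEMP_RESOLUTION) * TEMP_RESOLUTION
    missing = rng.random(n) < params.missing_prob
    oral[missing] = np.nan
    illness = np.zeros(n, dtype=bool)
    for d in params.fever_days:
        illness[d - 1] = True
    series = CycleSeries(
        participant_id=participant_id,
        temps=oral,
        start_date=start_date,
        device="oral",
        illness=illness,
    )
    truth = CycleGroundTruth(
        participant_id=participant_id,
        ovulatory=params.ovulatory,
        ovulation_day=params.ovulation_day,
        shift_day=None if not params.ovulatory else params.ovulation_day + 1,
        shift_magnitude=params.shift_magnitude if params.ovulatory else 0.0,
        luteal_length=params.luteal_length if params.ovulatory else None,
        is_control=False,
        true_temps=truth_temps,
    )
    return series, truth


def generate_overnight_stream(
    cycle: CycleSeries,
    night_index: int,
    device: DeviceModel,
    seed,
    true_temp_c: float | None = None,
    window_minutes: int = 480,
    wake_jitter_minutes: int = 60,
    worn: bool = True,
) -> MinuteStream:
    """Generate one night's minute-level armband stream.

    ``night_index`` is the cycle day of the *morning* the night ends on.  The
    underlying level is the affine device transform of ``true_temp_c`` (the
    day's noise-free temperature; defaults to the series' recorded value)
    plus a per-night environmental shift.  The first
    ``stabilization_minutes`` ramp linearly from 2 degC below the level.  A
    non-wear night yields an all-off-body stream with NaN temperatures.
    """
    if not 1 <= night_index <= cycle.cycle_length:
        raise ValueError(f"night_index {night_index} outside cycle")
    rng = _rng(seed)
    if true_temp_c is None:
        true_temp_c = float(cycle.temps[night_index - 1])
    morning = cycle.date_of_day(night_index)

    jitter = rng.uniform(-wake_jitter_minutes, wake_jitter_minutes)
    wake = np.datetime64(morning, "m") + np.timedelta64(
        int(round(DEFAULT_WAKE_HOUR * 60 + jitter)), "m"
    )
    n_post = 10  # trailing off-body minutes after removal
    start = wake - np.timedelta64(window_minutes, "m")
    ts = start + np.arange(window_minutes + n_post) * np.timedelta64(1, "m")

    temps = np.full(window_minutes + n_post, np.nan)
    on_body = np.zeros(window_minutes + n_post, dtype=bool)
    if worn and np.isfinite(true_temp_c):
        level = device.level(true_temp_c) + rng.normal(0.0, device.night_effect_sd)
        minute = np.arange(window_minutes, dtype=float)
        ramp = np.where(
            minute < device.stabilization_minutes,
            level - 2.0 * (1.0 - minute / device.stabilization_minutes),
            level,
        )
        vals = ramp + rng.normal(0.0, device.stream_noise_sd, size=window_minutes)
        vals = np.clip(vals, device.clip_low, device.clip_high)
        temps[:window_minutes] = np.round(vals / TEMP_RESOLUTION) * TEMP_RESOLUTION
        on_body[:window_minutes] = True
    return MinuteStream(
        participant_id=cycle.participant_id,
        night_date=morning,
        timestamps=ts,
        temp_c=temps,
        on_body=on_body,
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a reproducible cohort of cycles plus nightly armband streams.

    Night wear is missed independently with the cycle's ``missing_prob``
    (oral and armband compliance lapses are modelled as independent).
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_participants)
    participants = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pid = f"P{i + 1:03d}"
        is_control = rng.random() < config.fraction_control
        ovulatory = (not is_control) and rng.random() < config.fraction_ovulatory
        params = config.cycles.sample(ovulatory, rng)
        series, truth = generate_cycle(params, rng, participant_id=pid)
        truth.is_control = is_control
        streams = []
        for day in range(1, params.cycle_length + 1):
            worn = rng.random() >= params.missing_prob
            streams.append(
                generate_overnight_stream(
                    series,
                    day,
                    config.device,
                    rng,
                    true_temp_c=float(truth.true_temps[day - 1]),
                    window_minutes=config.window_minutes,
                    wake_jitter_minutes=config.wake_jitter_minutes,
                    worn=worn,
                )
            )
        participants.append(
            ParticipantData(
                participant_id=pid,
                params=params,
                series=series,
                truth=truth,
                streams=streams,
            )
        )
    return Cohort(config=config, participants=participants)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write a cohort to CSV/JSON files; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    comments = {"seed": cohort.config.seed, "config_hash": cohort.config.config_hash()}
    paths = {
        "daily": outdir / "daily.csv",
        "minutes": outdir / "minutes.csv",
        "ground_truth": outdir / "ground_truth.csv",
        "config": outdir / "config.json",
    }
    write_daily_csv(cohort.oral_series(), paths["daily"], header_comments=comments)
    write_minute_csv(cohort.all_streams(), paths["minutes"], header_comments=comments)
    with paths["ground_truth"].open("w") as fh:
        fh.write(f"# seed={cohort.config.seed}\n")
        cohort.ground_truth_table().to_csv(fh, index=False)
    paths["config"].write_text(cohort.config.to_json() + "\n")
    return paths
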
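"""Rule-based ovulation calling from daily basal-temperature series.

Two classifiers are provided, mirroring how BBT charts are read in practice:

* :func:`classify_visual` — the chart-reading criteria: a *biphasic* pattern
  (three consecutive temperatures each more than 0.2 degC above the maximum
  of the six preceding usable temperatures, near the expected ovulation day
  two weeks before the next menses), an *adequate thermal shift* (sustained
  for at least 11 days, rise completed in under 2 days, no deep falls back
  to the pre-shift level during the luteal phase), and a supportive (never
  decisive) pre-rise *nadir*.

* :func:`classify_mtm` — a quantitative mean-temperature rule: the shift day
  is the first day starting a 3-day run above the cycle mean such that at
  least 11 days from there to cycle end exceed the mean and none drops more
  than 0.1 degC below it.  (The classical mean-temperature method is cited
  in the literature without a complete operational definition; this is the
  package's documented operationalisation.)

Both map every series to one of three categories — ovulatory, anovulatory,
inconclusive — with inconclusive reserved for incomplete data (fewer than 17
recorded days, more than 20% of days missing, an unanchorable window, or
undeterminable criteria).  Fever-flagged days are excluded from all
criterion computations.  :func:`adjudicate_majority` combines 2-3 raters'
calls by majority, escalating 2-way disagreements.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .temperature_io import CycleSeries

CATEGORIES = ("ovulatory", "anovulatory", "inconclusive")

#: biphasic threshold: the three shifted days must exceed the reference by
#: strictly more than this, degC
BIPHASIC_DELTA = 0.2
#: days either side of the expected ovulation day searched for the shift
DEFAULT_WINDOW_HALFWIDTH = 4
#: minimum sustained elevation for an adequate thermal shift, days
MIN_SUSTAINED_DAYS = 11
#: completeness rules: minimum recorded days and maximum missing fraction
MIN_RECORDED_DAYS = 17
MAX_MISSING_FRACTION = 0.2
#: luteal-run tolerance below the cycle mean for the quantitative rule, degC
MTM_DIP_TOLERANCE = 0.1

# comparisons are done at this guard band so that a shift of exactly
# 0.2 degC (up to float error) never counts as "> 0.2"
_EPS = 1e-9


def _gt(a: float, b: float) -> bool:
    """Strict greater-than robust to float representation error."""
    return a > b + _EPS


@dataclass
class CriterionOutcome:
    """Outcome of one visual criterion; ``passed`` is None when the data do
    not allow a determination."""

    name: str
    passed: Optional[bool]
    detail: str = ""


@dataclass
class OvulationCall:
    """Categorical ovulation call for one cycle, with supporting evidence."""

    participant_id: str
    method: str  # "visual" | "mtm" | "adjudicated"
    category: str
    shift_day: Optional[int] = None
    nadir_day: Optional[int] = None
    luteal_length_days: Optional[int] = None
    rise_days: Optional[int] = None
    reasons: list[CriterionOutcome] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class BiphasicResult:
    shift_day: Optional[int]
    undetermined: bool = False
    detail: str = ""


@dataclass
class ThermalShiftResult:
    outcome: CriterionOutcome
    luteal_length_days: Optional[int] = None
    rise_days: Optional[int] = None
    reference: Optional[float] = None


@dataclass
class Adjudication:
    """Majority decision over 2-3 raters; ``category`` is None while a third
    rater is still needed."""

    category: Optional[str]
    needs_third_rater: bool
    votes: tuple[str, ...]


def expected_ovulation_day(series: CycleSeries) -> Optional[int]:
    """Expected ovulation day: two weeks before the next menses.

    With day ``cycle_length`` the last day before the next menses, the day
    with exactly 14 days remaining (inclusive) is ``cycle_length - 13``.
    Returns None when the next menses was not observed, in which case the
    biphasic search window cannot be anchored.
    """
    if not series.next_menses_known:
        return None
    return series.cycle_length - 13


def _preceding_usable(usable_days: np.ndarray, day: int, k: int = 6) -> np.ndarray:
    """The (up to) ``k`` most recent usable 1-based days strictly before ``day``."""
    prior = usable_days[usable_days < day]
    return prior[-k:]


def detect_biphasic_shift(
    series: CycleSeries,
    window_center: int,
    window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH,
) -> BiphasicResult:
    """Find the first day of a 3-day sustained shift near the expected
    ovulation day.

    A candidate day ``d`` qualifies when the temperatures on ``d``, ``d+1``
    and ``d+2`` each exceed the maximum of the six preceding usable
    temperatures by more than 0.2 degC.  Candidates range over
    ``[center - halfwidth, center + halfwidth]``.  If no candidate has six
    usable preceding days the search is undetermined (feeds inconclusive)
    rather than negative.
    """
    temps = series.temps
    usable = series.usable_mask()
    usable_days = np.nonzero(usable)[0] + 1  # 1-based
    lo = max(1, window_center - window_halfwidth)
    hi = min(series.cycle_length - 2, window_center + window_halfwidth)
    any_evaluable = False
    for d in range(lo, hi + 1):
        prev = _preceding_usable(usable_days, d)
        if len(prev) < 6:
            continue
        any_evaluable = True
        triple = temps[d - 1 : d + 2]
        if not all(usable[d - 1 : d + 2]):
            continue
        reference = float(temps[prev - 1].max())
        if all(_gt(t - reference, BIPHASIC_DELTA) for t in triple):
            return BiphasicResult(shift_day=d, detail=f"3-day shift from day {d}")
    if not any_evaluable:
        return BiphasicResult(
            shift_day=None,
            undetermined=True,
            detail="fewer than 6 usable preceding days for every candidate",
        )
    return BiphasicResult(shift_day=None, detail="no 3-day sustained shift > 0.2 degC")


def check_thermal_shift_adequacy(series: CycleSeries, shift_day: int) -> ThermalShiftResult:
    """Check whether a detected shift is an adequate thermal shift.

    Requires (i) the elevation to span at least 11 days through cycle end
    with every usable luteal temperature strictly above the pre-shift
    reference (the maximum of the six preceding usable days) — a luteal
    temperature at or below the reference is a "deep fall"; and (ii) the
    rise to complete in under 2 days (the last usable pre-shift day is the
    day before the shift).  More than two missing luteal days make the
    criterion undeterminable.
    """
    temps = series.temps
    usable = series.usable_mask()
    usable_days = np.nonzero(usable)[0] + 1
    prev = _preceding_usable(usable_days, shift_day)
    if len(prev) < 6:
        return ThermalShiftResult(
            CriterionOutcome("thermal_shift", None, "insufficient pre-shift data")
        )
    reference = float(temps[prev - 1].max())
    luteal_idx = np.arange(shift_day - 1, series.cycle_length)
    luteal_length = int(series.cycle_length - shift_day + 1)
    n_missing = int((~np.isfinite(temps[luteal_idx])).sum())
    if n_missing > 2:
        return ThermalShiftResult(
            CriterionOutcome(
                "thermal_shift", None, f"{n_missing} luteal temperatures missing"
            ),
            luteal_length_days=luteal_length,
            reference=reference,
        )
    luteal_usable = temps[luteal_idx][usable[luteal_idx]]
    failures = []
    if luteal_length < MIN_SUSTAINED_DAYS:
        failures.append(f"sustained {luteal_length} < {MIN_SUSTAINED_DAYS} days")
    deep = [t for t in luteal_usable if not _gt(t, reference)]
    if deep:
        failures.append(
            f"deep fall: {len(deep)} luteal temperature(s) at/below pre-shift reference"
        )
    rise_days = int(shift_day - prev[-1])
    if not rise_days < 2:
        failures.append(f"rise spans {rise_days} days (>= 2)")
    outcome = CriterionOutcome(
        "thermal_shift",
        passed=not failures,
        detail="; ".join(failures) if failures else "adequate",
    )
    return ThermalShiftResult(
        outcome,
        luteal_length_days=luteal_length,
        rise_days=rise_days,
        reference=reference,
    )


def detect_nadir(series: CycleSeries, shift_day: int) -> Optional[int]:
    """Supportive nadir: lowest usable day within the three days before the
    shift, provided it sits strictly below the mean of the six usable days
    preceding the shift."""
    temps = series.temps
    usable = series.usable_mask()
    usable_days = np.nonzero(usable)[0] + 1
    prev = _preceding_usable(usable_days, shift_day)
    if len(prev) < 6:
        return None
    baseline = float(temps[prev - 1].mean())
    candidates = [d for d in range(max(1, shift_day - 3), shift_day) if usable[d - 1]]
    if not candidates:
        return None
    nadir_day = min(candidates, key=lambda d: (temps[d - 1], d))
    if _gt(baseline, float(temps[nadir_day - 1])):
        return nadir_day
    return None


def _completeness_failure(series: CycleSeries) -> Optional[str]:
    n = series.cycle_length
    n_present = series.n_present
    if n_present < MIN_RECORDED_DAYS:
        return f"only {n_present} recorded days (< {MIN_RECORDED_DAYS})"
    missing_frac = 1.0 - n_present / n
    if _gt(missing_frac, MAX_MISSING_FRACTION):
        return f"{missing_frac:.0%} of days missing (> {MAX_MISSING_FRACTION:.0%})"
    return None


def classify_visual(
    series: CycleSeries,
    window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH,
) -> OvulationCall:
    """Classify one cycle by the visual chart-reading criteria.

    Biphasic pattern and adequate thermal shift are both required for an
    ovulatory call; a nadir is recorded as supportive evidence only.
    Incomplete data or undeterminable criteria give ``inconclusive``.
    """
    reasons: list[CriterionOutcome] = []
    incomplete = _completeness_failure(series)
    if incomplete is not None:
        reasons.append(CriterionOutcome("completeness", False, incomplete))
        return OvulationCall(series.participant_id, "visual", "inconclusive", reasons=reasons)

    center = expected_ovulation_day(series)
    if center is None:
        reasons.append(
            CriterionOutcome("biphasic", None, "next menses unknown; window unanchored")
        )
        return OvulationCall(series.participant_id, "visual", "inconclusive", reasons=reasons)

    bi = detect_biphasic_shift(series, center, window_halfwidth)
    if bi.undetermined:
        reasons.append(CriterionOutcome("biphasic", None, bi.detail))
        return OvulationCall(series.participant_id, "visual", "inconclusive", reasons=reasons)
    if bi.shift_day is None:
        reasons.append(CriterionOutcome("biphasic", False, bi.detail))
        return OvulationCall(series.participant_id, "visual", "anovulatory", reasons=reasons)
    reasons.append(CriterionOutcome("biphasic", True, bi.detail))

    th = check_thermal_shift_adequacy(series, bi.shift_day)
    reasons.append(th.outcome)
    nadir_day = detect_nadir(series, bi.shift_day)
    reasons.append(
        CriterionOutcome(
            "nadir",
            nadir_day is not None,
            f"nadir on day {nadir_day}" if nadir_day is not None else "no nadir (supportive only)",
        )
    )
    if th.outcome.passed is None:
        return OvulationCall(
            series.participant_id,
            "visual",
            "inconclusive",
            shift_day=bi.shift_day,
            nadir_day=nadir_day,
            reasons=reasons,
        )
    category = "ovulatory" if th.outcome.passed else "anovulatory"
    return OvulationCall(
        series.participant_id,
        "visual",
        category,
        shift_day=bi.shift_day if category == "ovulatory" else None,
        nadir_day=nadir_day,
        luteal_length_days=th.luteal_length_days if category == "ovulatory" else None,
        rise_days=th.rise_days,
        reasons=reasons,
    )


def classify_mtm(series: CycleSeries) -> OvulationCall:
    """Classify one cycle by the quantitative mean-temperature rule.

    The cycle mean is taken over all usable (recorded, non-fever) days.  The
    cycle is ovulatory when some day ``d`` starts a 3-day run strictly above
    the mean, at least 11 usable days from ``d`` to cycle end exceed the
    mean, and no usable day in that span falls more than 0.1 degC below it.
    """
    reasons: list[CriterionOutcome] = []
    incomplete = _completeness_failure(series)
    if incomplete is not None:
        reasons.append(CriterionOutcome("completeness", False, incomplete))
        return OvulationCall(series.participant_id, "mtm", "inconclusive", reasons=reasons)

    temps = series.temps
    usable = series.usable_mask()
    if not usable.any():
        reasons.append(CriterionOutcome("mean_shift", None, "no usable temperatures"))
        return OvulationCall(series.participant_id, "mtm", "inconclusive", reasons=reasons)
    cycle_mean = float(temps[usable].mean())

    n = series.cycle_length
    for d in range(1, n - 1):
        idx = slice(d - 1, d + 2)
        if not usable[idx].all():
            continue
        if not all(_gt(t, cycle_mean) for t in temps[idx]):
            continue
        tail = np.arange(d - 1, n)
        tail_usable = tail[usable[tail]]
        n_above = int(sum(_gt(temps[i], cycle_mean) for i in tail_usable))
        if n_above < MIN_SUSTAINED_DAYS:
            continue
        if any(_gt(cycle_mean - MTM_DIP_TOLERANCE, temps[i]) for i in tail_usable):
            continue
        reasons.append(
            CriterionOutcome(
                "mean_shift",
                True,
                f"{n_above} days above cycle mean {cycle_mean:.2f} from day {d}",
            )
        )
        return OvulationCall(
            series.participant_id,
            "mtm",
            "ovulatory",
            shift_day=d,
            luteal_length_days=n - d + 1,
            reasons=reasons,
        )
    reasons.append(
        CriterionOutcome(
            "mean_shift", False, f"no sustained run above cycle mean {cycle_mean:.2f}"
        )
    )
    return OvulationCall(series.participant_id, "mtm", "anovulatory", reasons=reasons)


def adjudicate_majority(calls: Sequence[OvulationCall]) -> Adjudication:
    """Combine 2-3 raters' calls by majority.

    Two concordant calls decide; two discordant calls escalate (category
    None, ``needs_third_rater``); with three calls the modal category wins
    and a three-way tie is inconclusive.
    """
    if not 2 <= len(calls) <= 3:
        raise ValueError(f"adjudication needs 2 or 3 calls, got {len(calls)}")
    votes = tuple(c.category for c in calls)
    if len(votes) == 2:
        if votes[0] == votes[1]:
            return Adjudication(votes[0], needs_third_rater=False, votes=votes)
        return Adjudication(None, needs_third_rater=True, votes=votes)
    counts = Counter(votes)
    cat, top = counts.most_common(1)[0]
    if top >= 2:
        return Adjudication(cat, needs_third_rater=False, votes=votes)
    return Adjudication("inconclusive", needs_third_rater=False, votes=votes)
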
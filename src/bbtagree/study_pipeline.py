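"""End-to-end device-comparison pipeline.

Simulate (or load) a cohort, reduce the wearable streams to daily pre-waking
means, classify every participant's cycle by both the visual criteria and
the quantitative mean-temperature rule on both devices, and report the
continuous (Spearman + Bland–Altman per pre-waking interval) and
categorical (four pairwise Cohen's kappa comparisons) agreement between
methods.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import method_agreement as ma
from . import ovulation_calls as oc
from . import temperature_io as tio
from .synthetic_cohort import Cohort, CohortConfig, generate_cohort

#: participants need at least this many recorded oral temperatures to be analyzable
MIN_ANALYZABLE_DAYS = 17

#: armband interval used for the daily chart series fed to the classifiers
DEFAULT_CHART_INTERVAL = 60

#: the four between-method categorical comparisons reported
COMPARISONS = (
    ("quant_armband_vs_quant_oral", ("mtm", "armband"), ("mtm", "oral")),
    ("visual_armband_vs_visual_oral", ("visual", "armband"), ("visual", "oral")),
    ("quant_armband_vs_visual_armband", ("mtm", "armband"), ("visual", "armband")),
    ("quant_oral_vs_visual_oral", ("mtm", "oral"), ("visual", "oral")),
)


@dataclass
class ExclusionLog:
    rule: str
    excluded: list[tuple[str, str]]  # (participant_id, reason)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


@dataclass
class StudyReport:
    """Full report of one pipeline run."""

    n_analyzable: int
    exclusions: ExclusionLog
    counts: pd.DataFrame  # rows: method x device; cols: the three categories
    calls: dict[tuple[str, str], list[oc.OvulationCall]]
    agreements: dict[str, Optional[ma.AgreementResult]]
    correlations: dict[int, ma.CorrelationResult]
    bland_altman: dict[int, ma.BlandAltmanResult]
    interval_rho: dict[str, float]  # pairwise armband interval correlations
    seed: Optional[int]
    config_hash: Optional[str]

    def to_dict(self) -> dict:
        def agree_d(a: Optional[ma.AgreementResult]):
            if a is None:
                return None
            return {
                "kappa": round(a.kappa, 4),
                "overall_pct": round(a.overall_pct, 2),
                "per_category_pct": {k: round(v, 2) for k, v in a.per_category_pct.items()},
                "interpretation": a.interpretation,
                "n": a.n,
            }

        return {
            "n_analyzable": self.n_analyzable,
            "exclusions": {
                "rule": self.exclusions.rule,
                "n_excluded": self.exclusions.n_excluded,
                "excluded": [list(e) for e in self.exclusions.excluded],
            },
            "counts": {
                f"{m}_{d}": {c: int(row[c]) for c in oc.CATEGORIES}
                for (m, d), row in self.counts.iterrows()
            },
            "agreements": {k: agree_d(v) for k, v in self.agreements.items()},
            "correlations": {
                str(k): {"rho": round(v.rho, 4), "p_value": round(v.p_value, 6), "n": v.n}
                for k, v in self.correlations.items()
            },
            "bland_altman": {
                str(k): {
                    "bias": round(v.bias, 4),
                    "sd_diff": round(v.sd_diff, 4),
                    "loa_low": round(v.loa_low, 4),
                    "loa_high": round(v.loa_high, 4),
                    "prop_bias_slope": round(v.prop_bias_slope, 4),
                    "n": v.n,
                }
                for k, v in self.bland_altman.items()
            },
            "interval_rho": {k: round(v, 4) for k, v in self.interval_rho.items()},
            "provenance": {"seed": self.seed, "config_hash": self.config_hash},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        d = self.to_dict()
        lines = [
            f"Analyzable participants: {self.n_analyzable} "
            f"({self.exclusions.n_excluded} excluded: {self.exclusions.rule})",
            "",
            "Classification counts (method, device | ovulatory anovulatory inconclusive):",
        ]
        for key, row in d["counts"].items():
            lines.append(
                f"  {key:18s} {row['ovulatory']:3d} {row['anovulatory']:3d} {row['inconclusive']:3d}"
            )
        lines.append("")
        lines.append("Between-method agreement (kappa / overall %):")
        for k, v in d["agreements"].items():
            if v is None:
                lines.append(f"  {k:34s} kappa undefined (both raters constant)")
            else:
                lines.append(
                    f"  {k:34s} {v['kappa']:7.4f} / {v['overall_pct']:6.2f}%  [{v['interpretation']}]"
                )
        lines.append("")
        lines.append("Oral vs armband, per pre-waking interval (rho; BA bias [LoA], slope):")
        for k in sorted(self.correlations):
            c, b = d["correlations"][str(k)], d["bland_altman"][str(k)]
            lines.append(
                f"  {k:3d} min  rho={c['rho']:6.3f}  bias={b['bias']:5.3f} "
                f"[{b['loa_low']:.2f}, {b['loa_high']:.2f}]  slope={b['prop_bias_slope']:6.3f}"
            )
        lines.append("")
        lines.append(
            f"Armband interval-to-interval rho: "
            f"{min(self.interval_rho.values()):.3f}-{max(self.interval_rho.values()):.3f}"
        )
        lines.append(f"Provenance: seed={self.seed} config_hash={self.config_hash}")
        return "\n".join(lines)


def exclusion_filter(
    cycles: Sequence[tio.CycleSeries],
    min_days: int = MIN_ANALYZABLE_DAYS,
) -> tuple[list[tio.CycleSeries], ExclusionLog]:
    """Drop participants with too few recorded oral temperatures."""
    kept, excluded = [], []
    for s in cycles:
        if s.n_present < min_days:
            excluded.append(
                (s.participant_id, f"{s.n_present} recorded days (< {min_days})")
            )
        else:
            kept.append(s)
    log = ExclusionLog(
        rule=f"at least {min_days} recorded oral temperatures required",
        excluded=excluded,
    )
    return kept, log


def _pairwise_interval_rho(table: pd.DataFrame) -> dict[str, float]:
    out = {}
    ks = tio.PREWAKING_INTERVALS
    for i, a in enumerate(ks):
        for b in ks[i + 1 :]:
            try:
                res = ma.spearman(table[f"armband_{a}"], table[f"armband_{b}"])
                out[f"{a}_vs_{b}"] = res.rho
            except (ValueError, ma.DegenerateDataError):
                continue
    return out


def run_study(
    config: CohortConfig | None = None,
    cohort: Cohort | None = None,
    daily_csv: str | Path | None = None,
    minute_csv: str | Path | None = None,
    chart_interval: int = DEFAULT_CHART_INTERVAL,
) -> StudyReport:
    """Run the full comparison, from simulation config or from CSV inputs.

    Exactly one input mode must be given: a :class:`CohortConfig` (or a
    pre-built :class:`Cohort`) for simulation mode, or paths to a daily-log
    CSV plus a minute-stream CSV for data mode.
    """
    seed = config_hash = None
    if cohort is None and config is not None:
        cohort = generate_cohort(config)
    if cohort is not None:
        oral = cohort.oral_series()
        streams = cohort.all_streams()
        seed = cohort.config.seed
        config_hash = cohort.config.config_hash()
    elif daily_csv is not None and minute_csv is not None:
        oral = [s for s in tio.read_daily_csv(daily_csv) if s.device == "oral"]
        streams = tio.read_minute_csv(minute_csv)
    else:
        raise ValueError("provide either a config/cohort or daily+minute CSV paths")

    oral, exclusions = exclusion_filter(oral)
    if not oral:
        raise ValueError(
            f"zero analyzable participants ({exclusions.n_excluded} excluded: "
            f"{exclusions.rule})"
        )
    kept_ids = {s.participant_id for s in oral}
    streams = [s for s in streams if s.participant_id in kept_ids]

    table = tio.daily_basal_table(oral, streams)
    arm = tio.armband_series(table, oral, interval_minutes=chart_interval)

    calls: dict[tuple[str, str], list[oc.OvulationCall]] = {}
    for device, series_list in (("oral", oral), ("armband", arm)):
        ordered = sorted(series_list, key=lambda s: s.participant_id)
        calls[("visual", device)] = [oc.classify_visual(s) for s in ordered]
        calls[("mtm", device)] = [oc.classify_mtm(s) for s in ordered]

    counts = pd.DataFrame(
        {
            cat: [sum(c.category == cat for c in calls[key]) for key in calls]
            for cat in oc.CATEGORIES
        },
        index=pd.MultiIndex.from_tuples(calls.keys(), names=["method", "device"]),
    )

    agreements: dict[str, Optional[ma.AgreementResult]] = {}
    for name, key_a, key_b in COMPARISONS:
        try:
            agreements[name] = ma.kappa_from_calls(calls[key_a], calls[key_b])
        except ma.UndefinedKappaError:
            agreements[name] = None

    correlations, bas = {}, {}
    for k in tio.PREWAKING_INTERVALS:
        col = table[f"armband_{k}"]
        try:
            correlations[k] = ma.spearman(table["oral"], col)
        except (ValueError, ma.DegenerateDataError):
            continue
        bas[k] = ma.bland_altman(table["oral"], col)

    return StudyReport(
        n_analyzable=len(oral),
        exclusions=exclusions,
        counts=counts,
        calls=calls,
        agreements=agreements,
        correlations=correlations,
        bland_altman=bas,
        interval_rho=_pairwise_interval_rho(table),
        seed=seed,
        config_hash=config_hash,
    )


def calls_to_frame(calls: Sequence[oc.OvulationCall]) -> pd.DataFrame:
    """Flatten calls to the CSV schema used by the ``classify`` command."""
    rows = []
    for c in calls:
        rows.append(
            {
                "participant_id": c.participant_id,
                "method": c.method,
                "category": c.category,
                "shift_day": c.shift_day,
                "nadir_day": c.nadir_day,
                "luteal_length": c.luteal_length_days,
                "rise_days": c.rise_days,
                "reasons": " | ".join(
                    f"{r.name}={'?' if r.passed is None else r.passed}: {r.detail}"
                    for r in c.reasons
                ),
            }
        )
    return pd.DataFrame(rows)
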
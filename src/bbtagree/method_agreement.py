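"""Between-method agreement statistics.

Continuous temperature comparisons use Spearman rank correlation and
Bland–Altman analysis (bias, 95% limits of agreement, and a least-squares
slope of difference on mean capturing proportional bias).  Categorical
ovulation-call comparisons use unweighted Cohen's kappa on a 3x3
contingency table over (ovulatory, anovulatory, inconclusive), with the
study's percent-agreement convention: per-category agreement is the
concordant count in that category divided by the *total* number of pairs,
so the three per-category percentages sum to the overall agreement.

Kappa interpretation bands: > .75 excellent, .4 to .75 (inclusive) fair to
good, < .4 moderate to poor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.inter_rater import cohens_kappa as _sm_cohens_kappa

from .ovulation_calls import CATEGORIES, OvulationCall


class DegenerateDataError(ValueError):
    """Inputs do not support the requested statistic (e.g. zero variance)."""


class UndefinedKappaError(ValueError):
    """Expected agreement is 1 (both raters constant and identical), so
    kappa is undefined — distinct from kappa = 0."""


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int


@dataclass
class BlandAltmanResult:
    bias: float  # mean of method1 - method2
    sd_diff: float
    loa_low: float
    loa_high: float
    prop_bias_slope: float
    n: int


@dataclass
class AgreementResult:
    kappa: float
    overall_pct: float
    per_category_pct: dict[str, float]
    interpretation: Optional[str]
    n: int


@dataclass
class ContingencyTable:
    """Square cross-tabulation of two raters' categorical calls.

    Rows index rater A's category, columns rater B's, both in the fixed
    order (ovulatory, anovulatory, inconclusive).
    """

    counts: np.ndarray
    categories: tuple[str, ...] = CATEGORIES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.categories)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @classmethod
    def from_calls(
        cls,
        calls_a: Sequence[OvulationCall | str],
        calls_b: Sequence[OvulationCall | str],
    ) -> "ContingencyTable":
        if len(calls_a) != len(calls_b):
            raise ValueError(
                f"call lists differ in length: {len(calls_a)} vs {len(calls_b)}"
            )
        idx = {c: i for i, c in enumerate(CATEGORIES)}
        counts = np.zeros((len(CATEGORIES), len(CATEGORIES)), dtype=int)
        for a, b in zip(calls_a, calls_b):
            ca = a.category if isinstance(a, OvulationCall) else a
            cb = b.category if isinstance(b, OvulationCall) else b
            counts[idx[ca], idx[cb]] += 1
        return cls(counts)


def _paired_finite(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with average-rank ties and a two-sided p.

    Pairs with any missing member are dropped listwise; fewer than three
    complete pairs or a zero-variance input are errors.
    """
    x, y = _paired_finite(x, y)
    if len(x) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance input: rank correlation undefined")
    res = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(res.statistic), p_value=float(res.pvalue), n=len(x))


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland–Altman comparison of paired measurements (x - y vs their mean)."""
    x, y = _paired_finite(x, y)
    if len(x) < 2:
        raise ValueError(f"need >= 2 complete pairs, got {len(x)}")
    diff = x - y
    mean = (x + y) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.ptp(mean) == 0:
        slope = 0.0 if np.ptp(diff) == 0 else float("nan")
    else:
        slope = float(stats.linregress(mean, diff).slope)
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        prop_bias_slope=slope,
        n=len(x),
    )


def interpret_kappa(kappa: float) -> Optional[str]:
    """Map a kappa value to its interpretation band (None if undefined)."""
    if kappa is None or not np.isfinite(kappa):
        return None
    if kappa > 0.75:
        return "excellent"
    if kappa >= 0.4:
        return "fair-to-good"
    return "moderate-to-poor"


def cohens_kappa(table: ContingencyTable) -> AgreementResult:
    """Unweighted Cohen's kappa plus the study's agreement percentages.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the diagonal fraction and p_e
    the chance agreement from the marginals.  Overall agreement is
    p_o * 100; each category's agreement is its diagonal cell over the total
    n * 100 (so the per-category values sum to the overall).
    """
    n = table.n
    if n < 1:
        raise ValueError("contingency table is empty")
    counts = table.counts
    p_o = float(np.trace(counts)) / n
    p_e = float(table.row_marginals @ table.col_marginals) / n**2
    if 1.0 - p_e < 1e-12:
        raise UndefinedKappaError(
            "both raters constant in the same category: kappa undefined"
        )
    kappa = float(_sm_cohens_kappa(counts, return_results=False))
    per_cat = {
        c: float(counts[i, i]) / n * 100.0 for i, c in enumerate(table.categories)
    }
    return AgreementResult(
        kappa=kappa,
        overall_pct=p_o * 100.0,
        per_category_pct=per_cat,
        interpretation=interpret_kappa(kappa),
        n=n,
    )


def kappa_from_calls(
    calls_a: Sequence[OvulationCall | str],
    calls_b: Sequence[OvulationCall | str],
) -> AgreementResult:
    """Cohen's kappa for two aligned lists of ovulation calls."""
    return cohens_kappa(ContingencyTable.from_calls(calls_a, calls_b))


def plot_bland_altman(result: BlandAltmanResult, x, y, path) -> None:
    """Write a Bland–Altman plot (difference vs mean with bias and LoA)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x, y = _paired_finite(x, y)
    diff = x - y
    mean = (x + y) / 2.0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, diff, s=12, alpha=0.6)
    for val, style, label in [
        (result.bias, "-", f"bias {result.bias:.2f}"),
        (result.loa_low, "--", f"LoA {result.loa_low:.2f}"),
        (result.loa_high, "--", f"LoA {result.loa_high:.2f}"),
    ]:
        ax.axhline(val, linestyle=style, color="k", linewidth=0.8)
        ax.annotate(label, (mean.min(), val), fontsize=7, va="bottom")
    ax.set_xlabel("mean of methods (degC)")
    ax.set_ylabel("difference (degC)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
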
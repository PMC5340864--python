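"""Growth-curve, viability and competition-fitness analytics.

Viable densities come from dilution-spot plating: 10 ul of a 10^-k serial
dilution is spotted on a plate and colonies counted, so
``CFU/ml = colonies * 10^k * (1000 / spot volume in ul)``.  The
volume correction is applied by default (a 10 ul spot undercounts per-ml
density 100-fold otherwise) but can be disabled to reproduce the bare
"dilution factor times colonies" convention.  A spot with zero colonies is
*below detection* at the density one colony would represent — never
recorded as zero.

Growth curves over several days of incubation show the hallmark of
long-term batch culture: a peak on day 1, a >100-fold death-phase drop to a
trough around day 4 and a partial recovery ("the dip").  Densities span
decades, so replicates are averaged and compared on the log10 scale, and
per-day strain differences use Student's two-sample t test (equal
variances, as named; Welch and paired variants by flag) against a fixed
significance threshold (default P <= 0.025).

Competition assays follow two marked strains through serial passages.  The
log10 ratio of their densities summarizes the outcome (10,000:1 -> 4.0);
an endpoint t test compares the strains at the final passage; and the
selection coefficient is the least-squares slope of the natural-log ratio
against cumulative generations.  On the simulator's fitness scale
(per-doubling multiplier 1 + s) that slope equals ln(1 + s), so the
estimate is reported both ways.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CfuCount:
    """A viable-count estimate, possibly a below-detection bound."""

    value: float
    below_detection: bool = False


def cfu_per_ml(
    colonies: int,
    dilution_step: int,
    spot_volume_ul: float = 10.0,
    volume_corrected: bool = True,
) -> CfuCount:
    """CFU/ml from a dilution-spot colony count.

    ``dilution_step`` k means the spot came from a 10^-k dilution.  Zero
    colonies returns the detection limit (the density one colony would
    imply) flagged as below detection.
    """
    if colonies < 0:
        raise ValueError("colonies must be >= 0")
    if dilution_step < 0:
        raise ValueError("dilution_step must be >= 0")
    if spot_volume_ul <= 0:
        raise ValueError("spot_volume_ul must be > 0")
    correction = (1000.0 / spot_volume_ul) if volume_corrected else 1.0
    if colonies == 0:
        return CfuCount(10.0 ** dilution_step * correction, below_detection=True)
    return CfuCount(colonies * 10.0 ** dilution_step * correction)


@dataclass(frozen=True)
class DipMetrics:
    """Peak/trough/recovery structure of a multi-day growth curve.

    ``has_dip`` is False for monotone non-decreasing (including flat)
    curves; the remaining fields are then None apart from the peak.
    """

    has_dip: bool
    peak_day: float
    peak_density: float
    trough_day: float | None = None
    trough_density: float | None = None
    drop_fold: float | None = None
    exit_day: float | None = None
    recovery_fold: float | None = None


def average_replicates(curve: pd.DataFrame) -> dict[float, float]:
    """Geometric-mean density per day across replicates (log10 averaging)."""
    grouped = curve.groupby("day")["cfu_per_ml"].apply(
        lambda v: 10.0 ** np.mean(np.log10(v))
    )
    return {float(day): float(val) for day, val in grouped.items()}


def dip_metrics(curve: Mapping[float, float] | pd.DataFrame) -> DipMetrics:
    """Locate the death-phase dip of one strain's growth curve.

    The peak is the global maximum (earliest day on ties); the trough is
    the global minimum strictly after the peak (earliest on ties); the exit
    is the first post-trough day with strictly higher density.  Replicate
    tables are averaged (geometric mean) first — averaging before detection
    is the chosen order.
    """
    if isinstance(curve, pd.DataFrame):
        curve = average_replicates(curve)
    days = sorted(float(d) for d in curve)
    if len(days) < 3:
        raise ValueError("dip detection requires at least 3 time points")
    dens = {float(d): float(curve[d]) for d in curve}
    if any(v <= 0 for v in dens.values()):
        raise ValueError("densities must be > 0 (encode below-detection upstream)")
    peak_day = max(days, key=lambda d: (dens[d], -d))
    peak = dens[peak_day]
    after = [d for d in days if d > peak_day]
    if not after:
        return DipMetrics(False, peak_day, peak)
    trough_day = min(after, key=lambda d: (dens[d], d))
    trough = dens[trough_day]
    if trough >= peak:
        return DipMetrics(False, peak_day, peak)
    exit_day = next(
        (d for d in days if d > trough_day and dens[d] > trough), None
    )
    recovery = dens[exit_day] / trough if exit_day is not None else None
    return DipMetrics(
        has_dip=True,
        peak_day=peak_day,
        peak_density=peak,
        trough_day=trough_day,
        trough_density=trough,
        drop_fold=peak / trough,
        exit_day=exit_day,
        recovery_fold=recovery,
    )


class TTestResult(NamedTuple):
    statistic: float
    pvalue: float
    n1: int
    n2: int


def log_t_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    equal_var: bool = True,
    paired: bool = False,
) -> TTestResult:
    """Student's t test on log10-transformed densities.

    Degenerate (zero-variance) inputs are handled explicitly with a
    warning: equal means give t = 0, p = 1; separated means with no
    within-group variance give an infinite statistic and p = 0.
    """
    a = np.log10(np.asarray(values_a, dtype=float))
    b = np.log10(np.asarray(values_b, dtype=float))
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        logger.warning("degenerate (zero) variance in both groups")
        if np.isclose(a.mean(), b.mean()):
            return TTestResult(0.0, 1.0, len(a), len(b))
        return TTestResult(math.copysign(math.inf, a.mean() - b.mean()), 0.0,
                           len(a), len(b))
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal replicate counts")
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(float(res.statistic), float(res.pvalue), len(a), len(b))


def compare_growth_curves(
    curve_a: pd.DataFrame,
    curve_b: pd.DataFrame,
    alpha: float = 0.025,
    equal_var: bool = True,
    paired: bool = False,
) -> pd.DataFrame:
    """Per-day t tests between two replicate-resolved growth curves.

    Inputs are long tables with columns replicate, day, cfu_per_ml (one
    strain each).  Only days present in both curves are compared; a day
    with fewer than two replicates on either side is skipped with a notice.
    Returns one row per shared day with the statistic, p-value and a
    significance flag at ``alpha``.
    """
    columns = ["day", "n_a", "n_b", "mean_log10_a", "mean_log10_b",
               "t", "p", "significant"]
    days = sorted(set(curve_a["day"]) & set(curve_b["day"]))
    rows = []
    for day in days:
        va = curve_a.loc[curve_a["day"] == day, "cfu_per_ml"].to_numpy(dtype=float)
        vb = curve_b.loc[curve_b["day"] == day, "cfu_per_ml"].to_numpy(dtype=float)
        if len(va) < 2 or len(vb) < 2:
            logger.info("day %s skipped: missing replicate", day)
            continue
        result = log_t_test(va, vb, equal_var=equal_var, paired=paired)
        rows.append(
            {
                "day": float(day),
                "n_a": result.n1,
                "n_b": result.n2,
                "mean_log10_a": float(np.mean(np.log10(va))),
                "mean_log10_b": float(np.mean(np.log10(vb))),
                "t": result.statistic,
                "p": result.pvalue,
                "significant": result.pvalue <= alpha,
            }
        )
    return pd.DataFrame(rows, columns=columns)


def competition_log_ratio(
    series: pd.DataFrame,
    strain1: str,
    strain2: str,
) -> pd.DataFrame:
    """Per-replicate, per-passage log10(strain1 / strain2) density ratio.

    ``series`` is a long table with columns replicate, passage, strain,
    cfu_per_ml and optionally below_detection.  A below-detection
    denominator right-censors the ratio (the true value is >= the computed
    bound); a below-detection numerator left-censors it.  Censored rows are
    flagged, never dropped here.
    """
    df = series.copy()
    if "below_detection" not in df.columns:
        df["below_detection"] = False
    rows = []
    for (rep, passage), group in df.groupby(["replicate", "passage"]):
        g1 = group[group["strain"] == strain1]
        g2 = group[group["strain"] == strain2]
        if len(g1) != 1 or len(g2) != 1:
            logger.info(
                "replicate %s passage %s: need exactly one row per strain; skipped",
                rep, passage,
            )
            continue
        v1 = float(g1["cfu_per_ml"].iloc[0])
        v2 = float(g2["cfu_per_ml"].iloc[0])
        bd1 = bool(g1["below_detection"].iloc[0])
        bd2 = bool(g2["below_detection"].iloc[0])
        value = math.log10(v1 / v2)
        if bd1 and bd2:
            direction = "indeterminate"
        elif bd2:
            direction = ">="
        elif bd1:
            direction = "<="
        else:
            direction = "="
        rows.append(
            {
                "replicate": rep,
                "passage": passage,
                "log10_ratio": value,
                "censored": direction != "=",
                "censor_direction": direction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["replicate", "passage", "log10_ratio", "censored",
                 "censor_direction"],
    )


def endpoint_test(
    series: pd.DataFrame,
    endpoint_passage: int,
    strain1: str,
    strain2: str,
    equal_var: bool = True,
) -> TTestResult:
    """Student's t test between the two strains at the endpoint passage.

    Compares log10 CFU/ml across replicates.  With a single replicate no
    test is possible — report the per-replicate log ratio instead.
    """
    at_end = series[series["passage"] == endpoint_passage]
    v1 = at_end.loc[at_end["strain"] == strain1, "cfu_per_ml"].to_numpy(dtype=float)
    v2 = at_end.loc[at_end["strain"] == strain2, "cfu_per_ml"].to_numpy(dtype=float)
    if len(v1) < 2 or len(v2) < 2:
        raise ValueError(
            "endpoint test needs >= 2 replicates per strain; with a single "
            "replicate report competition_log_ratio instead"
        )
    return log_t_test(v1, v2, equal_var=equal_var)


class SelectionEstimate(NamedTuple):
    """Least-squares selection-coefficient estimate.

    ``slope_per_generation`` is the slope of ln(strain1/strain2) per
    generation; ``growth_advantage`` is ``exp(slope) - 1``, the equivalent
    per-doubling fitness advantage s in the simulator's (1 + s) convention.
    """

    slope_per_generation: float
    stderr: float
    growth_advantage: float
    n_points: int


def estimate_selection_coefficient(
    log_ratios: pd.DataFrame,
    generations_per_passage: float,
) -> SelectionEstimate:
    """Selection coefficient from a competition log-ratio series.

    Fits ln-ratio against cumulative generations (passage number times
    ``generations_per_passage``) by ordinary least squares over all finite,
    uncensored points (censored points are dropped with a warning).
    """
    if generations_per_passage <= 0:
        raise ValueError("generations_per_passage must be > 0")
    df = log_ratios
    if "censored" in df.columns:
        n_censored = int(df["censored"].sum())
        if n_censored:
            logger.warning("dropping %d censored ratio points", n_censored)
        df = df[~df["censored"]]
    df = df[np.isfinite(df["log10_ratio"])]
    if df["passage"].nunique() < 2:
        raise ValueError("need finite ratios at >= 2 distinct passages")
    x = df["passage"].to_numpy(dtype=float) * generations_per_passage
    y = df["log10_ratio"].to_numpy(dtype=float) * math.log(10.0)
    fit = stats.linregress(x, y)
    stderr = float(fit.stderr) if np.isfinite(fit.stderr) else math.nan
    slope = float(fit.slope)
    return SelectionEstimate(slope, stderr, math.expm1(slope), len(df))
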
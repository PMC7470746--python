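"""Time-series estimators for growth, death, fitness and colony screens.

The statistics here follow the conventions of small-window slope fitting on
logged measurements: maximal growth rate is the steepest least-squares slope
of ln(intensity) over 4-point sliding windows restricted to the quarter of
maximal intensity (guaranteeing at least two doublings of headroom before
other nutrients bite); relative fitness in a two-genotype competition is the
steepest 3-point slope of ln(count ratio) per generation, divided by ln2 so
that a fitness of 1 means one extra doubling per generation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator

from .errors import EstimationError, InvalidArgumentError

__all__ = [
    "FluorescenceSeries",
    "RatioTrajectory",
    "FitnessResult",
    "ColonyClassCount",
    "DeathMetrics",
    "FrequencyDependence",
    "GrowthRateEstimator",
    "CompetitionFitnessEstimator",
    "max_growth_rate",
    "death_metrics",
    "competition_fitness",
    "frequency_dependence",
    "auxotroph_frequency",
]

LN2 = math.log(2.0)


@dataclass
class FluorescenceSeries:
    """Total-fluorescence time course, normalized to the first time point."""

    time: np.ndarray  # h, strictly increasing
    norm_intensity: np.ndarray  # dimensionless, >= 0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.norm_intensity = np.asarray(self.norm_intensity, dtype=float)
        if self.time.size != self.norm_intensity.size:
            raise InvalidArgumentError("time and intensity lengths differ")
        if self.time.size < 2 or np.any(np.diff(self.time) <= 0):
            raise InvalidArgumentError("time must be strictly increasing, >= 2 points")
        if np.any(self.norm_intensity < 0):
            raise InvalidArgumentError("intensity must be >= 0")

    @classmethod
    def from_raw(cls, time, intensity) -> "FluorescenceSeries":
        intensity = np.asarray(intensity, dtype=float)
        if intensity[0] <= 0:
            raise InvalidArgumentError("first intensity must be > 0 to normalize")
        return cls(time=np.asarray(time, float), norm_intensity=intensity / intensity[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.time, "norm_intensity": self.norm_intensity})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FluorescenceSeries":
        return cls(frame["time_h"].to_numpy(), frame["norm_intensity"].to_numpy())


@dataclass
class RatioTrajectory:
    """Two-genotype counts over generations (a = consumer, b = competitor)."""

    generation: np.ndarray
    count_a: np.ndarray
    count_b: np.ndarray

    def __post_init__(self) -> None:
        self.generation = np.asarray(self.generation, dtype=float)
        self.count_a = np.asarray(self.count_a, dtype=float)
        self.count_b = np.asarray(self.count_b, dtype=float)
        n = self.generation.size
        if self.count_a.size != n or self.count_b.size != n:
            raise InvalidArgumentError("trajectory columns must be equal length")
        if n < 2 or np.any(np.diff(self.generation) <= 0):
            raise InvalidArgumentError("generation axis must be strictly increasing")
        if np.any(self.count_a < 0) or np.any(self.count_b < 0):
            raise InvalidArgumentError("counts must be >= 0")

    def ratio(self) -> np.ndarray:
        if np.any(self.count_b <= 0):
            raise EstimationError("count_b must be > 0 wherever a ratio is formed")
        return self.count_a / self.count_b

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"generation": self.generation, "count_a": self.count_a, "count_b": self.count_b}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RatioTrajectory":
        return cls(
            frame["generation"].to_numpy(),
            frame["count_a"].to_numpy(),
            frame["count_b"].to_numpy(),
        )


@dataclass(frozen=True)
class FitnessResult:
    """Relative-fitness statistic with its window and starting frequency."""

    relative_fitness: float  # dimensionless: steepest slope of ln ratio / ln2
    window_start_index: int  # index of the first point of the chosen window
    start_fraction: float  # count_a/(count_a+count_b) at that point


@dataclass(frozen=True)
class ColonyClassCount:
    """One colony-size class of an auxotroph screen."""

    colonies_counted: int
    screened: int
    auxotrophs_found: int

    def __post_init__(self) -> None:
        if min(self.colonies_counted, self.screened, self.auxotrophs_found) < 0:
            raise InvalidArgumentError("screen counts must be >= 0")
        if self.auxotrophs_found > self.screened:
            raise InvalidArgumentError("auxotrophs_found cannot exceed screened")


@dataclass(frozen=True)
class DeathMetrics:
    endpoint_survival: float  # last/first intensity
    death_rate: float  # per hour, from the post-peak ln-intensity decline
    flag: Optional[str] = None  # "no_decline" when the series never falls


def _window_slope(t: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y vs t (handles uneven spacing)."""
    t = t - t.mean()
    return float((t * (y - y.mean())).sum() / (t * t).sum())


def max_growth_rate(
    series: FluorescenceSeries, window: int = 4, cutoff_fraction: float = 0.25
) -> float:
    """Steepest sliding-window slope of ln(intensity) vs time (per hour).

    Windows of ``window`` consecutive positive samples are eligible when
    their last point sits at or below ``cutoff_fraction`` of the series
    maximum, so the estimate is taken at least two doublings before the
    culture tops out.  If no window clears the cutoff (e.g. a flat series)
    all windows are used and a warning is issued.
    """
    t, intensity = series.time, series.norm_intensity
    positive = intensity > 0
    if not positive.all():
        warnings.warn("non-positive intensities excluded from growth-rate fit")
    threshold = cutoff_fraction * intensity[positive].max()
    slopes_eligible: List[float] = []
    slopes_all: List[float] = []
    for i in range(t.size - window + 1):
        seg = slice(i, i + window)
        if not positive[seg].all():
            continue
        slope = _window_slope(t[seg], np.log(intensity[seg]))
        slopes_all.append(slope)
        if intensity[i + window - 1] <= threshold:
            slopes_eligible.append(slope)
    if not slopes_all:
        raise EstimationError(f"need at least {window} consecutive positive points")
    if not slopes_eligible:
        warnings.warn(
            "no window below the intensity cutoff; using all windows instead"
        )
        slopes_eligible = slopes_all
    return max(slopes_eligible)


class GrowthRateEstimator(BaseEstimator):
    """Sklearn-style wrapper for :func:`max_growth_rate`."""

    def __init__(self, window: int = 4, cutoff_fraction: float = 0.25):
        self.window = window
        self.cutoff_fraction = cutoff_fraction

    def fit(self, series: FluorescenceSeries, y=None) -> "GrowthRateEstimator":
        self.growth_rate_ = max_growth_rate(series, self.window, self.cutoff_fraction)
        return self


def death_metrics(series: FluorescenceSeries) -> DeathMetrics:
    """Endpoint survival and the exponential death rate after the peak.

    survival = last/first intensity; death rate = minus the least-squares
    slope of ln(intensity) over the declining segment from the global
    maximum (first occurrence) to the end.  A series that never declines
    gets rate 0 with a ``no_decline`` flag.
    """
    intensity = series.norm_intensity
    if intensity[0] <= 0:
        raise EstimationError("first intensity must be > 0")
    survival = float(intensity[-1] / intensity[0])
    peak = int(np.argmax(intensity))
    if peak == intensity.size - 1:
        return DeathMetrics(survival, 0.0, flag="no_decline")
    seg = slice(peak, None)
    t_seg, i_seg = series.time[seg], intensity[seg]
    pos = i_seg > 0
    if pos.sum() < 2:
        raise EstimationError("not enough positive points after the peak")
    slope = _window_slope(t_seg[pos], np.log(i_seg[pos]))
    return DeathMetrics(survival, -slope, flag=None)


def competition_fitness(traj: RatioTrajectory, window: int = 3) -> FitnessResult:
    """Steepest 3-point slope of ln(count_a/count_b) per generation, over ln2.

    Windows containing a zero count are skipped; among equally steep windows
    the earliest wins.  start_fraction is count_a/(count_a+count_b) at the
    first point of the chosen window.
    """
    gen, a, b = traj.generation, traj.count_a, traj.count_b
    best: Optional[Tuple[float, int]] = None
    for i in range(gen.size - window + 1):
        seg = slice(i, i + window)
        if np.any(a[seg] <= 0) or np.any(b[seg] <= 0):
            continue
        slope = _window_slope(gen[seg], np.log(a[seg] / b[seg]))
        if best is None or slope > best[0]:
            best = (slope, i)
    if best is None:
        raise EstimationError("no 3-point window with positive counts in both channels")
    slope, i = best
    return FitnessResult(
        relative_fitness=slope / LN2,
        window_start_index=i,
        start_fraction=float(a[i] / (a[i] + b[i])),
    )


class CompetitionFitnessEstimator(BaseEstimator):
    """Sklearn-style wrapper for :func:`competition_fitness`."""

    def __init__(self, window: int = 3):
        self.window = window

    def fit(self, traj: RatioTrajectory, y=None) -> "CompetitionFitnessEstimator":
        result = competition_fitness(traj, self.window)
        self.relative_fitness_ = result.relative_fitness
        self.window_start_index_ = result.window_start_index
        self.start_fraction_ = result.start_fraction
        return self


@dataclass
class FrequencyDependence:
    """Paired (start_fraction, relative_fitness) table with a rank summary."""

    table: pd.DataFrame
    rank_correlation: float  # Spearman rho; NaN when undefined
    sign: Optional[int]  # -1/0/+1, None when the correlation is undefined


def frequency_dependence(results: Sequence[FitnessResult]) -> FrequencyDependence:
    """Relative fitness against starting frequency, with rank-correlation sign.

    A negative sign is the signature of negative frequency-dependent
    selection: the advantage shrinks as the genotype becomes common.
    """
    if len(results) == 0:
        raise InvalidArgumentError("need at least one fitness result")
    table = pd.DataFrame(
        {
            "start_fraction": [r.start_fraction for r in results],
            "relative_fitness": [r.relative_fitness for r in results],
        }
    ).sort_values("start_fraction", ignore_index=True)
    if len(results) < 2 or table["relative_fitness"].nunique() == 1:
        return FrequencyDependence(table, float("nan"), None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = spearmanr(table["start_fraction"], table["relative_fitness"]).statistic
    if np.isnan(rho):
        return FrequencyDependence(table, float("nan"), None)
    return FrequencyDependence(table, float(rho), int(np.sign(rho)))


def auxotroph_frequency(classes: Iterable[ColonyClassCount]) -> float:
    """Colony-size-weighted auxotroph frequency across size classes.

    Each class contributes (its share of counted colonies) × (auxotroph
    fraction among the colonies screened from that class).
    """
    classes = [
        c if isinstance(c, ColonyClassCount) else ColonyClassCount(*c) for c in classes
    ]
    total = sum(c.colonies_counted for c in classes)
    if total <= 0:
        raise InvalidArgumentError("total colonies counted must be > 0")
    freq = 0.0
    for c in classes:
        if c.colonies_counted == 0:
            continue
        if c.screened == 0:
            raise EstimationError("a class with colonies was never screened")
        freq += (c.colonies_counted / total) * (c.auxotrophs_found / c.screened)
    return freq
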
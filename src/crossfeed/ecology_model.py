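"""Releaser–consumer–organosulfur chemostat ecology.

A nutrient-limited "releaser" population (e.g. a lysine auxotroph growing in a
lysine-limited chemostat) exports an organosulfur pool (glutathione and its
conjugates, counted in GSH equivalents) at a per-cell rate ``r``.  A second,
organosulfur-requiring "consumer" population grows on that pool, spending ``c``
fmole per cell division.  At steady state the organosulfur balance

    dO/dt = r·R − c·g·C = 0

predicts the consumer-to-releaser ratio C/R = r/(c·g), where ``g`` is the
shared growth rate (equal to the dilution rate in a chemostat).  This module
houses that model, the release-rate estimator r = dil·[orgS]_ss/[Live]_ss,
dead-cell lysis attribution, and the culture-device arithmetic (flow rate,
dilution rate, photodetector OD).

Units: concentrations in fmole/mL (1 μM = 1e6 fmole/mL), densities in
cells/mL, time in hours, generations = time·g/ln2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from sklearn.base import BaseEstimator

from .errors import EstimationError, InvalidArgumentError, NumericalError

__all__ = [
    "LN2",
    "UM_TO_FMOLE_PER_ML",
    "EcologyParams",
    "CultureSeries",
    "CultureConfig",
    "CocultureState",
    "LiveReleaseAttribution",
    "ReleaseRateEstimator",
    "flow_rate",
    "dilution_rate",
    "od_from_intensity",
    "estimate_release_rate",
    "per_cell_content",
    "dead_release_bound",
    "attribute_live_release",
    "predict_steady_ratio",
    "steady_state_organosulfur",
    "coculture_fixed_point",
    "simulate_coculture",
]

LN2 = math.log(2.0)

#: 1 μM expressed in the internal concentration unit (fmole/mL).
UM_TO_FMOLE_PER_ML = 1.0e6


@dataclass(frozen=True)
class EcologyParams:
    """Constants of the releaser–consumer–organosulfur model.

    Parameters
    ----------
    r : float
        Organosulfur release rate, fmole GSH-equivalent per releaser cell
        per hour.
    c : float
        Organosulfur consumed per consumer birth, fmole per cell.
    g : float
        Shared growth rate at steady state (= dilution rate in a chemostat),
        per hour.
    dil : float
        Dilution rate of the culture device, per hour.
    gmax_consumer : float
        Maximal consumer growth rate for the Monod uptake closure, per hour.
    K_half : float
        Organosulfur half-saturation of consumer growth, fmole/mL.
    """

    r: float = 0.02
    c: float = 2.0
    g: float = LN2 / 8.0
    dil: float = LN2 / 8.0
    gmax_consumer: float = 0.35
    K_half: float = 1.0e5

    def __post_init__(self) -> None:
        for name in ("r", "c", "g", "dil", "gmax_consumer", "K_half"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise InvalidArgumentError(
                    f"EcologyParams.{name} must be finite and >= 0, got {value!r}"
                )


@dataclass
class CultureSeries:
    """Timestamped live/dead densities and metabolite level from one vessel."""

    time: np.ndarray  # h, strictly increasing
    live_density: np.ndarray  # cells/mL
    dead_density: np.ndarray  # cells/mL
    metabolite: np.ndarray  # fmole/mL, GSH equivalents

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.live_density = np.asarray(self.live_density, dtype=float)
        self.dead_density = np.asarray(self.dead_density, dtype=float)
        self.metabolite = np.asarray(self.metabolite, dtype=float)
        n = self.time.size
        for name in ("live_density", "dead_density", "metabolite"):
            col = getattr(self, name)
            if col.size != n:
                raise InvalidArgumentError(
                    f"CultureSeries.{name} has {col.size} rows, expected {n}"
                )
            if np.any(col < 0):
                raise InvalidArgumentError(f"CultureSeries.{name} must be >= 0")
        if n < 1 or np.any(np.diff(self.time) <= 0):
            raise InvalidArgumentError("CultureSeries.time must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.time,
                "live_per_ml": self.live_density,
                "dead_per_ml": self.dead_density,
                "metabolite_fmole_per_ml": self.metabolite,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CultureSeries":
        return cls(
            time=frame["time_h"].to_numpy(),
            live_density=frame["live_per_ml"].to_numpy(),
            dead_density=frame["dead_per_ml"].to_numpy(),
            metabolite=frame["metabolite_fmole_per_ml"].to_numpy(),
        )


@dataclass(frozen=True)
class CultureConfig:
    """Continuous-culture device settings (chemostat or turbidostat)."""

    vessel_volume: float  # mL
    doubling_time: float  # h
    reservoir_conc: float = 21.0  # μM limiting nutrient
    mode: str = "chemostat"
    od_setpoint: Optional[float] = None  # turbidostat only

    def __post_init__(self) -> None:
        if self.vessel_volume <= 0:
            raise InvalidArgumentError("vessel_volume must be > 0")
        if self.doubling_time <= 0:
            raise InvalidArgumentError("doubling_time must be > 0")
        if self.mode not in ("chemostat", "turbidostat"):
            raise InvalidArgumentError(f"unknown culture mode {self.mode!r}")


@dataclass(frozen=True)
class CocultureState:
    """State of a two-genotype coculture: densities plus the shared pool."""

    R: float  # releaser, cells/mL
    C: float  # consumer, cells/mL
    O: float  # organosulfur, fmole/mL

    def __post_init__(self) -> None:
        if self.R < 0 or self.C < 0 or self.O < 0:
            raise InvalidArgumentError("CocultureState components must be >= 0")


def flow_rate(config: CultureConfig) -> float:
    """Medium flow rate (mL/h) that yields the configured doubling time.

    f = ln(2) · V / T_D for a vessel of volume V run at doubling time T_D.
    """
    return LN2 * config.vessel_volume / config.doubling_time


def dilution_rate(doubling_time: float) -> float:
    """Dilution rate (per hour) equivalent to a doubling time: ln2 / T_D."""
    if not doubling_time > 0:
        raise InvalidArgumentError("doubling_time must be > 0")
    return LN2 / doubling_time


def od_from_intensity(I: float, I0: float, conventional: bool = False) -> float:
    """Optical density from photodetector intensity.

    The culture device logs OD = log10(I/I0) against the blank intensity I0
    (the device's own convention; turbidity then drives the reading negative).
    With ``conventional=True`` the sign is flipped to the textbook
    −log10(I/I0) attenuation.
    """
    if not (I > 0 and I0 > 0):
        raise InvalidArgumentError("intensities must be > 0")
    od = math.log10(I / I0)
    return -od if conventional else od


def estimate_release_rate(
    series: CultureSeries,
    dil: float,
    steady_window: Optional[Tuple[float, float]] = None,
) -> float:
    """Per-cell metabolite release rate from a steady-state culture.

    r = dil × mean([orgS]) / mean([Live]) over the steady-state window
    (default: the last quarter of the series).
    """
    if dil < 0:
        raise InvalidArgumentError("dil must be >= 0")
    t0, t1 = float(series.time[0]), float(series.time[-1])
    if steady_window is None:
        steady_window = (t0 + 0.75 * (t1 - t0), t1)
    lo, hi = steady_window
    if lo > hi or lo < t0 or hi > t1:
        raise InvalidArgumentError(
            f"steady_window {steady_window} outside data span ({t0}, {t1})"
        )
    mask = (series.time >= lo) & (series.time <= hi)
    if not mask.any():
        raise InvalidArgumentError("steady_window contains no samples")
    live = series.live_density[mask]
    if np.any(live <= 0):
        raise EstimationError("live density must be > 0 throughout the window")
    return dil * float(series.metabolite[mask].mean()) / float(live.mean())


class ReleaseRateEstimator(BaseEstimator):
    """Sklearn-style wrapper around :func:`estimate_release_rate`.

    Parameters
    ----------
    dil : float
        Dilution rate of the culture, per hour.
    steady_window : tuple of float, optional
        Explicit (start, end) of the steady-state window in hours; by
        default the last ``window_fraction`` of the series is used.
    window_fraction : float
        Fraction of the time span treated as steady state when no explicit
        window is given.
    """

    def __init__(self, dil: float = LN2 / 8.0,
                 steady_window: Optional[Tuple[float, float]] = None,
                 window_fraction: float = 0.25):
        self.dil = dil
        self.steady_window = steady_window
        self.window_fraction = window_fraction

    def fit(self, series: CultureSeries, y=None) -> "ReleaseRateEstimator":
        window = self.steady_window
        if window is None:
            t0, t1 = float(series.time[0]), float(series.time[-1])
            window = (t1 - self.window_fraction * (t1 - t0), t1)
        self.window_ = window
        self.release_rate_ = estimate_release_rate(series, self.dil, window)
        self.n_samples_ = int(
            ((series.time >= window[0]) & (series.time <= window[1])).sum()
        )
        return self


def per_cell_content(total_metabolite: float, total_cells: float) -> float:
    """Average metabolite per cell (fmole/cell) from a bulk extract."""
    if total_metabolite < 0:
        raise InvalidArgumentError("total_metabolite must be >= 0")
    if not total_cells > 0:
        raise InvalidArgumentError("total_cells must be > 0")
    return total_metabolite / total_cells


def dead_release_bound(dead_density: float, content: float) -> float:
    """Upper bound on supernatant concentration explainable by dead-cell lysis.

    The product of dead-cell density (cells/mL) and average per-cell content
    (fmole/cell): the concentration reached if every dead cell lysed and
    released its entire store.
    """
    if dead_density < 0 or content < 0:
        raise InvalidArgumentError("inputs must be >= 0")
    return dead_density * content


@dataclass(frozen=True)
class LiveReleaseAttribution:
    """Outcome of comparing a measured pool with the dead-lysis bound."""

    measured: float  # fmole/mL
    bound: float  # fmole/mL
    excess: float  # fmole/mL, measured − bound (may be negative)
    live_release: bool  # True when measured exceeds the dead-cell bound


def attribute_live_release(
    measured: float, dead_density: float, content: float
) -> LiveReleaseAttribution:
    """Flag release as live-cell-driven when it exceeds the dead-lysis bound."""
    if measured < 0:
        raise InvalidArgumentError("measured concentration must be >= 0")
    bound = dead_release_bound(dead_density, content)
    return LiveReleaseAttribution(
        measured=measured,
        bound=bound,
        excess=measured - bound,
        live_release=measured > bound,
    )


def predict_steady_ratio(params: EcologyParams) -> float:
    """Predicted steady-state consumer-to-releaser ratio C/R = r/(c·g)."""
    if params.c == 0 or params.g == 0:
        raise InvalidArgumentError("c and g must be > 0 for a steady-state ratio")
    return params.r / (params.c * params.g)


def steady_state_organosulfur(params: EcologyParams) -> float:
    """Pool level O* at which the consumer grows exactly at rate g.

    From the Monod closure g = gmax·O/(K+O): O* = K·g/(gmax − g).
    """
    if params.gmax_consumer <= params.g:
        raise InvalidArgumentError(
            "gmax_consumer must exceed g for a coexistence steady state"
        )
    return params.K_half * params.g / (params.gmax_consumer - params.g)


def coculture_fixed_point(params: EcologyParams, total_density: float) -> float:
    """Exact fixed-point ratio C/R of the closed serial-dilution model.

    The closed model dilutes the pool alongside the cells, so its fixed point
    sits slightly below the idealized r/(c·g): with O* = K·g/(gmax−g) and
    total density N, solving r·R = c·g·C + g·O* at R = N/(1+x) gives

        x = (r − g·O*/N) / (c·g + g·O*/N).

    The correction term g·O*/N (fmole/cell/h) is the pool washout charged
    per releaser cell; it vanishes as N → ∞.
    """
    if not total_density > 0:
        raise InvalidArgumentError("total_density must be > 0")
    o_star = steady_state_organosulfur(params)
    loss = params.g * o_star / total_density
    if params.r <= loss:
        return 0.0
    return (params.r - loss) / (params.c * params.g + loss)


def _coculture_rhs(t, y, params: EcologyParams, mode: str):
    R, C, O = max(y[0], 0.0), max(y[1], 0.0), max(y[2], 0.0)
    gC = params.gmax_consumer * O / (params.K_half + O) if O > 0 else 0.0
    if mode == "serial":
        total = R + C
        d_eff = (params.g * R + gC * C) / total if total > 0 else 0.0
    elif mode == "chemostat":
        d_eff = params.dil
    else:  # batch: no dilution, used for mass-budget checks
        d_eff = 0.0
    dR = (params.g - d_eff) * R
    dC = (gC - d_eff) * C
    dO = params.r * R - params.c * gC * C - d_eff * O
    # two auxiliary integrals: cumulative releaser cell-hours and consumer births
    return (dR, dC, dO, R, gC * C)


def simulate_coculture(
    params: EcologyParams,
    init: CocultureState,
    duration: float,
    step: float = 1.0,
    mode: str = "serial",
    rtol: float = 1e-8,
) -> pd.DataFrame:
    """Integrate the closed releaser–consumer–organosulfur dynamics.

    The organosulfur balance dO/dt = r·R − c·g_C(O)·C − d_eff·O is closed
    with Monod consumer uptake g_C(O) = gmax·O/(K+O) and an effective
    dilution d_eff that either holds total cell density constant
    (``mode="serial"``, mimicking periodic dilution of batch cocultures),
    equals the device dilution rate (``mode="chemostat"``) or is zero
    (``mode="batch"``, for mass-budget checks).  Populations follow
    dR/dt = (g − d_eff)·R and dC/dt = (g_C − d_eff)·C.

    Returns a tidy frame with columns time_h, generation, releaser_per_ml,
    consumer_per_ml, orgs_fmole_per_ml, ratio (C/R), plus the running
    integrals cum_releaser_cell_h and cum_consumer_births used by
    conservation checks.
    """
    if mode not in ("serial", "chemostat", "batch"):
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    if not (duration > 0 and step > 0):
        raise InvalidArgumentError("duration and step must be > 0")
    t_eval = np.arange(0.0, duration + step / 2.0, step)
    y0 = (init.R, init.C, init.O, 0.0, 0.0)
    scale = max(init.R + init.C, init.O, 1.0)
    sol = solve_ivp(
        _coculture_rhs,
        (0.0, float(t_eval[-1])),
        y0,
        t_eval=t_eval,
        args=(params, mode),
        method="LSODA",
        rtol=rtol,
        atol=rtol * scale,
    )
    if not sol.success:
        raise NumericalError(f"coculture integration failed: {sol.message}")
    R, C, O = sol.y[0], sol.y[1], sol.y[2]
    neg_tol = 1e-6 * scale
    if min(R.min(), C.min(), O.min()) < -neg_tol:
        raise NumericalError("trajectory went negative beyond tolerance")
    R, C, O = np.maximum(R, 0.0), np.maximum(C, 0.0), np.maximum(O, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(R > 0, C / np.where(R > 0, R, 1.0), np.inf)
    return pd.DataFrame(
        {
            "time_h": sol.t,
            "generation": sol.t * params.g / LN2,
            "releaser_per_ml": R,
            "consumer_per_ml": C,
            "orgs_fmole_per_ml": O,
            "ratio": ratio,
            "cum_releaser_cell_h": sol.y[3],
            "cum_consumer_births": sol.y[4],
        }
    )
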
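"""Synthetic inputs with the statistical structure the analysis assumes.

Every table the pipeline consumes can be generated here: lysine-limited
chemostat time series approaching steady state, fluorescence-derivatized
glutathione chromatograms on a drifting baseline, yield-based bioassay
plates, coculture log-ratio trajectories, and grow-then-die fluorescence
time courses.  Noise models: multiplicative log-normal (unit mean) on
positive-valued measurements (densities, OD, intensities), additive
Gaussian on chromatogram detector signal, binomial sampling on competition
counts.  Fixed seed plus fixed parameters gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .ecology_model import (
    LN2,
    CocultureState,
    CultureSeries,
    EcologyParams,
    simulate_coculture,
    steady_state_organosulfur,
)
from .errors import InvalidArgumentError, NumericalError
from .kinetics_fitness import FluorescenceSeries, RatioTrajectory

__all__ = [
    "NoiseSpec",
    "ChromatogramSpec",
    "DEATH_RATE_PRESETS",
    "LYSINE_YIELD_CELLS_PER_UM",
    "gen_chemostat_series",
    "gen_chromatogram",
    "gen_bioassay_plate",
    "gen_competition",
    "gen_fluorescence_series",
]

#: cells/mL per μM of limiting lysine: 7e6 cells/mL from 21 μM reservoir.
LYSINE_YIELD_CELLS_PER_UM = 7.0e6 / 21.0

#: per-capita death rate presets (per hour) contrasting the two limitations.
DEATH_RATE_PRESETS = {"lysine": 0.10, "glucose": 0.01}


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise settings shared by all generators.

    relative_sd is a dimensionless fraction applied multiplicatively
    (log-normal, unit mean); additive_sd is in the units of the signal it
    perturbs.  The same seed and parameters always reproduce the same draw.
    """

    relative_sd: float = 0.0
    additive_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sd < 0 or self.additive_sd < 0:
            raise InvalidArgumentError("noise standard deviations must be >= 0")

    @property
    def silent(self) -> bool:
        return self.relative_sd == 0 and self.additive_sd == 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def multiplicative(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Unit-mean log-normal factors with relative sd ``relative_sd``."""
        if self.relative_sd == 0:
            return np.ones(n)
        sigma = math.sqrt(math.log1p(self.relative_sd**2))
        return np.exp(rng.normal(-sigma**2 / 2.0, sigma, n))


@dataclass(frozen=True)
class ChromatogramSpec:
    """Shape of a synthetic chromatogram: Gaussian peaks on a linear baseline."""

    peaks: Tuple[Tuple[float, float, float], ...] = ((7.0, 100.0, 0.05),)
    baseline_slope: float = 0.0  # signal/min
    baseline_intercept: float = 0.0  # signal units
    sampling_interval: float = 0.005  # min
    time_range: Tuple[float, float] = (6.0, 9.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(tuple(p) for p in self.peaks))
        lo, hi = self.time_range
        if not lo < hi:
            raise InvalidArgumentError("time_range must be non-empty (lo < hi)")
        if self.sampling_interval <= 0:
            raise InvalidArgumentError("sampling_interval must be > 0")
        for rt, amp, sigma in self.peaks:
            if sigma <= 0:
                raise InvalidArgumentError("peak width_sigma must be > 0")
            if rt - 4 * sigma < lo or rt + 4 * sigma > hi:
                raise InvalidArgumentError(
                    f"time_range must cover peak at {rt} min +/- 4 sigma"
                )


def gen_chemostat_series(
    params: EcologyParams,
    reservoir_conc: float = 21.0,
    duration: float = 120.0,
    step: float = 1.0,
    noise: NoiseSpec = NoiseSpec(),
    *,
    death_rate: Optional[float] = None,
    limitation: str = "lysine",
    yield_cells_per_uM: float = LYSINE_YIELD_CELLS_PER_UM,
    gmax_growth: float = LN2 / 1.6,
    K_nutrient_uM: float = 0.5,
    inoculum_per_ml: float = 1.0e5,
) -> CultureSeries:
    """Single-population chemostat run approaching steady state.

    Live cells grow on the limiting nutrient with Monod kinetics
    (gmax ``gmax_growth``, half-saturation ``K_nutrient_uM``), die at a
    constant per-capita rate (preset by ``limitation`` unless ``death_rate``
    is given), and are washed out at ``params.dil``; dead cells accumulate
    and wash out at the same rate; the metabolite pool obeys
    dO/dt = r·N_live − dil·O.  With a 21 μM reservoir and the lysine yield
    constant the zero-death steady state sits at ~7e6 live cells/mL.
    """
    if not (duration > 0 and step > 0):
        raise InvalidArgumentError("duration and step must be > 0")
    if reservoir_conc < 0 or inoculum_per_ml <= 0:
        raise InvalidArgumentError("reservoir_conc >= 0 and inoculum > 0 required")
    if death_rate is None:
        if limitation not in DEATH_RATE_PRESETS:
            raise InvalidArgumentError(f"unknown limitation preset {limitation!r}")
        death_rate = DEATH_RATE_PRESETS[limitation]
    if death_rate < 0:
        raise InvalidArgumentError("death_rate must be >= 0")

    dil, r = params.dil, params.r

    def rhs(t, y):
        N, D, L, O = (max(v, 0.0) for v in y)
        gN = gmax_growth * L / (K_nutrient_uM + L) if L > 0 else 0.0
        dN = (gN - death_rate - dil) * N
        dD = death_rate * N - dil * D
        dL = dil * (reservoir_conc - L) - gN * N / yield_cells_per_uM
        dO = r * N - dil * O
        return (dN, dD, dL, dO)

    t_eval = np.arange(0.0, duration + step / 2.0, step)
    sol = solve_ivp(
        rhs,
        (0.0, float(t_eval[-1])),
        (inoculum_per_ml, 0.0, reservoir_conc, 0.0),
        t_eval=t_eval,
        method="LSODA",
        rtol=1e-8,
        atol=1e-8 * max(inoculum_per_ml, reservoir_conc, 1.0),
    )
    if not sol.success:
        raise NumericalError(f"chemostat integration failed: {sol.message}")
    live, dead, metab = (np.maximum(sol.y[i], 0.0) for i in (0, 1, 3))
    rng = noise.rng()
    n = t_eval.size
    live = live * noise.multiplicative(rng, n)
    dead = dead * noise.multiplicative(rng, n)
    metab = metab * noise.multiplicative(rng, n)
    return CultureSeries(sol.t, live, dead, metab)


def gen_chromatogram(spec: ChromatogramSpec, noise: NoiseSpec = NoiseSpec()) -> pd.DataFrame:
    """Gaussian peaks plus a linear baseline plus additive detector noise.

    Returns a frame with columns rt_min (strictly increasing) and signal.
    """
    lo, hi = spec.time_range
    rt = np.arange(lo, hi + spec.sampling_interval / 2.0, spec.sampling_interval)
    signal = spec.baseline_intercept + spec.baseline_slope * rt
    for center, amplitude, sigma in spec.peaks:
        signal = signal + amplitude * np.exp(-((rt - center) ** 2) / (2.0 * sigma**2))
    if noise.additive_sd > 0:
        signal = signal + noise.rng().normal(0.0, noise.additive_sd, rt.size)
    return pd.DataFrame({"rt_min": rt, "signal": signal})


_GSSG_LABELS = {"GSSG", "GS-SG"}


def gen_bioassay_plate(
    curve_slope: float,
    blank_od: float,
    saturation_od: float,
    concs: Sequence[float],
    replicates: int = 3,
    noise: NoiseSpec = NoiseSpec(),
    compounds: Sequence[str] = ("GSH",),
) -> pd.DataFrame:
    """Yield-based bioassay plate: tester-strain final OD vs concentration.

    final OD = min(blank + slope·conc_equiv, saturation) × noise, where the
    GSH-equivalent concentration of a GS-SG well is twice its molar
    concentration (one disulfide reduces to two GSH).  Columns: compound,
    conc_uM, replicate, od600.
    """
    concs = np.asarray(list(concs), dtype=float)
    if np.any(concs < 0):
        raise InvalidArgumentError("concentrations must be >= 0")
    if replicates < 1:
        raise InvalidArgumentError("replicates must be >= 1")
    if curve_slope < 0 or blank_od < 0 or saturation_od < blank_od:
        raise InvalidArgumentError("slope, blank >= 0 and saturation >= blank required")
    rng = noise.rng()
    rows = []
    for compound in compounds:
        factor = 2.0 if compound.upper() in _GSSG_LABELS else 1.0
        for conc in concs:
            expected = min(blank_od + curve_slope * factor * conc, saturation_od)
            factors = noise.multiplicative(rng, replicates)
            for rep in range(replicates):
                rows.append(
                    {
                        "compound": compound,
                        "conc_uM": conc,
                        "replicate": rep,
                        "od600": expected * factors[rep],
                    }
                )
    return pd.DataFrame(rows)


def gen_competition(
    params: EcologyParams,
    init_ratio: float,
    n_generations: int,
    sampling_counts: int = 10_000,
    noise: NoiseSpec = NoiseSpec(),
    total_density: float = 3.0e6,
    mode: str = "serial",
) -> RatioTrajectory:
    """Two-genotype competition counts sampled once per generation.

    The deterministic consumer fraction comes from the coculture model; at
    each generation ``sampling_counts`` events are scored.  With silent
    noise the expected (real-valued) counts are emitted; otherwise counts
    are binomial draws, mimicking flow-cytometry sampling.  count_a is the
    consumer, count_b the releaser-background competitor.
    """
    if not init_ratio > 0:
        raise InvalidArgumentError("init_ratio must be > 0")
    if n_generations < 3:
        raise InvalidArgumentError("n_generations must be >= 3")
    if sampling_counts < 1:
        raise InvalidArgumentError("sampling_counts must be >= 1")
    C0 = total_density * init_ratio / (1.0 + init_ratio)
    R0 = total_density - C0
    O0 = steady_state_organosulfur(params)
    gen_step_h = LN2 / params.g
    traj = simulate_coculture(
        params,
        CocultureState(R=R0, C=C0, O=O0),
        duration=n_generations * gen_step_h,
        step=gen_step_h,
        mode=mode,
    )
    total = traj["releaser_per_ml"] + traj["consumer_per_ml"]
    fraction = (traj["consumer_per_ml"] / total).to_numpy()
    generations = traj["generation"].to_numpy()
    if noise.silent:
        count_a = fraction * sampling_counts
        count_b = (1.0 - fraction) * sampling_counts
    else:
        rng = noise.rng()
        count_a = rng.binomial(sampling_counts, np.clip(fraction, 0.0, 1.0)).astype(float)
        count_b = sampling_counts - count_a
    return RatioTrajectory(generation=generations, count_a=count_a, count_b=count_b)


def gen_fluorescence_series(
    growth_rate: float,
    death_rate: float,
    switch_time: float,
    duration: float,
    step: float = 0.5,
    noise: NoiseSpec = NoiseSpec(),
) -> FluorescenceSeries:
    """Grow-then-die fluorescence time course, normalized to time zero.

    log intensity rises at ``growth_rate`` until ``switch_time`` and falls
    at ``death_rate`` afterwards; after multiplicative noise the series is
    re-normalized so the first sample is exactly 1.
    """
    if not duration > 0:
        raise InvalidArgumentError("duration must be > 0")
    if step <= 0:
        raise InvalidArgumentError("step must be > 0")
    if growth_rate < 0 or death_rate < 0 or switch_time < 0:
        raise InvalidArgumentError("rates and switch_time must be >= 0")
    t = np.arange(0.0, duration + step / 2.0, step)
    log_i = growth_rate * np.minimum(t, switch_time) - death_rate * np.maximum(
        0.0, t - switch_time
    )
    intensity = np.exp(log_i)
    if not noise.silent:
        intensity = intensity * noise.multiplicative(noise.rng(), t.size)
    intensity = intensity / intensity[0]
    return FluorescenceSeries(time=t, norm_intensity=intensity)
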
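"""Yield- and rate-based auxotroph bioassays for organosulfur quantification.

A tester strain that cannot synthesize organosulfurs converts the unknown
pool in a supernatant into growth: in yield mode the final turbidity of a
saturated microplate culture is compared against known GSH standards (the
result is expressed in GSH equivalents, with one GS-SG disulfide counting as
two GSH); in rate mode the maximal growth rate of the tester is inverted
through a monotone (concentration, rate) calibration, as used for
methionine-equivalent niche estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import CalibrationError, InvalidArgumentError
from .hplc_quant import LinearCalibration, StandardCurve
from .kinetics_fitness import FluorescenceSeries, max_growth_rate

__all__ = [
    "GSSG_TO_GSH_EQUIVALENTS",
    "DEFAULT_YIELD_LINEAR_RANGE",
    "EquivalentResult",
    "YieldBioassay",
    "RateBioassay",
    "fit_yield_curve",
    "infer_gsh_equivalents",
    "gssg_to_equivalents",
    "rate_bioassay",
]

#: GSH molecules produced by reducing one GS-SG disulfide.
GSSG_TO_GSH_EQUIVALENTS = 2.0

#: default linear range (μM GSH) of the yield-based standard curve.
DEFAULT_YIELD_LINEAR_RANGE: Tuple[float, float] = (0.0, 2.0)


@dataclass(frozen=True)
class EquivalentResult:
    """Organosulfur concentration in tester-strain equivalents, with a flag."""

    estimate: float  # μM GSH equivalents (methionine equivalents in rate mode)
    flag: str  # "ok" | "below_detection" | "above_range"
    stderr: Optional[float] = None  # propagated from the calibration fit


def fit_yield_curve(
    standards: pd.DataFrame,
    compound: str = "GSH",
    linear_range: Tuple[float, float] = DEFAULT_YIELD_LINEAR_RANGE,
) -> StandardCurve:
    """OLS fit of mean final OD vs concentration over the linear range.

    ``standards`` is a plate table with columns compound, conc_uM, od600
    (replicate optional).  Replicates are summarized by their mean; the
    detection floor is the blank mean plus two blank standard deviations.
    Standards outside ``linear_range`` (e.g. a saturating top point) are
    excluded from the fit.  Without blank wells a warning is issued and the
    floor falls back to the lowest standard's mean OD.
    """
    rows = standards[standards["compound"] == compound]
    if rows.empty:
        raise CalibrationError(f"no standards for compound {compound!r}")
    lo, hi = linear_range
    in_range = rows[(rows["conc_uM"] >= lo) & (rows["conc_uM"] <= hi)]
    means = in_range.groupby("conc_uM")["od600"].mean()
    if means.size < 2:
        raise CalibrationError("need >= 2 distinct standard concentrations in range")
    blanks = rows[rows["conc_uM"] == 0]["od600"]
    if blanks.empty:
        warnings.warn("no blank wells; detection floor set from the lowest standard")
        floor = float(means.iloc[0])
    else:
        sd = float(blanks.std(ddof=1)) if blanks.size > 1 else 0.0
        floor = float(blanks.mean()) + 2.0 * sd
    cal = LinearCalibration().fit(means.index.to_numpy(), means.to_numpy())
    return StandardCurve(
        points=pd.DataFrame(
            {"concentration": means.index.to_numpy(), "response": means.to_numpy()}
        ),
        slope=cal.slope_,
        intercept=cal.intercept_,
        valid_range=cal.valid_range_,
        detection_floor=floor,
        slope_stderr=cal.slope_stderr_,
        intercept_stderr=cal.intercept_stderr_,
    )


def infer_gsh_equivalents(unknown_od: float, curve: StandardCurve) -> EquivalentResult:
    """Invert the yield curve: OD → μM GSH equivalents, with range flags.

    OD at or below the detection floor flags ``below_detection``; estimates
    beyond the calibrated maximum flag ``above_range``.  The point estimate
    is always reported alongside the flag.
    """
    conc = curve.inverse(unknown_od)
    flag = "ok"
    if curve.detection_floor is not None and unknown_od <= curve.detection_floor:
        flag = "below_detection"
    elif conc > curve.valid_range[1]:
        flag = "above_range"
    stderr = None
    if np.isfinite(curve.slope_stderr) and curve.slope != 0:
        # first-order propagation of the fit uncertainty through the inversion
        stderr = float(
            np.hypot(curve.intercept_stderr, conc * curve.slope_stderr)
            / abs(curve.slope)
        )
    return EquivalentResult(estimate=float(conc), flag=flag, stderr=stderr)


def gssg_to_equivalents(conc_gssg: float) -> float:
    """GS-SG concentration (μM) → GSH equivalents (μM): exactly twice."""
    if conc_gssg < 0:
        raise InvalidArgumentError("concentration must be >= 0")
    return GSSG_TO_GSH_EQUIVALENTS * conc_gssg


def rate_bioassay(
    series: FluorescenceSeries,
    rate_curve: Sequence[Tuple[float, float]],
) -> EquivalentResult:
    """Rate-based bioassay: invert a monotone (conc, max growth rate) curve.

    The tester's maximal growth rate is computed with the 4-point sliding
    window estimator, then mapped to concentration by monotone
    piecewise-linear interpolation of the calibration (replicates averaged
    per concentration).  Rates outside the calibrated span are clipped to
    the nearest endpoint and flagged.
    """
    curve = pd.DataFrame(rate_curve, columns=["conc_uM", "rate"])
    if curve.empty:
        raise CalibrationError("empty rate curve")
    means = curve.groupby("conc_uM")["rate"].mean()
    if means.size < 2:
        raise CalibrationError("need >= 2 distinct calibration concentrations")
    rates = means.to_numpy()
    if np.any(np.diff(rates) < 0):
        raise CalibrationError("rate curve must be monotone non-decreasing")
    concs = means.index.to_numpy()
    rate = max_growth_rate(series)
    flag = "ok"
    if rate < rates[0]:
        flag = "below_detection"
    elif rate > rates[-1]:
        flag = "above_range"
    conc = float(np.interp(rate, rates, concs))
    return EquivalentResult(estimate=conc, flag=flag)


class YieldBioassay(BaseEstimator):
    """Sklearn-style yield-mode bioassay: fit on a standards plate, predict
    GSH equivalents from final OD readings."""

    def __init__(
        self,
        compound: str = "GSH",
        linear_range: Tuple[float, float] = DEFAULT_YIELD_LINEAR_RANGE,
    ):
        self.compound = compound
        self.linear_range = linear_range

    def fit(self, standards: pd.DataFrame, y=None) -> "YieldBioassay":
        self.curve_ = fit_yield_curve(standards, self.compound, self.linear_range)
        return self

    def predict(self, od600) -> np.ndarray:
        od = np.asarray(od600, dtype=float).reshape(-1)
        return np.array([infer_gsh_equivalents(v, self.curve_).estimate for v in od])

    def predict_result(self, od600: float) -> EquivalentResult:
        return infer_gsh_equivalents(od600, self.curve_)


class RateBioassay(BaseEstimator):
    """Sklearn-style rate-mode bioassay: fit on a (conc, rate) calibration,
    predict concentration from tester growth curves."""

    def fit(self, rate_curve: Sequence[Tuple[float, float]], y=None) -> "RateBioassay":
        self.rate_curve_ = list(rate_curve)
        return self

    def predict_result(self, series: FluorescenceSeries) -> EquivalentResult:
        return rate_bioassay(series, self.rate_curve_)
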
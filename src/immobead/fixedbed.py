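"""Fixed-bed reactor bookkeeping and kinetic parameter estimation.

Estimation uses the linearized form of the integrated Michaelis-Menten
equation. Dividing the integrated relation

    Km * ln(S0/St) + (S0 - St) = Vmax * t

by ``Km * t`` and writing it in terms of the conversion X = (S0 - St)/S0
(note ln(S0/St) = -ln(1 - X)) gives

    ln(1 - X)/t = (S0/Km) * (X/t) - Vmax/Km,

so a plot of ln(1-X)/t against X/t is a straight line with slope +S0/Km
and intercept -Vmax/Km. (Both quantities are negative for consuming
kinetics, so the line climbs toward the origin.) Ordinary least squares
on that line recovers (Km, Vmax) exactly from noiseless data because the
linearization is an algebraic rearrangement, not an approximation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kinetics import ConversionSeries

__all__ = [
    "ReactorSpec",
    "FitResult",
    "CompleteConversionError",
    "EstimationError",
    "residence_time",
    "void_fraction",
    "entrapment_efficiency",
    "linearize",
    "estimate_km_vmax",
    "write_fit_table",
]

logger = logging.getLogger(__name__)

# Conversions at or above this are indistinguishable from complete conversion
# in double precision and make the log term blow up.
_X_COMPLETE = 1.0 - 1e-12

FIT_TABLE_HEADER = [
    "S0_g_per_L",
    "Km_g_per_L",
    "Vmax_g_per_L_min",
    "k2_per_min",
    "r_squared",
    "n_points",
]


class CompleteConversionError(ValueError):
    """An observation is at (numerically) complete conversion, X >= 1 - 1e-12."""


class EstimationError(RuntimeError):
    """The regression produced physically inadmissible parameters."""


@dataclass(frozen=True)
class ReactorSpec:
    """Packed-bed geometry and operating point.

    vr : reactor volume, cm^3;  epsilon : bed voidage in (0,1);
    q : volumetric feed flow rate, mL/min;  vb : bead volume, cm^3 (optional).
    """

    vr: float
    epsilon: float
    q: float
    vb: float | None = None

    def __post_init__(self) -> None:
        if not self.vr > 0:
            raise ValueError(f"reactor volume must be positive, got {self.vr}")
        if not 0 < self.epsilon < 1:
            raise ValueError(f"voidage must lie in (0, 1), got {self.epsilon}")
        if not self.q > 0:
            raise ValueError(f"flow rate must be positive, got {self.q}")
        if self.vb is not None and not self.vb > 0:
            raise ValueError(f"bead volume must be positive when given, got {self.vb}")


@dataclass(frozen=True)
class FitResult:
    """Outcome of the linearized integrated-MM regression for one S0."""

    s0: float
    slope: float
    intercept: float
    km_hat: float
    vmax_hat: float
    r_squared: float
    n_points: int


def residence_time(spec: ReactorSpec) -> float:
    """Mean residence time of the liquid in the bed: t = eps * VR / Q, min.

    Only the interstitial (void) volume eps*VR is available to the flowing
    liquid, so the holdup time is that volume over the volumetric flow rate.
    """
    return spec.epsilon * spec.vr / spec.q


def void_fraction(void_volume: float, reactor_volume: float) -> float:
    """Bed voidage: interstitial liquid volume over total reactor volume."""
    if reactor_volume <= 0:
        raise ValueError("reactor volume must be positive")
    if void_volume < 0 or void_volume > reactor_volume:
        raise ValueError(
            f"void volume {void_volume} outside [0, reactor volume {reactor_volume}]"
        )
    return void_volume / reactor_volume


def entrapment_efficiency(c_en: float, c_un: float) -> float:
    """Percent of loaded enzyme retained in the beads: 100*(Cen - Cun)/Cen."""
    if c_en <= 0:
        raise ValueError("loaded enzyme concentration must be positive")
    if c_un < 0 or c_un > c_en:
        raise ValueError(f"unentrapped amount {c_un} outside [0, {c_en}]")
    return 100.0 * (c_en - c_un) / c_en


def linearize(
    series: ConversionSeries, on_complete: str = "raise"
) -> tuple[np.ndarray, np.ndarray]:
    """Map observations to the (X/t, ln(1-X)/t) plane.

    Returns ``(x, y)`` with ``x = X/t`` and ``y = ln(1-X)/t``. Points from
    noiseless integrated-MM data are exactly collinear.

    Observations at complete conversion (X >= 1 - 1e-12) have an undefined
    log term; they raise :class:`CompleteConversionError` by default, or are
    dropped with a warning when ``on_complete="drop"``. They are never
    clipped, which would bias the slope.
    """
    if on_complete not in ("raise", "drop"):
        raise ValueError('on_complete must be "raise" or "drop"')
    x_conv = (series.s0 - series.st) / series.s0
    complete = x_conv >= _X_COMPLETE
    if complete.any():
        if on_complete == "raise":
            raise CompleteConversionError(
                f"{int(complete.sum())} observation(s) at complete conversion "
                f"(S0={series.s0}); pass on_complete='drop' to exclude them"
            )
        logger.warning(
            "dropping %d observation(s) at complete conversion (S0=%g)",
            int(complete.sum()),
            series.s0,
        )
    keep = ~complete
    t = series.t[keep]
    x_conv = x_conv[keep]
    st = series.st[keep]
    # ln(1-X) = ln(St/S0) evaluated from St directly: forming 1-X first
    # loses ~6 digits once X ~ 1 - 1e-10 and would bias high-conversion fits.
    y = (np.log(st) - np.log(series.s0)) / t
    return x_conv / t, y


def estimate_km_vmax(
    series: ConversionSeries, on_complete: str = "raise"
) -> FitResult:
    """Estimate (Km, Vmax) by OLS on the linearized integrated-MM relation.

    The regression of y = ln(1-X)/t on x = X/t has slope S0/Km and
    intercept -Vmax/Km, so Km_hat = S0/slope and Vmax_hat =
    -intercept*Km_hat.
    """
    x, y = linearize(series, on_complete=on_complete)
    if np.unique(x).size < 2:
        raise EstimationError(
            f"need at least 2 distinct linearized points, got {np.unique(x).size}"
        )
    fit = stats.linregress(x, y)
    if fit.slope <= 0:
        raise EstimationError(
            f"nonpositive slope {fit.slope:.6g} implies nonpositive Km; "
            "data are inconsistent with saturable consumption kinetics"
        )
    km_hat = series.s0 / fit.slope
    vmax_hat = -fit.intercept * km_hat
    if vmax_hat <= 0:
        raise EstimationError(
            f"nonpositive Vmax estimate {vmax_hat:.6g} (intercept {fit.intercept:.6g})"
        )
    # r from linregress is NaN for a 2-point exact fit's zero variance edge
    # cases; an exact interpolating line has r^2 = 1 by construction.
    r2 = 1.0 if x.size == 2 else float(fit.rvalue**2)
    return FitResult(
        s0=series.s0,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        km_hat=float(km_hat),
        vmax_hat=float(vmax_hat),
        r_squared=r2,
        n_points=int(x.size),
    )


def write_fit_table(fits: Sequence[FitResult], path, e0: float | None = None) -> None:
    """Serialize fit results; k2 = Vmax/E0 is filled when E0 is known."""
    rows = []
    for f in fits:
        k2 = f.vmax_hat / e0 if e0 else math.nan
        rows.append([f.s0, f.km_hat, f.vmax_hat, k2, f.r_squared, f.n_points])
    frame = pd.DataFrame(rows, columns=FIT_TABLE_HEADER)
    frame.to_csv(path, index=False, float_format="%.12g")
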
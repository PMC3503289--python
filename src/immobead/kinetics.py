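"""Michaelis-Menten rate law and its integrated fixed-bed form.

All quantities live in a single internal unit system: g, L, cm, min.
Literature values quoted per second (a common convention for Vmax and the
turnover number k2) are converted on ingestion via
:meth:`MMKinetics.from_seconds`.

The central relation is the integrated Michaelis-Menten equation

    Km * ln(S0/St) + (S0 - St) = Vmax * t,

which links the inlet substrate concentration ``S0``, the outlet
concentration ``St`` and the residence time ``t`` of a fixed-bed reactor
operating at steady state. It is exact for irreversible single-substrate
MM kinetics with no inhibition, and it is the forward model behind both
the parameter estimator (:mod:`immobead.fixedbed`) and the synthetic data
generator (:mod:`immobead.synthetic`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "MMKinetics",
    "ConversionSeries",
    "mm_rate",
    "integrated_time",
    "predict_outlet",
    "conversion",
    "turnover_number",
    "read_conversion_csv",
    "write_conversion_csv",
]

_REL_CONSISTENCY = 1e-9
CONVERSION_CSV_HEADER = ["S0_g_per_L", "t_min", "St_g_per_L"]


@dataclass(frozen=True)
class MMKinetics:
    """Michaelis-Menten parameter set.

    Parameters
    ----------
    km : float
        Michaelis constant, g/L. Substrate concentration at half-maximal rate.
    vmax : float
        Maximal volumetric rate, g/(L*min).
    k2 : float, optional
        Turnover number, 1/min. If given together with ``e0`` it must satisfy
        ``vmax == k2 * e0``.
    e0 : float, optional
        Initial enzyme concentration, g/L.
    k1, k_minus1 : float, optional
        Elementary rate constants of the enzyme-substrate binding step.
        Informational only: they are not identifiable from (km, vmax), but if
        all three of ``k1``, ``k_minus1``, ``k2`` are supplied they must be
        consistent with ``km = (k_minus1 + k2) / k1``.
    """

    km: float
    vmax: float
    k2: float | None = None
    e0: float | None = None
    k1: float | None = None
    k_minus1: float | None = None

    def __post_init__(self) -> None:
        if not (self.km > 0 and math.isfinite(self.km)):
            raise ValueError(f"Km must be positive and finite, got {self.km}")
        if not (self.vmax > 0 and math.isfinite(self.vmax)):
            raise ValueError(f"Vmax must be positive and finite, got {self.vmax}")
        for name in ("k2", "e0", "k1"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive when given, got {v}")
        if self.k_minus1 is not None and self.k_minus1 < 0:
            raise ValueError(f"k_minus1 must be nonnegative, got {self.k_minus1}")
        if self.k2 is not None and self.e0 is not None:
            if abs(self.vmax - self.k2 * self.e0) / self.vmax >= _REL_CONSISTENCY:
                raise ValueError(
                    f"inconsistent parameters: Vmax={self.vmax} != k2*E0="
                    f"{self.k2 * self.e0}"
                )
        if self.k1 is not None and self.k_minus1 is not None and self.k2 is not None:
            km_implied = (self.k_minus1 + self.k2) / self.k1
            if abs(self.km - km_implied) / self.km >= _REL_CONSISTENCY:
                raise ValueError(
                    f"inconsistent parameters: Km={self.km} != (k_minus1+k2)/k1="
                    f"{km_implied}"
                )

    @classmethod
    def from_seconds(
        cls,
        km: float,
        vmax_per_s: float,
        k2_per_s: float | None = None,
        e0: float | None = None,
        k1_per_s: float | None = None,
        k_minus1_per_s: float | None = None,
    ) -> "MMKinetics":
        """Build from per-second rates (converted to per-minute internally)."""
        conv = lambda v: None if v is None else 60.0 * v
        return cls(
            km=km,
            vmax=60.0 * vmax_per_s,
            k2=conv(k2_per_s),
            e0=e0,
            k1=conv(k1_per_s),
            k_minus1=conv(k_minus1_per_s),
        )


@dataclass(frozen=True)
class ConversionSeries:
    """Outlet-concentration observations for one fixed-bed experiment.

    ``s0`` is the inlet (initial) substrate concentration in g/L; each
    observation pairs a residence time ``t`` (min, strictly increasing)
    with the measured outlet concentration ``St`` (g/L, never above s0).
    """

    s0: float
    t: np.ndarray
    st: np.ndarray
    replicate: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        st = np.asarray(self.st, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "st", st)
        if not self.s0 > 0:
            raise ValueError(f"S0 must be positive, got {self.s0}")
        if t.shape != st.shape or t.ndim != 1 or t.size == 0:
            raise ValueError("t and St must be equal-length 1-D arrays")
        if not np.all(t > 0):
            raise ValueError("residence times must be strictly positive")
        if not np.all(np.diff(t) > 0):
            raise ValueError("residence times must be strictly increasing")
        if np.any(st < 0) or np.any(st > self.s0):
            raise ValueError("outlet concentrations must lie in [0, S0]")

    def __len__(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                CONVERSION_CSV_HEADER[0]: self.s0,
                CONVERSION_CSV_HEADER[1]: self.t,
                CONVERSION_CSV_HEADER[2]: self.st,
            }
        )


def mm_rate(s: float | np.ndarray, k: MMKinetics) -> float | np.ndarray:
    """MM rate v = Vmax*S/(Km+S), g/(L*min). Bounded above by Vmax."""
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0):
        raise ValueError("substrate concentration must be nonnegative")
    out = k.vmax * s_arr / (k.km + s_arr)
    return float(out) if np.isscalar(s) or out.ndim == 0 else out


def integrated_time(s0: float, st: float, k: MMKinetics) -> float:
    """Time for the outlet concentration to fall from ``s0`` to ``st``.

    Evaluates ``[Km*ln(S0/St) + (S0 - St)] / Vmax``. Diverges as St -> 0
    (the logarithmic term), hence ``st`` must be strictly positive.
    """
    if st <= 0:
        raise ValueError("St must be strictly positive (log term diverges at 0)")
    if st > s0:
        raise ValueError(f"St={st} exceeds S0={s0}")
    return (k.km * math.log(s0 / st) + (s0 - st)) / k.vmax


def predict_outlet(s0: float, t: float, k: MMKinetics) -> float:
    """Outlet concentration after residence time ``t`` — inverse of
    :func:`integrated_time`.

    The integrated MM relation is strictly monotone in St, so the root is
    bracketed and found with Brent's method to near machine precision.
    """
    if s0 <= 0:
        raise ValueError(f"S0 must be positive, got {s0}")
    if t < 0:
        raise ValueError(f"t must be nonnegative, got {t}")
    if t == 0.0:
        return s0
    # Work in u = ln(St): the root can be astronomically small (the log term
    # balances Vmax*t), so only a log-space bracket gives uniform *relative*
    # accuracy. g is strictly decreasing in u.
    g = lambda u: k.km * (math.log(s0) - u) + (s0 - math.exp(u)) - k.vmax * t
    # At u_lo the log term alone exceeds Vmax*t + S0, so g(u_lo) >= S0 > 0.
    u_lo = math.log(s0) - (k.vmax * t + s0) / k.km
    u_hi = math.log(s0)
    try:
        u = brentq(g, u_lo, u_hi, xtol=1e-14, rtol=4 * np.finfo(float).eps,
                   maxiter=200)
    except Exception as exc:  # pragma: no cover - diagnostics path
        raise ArithmeticError(
            f"root find for outlet concentration did not converge "
            f"(S0={s0}, t={t}, Km={k.km}, Vmax={k.vmax}): {exc}"
        ) from exc
    return float(min(math.exp(u), s0))


def conversion(s0: float, st: float) -> float:
    """Fractional conversion X = (S0 - St)/S0 in [0, 1]."""
    if s0 <= 0:
        raise ValueError(f"S0 must be positive, got {s0}")
    if st < 0 or st > s0:
        raise ValueError(f"St={st} outside [0, S0={s0}]")
    return (s0 - st) / s0


def turnover_number(vmax: float, e0: float) -> float:
    """Turnover number k2 = Vmax/E0 (units of 1/time, matching vmax)."""
    if e0 <= 0:
        raise ValueError(f"E0 must be positive, got {e0}")
    return vmax / e0


def write_conversion_csv(series: Sequence[ConversionSeries], path) -> None:
    """Write one or more series as CSV, one row per observation.

    A ``replicate`` column is appended only when some series carries a
    nonzero replicate index, so single-experiment files keep the plain
    three-column dialect.
    """
    frames = []
    with_rep = any(s.replicate != 0 for s in series)
    for s in series:
        f = s.to_frame()
        if with_rep:
            f["replicate"] = s.replicate
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")


def read_conversion_csv(path) -> list[ConversionSeries]:
    """Read a conversion CSV back into one series per distinct S0
    (and per replicate, when that column is present)."""
    frame = pd.read_csv(path)
    missing = [c for c in CONVERSION_CSV_HEADER if c not in frame.columns]
    if missing:
        raise ValueError(f"conversion CSV missing columns: {missing}")
    keys = [CONVERSION_CSV_HEADER[0]]
    if "replicate" in frame.columns:
        keys.append("replicate")
    out = []
    for key, grp in frame.groupby(keys, sort=False):
        s0 = float(key[0] if isinstance(key, tuple) else key)
        rep = int(key[1]) if len(keys) == 2 else 0
        grp = grp.sort_values(CONVERSION_CSV_HEADER[1])
        out.append(
            ConversionSeries(
                s0=s0,
                t=grp[CONVERSION_CSV_HEADER[1]].to_numpy(),
                st=grp[CONVERSION_CSV_HEADER[2]].to_numpy(),
                replicate=rep,
            )
        )
    return out
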
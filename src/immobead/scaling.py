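"""Dimensionless groups linking lab-frame parameters to the bead PDE.

With bead radius R, substrate diffusivity Ds and kinetics (Km, Vmax), the
reaction-diffusion problem inside the bead is governed by three groups:

* the Thiele modulus  phi = (R/3) * sqrt(Vmax / (Km * Ds)),
  comparing the intrinsic reaction rate with intraparticle diffusion
  (the source term of the dimensionless PDE is 9*phi^2 * Cs/(1 + beta*Cs));
* the saturation parameter  beta = S0/Km
  (beta -> 0: first-order kinetics; beta >> 1: zero-order);
* the diffusivity ratio  lambda = Dp/Ds for the product.

Concentrations are scaled by S0, lengths by R, and time by R^2/Ds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .kinetics import MMKinetics

__all__ = [
    "BeadTransport",
    "DimensionlessGroups",
    "thiele_modulus",
    "saturation_parameter",
    "nondimensionalize",
    "redimensionalize",
    "make_groups",
]

#: Default bead radius, cm (2 mm diameter alginate bead).
DEFAULT_RADIUS_CM = 0.1
#: Default substrate effective diffusivity in the hydrogel, cm^2/min.
DEFAULT_DS_CM2_PER_MIN = 7.8e-8


@dataclass(frozen=True)
class BeadTransport:
    """Bead geometry and intraparticle transport constants.

    r : bead radius, cm;  ds/dp : substrate/product effective
    diffusivities, cm^2/min. ``dp`` defaults to ``ds`` (lambda = 1).
    """

    r: float = DEFAULT_RADIUS_CM
    ds: float = DEFAULT_DS_CM2_PER_MIN
    dp: float | None = None

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"bead radius must be positive, got {self.r}")
        if not self.ds > 0:
            raise ValueError(f"Ds must be positive, got {self.ds}")
        if self.dp is not None and not self.dp > 0:
            raise ValueError(f"Dp must be positive when given, got {self.dp}")

    @property
    def dp_effective(self) -> float:
        return self.ds if self.dp is None else self.dp


@dataclass(frozen=True)
class DimensionlessGroups:
    """(phi, beta, lambda) plus the time scale R^2/Ds that produced them."""

    phi: float
    beta: float
    lam: float
    tau_scale: float

    def __post_init__(self) -> None:
        for name in ("phi", "beta", "lam", "tau_scale"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be positive and finite, got {v}")


def thiele_modulus(bt: BeadTransport, k: MMKinetics) -> float:
    """phi = (R/3) * sqrt(Vmax/(Km*Ds)); units cancel in the g,L,cm,min system."""
    return (bt.r / 3.0) * math.sqrt(k.vmax / (k.km * bt.ds))


def saturation_parameter(s0: float, km: float) -> float:
    """beta = S0/Km."""
    if km <= 0:
        raise ValueError(f"Km must be positive, got {km}")
    if s0 <= 0:
        raise ValueError(f"S0 must be positive, got {s0}")
    return s0 / km


def nondimensionalize(
    s: float,
    p: float,
    t: float,
    r: float,
    z: float,
    s0: float,
    bt: BeadTransport,
) -> tuple[float, float, float, float, float]:
    """Scale lab-frame state to (Cs, Cp, tau, r_dot, z_dot)."""
    if s0 <= 0:
        raise ValueError(f"S0 must be positive, got {s0}")
    tau_scale = bt.r**2 / bt.ds
    return (s / s0, p / s0, t / tau_scale, r / bt.r, z / bt.r)


def redimensionalize(
    cs: float,
    cp: float,
    tau: float,
    r_dot: float,
    z_dot: float,
    s0: float,
    bt: BeadTransport,
) -> tuple[float, float, float, float, float]:
    """Inverse of :func:`nondimensionalize`."""
    if s0 <= 0:
        raise ValueError(f"S0 must be positive, got {s0}")
    tau_scale = bt.r**2 / bt.ds
    return (cs * s0, cp * s0, tau * tau_scale, r_dot * bt.r, z_dot * bt.r)


def make_groups(bt: BeadTransport, k: MMKinetics, s0: float) -> DimensionlessGroups:
    """Bundle the groups for one operating point (one S0, one kinetic fit)."""
    return DimensionlessGroups(
        phi=thiele_modulus(bt, k),
        beta=saturation_parameter(s0, k.km),
        lam=bt.dp_effective / bt.ds,
        tau_scale=bt.r**2 / bt.ds,
    )
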
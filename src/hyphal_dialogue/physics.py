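"""Brownian-diffusion bound on the size of the exchanged signaling component.

A particle diffusing in three dimensions covers a mean-square distance
``L^2 = 6 D t``; with the Stokes-Einstein relation ``D = kB T / (6 pi eta r)``
this gives an upper bound on the radius of a particle that must cross the
gap ``L`` between two hyphal tips within a time ``t``:

    r <= kB T / (pi eta) * t / L^2

At 298.15 K in water (eta = 0.89 mPa s) the prefactor ``kB T / (pi eta)`` is
about 1.5e-18 m^2/s.

Note on the commonly quoted end value: at L = 10 um and t = 10 s the formula
yields r ~ 1.5e-7 m, whereas the nanometre-scale bound usually stated for
this argument (r <~ 1.5 nm, diameter ~3 nm) corresponds to L ~ 100 um or
t ~ 0.1 s.  The functions here return the formula result unmodified; the
discrepancy is flagged, never silently reconciled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BOLTZMANN_CONSTANT",
    "DiffusionContext",
    "stokes_einstein_D",
    "traversal_time",
    "prefactor",
    "radius_upper_bound",
]

#: exact 2019 SI value, J/K
BOLTZMANN_CONSTANT = 1.380649e-23


@dataclass(frozen=True)
class DiffusionContext:
    """Solvent conditions: temperature (K) and dynamic viscosity (Pa s).

    Defaults are water at 25 degrees C.
    """

    temperature: float = 298.15
    eta: float = 8.9e-4
    kB: float = BOLTZMANN_CONSTANT

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise ValueError(f"temperature must be > 0, got {self.temperature!r}")
        if not (self.eta > 0):
            raise ValueError(f"eta must be > 0, got {self.eta!r}")


_DEFAULT = DiffusionContext()


def stokes_einstein_D(r: float, ctx: DiffusionContext = _DEFAULT) -> float:
    """Diffusion coefficient (m^2/s) of a sphere of radius ``r`` (m)."""
    if not (r > 0):
        raise ValueError(f"radius must be > 0, got {r!r}")
    return ctx.kB * ctx.temperature / (6 * math.pi * ctx.eta * r)


def traversal_time(L: float, D: float) -> float:
    """Time (s) to cover mean-square distance ``L`` (m) by 3-d diffusion:
    ``t = L^2 / (6 D)``."""
    if not (L > 0):
        raise ValueError(f"L must be > 0, got {L!r}")
    if not (D > 0):
        raise ValueError(f"D must be > 0, got {D!r}")
    return L * L / (6 * D)


def prefactor(ctx: DiffusionContext = _DEFAULT) -> float:
    """The constant ``kB T / (pi eta)`` (m^2/s) multiplying ``t / L^2`` in
    the radius bound; ~1.5e-18 m^2/s for water at 25 degrees C."""
    return ctx.kB * ctx.temperature / (math.pi * ctx.eta)


def radius_upper_bound(L: float, t: float, ctx: DiffusionContext = _DEFAULT) -> float:
    """Largest radius (m) that can diffuse across ``L`` (m) within ``t`` (s).

    ``r = kB T t / (pi eta L^2)``.  See the module note about the magnitude
    of this bound at L = 10 um, t = 10 s.
    """
    if not (L > 0):
        raise ValueError(f"L must be > 0, got {L!r}")
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t!r}")
    return prefactor(ctx) * t / (L * L)
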
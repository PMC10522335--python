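"""Coupled two-cell excitable-oscillator model of hyphal cell-to-cell signaling.

Each of two fungal hyphae is described by five variables: an activator ``A``,
an inhibitor ``I``, free vesicles ``X``, membrane-docked vesicles ``Y`` and
the concentration ``Z`` of the extracellular signaling component at the
hyphal tip.  Uptake of extracellular signal (``+A*Z``) excites the activator,
the activator drives vesicle docking, and the delayed inhibitor gates vesicle
release back into the extracellular pool.  The two tips exchange signal
through a conservative flux ``kz*exp(-d)*(Z_other - Z_self)`` whose magnitude
decays exponentially with the inter-cell distance ``d``; the bulk medium
exchanges with each tip pool at rate ``kcext``.

This module provides the deterministic drift ``F`` and the per-reaction noise
propensities ``G`` of the Langevin description

    dU = tau * F(U) dt + tau * sqrt(1/Omega) * (noise channels)

where ``Omega`` is the system size controlling fluctuation magnitude.  The
time-scaling constant ``tau`` is applied by the integrator, not here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ModelParameters",
    "SystemState",
    "NoiseChannel",
    "CANONICAL_INITIAL_STATE",
    "STATE_NAMES",
    "VARIABLES",
    "default_parameters",
    "drift",
    "noise_propensities",
    "coupling_rate",
]

VARIABLES = ("A", "I", "X", "Y", "Z")
#: state-vector ordering: cell 1 then cell 2, A I X Y Z within each cell
STATE_NAMES = tuple(f"{v}{c}" for c in (1, 2) for v in VARIABLES)

#: canonical initial condition used for all simulations unless overridden
CANONICAL_INITIAL_STATE = np.array(
    [0.7065, 0.7145, 0.0, 0.0, 1.0, 0.7065, 0.7145, 0.0, 0.0, 1.0]
)


@dataclass(frozen=True)
class ModelParameters:
    """The 16 model constants.

    Defaults are the published set used for every figure-level result;
    ``d`` (the inter-cell distance) is the one knob scenarios vary and
    defaults to 10 (the "long distance" condition).
    """

    tau: float = 8.48       # time-scaling constant (multiplies drift and noise)
    epsilon: float = 0.55   # inhibitor time-scale separation
    alpha: float = 12.4     # activator linear decay coefficient
    beta: float = 8.05      # activator quadratic self-amplification
    gamma: float = 8.0      # inhibitor production gain
    k: float = 6.0          # inhibitor-production half-saturation constant
    a0: float = 5.6         # basal activator production
    i0: float = 0.1         # basal inhibitor production
    x0: float = 1.0         # basal free-vesicle production
    k1: float = 0.1         # vesicle-docking rate coefficient
    k2: float = 1.0         # vesicle-release rate coefficient
    kz: float = 10.0        # tip-to-tip extracellular exchange coefficient
    kcext: float = 5.0      # media-exchange rate
    cmedia: float = 1.0     # bulk-media signaling concentration
    d: float = 10.0         # inter-cell distance (dimensionless)
    omega: float = 1000.0   # system size (noise ~ 1/sqrt(omega))

    def __post_init__(self) -> None:
        positive = (
            "tau", "epsilon", "alpha", "beta", "gamma", "k",
            "a0", "i0", "x0", "k1", "k2", "kz", "kcext", "omega",
        )
        for name in positive:
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"parameter {name!r} must be strictly positive, got {value!r}")
        if not (math.isfinite(self.cmedia) and self.cmedia >= 0):
            raise ValueError(f"parameter 'cmedia' must be >= 0, got {self.cmedia!r}")
        if not (math.isfinite(self.d) and self.d >= 0):
            raise ValueError(f"parameter 'd' must be >= 0, got {self.d!r}")

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields changed (validated)."""
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping: dict[str, float]) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown parameter field(s): {sorted(unknown)}")
        return cls(**mapping)


def default_parameters(**overrides: float) -> ModelParameters:
    """The published parameter set, optionally with per-field overrides."""
    return ModelParameters(**overrides)


@dataclass(frozen=True)
class SystemState:
    """The ten model variables, cell 1 then cell 2."""

    a1: float
    i1: float
    x1: float
    y1: float
    z1: float
    a2: float
    i2: float
    x2: float
    y2: float
    z2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a1, self.i1, self.x1, self.y1, self.z1,
                         self.a2, self.i2, self.x2, self.y2, self.z2])

    @classmethod
    def from_array(cls, u: Sequence[float]) -> "SystemState":
        u = np.asarray(u, dtype=float)
        if u.shape != (10,):
            raise ValueError(f"state must have 10 entries, got shape {u.shape}")
        return cls(*u.tolist())


@dataclass(frozen=True)
class NoiseChannel:
    """One evaluated Langevin noise channel.

    ``channel_index`` follows the per-cell 1..19 numbering of the model's
    independent Wiener processes (A: 1-6, I: 7-9, X: 10-11, Y: 12-13,
    Z: 14-19).  ``sign`` records whether the underlying reaction adds to or
    removes from the target variable; it does not affect the variance.
    """

    cell: int
    channel_index: int
    target_variable: str
    propensity: float
    sign: int


def _as_state_array(state, where: str) -> np.ndarray:
    u = state.as_array() if isinstance(state, SystemState) else np.asarray(state, dtype=float)
    if u.shape != (10,):
        raise ValueError(f"{where}: state must have 10 entries, got shape {u.shape}")
    if not np.all(np.isfinite(u)):
        bad = int(np.flatnonzero(~np.isfinite(u))[0])
        raise ValueError(f"{where}: non-finite value in state variable {STATE_NAMES[bad]}")
    return u


def coupling_rate(params: ModelParameters, d: float | None = None) -> float:
    """Tip-to-tip exchange rate ``kz * exp(-d)`` at distance ``d``."""
    if d is None:
        d = params.d
    if not (math.isfinite(d) and d >= 0) and not d == math.inf:
        raise ValueError(f"distance must be >= 0, got {d!r}")
    return params.kz * math.exp(-d)


def drift(state, params: ModelParameters, d: float | None = None) -> np.ndarray:
    """Deterministic drift F(U), un-scaled by tau.

    Per cell c (with the partner's tip pool Z_o):

        dA = a0 - alpha*A + beta*A^2 - A^3 - A*I + A*Z
        dI = epsilon * (i0 + gamma*A^2/(A^2 + k) - I)
        dX = x0 - k1*A^2*X
        dY = k1*A^2*X - k2*Y/(A^3 + 1)
        dZ = -kcext*(Z - cmedia) + k2*Y/(A^3 + 1) - A*Z + cr*(Z_o - Z)

    with ``cr = kz*exp(-d)``.
    """
    u = _as_state_array(state, "drift")
    p = params
    cr = coupling_rate(p, d)
    out = np.empty(10)
    for c in (0, 1):
        a, i, x, y, z = u[5 * c: 5 * c + 5]
        z_other = u[5 * (1 - c) + 4]
        release = p.k2 * y / (a ** 3 + 1.0)
        out[5 * c + 0] = p.a0 - p.alpha * a + p.beta * a * a - a ** 3 - a * i + a * z
        out[5 * c + 1] = p.epsilon * (p.i0 + p.gamma * a * a / (a * a + p.k) - i)
        out[5 * c + 2] = p.x0 - p.k1 * a * a * x
        out[5 * c + 3] = p.k1 * a * a * x - release
        out[5 * c + 4] = (-p.kcext * (z - p.cmedia) + release - a * z
                          + cr * (z_other - z))
    return out


def noise_propensities(state, params: ModelParameters, d: float | None = None) -> list[NoiseChannel]:
    """All 38 noise-channel magnitudes (19 per cell), evaluated at ``state``.

    Channels are grouped per target variable exactly as the model defines
    them; reactions shared between the Y and Z balance (the vesicle-release
    flux) carry distinct channel indices, i.e. independent Wiener processes.
    Negative state entries are clamped to zero before evaluation so every
    propensity is nonnegative.
    """
    u = _as_state_array(state, "noise_propensities")
    u = np.maximum(u, 0.0)
    p = params
    cr = coupling_rate(p, d)
    channels: list[NoiseChannel] = []
    for c in (0, 1):
        a, i, x, y, z = u[5 * c: 5 * c + 5]
        z_other = u[5 * (1 - c) + 4]
        release = p.k2 * y / (a ** 3 + 1.0)
        per_cell = [
            # A: production, linear decay, quadratic amplification, cubic decay,
            #    inhibition, uptake
            ("A", p.a0, +1), ("A", p.alpha * a, -1), ("A", p.beta * a * a, +1),
            ("A", a ** 3, -1), ("A", a * i, -1), ("A", a * z, +1),
            # I: basal production, activator-driven production, decay
            ("I", p.epsilon * p.i0, +1),
            ("I", p.epsilon * p.gamma * a * a / (a * a + p.k), +1),
            ("I", p.epsilon * i, -1),
            # X: production, docking
            ("X", p.x0, +1), ("X", p.k1 * a * a * x, -1),
            # Y: docking, release
            ("Y", p.k1 * a * a * x, +1), ("Y", release, -1),
            # Z: media out, media in, release, uptake, influx from partner,
            #    efflux to partner
            ("Z", p.kcext * z, -1), ("Z", p.kcext * p.cmedia, +1),
            ("Z", release, +1), ("Z", a * z, -1),
            ("Z", cr * z_other, +1), ("Z", cr * z, -1),
        ]
        for j, (var, g, sign) in enumerate(per_cell, start=1):
            channels.append(NoiseChannel(cell=c + 1, channel_index=j,
                                         target_variable=var, propensity=float(g),
                                         sign=sign))
    return channels


def aggregated_noise_scale(state, params: ModelParameters, d: float | None = None,
                           mode: str = "chemical-langevin") -> np.ndarray:
    """Per-variable effective noise amplitude s_v (10 entries).

    Independent Gaussian channels add in variance, so the per-variable
    amplitude is ``sqrt(sum g^2)`` when channel amplitudes are the raw
    propensities (``mode="as-printed"``) and ``sqrt(sum g)`` when each
    channel has amplitude ``sqrt(g)`` (``mode="chemical-langevin"``, the
    default).  The integrator multiplies by ``tau * sqrt(dt/omega)``.
    """
    if mode not in ("chemical-langevin", "as-printed"):
        raise ValueError(f"unknown noise mode {mode!r}")
    out = np.zeros(10)
    for ch in noise_propensities(state, params, d):
        v = 5 * (ch.cell - 1) + VARIABLES.index(ch.target_variable)
        out[v] += ch.propensity ** 2 if mode == "as-printed" else ch.propensity
    return np.sqrt(out)
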
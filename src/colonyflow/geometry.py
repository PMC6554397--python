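"""Channel geometry, flow conditions and transport timescales.

The experimental system is a rectangular microchannel (length ``L`` along
the flow, width ``w``, height ``h``, cross-section ``A = w*h``) perfused at
a volumetric rate ``Q``, giving a mean flow velocity ``v = Q/A``.  A
planktonic swimmer is advected down the channel in a residence time
``tau_a = L/v`` while exploring the channel depth by effectively diffusive
swimming with timescale ``tau_D = h^2/D``.  Their ratio

    Pe = tau_D / tau_a = h^2 v / (D L)

is a Peclet number that controls whether a cell reaches the floor before
being washed out (Pe small) or not (Pe large).  Everything downstream of
this module (transport simulation, colonization, quantification) is
parameterised through these three types.

Internal units are strictly SI; use :mod:`colonyflow.units` or the
``from_lab_units`` constructors to convert from laboratory units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import units
from .errors import InvalidGeometryError, InvalidParameterError

#: Effective diffusivity of an unbiased swimmer (m^2/s); 4e-6 cm^2/s, the
#: standard literature value for run-and-tumble E. coli adopted for
#: C. crescentus swarmer cells.
D_SWIM = units.cm2_s_to_m2_s(4e-6)

#: Passive (Stokes-Einstein order) diffusivity of a nonmotile ~1 um cell
#: (m^2/s); used for flagellum-less mutants, which are only transported by
#: flow and thermal motion.
D_PASSIVE = units.cm2_s_to_m2_s(2e-9)


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular microchannel: length, width, height in metres.

    Channels are wider than tall (``height <= width``); the cross-section
    area ``A = width * height`` is derived.
    """

    length: float
    width: float
    height: float

    def __post_init__(self) -> None:
        for name in ("length", "width", "height"):
            if not getattr(self, name) > 0:
                raise InvalidGeometryError(f"{name} must be strictly positive")
        if self.height > self.width:
            raise InvalidGeometryError(
                "channels are wider than tall: height must not exceed width"
            )

    @property
    def area(self) -> float:
        """Cross-sectional area A = w*h (m^2)."""
        return self.width * self.height

    @property
    def floor_area(self) -> float:
        """Colonizable floor area L*w (m^2)."""
        return self.length * self.width

    @classmethod
    def from_lab_units(
        cls, length_cm: float, width_um: float, height_um: float
    ) -> "ChannelGeometry":
        return cls(
            length=units.cm_to_m(length_cm),
            width=units.um_to_m(width_um),
            height=units.um_to_m(height_um),
        )


@dataclass(frozen=True)
class FlowCondition:
    """Volumetric rate Q (m^3/s) and mean velocity v (m/s) for a geometry.

    Either ``flow_rate`` or ``velocity`` may be given; the other is derived
    from ``v = Q/A``.  If both are given they must be consistent.
    """

    geometry: ChannelGeometry
    flow_rate: float = field(default=None)  # type: ignore[assignment]
    velocity: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        q, v = self.flow_rate, self.velocity
        if q is None and v is None:
            raise InvalidParameterError("provide flow_rate or velocity")
        if q is None:
            q = v * self.geometry.area
            object.__setattr__(self, "flow_rate", q)
        elif v is None:
            v = mean_velocity(q, self.geometry)
            object.__setattr__(self, "velocity", v)
        if q < 0 or v < 0:
            raise InvalidParameterError("flow rate and velocity must be >= 0")
        if not math.isclose(v * self.geometry.area, q, rel_tol=1e-9, abs_tol=1e-30):
            raise InvalidParameterError(
                f"inconsistent flow condition: v*A = {v * self.geometry.area!r} "
                f"but Q = {q!r}"
            )

    @classmethod
    def from_lab_units(
        cls,
        geometry: ChannelGeometry,
        rate_ul_min: float | None = None,
        velocity_mm_s: float | None = None,
    ) -> "FlowCondition":
        return cls(
            geometry=geometry,
            flow_rate=None if rate_ul_min is None else units.ul_min_to_m3_s(rate_ul_min),
            velocity=None if velocity_mm_s is None else units.mm_s_to_m_s(velocity_mm_s),
        )


@dataclass(frozen=True)
class TransportScales:
    """Advective/diffusive timescales and their ratio, the Peclet number.

    ``tau_a = L/v`` (s), ``tau_d = h^2/D`` (s), ``pe = tau_d/tau_a``.
    At ``v = 0`` the residence time is infinite and ``pe = 0`` by
    convention, so the quiescent limit is representable.
    """

    diffusivity: float
    tau_a: float
    tau_d: float
    pe: float


def mean_velocity(flow_rate: float, geometry: ChannelGeometry) -> float:
    """Mean flow velocity v = Q/A (m/s) for a volumetric rate Q (m^3/s)."""
    if flow_rate < 0:
        raise InvalidParameterError("flow rate must be >= 0")
    return flow_rate / geometry.area


def peclet(velocity: float, geometry: ChannelGeometry, diffusivity: float = D_SWIM) -> float:
    """Peclet number Pe = h^2 v / (D L) (dimensionless)."""
    if diffusivity <= 0:
        raise InvalidParameterError("diffusivity must be strictly positive")
    if velocity < 0:
        raise InvalidParameterError("velocity must be >= 0")
    return geometry.height**2 * velocity / (diffusivity * geometry.length)


def timescales(
    velocity: float, geometry: ChannelGeometry, diffusivity: float = D_SWIM
) -> TransportScales:
    """Residence and cross-channel diffusion timescales plus Pe.

    ``velocity == 0`` yields ``tau_a = inf`` and ``pe = 0`` rather than an
    error, so limit cases remain testable.
    """
    if diffusivity <= 0:
        raise InvalidParameterError("diffusivity must be strictly positive")
    if velocity < 0:
        raise InvalidParameterError("velocity must be >= 0")
    tau_d = geometry.height**2 / diffusivity
    if velocity == 0:
        return TransportScales(diffusivity, math.inf, tau_d, 0.0)
    tau_a = geometry.length / velocity
    return TransportScales(diffusivity, tau_a, tau_d, tau_d / tau_a)
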
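"""Brownian-dynamics transport of planktonic swimmers in a channel.

Particles are advected along the channel (``x``) by the flow and diffuse
across its depth (``z``, 0 at the glass floor) with the effective swimming
diffusivity ``D``.  The ceiling reflects; the floor is partially absorbing,
parameterised by a wall reactivity ``kappa`` (m/s).  The dimensionless
reactivity ``kappa*h/D`` selects the capture regime: for
``kappa*h/D << 1`` (reaction-limited) the depth distribution stays nearly
uniform and the attachment probability of a cell traversing the channel is

    p_att = 1 - exp(-kappa * L / (v * h))  ~=  (kappa*h/D) / Pe

i.e. attachment scales like the inverse Peclet number, the regime observed
for swarmer-cell adhesion.  A perfectly absorbing floor would instead give
p ~ Pe^(-1/2..-1/3), so the reactive boundary is an essential model
ingredient, not a numerical convenience.

The reactive floor is discretised with the reflect-or-absorb rule of
Erban & Chapman: on each floor contact the particle sticks with probability
``P = kappa * sqrt(pi*dt/D)``, which makes the continuum absorption rate
independent of the timestep as ``dt -> 0``.

Two capture estimators are available:

``analog``
    Bernoulli absorption; produces discrete attachment events with
    positions and times (needed for dispersal kernels) and a binomial
    confidence interval.
``weighted``
    Implicit capture (survival biasing): every particle carries a survival
    weight which is reduced by ``(1 - P)`` at each floor contact, and the
    absorbed weight is accumulated.  This is the classic variance-reduction
    scheme for rare capture events and yields a far lower-variance estimate
    of the same probability at large Pe.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import InvalidParameterError, RegimeError
from .geometry import ChannelGeometry, D_SWIM, FlowCondition, peclet

#: kappa*h/D below this value counts as reaction-limited capture.
REACTION_LIMITED_THRESHOLD = 0.1

#: Default dimensionless wall reactivity; deep in the reaction-limited
#: regime, where p_att ~ (kappa h / D) / Pe.
DEFAULT_KAPPA_H_OVER_D = 0.01


@dataclass(frozen=True)
class TransportParams:
    """Physical and numerical parameters of a transport simulation."""

    geometry: ChannelGeometry
    flow: FlowCondition
    diffusivity: float = D_SWIM
    kappa: float = field(default=None)  # type: ignore[assignment]
    dt: float = field(default=None)  # type: ignore[assignment]
    profile: str = "plug"
    max_time: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.diffusivity < 0:
            raise InvalidParameterError("diffusivity must be >= 0 (use D_PASSIVE for nonmotile)")
        if self.diffusivity == 0 and self.dt is None:
            raise InvalidParameterError("an explicit dt is required in the pure-advection limit")
        if self.kappa is None:
            object.__setattr__(
                self,
                "kappa",
                DEFAULT_KAPPA_H_OVER_D * self.diffusivity / self.geometry.height,
            )
        if self.kappa < 0:
            raise InvalidParameterError("kappa must be >= 0")
        if self.profile not in ("plug", "parabolic"):
            raise InvalidParameterError("profile must be 'plug' or 'parabolic'")
        if self.dt is None:
            object.__setattr__(self, "dt", self.default_dt())
        if self.dt <= 0:
            raise InvalidParameterError("dt must be > 0")
        if self.max_time is None:
            object.__setattr__(self, "max_time", self.default_max_time())

    # -- derived quantities -------------------------------------------------
    @property
    def kappa_h_over_d(self) -> float:
        """Dimensionless wall reactivity kappa*h/D."""
        if self.diffusivity == 0:
            return math.inf if self.kappa > 0 else 0.0
        return self.kappa * self.geometry.height / self.diffusivity

    @property
    def reaction_limited(self) -> bool:
        return self.kappa_h_over_d < REACTION_LIMITED_THRESHOLD

    @property
    def pe(self) -> float:
        if self.diffusivity == 0:
            # pure advection: no cross-channel transport at all
            return math.inf if self.flow.velocity > 0 else 0.0
        return peclet(self.flow.velocity, self.geometry, self.diffusivity)

    def default_dt(self) -> float:
        """Timestep with rms diffusive step <= h/50 and advective step <= L/100."""
        h, L, v = self.geometry.height, self.geometry.length, self.flow.velocity
        dt = (h / 50.0) ** 2 / (2.0 * self.diffusivity)
        if v > 0:
            dt = min(dt, L / (100.0 * v))
        return dt

    def default_max_time(self) -> float:
        """10 residence times under flow; 10 capture times in quiescence."""
        g = self.geometry
        if self.flow.velocity > 0:
            return 10.0 * g.length / self.flow.velocity
        if self.diffusivity == 0:
            raise InvalidParameterError("max_time required with zero flow and zero diffusivity")
        tau_d = g.height**2 / self.diffusivity
        tau_react = g.height / self.kappa if self.kappa > 0 else 0.0
        return 10.0 * (tau_react + tau_d)


@dataclass
class AttachmentOutcome:
    """Terminal statistics of a transport simulation.

    ``n_attached + n_exited == n_total`` always; particles still airborne
    at ``max_time`` are counted as exited (right-censored).  For the
    weighted estimator, ``probability`` is the mean absorbed weight and
    the confidence interval is a normal approximation over particles.
    """

    n_total: int
    n_attached: int
    n_exited: int
    probability: float
    ci_low: float
    ci_high: float
    x_att: np.ndarray
    t_att: np.ndarray
    mode: str
    pe: float
    seed: int

    def __post_init__(self) -> None:
        assert self.n_attached + self.n_exited == self.n_total


@dataclass(frozen=True)
class DispersalKernel:
    """Empirical downstream-displacement distribution of reattached cells."""

    displacements: np.ndarray
    mean: float
    std: float

    @property
    def n(self) -> int:
        return self.displacements.size


@dataclass(frozen=True)
class ScalingFit:
    """OLS fit of log10(p_att) on log10(Pe): slope is the power-law exponent."""

    slope: float
    intercept: float
    stderr: float


def sticking_probability_per_contact(kappa: float, diffusivity: float, dt: float) -> float:
    """Per-contact sticking probability P = kappa*sqrt(pi*dt/D), clipped to [0, 1].

    This discretisation of a Robin (partially absorbing) boundary keeps the
    continuum absorption rate dt-invariant.  A result above 0.5 means the
    timestep is too coarse for the requested reactivity and a warning is
    issued.
    """
    if kappa < 0:
        raise InvalidParameterError("kappa must be >= 0")
    if diffusivity <= 0:
        raise InvalidParameterError("diffusivity must be > 0")
    if dt <= 0:
        raise InvalidParameterError("dt must be > 0")
    p = kappa * math.sqrt(math.pi * dt / diffusivity)
    if p > 0.5:
        warnings.warn(
            f"per-contact sticking probability {p:.3g} > 0.5: "
            "dt is too coarse for the requested kappa",
            stacklevel=2,
        )
    return min(p, 1.0)


def _release(release, n: int, h: float, rng: np.random.Generator):
    if release == "uniform_inlet":
        return np.zeros(n), rng.uniform(0.0, h, n)
    if isinstance(release, tuple) and len(release) == 2 and release[0] == "floor_point":
        x0 = float(release[1])
        return np.full(n, x0), np.zeros(n)
    raise InvalidParameterError(
        "release must be 'uniform_inlet' or ('floor_point', x0)"
    )


def simulate_transport(
    params: TransportParams,
    n: int,
    release="uniform_inlet",
    capture: str = "analog",
    seed: int = 0,
) -> AttachmentOutcome:
    """Simulate ``n`` particles until attachment, exit, or ``max_time``.

    Plug flow advects every height equally at ``v``; the parabolic profile
    uses the plane-Poiseuille form ``u(z) = 6 v (z/h)(1 - z/h)``.  Results
    are deterministic given ``seed``.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if capture not in ("analog", "weighted"):
        raise InvalidParameterError("capture must be 'analog' or 'weighted'")

    g = params.geometry
    h, L = g.height, g.length
    v, D, dt = params.flow.velocity, params.diffusivity, params.dt
    if dt * v > L / 100.0 * (1 + 1e-12):
        warnings.warn("advective step dt*v exceeds L/100; results may be coarse", stacklevel=2)
    if D == 0:
        p_stick = 0.0
        sigma = 0.0
    else:
        p_stick = sticking_probability_per_contact(params.kappa, D, dt)
        sigma = math.sqrt(2.0 * D * dt)

    rng = np.random.default_rng(seed)
    x, z = _release(release, n, h, rng)
    active = np.ones(n, dtype=bool)
    weight = np.ones(n) if capture == "weighted" else None
    absorbed = np.zeros(n) if capture == "weighted" else None

    x_att: list[np.ndarray] = []
    t_att: list[np.ndarray] = []
    n_attached = 0
    t = 0.0
    parabolic = params.profile == "parabolic"

    while active.any() and t < params.max_time:
        idx = np.flatnonzero(active)
        zi = z[idx]
        if parabolic:
            u = 6.0 * v * (zi / h) * (1.0 - zi / h)
        else:
            u = v
        xi = x[idx] + u * dt
        if sigma > 0:
            zi = zi + sigma * rng.standard_normal(idx.size)
        # reflecting ceiling
        over = zi > h
        zi[over] = 2.0 * h - zi[over]
        # partially absorbing floor
        below = zi < 0.0
        if below.any():
            bidx = np.flatnonzero(below)
            if capture == "analog" and p_stick > 0:
                stick = rng.random(bidx.size) < p_stick
                hit = bidx[stick]
                if hit.size:
                    gidx = idx[hit]
                    active[gidx] = False
                    x_att.append(np.clip(xi[hit], 0.0, L))
                    t_att.append(np.full(hit.size, t + dt))
                    n_attached += hit.size
            elif capture == "weighted" and p_stick > 0:
                gidx = idx[bidx]
                absorbed[gidx] += weight[gidx] * p_stick
                weight[gidx] *= 1.0 - p_stick
            zi = np.abs(zi)
        z[idx] = np.clip(zi, 0.0, h)
        x[idx] = xi
        # exit at the outlet
        gone = active & (x > L)
        active[gone] = False
        t += dt

    # anything still airborne at max_time is censored as exited
    n_exited = n - n_attached
    x_att_arr = np.concatenate(x_att) if x_att else np.empty(0)
    t_att_arr = np.concatenate(t_att) if t_att else np.empty(0)

    if capture == "analog":
        p_hat = n_attached / n
        lo, hi = proportion_confint(n_attached, n, alpha=0.05, method="wilson")
    else:
        per_particle = absorbed
        p_hat = float(per_particle.mean())
        se = float(per_particle.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        lo, hi = max(0.0, p_hat - 1.96 * se), min(1.0, p_hat + 1.96 * se)

    return AttachmentOutcome(
        n_total=n,
        n_attached=n_attached,
        n_exited=n_exited,
        probability=p_hat,
        ci_low=float(lo),
        ci_high=float(hi),
        x_att=x_att_arr,
        t_att=t_att_arr,
        mode=capture,
        pe=params.pe,
        seed=seed,
    )


def analytic_p_att(params: TransportParams) -> float:
    """Reaction-limited attachment probability 1 - exp(-kappa*L/(v*h)).

    Valid only for ``kappa*h/D < 0.1`` (well-mixed depth profile); note
    ``kappa*L/(v*h) = (kappa*h/D) / Pe``, so ``p ~ Pe^-1`` for small p.
    Raises :class:`RegimeError` outside the reaction-limited regime, where
    capture becomes transport-limited and this form is invalid.
    """
    if not params.reaction_limited:
        raise RegimeError(
            f"kappa*h/D = {params.kappa_h_over_d:.3g} >= {REACTION_LIMITED_THRESHOLD}: "
            "the well-mixed reaction-limited form does not apply"
        )
    if params.kappa == 0:
        return 0.0
    v = params.flow.velocity
    if v == 0:
        return 1.0
    expo = params.kappa * params.geometry.length / (v * params.geometry.height)
    return 1.0 - math.exp(-expo)


def dispersal_kernel(outcome: AttachmentOutcome, release_x: float) -> DispersalKernel:
    """Downstream displacements ``x_att - release_x`` of attached particles.

    An outcome without attachments returns an empty kernel (``n == 0``)
    rather than raising.
    """
    disp = outcome.x_att - release_x
    if disp.size == 0:
        return DispersalKernel(displacements=disp, mean=math.nan, std=math.nan)
    return DispersalKernel(
        displacements=disp,
        mean=float(disp.mean()),
        std=float(disp.std(ddof=1)) if disp.size > 1 else 0.0,
    )


def fit_scaling_exponent(pe_values, p_values) -> ScalingFit:
    """OLS of log10(p_att) against log10(Pe); the slope is the exponent.

    Requires at least three strictly positive (Pe, p) pairs; a nonpositive
    entry raises an error naming the offending index.
    """
    pe = np.asarray(pe_values, dtype=float)
    p = np.asarray(p_values, dtype=float)
    if pe.shape != p.shape or pe.ndim != 1:
        raise InvalidParameterError("pe_values and p_values must be 1-d and equal length")
    if pe.size < 3:
        raise InvalidParameterError("need at least 3 (Pe, p) pairs")
    for name, arr in (("Pe", pe), ("p", p)):
        bad = np.flatnonzero(~(arr > 0))
        if bad.size:
            raise InvalidParameterError(
                f"nonpositive {name} value at index {int(bad[0])}: {arr[bad[0]]!r}"
            )
    res = stats.linregress(np.log10(pe), np.log10(p))
    return ScalingFit(slope=float(res.slope), intercept=float(res.intercept),
                      stderr=float(res.stderr))
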
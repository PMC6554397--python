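"""Agent-based simulation of surface colonization under flow.

Surface-anchored (stalked) mother cells divide asymmetrically at renewal
intervals ``T_div`` (coefficient of variation ``division_cv``).  At each
division the mother persists and the swarmer daughter either

* attaches next to its mother (probability ``p_near``), continuing the
  clonal microcolony, or
* is released into the bulk, where it is advected downstream while
  exploring the channel depth by swimming; it reattaches at a downstream
  site or is washed out of the channel.

Bulk fate uses an exponential waiting-time kernel whose rate combines the
reaction resistance ``h/kappa`` and the mean vertical first-passage
resistance ``h^2/(3 D)`` in series::

    rate = 1 / (h/kappa + h^2/(3*D))

For motile cells at the default reactivity (``kappa*h/D = 0.01``) the
reaction term dominates and the implied attachment probability over the
remaining channel length reduces to ``1 - exp(-kappa*(L-x)/(v*h))``, the
same closed form validated against the Brownian-dynamics simulator in
:mod:`colonyflow.transport`.  For nonmotile cells (``D = D_PASSIVE``) the
diffusion term dominates and reattachment is strongly suppressed, which is
what loss of flagellar motility does experimentally.

Local attachment uses downstream-biased nearest-free-site placement on a
lattice with one cell per site: the daughter is proposed one cell length
downstream of its mother with a small isotropic jitter and takes the
nearest unoccupied site (nearest in physical distance).  The lattice is
anisotropic, matched to the cell outline -- axial spacing equal to the
cell length, lateral spacing ``footprint/length`` -- so site area equals
the cell footprint and neighbouring cells tile without overlap.  This
Eden-like rule approximates excluded volume, so microcolonies grow as
compact monolayer patches whose area tracks their cell count, as in
micrographs.

Positions are stored in SI metres; attached cells never detach.
"""

from __future__ import annotations

import heapq
import math
import random
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .geometry import ChannelGeometry, D_SWIM, FlowCondition

GREEN, MAGENTA = 0, 1
COLOR_NAMES = {GREEN: "green", MAGENTA: "magenta"}

#: Physical search radius for nearest-free-site placement (m); far beyond
#: any microcolony radius at the population sizes simulated here.
_SEARCH_RADIUS_M = 40e-6


def _search_offsets(sx: float, sy: float) -> list[tuple[int, int]]:
    """Lattice offsets sorted by physical distance for spacings (sx, sy)."""
    ni = int(_SEARCH_RADIUS_M / sx)
    nj = int(_SEARCH_RADIUS_M / sy)
    r2 = _SEARCH_RADIUS_M**2
    return sorted(
        (
            (di, dj)
            for di in range(-ni, ni + 1)
            for dj in range(-nj, nj + 1)
            if (di * sx) ** 2 + (dj * sy) ** 2 <= r2
        ),
        key=lambda o: ((o[0] * sx) ** 2 + (o[1] * sy) ** 2, o[0], o[1]),
    )


@dataclass(frozen=True)
class ColonizationParams:
    """Parameters of the agent-based colonization model.

    ``t_div`` is the mean division interval (s, default 5400 s, a typical
    C. crescentus doubling in rich medium), ``p_near`` the probability that
    a daughter attaches beside her mother, ``offset``/``jitter`` the local
    daughter placement proposal (m), ``footprint`` the area of one cell on
    the surface (m^2; 1.29 um^2).
    """

    geometry: ChannelGeometry
    flow: FlowCondition
    diffusivity: float = D_SWIM
    kappa: float = field(default=None)  # type: ignore[assignment]
    t_div: float = 5400.0
    division_cv: float = 0.15
    p_near: float = 0.4
    offset: float = 2.0e-6
    jitter: float = 0.3e-6
    footprint: float = 1.29e-12
    aspect: float = 2.5
    cap: int = 500_000

    def __post_init__(self) -> None:
        if self.kappa is None:
            # default dimensionless reactivity kappa*h/D = 0.01
            object.__setattr__(self, "kappa", 0.01 * self.diffusivity / self.geometry.height)
        if not (0.0 <= self.p_near <= 1.0):
            raise InvalidParameterError("p_near must lie in [0, 1]")
        if self.t_div <= 0 or self.footprint <= 0:
            raise InvalidParameterError("t_div and footprint must be > 0")
        if self.diffusivity <= 0 or self.kappa < 0:
            raise InvalidParameterError("diffusivity must be > 0 and kappa >= 0")

    @property
    def cell_length(self) -> float:
        """Major-axis length of the elliptical footprint (m)."""
        return 2.0 * math.sqrt(self.footprint * self.aspect / math.pi)

    @property
    def site_spacing(self) -> tuple[float, float]:
        """Anisotropic lattice spacings (axial, lateral): one cell per site.

        Axial spacing equals the cell length; lateral spacing is
        ``footprint/length`` so that site area equals the footprint.
        """
        sx = self.cell_length
        return sx, self.footprint / sx

    @property
    def bulk_attach_rate(self) -> float:
        """Exponential attachment rate 1/(h/kappa + h^2/(3D)) (1/s)."""
        if self.kappa == 0:
            return 0.0
        h = self.geometry.height
        return 1.0 / (h / self.kappa + h * h / (3.0 * self.diffusivity))


@dataclass
class ColonizationSnapshot:
    """State of the surface population at one instant.

    Arrays are parallel per cell: positions (m), lineage color (0 green /
    1 magenta), founder id (each bulk reattachment founds a new lineage
    patch and receives a fresh id), birth time (s).  ``counts`` is the
    cumulative event ledger; local + reattached + washed_out == divisions.
    """

    time: float
    x: np.ndarray
    y: np.ndarray
    color: np.ndarray
    founder: np.ndarray
    birth: np.ndarray
    counts: dict

    @property
    def n_cells(self) -> int:
        return self.x.size

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_um": self.x * 1e6,
                "y_um": self.y * 1e6,
                "color": [COLOR_NAMES[c] for c in self.color],
                "founder_id": self.founder,
                "birth_s": self.birth,
            }
        )


def bulk_fate(x: float, y: float, params: ColonizationParams, rng: random.Random):
    """Resolve a daughter released into the bulk at floor position (x, y).

    Draws an exponential attachment waiting time at ``bulk_attach_rate``;
    the cell is carried ``v*t`` downstream and lands there unless that is
    past the outlet (washout).  Lateral position diffuses with variance
    ``2*D*t`` and reflects at the sidewalls.  Returns ``("attached", x2,
    y2)`` or ``("washed_out",)``.
    """
    g = params.geometry
    if not (0.0 <= x <= g.length and 0.0 <= y <= g.width):
        raise InvalidParameterError("release position outside the channel floor")
    rate = params.bulk_attach_rate
    v = params.flow.velocity
    if rate == 0.0:
        return ("washed_out",) if v > 0 else ("washed_out",)
    t = rng.expovariate(rate)
    x2 = x + v * t
    if x2 > g.length:
        return ("washed_out",)
    y2 = y + rng.gauss(0.0, math.sqrt(2.0 * params.diffusivity * t))
    # fold into [0, w] (reflecting sidewalls)
    w = g.width
    y2 = math.fmod(y2, 2.0 * w)
    if y2 < 0:
        y2 += 2.0 * w
    if y2 > w:
        y2 = 2.0 * w - y2
    return ("attached", x2, y2)


class ColonizationRun:
    """Mutable simulation state; create via :func:`init_population`."""

    def __init__(self, params: ColonizationParams, seed: int):
        self.params = params
        self.rng = random.Random(seed)
        self.seed = seed
        self.time = 0.0
        self.xs: list[float] = []
        self.ys: list[float] = []
        self.colors: list[int] = []
        self.founders: list[int] = []
        self.births: list[float] = []
        self.heap: list[tuple[float, int]] = []
        self.lattice: set[tuple[int, int]] = set()
        self.next_founder = 0
        self.capped = False
        self.counts = {
            "divisions": 0,
            "local_attachments": 0,
            "reattachments": 0,
            "washouts": 0,
        }
        g = params.geometry
        self._sx, self._sy = params.site_spacing
        self._imax = int(g.length / self._sx)
        self._jmax = int(g.width / self._sy)
        self._offsets = _search_offsets(self._sx, self._sy)

    # -- internal helpers ---------------------------------------------------
    def _interval(self) -> float:
        p = self.params
        return max(0.2 * p.t_div, self.rng.gauss(p.t_div, p.division_cv * p.t_div))

    def _take_site(self, px: float, py: float) -> tuple[float, float]:
        """Nearest free lattice site to the proposal point (Eden placement)."""
        sx, sy = self._sx, self._sy
        i0 = min(max(round(px / sx), 0), self._imax)
        j0 = min(max(round(py / sy), 0), self._jmax)
        for di, dj in self._offsets:
            ij = (i0 + di, j0 + dj)
            if 0 <= ij[0] <= self._imax and 0 <= ij[1] <= self._jmax and ij not in self.lattice:
                self.lattice.add(ij)
                return ij[0] * sx, ij[1] * sy
        # pathological local saturation: place at the proposal, untracked
        return min(max(px, 0.0), self._imax * sx), min(max(py, 0.0), self._jmax * sy)

    def _add_cell(self, x: float, y: float, color: int, founder: int, t: float) -> None:
        idx = len(self.xs)
        self.xs.append(x)
        self.ys.append(y)
        self.colors.append(color)
        self.founders.append(founder)
        self.births.append(t)
        heapq.heappush(self.heap, (t + self._interval(), idx))

    # -- public API ---------------------------------------------------------
    def advance(self, until: float) -> ColonizationSnapshot:
        """Process division events up to ``until`` and return a snapshot."""
        if until < self.time:
            raise InvalidParameterError("cannot advance to an earlier time")
        p, rng = self.params, self.rng
        while self.heap and self.heap[0][0] <= until and not self.capped:
            if len(self.xs) >= p.cap:
                self.capped = True
                warnings.warn(
                    f"population cap {p.cap} reached at t={self.heap[0][0]:.0f}s; "
                    "simulation truncated",
                    stacklevel=2,
                )
                break
            t, i = heapq.heappop(self.heap)
            self.counts["divisions"] += 1
            heapq.heappush(self.heap, (t + self._interval(), i))
            xm, ym = self.xs[i], self.ys[i]
            if rng.random() < p.p_near:
                px = xm + p.offset + rng.gauss(0.0, p.jitter)
                py = ym + rng.gauss(0.0, p.jitter)
                x2, y2 = self._take_site(px, py)
                self._add_cell(x2, y2, self.colors[i], self.founders[i], t)
                self.counts["local_attachments"] += 1
            else:
                fate = bulk_fate(xm, ym, p, rng)
                if fate[0] == "attached":
                    x2, y2 = self._take_site(fate[1], fate[2])
                    fid = self.next_founder
                    self.next_founder += 1
                    self._add_cell(x2, y2, self.colors[i], fid, t)
                    self.counts["reattachments"] += 1
                else:
                    self.counts["washouts"] += 1
        self.time = until
        return self.snapshot()

    def snapshot(self) -> ColonizationSnapshot:
        return ColonizationSnapshot(
            time=self.time,
            x=np.array(self.xs),
            y=np.array(self.ys),
            color=np.array(self.colors, dtype=np.int8),
            founder=np.array(self.founders, dtype=np.int64),
            birth=np.array(self.births),
            counts=dict(self.counts),
        )


def init_population(
    n_founders: int,
    color_fractions: tuple[float, float],
    params: ColonizationParams,
    seed: int = 0,
) -> ColonizationRun:
    """Seed the floor with founder cells at uniform random positions.

    Colors are drawn independently with the given (green, magenta)
    fractions; division clocks are drawn from the division-interval
    distribution.  Deterministic given ``seed``.
    """
    if n_founders < 1:
        raise InvalidParameterError("n_founders must be >= 1")
    if len(color_fractions) != 2 or abs(sum(color_fractions) - 1.0) > 1e-9 or min(color_fractions) < 0:
        raise InvalidParameterError("color_fractions must be two nonnegative values summing to 1")
    g = params.geometry
    if n_founders * params.footprint > 0.25 * g.floor_area:
        raise InvalidParameterError("n_founders exceeds the floor packing bound")
    run = ColonizationRun(params, seed)
    for k in range(n_founders):
        px = run.rng.uniform(0.0, g.length)
        py = run.rng.uniform(0.0, g.width)
        x, y = run._take_site(px, py)
        color = GREEN if run.rng.random() < color_fractions[0] else MAGENTA
        run._add_cell(x, y, color, run.next_founder, 0.0)
        run.next_founder += 1
    return run


def run_colonization(
    params: ColonizationParams,
    n_founders: int,
    snapshot_times,
    color_fractions: tuple[float, float] = (0.5, 0.5),
    seed: int = 0,
) -> list[ColonizationSnapshot]:
    """Initialise and advance through sorted ``snapshot_times`` (seconds)."""
    times = list(snapshot_times)
    if times != sorted(times):
        raise InvalidParameterError("snapshot_times must be sorted")
    run = init_population(n_founders, color_fractions, params, seed)
    return [run.advance(t) for t in times]


def colony_table(snapshot: ColonizationSnapshot, min_cells: int = 1) -> pd.DataFrame:
    """Per-lineage-patch summary: founder id, color, cell count, centroid (um).

    Ground-truth counterpart of image-based colony statistics: each founder
    id is one clonal patch.  ``min_cells`` mirrors the image-side minimum
    colony size filter.
    """
    if snapshot.n_cells == 0:
        return pd.DataFrame(columns=["founder_id", "color", "n_cells", "cx_um", "cy_um"])
    df = pd.DataFrame(
        {
            "founder_id": snapshot.founder,
            "color": snapshot.color,
            "x_um": snapshot.x * 1e6,
            "y_um": snapshot.y * 1e6,
        }
    )
    grouped = df.groupby("founder_id").agg(
        color=("color", "first"),
        n_cells=("x_um", "size"),
        cx_um=("x_um", "mean"),
        cy_um=("y_um", "mean"),
    )
    grouped = grouped[grouped["n_cells"] >= min_cells].reset_index()
    return grouped
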
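"""Synthetic two-channel fluorescence rendering with ground-truth masks.

Surface populations are rasterised into two single-channel images (one per
constitutive fluorophore, mirroring separate mKate/Venus acquisitions):
each cell is painted as a filled ellipse of the configured footprint
oriented along the flow, the image is Gaussian-blurred, and a linear
background gradient plus additive Gaussian noise are applied.  The
ground-truth label masks are the pre-blur, pre-noise cell labels, so the
downstream quantification pipeline can be validated pixel-for-pixel.

The default pixel size of 0.1791 um/px is back-derived from the empirical
equivalence of the mean cell footprint, 1.29 um^2 ~= 40.2 px
(sqrt(1.29/40.2) = 0.1791); it makes the 15-px and 200-px area thresholds
of the quantification pipeline physically meaningful on synthetic data.

A small set of named, seed-pinned toy fixtures with exactly known ground
truth (squares, checkerboards, saturated fields) exercises every branch of
the quantification pipeline without any real microscopy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage import draw

from .colonize import ColonizationSnapshot, GREEN, MAGENTA
from .errors import InvalidParameterError

#: Default raster scale (um per pixel), back-derived from 1.29 um^2 ~= 40.2 px.
DEFAULT_PIXEL_UM = 0.1791

FIXTURE_NAMES = (
    "blank",
    "single_cell",
    "two_squares_gap6",
    "two_squares_gap20",
    "checkerboard_mixed",
    "segregated_halves",
    "near_saturated",
)


@dataclass(frozen=True)
class RenderParams:
    """Optical and noise parameters of the synthetic microscope.

    ``aspect`` is the cell's major/minor axis ratio (a 1.29 um^2 ellipse at
    aspect 2.5 is ~2.0 x 0.8 um, a typical C. crescentus outline);
    ``blur_um`` a Gaussian optical blur; ``background``/``gradient`` a
    linear shading plane; ``noise`` the additive Gaussian noise scale
    (camera counts).
    """

    pixel_um: float = DEFAULT_PIXEL_UM
    footprint_um2: float = 1.29
    aspect: float = 2.5
    blur_um: float = 0.15
    background: float = 100.0
    gradient: float = 20.0
    noise: float = 10.0
    amplitude: float = 1000.0

    def __post_init__(self) -> None:
        if self.pixel_um <= 0 or self.footprint_um2 <= 0:
            raise InvalidParameterError("pixel size and footprint must be > 0")
        if self.blur_um < 0 or self.noise < 0 or self.background < 0:
            raise InvalidParameterError("blur, noise and background must be >= 0")

    @property
    def semi_axes_um(self) -> tuple[float, float]:
        """Semi-major (along flow) and semi-minor axes in um."""
        b = math.sqrt(self.footprint_um2 / (math.pi * self.aspect))
        return self.aspect * b, b


@dataclass
class SyntheticImage:
    """Two-channel raster plus per-channel ground-truth label masks."""

    channels: tuple[np.ndarray, np.ndarray]  # (green, magenta), uint16
    truth: tuple[np.ndarray, np.ndarray]  # int32 label images, pre-blur
    pixel_um: float
    params: RenderParams | None
    seed: int | None

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (*self.channels, *self.truth)}
        if len(shapes) != 1:
            raise InvalidParameterError("rasters and masks must share dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[0].shape

    def truth_table(self) -> pd.DataFrame:
        """Centroids and areas (px) of every ground-truth object."""
        rows = []
        for ch, lab in zip(("green", "magenta"), self.truth):
            for oid in np.unique(lab):
                if oid == 0:
                    continue
                rr, cc = np.nonzero(lab == oid)
                rows.append(
                    {
                        "channel": ch,
                        "label": int(oid),
                        "area_px": rr.size,
                        "row": float(rr.mean()),
                        "col": float(cc.mean()),
                    }
                )
        return pd.DataFrame(rows, columns=["channel", "label", "area_px", "row", "col"])

    def write(self, prefix: str) -> None:
        """Write `<prefix>_{green,magenta}.tif`, truth labels and a truth CSV."""
        for name, raster, lab in zip(
            ("green", "magenta"), self.channels, self.truth
        ):
            tifffile.imwrite(f"{prefix}_{name}.tif", raster)
            tifffile.imwrite(f"{prefix}_truth_{name}.tif", lab.astype(np.int32))
        self.truth_table().to_csv(f"{prefix}_truth.csv", index=False)


def _paint(
    lab: np.ndarray,
    rows_um,
    cols_um,
    params: RenderParams,
    start_label: int = 1,
) -> int:
    """Paint filled ellipses (flow along columns) into a label image."""
    a_um, b_um = params.semi_axes_um
    a_px = a_um / params.pixel_um
    b_px = b_um / params.pixel_um
    label = start_label
    for r_um, c_um in zip(rows_um, cols_um):
        rr, cc = draw.ellipse(
            r_um / params.pixel_um,
            c_um / params.pixel_um,
            b_px,
            a_px,
            shape=lab.shape,
        )
        lab[rr, cc] = label
        label += 1
    return label


def render(
    population,
    window_um: tuple[float, float, float, float],
    params: RenderParams | None = None,
    seed: int = 0,
) -> SyntheticImage:
    """Render the cells falling inside a floor window into a SyntheticImage.

    ``population`` is a :class:`~colonyflow.colonize.ColonizationSnapshot`
    or a DataFrame with columns ``x_um, y_um, color`` (color ``green`` /
    ``magenta`` or 0/1).  ``window_um = (x0, y0, width, height)`` selects
    the imaged region of the channel floor in absolute um coordinates;
    image columns run along the flow (x), rows across the channel (y).
    Deterministic given ``seed``; ground truth is independent of the noise
    seed by construction.
    """
    params = params or RenderParams()
    x0, y0, wx, wy = window_um
    a_um, _ = params.semi_axes_um
    if wx < 2 * a_um or wy < 2 * a_um:
        raise InvalidParameterError("window smaller than one cell footprint")

    if isinstance(population, ColonizationSnapshot):
        x_um = population.x * 1e6
        y_um = population.y * 1e6
        color = population.color
    else:
        x_um = np.asarray(population["x_um"], dtype=float)
        y_um = np.asarray(population["y_um"], dtype=float)
        col = population["color"]
        color = np.array(
            [c if isinstance(c, (int, np.integer)) else {"green": GREEN, "magenta": MAGENTA}[c] for c in col],
            dtype=np.int8,
        )

    ny = int(round(wy / params.pixel_um))
    nx = int(round(wx / params.pixel_um))
    margin = 2 * a_um
    keep = (
        (x_um >= x0 - margin)
        & (x_um <= x0 + wx + margin)
        & (y_um >= y0 - margin)
        & (y_um <= y0 + wy + margin)
    )

    truth = []
    rasters = []
    rng = np.random.default_rng(seed)
    sigma_px = params.blur_um / params.pixel_um
    for ch in (GREEN, MAGENTA):
        lab = np.zeros((ny, nx), dtype=np.int32)
        sel = keep & (color == ch)
        _paint(lab, y_um[sel] - y0, x_um[sel] - x0, params)
        truth.append(lab)
        img = np.where(lab > 0, params.amplitude, 0.0)
        if sigma_px > 0:
            img = ndimage.gaussian_filter(img, sigma_px)
        img += params.background + params.gradient * (
            np.arange(nx, dtype=float)[None, :] / max(nx - 1, 1)
        )
        if params.noise > 0:
            img += rng.normal(0.0, params.noise, size=img.shape)
        rasters.append(np.clip(img, 0, 65535).astype(np.uint16))

    return SyntheticImage(
        channels=(rasters[0], rasters[1]),
        truth=(truth[0], truth[1]),
        pixel_um=params.pixel_um,
        params=params,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# deterministic toy fixtures with exactly known ground truth
# ---------------------------------------------------------------------------

def _blocks_image(shape, green_boxes, magenta_boxes, pixel_um, seed=0, noise=5.0):
    """Build a SyntheticImage from lists of (r0, c0, height, width) boxes."""
    rng = np.random.default_rng(seed)
    chans, labs = [], []
    for boxes in (green_boxes, magenta_boxes):
        lab = np.zeros(shape, dtype=np.int32)
        for k, (r0, c0, hh, ww) in enumerate(boxes, start=1):
            lab[r0 : r0 + hh, c0 : c0 + ww] = k
        img = np.where(lab > 0, 1000.0, 0.0) + 100.0
        if noise > 0:
            img += rng.normal(0.0, noise, size=shape)
        chans.append(np.clip(img, 0, 65535).astype(np.uint16))
        labs.append(lab)
    return SyntheticImage(
        channels=(chans[0], chans[1]),
        truth=(labs[0], labs[1]),
        pixel_um=pixel_um,
        params=None,
        seed=seed,
    )


def make_fixture(name: str) -> SyntheticImage:
    """Return a named deterministic fixture with documented ground truth.

    ``blank``: background and noise only.  ``single_cell``: one rendered
    cell at the default pixel scale (truth area ~= 40 px).
    ``two_squares_gap6``/``two_squares_gap20``: two 20x20-px squares
    separated along the flow by 6 or 20 px; a disk-radius-5 closing merges
    the former but not the latter.  ``checkerboard_mixed``: alternating
    green/magenta 10x10 colonies on a 30-px grid (cross-lineage nearest
    neighbour = 30 px).  ``segregated_halves``: one green and one magenta
    block with centroids 80 px apart.  ``near_saturated``: true coverage
    ~0.85, above the 80% analysis gate.  Geometric fixtures use a pixel
    size of 1.0 um for round-number distances.
    """
    if name == "blank":
        rng = np.random.default_rng(7)
        shape = (256, 256)
        img = np.clip(100.0 + rng.normal(0.0, 10.0, shape), 0, 65535).astype(np.uint16)
        img2 = np.clip(100.0 + rng.normal(0.0, 10.0, shape), 0, 65535).astype(np.uint16)
        z = np.zeros(shape, dtype=np.int32)
        return SyntheticImage((img, img2), (z, z.copy()), DEFAULT_PIXEL_UM, None, 7)

    if name == "single_cell":
        # subpixel-pinned so the rasterised footprint is exactly 40 px
        cells = pd.DataFrame({"x_um": [12.085], "y_um": [12.051], "color": ["green"]})
        return render(cells, (0.0, 0.0, 24.0, 24.0), RenderParams(), seed=11)

    if name == "two_squares_gap6":
        return _blocks_image(
            (128, 128),
            green_boxes=[(54, 30, 20, 20), (54, 56, 20, 20)],  # gap = 56-50 = 6 px
            magenta_boxes=[],
            pixel_um=1.0,
            seed=13,
        )

    if name == "two_squares_gap20":
        return _blocks_image(
            (128, 128),
            green_boxes=[(54, 20, 20, 20), (54, 60, 20, 20)],  # gap = 60-40 = 20 px
            magenta_boxes=[],
            pixel_um=1.0,
            seed=13,
        )

    if name == "checkerboard_mixed":
        green, magenta = [], []
        for i in range(4):
            for j in range(4):
                box = (25 + 30 * i - 5, 25 + 30 * j - 5, 10, 10)
                (green if (i + j) % 2 == 0 else magenta).append(box)
        return _blocks_image((150, 150), green, magenta, pixel_um=1.0, seed=17)

    if name == "segregated_halves":
        # centroids at columns 30 and 110 on the same rows: distance 80 px,
        # block-edge gap 60 px
        return _blocks_image(
            (128, 128),
            green_boxes=[(44, 20, 40, 20)],
            magenta_boxes=[(44, 100, 40, 20)],
            pixel_um=1.0,
            seed=19,
        )

    if name == "near_saturated":
        shape = (200, 200)
        lab = np.zeros(shape, dtype=np.int32)
        lab[0:185, 0:184] = 1  # coverage 0.851
        rng = np.random.default_rng(23)
        img = np.where(lab > 0, 1000.0, 0.0) + 100.0 + rng.normal(0, 5.0, shape)
        img = np.clip(img, 0, 65535).astype(np.uint16)
        empty = np.zeros(shape, dtype=np.int32)
        bg = np.clip(100.0 + rng.normal(0, 5.0, shape), 0, 65535).astype(np.uint16)
        return SyntheticImage((img, bg), (lab, empty), DEFAULT_PIXEL_UM, None, 23)

    raise InvalidParameterError(
        f"unknown fixture {name!r}; valid fixtures: {', '.join(FIXTURE_NAMES)}"
    )
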
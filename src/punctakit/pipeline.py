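"""Single-cell puncta measurement chain.

The chain mirrors the standard ImageJ/Fiji workflow for quantifying
fluorescent vesicle markers in a confocal image of one cell:

1. spatial calibration (pixels -> micrometres),
2. overlay of the z-stack into a single 2-D image,
3. conversion to 8-bit grayscale,
4. white top-hat filtering to suppress background structures larger
   than the structuring element,
5. fixed-value thresholding,
6. connected-component "particle" analysis yielding one row per
   punctum with its area in square micrometres.

Each stage is exposed as a standalone function; :func:`run_pipeline`
composes them and records every parameter in the output provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from skimage import measure, morphology
from skimage.filters import threshold_otsu

__all__ = [
    "CalibratedImage",
    "PipelineParams",
    "PunctaTable",
    "PUNCTA_COLUMNS",
    "calibrate",
    "overlay_stack",
    "to_eight_bit",
    "white_top_hat",
    "threshold",
    "label_components",
    "analyze_particles",
    "run_pipeline",
]

PUNCTA_COLUMNS = (
    "label",
    "area_um2",
    "area_px",
    "centroid_x_um",
    "centroid_y_um",
    "equivalent_diameter_um",
)


@dataclass(frozen=True)
class CalibratedImage:
    """A 2-D intensity grid with a physical scale attached.

    Parameters
    ----------
    pixels:
        2-D array of nonnegative intensities.
    um_per_pixel:
        Side length of one pixel in micrometres (isotropic).
    channel_id:
        Free-form marker/channel label (e.g. ``"LC3B"``).
    bit_depth:
        ``"native"`` for raw acquisition values, ``"eight_bit"`` after
        :func:`to_eight_bit`.
    """

    pixels: np.ndarray
    um_per_pixel: float
    channel_id: str = ""
    bit_depth: Literal["native", "eight_bit"] = "native"

    def __post_init__(self) -> None:
        if self.um_per_pixel is None or not self.um_per_pixel > 0:
            raise ValueError(
                f"um_per_pixel must be positive, got {self.um_per_pixel!r}"
            )
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {px.shape}")
        object.__setattr__(self, "pixels", px)
        if self.bit_depth == "eight_bit":
            if px.dtype != np.uint8:
                raise ValueError("eight_bit images must have dtype uint8")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class PipelineParams:
    """Parameters of the measurement chain.

    ``threshold_value`` is an integer in [0, 255] applied to the 8-bit
    top-hat-filtered image (foreground = intensity >= T, the ImageJ
    dark-background convention).  The string ``"otsu"`` selects the
    threshold automatically; automatic mode is meant for exploratory
    runs only, because group comparisons require the same fixed
    threshold for every cell of a replicate.
    """

    tophat_radius_px: int = 15
    threshold_value: int | str = 110
    connectivity: Literal[4, 8] = 8
    min_area_um2: float = 0.0
    projection: Literal["max", "sum"] = "max"

    def __post_init__(self) -> None:
        if self.tophat_radius_px < 1:
            raise ValueError("tophat_radius_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_area_um2 < 0:
            raise ValueError("min_area_um2 must be nonnegative")
        if self.projection not in ("max", "sum"):
            raise ValueError("projection must be 'max' or 'sum'")
        if isinstance(self.threshold_value, str):
            if self.threshold_value != "otsu":
                raise ValueError(
                    "threshold_value must be an integer in [0, 255] or 'otsu'"
                )
        elif not 0 <= int(self.threshold_value) <= 255:
            raise ValueError("threshold_value outside [0, 255]")

    def as_dict(self) -> dict:
        return {
            "tophat_radius_px": self.tophat_radius_px,
            "threshold_value": self.threshold_value,
            "connectivity": self.connectivity,
            "min_area_um2": self.min_area_um2,
            "projection": self.projection,
        }


@dataclass
class PunctaTable:
    """Per-punctum measurements for one cell and channel.

    ``df`` has one row per detected punctum with columns
    :data:`PUNCTA_COLUMNS`; centroids are in micrometres from the image
    origin (x = column axis, y = row axis).  ``label_image`` keeps the
    integer component labels so downstream stages (peripheral analysis,
    colocalization within large puncta) can rebuild pixel masks.
    """

    df: pd.DataFrame
    um_per_pixel: float
    provenance: dict = field(default_factory=dict)
    label_image: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.df)

    @property
    def areas_um2(self) -> np.ndarray:
        return self.df["area_um2"].to_numpy()

    def large_labels(self, min_area_um2: float) -> np.ndarray:
        """Labels of puncta with area strictly greater than ``min_area_um2``."""
        sel = self.df["area_um2"] > min_area_um2
        return self.df.loc[sel, "label"].to_numpy()


def calibrate(
    pixels: np.ndarray, um_per_pixel: float, channel_id: str = ""
) -> CalibratedImage:
    """Attach a micrometre-per-pixel scale to a raw intensity grid.

    All downstream areas are reported as ``pixel_count * um_per_pixel**2``.
    Raises ``ValueError`` for a missing or non-positive scale.
    """
    if um_per_pixel is None or not um_per_pixel > 0:
        raise ValueError(f"um_per_pixel must be positive, got {um_per_pixel!r}")
    return CalibratedImage(np.asarray(pixels), float(um_per_pixel), channel_id)


def overlay_stack(
    stack: Sequence[CalibratedImage], method: Literal["max", "sum"] = "max"
) -> CalibratedImage:
    """Collapse an ordered z-stack into a single 2-D image.

    Default is the maximum-intensity projection, the standard way of
    overlaying sparse bright puncta; ``method="sum"`` gives a sum
    projection instead.  All slices must share shape, scale and channel.
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    first = stack[0]
    for sl in stack[1:]:
        if sl.shape != first.shape:
            raise ValueError("stack slices differ in shape")
        if sl.um_per_pixel != first.um_per_pixel:
            raise ValueError("stack slices differ in um_per_pixel")
        if sl.channel_id != first.channel_id:
            raise ValueError("stack slices differ in channel_id")
    arr = np.stack([sl.pixels for sl in stack])
    proj = arr.max(axis=0) if method == "max" else arr.sum(axis=0)
    return replace(first, pixels=proj)


def to_eight_bit(img: CalibratedImage) -> CalibratedImage:
    """Linear min-max rescale to [0, 255] with round-half-up.

    A constant image maps to all zeros.  An image that already spans
    exactly [0, 255] in integers is returned value-identical.
    """
    px = np.asarray(img.pixels, dtype=float)
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        out = np.zeros(px.shape, dtype=np.uint8)
    else:
        scaled = (px - lo) * (255.0 / (hi - lo))
        out = np.floor(scaled + 0.5).clip(0, 255).astype(np.uint8)
    return CalibratedImage(out, img.um_per_pixel, img.channel_id, "eight_bit")


def white_top_hat(img: CalibratedImage, radius_px: int) -> CalibratedImage:
    """White top-hat: image minus its morphological opening by a disc.

    Removes structures wider than the disc (diffuse cytoplasmic signal,
    uneven background) while preserving bright puncta narrower than it.
    The output is nonnegative and pointwise <= the input.
    """
    if radius_px < 1:
        raise ValueError("structuring-element radius must be >= 1")
    if img.bit_depth != "eight_bit":
        raise ValueError("white_top_hat expects an 8-bit image; call to_eight_bit first")
    footprint = morphology.disk(int(radius_px))
    out = morphology.white_tophat(img.pixels, footprint)
    return replace(img, pixels=out)


def threshold(img: CalibratedImage, value_or_method: int | str) -> np.ndarray:
    """Binarize an 8-bit image: foreground = intensity >= T.

    ``value_or_method`` is either a fixed integer threshold in [0, 255]
    or ``"otsu"`` for automatic selection (exploratory use only).
    Returns a boolean mask.
    """
    if img.bit_depth != "eight_bit":
        raise ValueError("threshold expects an 8-bit image")
    if isinstance(value_or_method, str):
        if value_or_method != "otsu":
            raise ValueError(f"unknown auto-threshold method {value_or_method!r}")
        value = float(threshold_otsu(img.pixels))
    else:
        value = int(value_or_method)
        if not 0 <= value <= 255:
            raise ValueError(f"threshold {value} outside [0, 255]")
    return img.pixels >= value


def label_components(mask: np.ndarray, connectivity: Literal[4, 8] = 8) -> np.ndarray:
    """Integer-label the connected components of a binary mask.

    ``connectivity=4`` joins edge neighbours only; ``8`` also joins
    diagonals (the ImageJ Analyze Particles behaviour and the default).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    # skimage: connectivity 1 == 4-connected, 2 == 8-connected
    return measure.label(np.asarray(mask, dtype=bool), connectivity=1 if connectivity == 4 else 2)


def analyze_particles(
    mask: np.ndarray,
    um_per_pixel: float,
    connectivity: Literal[4, 8] = 8,
    min_area_um2: float = 0.0,
) -> PunctaTable:
    """Connected-component particle analysis of a binary mask.

    One row per component with area >= ``min_area_um2``; areas in
    square micrometres, centroids in micrometres from the image origin.
    An empty mask yields an empty table.
    """
    if um_per_pixel is None or not um_per_pixel > 0:
        raise ValueError("um_per_pixel must be positive")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    labels = label_components(mask, connectivity)
    px_area = um_per_pixel**2
    rows = []
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for region in measure.regionprops(labels):
        area_um2 = region.area * px_area
        if area_um2 < min_area_um2:
            continue
        keep[region.label] = True
        cy, cx = region.centroid
        rows.append(
            (
                region.label,
                area_um2,
                int(region.area),
                cx * um_per_pixel,
                cy * um_per_pixel,
                2.0 * np.sqrt(area_um2 / np.pi),
            )
        )
    df = pd.DataFrame(rows, columns=list(PUNCTA_COLUMNS))
    label_image = np.where(keep[labels], labels, 0)
    return PunctaTable(
        df=df,
        um_per_pixel=float(um_per_pixel),
        provenance={"connectivity": connectivity, "min_area_um2": min_area_um2},
        label_image=label_image,
    )


def run_pipeline(
    stack: Sequence[CalibratedImage] | CalibratedImage,
    params: PipelineParams | None = None,
    image_id: str = "",
) -> PunctaTable:
    """Run the full measurement chain on a calibrated z-stack.

    calibrate -> overlay -> 8-bit -> white top-hat -> threshold ->
    particle analysis.  A single image is treated as a one-slice stack.
    Provenance records every parameter together with the image geometry.
    """
    params = params or PipelineParams()
    if isinstance(stack, CalibratedImage):
        stack = [stack]
    proj = overlay_stack(stack, method=params.projection)
    eight = to_eight_bit(proj)
    filtered = white_top_hat(eight, params.tophat_radius_px)
    mask = threshold(filtered, params.threshold_value)
    table = analyze_particles(
        mask,
        um_per_pixel=proj.um_per_pixel,
        connectivity=params.connectivity,
        min_area_um2=params.min_area_um2,
    )
    table.provenance = {
        "image_id": image_id,
        "channel_id": proj.channel_id,
        "n_slices": len(stack),
        "image_shape": list(proj.shape),
        "um_per_pixel": proj.um_per_pixel,
        "eight_bit_rescale": "per-image min-max",
        **params.as_dict(),
    }
    return table
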
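"""Two-channel colocalization by no-threshold Pearson correlation.

Each channel is background-suppressed with the same white top-hat
filter used for puncta detection, then the Pearson correlation of pixel
intensities is computed over a region of interest with *no* intensity
threshold.  The ROI defaults to the estimated cell mask (background
pixels outside the cell would inflate the coefficient); whole-frame
mode and an ROI restricted to large puncta are also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pipeline import CalibratedImage, PunctaTable, to_eight_bit, white_top_hat

__all__ = [
    "ColocResult",
    "pearson_no_threshold",
    "percent_reduction",
    "coloc_in_large_puncta",
]


@dataclass
class ColocResult:
    """Pearson colocalization over one ROI.

    ``pearson_r`` is ``None`` (missing) when undefined: fewer than two
    ROI pixels or a constant channel.
    """

    pearson_r: float | None
    n_pixels: int
    roi: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pearson_r is not None and abs(self.pearson_r) > 1 + 1e-12:
            raise ValueError("|r| must not exceed 1")


def _prepare(ch: CalibratedImage, tophat_radius_px: int | None) -> np.ndarray:
    if tophat_radius_px is None:
        return np.asarray(ch.pixels, dtype=float)
    eight = ch if ch.bit_depth == "eight_bit" else to_eight_bit(ch)
    return np.asarray(white_top_hat(eight, tophat_radius_px).pixels, dtype=float)


def _pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    if a.size < 2:
        return None
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None  # correlation undefined for a constant channel
    return float(np.corrcoef(a, b)[0, 1])


def pearson_no_threshold(
    ch1: CalibratedImage,
    ch2: CalibratedImage,
    roi: np.ndarray | None = None,
    tophat_radius_px: int | tuple[int, int] | None = 15,
    roi_label: str | None = None,
) -> ColocResult:
    """No-threshold Pearson correlation of two co-registered channels.

    ``roi`` is a boolean mask (``None`` = whole frame).  Both channels
    are top-hat filtered before correlation; pass
    ``tophat_radius_px=None`` to correlate raw intensities.  The radii
    may differ per channel (tuple).
    """
    if ch1.shape != ch2.shape:
        raise ValueError("channel shapes differ")
    if ch1.um_per_pixel != ch2.um_per_pixel:
        raise ValueError("channel calibrations differ")
    if isinstance(tophat_radius_px, tuple):
        r1, r2 = tophat_radius_px
    else:
        r1 = r2 = tophat_radius_px
    a = _prepare(ch1, r1)
    b = _prepare(ch2, r2)
    if roi is None:
        roi = np.ones(a.shape, dtype=bool)
        label = roi_label or "whole-frame"
    else:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != a.shape:
            raise ValueError("ROI shape differs from channel shape")
        label = roi_label or "mask"
    av, bv = a[roi], b[roi]
    return ColocResult(
        pearson_r=_pearson(av, bv),
        n_pixels=int(roi.sum()),
        roi=label,
        params={"tophat_radius_px": (r1, r2), "threshold": "none"},
    )


def percent_reduction(r_control: float, r_treated: float) -> float:
    """Signed percent change of a coefficient relative to control.

    ``100 * (r_control - r_treated) / r_control``; an increase under
    treatment comes out negative.  Round the result for report echo
    (e.g. 0.829 -> 0.515 prints as a 38% reduction).
    """
    if r_control == 0:
        raise ValueError("control coefficient is zero; reduction undefined")
    return 100.0 * (r_control - r_treated) / r_control


def coloc_in_large_puncta(
    ch1: CalibratedImage,
    ch2: CalibratedImage,
    table: PunctaTable,
    min_area_um2: float = 10.0,
    tophat_radius_px: int | tuple[int, int] | None = 15,
) -> ColocResult:
    """Pearson correlation restricted to the union of large puncta.

    The ROI is built from the reference-channel puncta table: pixels of
    every punctum with area strictly above ``min_area_um2``.  With no
    such puncta the result is missing.
    """
    if table.label_image is None:
        raise ValueError("puncta table lacks a label image")
    labels = table.large_labels(min_area_um2)
    roi = np.isin(table.label_image, labels) & (table.label_image > 0)
    if not roi.any():
        return ColocResult(
            pearson_r=None,
            n_pixels=0,
            roi="large-puncta",
            params={"min_area_um2": min_area_um2},
        )
    result = pearson_no_threshold(
        ch1, ch2, roi=roi, tophat_radius_px=tophat_radius_px, roi_label="large-puncta"
    )
    result.params["min_area_um2"] = min_area_um2
    return result
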
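"""Visual quality-control overlays."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from skimage import measure

from .pipeline import CalibratedImage, PunctaTable
from .periphery import CellGeometry

__all__ = ["render_qc"]


def render_qc(
    img: CalibratedImage,
    table: PunctaTable | None,
    geom: CellGeometry | None,
    out_path,
    scalebar_um: float = 10.0,
) -> Path:
    """Write a PNG overlay of detected puncta, band boundary and scale bar.

    Puncta outlines come from the table's label image; the peripheral
    band (if computed on ``geom``) is drawn as its inner boundary
    contour.  Intended for eyeballing a run, not for measurement.
    """
    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(np.asarray(img.pixels), cmap="gray")
    if table is not None and table.label_image is not None and len(table):
        for label in table.df["label"]:
            for contour in measure.find_contours(table.label_image == label, 0.5):
                ax.plot(contour[:, 1], contour[:, 0], color="orange", lw=0.8)
    if geom is not None:
        for contour in measure.find_contours(geom.cell_mask.astype(float), 0.5):
            ax.plot(contour[:, 1], contour[:, 0], color="cyan", lw=1.0)
        if geom.band_mask is not None:
            interior = geom.cell_mask & ~geom.band_mask
            for contour in measure.find_contours(interior.astype(float), 0.5):
                ax.plot(
                    contour[:, 1], contour[:, 0], color="magenta", lw=1.0, ls="--"
                )
    # scale bar, bottom-right
    bar_px = scalebar_um / img.um_per_pixel
    h, w = img.shape
    ax.plot(
        [w - bar_px - 10, w - 10], [h - 15, h - 15], color="white", lw=3
    )
    ax.text(
        w - bar_px / 2 - 10,
        h - 25,
        f"{scalebar_um:g} µm",
        color="white",
        ha="center",
        fontsize=8,
    )
    ax.set_axis_off()
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out_path
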
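"""Small helpers shared across test modules."""

import math

import numpy as np
import pandas as pd

from punctakit import PunctaTable


def circular_mask(shape, center_rc, radius_px):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center_rc[0]) ** 2 + (xx - center_rc[1]) ** 2 <= radius_px**2


def table_from_truth(truth, um_per_pixel, center_px, rotate90: int = 0, grid: int = 320):
    """Build a PunctaTable directly from ground-truth centroids.

    Centroids are re-expressed relative to a cell centered at
    ``center_px`` (row, col) on a ``grid``-sized field, optionally
    rotated by ``rotate90`` quarter turns of that field.
    """
    cx, cy = truth.cell_center_um
    rows = []
    span = (grid - 1) * um_per_pixel
    for i, p in enumerate(truth.puncta, start=1):
        x = center_px[1] * um_per_pixel + (p.centroid_um[0] - cx)
        y = center_px[0] * um_per_pixel + (p.centroid_um[1] - cy)
        for _ in range(rotate90 % 4):
            x, y = y, span - x
        rows.append(
            {
                "label": i,
                "area_um2": p.area_um2,
                "area_px": max(p.rendered_area_px or 1, 1),
                "centroid_x_um": x,
                "centroid_y_um": y,
                "equivalent_diameter_um": 2 * math.sqrt(p.area_um2 / math.pi),
            }
        )
    return PunctaTable(df=pd.DataFrame(rows), um_per_pixel=um_per_pixel)
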
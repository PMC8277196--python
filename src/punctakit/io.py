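"""TIFF / CSV / JSON input-output with provenance sidecars.

Stacks are written as multi-page TIFF, channel-major (all slices of
channel 0, then channel 1, ...), with the micrometre-per-pixel scale
recorded in the TIFF resolution tags.  A scale passed explicitly by
the caller always wins over the resolution tags (with a logged
warning when both are present and disagree).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .pipeline import CalibratedImage, PunctaTable, PUNCTA_COLUMNS
from .simulate import GroundTruth

log = logging.getLogger("punctakit")

__all__ = [
    "write_stack_tiff",
    "read_stack_tiff",
    "write_ground_truth",
    "read_ground_truth",
    "write_puncta_table",
    "read_puncta_table",
    "file_sha256",
    "write_manifest",
]


def write_stack_tiff(
    path,
    channels: Sequence[Sequence[CalibratedImage]] | Sequence[CalibratedImage],
) -> Path:
    """Write one or more channel stacks to a multi-page TIFF.

    Accepts a single stack (list of slices) or a list of stacks, one
    per channel; pages are written channel-major.  The scale goes into
    the resolution tags as pixels-per-centimetre.
    """
    path = Path(path)
    if channels and isinstance(channels[0], CalibratedImage):
        channels = [channels]  # type: ignore[list-item]
    scale = channels[0][0].um_per_pixel
    pages = [
        np.asarray(sl.pixels, dtype=np.float32)
        for stack in channels
        for sl in stack
    ]
    px_per_cm = 1.0e4 / scale
    tifffile.imwrite(
        path,
        np.stack(pages),
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        photometric="minisblack",
        metadata={
            "um_per_pixel": scale,
            "n_channels": len(channels),
            "n_slices": len(channels[0]),
            "channel_ids": [stack[0].channel_id for stack in channels],
        },
    )
    return path


def _scale_from_tags(tif: tifffile.TiffFile) -> float | None:
    page = tif.pages[0]
    tag = page.tags.get("XResolution")
    unit = page.tags.get("ResolutionUnit")
    if tag is None:
        return None
    num, den = tag.value
    if num == 0:
        return None
    px_per_unit = num / den
    unit_um = {2: 25400.0, 3: 10000.0}.get(getattr(unit.value, "value", unit.value) if unit else 3, 10000.0)
    return unit_um / px_per_unit


def read_stack_tiff(
    path,
    um_per_pixel: float | None = None,
    n_channels: int | None = None,
    channel_ids: Sequence[str] | None = None,
) -> list[list[CalibratedImage]]:
    """Read a channel-major multi-page TIFF into channel stacks.

    The scale comes from the TIFF resolution tags unless
    ``um_per_pixel`` is given, which overrides the tags (a disagreement
    is logged).  Returns ``channels[c][z]`` as calibrated images.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
        tag_scale = _scale_from_tags(tif)
    if arr.ndim == 2:
        arr = arr[None]
    scale = um_per_pixel
    if scale is None:
        scale = meta.get("um_per_pixel", tag_scale)
        if scale is None:
            raise ValueError(
                f"{path}: no scale in TIFF metadata; pass um_per_pixel"
            )
    elif tag_scale is not None and abs(tag_scale - scale) / scale > 1e-3:
        log.warning(
            "%s: overriding TIFF resolution tags (%.4g um/px) with "
            "user-supplied scale %.4g um/px",
            path,
            tag_scale,
            scale,
        )
    n_ch = n_channels or int(meta.get("n_channels", 1))
    if arr.shape[0] % n_ch:
        raise ValueError(
            f"{path}: {arr.shape[0]} pages not divisible by {n_ch} channels"
        )
    n_slices = arr.shape[0] // n_ch
    ids = list(channel_ids or meta.get("channel_ids") or [f"ch{c}" for c in range(n_ch)])
    return [
        [
            CalibratedImage(arr[c * n_slices + z], float(scale), ids[c])
            for z in range(n_slices)
        ]
        for c in range(n_ch)
    ]


def write_ground_truth(truth: GroundTruth, path) -> Path:
    path = Path(path)
    path.write_text(truth.to_json())
    return path


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())


def write_puncta_table(table: PunctaTable, path) -> Path:
    """Write a puncta table as CSV plus a JSON provenance sidecar."""
    path = Path(path)
    cols = [c for c in PUNCTA_COLUMNS if c in table.df.columns]
    table.df.to_csv(path, index=False, columns=cols)
    sidecar = path.with_suffix(".provenance.json")
    sidecar.write_text(
        json.dumps(
            {"um_per_pixel": table.um_per_pixel, **table.provenance},
            indent=2,
            default=str,
        )
    )
    return path


def read_puncta_table(path) -> PunctaTable:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(".provenance.json")
    prov = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return PunctaTable(
        df=df, um_per_pixel=float(prov.get("um_per_pixel", 1.0)), provenance=prov
    )


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, files: Sequence[Path], extra: dict | None = None) -> Path:
    """Write a machine-readable manifest listing every output with its hash."""
    out_dir = Path(out_dir)
    manifest = {
        "files": {
            str(Path(f).relative_to(out_dir)): file_sha256(f) for f in files
        },
        **(extra or {}),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
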
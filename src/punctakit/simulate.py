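"""Synthetic confocal-like single-cell images with known ground truth.

The generator emulates a confocal z-stack of one immunolabelled oocyte:
a disc-shaped cell body (default 75 um diameter) containing a dimmer
nucleus, with bright puncta spanning roughly 0.03 um^2 to beyond
10 um^2 rendered on a noisy background, imaged as 15 slices at 1 um
spacing.  Every planted punctum is recorded in a :class:`GroundTruth`
object, so each stage of the measurement pipeline can be tested against
exact truth without any real image data.

Puncta are rendered as Gaussian-blurred *hard discs* rather than pure
Gaussian spots: the pipeline measures projected area, so the fixtures
must have a well-defined true area (pi * r^2).  Each punctum lives on
one home slice and attenuates into neighbouring slices following a
Gaussian axial profile, which makes the z-overlay stage do real work.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .pipeline import CalibratedImage

__all__ = [
    "AcquisitionParams",
    "TruthSpec",
    "PunctumRecord",
    "GroundTruth",
    "generate_cell",
    "generate_correlated_pair",
    "generate_peripheral_cohort",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """Imaging geometry and noise of the simulated acquisition.

    Defaults reproduce the confocal setup the package targets: a
    15-slice z-stack at 1 um spacing.  ``psf_sigma_um`` is the lateral
    blur applied after disc rendering; ``axial_sigma_um`` controls how
    fast a punctum's intensity decays on neighbouring slices.  Noise is
    Poisson shot noise, Gaussian read noise (sd = ``noise_scale``),
    both, or none.
    """

    um_per_pixel: float = 0.25
    image_size_px: tuple[int, int] = (384, 384)
    n_slices: int = 15
    slice_spacing_um: float = 1.0
    psf_sigma_um: float = 0.1
    axial_sigma_um: float = 0.75
    background_level: float = 5.0
    noise_model: Literal["none", "gaussian", "poisson", "poisson_gaussian"] = (
        "poisson_gaussian"
    )
    noise_scale: float = 2.0

    def __post_init__(self) -> None:
        if not self.um_per_pixel > 0:
            raise ValueError("um_per_pixel must be positive")
        if any(s <= 0 for s in self.image_size_px):
            raise ValueError("image_size_px must be positive")
        if self.n_slices < 1 or not self.slice_spacing_um > 0:
            raise ValueError("need n_slices >= 1 and positive slice spacing")
        if self.psf_sigma_um < 0 or self.noise_scale < 0:
            raise ValueError("psf_sigma_um and noise_scale must be nonnegative")
        if self.noise_model not in ("none", "gaussian", "poisson", "poisson_gaussian"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


@dataclass(frozen=True)
class TruthSpec:
    """Distribution parameters for the planted puncta population.

    ``size_mixture`` is a tuple of ``(weight, lower_um2, upper_um2)``
    area classes; each punctum draws its class by weight and its area
    uniformly within the class.  ``class_counts`` — a tuple of
    ``(count, lower_um2, upper_um2)`` — overrides the mixture with
    exact per-class counts (used to plant group effects).  Placement:

    - ``"cytoplasm"``: punctum fits fully between nucleus and cell edge
      (default; the markers being emulated are cytoplasmic),
    - ``"disc"``: anywhere inside the cell, still fully contained,
    - ``"disc_centroid"``: centroid uniform over the whole cell disc,
      with no containment margin — the mode whose peripheral-band
      fraction follows the analytic annulus law exactly.

    ``peripheral_bias``: if not None, each punctum with area >
    ``bias_min_area_um2`` is placed with its centroid inside the outer
    ``band_width_um`` band with this probability (else strictly inside).
    """

    n_puncta: int = 80
    size_mixture: tuple[tuple[float, float, float], ...] = (
        (0.45, 0.03, 0.196),
        (0.35, 0.196, 1.767),
        (0.15, 1.767, 6.0),
        (0.05, 10.5, 18.0),
    )
    class_counts: tuple[tuple[int, float, float], ...] | None = None
    peak_range: tuple[float, float] = (150.0, 170.0)
    placement: Literal["cytoplasm", "disc", "disc_centroid"] = "cytoplasm"
    min_separation_um: float = 2.0
    cell_diameter_um: float = 75.0
    nucleus_diameter_um: float = 25.0
    cell_interior_level: float = 25.0
    nucleus_level: float = 15.0
    peripheral_bias: float | None = None
    bias_min_area_um2: float = 10.0
    band_width_um: float = 10.0
    channel_id: str = "ch0"

    def __post_init__(self) -> None:
        if self.n_puncta < 0:
            raise ValueError("n_puncta must be nonnegative")
        if self.cell_diameter_um <= self.nucleus_diameter_um:
            raise ValueError("cell diameter must exceed nucleus diameter")
        if self.peripheral_bias is not None and not 0 <= self.peripheral_bias <= 1:
            raise ValueError("peripheral_bias must lie in [0, 1]")
        if self.band_width_um >= self.cell_diameter_um / 2:
            raise ValueError("band wider than cell radius")
        for w, lo, hi in self.size_mixture:
            if w < 0 or lo <= 0 or hi <= lo:
                raise ValueError("invalid size_mixture entry")

    @property
    def cell_radius_um(self) -> float:
        return self.cell_diameter_um / 2.0

    @property
    def nucleus_radius_um(self) -> float:
        return self.nucleus_diameter_um / 2.0


@dataclass
class PunctumRecord:
    """Ground truth for one planted punctum."""

    centroid_um: tuple[float, float]  # (x, y) from image origin
    radius_um: float
    peak_intensity: float
    channel_id: str
    home_slice: int
    shared: bool = False
    in_band: bool | None = None
    rendered_area_px: int | None = None  # pixel count of the hard disc as drawn

    @property
    def area_um2(self) -> float:
        return float(np.pi * self.radius_um**2)


@dataclass
class GroundTruth:
    """Complete truth for one simulated cell (all channels)."""

    puncta: list[PunctumRecord]
    cell_center_um: tuple[float, float]
    cell_radius_um: float
    nucleus_center_um: tuple[float, float]
    nucleus_radius_um: float
    seed: int
    band_width_um: float | None = None

    def __post_init__(self) -> None:
        if not self.cell_radius_um > self.nucleus_radius_um:
            raise ValueError("cell radius must exceed nucleus radius")
        for p in self.puncta:
            if p.radius_um <= 0:
                raise ValueError("punctum radius must be positive")

    def channel(self, channel_id: str) -> list[PunctumRecord]:
        return [p for p in self.puncta if p.channel_id == channel_id]

    @property
    def n_puncta(self) -> int:
        return len(self.puncta)

    def areas_um2(self, channel_id: str | None = None) -> np.ndarray:
        recs = self.puncta if channel_id is None else self.channel(channel_id)
        return np.array([p.area_um2 for p in recs])

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        puncta = [
            PunctumRecord(**{**p, "centroid_um": tuple(p["centroid_um"])})
            for p in d.pop("puncta")
        ]
        d["cell_center_um"] = tuple(d["cell_center_um"])
        d["nucleus_center_um"] = tuple(d["nucleus_center_um"])
        return cls(puncta=puncta, **d)


# ---------------------------------------------------------------------------
# placement and rendering internals


def _sample_radius_um(spec: TruthSpec, rng: np.random.Generator) -> float:
    weights = np.array([w for w, _, _ in spec.size_mixture], dtype=float)
    weights /= weights.sum()
    k = rng.choice(len(weights), p=weights)
    _, lo, hi = spec.size_mixture[k]
    area = rng.uniform(lo, hi)
    return float(np.sqrt(area / np.pi))


def _uniform_in_annulus(
    rng: np.random.Generator, r_inner: float, r_outer: float
) -> tuple[float, float]:
    """Area-uniform point in the annulus r_inner <= d <= r_outer."""
    u = rng.uniform()
    d = np.sqrt(u * (r_outer**2 - r_inner**2) + r_inner**2)
    theta = rng.uniform(0.0, 2.0 * np.pi)
    return float(d * np.cos(theta)), float(d * np.sin(theta))


def _place_punctum(
    spec: TruthSpec,
    rng: np.random.Generator,
    radius_um: float,
    placed: list[tuple[float, float, float]],
    cell_center: tuple[float, float],
) -> tuple[float, float]:
    """Sample a centroid honouring placement mode, bias and separation."""
    R = spec.cell_radius_um
    cx0, cy0 = cell_center
    large = radius_um**2 * np.pi > spec.bias_min_area_um2

    for _ in range(20000):
        if spec.peripheral_bias is not None and large:
            if rng.uniform() < spec.peripheral_bias:
                inner = R - spec.band_width_um
                outer = R if spec.placement == "disc_centroid" else R - radius_um
                inner = min(inner, outer - 1e-9)
            else:
                inner, outer = 0.0, R - spec.band_width_um
            dx, dy = _uniform_in_annulus(rng, max(inner, 0.0), outer)
        elif spec.placement == "disc_centroid":
            dx, dy = _uniform_in_annulus(rng, 0.0, R)
        else:
            outer = R - radius_um
            if outer <= 0:
                raise ValueError(
                    f"punctum of radius {radius_um:.3g} um cannot fit in a "
                    f"cell of radius {R:.3g} um"
                )
            inner = (
                spec.nucleus_radius_um + radius_um
                if spec.placement == "cytoplasm"
                else 0.0
            )
            if inner >= outer:
                raise ValueError("no room between nucleus and cell edge")
            dx, dy = _uniform_in_annulus(rng, inner, outer)
        x, y = cx0 + dx, cy0 + dy
        if spec.min_separation_um == 0:
            return x, y  # overlap permitted: placement stays exactly uniform
        ok = all(
            np.hypot(x - px, y - py) >= spec.min_separation_um + radius_um + pr
            for px, py, pr in placed
        )
        if ok:
            return x, y
    raise ValueError(
        f"could not place punctum (radius {radius_um:.3g} um) after 20000 "
        "attempts; reduce n_puncta or min_separation_um"
    )


def _disc_pixels(
    shape: tuple[int, int], cx_px: float, cy_px: float, r_px: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel indices of a hard disc (pixel-center rule, at least one pixel)."""
    h, w = shape
    lo_r = max(int(np.floor(cy_px - r_px)) - 1, 0)
    hi_r = min(int(np.ceil(cy_px + r_px)) + 2, h)
    lo_c = max(int(np.floor(cx_px - r_px)) - 1, 0)
    hi_c = min(int(np.ceil(cx_px + r_px)) + 2, w)
    if lo_r < hi_r and lo_c < hi_c:
        yy, xx = np.mgrid[lo_r:hi_r, lo_c:hi_c]
        inside = (yy - cy_px) ** 2 + (xx - cx_px) ** 2 <= r_px**2
        if inside.any():
            return yy[inside], xx[inside]
    # sub-pixel punctum: light the nearest pixel so it is not lost
    rr = int(np.clip(round(cy_px), 0, h - 1))
    cc = int(np.clip(round(cx_px), 0, w - 1))
    return np.array([rr]), np.array([cc])


def _add_disc(arr: np.ndarray, cx_px: float, cy_px: float, r_px: float, value: float) -> None:
    rows, cols = _disc_pixels(arr.shape, cx_px, cy_px, r_px)
    arr[rows, cols] += value


def _render_stack(
    puncta: Sequence[PunctumRecord],
    truth_geom: GroundTruth,
    spec: TruthSpec,
    acq: AcquisitionParams,
    rng: np.random.Generator,
    channel_id: str,
) -> list[CalibratedImage]:
    h, w = acq.image_size_px
    scale = acq.um_per_pixel
    stack = np.zeros((acq.n_slices, h, w), dtype=float)
    stack += acq.background_level

    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = truth_geom.cell_center_um
    d2 = (yy * scale - cy) ** 2 + (xx * scale - cx) ** 2
    cell = d2 <= truth_geom.cell_radius_um**2
    nucleus = d2 <= truth_geom.nucleus_radius_um**2
    body = np.where(nucleus, spec.nucleus_level, spec.cell_interior_level)
    stack += np.where(cell, body, 0.0)

    sig_z = acq.axial_sigma_um
    for p in puncta:
        px, py = p.centroid_um[0] / scale, p.centroid_um[1] / scale
        r_px = p.radius_um / scale
        p.rendered_area_px = len(_disc_pixels((h, w), px, py, r_px)[0])
        for z in range(acq.n_slices):
            dz = (z - p.home_slice) * acq.slice_spacing_um
            att = float(np.exp(-(dz**2) / (2.0 * sig_z**2))) if sig_z > 0 else float(dz == 0)
            if att < 1e-3:
                continue
            _add_disc(stack[z], px, py, r_px, p.peak_intensity * att)

    if acq.psf_sigma_um > 0:
        sig_px = acq.psf_sigma_um / scale
        for z in range(acq.n_slices):
            stack[z] = gaussian_filter(stack[z], sig_px)

    if acq.noise_model in ("poisson", "poisson_gaussian"):
        stack = rng.poisson(np.clip(stack, 0, None)).astype(float)
    if acq.noise_model in ("gaussian", "poisson_gaussian") and acq.noise_scale > 0:
        stack += rng.normal(0.0, acq.noise_scale, size=stack.shape)
    stack = np.clip(stack, 0.0, None)

    return [CalibratedImage(stack[z], scale, channel_id) for z in range(acq.n_slices)]


def _field_center_um(acq: AcquisitionParams) -> tuple[float, float]:
    h, w = acq.image_size_px
    return (w - 1) / 2.0 * acq.um_per_pixel, (h - 1) / 2.0 * acq.um_per_pixel


def _check_cell_fits(spec: TruthSpec, acq: AcquisitionParams) -> None:
    h, w = acq.image_size_px
    half_extent = min(h, w) / 2.0 * acq.um_per_pixel
    if spec.cell_radius_um >= half_extent:
        raise ValueError(
            f"cell radius {spec.cell_radius_um} um does not fit the "
            f"{h}x{w} px field at {acq.um_per_pixel} um/px"
        )


def _sample_puncta(
    spec: TruthSpec,
    acq: AcquisitionParams,
    rng: np.random.Generator,
    center: tuple[float, float],
    channel_id: str,
    placed: list[tuple[float, float, float]],
) -> list[PunctumRecord]:
    if spec.class_counts is not None:
        radii = [
            float(np.sqrt(rng.uniform(lo, hi) / np.pi))
            for count, lo, hi in spec.class_counts
            for _ in range(count)
        ]
    else:
        radii = [_sample_radius_um(spec, rng) for _ in range(spec.n_puncta)]
    records = []
    R, w_band = spec.cell_radius_um, spec.band_width_um
    for r_um in radii:
        x, y = _place_punctum(spec, rng, r_um, placed, center)
        placed.append((x, y, r_um))
        d = float(np.hypot(x - center[0], y - center[1]))
        records.append(
            PunctumRecord(
                centroid_um=(x, y),
                radius_um=r_um,
                peak_intensity=float(rng.uniform(*spec.peak_range)),
                channel_id=channel_id,
                home_slice=int(rng.integers(acq.n_slices)),
                in_band=bool(d > R - w_band),
            )
        )
    return records


# ---------------------------------------------------------------------------
# public generators


def generate_cell(
    spec: TruthSpec | None = None,
    acq: AcquisitionParams | None = None,
    seed: int = 0,
) -> tuple[list[CalibratedImage], GroundTruth]:
    """Simulate one single-cell z-stack with full ground truth.

    Returns the stack (one :class:`CalibratedImage` per slice) and the
    :class:`GroundTruth` describing every planted punctum.  The same
    ``(spec, acq, seed)`` triple always produces bit-identical output.
    """
    spec = spec or TruthSpec()
    acq = acq or AcquisitionParams()
    _check_cell_fits(spec, acq)
    rng = np.random.default_rng(seed)
    center = _field_center_um(acq)
    truth = GroundTruth(
        puncta=[],
        cell_center_um=center,
        cell_radius_um=spec.cell_radius_um,
        nucleus_center_um=center,
        nucleus_radius_um=spec.nucleus_radius_um,
        seed=seed,
        band_width_um=spec.band_width_um,
    )
    placed: list[tuple[float, float, float]] = []
    truth.puncta = _sample_puncta(spec, acq, rng, center, spec.channel_id, placed)
    stack = _render_stack(truth.puncta, truth, spec, acq, rng, spec.channel_id)
    return stack, truth


def generate_correlated_pair(
    coloc_fraction: float,
    acq: AcquisitionParams | None = None,
    seed: int = 0,
    spec: TruthSpec | None = None,
    channel_ids: tuple[str, str] = ("ch0", "ch1"),
) -> tuple[tuple[list[CalibratedImage], list[CalibratedImage]], GroundTruth]:
    """Simulate a two-channel cell with a controlled shared-puncta fraction.

    ``coloc_fraction`` of the puncta are placed at identical coordinates
    (and sizes) in both channels; the remainder are placed independently
    per channel.  Ground-truth records carry a ``shared`` flag and the
    owning ``channel_id`` (shared puncta appear once per channel).
    """
    if not 0.0 <= coloc_fraction <= 1.0:
        raise ValueError(f"coloc_fraction must lie in [0, 1], got {coloc_fraction}")
    spec = spec or TruthSpec()
    acq = acq or AcquisitionParams()
    _check_cell_fits(spec, acq)
    rng = np.random.default_rng(seed)
    center = _field_center_um(acq)
    truth = GroundTruth(
        puncta=[],
        cell_center_um=center,
        cell_radius_um=spec.cell_radius_um,
        nucleus_center_um=center,
        nucleus_radius_um=spec.nucleus_radius_um,
        seed=seed,
        band_width_um=spec.band_width_um,
    )
    n_shared = int(round(coloc_fraction * spec.n_puncta))
    n_private = spec.n_puncta - n_shared

    shared_spec = replace(spec, n_puncta=n_shared, class_counts=None)
    placed_a: list[tuple[float, float, float]] = []
    shared = _sample_puncta(shared_spec, acq, rng, center, channel_ids[0], placed_a)
    for p in shared:
        p.shared = True
    placed_b = list(placed_a)

    private_spec = replace(spec, n_puncta=n_private, class_counts=None)
    priv_a = _sample_puncta(private_spec, acq, rng, center, channel_ids[0], placed_a)
    priv_b = _sample_puncta(private_spec, acq, rng, center, channel_ids[1], placed_b)

    shared_b = [
        replace_record(p, channel_id=channel_ids[1]) for p in shared
    ]
    truth.puncta = shared + priv_a + shared_b + priv_b

    stack_a = _render_stack(
        shared + priv_a, truth, spec, acq, rng, channel_ids[0]
    )
    stack_b = _render_stack(
        shared_b + priv_b, truth, spec, acq, rng, channel_ids[1]
    )
    return (stack_a, stack_b), truth


def replace_record(p: PunctumRecord, **kw) -> PunctumRecord:
    d = {
        "centroid_um": p.centroid_um,
        "radius_um": p.radius_um,
        "peak_intensity": p.peak_intensity,
        "channel_id": p.channel_id,
        "home_slice": p.home_slice,
        "shared": p.shared,
        "in_band": p.in_band,
        "rendered_area_px": p.rendered_area_px,
    }
    d.update(kw)
    return PunctumRecord(**d)


def generate_peripheral_cohort(
    n_large_puncta: int,
    peripheral_bias: float | None,
    seed: int = 0,
    acq: AcquisitionParams | None = None,
    spec: TruthSpec | None = None,
    render: bool = True,
) -> tuple[list[CalibratedImage] | None, GroundTruth]:
    """Simulate a cell whose large puncta have a known peripheral bias.

    ``peripheral_bias`` in [0, 1] forces each large punctum (area above
    the 10 um^2 cutoff) into the outer band with that probability;
    ``None`` places centroids uniformly over the whole cell disc, the
    regime in which the fraction of centroids falling in an outer band
    of width ``w`` follows the annulus law ``1 - ((R - w) / R)**2``.
    Ground truth records band membership per punctum.  With
    ``render=False`` only the truth is produced (fast Monte-Carlo use).
    """
    acq = acq or AcquisitionParams()
    base = spec or TruthSpec(min_separation_um=0.0)
    spec = replace(
        base,
        n_puncta=n_large_puncta,
        class_counts=None,
        size_mixture=((1.0, 10.5, 16.0),),
        peripheral_bias=peripheral_bias,
        placement="disc_centroid" if peripheral_bias is None else base.placement,
        min_separation_um=0.0 if peripheral_bias is None else base.min_separation_um,
    )
    if spec.band_width_um >= spec.cell_radius_um:
        raise ValueError("band wider than cell radius")
    if not render:
        rng = np.random.default_rng(seed)
        center = _field_center_um(acq)
        truth = GroundTruth(
            puncta=[],
            cell_center_um=center,
            cell_radius_um=spec.cell_radius_um,
            nucleus_center_um=center,
            nucleus_radius_um=spec.nucleus_radius_um,
            seed=seed,
            band_width_um=spec.band_width_um,
        )
        truth.puncta = _sample_puncta(spec, acq, rng, center, spec.channel_id, [])
        return None, truth
    return generate_cell(spec, acq, seed)
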
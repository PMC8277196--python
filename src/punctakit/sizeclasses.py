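"""Vesicle size classes and per-cell size-distribution profiles.

Detected puncta are binned by projected area into biologically named
classes — phagophore (< 0.196 um^2), autophagosome (0.5–1.5 um in
diameter, i.e. 0.196–1.767 um^2), lysosome (0.03–0.5 um^2), amphisome
(> 10 um^2) — plus arbitrary ladder bins (1 um^2 steps up to > 10 um^2
for LC3B/BECN1, 0.1 um^2 steps up to > 1 um^2 for LAMP1).

Bin-edge convention: intervals are left-closed/right-open, except that
named ranges written with an en dash ("0.196–1.767") include their
printed upper bound and "> x" classes are strictly open below.  Each
built-in scheme is a true partition of (0, inf), so every punctum falls
in exactly one class and class counts always sum to the total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .pipeline import PunctaTable

__all__ = [
    "SizeClass",
    "SizeClassScheme",
    "SizeProfile",
    "diameter_to_area",
    "area_to_diameter",
    "classify",
    "count_in_range",
    "builtin_schemes",
    "load_scheme",
    "save_scheme",
]


def diameter_to_area(diameter_um: float) -> float:
    """Projected area of a circle of the given diameter: pi * (d/2)^2.

    Maps the literature's diameter-based vesicle definitions onto the
    area scale the particle analysis reports (0.5 um -> 0.196 um^2,
    1.5 um -> 1.767 um^2, to three decimals).
    """
    if not diameter_um > 0:
        raise ValueError(f"diameter must be positive, got {diameter_um}")
    return math.pi * (diameter_um / 2.0) ** 2


def area_to_diameter(area_um2: float) -> float:
    """Equivalent circular diameter: 2 * sqrt(area / pi)."""
    if not area_um2 > 0:
        raise ValueError(f"area must be positive, got {area_um2}")
    return 2.0 * math.sqrt(area_um2 / math.pi)


@dataclass(frozen=True)
class SizeClass:
    """One area bin; bounds in um^2, ``upper_um2`` may be infinite."""

    name: str
    lower_um2: float
    upper_um2: float
    lower_inclusive: bool = True
    upper_inclusive: bool = False

    def __post_init__(self) -> None:
        if self.lower_um2 < 0 or self.upper_um2 <= self.lower_um2:
            raise ValueError(f"invalid bounds for class {self.name!r}")

    def contains(self, area_um2: float) -> bool:
        lo_ok = (
            area_um2 >= self.lower_um2
            if self.lower_inclusive
            else area_um2 > self.lower_um2
        )
        hi_ok = (
            area_um2 <= self.upper_um2
            if self.upper_inclusive
            else area_um2 < self.upper_um2
        )
        return lo_ok and hi_ok


@dataclass(frozen=True)
class SizeClassScheme:
    """An ordered set of area bins tied to one marker context.

    A *partitioning* scheme tiles (0, inf) with no gaps or overlaps;
    all built-in schemes are partitioning, which is what guarantees the
    conservation property (class counts sum to the number of puncta).
    """

    name: str
    classes: tuple[SizeClass, ...]
    marker_context: str = ""

    def __post_init__(self) -> None:
        cls = sorted(self.classes, key=lambda c: c.lower_um2)
        object.__setattr__(self, "classes", tuple(cls))
        for a, b in zip(cls, cls[1:]):
            if a.upper_um2 > b.lower_um2:
                raise ValueError(
                    f"classes {a.name!r} and {b.name!r} overlap in scheme "
                    f"{self.name!r}"
                )

    @property
    def is_partition(self) -> bool:
        cls = self.classes
        if not cls or cls[0].lower_um2 != 0.0 or cls[0].lower_inclusive:
            return False
        if not math.isinf(cls[-1].upper_um2):
            return False
        for a, b in zip(cls, cls[1:]):
            if a.upper_um2 != b.lower_um2:
                return False
            if a.upper_inclusive == b.lower_inclusive:
                return False  # boundary double-counted or dropped
        return True

    def assign(self, area_um2: float) -> str:
        for c in self.classes:
            if c.contains(area_um2):
                return c.name
        raise ValueError(
            f"area {area_um2} um^2 not covered by scheme {self.name!r}"
        )

    def class_names(self) -> list[str]:
        return [c.name for c in self.classes]


@dataclass
class SizeProfile:
    """Per-cell count of puncta in each class of one scheme."""

    counts: dict[str, int]
    total: int
    cell_id: str = ""
    scheme_name: str = ""

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "scheme": self.scheme_name,
                "class": list(self.counts),
                "count": list(self.counts.values()),
            }
        )


def classify(table: PunctaTable, scheme: SizeClassScheme, cell_id: str = "") -> SizeProfile:
    """Assign every punctum of a table to exactly one class of a scheme."""
    counts = {name: 0 for name in scheme.class_names()}
    for area in table.areas_um2:
        counts[scheme.assign(float(area))] += 1
    profile = SizeProfile(
        counts=counts, total=len(table), cell_id=cell_id, scheme_name=scheme.name
    )
    if scheme.is_partition and sum(counts.values()) != profile.total:
        raise AssertionError("partition scheme failed to conserve puncta")
    return profile


def count_in_range(
    table: PunctaTable, lower_um2: float, upper_um2: float | None = None
) -> int:
    """Count puncta with ``lower <= area`` (and ``area < upper`` if bounded)."""
    if upper_um2 is not None and not lower_um2 < upper_um2:
        raise ValueError("lower bound must be below upper bound")
    areas = table.areas_um2
    sel = areas >= lower_um2
    if upper_um2 is not None:
        sel &= areas < upper_um2
    return int(sel.sum())


# ---------------------------------------------------------------------------
# built-in schemes

_AUTOPHAGOSOME_LO = round(diameter_to_area(0.5), 3)  # 0.196
_AUTOPHAGOSOME_HI = round(diameter_to_area(1.5), 3)  # 1.767


def _ladder(start: float, stop: float, step: float, last_closed: bool) -> list[SizeClass]:
    """Ladder bins of equal width; the final bin closes at ``stop`` so the
    following "> stop" class (open below) leaves no gap."""
    out = []
    edges = []
    e = start
    while e < stop - 1e-9:
        edges.append(e)
        e += step
    edges.append(stop)
    for i, (lo, hi) in enumerate(zip(edges, edges[1:])):
        is_last = i == len(edges) - 2
        out.append(
            SizeClass(
                name=f"{lo:g}-{hi:g}",
                lower_um2=round(lo, 6),
                upper_um2=round(hi, 6),
                lower_inclusive=i > 0,
                upper_inclusive=is_last and last_closed,
            )
        )
    return out


def _lc3b_scheme() -> SizeClassScheme:
    classes = [
        SizeClass("phagophore", 0.0, _AUTOPHAGOSOME_LO, lower_inclusive=False),
        SizeClass(
            "autophagosome",
            _AUTOPHAGOSOME_LO,
            _AUTOPHAGOSOME_HI,
            lower_inclusive=True,
            upper_inclusive=True,
        ),
    ]
    # 1-um^2 ladder from the autophagosome bound up to the amphisome cutoff
    edges = [_AUTOPHAGOSOME_HI] + [float(k) for k in range(2, 11)]
    for i, (lo, hi) in enumerate(zip(edges, edges[1:])):
        classes.append(
            SizeClass(
                name=f"{lo:g}-{hi:g}",
                lower_um2=lo,
                upper_um2=hi,
                lower_inclusive=False,
                upper_inclusive=True,
            )
        )
    classes.append(
        SizeClass("amphisome", 10.0, math.inf, lower_inclusive=False)
    )
    return SizeClassScheme("lc3b", tuple(classes), marker_context="LC3B")


def _becn1_scheme() -> SizeClassScheme:
    classes = _ladder(0.0, 10.0, 1.0, last_closed=True)
    classes[0] = SizeClass(
        "0-1", 0.0, 1.0, lower_inclusive=False, upper_inclusive=False
    )
    classes.append(SizeClass(">10", 10.0, math.inf, lower_inclusive=False))
    return SizeClassScheme("becn1", tuple(classes), marker_context="BECN1")


def _lamp1_scheme() -> SizeClassScheme:
    classes = [
        SizeClass("<0.03", 0.0, 0.03, lower_inclusive=False),
        SizeClass(
            "lysosome", 0.03, 0.5, lower_inclusive=True, upper_inclusive=True
        ),
    ]
    edges = [0.5 + 0.1 * k for k in range(0, 6)]
    for i, (lo, hi) in enumerate(zip(edges, edges[1:])):
        classes.append(
            SizeClass(
                name=f"{lo:g}-{hi:g}",
                lower_um2=round(lo, 6),
                upper_um2=round(hi, 6),
                lower_inclusive=False,
                upper_inclusive=True,
            )
        )
    classes.append(SizeClass(">1", 1.0, math.inf, lower_inclusive=False))
    return SizeClassScheme("lamp1", tuple(classes), marker_context="LAMP1")


def builtin_schemes() -> dict[str, SizeClassScheme]:
    """The shipped schemes: ``lc3b``, ``becn1`` (1 um^2 ladder) and
    ``lamp1`` (0.1 um^2 ladder)."""
    return {s.name: s for s in (_lc3b_scheme(), _becn1_scheme(), _lamp1_scheme())}


# ---------------------------------------------------------------------------
# YAML I/O


def save_scheme(scheme: SizeClassScheme, path) -> None:
    doc = {
        "name": scheme.name,
        "marker_context": scheme.marker_context,
        "classes": [
            {
                "name": c.name,
                "lower_um2": c.lower_um2,
                "upper_um2": "inf" if math.isinf(c.upper_um2) else c.upper_um2,
                "lower_inclusive": c.lower_inclusive,
                "upper_inclusive": c.upper_inclusive,
            }
            for c in scheme.classes
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_scheme(path) -> SizeClassScheme:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    classes = tuple(
        SizeClass(
            name=c["name"],
            lower_um2=float(c["lower_um2"]),
            upper_um2=math.inf if c["upper_um2"] == "inf" else float(c["upper_um2"]),
            lower_inclusive=bool(c.get("lower_inclusive", True)),
            upper_inclusive=bool(c.get("upper_inclusive", False)),
        )
        for c in doc["classes"]
    )
    return SizeClassScheme(doc["name"], classes, doc.get("marker_context", ""))
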
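"""Platform structural geometry: depth strata and surface-area allocation.

A platform jacket is idealised as a truncated pyramid whose square-ish
cross-section flares linearly in side length from the surface to the
seafloor.  Total structural surface area is allocated among the three
depth strata (shallow: surface to the partial-removal cut; midwater: cut
to 2 m above the seafloor; base: the bottom 2 m) in proportion to the
truncated-pyramid volume of each depth slab.  When measured sub-habitat
areas are available they are used directly and this allocator is bypassed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PyramidSpec",
    "truncated_pyramid_volume",
    "allocate_surface_area",
    "per_seafloor_density",
]


@dataclass(frozen=True)
class PyramidSpec:
    """Truncated-pyramid envelope of a platform jacket.

    Cross-section side lengths interpolate linearly between the top and
    bottom faces, so cross-sectional area is quadratic in depth.
    """

    top_depth: float
    bottom_depth: float
    top_area: float
    bottom_area: float

    def __post_init__(self) -> None:
        if not self.bottom_depth > self.top_depth:
            raise ValueError("bottom_depth must exceed top_depth")
        if self.top_area <= 0 or self.bottom_area <= 0:
            raise ValueError("cross-sectional areas must be > 0")

    def side_at(self, depth: float) -> float:
        """Cross-section side length (m) at a given depth, by linear interpolation."""
        s_top = math.sqrt(self.top_area)
        s_bot = math.sqrt(self.bottom_area)
        f = (depth - self.top_depth) / (self.bottom_depth - self.top_depth)
        return s_top + f * (s_bot - s_top)

    def area_at(self, depth: float) -> float:
        return self.side_at(depth) ** 2

    def slab_volume(self, d1: float, d2: float) -> float:
        """Volume of the slab between depths d1 < d2, m^3."""
        if not d2 > d1:
            raise ValueError("slab requires d2 > d1")
        return truncated_pyramid_volume(d2 - d1, self.area_at(d1), self.area_at(d2))


def truncated_pyramid_volume(h: float, A1: float, A2: float) -> float:
    """V = (h/3) * (A1 + A2 + sqrt(A1*A2)) for a frustum of height h."""
    if h <= 0:
        raise ValueError(f"height must be > 0, got {h}")
    if A1 < 0 or A2 < 0:
        raise ValueError("cross-sectional areas must be >= 0")
    return (h / 3.0) * (A1 + A2 + math.sqrt(A1 * A2))


def allocate_surface_area(
    total_area: float,
    spec: PyramidSpec,
    cut_depth: float,
    seafloor_depth: float,
    base_band: float = 2.0,
) -> dict[str, float]:
    """Split total structural surface area among the three depth strata.

    The strata are half-open bands [0, cut), [cut, seafloor - base_band)
    and [seafloor - base_band, seafloor]; each receives area in proportion
    to its truncated-pyramid slab volume.  The three shares sum to
    ``total_area`` by construction.
    """
    if total_area < 0:
        raise ValueError("total_area must be >= 0")
    if not (0 < cut_depth < seafloor_depth - base_band):
        raise ValueError(
            f"strata boundaries must satisfy 0 < cut_depth ({cut_depth}) "
            f"< seafloor_depth - base_band ({seafloor_depth} - {base_band})"
        )
    bounds = [0.0, cut_depth, seafloor_depth - base_band, seafloor_depth]
    vols = [spec.slab_volume(a, b) for a, b in zip(bounds, bounds[1:])]
    vtot = sum(vols)
    return {
        name: total_area * v / vtot
        for name, v in zip(("shallow", "midwater", "base"), vols)
    }


def per_seafloor_density(overall_kg: float, footprint_area: float) -> float:
    """Express an overall platform metric per m^2 of seafloor footprint.

    Input in kg (or kg/yr), output in g/m^2 (or g/m^2/yr), the scale used
    for cross-ecosystem comparisons of fish production.
    """
    if footprint_area <= 0:
        raise ValueError(f"footprint area must be > 0, got {footprint_area}")
    return overall_kg * 1000.0 / footprint_area
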
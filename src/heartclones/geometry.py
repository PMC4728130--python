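"""Half-heart slab geometry.

The embryonic heart at e13.5 is approximated as a sphere; each lateral
half is modeled as a rectangular slab whose face area equals half the
sphere's surface area and whose depth spans epicardium to endocardium.
All lengths are in micrometres (µm) throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GeometryParams",
    "sphere_surface_area",
    "make_half_heart_slab",
    "DEFAULT_HEART_RADIUS",
    "DEFAULT_SLAB_DEPTH",
]

#: Default heart radius at e13.5 (µm).
DEFAULT_HEART_RADIUS = 315.0
#: Default epicardium-to-endocardium depth (µm).
DEFAULT_SLAB_DEPTH = 97.5


def sphere_surface_area(radius: float) -> float:
    """Surface area ``4*pi*r**2`` of a sphere of the given radius (µm²).

    Raises
    ------
    ValueError
        If ``radius`` is negative.
    """
    if radius < 0:
        raise ValueError(f"radius must be non-negative, got {radius}")
    return 4.0 * math.pi * radius * radius


@dataclass(frozen=True)
class GeometryParams:
    """Dimensions of one simulated half-heart region.

    Attributes
    ----------
    heart_radius : float
        Radius of the spherical heart approximation (µm).
    slab_depth : float
        Slab depth, epicardium to endocardium (µm).
    total_surface_area : float
        Sphere surface area ``4*pi*heart_radius**2`` (µm²).
    half_area : float
        Face area of the half-heart slab, half the sphere surface (µm²).
    slab_side : float
        Side of the square slab face, ``sqrt(half_area)`` (µm).
    """

    heart_radius: float
    slab_depth: float
    total_surface_area: float
    half_area: float
    slab_side: float

    @property
    def volume(self) -> float:
        """Slab volume ``half_area * slab_depth`` (µm³)."""
        return self.half_area * self.slab_depth


def make_half_heart_slab(
    heart_radius: float = DEFAULT_HEART_RADIUS,
    depth: float = DEFAULT_SLAB_DEPTH,
) -> GeometryParams:
    """Derive the half-heart slab from the spherical approximation.

    The slab is a square tile of area ``2*pi*heart_radius**2`` (half the
    sphere's surface) extruded to the given depth.  Areas are computed
    from the exact formula, not from rounded printed values.

    Raises
    ------
    ValueError
        If ``heart_radius`` or ``depth`` is not strictly positive.
    """
    if heart_radius <= 0:
        raise ValueError(f"heart_radius must be positive, got {heart_radius}")
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    total = sphere_surface_area(heart_radius)
    half = total / 2.0
    return GeometryParams(
        heart_radius=float(heart_radius),
        slab_depth=float(depth),
        total_surface_area=total,
        half_area=half,
        slab_side=math.sqrt(half),
    )
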
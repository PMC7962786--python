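"""Screen/image geometry and pixel <-> visual-degree conversion.

Coordinate convention used throughout the package: origin at the top-left
corner of the screen, x increasing rightward, y increasing downward,
0-based pixel indices, positions measured at pixel centers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ScreenGeometry",
    "ImageFrame",
    "px_per_degree",
]


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display geometry.

    Parameters
    ----------
    width_px, height_px
        Display resolution in pixels.
    width_cm, height_cm
        Physical display size in centimeters.
    viewing_distance_cm
        Eye-to-screen distance in centimeters.
    """

    width_px: int
    height_px: int
    width_cm: float
    height_cm: float
    viewing_distance_cm: float

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_cm", "height_cm", "viewing_distance_cm"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"ScreenGeometry.{name} must be strictly positive, got {v!r}")

    @property
    def cm_per_px_x(self) -> float:
        return self.width_cm / self.width_px

    @property
    def cm_per_px_y(self) -> float:
        return self.height_cm / self.height_px

    def check_square_pixels(self, tol: float = 0.01) -> None:
        """Raise if horizontal and vertical pixel pitch disagree by more than ``tol``.

        The isotropic px/deg conversion assumes square pixels; this makes the
        assumption explicit instead of silently wrong.
        """
        rel = abs(self.cm_per_px_x - self.cm_per_px_y) / self.cm_per_px_x
        if rel > tol:
            raise ValueError(
                f"pixel pitch anisotropy {rel:.2%} exceeds tolerance {tol:.2%}; "
                "isotropic degree conversion is not valid for this display"
            )


@dataclass(frozen=True)
class ImageFrame:
    """Placement of the stimulus image rectangle on the screen, in pixels."""

    origin_x_px: int
    origin_y_px: int
    width_px: int
    height_px: int

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("ImageFrame dimensions must be strictly positive")

    @classmethod
    def centered(cls, geom: ScreenGeometry, width_px: int, height_px: int) -> "ImageFrame":
        """Image rectangle centered on the screen (the default stimulus placement)."""
        frame = cls(
            origin_x_px=(geom.width_px - width_px) // 2,
            origin_y_px=(geom.height_px - height_px) // 2,
            width_px=width_px,
            height_px=height_px,
        )
        frame.require_within(geom)
        return frame

    def require_within(self, geom: ScreenGeometry) -> None:
        if (
            self.origin_x_px < 0
            or self.origin_y_px < 0
            or self.origin_x_px + self.width_px > geom.width_px
            or self.origin_y_px + self.height_px > geom.height_px
        ):
            raise ValueError("image rectangle does not lie within screen bounds")

    def contains(self, x_px: float, y_px: float) -> bool:
        """Whether a screen-coordinate point falls inside the image rectangle."""
        return (
            self.origin_x_px <= x_px < self.origin_x_px + self.width_px
            and self.origin_y_px <= y_px < self.origin_y_px + self.height_px
        )

    @property
    def center(self) -> tuple[float, float]:
        return (
            self.origin_x_px + (self.width_px - 1) / 2.0,
            self.origin_y_px + (self.height_px - 1) / 2.0,
        )


def px_per_degree(geom: ScreenGeometry, check_isotropy: bool = True) -> float:
    """Pixels subtending one degree of visual angle at screen center.

    A single isotropic scale computed from the horizontal axis; the vertical
    axis is used only as a consistency check (``check_isotropy``).
    """
    if check_isotropy:
        geom.check_square_pixels()
    deg_per_px = math.degrees(math.atan(geom.cm_per_px_x / geom.viewing_distance_cm))
    return 1.0 / deg_per_px


def px_to_deg(value_px: float, geom: ScreenGeometry) -> float:
    """Convert a pixel distance to visual degrees (small-angle, screen center)."""
    return value_px / px_per_degree(geom, check_isotropy=False)


def deg_to_px(value_deg: float, geom: ScreenGeometry) -> float:
    """Convert a visual-degree distance to pixels (inverse of :func:`px_to_deg`)."""
    return value_deg * px_per_degree(geom, check_isotropy=False)


#: Geometry of the study display: 1920x1080 px, 51.5x29 cm, viewed at 60 cm.
DEFAULT_GEOMETRY = ScreenGeometry(
    width_px=1920, height_px=1080, width_cm=51.5, height_cm=29.0, viewing_distance_cm=60.0
)
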
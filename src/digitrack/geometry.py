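"""Display geometry, pixel/degree conversion and foveated-rendering math.

Coordinate convention used throughout the package: origin at the top-left
pixel, 0-based indices, x increases rightward and y increases *downward*.
An "upward" shift therefore subtracts from y.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "DisplaySpec",
    "RenderConfig",
    "Trajectory",
    "TABLET_DISPLAY",
    "EYETRACKER_DISPLAY",
    "px_to_degrees",
    "degrees_to_px",
    "blur_image",
    "composite_aperture",
    "truncate_at_path_threshold",
]

_CM_PER_INCH = 2.54


class GeometryError(ValueError):
    """Raised for invalid display geometry or incompatible grids."""


@dataclass(frozen=True)
class DisplaySpec:
    """Physical and pixel geometry of a display plus viewing distance.

    All pixel<->degree conversions in the package flow through this type.
    ``pixels_per_inch`` may be given explicitly (it then must agree with
    ``width_px / width_cm`` within 1%) or derived from the width fields.
    """

    width_px: int
    height_px: int
    width_cm: float
    height_cm: float
    viewing_distance_cm: float
    pixels_per_inch: float | None = None

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_cm", "height_cm",
                     "viewing_distance_cm"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        derived = self.width_px / self.width_cm * _CM_PER_INCH
        if self.pixels_per_inch is None:
            object.__setattr__(self, "pixels_per_inch", derived)
        elif abs(self.pixels_per_inch - derived) > 0.01 * derived:
            raise GeometryError(
                f"pixels_per_inch={self.pixels_per_inch} inconsistent with "
                f"width_px/width_cm (derived {derived:.1f})"
            )

    @property
    def cm_per_px(self) -> float:
        return _CM_PER_INCH / self.pixels_per_inch

    @classmethod
    def from_ppi(cls, width_px: int, height_px: int, ppi: float,
                 viewing_distance_cm: float) -> "DisplaySpec":
        return cls(
            width_px=width_px,
            height_px=height_px,
            width_cm=width_px / ppi * _CM_PER_INCH,
            height_cm=height_px / ppi * _CM_PER_INCH,
            viewing_distance_cm=viewing_distance_cm,
            pixels_per_inch=ppi,
        )


#: 267-PPI tablet surface viewed at 32 cm (2736x1824 px, 26 x 17.3 cm).
TABLET_DISPLAY = DisplaySpec.from_ppi(2736, 1824, 267.0, 32.0)

#: 1280x1024 monitor, 33.8 x 27.4 cm, viewed at 50 cm.
EYETRACKER_DISPLAY = DisplaySpec(1280, 1024, 33.8, 27.4, 50.0)


def px_to_degrees(length_px: float, display: DisplaySpec) -> float:
    """Convert an on-screen length in pixels to degrees of visual angle.

    Uses the linear small-angle convention
    ``deg = (px * cm_per_px / distance_cm) * 180 / pi``,
    which is homogeneous: f(k*x) = k*f(x).
    """
    length_px = np.asarray(length_px, dtype=float)
    if np.any(length_px < 0):
        raise ValueError("length_px must be nonnegative")
    if display.viewing_distance_cm <= 0:
        raise GeometryError("viewing distance must be positive")
    rad = length_px * display.cm_per_px / display.viewing_distance_cm
    return float(np.degrees(rad)) if np.isscalar(rad) or rad.ndim == 0 \
        else np.degrees(rad)


def degrees_to_px(degrees: float, display: DisplaySpec) -> float:
    """Inverse of :func:`px_to_degrees`."""
    return float(np.radians(degrees) * display.viewing_distance_cm
                 / display.cm_per_px)


@dataclass(frozen=True)
class RenderConfig:
    """Foveated-rendering parameters, in pixels of the native display.

    blur_sigma_px degrades the periphery, aperture_sigma_px sets the size of
    the full-resolution window, vertical_offset_px shifts the window upward
    from the finger contact point, and path_threshold_px is the cumulative
    track-path length at which exploration stops.
    """

    blur_sigma_px: float = 40.0
    aperture_sigma_px: float = 110.0
    vertical_offset_px: float = 80.0
    path_threshold_px: float = 4000.0

    def __post_init__(self) -> None:
        for name in ("blur_sigma_px", "aperture_sigma_px",
                     "vertical_offset_px", "path_threshold_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class Trajectory:
    """Regularly sampled exploration path (aperture-center coordinates)."""

    sample_times: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    display: DisplaySpec | None = None
    subject_id: str = ""
    image_id: str = ""
    under_threshold: bool = False

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        n = len(self.sample_times)
        if len(self.xs) != n or len(self.ys) != n:
            raise ValueError("sample_times, xs, ys must have equal length")
        if n > 1 and np.any(np.diff(self.sample_times) <= 0):
            raise ValueError("sample_times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.sample_times)

    def path_lengths(self) -> np.ndarray:
        """Cumulative Euclidean path length at each sample (0 at the first)."""
        steps = np.hypot(np.diff(self.xs), np.diff(self.ys))
        return np.concatenate([[0.0], np.cumsum(steps)])


def blur_image(image: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian-blur an intensity grid, per channel, with reflective padding.

    Reflective boundaries keep total intensity exactly conserved and avoid
    the dark frame a zero-padded blur would introduce at the image edges.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    if image.ndim == 2:
        return gaussian_filter(image, sigma=sigma_px, mode="reflect")
    if image.ndim == 3:
        return gaussian_filter(image, sigma=(sigma_px, sigma_px, 0),
                               mode="reflect")
    raise ValueError(f"expected 2-D or 3-D image, got ndim={image.ndim}")


def aperture_alpha(shape: tuple[int, int], contact_xy: tuple[float, float],
                   cfg: RenderConfig) -> np.ndarray:
    """Gaussian alpha mask centered vertical_offset_px above the contact point."""
    h, w = shape
    cx, cy = contact_xy
    center_y = cy - cfg.vertical_offset_px  # upward = smaller y
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (xx - cx) ** 2 + (yy - center_y) ** 2
    return np.exp(-d2 / (2.0 * cfg.aperture_sigma_px ** 2))


def composite_aperture(native: np.ndarray, blurred: np.ndarray,
                       contact_xy: tuple[float, float],
                       cfg: RenderConfig) -> np.ndarray:
    """Blend native and blurred images through the Gaussian aperture window.

    out = a * native + (1 - a) * blurred with a = exp(-d^2 / (2 sigma_a^2)),
    d measured from the window center placed vertical_offset_px above the
    contact point.
    """
    native = np.asarray(native, dtype=float)
    blurred = np.asarray(blurred, dtype=float)
    if native.shape != blurred.shape:
        raise ValueError(
            f"shape mismatch: native {native.shape} vs blurred {blurred.shape}")
    h, w = native.shape[:2]
    cx, cy = contact_xy
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"contact point {contact_xy} outside {w}x{h} image")
    a = aperture_alpha((h, w), contact_xy, cfg)
    if native.ndim == 3:
        a = a[..., None]
    return a * native + (1.0 - a) * blurred


def truncate_at_path_threshold(traj: Trajectory,
                               threshold_px: float) -> Trajectory:
    """Cut a trajectory at the sample where cumulative path length reaches
    ``threshold_px``.

    Returns the shortest prefix whose cumulative Euclidean path length is at
    least the threshold. If the full path never reaches it, the whole
    trajectory is returned with ``under_threshold=True``.
    """
    if len(traj) < 2:
        raise ValueError("trajectory needs at least 2 samples")
    cumlen = traj.path_lengths()
    idx = np.searchsorted(cumlen, threshold_px)
    if idx >= len(traj):
        return replace(traj, under_threshold=True)
    end = idx + 1
    return Trajectory(
        sample_times=traj.sample_times[:end],
        xs=traj.xs[:end],
        ys=traj.ys[:end],
        display=traj.display,
        subject_id=traj.subject_id,
        image_id=traj.image_id,
        under_threshold=False,
    )
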
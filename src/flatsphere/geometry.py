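"""Closed-form spherical model of a flattened eyecup.

The eyecup is modeled as a sphere of radius ``R`` whose south pole is the
optic nerve head.  When the cup is cut into ``n`` lobes and flattened, a
concentric circle of radius ``L`` (the geodesic distance from the south
pole, preserved by the flattening) has perimeter ``2*pi*L`` but carries only
``2*pi*R*sin(theta)`` of tissue, where ``theta = pi - L/R`` is the polar
angle of that latitude.  The difference is the total interlobe gap length

    G(L) = 2*pi * (L - R*sin(pi - L/R)).

Flattening also distorts the tissue itself; the distortion is modeled as an
additive gap error ``E = k*sin(theta)`` with a tissue distortion
coefficient ``k`` (a length, conventionally reported as ``k/(2*pi)``),
giving the corrected gap law

    G(L) = 2*pi * (L - (R - k/(2*pi))*sin(pi - L/R)).

All functions here are pure and operate in consistent length units
(millimeters throughout the package); angles are radians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "SphereModel",
    "ideal_gap",
    "corrected_gap",
    "latitude_angle",
    "corneal_angle",
    "flatmount_point_to_sphere",
]

# relative slack for L <= pi*R checks, so L = pi*R built from floats passes
_REL_EPS = 1e-9


@dataclass
class SphereModel:
    """A fitted eyeball sphere.

    Parameters
    ----------
    R : float
        Sphere radius in mm; must be positive.
    k : float
        Tissue distortion coefficient in mm (same length unit as ``R``).
        Users conventionally see ``k/(2*pi)``, exposed as :attr:`k_over_2pi`.
    theta_cornea : float, optional
        Corneal angle in radians, in ``[0, pi]`` when set.
    """

    R: float
    k: float = 0.0
    theta_cornea: Optional[float] = None
    warnings_: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.R) or self.R <= 0:
            raise ValueError(f"sphere radius R must be positive and finite, got {self.R}")
        if self.theta_cornea is not None and not (0.0 <= self.theta_cornea <= np.pi):
            raise ValueError(
                f"corneal angle must lie in [0, pi] radians, got {self.theta_cornea}"
            )
        if not self.is_physical:
            msg = (
                f"k/2pi = {self.k_over_2pi:.4g} mm is not smaller than R = {self.R:.4g} mm; "
                "the distortion correction exceeds the sphere radius"
            )
            self.warnings_.append(msg)
            warnings.warn(msg, stacklevel=2)

    @property
    def k_over_2pi(self) -> float:
        return self.k / (2.0 * np.pi)

    @property
    def is_physical(self) -> bool:
        """True when the correction does not exceed the radius (k/2pi < R)."""
        return self.k_over_2pi < self.R

    @property
    def theta_cornea_deg(self) -> Optional[float]:
        return None if self.theta_cornea is None else float(np.degrees(self.theta_cornea))


def _validate_L(L, R: float):
    if not np.isfinite(R) or R <= 0:
        raise ValueError(f"sphere radius R must be positive and finite, got {R}")
    L = np.asarray(L, dtype=float)
    lmax = np.pi * R
    if np.any(L < -_REL_EPS * lmax) or np.any(L > lmax * (1.0 + _REL_EPS)):
        raise ValueError(
            f"arc distance L must lie in [0, pi*R] = [0, {lmax:.6g}] for R = {R:.6g}"
        )
    return np.clip(L, 0.0, lmax)


def ideal_gap(L, R: float):
    """Total interlobe gap length on the concentric circle of radius ``L``.

    Distortion-free gap law ``G = 2*pi*(L - R*sin(pi - L/R))``.

    Parameters
    ----------
    L : float or array_like
        Arc (geodesic) distance from the south pole, ``0 <= L <= pi*R``,
        in the same length unit as ``R``.
    R : float
        Sphere radius (> 0).

    Returns
    -------
    float or ndarray
        Gap length ``G`` with ``0 <= G <= 2*pi*L``.
    """
    L = _validate_L(L, R)
    G = 2.0 * np.pi * (L - R * np.sin(np.pi - L / R))
    # the closed form is >= 0 analytically; clip float round-off near L=0
    G = np.clip(G, 0.0, None)
    return G if G.ndim else float(G)


def corrected_gap(L, R: float, k: float):
    """Gap length under the tissue-distortion-corrected law.

    ``G = 2*pi*(L - (R - k/(2*pi))*sin(pi - L/R))``; equivalently the ideal
    gap plus the distortion term ``k*sin(pi - L/R)``.  Reduces exactly to
    :func:`ideal_gap` when ``k = 0``.
    """
    L = _validate_L(L, R)
    G = 2.0 * np.pi * (L - (R - k / (2.0 * np.pi)) * np.sin(np.pi - L / R))
    if k >= 0:
        G = np.clip(G, 0.0, None)
    return G if G.ndim else float(G)


def latitude_angle(L, R: float):
    """Polar (latitude) angle ``theta = pi - L/R`` of a flatmount point.

    ``theta = pi`` at the south pole (optic nerve head), ``pi/2`` at the
    equator, ``0`` at the north pole.  Raises if ``L > pi*R`` (point beyond
    the unfolded hemisphere extent).
    """
    L = np.asarray(L, dtype=float)
    if np.any(L > np.pi * R * (1.0 + _REL_EPS)):
        raise ValueError(
            f"point beyond unfolded hemisphere extent: L > pi*R = {np.pi * R:.6g}"
        )
    L = _validate_L(L, R)
    theta = np.pi - L / R
    return theta if theta.ndim else float(theta)


def corneal_angle(M_max: float, R: float) -> float:
    """Corneal angle from the longest lobe middle-axis length.

    The farthest tissue extent ``M_max`` marks the rim of the removed
    corneal dome; its polar angle ``theta = pi - M_max/R`` characterizes how
    much of the sphere the tissue covers (report in degrees with
    ``math.degrees``).
    """
    if M_max <= 0:
        raise ValueError(f"M_max must be positive, got {M_max}")
    if M_max > np.pi * R * (1.0 + _REL_EPS):
        raise ValueError(
            f"M_max = {M_max:.6g} exceeds pi*R = {np.pi * R:.6g}; "
            "the sphere radius may be underestimated"
        )
    return latitude_angle(M_max, R)


def _wrap_angle(a):
    """Wrap angle(s) to (-pi, pi]."""
    return np.arctan2(np.sin(a), np.cos(a))


def image_azimuth(point: Sequence[float], origin: Sequence[float]) -> float:
    """Azimuth of ``point`` about ``origin`` in image coordinates.

    Computed as ``atan2(-(y - y0), x - x0)`` so angles run counter-clockwise
    in the standard on-screen orientation despite y-down pixel coordinates.
    """
    return float(np.arctan2(-(point[1] - origin[1]), point[0] - origin[0]))


def flatmount_point_to_sphere(
    point: Sequence[float],
    annotations,
    scale_um_per_px: float,
    model: SphereModel,
    profile=None,
    image_shape: Optional[Tuple[int, int]] = None,
) -> Tuple[float, float, int]:
    """Map a flatmount pixel to (latitude, longitude, lobe index) on the sphere.

    Latitude comes from the gap model: the pixel's radial distance to the
    optic nerve head, converted to mm, is the geodesic distance ``L`` and
    ``theta = pi - L/R``.  Longitude is this package's convention: each of
    the ``n`` lobes owns a ``2*pi/n`` longitude sector centered on its
    middle-axis azimuth, and the pixel's within-lobe azimuthal offset is
    rescaled by the per-lobe angular half-width at its radius,
    ``w(L) = (2*pi*L - G(L)) / (2*n*L)``, to fill that sector.

    Parameters
    ----------
    point : (x, y) pixel coordinates.
    annotations : AnnotationSet with origin and lobe markers.
    scale_um_per_px : image scale, microns per pixel.
    model : fitted :class:`SphereModel`.
    profile : GapProfile, optional
        When provided, its lobe axis lengths bound the radial extent of
        each lobe (points beyond are reported as off-tissue).
    image_shape : (height, width), optional
        When provided, points outside the frame raise.

    Returns
    -------
    (theta, phi, lobe) : latitude angle and longitude in radians, and the
    index of the nearest lobe axis.
    """
    x, y = float(point[0]), float(point[1])
    if image_shape is not None:
        h, w_img = image_shape[:2]
        if not (0 <= x < w_img and 0 <= y < h):
            raise ValueError(f"point {point} lies outside the image {image_shape}")
    x0, y0 = annotations.origin
    L_px = float(np.hypot(x - x0, y - y0))
    L_mm = L_px * scale_um_per_px / 1000.0
    if L_mm > np.pi * model.R * (1.0 + _REL_EPS):
        raise ValueError(
            f"point at L = {L_mm:.4g} mm is farther than pi*R = {np.pi * model.R:.4g} mm "
            "from the origin"
        )
    markers = np.asarray(annotations.lobe_markers, dtype=float)
    n = len(markers)
    axis_az = np.arctan2(-(markers[:, 1] - y0), markers[:, 0] - x0)

    if L_px == 0.0:
        # south pole: longitude is degenerate; fixed by convention
        return float(np.pi), 0.0, 0

    alpha = image_azimuth((x, y), (x0, y0))
    d = np.abs(_wrap_angle(alpha - axis_az))
    lobe = int(np.argmin(d))
    dalpha = float(_wrap_angle(alpha - axis_az[lobe]))

    G = corrected_gap(L_mm, model.R, model.k)
    w = (2.0 * np.pi * L_mm - G) / (2.0 * n * L_mm)
    if w <= 0:
        raise ValueError(
            f"no tissue at radius L = {L_mm:.4g} mm (gap spans the full circle)"
        )
    if abs(dalpha) > w * (1.0 + 1e-9):
        raise ValueError(
            f"point not on tissue: azimuthal offset {abs(dalpha):.4g} rad exceeds the "
            f"half-width {w:.4g} rad of nearest lobe {lobe}"
        )
    if profile is not None and hasattr(profile, "M_mm"):
        M = np.asarray(profile.M_mm, dtype=float)
        if lobe < len(M) and L_mm > M[lobe] * (1.0 + _REL_EPS):
            raise ValueError(
                f"point not on tissue: radius {L_mm:.4g} mm exceeds lobe {lobe} "
                f"axis length {M[lobe]:.4g} mm"
            )

    theta = latitude_angle(L_mm, model.R)
    phi = float(_wrap_angle(axis_az[lobe] + dalpha * (np.pi / n) / w))
    return theta, phi, lobe
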
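"""Synthetic flatmount generation with known ground truth.

Every stage of the pipeline is testable without real microscopy data:
:func:`simulate_profile` evaluates the corrected gap law directly (with
optional multiplicative measurement noise), :func:`render_flatmount` draws
a full n-lobe flatmount image whose interlobe gaps follow the same law,
and :func:`make_dataset` writes a cohort of images + annotation sidecars +
manifest emulating a calibration study (ground truth recorded as an
eyeball *diameter*, matching the convention of micrometer measurements on
intact eyes).

Defaults emulate the study conditions: 4 lobes on evenly spaced axes
(45/135/225/315 degrees), lobe middle-axis lengths drawn in
[0.55, 0.75]*pi*R so lobes extend past the equator, radii in the observed
ground-truth range 1.47-1.71 mm, distortion coefficients k/2pi centered on
0.1355 mm, and a 10 um/px scale.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Optional, Sequence, Tuple, Union

import imageio.v3 as iio
import numpy as np

from flatsphere.geometry import corrected_gap
from flatsphere.measurement import AnnotationSet, GapProfile

__all__ = [
    "SyntheticSample",
    "ProfileSample",
    "simulate_profile",
    "simulate_cohort",
    "render_flatmount",
    "make_dataset",
]

TISSUE_RGB = (178, 24, 43)  # saturated red, far from white background in S
DEFAULT_LOBE_LENGTH_RANGE = (0.55, 0.75)  # fraction of pi*R
DEFAULT_K_OVER_2PI_MEAN = 0.1355  # mm
DEFAULT_R_RANGE = (1.47, 1.71)  # mm


@dataclass
class SyntheticSample:
    """A rendered flatmount with its ground truth."""

    image: np.ndarray
    annotations: AnnotationSet
    R: float
    k: float
    n_lobes: int
    azimuths: np.ndarray
    lobe_lengths_mm: np.ndarray
    scale_um_per_px: float
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_lobes < 2:
            raise ValueError("a flatmount needs at least 2 lobes")
        if np.any(np.asarray(self.lobe_lengths_mm) > np.pi * self.R * (1 + 1e-9)):
            raise ValueError("lobe lengths cannot exceed pi*R")


class ProfileSample(NamedTuple):
    """A simulated gap profile with its generating parameters."""

    profile: GapProfile
    R: float
    k: float


def simulate_profile(
    R: float,
    k: float,
    M_min: Optional[float] = None,
    n_points: int = 500,
    noise_sd_frac: float = 0.0,
    seed=None,
    scale_um_per_px: float = 10.0,
    lobe_lengths: Optional[Sequence[float]] = None,
    image_id: str = "",
) -> GapProfile:
    """Forward-simulate a gap profile from the corrected gap law.

    Radii form an arithmetic sequence from one pixel's length to ``M_min``
    (mm); gaps are ``corrected_gap(L_i, R, k) * (1 + eps_i)`` with
    ``eps_i ~ Normal(0, noise_sd_frac)``, clamped to ``[0, 2*pi*L_i]``.
    Either ``M_min`` or explicit ``lobe_lengths`` (from which M_min is
    taken) must be given.
    """
    if noise_sd_frac < 0:
        raise ValueError("noise_sd_frac must be >= 0")
    if lobe_lengths is not None:
        M = np.asarray(lobe_lengths, dtype=float)
        M_min = float(np.min(M))
    else:
        if M_min is None:
            raise ValueError("provide M_min or lobe_lengths")
        M = np.full(4, float(M_min))
    if not 0 < M_min <= np.pi * R * (1 + 1e-9):
        raise ValueError(f"M_min must lie in (0, pi*R] = (0, {np.pi * R:.6g}] mm")

    eps = scale_um_per_px / 1000.0  # one pixel, in mm
    L_mm = np.linspace(eps, M_min, n_points)
    G = np.asarray(corrected_gap(L_mm, R, k), dtype=float)
    if noise_sd_frac > 0:
        rng = np.random.default_rng(seed)
        G = G * (1.0 + rng.normal(0.0, noise_sd_frac, n_points))
    G = np.clip(G, 0.0, 2.0 * np.pi * L_mm)
    return GapProfile(
        L_px=L_mm * 1000.0 / scale_um_per_px,
        L_mm=L_mm,
        G_mm=G,
        M_mm=M,
        scale_um_per_px=scale_um_per_px,
        image_id=image_id,
    )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated at zero (redraw), degenerate when sd=0."""
    if sd == 0:
        return max(mean, 0.0)
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v >= 0:
            return float(v)
    raise RuntimeError("truncated-normal rejection sampling failed")


def simulate_cohort(
    m: int = 10,
    n_points: int = 500,
    R_range: Tuple[float, float] = DEFAULT_R_RANGE,
    k_over_2pi_mean: float = DEFAULT_K_OVER_2PI_MEAN,
    k_over_2pi_sd: float = 0.01,
    noise_sd_frac: float = 0.01,
    scale_um_per_px: float = 10.0,
    seed=None,
) -> list:
    """Simulate a calibration cohort of gap profiles.

    Radii are uniform on ``R_range``; per-sample ``k/2pi`` is normal with
    the given mean/sd, truncated at zero; lobe middle-axis lengths are
    uniform on [0.55, 0.75]*pi*R; gaps carry multiplicative Gaussian noise.
    Returns a list of :class:`ProfileSample`.
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    out = []
    for i in range(m):
        R = float(rng.uniform(*R_range))
        k = 2 * np.pi * _truncated_normal(rng, k_over_2pi_mean, k_over_2pi_sd)
        lobes = rng.uniform(*DEFAULT_LOBE_LENGTH_RANGE, 4) * np.pi * R
        profile = simulate_profile(
            R,
            k,
            lobe_lengths=lobes,
            n_points=n_points,
            noise_sd_frac=noise_sd_frac,
            seed=rng,
            scale_um_per_px=scale_um_per_px,
            image_id=f"sim_{i:03d}",
        )
        out.append(ProfileSample(profile=profile, R=R, k=k))
    return out


def render_flatmount(
    R: float,
    k: float,
    n_lobes: int = 4,
    lobe_lengths: Optional[Sequence[float]] = None,
    scale_um_per_px: float = 10.0,
    seed=None,
    azimuths: Optional[Sequence[float]] = None,
    noise_sd_frac: float = 0.0,
    margin_px: int = 20,
    image_id: str = "",
) -> SyntheticSample:
    """Render an n-lobe flatmount image obeying the corrected gap law.

    At every flatmount radius ``L`` the total tissue angle is
    ``(2*pi*L - G(L)) / L`` radians, split equally among the lobes and
    centered on their axis azimuths; a pixel is tissue iff its angular
    distance to the nearest axis is within the per-lobe half-width and its
    radius is within that lobe's length.  Optional ``noise_sd_frac``
    perturbs each lobe's local gap share with a smooth multiplicative
    radial field (knot-interpolated), emulating irregular cut edges.

    Tissue is drawn saturated red on a white background; annotations place
    the origin at the image center and one marker at each lobe-axis tip.
    """
    if n_lobes < 2:
        raise ValueError("n_lobes must be >= 2")
    if k / (2 * np.pi) >= R:
        raise ValueError(
            f"k too large for R: k/2pi = {k / (2 * np.pi):.4g} >= R = {R:.4g} mm "
            "leaves no tissue at any radius"
        )
    rng = np.random.default_rng(seed)
    if lobe_lengths is None:
        lobe_lengths = rng.uniform(*DEFAULT_LOBE_LENGTH_RANGE, n_lobes) * np.pi * R
    lobe_lengths = np.asarray(lobe_lengths, dtype=float)
    if len(lobe_lengths) != n_lobes:
        raise ValueError("need one lobe length per lobe")
    if np.any(lobe_lengths > np.pi * R * (1 + 1e-9)) or np.any(lobe_lengths <= 0):
        raise ValueError("lobe lengths must lie in (0, pi*R] mm")
    if azimuths is None:
        azimuths = np.pi / n_lobes + 2 * np.pi * np.arange(n_lobes) / n_lobes
    azimuths = np.mod(np.asarray(azimuths, dtype=float) + np.pi, 2 * np.pi) - np.pi

    px_per_mm = 1000.0 / scale_um_per_px
    half = int(np.ceil(np.max(lobe_lengths) * px_per_mm)) + margin_px
    side = 2 * half + 1
    cx = cy = half

    ys, xs = np.mgrid[0:side, 0:side]
    dx = xs - cx
    dy_up = -(ys - cy)  # y-down pixels -> counter-clockwise azimuths
    L_px = np.hypot(dx, dy_up)
    L_mm = L_px * scale_um_per_px / 1000.0
    alpha = np.arctan2(dy_up, dx)

    with np.errstate(invalid="ignore", divide="ignore"):
        G = 2.0 * np.pi * (L_mm - (R - k / (2 * np.pi)) * np.sin(np.pi - L_mm / R))
        w = (2.0 * np.pi * L_mm - G) / (2.0 * n_lobes * L_mm)
    w = np.where(L_px == 0, np.pi / n_lobes, w)

    # smooth per-lobe perturbation of the local gap share
    if noise_sd_frac > 0:
        knots_L = np.linspace(0.0, np.pi * R, 40)
        knots = rng.normal(0.0, noise_sd_frac, (n_lobes, knots_L.size))
        eps_of_L = [np.interp(L_mm, knots_L, knots[j]) for j in range(n_lobes)]
    else:
        eps_of_L = None

    fg = np.zeros((side, side), dtype=bool)
    dmin = np.full((side, side), np.inf)
    nearest = np.zeros((side, side), dtype=np.int8)
    for j, az in enumerate(azimuths):
        d = np.abs(np.arctan2(np.sin(alpha - az), np.cos(alpha - az)))
        upd = d < dmin
        dmin = np.where(upd, d, dmin)
        nearest = np.where(upd, j, nearest)
    for j in range(n_lobes):
        wj = w
        if eps_of_L is not None:
            with np.errstate(invalid="ignore", divide="ignore"):
                wj = np.clip(w - G * eps_of_L[j] / (2.0 * n_lobes * L_mm), 0.0, None)
            wj = np.where(L_px == 0, np.pi / n_lobes, wj)
        sel = (nearest == j) & (dmin <= wj) & (L_mm <= lobe_lengths[j])
        fg |= sel
    fg[cy, cx] = True

    image = np.full((side, side, 3), 255, dtype=np.uint8)
    image[fg] = TISSUE_RGB

    markers = []
    for j, az in enumerate(azimuths):
        r_px = lobe_lengths[j] * px_per_mm
        mx = int(round(cx + r_px * np.cos(az)))
        my = int(round(cy - r_px * np.sin(az)))
        markers.append((int(np.clip(mx, 0, side - 1)), int(np.clip(my, 0, side - 1))))
    ann = AnnotationSet(origin=(cx, cy), lobe_markers=markers, image_id=image_id)

    return SyntheticSample(
        image=image,
        annotations=ann,
        R=R,
        k=k,
        n_lobes=n_lobes,
        azimuths=azimuths,
        lobe_lengths_mm=lobe_lengths,
        scale_um_per_px=scale_um_per_px,
        seed=seed,
    )


def make_dataset(
    m: int,
    out_dir: Union[str, Path],
    R_range: Tuple[float, float] = DEFAULT_R_RANGE,
    k_over_2pi_mean: float = DEFAULT_K_OVER_2PI_MEAN,
    k_over_2pi_sd: float = 0.05,
    noise_sd_frac: float = 0.0,
    scale_um_per_px: float = 10.0,
    n_lobes: int = 4,
    seed=None,
):
    """Write a synthetic calibration cohort to disk.

    Produces ``sample_XXX.png`` images, ``sample_XXX.json`` annotation
    sidecars, a ``manifest.csv`` (image_name, image_path,
    ground_truth_diameter_mm, microns_per_pixel; diameter = 2R per the
    convention of whole-eye micrometry) and a ``ground_truth.csv`` with the
    underlying parameters.  Fully reproducible from the seed.

    Returns the manifest path.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    manifest_rows = []
    truth_rows = []
    for i in range(m):
        name = f"sample_{i:03d}"
        R = float(rng.uniform(*R_range))
        k = 2 * np.pi * _truncated_normal(rng, k_over_2pi_mean, k_over_2pi_sd)
        lobes = rng.uniform(*DEFAULT_LOBE_LENGTH_RANGE, n_lobes) * np.pi * R
        sample = render_flatmount(
            R,
            k,
            n_lobes=n_lobes,
            lobe_lengths=lobes,
            scale_um_per_px=scale_um_per_px,
            seed=rng,
            noise_sd_frac=noise_sd_frac,
            image_id=name,
        )
        iio.imwrite(out / f"{name}.png", sample.image)
        sample.annotations.to_json(out / f"{name}.json")
        manifest_rows.append(
            [name, f"{name}.png", repr(2.0 * R), repr(float(scale_um_per_px))]
        )
        truth_rows.append(
            [name, repr(R), repr(k), repr(k / (2 * np.pi))]
            + [repr(float(x)) for x in lobes]
        )

    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["image_name", "image_path", "ground_truth_diameter_mm", "microns_per_pixel"]
        )
        w.writerows(manifest_rows)
    with open(out / "ground_truth.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["image_name", "R_mm", "k_mm", "k_over_2pi_mm"]
            + [f"lobe_length_{j}_mm" for j in range(n_lobes)]
        )
        w.writerows(truth_rows)
    return manifest
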
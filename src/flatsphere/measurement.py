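"""Gap-profile measurement from flatmount images.

Turns an RGB flatmount image plus a manual annotation (optic-nerve-head
origin and one marker per lobe tip) into a :class:`GapProfile`: paired
arrays of concentric-circle radii ``L_i`` and interlobe gap lengths
``G_i``, together with the lobe middle-axis lengths ``M_1..M_n``.

Segmentation follows the HSV route: Otsu's threshold on the saturation
channel separates stained tissue (saturated) from background.  Gap lengths
are measured on 1-pixel-thick rasterized circles centered on the origin,
normalized by the angular fraction of background pixels on each ring:
``G_i = frac_background * 2*pi*L_i``.  The fraction normalization removes
the bias a rasterized ring's pixel count would otherwise introduce.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu

__all__ = [
    "AnnotationSet",
    "GapProfile",
    "segment_tissue",
    "lobe_axis_lengths",
    "circle_pixels",
    "measure_gap_profile",
    "read_manifest",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = (
    "image_name",
    "image_path",
    "ground_truth_diameter_mm",
    "microns_per_pixel",
)


@dataclass
class AnnotationSet:
    """Manual landmarks for one flatmount image.

    ``origin`` is the optic nerve head (center of the concentric circles);
    ``lobe_markers`` are the distal points of each lobe's middle axis.
    Pixel coordinates are 0-based ``(x=column, y=row)``, y down.
    """

    origin: Tuple[float, float]
    lobe_markers: List[Tuple[float, float]]
    image_id: str = ""

    def __post_init__(self) -> None:
        self.origin = (float(self.origin[0]), float(self.origin[1]))
        self.lobe_markers = [(float(x), float(y)) for x, y in self.lobe_markers]
        if len(self.lobe_markers) < 2:
            raise ValueError(
                f"need at least 2 lobe markers, got {len(self.lobe_markers)}"
            )
        for m in self.lobe_markers:
            if m == self.origin:
                raise ValueError(f"lobe marker {m} coincides with the origin")

    @property
    def n_lobes(self) -> int:
        return len(self.lobe_markers)

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "image_id": self.image_id,
            "origin": list(self.origin),
            "lobe_markers": [list(m) for m in self.lobe_markers],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "AnnotationSet":
        d = json.loads(Path(path).read_text())
        return cls(
            origin=tuple(d["origin"]),
            lobe_markers=[tuple(m) for m in d["lobe_markers"]],
            image_id=d.get("image_id", Path(path).stem),
        )

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "AnnotationSet":
        """Read the CSV sidecar format: columns image_id,role,x,y with role
        'origin' (one row) or 'marker'."""
        origin = None
        markers: List[Tuple[float, float]] = []
        image_id = ""
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                image_id = row["image_id"]
                xy = (float(row["x"]), float(row["y"]))
                if row["role"] == "origin":
                    origin = xy
                elif row["role"] == "marker":
                    markers.append(xy)
                else:
                    raise ValueError(f"unknown annotation role {row['role']!r}")
        if origin is None:
            raise ValueError(f"no origin row in {path}")
        return cls(origin=origin, lobe_markers=markers, image_id=image_id)


@dataclass
class GapProfile:
    """Concentric-circle gap measurements for one flatmount.

    ``L_px``/``L_mm`` are strictly increasing circle radii (an arithmetic
    sequence over ``[1 px, M_min]`` when produced by
    :func:`measure_gap_profile`); ``G_mm`` the aligned gap lengths;
    ``M_mm`` the lobe middle-axis lengths.
    """

    L_px: np.ndarray
    L_mm: np.ndarray
    G_mm: np.ndarray
    M_mm: np.ndarray
    scale_um_per_px: float
    image_id: str = ""

    def __post_init__(self) -> None:
        self.L_px = np.asarray(self.L_px, dtype=float)
        self.L_mm = np.asarray(self.L_mm, dtype=float)
        self.G_mm = np.asarray(self.G_mm, dtype=float)
        self.M_mm = np.asarray(self.M_mm, dtype=float)
        if not (len(self.L_px) == len(self.L_mm) == len(self.G_mm)):
            raise ValueError("L_px, L_mm and G_mm must have equal length")
        if len(self.L_mm) >= 2 and not np.all(np.diff(self.L_mm) > 0):
            raise ValueError("circle radii L must be strictly increasing")
        ub = 2.0 * np.pi * self.L_mm
        if np.any(self.G_mm < -1e-12) or np.any(self.G_mm > ub * (1 + 1e-9) + 1e-12):
            raise ValueError("gap lengths must satisfy 0 <= G_i <= 2*pi*L_i")

    @property
    def n_points(self) -> int:
        return len(self.L_mm)

    @property
    def M_min_mm(self) -> float:
        return float(np.min(self.M_mm))

    @property
    def M_max_mm(self) -> float:
        return float(np.max(self.M_mm))

    def to_csv(self, path: Union[str, Path]) -> None:
        """Write the profile as CSV with '#'-prefixed metadata header lines."""
        with open(path, "w", newline="") as fh:
            fh.write(f"# image_id={self.image_id}\n")
            fh.write(f"# scale_um_per_px={self.scale_um_per_px!r}\n")
            fh.write("# M_mm=" + ",".join(repr(float(m)) for m in self.M_mm) + "\n")
            w = csv.writer(fh)
            w.writerow(["L_px", "L_mm", "G_mm"])
            for lp, lm, g in zip(self.L_px, self.L_mm, self.G_mm):
                w.writerow([repr(float(lp)), repr(float(lm)), repr(float(g))])

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "GapProfile":
        meta = {}
        rows = []
        with open(path, newline="") as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    meta[key.strip()] = val
                else:
                    rows.append(line)
        data = list(csv.reader(rows))
        header, body = data[0], data[1:]
        cols = {h: i for i, h in enumerate(header)}
        arr = np.array([[float(r[cols[c]]) for c in ("L_px", "L_mm", "G_mm")] for r in body])
        return cls(
            L_px=arr[:, 0],
            L_mm=arr[:, 1],
            G_mm=arr[:, 2],
            M_mm=np.array([float(v) for v in meta["M_mm"].split(",")]),
            scale_um_per_px=float(meta["scale_um_per_px"]),
            image_id=meta.get("image_id", ""),
        )


def segment_tissue(image: np.ndarray) -> np.ndarray:
    """Binary background mask from an RGB flatmount image.

    The image is converted to HSV and Otsu's threshold is applied to the
    saturation channel; the class with the lower mean saturation is labeled
    background (antibody-stained tissue is the saturated signal).

    Returns a boolean array, True = background.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError(f"expected an RGB image (H, W, 3), got shape {image.shape}")
    sat = rgb2hsv(image[..., :3])[..., 1]
    if np.ptp(sat) == 0:
        raise ValueError("cannot threshold uniform image: single-valued saturation")
    t = threshold_otsu(sat)
    low = sat <= t
    high = ~low
    if not low.any() or not high.any():
        raise ValueError("cannot threshold uniform image: degenerate Otsu split")
    # background = lower-mean-saturation class
    if sat[low].mean() <= sat[high].mean():
        return low
    return high


def lobe_axis_lengths(
    annotations: AnnotationSet, scale_um_per_px: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Lobe middle-axis lengths ``M_1..M_n`` in pixels and mm.

    Each length is the Euclidean distance from the origin to a lobe marker;
    mm = px * (um/px) / 1000.
    """
    o = np.asarray(annotations.origin, dtype=float)
    mk = np.asarray(annotations.lobe_markers, dtype=float)
    M_px = np.hypot(*(mk - o).T)
    if np.any(M_px == 0):
        raise ValueError("lobe marker coincides with the origin")
    return M_px, M_px * scale_um_per_px / 1000.0


def circle_pixels(
    center: Sequence[float], radius: float, image_shape: Tuple[int, int]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pixels of a 1-pixel-thick closed circle (midpoint ring).

    A pixel belongs to the ring of integer radius ``r`` iff its Euclidean
    distance to the center lies within half a pixel of ``r``.  Rings of
    consecutive radii therefore tile the plane without gaps or overlaps,
    which keeps arc-fraction estimates unbiased; the expected pixel count
    equals the annulus area ``2*pi*r``.  (Membership is unambiguous: a
    pixel distance can never equal ``r + 1/2`` exactly, since
    ``4*(dx^2 + dy^2)`` is even while ``(2r+1)^2`` is odd.)

    Parameters
    ----------
    center : (x, y) pixel coordinates of the circle center.
    radius : circle radius in pixels (rounded to the nearest integer >= 1).
    image_shape : (height, width); pixels outside are flagged, not dropped
        (tissue cannot exist outside the frame).

    Returns
    -------
    xs, ys, in_bounds : pixel coordinates (each pixel once, sorted) and a
        boolean flag per pixel, False where the pixel falls off the image.
    """
    r = int(round(radius))
    if r < 1:
        raise ValueError(f"radius must be >= 1 pixel, got {radius}")
    cx, cy = int(round(center[0])), int(round(center[1]))

    dx = np.arange(-r, r + 1)
    lo = np.sqrt(np.maximum((r - 0.5) ** 2 - dx * dx, 0.0))
    hi = np.sqrt((r + 0.5) ** 2 - dx * dx)
    y_lo = np.ceil(lo).astype(np.int64)
    y_hi = np.floor(hi).astype(np.int64)
    counts = y_hi - y_lo + 1
    col = np.repeat(np.arange(dx.size), counts)
    offs = np.arange(counts.sum()) - np.repeat(np.cumsum(counts) - counts, counts)
    dys = y_lo[col] + offs
    dxs = dx[col]
    pix = np.concatenate(
        [np.stack([dxs, dys], axis=1), np.stack([dxs, -dys], axis=1)]
    )
    pix = np.unique(pix, axis=0)
    xs, ys = cx + pix[:, 0], cy + pix[:, 1]
    h, w = image_shape[:2]
    in_bounds = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
    return xs, ys, in_bounds


def measure_gap_profile(
    mask: np.ndarray,
    annotations: AnnotationSet,
    scale_um_per_px: float,
    n_points: int = 500,
) -> GapProfile:
    """Measure the interlobe gap profile on concentric circles.

    Circle radii form an arithmetic sequence of ``n_points`` values over
    ``[1, M_min]`` pixels (``M_min`` = shortest lobe middle axis).  For each
    radius the gap length is the background angular fraction on the
    rasterized ring times the true circumference:
    ``G_i = (n_background / n_ring) * 2*pi*L_i`` (in mm).  Ring pixels that
    fall outside the frame count as background, with a warning.

    Parameters
    ----------
    mask : boolean background mask from :func:`segment_tissue` (True = background).
    annotations : landmarks defining the origin and lobe axes.
    scale_um_per_px : image scale.
    n_points : length of the radius sequence (default 500).
    """
    mask = np.asarray(mask, dtype=bool)
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2, got {n_points}")
    h, w = mask.shape
    x0, y0 = annotations.origin
    ix0, iy0 = int(round(x0)), int(round(y0))
    if not (1 <= ix0 < w - 1 and 1 <= iy0 < h - 1):
        raise ValueError(
            f"origin {annotations.origin} lies outside or on the edge of the image"
        )
    M_px, M_mm = lobe_axis_lengths(annotations, scale_um_per_px)
    M_min_px = float(np.min(M_px))
    if M_min_px < 10:
        raise ValueError(
            f"shortest lobe axis is {M_min_px:.1f} px; need >= 10 px to sample "
            f"{n_points} radii meaningfully"
        )

    L_px = np.linspace(1.0, M_min_px, n_points)
    L_mm = L_px * scale_um_per_px / 1000.0
    frac = np.empty(n_points)
    left_frame = False
    cache: dict = {}
    for i, r in enumerate(L_px):
        key = int(round(r))
        if key not in cache:
            xs, ys, inb = circle_pixels((x0, y0), key, mask.shape)
            n_total = len(xs)
            n_bg = int(np.count_nonzero(mask[ys[inb], xs[inb]])) + int(
                np.count_nonzero(~inb)
            )
            cache[key] = (n_bg / n_total, bool((~inb).any()))
        frac[i], oob = cache[key]
        left_frame = left_frame or oob
    if left_frame:
        warnings.warn(
            "some measurement circles leave the image frame; out-of-bounds pixels "
            "were counted as background",
            stacklevel=2,
        )
    G_mm = frac * 2.0 * np.pi * L_mm
    return GapProfile(
        L_px=L_px,
        L_mm=L_mm,
        G_mm=G_mm,
        M_mm=M_mm,
        scale_um_per_px=scale_um_per_px,
        image_id=annotations.image_id,
    )


def read_manifest(path: Union[str, Path]):
    """Read the cohort manifest CSV into a pandas DataFrame.

    Columns: image_name, image_path, ground_truth_diameter_mm (may be empty
    for non-calibration samples), microns_per_pixel.
    """
    import pandas as pd

    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns {missing}")
    return df
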
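"""Input/output and core geometric containers.

This module owns the four containers the pipeline passes around — grayscale
images, user-drawn seed points, closed contours and binary masks — together
with every reader/writer the tool needs (PNG/TIFF images, CSV/JSON seed and
contour files, PNG masks, CSV/JSON reports) and the contour rasterizer that
turns a converged snake front into a pixel mask.

Coordinate convention: ``(row, col)``, 0-based, with pixel centers at integer
coordinates. Contours are closed by construction (the last vertex connects
back to the first; no duplicated endpoint) and stored counterclockwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from shapely.geometry import LinearRing

__all__ = [
    "GrayImage",
    "SeedPoints",
    "ContourCurve",
    "BinaryMask",
    "read_gray_image",
    "write_gray_image",
    "read_seed_points",
    "write_seed_points",
    "rasterize_contour",
    "read_contour",
    "write_contour",
    "read_mask",
    "write_mask",
    "write_report",
    "extract_avi_frames",
]

#: Rec. 601 luminance weights used to collapse RGB input to gray.
_LUMA = np.array([0.299, 0.587, 0.114])

MIN_IMAGE_SIDE = 16


class InputError(ValueError):
    """Raised when an external artifact cannot be read."""


class ValidationError(ValueError):
    """Raised when an object violates its structural invariants."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class GrayImage:
    """A 2-D grayscale image with intensities in [0, 255].

    Parameters
    ----------
    pixels
        2-D float array of intensities. Stored as float64 so preprocessing
        products (inpainted regions, blurred fields) keep sub-level precision;
        writers round to 8-bit.
    source_id
        Free-text provenance tag (file name, phantom spec hash, ...).
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValidationError("image must be 2-D")
        if min(self.pixels.shape) < MIN_IMAGE_SIDE:
            raise ValidationError(
                f"image sides must be >= {MIN_IMAGE_SIDE}, got {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("image intensities must be finite")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValidationError("image intensities must lie in [0, 255]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class SeedPoints:
    """Ordered user-drawn points on the organ border.

    At least three non-collinear points are required so a convex hull with
    nonzero area exists for the initial snake front.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError("seed points must be an (n, 2) array of (row, col)")
        if len(pts) < 3:
            raise ValidationError("insufficient seeds: need at least 3 points")
        if not np.all(np.isfinite(pts)):
            raise ValidationError("seed coordinates must be finite")
        # all-collinear check via the rank of centered coordinates
        centered = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
            raise ValidationError("degenerate hull: seed points are collinear")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    def validate_bounds(self, shape: tuple[int, int]) -> None:
        """Raise if any point lies outside an image of the given shape."""
        h, w = shape
        r, c = self.points[:, 0], self.points[:, 1]
        if (r < 0).any() or (c < 0).any() or (r > h - 1).any() or (c > w - 1).any():
            raise ValidationError(
                f"seed point out of bounds for image of shape {(h, w)}"
            )


def _signed_area(vertices: np.ndarray) -> float:
    """Shoelace signed area in the (row, col) frame treated as (x, y)."""
    r, c = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(r * np.roll(c, -1) - np.roll(r, -1) * c))


@dataclass
class ContourCurve:
    """A closed, simple polygonal contour — the snake front x(s).

    Vertices are ``(row, col)`` floats; the curve closes implicitly from the
    last vertex to the first and is stored with positive signed area
    (counterclockwise in the (row, col) frame).
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValidationError("contour vertices must be an (n, 2) array")
        if len(v) < 3:
            raise ValidationError("contour needs at least 3 vertices")
        if not np.all(np.isfinite(v)):
            raise ValidationError("contour coordinates must be finite")
        if _signed_area(v) < 0:
            v = v[::-1].copy()
        self.vertices = v

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def closed(self) -> bool:
        return True

    def is_simple(self) -> bool:
        """True when the closed polyline does not self-intersect."""
        ring = LinearRing(np.column_stack([self.vertices[:, 1], self.vertices[:, 0]]))
        return bool(ring.is_simple)

    def perimeter(self) -> float:
        d = np.roll(self.vertices, -1, axis=0) - self.vertices
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class BinaryMask:
    """Per-pixel membership map congruent with a parent image."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.pixels)
        if m.ndim != 2:
            raise ValidationError("mask must be 2-D")
        self.pixels = m.astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def area(self) -> int:
        """Foreground pixel count."""
        return int(self.pixels.sum())


# ---------------------------------------------------------------------------
# image readers/writers


def read_gray_image(path: str | Path) -> GrayImage:
    """Read a PNG/TIFF image as 8-bit grayscale.

    RGB(A) input is collapsed by Rec. 601 luminance (0.299 R + 0.587 G +
    0.114 B); an alpha channel, if present, is dropped.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read image {path}: {exc}") from exc
    if arr.size == 0:
        raise ValidationError(f"zero-size image: {path}")
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    return GrayImage(np.clip(np.asarray(arr, dtype=np.float64), 0, 255),
                     source_id=str(path))


def write_gray_image(img: GrayImage, path: str | Path) -> None:
    """Write an image as 8-bit PNG/TIFF (intensities rounded to integers)."""
    iio.imwrite(Path(path), np.rint(img.pixels).astype(np.uint8))


def extract_avi_frames(path: str | Path, out_dir: str | Path) -> list[Path]:
    """Dump every frame of an AVI to numbered 8-bit gray PNGs.

    Returns the written paths. Requires an imageio backend with video
    support; raises :class:`InputError` with a clear message otherwise.
    """
    path, out_dir = Path(path), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        frames = iio.imread(path, index=None)
    except Exception as exc:  # backend-dependent error types
        raise InputError(
            f"cannot decode video {path}: {exc} "
            "(an imageio video backend such as ffmpeg is required)"
        ) from exc
    written = []
    for i, frame in enumerate(np.atleast_3d(frames)):
        frame = np.asarray(frame, dtype=np.float64)
        if frame.ndim == 3:
            frame = frame[..., :3] @ _LUMA
        out = out_dir / f"frame_{i:05d}.png"
        iio.imwrite(out, np.clip(np.rint(frame), 0, 255).astype(np.uint8))
        written.append(out)
    return written


# ---------------------------------------------------------------------------
# seed points


def read_seed_points(
    path: str | Path, image_shape: tuple[int, int] | None = None
) -> SeedPoints:
    """Read seed points from CSV (``row,col`` header optional) or JSON.

    JSON may be a list of ``[row, col]`` pairs or ``{"points": [...]}``.
    When ``image_shape`` is given, every point is validated against it.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"seed file not found: {path}")
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        if isinstance(data, dict):
            data = data["points"]
        pts = np.asarray(data, dtype=np.float64)
    else:
        pts = _read_coord_csv(path)
    seeds = SeedPoints(pts)
    if image_shape is not None:
        seeds.validate_bounds(image_shape)
    return seeds


def write_seed_points(seeds: SeedPoints, path: str | Path) -> None:
    _write_coord_csv(seeds.points, path)


def _read_coord_csv(path: Path) -> np.ndarray:
    first = path.read_text().lstrip().splitlines()
    header = 0 if first and first[0].replace(" ", "").startswith("row,") else None
    df = pd.read_csv(path, header=header, names=["row", "col"])
    return df[["row", "col"]].to_numpy(dtype=np.float64)


def _write_coord_csv(points: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(points, columns=["row", "col"]).to_csv(
        Path(path), index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# contours and masks


def read_contour(path: str | Path) -> ContourCurve:
    """Read a contour from a ``row,col`` CSV written by :func:`write_contour`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"contour file not found: {path}")
    return ContourCurve(_read_coord_csv(path))


def write_contour(contour: ContourCurve, path: str | Path) -> None:
    _write_coord_csv(contour.vertices, path)


def read_mask(path: str | Path) -> BinaryMask:
    path = Path(path)
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read mask {path}: {exc}") from exc
    return BinaryMask(arr > 127)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit PNG with foreground 255, background 0."""
    iio.imwrite(Path(path), np.where(mask.pixels, 255, 0).astype(np.uint8))


def points_in_polygon(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even–odd (crossing-number) point-in-polygon test, boundary inclusive.

    Vectorized over ``points`` (an (m, 2) array of (row, col)); loops over
    polygon edges. A point whose center lies exactly on an edge counts as
    inside.
    """
    points = np.asarray(points, dtype=np.float64)
    verts = np.asarray(vertices, dtype=np.float64)
    r, c = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    on_edge = np.zeros(len(points), dtype=bool)
    n = len(verts)
    eps = 1e-12
    for i in range(n):
        r1, c1 = verts[i]
        r2, c2 = verts[(i + 1) % n]
        # exact on-segment test: zero cross product and within bounding box
        cross = (r2 - r1) * (c - c1) - (c2 - c1) * (r - r1)
        within = (
            (np.minimum(r1, r2) - eps <= r)
            & (r <= np.maximum(r1, r2) + eps)
            & (np.minimum(c1, c2) - eps <= c)
            & (c <= np.maximum(c1, c2) + eps)
        )
        on_edge |= (np.abs(cross) <= eps * max(1.0, abs(r2 - r1) + abs(c2 - c1))) & within
        # horizontal ray toward +col; half-open rule on the row interval
        crosses_row = (r1 > r) != (r2 > r)
        with np.errstate(divide="ignore", invalid="ignore"):
            c_inter = c1 + (r - r1) / (r2 - r1) * (c2 - c1)
        inside ^= crosses_row & (c < c_inter)
    return inside | on_edge


def rasterize_contour(contour: ContourCurve, shape: tuple[int, int]) -> BinaryMask:
    """Rasterize a simple closed contour to a mask on a pixel grid.

    A pixel belongs to the foreground when its center (integer (row, col))
    lies inside the polygon under the even–odd rule; centers exactly on an
    edge are included.
    """
    if not contour.is_simple():
        raise ValidationError("cannot rasterize a self-intersecting contour")
    h, w = shape
    v = contour.vertices
    if v[:, 0].max() < 0 or v[:, 0].min() > h - 1 or v[:, 1].max() < 0 or v[:, 1].min() > w - 1:
        raise ValidationError("contour lies entirely outside the image bounds")
    # restrict the per-pixel test to the contour's bounding box
    r0 = max(0, int(np.floor(v[:, 0].min())))
    r1 = min(h - 1, int(np.ceil(v[:, 0].max())))
    c0 = max(0, int(np.floor(v[:, 1].min())))
    c1 = min(w - 1, int(np.ceil(v[:, 1].max())))
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
    box = points_in_polygon(pts, v).reshape(rr.shape)
    mask = np.zeros((h, w), dtype=bool)
    mask[r0 : r1 + 1, c0 : c1 + 1] = box
    return BinaryMask(mask)


# ---------------------------------------------------------------------------
# reports


def write_report(report: dict | object, path: str | Path) -> None:
    """Write a report as JSON (``.json``) or single-row CSV (``.csv``).

    Accepts a plain dict or any dataclass-like object with ``__dict__``.
    """
    path = Path(path)
    data = report if isinstance(report, dict) else dict(vars(report))
    data = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in data.items()}
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, default=float) + "\n")
    else:
        pd.DataFrame([data]).to_csv(path, index=False)


def read_report(path: str | Path) -> dict:
    path = Path(path)
    if path.suffix.lower() == ".json":
        return json.loads(path.read_text())
    return pd.read_csv(path).iloc[0].to_dict()
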
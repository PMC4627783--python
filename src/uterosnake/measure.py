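"""Uterine shape measurements from a closed contour.

Four scalars summarize a segmentation:

* UA    — area enclosed by the contour (shoelace formula),
* UMXD  — maximum diameter: the maximum Feret diameter, i.e. the largest
          pairwise distance between boundary points,
* UMID  — minimum diameter: the minimum Feret width of the convex hull
          (the narrowest caliper distance over all directions),
* AULA  — angle of the long axis: orientation of the major axis of the
          ellipse fitted to the boundary by direct least squares
          (Fitzgibbon-type ellipse-specific conic fit), measured
          counterclockwise from the image column (horizontal) axis when the
          image is displayed with rows running down, in degrees in [0, 180).

Lengths are reported in pixels, or millimetres when a ``mm/px`` scale is
supplied (areas scale with its square).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

from .image_io import ContourCurve, ValidationError

__all__ = [
    "UterusMeasurements",
    "area",
    "diameters",
    "long_axis_angle",
    "ellipse_axes",
    "measure_all",
]


@dataclass
class UterusMeasurements:
    """The four shape measurements for one segmentation."""

    ua: float
    umxd: float
    umid: float
    aula: float
    units: str = "px"
    ellipse_major: float | None = None
    ellipse_minor: float | None = None

    def __post_init__(self) -> None:
        if self.ua <= 0:
            raise ValidationError("area must be positive")
        if not (self.umxd >= self.umid > 0):
            raise ValidationError("diameters must satisfy umxd >= umid > 0")
        if not (0 <= self.aula < 180):
            raise ValidationError("aula must lie in [0, 180)")


def area(contour: ContourCurve) -> float:
    """Enclosed area by the shoelace formula; orientation independent."""
    if not contour.is_simple():
        raise ValidationError("area of a self-intersecting contour is undefined")
    v = contour.vertices
    r, c = v[:, 0], v[:, 1]
    return abs(0.5 * float(np.sum(r * np.roll(c, -1) - np.roll(r, -1) * c)))


def _hull_vertices(contour: ContourCurve) -> np.ndarray:
    try:
        hull = ConvexHull(contour.vertices)
    except Exception as exc:
        raise ValidationError(f"degenerate contour: {exc}") from exc
    if hull.volume <= 0:
        raise ValidationError("degenerate contour: zero hull area")
    return contour.vertices[hull.vertices]  # counterclockwise order


def diameters(contour: ContourCurve) -> tuple[float, float]:
    """(maximum, minimum) Feret diameters of the contour.

    The maximum is the largest pairwise distance between hull vertices; the
    minimum is the smallest caliper width of the convex hull, attained for a
    direction perpendicular to one of its edges (rotating-calipers fact), so
    it is computed exactly as the minimum over hull edges of the farthest
    vertex distance from the edge's supporting line.
    """
    hv = _hull_vertices(contour)
    diff = hv[:, None, :] - hv[None, :, :]
    umxd = float(np.sqrt((diff**2).sum(-1)).max())

    edges = np.roll(hv, -1, axis=0) - hv
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    keep = lengths > 1e-12
    if not keep.any():
        raise ValidationError("degenerate contour: all hull edges have zero length")
    # unit normals of each edge; width = max projection of vertices onto normal
    normals = np.column_stack([-edges[keep, 1], edges[keep, 0]]) / lengths[keep, None]
    rel = hv[None, :, :] - hv[keep][:, None, :]
    widths = np.abs(np.einsum("eij,ej->ei", rel, normals)).max(axis=1)
    umid = float(widths.min())
    if umid <= 0:
        raise ValidationError("degenerate contour: zero minimum width")
    return umxd, umid


def _direct_ellipse_coeffs(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Ellipse-specific direct least-squares conic fit (Halir–Flusser).

    Returns conic coefficients (A, B, C, D, E, F) for
    A x^2 + B x y + C y^2 + D x + E y + F = 0 with B^2 - 4AC < 0
    guaranteed by the 4AC - B^2 = 1 constraint. Numerically stable
    block-decomposed formulation of the Fitzgibbon fit.
    """
    d1 = np.column_stack([x * x, x * y, y * y])
    d2 = np.column_stack([x, y, np.ones_like(x)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(f"no ellipse fit: singular system ({exc})") from exc
    m = s1 + s2 @ t
    # premultiply by inv(C) for constraint matrix C = [[0,0,2],[0,-1,0],[2,0,0]]
    m = np.vstack([m[2] / 2.0, -m[1], m[0] / 2.0])
    evals, evecs = np.linalg.eig(m)
    if np.iscomplexobj(evecs):
        evals, evecs = np.real(evals), np.real(evecs)
    # the ellipse solution is the eigenvector with 4ac - b^2 > 0
    cond = 4 * evecs[0] * evecs[2] - evecs[1] ** 2
    ok = cond > 0
    if not ok.any():
        raise ValidationError("no ellipse fit: conic degenerated")
    a1 = evecs[:, ok][:, 0]
    return np.concatenate([a1, t @ a1])


def _conic_to_geometry(coeffs: np.ndarray) -> tuple[float, float, float, float, float]:
    """Conic coefficients -> (xc, yc, semi_major, semi_minor, theta)."""
    A, B, C, D, E, F = coeffs
    den = B * B - 4 * A * C
    if den >= 0:
        raise ValidationError("no ellipse fit: conic is not an ellipse")
    xc = (2 * C * D - B * E) / den
    yc = (2 * A * E - B * D) / den
    f0 = A * xc * xc + B * xc * yc + C * yc * yc + D * xc + E * yc + F
    quad = np.array([[A, B / 2], [B / 2, C]])
    evals, evecs = np.linalg.eigh(quad)
    axes2 = -f0 / evals
    if not np.all(axes2 > 0):
        raise ValidationError("no ellipse fit: nonpositive axis")
    semi = np.sqrt(axes2)  # paired with evecs columns
    i_major = int(np.argmax(semi))
    major_dir = evecs[:, i_major]
    theta = float(np.arctan2(major_dir[1], major_dir[0]))
    return float(xc), float(yc), float(semi.max()), float(semi.min()), theta


def _fit_ellipse(vertices: np.ndarray) -> tuple[float, float, float]:
    """Fit an ellipse; return (major, minor, aula_degrees).

    Points are fitted in (x, y) = (col, -row) so that the returned angle is
    counterclockwise from the column axis in the displayed image (rows run
    down the screen). Coordinates are centered and isotropically rescaled
    before the conic fit for conditioning; neither transform changes the
    axis ratio or orientation, and the axes are scaled back.
    """
    if len(vertices) < 6:
        raise ValidationError("ellipse fit needs at least 6 vertices")
    xy = np.column_stack([vertices[:, 1], -vertices[:, 0]])
    centroid = xy.mean(axis=0)
    spread = float(np.sqrt(((xy - centroid) ** 2).sum(axis=1).mean()))
    if spread <= 0:
        raise ValidationError("no ellipse fit: zero-spread points")
    norm = (xy - centroid) / spread
    coeffs = _direct_ellipse_coeffs(norm[:, 0], norm[:, 1])
    _, _, semi_major, semi_minor, theta = _conic_to_geometry(coeffs)
    a, b = semi_major * spread, semi_minor * spread
    if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
        raise ValidationError("no ellipse fit: nonpositive axis")
    return 2 * a, 2 * b, float(np.degrees(theta) % 180.0)


def long_axis_angle(contour: ContourCurve) -> float:
    """Major-axis angle of the least-squares ellipse, degrees in [0, 180)."""
    return _fit_ellipse(contour.vertices)[2]


def ellipse_axes(contour: ContourCurve) -> tuple[float, float]:
    """(major, minor) full axis lengths of the least-squares ellipse."""
    major, minor, _ = _fit_ellipse(contour.vertices)
    return major, minor


def measure_all(
    contour: ContourCurve, scale_mm_per_px: float | None = None
) -> UterusMeasurements:
    """Compute all four measurements, optionally in millimetres.

    Without a scale the units field reads ``"px"``; with one, lengths are
    multiplied by the scale and the area by its square, and units read
    ``"mm"``. The fitted-ellipse axes are included as optional extras.
    """
    ua = area(contour)
    umxd, umid = diameters(contour)
    # densify sparse contours so the conic fit is well conditioned
    fit_vertices = contour.vertices
    if len(fit_vertices) < 64:
        from .snake import resample_closed

        fit_vertices = resample_closed(fit_vertices, 64)
    major, minor, aula = _fit_ellipse(fit_vertices)
    s = 1.0 if scale_mm_per_px is None else float(scale_mm_per_px)
    if scale_mm_per_px is not None and s <= 0:
        raise ValidationError("scale must be positive")
    return UterusMeasurements(
        ua=ua * s * s,
        umxd=umxd * s,
        umid=umid * s,
        aula=aula,
        units="px" if scale_mm_per_px is None else "mm",
        ellipse_major=major * s,
        ellipse_minor=minor * s,
    )
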
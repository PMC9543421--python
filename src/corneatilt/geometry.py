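"""Corneal surface geometry.

Analytic conicoid (biconic) surfaces, sampled elevation grids, polynomial
smoothing fits and 3D rigid rotations.  These primitives serve two roles:
the synthetic-data generator uses conicoids to build ground-truth corneas,
and the tilt estimator evaluates fitted heights and normals while tracing
rays.

Coordinate frame
----------------
The instrument (visual) axis is +z and light propagates toward +z; x is
nasal and y superior.  Heights are sagitta in millimetres measured from the
anterior apex plane, increasing into the eye, which matches the layout of
exported Scheimpflug elevation maps and makes corneal tilt a rotation of
the z axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ApertureError, FitError, OutOfDomainError

__all__ = [
    "ConicoidSurface",
    "ElevationGrid",
    "SmoothSurface",
    "RigidRotation",
    "RotatedSurface",
    "sagitta",
    "analytic_normal",
    "fit_smooth_surface",
    "rotation_from_angles",
    "angle_between_axes",
    "read_elevation_csv",
    "write_elevation_csv",
]

_Z_HAT = np.array([0.0, 0.0, 1.0])


def _as_float_arrays(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return x, y


@dataclass(frozen=True)
class ConicoidSurface:
    """Biconic conic-section surface z(x, y) with an optional apex offset.

    Along each principal meridian the surface is a conic with apical radius
    ``R`` (mm) and asphericity ``Q`` (Q = 0 sphere, Q = -1 paraboloid).
    Equal radii and asphericities reduce to a rotationally symmetric
    conicoid.  Sagitta is real only where
    ``1 - (1+Qx) x^2/Rx^2 - (1+Qy) y^2/Ry^2 >= 0``.
    """

    apex_radius_x: float
    apex_radius_y: float
    asphericity_x: float = 0.0
    asphericity_y: float = 0.0
    apex_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.apex_radius_x <= 0 or self.apex_radius_y <= 0:
            raise ValueError("apex radii must be positive")

    @classmethod
    def symmetric(
        cls, radius: float, asphericity: float = 0.0, apex_z: float = 0.0
    ) -> "ConicoidSurface":
        """Rotationally symmetric conicoid with its apex on the z axis."""
        return cls(radius, radius, asphericity, asphericity, (0.0, 0.0, apex_z))

    def _domain_term(self, xr, yr):
        rx, ry = self.apex_radius_x, self.apex_radius_y
        return (
            1.0
            - (1.0 + self.asphericity_x) * xr**2 / rx**2
            - (1.0 + self.asphericity_y) * yr**2 / ry**2
        )

    def height(self, x, y):
        """Sagitta in mm at (x, y); raises OutOfDomainError beyond the conic."""
        x, y = _as_float_arrays(x, y)
        x0, y0, z0 = self.apex_offset
        xr, yr = x - x0, y - y0
        w = self._domain_term(xr, yr)
        if np.any(w < -1e-12):
            raise OutOfDomainError(
                "point outside the real-sagitta domain of the conicoid"
            )
        w = np.clip(w, 0.0, None)
        u = xr**2 / self.apex_radius_x + yr**2 / self.apex_radius_y
        z = z0 + u / (1.0 + np.sqrt(w))
        return float(z) if z.ndim == 0 else z

    def gradient(self, x, y):
        """(dz/dx, dz/dy) at (x, y)."""
        x, y = _as_float_arrays(x, y)
        x0, y0, _ = self.apex_offset
        xr, yr = x - x0, y - y0
        rx, ry = self.apex_radius_x, self.apex_radius_y
        qx, qy = self.asphericity_x, self.asphericity_y
        w = self._domain_term(xr, yr)
        if np.any(w < -1e-12):
            raise OutOfDomainError(
                "point outside the real-sagitta domain of the conicoid"
            )
        sw = np.sqrt(np.clip(w, 1e-14, None))
        d = 1.0 + sw
        u = xr**2 / rx + yr**2 / ry
        ux, uy = 2.0 * xr / rx, 2.0 * yr / ry
        wx = -2.0 * (1.0 + qx) * xr / rx**2
        wy = -2.0 * (1.0 + qy) * yr / ry**2
        dx = wx / (2.0 * sw)
        dy = wy / (2.0 * sw)
        gx = (ux * d - u * dx) / d**2
        gy = (uy * d - u * dy) / d**2
        if gx.ndim == 0:
            return float(gx), float(gy)
        return gx, gy

    def normal(self, x, y):
        """Unit surface normal with positive z component."""
        gx, gy = self.gradient(x, y)
        return _normal_from_gradient(gx, gy)

    def domain_radius(self) -> float:
        """Radial extent of the real-sagitta domain (inf for Q <= -1)."""
        rads = []
        for r, q in (
            (self.apex_radius_x, self.asphericity_x),
            (self.apex_radius_y, self.asphericity_y),
        ):
            rads.append(math.inf if q <= -1.0 else r / math.sqrt(1.0 + q))
        return min(rads)


def _normal_from_gradient(gx, gy):
    gx = np.asarray(gx, dtype=float)
    gy = np.asarray(gy, dtype=float)
    ones = np.ones_like(gx)
    n = np.stack([-gx, -gy, ones], axis=-1)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    return n[()] if n.ndim > 1 else n


def sagitta(surface: ConicoidSurface, x, y):
    """Surface height (sag) in mm at (x, y), including the apex offset."""
    return surface.height(x, y)


def analytic_normal(surface: ConicoidSurface, x, y):
    """Unit normal of an analytic conicoid, oriented toward negative sag side
    (positive z component)."""
    return surface.normal(x, y)


# ---------------------------------------------------------------------------
# Elevation grids


@dataclass
class ElevationGrid:
    """Corneal heights sampled on a regular Cartesian grid.

    Rows run along y descending, columns along x ascending (the CSV layout);
    the grid is symmetric about (0, 0).  ``mask`` marks valid cells; invalid
    cells carry NaN heights.
    """

    spacing: float
    half_aperture: float
    heights: np.ndarray
    mask: np.ndarray
    surface_label: str = "anterior"

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        self.heights = np.asarray(self.heights, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.heights.shape != self.mask.shape:
            raise ValueError("heights and mask shapes differ")
        if self.surface_label not in ("anterior", "posterior"):
            raise ValueError("surface_label must be 'anterior' or 'posterior'")
        if not np.all(np.isfinite(self.heights[self.mask])):
            raise ValueError("non-finite height inside the validity mask")

    @property
    def x(self) -> np.ndarray:
        n = self.heights.shape[1]
        return (np.arange(n) - (n - 1) / 2.0) * self.spacing

    @property
    def y(self) -> np.ndarray:
        n = self.heights.shape[0]
        return ((n - 1) / 2.0 - np.arange(n)) * self.spacing

    def valid_points(self):
        """Flat arrays (x, y, z) of the valid samples."""
        xx, yy = np.meshgrid(self.x, self.y)
        m = self.mask & np.isfinite(self.heights)
        return xx[m], yy[m], self.heights[m]


def write_elevation_csv(grid: ElevationGrid, path) -> None:
    """Write the elevation-grid CSV dialect.

    Header lines carry spacing, half aperture and the surface label; the
    body is a dense height matrix in mm with NaN for invalid cells, rows in
    y-descending / columns in x-ascending order.  Finite values round-trip
    bit-identically (17 significant digits).
    """
    body = grid.heights.copy()
    body[~grid.mask] = np.nan
    with open(path, "w", encoding="ascii") as fh:
        fh.write(f"# spacing_mm={grid.spacing!r}\n")
        fh.write(f"# half_aperture_mm={grid.half_aperture!r}\n")
        fh.write(f"# surface={grid.surface_label}\n")
        for row in body:
            fh.write(
                ",".join("NaN" if not np.isfinite(v) else f"{v:.17g}" for v in row)
            )
            fh.write("\n")


def read_elevation_csv(path) -> ElevationGrid:
    """Read the elevation-grid CSV dialect written by :func:`write_elevation_csv`."""
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path, "r", encoding="ascii") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = value.strip()
            else:
                rows.append([float(v) for v in line.split(",")])
    try:
        spacing = float(meta["spacing_mm"])
        half_aperture = float(meta["half_aperture_mm"])
        label = meta["surface"]
    except KeyError as exc:  # pragma: no cover - malformed input path
        raise ValueError(f"missing elevation CSV header line: {exc}") from exc
    heights = np.asarray(rows, dtype=float)
    mask = np.isfinite(heights)
    return ElevationGrid(spacing, half_aperture, heights, mask, label)


# ---------------------------------------------------------------------------
# Polynomial smoothing fits


def _poly_terms(order: int) -> list[tuple[int, int]]:
    # all bivariate monomials with total degree <= order, graded order
    return [
        (total - j, j) for total in range(order + 1) for j in range(total + 1)
    ]


@dataclass
class SmoothSurface:
    """Smooth polynomial surface fitted to an elevation grid.

    Heights and gradients are evaluated from a bivariate polynomial of
    bounded total degree over coordinates scaled to the fitted aperture;
    this spans the same function space as disc (Zernike-style) polynomials
    through the same radial order.  Extrapolation beyond the fitted
    aperture is forbidden.
    """

    coeffs: np.ndarray
    terms: list[tuple[int, int]]
    aperture_radius: float
    rms_residual: float
    basis_order: int

    def _check_aperture(self, x, y):
        r2 = x * x + y * y
        if np.any(r2 > (self.aperture_radius * (1.0 + 1e-9)) ** 2):
            raise ApertureError(
                f"evaluation outside the fitted {self.aperture_radius} mm aperture"
            )

    def _powers(self, s, order):
        out = [np.ones_like(s)]
        for _ in range(order):
            out.append(out[-1] * s)
        return out

    def height(self, x, y):
        x, y = _as_float_arrays(x, y)
        self._check_aperture(x, y)
        a = self.aperture_radius
        xs, ys = x / a, y / a
        xp = self._powers(xs, self.basis_order)
        yp = self._powers(ys, self.basis_order)
        z = np.zeros_like(xs)
        for c, (i, j) in zip(self.coeffs, self.terms):
            z = z + c * xp[i] * yp[j]
        return float(z) if z.ndim == 0 else z

    def gradient(self, x, y):
        x, y = _as_float_arrays(x, y)
        self._check_aperture(x, y)
        a = self.aperture_radius
        xs, ys = x / a, y / a
        xp = self._powers(xs, self.basis_order)
        yp = self._powers(ys, self.basis_order)
        gx = np.zeros_like(xs)
        gy = np.zeros_like(ys)
        for c, (i, j) in zip(self.coeffs, self.terms):
            if i > 0:
                gx = gx + c * i * xp[i - 1] * yp[j]
            if j > 0:
                gy = gy + c * j * xp[i] * yp[j - 1]
        gx, gy = gx / a, gy / a
        if gx.ndim == 0:
            return float(gx), float(gy)
        return gx, gy

    def normal(self, x, y):
        gx, gy = self.gradient(x, y)
        return _normal_from_gradient(gx, gy)


def fit_smooth_surface(
    grid: ElevationGrid, basis_order: int = 8, fit_radius: float | None = None
) -> SmoothSurface:
    """Least-squares polynomial fit of an elevation grid.

    Parameters
    ----------
    grid
        Sampled heights with validity mask.
    basis_order
        Maximum total polynomial degree (default 8, the usual corneal
        topography choice).
    fit_radius
        Aperture radius in mm over which to fit; defaults to the smaller of
        the grid half-aperture and 4 mm (a central 8 mm zone).

    Returns the fitted surface with its RMS residual in mm.
    """
    if fit_radius is None:
        fit_radius = min(grid.half_aperture, 4.0)
    x, y, z = grid.valid_points()
    inside = x * x + y * y <= fit_radius**2 * (1.0 + 1e-12)
    x, y, z = x[inside], y[inside], z[inside]
    terms = _poly_terms(basis_order)
    if x.size < 2 * len(terms):
        raise FitError(
            f"{x.size} valid points is too few for a degree-{basis_order} fit"
        )
    xs, ys = x / fit_radius, y / fit_radius
    design = np.column_stack([xs**i * ys**j for (i, j) in terms])
    coeffs, _, rank, _ = np.linalg.lstsq(design, z, rcond=None)
    if rank < len(terms):
        raise FitError("rank-deficient design matrix in surface fit")
    resid = z - design @ coeffs
    rms = float(np.sqrt(np.mean(resid**2)))
    return SmoothSurface(coeffs, terms, fit_radius, rms, basis_order)


# ---------------------------------------------------------------------------
# Rigid rotations


@dataclass(frozen=True)
class RigidRotation:
    """Rotation Rx(alpha_x) @ Ry(alpha_y) about a pivot point.

    Two angles parameterise an axis direction; torsion about z is
    irrelevant to tilt.  The matrix is orthonormal with det +1.
    """

    alpha_x_deg: float
    alpha_y_deg: float
    pivot: tuple[float, float, float]
    matrix: np.ndarray = field(repr=False)

    def apply(self, points):
        """Rotate points (..., 3) about the pivot."""
        p = np.asarray(points, dtype=float)
        piv = np.asarray(self.pivot, dtype=float)
        return (p - piv) @ self.matrix.T + piv

    def apply_inverse(self, points):
        p = np.asarray(points, dtype=float)
        piv = np.asarray(self.pivot, dtype=float)
        return (p - piv) @ self.matrix + piv

    def apply_to_direction(self, direction):
        return np.asarray(direction, dtype=float) @ self.matrix.T

    def apply_inverse_to_direction(self, direction):
        return np.asarray(direction, dtype=float) @ self.matrix


def rotation_from_angles(
    alpha_x_deg: float,
    alpha_y_deg: float,
    pivot: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> RigidRotation:
    """Build the rotation Rx(alpha_x) @ Ry(alpha_y) about ``pivot``.

    Angles are in degrees and must lie in (-90, 90); zero angles give the
    identity.
    """
    for a in (alpha_x_deg, alpha_y_deg):
        if not -90.0 < a < 90.0:
            raise ValueError("rotation angles must lie in (-90, 90) degrees")
    ax, ay = math.radians(alpha_x_deg), math.radians(alpha_y_deg)
    ca, sa = math.cos(ax), math.sin(ax)
    cb, sb = math.cos(ay), math.sin(ay)
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]], dtype=float)
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]], dtype=float)
    return RigidRotation(alpha_x_deg, alpha_y_deg, tuple(pivot), rx @ ry)


def angle_between_axes(u, v) -> float:
    """3D angle between two axis directions, in degrees in [0, 180].

    Dot products slightly outside [-1, 1] from rounding are clamped; zero
    length inputs are rejected.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("zero-length axis vector")
    c = float(np.dot(u, v) / (nu * nv))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


# ---------------------------------------------------------------------------
# Rotated surface view


class RotatedSurface:
    """Height-field view of a rigidly rotated surface.

    A point p lies on the rotated surface iff q = R^T (p - pivot) + pivot
    lies on the base surface.  Heights are found by Newton iteration on z;
    gradients follow from the implicit function theorem; normals are the
    rotated base normals.
    """

    def __init__(self, base, rotation: RigidRotation):
        self.base = base
        self.rotation = rotation
        self._pivot = np.asarray(rotation.pivot, dtype=float)
        # dq/dz = R^T z_hat = third row of R
        self._m = rotation.matrix[2, :].copy()

    def _to_base(self, pts):
        return (pts - self._pivot) @ self.rotation.matrix + self._pivot

    def height(self, x, y):
        x, y = _as_float_arrays(x, y)
        scalar = x.ndim == 0
        x, y = np.atleast_1d(x), np.atleast_1d(y)
        z = np.atleast_1d(np.asarray(self.base.height(x, y), dtype=float)).copy()
        m0, m1, m2 = self._m
        for _ in range(60):
            q = self._to_base(np.stack([x, y, z], axis=-1))
            qx, qy, qz = q[..., 0], q[..., 1], q[..., 2]
            f = self.base.height(qx, qy) - qz
            if np.max(np.abs(f)) < 1e-13:
                break
            gx, gy = self.base.gradient(qx, qy)
            fp = gx * m0 + gy * m1 - m2
            z = z - f / fp
        else:  # pragma: no cover - defensive
            raise OutOfDomainError("rotated-surface height iteration failed")
        return float(z[0]) if scalar else z

    def gradient(self, x, y):
        x, y = _as_float_arrays(x, y)
        scalar = x.ndim == 0
        xv, yv = np.atleast_1d(x), np.atleast_1d(y)
        z = np.atleast_1d(np.asarray(self.height(xv, yv), dtype=float))
        q = self._to_base(np.stack([xv, yv, z], axis=-1))
        gx, gy = self.base.gradient(q[..., 0], q[..., 1])
        v = np.stack(
            [np.atleast_1d(gx), np.atleast_1d(gy), -np.ones_like(np.atleast_1d(gx))],
            axis=-1,
        )
        grad_f = v @ self.rotation.matrix.T  # R @ v for row vectors
        zx = -grad_f[..., 0] / grad_f[..., 2]
        zy = -grad_f[..., 1] / grad_f[..., 2]
        if scalar:
            return float(zx[0]), float(zy[0])
        return zx, zy

    def normal(self, x, y):
        gx, gy = self.gradient(x, y)
        return _normal_from_gradient(gx, gy)
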
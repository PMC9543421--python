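"""Snell-law ray tracing and corneal optical-axis (angle alpha) estimation.

The corneal optical axis is the path of light that traverses the anterior
and posterior corneal surfaces without net refraction.  Parallel rays are
directed toward the cornea along the instrument axis; the corneal model is
rotated in three dimensions inside a Levenberg-Marquardt loop until the
central ray exits undeviated.  The instrument axis stands in for the
visual (fixation) axis, so the 3D angle between the recovered optical axis
and +z is angle alpha, the measure of corneal tilt used throughout the
package.

A ray that exits parallel to the axis has an infinite focal length; to
keep the objective bounded and smooth the optimiser minimises the
transverse components of the exit-direction deviation instead, which
vanishes exactly where the focal length diverges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .exceptions import RayTraceError, TotalInternalReflectionError
from .geometry import (
    ElevationGrid,
    RigidRotation,
    RotatedSurface,
    angle_between_axes,
    fit_smooth_surface,
    rotation_from_angles,
)

__all__ = [
    "Ray",
    "CornealModel",
    "TiltResult",
    "TiltOptions",
    "refract",
    "intersect",
    "trace_through_cornea",
    "axial_crossing_distance",
    "central_ray_deviation",
    "rotate_model",
    "estimate_optical_axis",
]

_Z_HAT = np.array([0.0, 0.0, 1.0])

# Gullstrand refractive indices
N_AIR = 1.0
N_CORNEA = 1.376
N_AQUEOUS = 1.336


@dataclass(frozen=True)
class Ray:
    """A ray with an origin (mm) and a unit direction."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("ray direction must be unit length")
        object.__setattr__(self, "direction", d / n)

    def point(self, t: float) -> np.ndarray:
        return self.origin + t * self.direction


@dataclass(frozen=True)
class CornealModel:
    """Two refracting corneal surfaces with their media indices.

    The anterior surface separates air from stroma, the posterior surface
    stroma from aqueous humour.  Surfaces may be analytic conicoids,
    polynomial fits or rotated views of either.
    """

    anterior: object
    posterior: object
    n_air: float = N_AIR
    n_cornea: float = N_CORNEA
    n_aqueous: float = N_AQUEOUS

    def __post_init__(self):
        if min(self.n_air, self.n_cornea, self.n_aqueous) <= 0:
            raise ValueError("refractive indices must be positive")


@dataclass
class TiltResult:
    """Outcome of the optical-axis search."""

    optical_axis: np.ndarray
    angle_alpha_deg: float
    residual_deviation: float
    iterations: int
    converged: bool
    fitted_rotation: RigidRotation

    def to_json_dict(self) -> dict:
        return {
            "angle_alpha_deg": self.angle_alpha_deg,
            "optical_axis": [float(v) for v in self.optical_axis],
            "residual_deviation": self.residual_deviation,
            "iterations": self.iterations,
            "converged": self.converged,
            "fitted_alpha_x_deg": self.fitted_rotation.alpha_x_deg,
            "fitted_alpha_y_deg": self.fitted_rotation.alpha_y_deg,
        }


def refract(direction, normal, n1: float, n2: float):
    """Vector-form Snell refraction of a unit direction at a unit normal.

    The normal may point to either side; it is flipped internally so the
    incidence cosine is positive.  Raises TotalInternalReflectionError when
    no real transmitted ray exists.
    """
    d = np.asarray(direction, dtype=float)
    n = np.asarray(normal, dtype=float)
    d = d / np.linalg.norm(d)
    n = n / np.linalg.norm(n)
    cos_i = -float(np.dot(d, n))
    if cos_i < 0.0:
        n = -n
        cos_i = -cos_i
    mu = n1 / n2
    sin2_t = mu * mu * max(0.0, 1.0 - cos_i * cos_i)
    if sin2_t > 1.0:
        raise TotalInternalReflectionError(
            f"total internal reflection (n1={n1}, n2={n2}, cos_i={cos_i:.6f})"
        )
    cos_t = np.sqrt(1.0 - sin2_t)
    t = mu * d + (mu * cos_i - cos_t) * n
    return t / np.linalg.norm(t)


def intersect(ray: Ray, surface, t_guess: float | None = None) -> np.ndarray:
    """First intersection of a ray with a height-field surface.

    Newton iteration on the ray parameter drives the height mismatch below
    1e-12 mm, with a bisection fallback.  Raises RayTraceError when the ray
    misses the surface or leaves its aperture.
    """
    o, d = ray.origin, ray.direction
    try:
        if t_guess is None:
            z_ref = surface.height(0.0, 0.0)
            if abs(d[2]) > 1e-9:
                t = (z_ref - o[2]) / d[2]
            else:
                t = 0.0
        else:
            t = float(t_guess)
        for _ in range(100):
            p = o + t * d
            f = surface.height(p[0], p[1]) - p[2]
            if abs(f) < 1e-12:
                if t <= 1e-12:
                    raise RayTraceError("intersection behind the ray origin")
                return p
            gx, gy = surface.gradient(p[0], p[1])
            fp = gx * d[0] + gy * d[1] - d[2]
            if abs(fp) < 1e-15:
                raise RayTraceError("ray grazes the surface (degenerate slope)")
            t = t - f / fp
    except RayTraceError:
        raise
    except Exception as exc:
        raise RayTraceError(f"no intersection within the surface aperture: {exc}")
    raise RayTraceError("intersection iteration did not converge")


def trace_through_cornea(model: CornealModel, ray: Ray) -> Ray:
    """Trace a ray from air through both corneal surfaces.

    Applies two Snell refractions (air -> stroma at the anterior surface,
    stroma -> aqueous at the posterior) and returns the exit ray whose
    origin lies on the posterior surface.
    """
    p1 = intersect(ray, model.anterior)
    n1 = model.anterior.normal(p1[0], p1[1])
    d1 = refract(ray.direction, n1, model.n_air, model.n_cornea)
    inner = Ray(p1, d1)
    p2 = intersect(inner, model.posterior, t_guess=0.55)
    n2 = model.posterior.normal(p2[0], p2[1])
    d2 = refract(d1, n2, model.n_cornea, model.n_aqueous)
    return Ray(p2, d2)


def axial_crossing_distance(exit_ray: Ray, axis_ray: Ray) -> float:
    """Distance along the axis from the exit point to the closest approach.

    Measured as the projection onto the axis direction (the z-distance
    when the axis is the instrument z axis), which makes the value
    invariant under rigid rotation of the whole scene.  Returns +inf when
    the two directions are parallel within 1e-12: the exit ray never
    crosses the axis -- an infinite focal length.
    """
    d1, d2 = exit_ray.direction, axis_ray.direction
    cross = np.cross(d1, d2)
    denom = float(np.dot(cross, cross))
    if denom < 1e-24:
        return float("inf")
    w = axis_ray.origin - exit_ray.origin
    t1 = float(np.dot(np.cross(d2, cross), w)) / denom
    t2 = float(np.dot(np.cross(d1, cross), w)) / denom
    mid = 0.5 * (exit_ray.point(t1) + axis_ray.point(t2))
    return float(np.dot(mid - exit_ray.origin, d2))


def rotate_model(model: CornealModel, rotation: RigidRotation) -> CornealModel:
    """Rigidly rotate both corneal surfaces about the rotation pivot."""
    return CornealModel(
        RotatedSurface(model.anterior, rotation),
        RotatedSurface(model.posterior, rotation),
        model.n_air,
        model.n_cornea,
        model.n_aqueous,
    )


def central_ray_deviation(model: CornealModel, rotation: RigidRotation) -> np.ndarray:
    """Transverse exit-direction deviation of the central ray.

    Rotates the corneal model, traces the ray entering along the
    instrument axis through (0, 0), and returns the (x, y) components of
    (exit direction - z_hat).  A zero residual means the central ray
    passes undeviated, i.e. its focal length is infinite: this is the
    least-squares residual of the optical-axis search.
    """
    rotated = rotate_model(model, rotation)
    central = Ray(np.array([0.0, 0.0, -10.0]), _Z_HAT)
    exit_ray = trace_through_cornea(rotated, central)
    return exit_ray.direction[:2].copy()


@dataclass(frozen=True)
class TiltOptions:
    """Settings for the optical-axis search."""

    basis_order: int = 8
    fit_radius: float | None = None
    max_iterations: int = 200
    diff_step_deg: float = 6e-3  # finite-difference step, ~1e-4 rad
    residual_tol: float = 1e-8


def estimate_optical_axis(
    anterior: ElevationGrid,
    posterior: ElevationGrid,
    options: TiltOptions | None = None,
) -> TiltResult:
    """Estimate the corneal optical axis and angle alpha from elevation maps.

    Fits smooth polynomial surfaces to both grids, then runs a
    Levenberg-Marquardt search over the two tilt angles (about x then y,
    pivoting at the anterior apex) that null the central-ray deviation.
    The optical axis is the inverse of the fitted rotation applied to
    z_hat, expressed in the instrument frame; angle alpha is its 3D angle
    to the instrument (visual) axis.

    Non-convergence is reported through ``converged=False`` rather than an
    exception; the caller decides how to proceed.
    """
    opts = options or TiltOptions()
    ant = fit_smooth_surface(anterior, opts.basis_order, opts.fit_radius)
    post = fit_smooth_surface(posterior, opts.basis_order, opts.fit_radius)
    model = CornealModel(ant, post)

    def residual(params):
        rot = rotation_from_angles(params[0], params[1])
        return central_ray_deviation(model, rot)

    sol = least_squares(
        residual,
        x0=[0.0, 0.0],
        method="lm",
        diff_step=opts.diff_step_deg,
        xtol=1e-13,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=3 * opts.max_iterations,
    )
    rot = rotation_from_angles(float(sol.x[0]), float(sol.x[1]))
    axis = rot.apply_inverse_to_direction(_Z_HAT)
    axis = axis / np.linalg.norm(axis)
    resid = float(np.linalg.norm(sol.fun))
    converged = bool(sol.status > 0 and resid < opts.residual_tol)
    return TiltResult(
        optical_axis=axis,
        angle_alpha_deg=angle_between_axes(axis, _Z_HAT),
        residual_deviation=resid,
        iterations=int(sol.nfev),
        converged=converged,
        fitted_rotation=rot,
    )
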
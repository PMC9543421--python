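"""Synthetic corneas and cohorts with known ground truth.

Two generators live here.  ``make_cornea`` builds a tilted biconic cornea,
samples both surfaces onto elevation grids and adds measurement noise, so
the tilt estimator can be scored against a known rotation.  The cohort
generator draws (age, tilt, densitometry) triples from a linear-Gaussian
structural model calibrated so that the population means, SDs and pairwise
correlations equal a set of published cohort statistics; zonal and layer
densitometry values are coherent affine transforms of the overall value.

The default calibration targets are: age 42.8 +/- 20.0 years, corneal tilt
5.8 +/- 1.8 degrees, overall densitometry 17 +/- 7 GSU, and correlations
r(age, tilt) = 0.50, r(age, densitometry) = 0.91,
r(tilt, densitometry) = 0.45, with an 86-subject default cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .densitometry import validate_gsu
from .geometry import (
    ConicoidSurface,
    ElevationGrid,
    RigidRotation,
    RotatedSurface,
    rotation_from_angles,
)

__all__ = [
    "CorneaSpec",
    "CohortModel",
    "CohortRecord",
    "COHORT_COLUMNS",
    "TABLE_ZONE_STATS",
    "TABLE_LAYER_STATS",
    "make_cornea",
    "calibrate_cohort_model",
    "implied_correlations",
    "simulate_cohort",
]

# published per-zone and per-layer mean +/- SD used as default zonal targets
TABLE_ZONE_STATS: dict[str, tuple[float, float]] = {
    "0_2": (15.0, 4.0),
    "2_6": (14.0, 4.0),
    "6_10": (19.0, 9.0),
    "10_12": (26.0, 11.0),
}
TABLE_LAYER_STATS: dict[str, tuple[float, float]] = {
    "anterior": (23.0, 9.0),
    "central": (16.0, 6.0),
    "posterior": (13.0, 6.0),
}

COHORT_COLUMNS = [
    "id",
    "age_years",
    "tilt_deg",
    "gsu_overall",
    "gsu_zone_0_2",
    "gsu_zone_2_6",
    "gsu_zone_6_10",
    "gsu_zone_10_12",
    "gsu_layer_anterior",
    "gsu_layer_central",
    "gsu_layer_posterior",
]


# ---------------------------------------------------------------------------
# Synthetic corneas


@dataclass(frozen=True)
class CorneaSpec:
    """Recipe for one synthetic cornea.

    Radii/asphericities describe the untilted biconic surfaces; the true
    tilt is applied as a rotation about the anterior apex before sampling.
    Elevation noise is independent Gaussian per grid point, in micrometres.
    """

    anterior_radius: float = 7.8
    anterior_q: float = -0.25
    posterior_radius: float = 6.5
    posterior_q: float = -0.25
    central_thickness: float = 0.55
    tilt_x_deg: float = 0.0
    tilt_y_deg: float = 0.0
    noise_sd_um: float = 0.0
    spacing: float = 0.2
    half_aperture: float = 4.5
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd_um < 0:
            raise ValueError("noise SD must be non-negative")
        if self.spacing <= 0 or self.half_aperture <= 0:
            raise ValueError("grid spacing and aperture must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def _sample_surface(
    surface, rotation: RigidRotation, spec: CorneaSpec, rng, label: str
) -> ElevationGrid:
    n = 2 * int(round(spec.half_aperture / spec.spacing)) + 1
    coords = (np.arange(n) - (n - 1) / 2.0) * spec.spacing
    xx, yy = np.meshgrid(coords, -coords)  # rows y-descending
    mask = xx**2 + yy**2 <= spec.half_aperture**2 * (1 + 1e-12)
    domain = surface.domain_radius()
    if np.isfinite(domain) and spec.half_aperture > 0.9 * domain:
        raise ValueError(
            f"aperture {spec.half_aperture} mm exceeds the sagitta domain "
            f"({domain:.2f} mm) of the {label} surface"
        )
    rotated = RotatedSurface(surface, rotation)
    heights = np.full((n, n), np.nan)
    heights[mask] = rotated.height(xx[mask], yy[mask])
    if spec.noise_sd_um > 0:
        heights[mask] += rng.normal(0.0, spec.noise_sd_um * 1e-3, mask.sum())
    return ElevationGrid(spec.spacing, spec.half_aperture, heights, mask, label)


def make_cornea(spec: CorneaSpec):
    """Generate (anterior grid, posterior grid, true rotation) for a spec.

    Both conicoid surfaces are rotated by the true tilt about the anterior
    apex, sampled on the regular grid, and perturbed by independent
    Gaussian elevation noise.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    rotation = rotation_from_angles(spec.tilt_x_deg, spec.tilt_y_deg)
    anterior = ConicoidSurface.symmetric(spec.anterior_radius, spec.anterior_q)
    posterior = ConicoidSurface.symmetric(
        spec.posterior_radius, spec.posterior_q, apex_z=spec.central_thickness
    )
    ant_grid = _sample_surface(anterior, rotation, spec, rng, "anterior")
    post_grid = _sample_surface(posterior, rotation, spec, rng, "posterior")
    return ant_grid, post_grid, rotation


# ---------------------------------------------------------------------------
# Cohort model


@dataclass
class CohortModel:
    """Linear-Gaussian structural model age -> tilt -> densitometry.

    Standardised structural equations::

        tilt_z = r_at * age_z + e_t,            sd(e_t) = sqrt(1 - r_at^2)
        dens_z = b_age * age_z + b_tilt * tilt_z + e_d

    with ``b_age``/``b_tilt`` solving the two-predictor normal equations
    for the target correlation matrix, so the implied population
    correlations equal the targets exactly.  Raw scales are restored with
    the target means and SDs.  Zone/layer densitometry values share a
    loading on the overall z-score plus independent noise matched to the
    per-region SDs.
    """

    age_mean: float
    age_sd: float
    tilt_mean: float
    tilt_sd: float
    dens_mean: float
    dens_sd: float
    r_age_tilt: float
    r_age_dens: float
    r_tilt_dens: float
    beta_age: float
    beta_tilt: float
    resid_sd_tilt: float
    resid_sd_dens: float
    zone_stats: dict = field(default_factory=lambda: dict(TABLE_ZONE_STATS))
    layer_stats: dict = field(default_factory=lambda: dict(TABLE_LAYER_STATS))
    zone_loading: float = 0.9
    age_bounds: tuple[float, float] | None = (0.0, 100.0)
    # latent (pre-truncation) Gaussian parameters solved so the truncated
    # age distribution has exactly the target mean and SD
    age_latent_mean: float = 42.8
    age_latent_sd: float = 20.0


def calibrate_cohort_model(
    age_mean: float = 42.8,
    age_sd: float = 20.0,
    tilt_mean: float = 5.8,
    tilt_sd: float = 1.8,
    dens_mean: float = 17.0,
    dens_sd: float = 7.0,
    r_age_tilt: float = 0.50,
    r_age_dens: float = 0.91,
    r_tilt_dens: float = 0.45,
    zone_stats: dict | None = None,
    layer_stats: dict | None = None,
    zone_loading: float = 0.9,
    age_bounds: tuple[float, float] | None = (0.0, 100.0),
) -> CohortModel:
    """Solve the structural coefficients reproducing the target moments.

    The target correlation matrix must be positive definite.  The
    standardised densitometry coefficients solve the 2x2 normal
    equations::

        b_age  = (r_ad - r_td * r_at) / (1 - r_at^2)
        b_tilt = (r_td - r_ad * r_at) / (1 - r_at^2)

    Residual SDs follow from unit total variance.

    Ages are truncated Gaussian with plausibility bounds ``age_bounds``
    (default 0-100 years); the latent pre-truncation parameters are solved
    numerically so the truncated distribution has exactly the target mean
    and SD.  Bounds too tight to support the target SD (a truncated normal
    cannot exceed the uniform SD, (hi - lo)/sqrt(12)) are rejected.
    """
    corr = np.array(
        [
            [1.0, r_age_tilt, r_age_dens],
            [r_age_tilt, 1.0, r_tilt_dens],
            [r_age_dens, r_tilt_dens, 1.0],
        ]
    )
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() <= 1e-12:
        raise ValueError(
            f"target correlation matrix is not positive definite "
            f"(min eigenvalue {eigvals.min():.3e})"
        )
    denom = 1.0 - r_age_tilt**2
    beta_age = (r_age_dens - r_tilt_dens * r_age_tilt) / denom
    beta_tilt = (r_tilt_dens - r_age_dens * r_age_tilt) / denom
    var_t = 1.0 - r_age_tilt**2
    var_d = 1.0 - (beta_age * r_age_dens + beta_tilt * r_tilt_dens)
    if var_t <= 0 or var_d <= 0:
        raise ValueError("non-positive residual variance implied by targets")
    latent_mean, latent_sd = age_mean, age_sd
    if age_bounds is not None:
        latent_mean, latent_sd = _solve_truncated_latent(
            age_mean, age_sd, age_bounds
        )
    return CohortModel(
        age_mean=age_mean,
        age_sd=age_sd,
        tilt_mean=tilt_mean,
        tilt_sd=tilt_sd,
        dens_mean=dens_mean,
        dens_sd=dens_sd,
        r_age_tilt=r_age_tilt,
        r_age_dens=r_age_dens,
        r_tilt_dens=r_tilt_dens,
        beta_age=beta_age,
        beta_tilt=beta_tilt,
        resid_sd_tilt=float(np.sqrt(var_t)),
        resid_sd_dens=float(np.sqrt(var_d)),
        zone_stats=dict(zone_stats or TABLE_ZONE_STATS),
        layer_stats=dict(layer_stats or TABLE_LAYER_STATS),
        zone_loading=zone_loading,
        age_bounds=age_bounds,
        age_latent_mean=latent_mean,
        age_latent_sd=latent_sd,
    )


def _solve_truncated_latent(
    target_mean: float, target_sd: float, bounds: tuple[float, float]
) -> tuple[float, float]:
    """Latent Gaussian (mean, sd) whose truncation matches target moments."""
    from scipy import optimize, stats

    lo, hi = bounds
    if not lo < target_mean < hi:
        raise ValueError("age bounds must contain the target mean")
    if target_sd >= (hi - lo) / np.sqrt(12.0):
        raise ValueError(
            f"target SD {target_sd} is unattainable within bounds {bounds}: "
            f"a truncated normal cannot exceed SD {(hi - lo) / np.sqrt(12.0):.2f}"
        )

    def resid(p):
        mu, sig = p
        a, b = (lo - mu) / sig, (hi - mu) / sig
        mean, var = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [mean - target_mean, np.sqrt(var) - target_sd]

    sol = optimize.root(resid, [target_mean, target_sd * 1.05])
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError("latent age-parameter solve failed")
    return float(sol.x[0]), float(sol.x[1])


def implied_correlations(model: CohortModel) -> tuple[float, float, float]:
    """Closed-form population correlations implied by the structural model.

    Returns (r_age_tilt, r_age_dens, r_tilt_dens); by construction these
    equal the calibration targets.
    """
    r_at = model.r_age_tilt
    r_ad = model.beta_age + model.beta_tilt * r_at
    r_td = model.beta_age * r_at + model.beta_tilt
    return r_at, r_ad, r_td


@dataclass(frozen=True)
class CohortRecord:
    """One subject's age, tilt and regional densitometry (GSU)."""

    id: str
    age_years: float
    tilt_deg: float
    gsu_overall: float
    gsu_zone_0_2: float
    gsu_zone_2_6: float
    gsu_zone_6_10: float
    gsu_zone_10_12: float
    gsu_layer_anterior: float
    gsu_layer_central: float
    gsu_layer_posterior: float

    @classmethod
    def from_row(cls, row) -> "CohortRecord":
        return cls(**{k: row[k] for k in COHORT_COLUMNS})


def simulate_cohort(model: CohortModel, n: int = 86, seed: int = 0) -> pd.DataFrame:
    """Draw a synthetic cohort from the calibrated structural model.

    Ages are Gaussian (optionally truncated by resampling when the model
    sets ``age_bounds``); tilt and densitometry follow the structural
    equations.  Draws that violate physical ranges (negative tilt, GSU
    outside [0, 100]) are redrawn, not clamped, to preserve moments
    approximately; redraw counts are recorded in ``frame.attrs['redraws']``.
    Deterministic for a given seed.
    """
    if n < 4:
        raise ValueError("cohort size must be at least 4")
    rng = np.random.default_rng(seed)
    redraw_log: dict[str, int] = {}

    def redraw(make_values, eps, invalid, label):
        """Redraw Gaussian innovations whose outcomes fall out of range."""
        count = 0
        for _ in range(1000):
            values = make_values(eps)
            bad = invalid(values)
            if not bad.any():
                redraw_log[label] = count
                return values
            count += int(bad.sum())
            eps[bad] = rng.normal(0.0, 1.0, int(bad.sum()))
        raise RuntimeError(f"redraw loop for '{label}' failed to converge")

    age = model.age_latent_mean + model.age_latent_sd * rng.normal(0.0, 1.0, n)
    if model.age_bounds is not None:
        lo, hi = model.age_bounds
        total = 0
        for _ in range(1000):
            bad = (age < lo) | (age > hi)
            if not bad.any():
                break
            total += int(bad.sum())
            age[bad] = model.age_latent_mean + model.age_latent_sd * rng.normal(
                0.0, 1.0, int(bad.sum())
            )
        redraw_log["age"] = total
    # standardise by the target moments, which the truncated distribution
    # matches exactly by construction of the latent parameters
    age_z = (age - model.age_mean) / model.age_sd

    eps_t = rng.normal(0.0, 1.0, n)
    tilt = redraw(
        lambda e: model.tilt_mean
        + model.tilt_sd * (model.r_age_tilt * age_z + model.resid_sd_tilt * e),
        eps_t,
        lambda v: v < 0,
        "tilt",
    )
    tilt_z = (tilt - model.tilt_mean) / model.tilt_sd

    eps_d = rng.normal(0.0, 1.0, n)
    dens = redraw(
        lambda e: model.dens_mean
        + model.dens_sd
        * (model.beta_age * age_z + model.beta_tilt * tilt_z + model.resid_sd_dens * e),
        eps_d,
        lambda v: (v < 0) | (v > 100),
        "gsu_overall",
    )
    dens_z = (dens - model.dens_mean) / model.dens_sd

    lam = model.zone_loading
    noise_scale = np.sqrt(1.0 - lam**2)
    data = {
        "id": [f"S{i:05d}" for i in range(n)],
        "age_years": age,
        "tilt_deg": tilt,
        "gsu_overall": dens,
    }
    regions = [(f"gsu_zone_{k}", v) for k, v in model.zone_stats.items()]
    regions += [(f"gsu_layer_{k}", v) for k, v in model.layer_stats.items()]
    for col, (mean, sd) in regions:
        eps = rng.normal(0.0, 1.0, n)
        data[col] = redraw(
            lambda e, mean=mean, sd=sd: mean + sd * (lam * dens_z + noise_scale * e),
            eps,
            lambda v: (v < 0) | (v > 100),
            col,
        )

    frame = pd.DataFrame(data, columns=COHORT_COLUMNS)
    validate_gsu(frame[[c for c in COHORT_COLUMNS if c.startswith("gsu")]].to_numpy())
    frame.attrs["redraws"] = redraw_log
    frame.attrs["seed"] = seed
    return frame
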
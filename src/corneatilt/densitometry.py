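"""Regional Scheimpflug densitometry summaries.

Corneal backscatter is expressed in standardised greyscale units (GSU),
from 0 (maximum transparency) to 100 (minimum transparency).  The regional
assessment averages a densitometry volume over four concentric zones --
the central 2 mm disc and the 2-6, 6-10 and 10-12 mm annuli (by diameter)
-- and over three depth layers: the anterior 120 um, the posterior 60 um
and the central remainder, plus the full corneal depth.

The device's own aggregation weighting is proprietary; this module uses
volume-weighted means throughout and makes no claim of equality with
device output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import GsuValidationError

__all__ = [
    "DensitometryVolume",
    "RegionalDensitometry",
    "validate_gsu",
    "regional_summary",
    "ZONE_BOUNDS_MM",
    "ANTERIOR_LAYER_UM",
    "POSTERIOR_LAYER_UM",
]

# zone radial bounds in mm (zones are quoted by diameter: 0-2, 2-6, 6-10, 10-12)
ZONE_BOUNDS_MM: dict[str, tuple[float, float]] = {
    "0-2 mm": (0.0, 1.0),
    "2-6 mm": (1.0, 3.0),
    "6-10 mm": (3.0, 5.0),
    "10-12 mm": (5.0, 6.0),
}
ANTERIOR_LAYER_UM = 120.0
POSTERIOR_LAYER_UM = 60.0

_ZONES = list(ZONE_BOUNDS_MM)
_LAYERS = ["anterior", "central", "posterior", "total"]


def validate_gsu(values):
    """Validate GSU values against the standardised [0, 100] scale.

    Returns the values as a float array.  Out-of-range or non-finite cells
    are rejected with an error listing the offending indices; nothing is
    silently clamped.
    """
    arr = np.asarray(values, dtype=float)
    bad = ~np.isfinite(arr) | (arr < 0.0) | (arr > 100.0)
    if np.any(bad):
        idx = np.argwhere(bad)[:10]
        cells = [tuple(int(v) for v in i) for i in idx]
        raise GsuValidationError(
            f"{int(bad.sum())} GSU value(s) outside [0, 100]; "
            f"first offending cells: {cells}"
        )
    return arr


@dataclass
class DensitometryVolume:
    """GSU samples on a cylindrical (radius, azimuth, depth-fraction) grid.

    ``values`` has shape (n_r, n_azimuth, n_depth); ``r_edges`` spans
    [0, 6] mm, ``depth_edges`` spans [0, 1] as a fraction of the corneal
    thickness, and azimuth cells are uniform.  ``thickness_um`` carries the
    physical depth metadata needed to place the anterior/posterior layers.
    """

    values: np.ndarray
    r_edges: np.ndarray
    depth_edges: np.ndarray
    thickness_um: float

    def __post_init__(self):
        self.values = validate_gsu(self.values)
        self.r_edges = np.asarray(self.r_edges, dtype=float)
        self.depth_edges = np.asarray(self.depth_edges, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be 3D (radius, azimuth, depth)")
        if self.r_edges.size != self.values.shape[0] + 1:
            raise ValueError("r_edges length must be n_r + 1")
        if self.depth_edges.size != self.values.shape[2] + 1:
            raise ValueError("depth_edges length must be n_depth + 1")
        for e, lo, hi in ((self.r_edges, 0.0, 6.0), (self.depth_edges, 0.0, 1.0)):
            if np.any(np.diff(e) <= 0) or abs(e[0] - lo) > 1e-12 or abs(e[-1] - hi) > 1e-12:
                raise ValueError("cell edges must increase and span the full extent")
        if self.thickness_um <= 0:
            raise ValueError("corneal thickness must be positive")

    # -- constructors ------------------------------------------------------

    @classmethod
    def constant(
        cls, value: float, thickness_um: float = 550.0, n_r: int = 12,
        n_azimuth: int = 8, n_depth: int = 10,
    ) -> "DensitometryVolume":
        """Uniform volume at a single GSU value."""
        return cls(
            np.full((n_r, n_azimuth, n_depth), float(value)),
            np.linspace(0.0, 6.0, n_r + 1),
            np.linspace(0.0, 1.0, n_depth + 1),
            thickness_um,
        )

    @classmethod
    def from_zone_values(
        cls, zone_values, thickness_um: float = 550.0, n_azimuth: int = 8
    ) -> "DensitometryVolume":
        """Volume that is piecewise constant over the four concentric zones."""
        vals = np.asarray(zone_values, dtype=float)
        if vals.shape != (4,):
            raise ValueError("expected one value per zone (4 values)")
        edges = np.array([0.0, 1.0, 3.0, 5.0, 6.0])
        body = np.repeat(vals[:, None, None], n_azimuth, axis=1)
        body = np.repeat(body, 2, axis=2)
        return cls(body, edges, np.linspace(0.0, 1.0, 3), thickness_um)

    @classmethod
    def from_layer_values(
        cls, layer_values, thickness_um: float = 550.0, n_azimuth: int = 8
    ) -> "DensitometryVolume":
        """Volume piecewise constant over anterior/central/posterior layers."""
        vals = np.asarray(layer_values, dtype=float)
        if vals.shape != (3,):
            raise ValueError("expected one value per layer (3 values)")
        f_ant = ANTERIOR_LAYER_UM / thickness_um
        f_post = 1.0 - POSTERIOR_LAYER_UM / thickness_um
        edges = np.array([0.0, f_ant, f_post, 1.0])
        body = np.broadcast_to(vals[None, None, :], (6, n_azimuth, 3)).copy()
        return cls(body, np.linspace(0.0, 6.0, 7), edges, thickness_um)

    def rotated(self, steps: int) -> "DensitometryVolume":
        """Azimuthally rotated copy (cyclic shift of the azimuth cells)."""
        return DensitometryVolume(
            np.roll(self.values, steps, axis=1),
            self.r_edges.copy(),
            self.depth_edges.copy(),
            self.thickness_um,
        )


@dataclass
class RegionalDensitometry:
    """Zone-by-layer mean GSU table plus the overall mean.

    ``table`` is indexed by zone (rows) and layer (columns); the ``total``
    column is the depth-weighted mean per zone, ``layer_means`` are the
    full-disc means per layer, and ``overall`` is the volume-weighted mean
    of the whole 12 mm disc.
    """

    table: pd.DataFrame
    layer_means: dict[str, float]
    overall: float

    @property
    def zone_means(self) -> dict[str, float]:
        return {z: float(self.table.loc[z, "total"]) for z in _ZONES}

    def to_csv(self, path) -> None:
        """Serialise the standard regional summary rows to CSV."""
        rows = [
            ("Anterior", self.layer_means["anterior"]),
            ("Central", self.layer_means["central"]),
            ("Posterior", self.layer_means["posterior"]),
            ("0-2 mm", self.zone_means["0-2 mm"]),
            ("2-6 mm", self.zone_means["2-6 mm"]),
            ("6-10 mm", self.zone_means["6-10 mm"]),
            ("10-12 mm", self.zone_means["10-12 mm"]),
            ("Overall", self.overall),
        ]
        pd.DataFrame(rows, columns=["region", "mean_gsu"]).to_csv(path, index=False)


def _interval_overlap(lo, hi, a, b):
    return max(0.0, min(hi, b) - max(lo, a))


def regional_summary(volume: DensitometryVolume) -> RegionalDensitometry:
    """Aggregate a densitometry volume into the regional zone/layer table.

    Layer boundaries sit 120 um from the anterior surface and 60 um from
    the posterior surface, so the corneal thickness must exceed 180 um.
    Cell weights are physical volumes (annular area times depth extent);
    cells straddling a zone or layer boundary contribute their exact
    geometric overlap, so piecewise-constant volumes are summarised
    exactly.
    """
    t = volume.thickness_um
    if t <= ANTERIOR_LAYER_UM + POSTERIOR_LAYER_UM:
        raise ValueError(
            f"corneal thickness {t} um leaves no central layer "
            f"(needs > {ANTERIOR_LAYER_UM + POSTERIOR_LAYER_UM} um)"
        )
    layer_bounds_um = {
        "anterior": (0.0, ANTERIOR_LAYER_UM),
        "central": (ANTERIOR_LAYER_UM, t - POSTERIOR_LAYER_UM),
        "posterior": (t - POSTERIOR_LAYER_UM, t),
        "total": (0.0, t),
    }
    r_lo, r_hi = volume.r_edges[:-1], volume.r_edges[1:]
    d_lo_um, d_hi_um = volume.depth_edges[:-1] * t, volume.depth_edges[1:] * t

    # radial cell <-> zone overlap, as annular area (pi and the uniform
    # azimuth share cancel in every weighted mean)
    zone_area = {
        z: np.array(
            [
                max(0.0, min(hi, zb)**2 - max(lo, za)**2)
                if min(hi, zb) > max(lo, za)
                else 0.0
                for lo, hi in zip(r_lo, r_hi)
            ]
        )
        for z, (za, zb) in ZONE_BOUNDS_MM.items()
    }
    layer_depth = {
        lay: np.array(
            [_interval_overlap(lo, hi, a, b) for lo, hi in zip(d_lo_um, d_hi_um)]
        )
        for lay, (a, b) in layer_bounds_um.items()
    }

    def weighted_mean(area, depth):
        w = area[:, None, None] * np.ones((1, volume.values.shape[1], 1)) * depth[None, None, :]
        total_w = w.sum()
        return float((w * volume.values).sum() / total_w)

    table = pd.DataFrame(
        [
            [weighted_mean(zone_area[z], layer_depth[lay]) for lay in _LAYERS]
            for z in _ZONES
        ],
        index=_ZONES,
        columns=_LAYERS,
    )
    full_area = r_hi**2 - r_lo**2
    layer_means = {
        lay: weighted_mean(full_area, layer_depth[lay]) for lay in _LAYERS[:3]
    }
    overall = weighted_mean(full_area, layer_depth["total"])
    return RegionalDensitometry(table=table, layer_means=layer_means, overall=overall)
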
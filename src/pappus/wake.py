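"""Wake statistics from gridded PIV velocity fields behind a pappus.

The separated vortex ring behind a porous pappus shows up in a 2-D
(r = spanwise, z = streamwise) velocity field as a region of reversed
streamwise flow (negative u_z) downstream of the pappus centre.  This
module reproduces the post-processing chain applied to such fields:

1. mask noisy rows (robust outlier rule; the first image row is always
   removed) and keep the contiguous z-window around the pappus with at
   most one consecutive noisy row,
2. restrict the r extent to the triangular pappus silhouette
   (half-width L sin(tau/2)),
3. locate the minimum of u_z along the centre column (the recirculation
   core, reported as z_p / D with D the dry pappus diameter) and the
   nominal vortex length -- the downstream distance at which u_z recovers
   to 0.02 m/s, found by linear interpolation,
4. regress z_p / D on pappus angle across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "VelocityField",
    "VortexMetrics",
    "mask_noisy_rows",
    "restrict_to_pappus_width",
    "locate_min_uz",
    "nominal_vortex_length",
    "regress_zp_vs_angle",
    "HAIR_LENGTH",
]

HAIR_LENGTH = 7.41e-3  # m, pappus hair length defining the silhouette width
UZ_RECOVERY_THRESHOLD = 0.02  # m/s


@dataclass
class VelocityField:
    """Gridded 2-D wake velocity field with pappus metadata.

    ``u_r`` and ``u_z`` are (nz, nr) arrays on the rectangular grid formed
    by ``r_coords`` x ``z_coords``; z increases downstream.  ``masked_rows``
    holds indices of rows excluded from analysis; ``row_window`` the
    retained contiguous z-range (inclusive) once masking has run.
    """

    r_coords: np.ndarray
    z_coords: np.ndarray
    u_r: np.ndarray
    u_z: np.ndarray
    pappus_center: tuple[float, float]  # (r, z), m
    pappus_angle: float  # degrees
    dry_diameter: float  # m, for nondimensionalisation
    hair_length: float = HAIR_LENGTH
    masked_rows: list = field(default_factory=list)
    row_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.r_coords = np.asarray(self.r_coords, dtype=float)
        self.z_coords = np.asarray(self.z_coords, dtype=float)
        self.u_r = np.asarray(self.u_r, dtype=float)
        self.u_z = np.asarray(self.u_z, dtype=float)
        shape = (self.z_coords.size, self.r_coords.size)
        if self.u_z.shape != shape or self.u_r.shape != shape:
            raise ValueError("velocity arrays must be shaped (nz, nr)")
        for c in (self.r_coords, self.z_coords):
            if c.size > 1 and not (np.all(np.diff(c) > 0) or np.all(np.diff(c) < 0)):
                raise ValueError("grid coordinates must be monotone")

    @property
    def center_col(self) -> int:
        return int(np.argmin(np.abs(self.r_coords - self.pappus_center[0])))

    @property
    def center_row(self) -> int:
        return int(np.argmin(np.abs(self.z_coords - self.pappus_center[1])))


@dataclass
class VortexMetrics:
    """Wake summary for one masked, width-restricted field."""

    zp_over_D: float
    min_uz: float
    nominal_length_over_D: float | None
    masked_rows: list

    def __post_init__(self) -> None:
        if self.zp_over_D < 0:
            raise ValueError("z_p/D must be non-negative")
        if self.nominal_length_over_D is not None and self.nominal_length_over_D < 0:
            raise ValueError("nominal length must be non-negative")


def compute_metrics(field: VelocityField) -> VortexMetrics:
    """Full chain: mask rows, restrict width, extract the wake metrics."""
    fld = restrict_to_pappus_width(mask_noisy_rows(field))
    zp, min_uz = locate_min_uz(fld)
    return VortexMetrics(
        zp_over_D=zp,
        min_uz=min_uz,
        nominal_length_over_D=nominal_vortex_length(fld),
        masked_rows=list(fld.masked_rows),
    )


def _noisy_rows(
    field: VelocityField, rel_factor: float = 5.0, abs_fraction: float = 0.5
) -> np.ndarray:
    """Boolean flags per row: True when the u_z profile across r is noisy.

    The statistic is the row's roughness -- the median absolute jump of u_z
    between adjacent r nodes.  A physical profile (freestream, or a smooth
    recirculation bubble) varies gently node to node, whereas spurious PIV
    rows jitter with amplitude comparable to the velocity scale.  A row is
    noisy when its roughness exceeds ``rel_factor`` times the typical row
    roughness (floored at 5% of the median speed, so smooth fields with
    near-zero roughness are not over-flagged), or ``abs_fraction`` times
    the median absolute velocity (so globally corrupted fields are still
    caught).
    """
    uz = field.u_z
    rough = np.median(np.abs(np.diff(uz, axis=1)), axis=1)
    speed_scale = np.median(np.abs(uz))
    base = max(float(np.median(rough)), 0.05 * speed_scale, 1e-12)
    return (rough > rel_factor * base) | (rough > abs_fraction * speed_scale + 1e-12)


def mask_noisy_rows(
    field: VelocityField, rel_factor: float = 5.0, abs_fraction: float = 0.5
) -> VelocityField:
    """Mask noisy rows and clip to the vortex window around the pappus.

    The first row is always masked.  Starting from the row nearest the
    pappus centre, the retained window extends in both z directions until
    two consecutive noisy rows are met (a single isolated noisy row is
    stepped over but stays masked).  Idempotent.
    """
    nz = field.z_coords.size
    if nz < 5:
        raise ValueError("need at least 5 rows to identify the vortex window")
    noisy = _noisy_rows(field, rel_factor, abs_fraction)
    noisy[0] = True  # first image row is always noisy
    if noisy.all():
        raise ValueError("all rows flagged as noisy")

    start = field.center_row
    if noisy[start] and start + 1 < nz and not noisy[start + 1]:
        start += 1
    lo = hi = start
    i = start - 1
    while i >= 0:
        if noisy[i] and (i == 0 or noisy[i - 1]):
            break
        lo = i if not noisy[i] else lo
        i -= 1
    i = start + 1
    while i < nz:
        if noisy[i] and (i == nz - 1 or noisy[i + 1]):
            break
        hi = i if not noisy[i] else hi
        i += 1

    return replace(
        field,
        masked_rows=sorted(set(np.flatnonzero(noisy).tolist()) | set(field.masked_rows)),
        row_window=(lo, hi),
    )


def restrict_to_pappus_width(field: VelocityField) -> VelocityField:
    """Keep columns within the triangular pappus silhouette.

    Retains nodes with |r - r_center| <= L sin(tau/2) (closed interval).
    Idempotent.
    """
    half_width = field.hair_length * np.sin(np.deg2rad(field.pappus_angle) / 2.0)
    keep = np.abs(field.r_coords - field.pappus_center[0]) <= half_width + 1e-12
    if not keep.any():
        raise ValueError("no grid columns fall inside the pappus width")
    return replace(
        field,
        r_coords=field.r_coords[keep],
        u_r=field.u_r[:, keep],
        u_z=field.u_z[:, keep],
    )


def _window_center_profile(field: VelocityField):
    """(z offsets from pappus centre, u_z) on the centre column, unmasked rows
    of the retained window, downstream of the pappus centre."""
    lo, hi = field.row_window if field.row_window is not None else (0, field.z_coords.size - 1)
    rows = [
        i
        for i in range(lo, hi + 1)
        if i not in field.masked_rows and field.z_coords[i] >= field.pappus_center[1]
    ]
    z = field.z_coords[rows] - field.pappus_center[1]
    uz = field.u_z[rows, field.center_col]
    return np.asarray(z), np.asarray(uz)


def locate_min_uz(field: VelocityField) -> tuple[float, float]:
    """(z_p / D, min u_z): the recirculation core on the centre column.

    z_p is the downstream distance from the pappus centre to the node where
    u_z is minimal, nondimensionalised by the dry pappus diameter.
    """
    z, uz = _window_center_profile(field)
    if z.size == 0:
        raise ValueError("no usable rows downstream of the pappus centre")
    i = int(np.argmin(uz))
    return float(z[i] / field.dry_diameter), float(uz[i])


def nominal_vortex_length(
    field: VelocityField, threshold: float = UZ_RECOVERY_THRESHOLD
) -> float | None:
    """Distance (in units of the dry diameter) to flow recovery at ``threshold``.

    Walks downstream along the centre column from the pappus centre and
    returns the first upward crossing of u_z = threshold, linearly
    interpolated between grid rows; ``None`` (with a warning) when the flow
    never dips below and recovers through the threshold inside the window.
    """
    z, uz = _window_center_profile(field)
    below = uz < threshold
    for i in range(1, z.size):
        if below[i - 1] and uz[i] >= threshold:
            frac = (threshold - uz[i - 1]) / (uz[i] - uz[i - 1])
            z_cross = z[i - 1] + frac * (z[i] - z[i - 1])
            return float(z_cross / field.dry_diameter)
    warnings.warn("u_z never recovers through the threshold inside the window")
    return None


def regress_zp_vs_angle(samples) -> tuple[float, float, float]:
    """OLS of z_p / D on pappus angle (degrees): (intercept, slope, R^2)."""
    samples = list(samples)
    if len(samples) < 3:
        raise ValueError("need at least 3 (angle, z_p/D) samples")
    tau = np.array([s[0] for s in samples], dtype=float)
    y = np.array([s[1] for s in samples], dtype=float)
    if np.allclose(tau, tau[0]):
        raise ValueError("pappus angle is constant; regression undefined")
    res = stats.linregress(tau, y)
    return float(res.intercept), float(res.slope), float(res.rvalue**2)


def predict_zp(intercept: float, slope: float, tau) -> np.ndarray:
    """Predicted z_p / D at pappus angle(s) ``tau`` in degrees."""
    return intercept + slope * np.asarray(tau, dtype=float)


def load_field(field_csv, meta: dict) -> VelocityField:
    """Build a :class:`VelocityField` from a long-format CSV and metadata.

    CSV columns: r_m, z_m, u_r, u_z (one row per grid node).  ``meta`` keys:
    center_r_m, center_z_m, pappus_angle_deg, dry_diameter_m.
    """
    import pandas as pd

    df = pd.read_csv(field_csv)
    r = np.unique(df["r_m"].to_numpy())
    z = np.unique(df["z_m"].to_numpy())
    piv = df.pivot_table(index="z_m", columns="r_m", sort=True)
    return VelocityField(
        r_coords=r,
        z_coords=z,
        u_r=piv["u_r"].to_numpy(),
        u_z=piv["u_z"].to_numpy(),
        pappus_center=(float(meta["center_r_m"]), float(meta["center_z_m"])),
        pappus_angle=float(meta["pappus_angle_deg"]),
        dry_diameter=float(meta["dry_diameter_m"]),
    )
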
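"""Pappus geometry and drop-test aerodynamics.

The dandelion pappus is modelled as a crown of ``n_hairs`` straight,
non-overlapping filaments of length ``hair_length`` attached at a point.
The pappus angle tau is the full angle between the two outermost hairs
(about 180 degrees when dry and fully open, shrinking as the pappus closes
in moist air), so each hair is inclined tau/2 from the flow axis and its
projected (silhouette) length is ``hair_length * sin(tau/2)``.

From that geometry the module derives projected area, porosity, the pappus
diameter used as the Reynolds length scale, the drag coefficient at terminal
velocity, and a one-parameter falling-velocity-versus-angle model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "DiasporeGeometry",
    "FluidEnvironment",
    "pappus_diameter",
    "projected_area",
    "porosity",
    "reynolds",
    "drag_coefficient",
    "weight_force",
    "velocity_basis",
    "fit_velocity_angle_model",
    "predict_velocity",
]

#: mean dry / wet diaspore mass (kg) from pooled weighings of drop-test samples
DRY_MASS = 0.614e-6
WET_MASS = 0.684e-6


@dataclass(frozen=True)
class DiasporeGeometry:
    """Geometry of a single diaspore's pappus.

    Parameters
    ----------
    n_hairs
        Number of pappus filaments (~100 for dandelion).
    hair_length
        Filament length in metres.
    hair_diameter
        Filament diameter in metres.
    pappus_angle
        Full angle between the outermost hairs, degrees, in [0, 180].
    mass
        Whole-diaspore mass in kg (achene + pappus, plus water when wet).
    """

    n_hairs: int = 100
    hair_length: float = 7.41e-3
    hair_diameter: float = 16e-6
    pappus_angle: float = 180.0
    mass: float = DRY_MASS

    def __post_init__(self) -> None:
        if self.n_hairs < 1:
            raise ValueError("n_hairs must be >= 1")
        if not 0.0 <= self.pappus_angle <= 180.0:
            raise ValueError("pappus_angle must be in [0, 180] degrees")
        if not self.hair_diameter < self.hair_length:
            raise ValueError("hair_diameter must be smaller than hair_length")
        if self.mass <= 0:
            raise ValueError("mass must be positive")

    @property
    def half_angle_rad(self) -> float:
        return math.radians(self.pappus_angle) / 2.0


@dataclass(frozen=True)
class FluidEnvironment:
    """Ambient air properties (defaults: air at 20 deg C)."""

    air_density: float = 1.0241  # kg m^-3
    kinematic_viscosity: float = 15.06e-6  # m^2 s^-1
    gravity: float = 9.81  # m s^-2

    def __post_init__(self) -> None:
        if min(self.air_density, self.kinematic_viscosity, self.gravity) <= 0:
            raise ValueError("all fluid properties must be strictly positive")


def pappus_diameter(geom: DiasporeGeometry) -> float:
    """Diameter of the circle enclosing the projected pappus, D = 2 L sin(tau/2)."""
    return 2.0 * geom.hair_length * math.sin(geom.half_angle_rad)


def projected_area(geom: DiasporeGeometry) -> float:
    """Solid (hair silhouette) projected area, A_h = n d L sin(tau/2).

    The apical plate where the hairs attach is excluded.
    """
    return (
        geom.n_hairs
        * geom.hair_diameter
        * geom.hair_length
        * math.sin(geom.half_angle_rad)
    )


def porosity(geom: DiasporeGeometry) -> float:
    """Fraction of empty space in the enclosing circle, clamped to [0, 1].

    porosity = 1 - A_h / A_c with A_c = pi (L sin(tau/2))^2.  The
    non-overlapping-hair model breaks down near full closure (the formula
    goes negative once sin(tau/2) < n d / (pi L), around tau ~ 8 degrees
    for default geometry), where the value is clamped to zero.
    """
    if geom.pappus_angle == 0:
        raise ValueError("porosity undefined for a fully closed pappus (tau = 0)")
    r = geom.hair_length * math.sin(geom.half_angle_rad)
    frac = projected_area(geom) / (math.pi * r * r)
    return float(min(1.0, max(0.0, 1.0 - frac)))


def reynolds(u: float, D: float, env: FluidEnvironment = FluidEnvironment()) -> float:
    """Reynolds number Re = u D / nu of the pappus at flow speed ``u``."""
    if D <= 0:
        raise ValueError("characteristic length D must be positive")
    if u < 0:
        raise ValueError("flow speed must be non-negative")
    return u * D / env.kinematic_viscosity


def drag_coefficient(
    geom: DiasporeGeometry, u: float, env: FluidEnvironment = FluidEnvironment()
) -> float:
    """Drag coefficient at terminal velocity, C_D = m g / (1/2 rho u^2 A_h).

    At steady descent drag balances weight, so the drag force is m g and the
    reference area is the solid silhouette area of the hairs.
    """
    if u <= 0:
        raise ValueError("falling velocity must be positive")
    A = projected_area(geom)
    if A <= 0:
        raise ValueError("projected area is zero (closed pappus)")
    return geom.mass * env.gravity / (0.5 * env.air_density * u * u * A)


def weight_force(mass: float, env: FluidEnvironment = FluidEnvironment()) -> float:
    """Weight m g (N). At terminal velocity this equals the drag force."""
    if mass < 0:
        raise ValueError("mass must be non-negative")
    return mass * env.gravity


# ---------------------------------------------------------------------------
# falling velocity vs pappus angle


def velocity_basis(
    pappus_angle: float | np.ndarray,
    convention: Literal["half", "full"] = "half",
) -> np.ndarray:
    """Basis function of the falling-velocity model, v = c * basis(tau).

    The model takes falling velocity proportional to cos^(-2/3) of an angle.
    Two conventions are supported:

    ``"half"`` (default)
        cos^(-2/3)(tau/2), finite on tau in (0, 180) degrees.
    ``"full"``
        cos^(-2/3)(tau), the literal reading, singular at tau = 90 degrees.
    """
    tau = np.deg2rad(np.asarray(pappus_angle, dtype=float))
    arg = tau / 2.0 if convention == "half" else tau
    c = np.cos(arg)
    with np.errstate(divide="ignore", invalid="ignore"):
        basis = np.sign(c) * np.abs(c) ** (-2.0 / 3.0)
    return basis


def fit_velocity_angle_model(
    records: Iterable[tuple[float, float]],
    convention: Literal["half", "full"] = "half",
    singular_tol: float = 1e-6,
) -> float:
    """Least-squares proportionality coefficient c of v = c * basis(tau).

    Parameters
    ----------
    records
        (pappus_angle_deg, falling_velocity_m_s) pairs; at least two, none
        at the basis singularity.

    Returns
    -------
    c : the fitted coefficient (m s^-1 at basis = 1).
    """
    rec = list(records)
    if len(rec) < 2:
        raise ValueError("need at least two drop-test records")
    tau = np.array([r[0] for r in rec], dtype=float)
    v = np.array([r[1] for r in rec], dtype=float)
    b = velocity_basis(tau, convention)
    bad = ~np.isfinite(b) | (np.abs(np.cos(np.deg2rad(tau) / (2 if convention == "half" else 1))) < singular_tol)
    if bad.any():
        raise ValueError(
            f"angles {tau[bad]} lie at/near the singularity of the "
            f"cos^(-2/3) basis ({convention!r} convention); remove them"
        )
    # one-parameter linear least squares through the origin
    return float(np.dot(b, v) / np.dot(b, b))


def predict_velocity(
    c: float,
    pappus_angle: float | np.ndarray,
    convention: Literal["half", "full"] = "half",
) -> np.ndarray:
    """Predicted falling velocity c * basis(tau) for angle(s) in degrees."""
    return c * velocity_basis(pappus_angle, convention)


def load_drop_tests(path) -> "pd.DataFrame":  # noqa: F821 - lazy import
    """Read a drop-test CSV: sample_id, pappus_angle_deg, falling_velocity_m_s, condition."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"sample_id", "pappus_angle_deg", "falling_velocity_m_s", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"drop-test CSV missing columns: {sorted(missing)}")
    return df
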
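"""Dispersal-kernel experiments: release conditioning, Models 1-5, KDEs.

Five scenario models combine three switches -- the weather class whose wind
speeds drive the simulation, the pappus state governing *detachment*
(which fitted detachment curve conditions the release wind), and the pappus
state governing *flight* (terminal velocity 0.3 m/s open, 0.7 m/s closed):

====== ======== ============ =========
model  weather  detachment   flight
====== ======== ============ =========
1      dry      open         open
2      wet      open         open
3      wet      closed       closed
4      dry      open         closed
5      dry      closed       open
====== ======== ============ =========

Model 1 is the realistic dry-weather baseline and Model 3 the realistic
wet-weather scenario with a morphing (closed) pappus; Models 2, 4 and 5
are counterfactuals isolating each switch.  Per-model summaries (median
distance, fraction of events beyond 100 m) are computed on the empirical
distances; kernel density estimates on log10 distance, renormalised in
distance space, support the combined (weather-weighted,
detachment-conditioned) kernels and their Jensen-Shannon comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.spatial.distance import jensenshannon
from scipy.stats import gaussian_kde

from pappus.survival import ParametricDetachmentFit, detachment_probability
from pappus.trajectory import (
    SETTLING_VELOCITY,
    CanopyConfig,
    EnsembleResult,
    FlightParams,
    simulate_ensemble,
)

__all__ = [
    "ModelSpec",
    "MODELS",
    "DispersalKernel",
    "sample_release_wind",
    "run_model",
    "run_all_models",
    "summarize",
    "kde",
    "kernel_median",
    "kernel_tail_fraction",
    "detachment_timecourse",
    "combine_kernels",
    "jensen_shannon",
    "sensitivity_report",
    "LDD_THRESHOLD",
]

LDD_THRESHOLD = 100.0  # m; events beyond this count as long-distance dispersal


@dataclass(frozen=True)
class ModelSpec:
    """One scenario: weather class, detachment pappus state, flight state."""

    weather_class: Literal["dry", "wet"]
    detach_state: Literal["open", "closed", "none"]
    flight_state: Literal["open", "closed"]

    @property
    def settling_velocity(self) -> float:
        return SETTLING_VELOCITY[self.flight_state]

    @property
    def detach_condition(self) -> str | None:
        """Weather condition whose fitted detachment curve applies.

        An open pappus detaches like the dry assay, a closed pappus like
        the wet assay; ``None`` disables release conditioning.
        """
        if self.detach_state == "none":
            return None
        return "dry" if self.detach_state == "open" else "wet"


MODELS: dict[int, ModelSpec] = {
    1: ModelSpec("dry", "open", "open"),
    2: ModelSpec("wet", "open", "open"),
    3: ModelSpec("wet", "closed", "closed"),
    4: ModelSpec("dry", "open", "closed"),
    5: ModelSpec("dry", "closed", "open"),
}


@dataclass
class DispersalKernel:
    """Normalised dispersal-distance density on a log-spaced grid."""

    grid: np.ndarray  # distances, m
    density: np.ndarray  # per metre; trapezoid integral = 1
    n_events: int
    summary: dict = field(default_factory=dict)

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


# ---------------------------------------------------------------------------
# release-wind sampling


def sample_release_wind(
    speeds,
    detach_fit: ParametricDetachmentFit | None,
    n: int,
    seed,
) -> np.ndarray:
    """Sample release wind speeds, conditioned on detachment when fitted.

    Draws u with probability proportional to f_weather(u) * F_detach(u) by
    rejection against the maximum of F on the observed support; with
    ``detach_fit=None`` this is a plain bootstrap of the weather class.
    """
    speeds = np.asarray(speeds, dtype=float)
    if speeds.size == 0:
        raise ValueError("empty wind-speed distribution")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(n)
    if n == 0:
        return np.empty(0)
    if detach_fit is None:
        return rng.choice(speeds, size=n, replace=True)

    f_max = float(np.max(detachment_probability(speeds, detach_fit)))
    if f_max <= 0:
        raise ValueError("detachment probability is zero on the whole support")
    out = np.empty(n)
    filled = 0
    while filled < n:
        batch = max(int((n - filled) / max(f_max, 1e-3) * 1.2), 64)
        cand = rng.choice(speeds, size=batch, replace=True)
        accept = rng.random(batch) < detachment_probability(cand, detach_fit) / f_max
        take = cand[accept][: n - filled]
        out[filled : filled + take.size] = take
        filled += take.size
    return out


# ---------------------------------------------------------------------------
# model runs and summaries


def run_model(
    spec: ModelSpec,
    weather_split: dict,
    detach_fits: dict,
    n: int = 10000,
    seed=None,
    cfg: CanopyConfig = CanopyConfig(),
    flight_kwargs: dict | None = None,
) -> EnsembleResult:
    """Run one scenario end to end: sample release winds, fly ``n`` diaspores.

    ``weather_split`` maps "dry"/"wet" to wind-speed arrays (from
    :func:`pappus.weather.split`); ``detach_fits`` maps condition to a
    converged :class:`ParametricDetachmentFit`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    speeds = weather_split[spec.weather_class]
    fit = None if spec.detach_condition is None else detach_fits[spec.detach_condition]
    u = sample_release_wind(speeds, fit, n, rng)
    flight = FlightParams(
        settling_velocity=spec.settling_velocity, **(flight_kwargs or {})
    )
    return simulate_ensemble(u, flight, cfg, rng=rng)


def run_all_models(
    weather_split: dict,
    detach_fits: dict,
    n: int = 10000,
    seed: int = 0,
    cfg: CanopyConfig = CanopyConfig(),
) -> dict[int, EnsembleResult]:
    """Run Models 1-5 with per-model seeds derived from ``seed``."""
    return {
        m: run_model(spec, weather_split, detach_fits, n=n, seed=seed * 10 + m, cfg=cfg)
        for m, spec in MODELS.items()
    }


def summarize(distances) -> tuple[float, float]:
    """(median distance m, fraction of events beyond 100 m), both empirical."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("no dispersal events to summarise")
    return float(np.median(d)), float(np.mean(d > LDD_THRESHOLD))


# ---------------------------------------------------------------------------
# kernel density estimation on log distance


def kde(
    distances,
    grid_size: int = 512,
    pad_decades: float = 0.5,
    grid: np.ndarray | None = None,
) -> DispersalKernel:
    """Gaussian KDE of log10(distance), mapped back to distance space.

    The density of y = log10(x) is estimated with Silverman bandwidth and
    transformed by f_x(x) = f_y(log10 x) / (x ln 10); the result is
    renormalised so its trapezoid integral over the grid is exactly 1.
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 10:
        raise ValueError("need at least 10 distances for a kernel estimate")
    if np.any(d <= 0):
        raise ValueError("distances must be positive for the log-scale KDE")
    logd = np.log10(d)
    est = gaussian_kde(logd, bw_method="silverman")
    if grid is None:
        grid = np.logspace(logd.min() - pad_decades, logd.max() + pad_decades, grid_size)
    else:
        grid = np.asarray(grid, dtype=float)
    dens = est(np.log10(grid)) / (grid * np.log(10.0))
    norm = np.trapezoid(dens, grid)
    med, ldd = summarize(d)
    return DispersalKernel(
        grid=grid,
        density=dens / norm,
        n_events=d.size,
        summary={"median_m": med, "ldd_fraction": ldd},
    )


def kernel_median(kernel: DispersalKernel) -> float:
    """Median of the kernel density (inverse of the trapezoid CDF at 0.5)."""
    x, f = kernel.grid, kernel.density
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) * np.diff(x))])
    cum /= cum[-1]
    return float(np.interp(0.5, cum, x))


def kernel_tail_fraction(kernel: DispersalKernel, threshold: float = LDD_THRESHOLD) -> float:
    """Probability mass of the kernel beyond ``threshold`` (tail integral)."""
    x, f = kernel.grid, kernel.density
    if threshold >= x[-1]:
        return 0.0
    mask = x >= threshold
    xs = np.concatenate([[threshold], x[mask]])
    fs = np.concatenate([[np.interp(threshold, x, f)], f[mask]])
    return float(np.trapezoid(fs, xs) / np.trapezoid(f, x))


# ---------------------------------------------------------------------------
# 48-hour detachment time course


def detachment_timecourse(
    speeds,
    detach_fit: ParametricDetachmentFit,
    duration: int = 172800,
    seed=None,
) -> tuple[float, float]:
    """Second-by-second detachment simulation over ``duration`` seconds.

    Each second draws a wind speed from the weather class and detaches the
    diaspore with probability F(u).  Returns (fraction of seconds with
    detachment, mean wind speed over detaching seconds; NaN if none).
    """
    if duration < 1:
        raise ValueError("duration must be at least 1 s")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.choice(np.asarray(speeds, dtype=float), size=int(duration), replace=True)
    p = detachment_probability(u, detach_fit)
    detached = rng.random(int(duration)) < p
    frac = float(np.mean(detached))
    mean_u = float(np.mean(u[detached])) if detached.any() else float("nan")
    return frac, mean_u


# ---------------------------------------------------------------------------
# kernel combination and comparison


def combine_kernels(
    k_dry: DispersalKernel,
    k_wet: DispersalKernel,
    freq_dry: float,
    detach_prob_dry: float,
    detach_prob_wet: float,
) -> DispersalKernel:
    """Mixture of a dry and a wet kernel, weighted by weather frequency and
    per-condition detachment probability.

    w_dry is proportional to freq_dry * P(detach | dry), w_wet to
    (1 - freq_dry) * P(detach | wet); the mixture density is renormalised.
    """
    w_dry = freq_dry * detach_prob_dry
    w_wet = (1.0 - freq_dry) * detach_prob_wet
    if w_dry < 0 or w_wet < 0 or (w_dry + w_wet) == 0:
        raise ValueError("weights must be non-negative and not all zero")
    w_dry, w_wet = w_dry / (w_dry + w_wet), w_wet / (w_dry + w_wet)

    if not np.array_equal(k_dry.grid, k_wet.grid):
        warnings.warn("kernel grids differ; interpolating the wet kernel")
        wet_dens = np.interp(k_dry.grid, k_wet.grid, k_wet.density, left=0.0, right=0.0)
    else:
        wet_dens = k_wet.density
    dens = w_dry * k_dry.density + w_wet * wet_dens
    norm = np.trapezoid(dens, k_dry.grid)
    return DispersalKernel(
        grid=k_dry.grid,
        density=dens / norm,
        n_events=k_dry.n_events + k_wet.n_events,
        summary={"w_dry": w_dry, "w_wet": w_wet},
    )


def mixture_weights(freq_dry: float, detach_ratio: float) -> tuple[float, float]:
    """(w_dry, w_wet) when wet detachment is ``detach_ratio`` times rarer than dry."""
    w_dry = freq_dry * detach_ratio
    w_wet = 1.0 - freq_dry
    s = w_dry + w_wet
    return w_dry / s, w_wet / s


def jensen_shannon(k_a: DispersalKernel, k_b: DispersalKernel) -> float:
    """Jensen-Shannon divergence (base-2 logarithm, in [0, 1]) of two kernels.

    The kernels are discretised to probability vectors with trapezoid
    weights on a common grid; unnormalised inputs are normalised with a
    warning.
    """
    if not np.array_equal(k_a.grid, k_b.grid):
        warnings.warn("kernel grids differ; interpolating the second kernel")
        b_dens = np.interp(k_a.grid, k_b.grid, k_b.density, left=0.0, right=0.0)
    else:
        b_dens = k_b.density
    x = k_a.grid
    w = np.empty_like(x)
    w[1:-1] = 0.5 * (x[2:] - x[:-2])
    w[0] = 0.5 * (x[1] - x[0])
    w[-1] = 0.5 * (x[-1] - x[-2])
    p = k_a.density * w
    q = b_dens * w
    for vec, name in ((p, "first"), (q, "second")):
        s = vec.sum()
        if abs(s - 1.0) > 1e-3:
            warnings.warn(f"{name} kernel not normalised (mass {s:.4f}); renormalising")
    p = p / p.sum()
    q = q / q.sum()
    return float(jensenshannon(p, q, base=2) ** 2)


# ---------------------------------------------------------------------------
# closure-constant sensitivity


def sensitivity_report(
    weather_split: dict,
    detach_fits: dict,
    n: int = 2000,
    seed: int = 0,
    model: int = 1,
    variations: dict | None = None,
) -> "pd.DataFrame":  # noqa: F821
    """Median / LDD sensitivity of a model to the turbulence closure constants.

    The closure constants (sigma_u, sigma_w multipliers and the Lagrangian
    timescale coefficient) are not uniquely determined by the literature the
    trajectory model follows, so absolute kernel statistics carry that
    uncertainty.  This report reruns one model with each constant perturbed
    by +/-20% and tabulates the resulting median and LDD fraction.
    """
    import pandas as pd

    variations = variations or {
        "sigma_u_coeff": 2.4,
        "sigma_w_coeff": 1.25,
        "tl_coeff": 0.5,
    }
    rows = []
    base = CanopyConfig()
    for name, default in [("baseline", None)] + [(k, v) for k, v in variations.items()]:
        factors = [1.0] if name == "baseline" else [0.8, 1.2]
        for f in factors:
            cfg = base if name == "baseline" else CanopyConfig(**{name: default * f})
            res = run_model(MODELS[model], weather_split, detach_fits, n=n, seed=seed, cfg=cfg)
            med, ldd = summarize(res.distances)
            rows.append(
                {"constant": name, "factor": f, "median_m": med, "ldd_fraction": ldd}
            )
    return pd.DataFrame(rows)
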
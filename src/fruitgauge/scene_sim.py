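"""Synthetic fruit/marker scenes and stress-driven growth trajectories.

The generator emulates the measurement setting the pipeline is built for:
an oblate-spheroid citrus fruit carrying a 15 mm square fiducial marker on
its top, photographed by a monocular pinhole camera from 8-10 cm at 0-20
degrees off the marker normal, while the host tree dries down between rain
events and the fruit grows at a water-potential-dependent daily rate.

Geometry of one scene (all closed form; rasterization is a fidelity layer
on top, see :func:`render_mask`):

* the marker lies in a plane at distance ``D`` from the camera and projects
  to area ``A_m = s^2 * cos(theta) * (f / D)^2`` pixels;
* the fruit silhouette is an ellipse with semi-axes ``a = d/2`` and
  ``b = (d/2) * sqrt(cos^2 theta + k^2 sin^2 theta)`` (``theta`` measured
  from the polar axis, which coincides with the marker normal), scaled by
  ``f / (D + k*d/2)`` — the fruit's widest section lies half a polar
  diameter *behind* the marker plane, so close cameras and large fruit lose
  relatively more fruit area than marker area.  This single perspective
  offset is what makes the naive area ratio a biased size measure.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    STREAM_CALIPER,
    STREAM_POSE,
    STREAM_PSI,
    STREAM_TRAJ,
    SimConfig,
    rng_for,
    stable_id_hash,
)

logger = logging.getLogger(__name__)


class UnknownTreeError(KeyError):
    """Raised when a tree id has no configured drying rate."""


class SceneOutOfFrameError(ValueError):
    """Raised when a projected scene does not fit inside the image grid."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FruitState:
    """True geometry of one fruit on one date.

    ``diameter_eq`` is the equatorial ("lateral") diameter in mm — the
    quantity a caliper measures.  ``flatness_k`` is the polar/equatorial
    ratio; k < 1 means an oblate fruit.
    """

    fruit_id: str
    tree_id: str
    date: dt.date
    diameter_eq: float
    flatness_k: float

    def __post_init__(self) -> None:
        if self.diameter_eq <= 0:
            raise ValueError("diameter_eq must be positive")
        if not (0 < self.flatness_k <= 1.2):
            raise ValueError("flatness_k must lie in (0, 1.2]")


@dataclass(frozen=True)
class CameraPose:
    """Camera placement relative to the marker plane."""

    distance_mm: float
    angle_deg: float
    focal_px: float

    def __post_init__(self) -> None:
        if self.distance_mm <= 0 or self.focal_px <= 0:
            raise ValueError("distance and focal length must be positive")
        if self.angle_deg < 0:
            raise ValueError("angle_deg must be non-negative")


@dataclass(frozen=True)
class SceneObservation:
    """Quantities extracted from (or analytically defined for) one photo."""

    fruit_id: str
    tree_id: str
    date: dt.date
    area_fruit_px: float
    area_marker_px: float
    ratio: float
    resolution_tier: str
    truth_diameter_mm: float
    pose: CameraPose


@dataclass
class PsiSeries:
    """One tree's dated pre-dawn leaf water potential record (MPa, <= 0)."""

    tree_id: str
    dates: list[dt.date]
    psi: np.ndarray

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        if len(self.dates) != len(self.psi):
            raise ValueError("dates and psi must have equal length")
        if np.any(self.psi > 0):
            raise ValueError("water potential must be <= 0 MPa")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValueError("dates must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tree_id": self.tree_id, "date": self.dates, "psi_MPa": self.psi}
        )


# ---------------------------------------------------------------------------
# water potential
# ---------------------------------------------------------------------------

def simulate_psi_series(config: SimConfig, tree_id: str) -> PsiSeries:
    """Simulate one tree's sampled pre-dawn water potential series.

    A daily latent path starts at the unstressed baseline ``c``, declines at
    the tree's drying rate plus white noise, is clipped to
    ``[psi_floor, c]`` and resets to ``c`` on each rain-event date.  The
    returned series subsamples this path every 7-10 days (jittered,
    seeded); the season's last day is always included so every analysis
    period is covered.
    """
    rates = config.resolved_drying_rates()
    if tree_id not in rates:
        raise UnknownTreeError(f"no drying rate configured for tree {tree_id!r}")
    rate = rates[tree_id]
    start, end = config.season
    n_days = (end - start).days
    if n_days <= 0:
        raise ValueError("empty season")

    rng = rng_for(config.seed, STREAM_PSI, stable_id_hash(tree_id))
    eps = rng.normal(0.0, config.psi_noise_sd, n_days) if config.psi_noise_sd > 0 else np.zeros(n_days)
    rain = {d for d in config.rain_events}

    c, floor = config.psi_baseline_c, config.psi_floor
    latent = np.empty(n_days + 1)
    latent[0] = c
    for t in range(1, n_days + 1):
        day = start + dt.timedelta(days=t)
        if day in rain:
            latent[t] = c
        else:
            latent[t] = min(c, max(floor, latent[t - 1] - rate + eps[t - 1]))

    lo, hi = config.sample_gap_days
    idx = [0]
    while True:
        nxt = idx[-1] + int(rng.integers(lo, hi + 1))
        if nxt >= n_days:
            break
        idx.append(nxt)
    if idx[-1] != n_days:
        idx.append(n_days)

    dates = [start + dt.timedelta(days=i) for i in idx]
    return PsiSeries(tree_id=tree_id, dates=dates, psi=latent[idx])


# ---------------------------------------------------------------------------
# growth law
# ---------------------------------------------------------------------------

def growth_alpha(config: SimConfig) -> float:
    """Slope of the growth law in mm/day per MPa."""
    return config.growth_anchor_rate / (config.growth_anchor_psi - config.psi_floor)


def growth_rate(psi, config: SimConfig):
    """Daily diameter growth (mm/day) at water potential ``psi`` (MPa).

    Piecewise linear: zero at the mortality floor (-2.0 MPa by default),
    rising through the anchor (0.25 mm/day at -0.8 MPa), clipped below at
    zero; monotone non-decreasing in psi.
    """
    p = np.asarray(psi, dtype=float)
    if np.any(p > 0):
        raise ValueError("water potential must be <= 0 MPa")
    alpha = growth_alpha(config)
    out = np.maximum(alpha * (p - config.psi_floor), 0.0)
    return float(out) if np.isscalar(psi) else out


# ---------------------------------------------------------------------------
# flatness
# ---------------------------------------------------------------------------

def sample_flatness(diameter_eq, config: SimConfig, rng: np.random.Generator | None = None,
                    noise=None):
    """Sample the polar/equatorial ratio ``k`` for fruit of given diameter.

    The flatness index ``F = 1 - k`` is linearly coupled to diameter
    (larger fruit are more oblate) with Gaussian noise calibrated so that
    across the reference population corr(diameter, F) is about 0.46; ``k``
    is clipped to the configured physical range.

    ``noise`` may be supplied explicitly (e.g. one persistent draw per
    fruit along a trajectory); otherwise it is drawn from ``rng``.
    """
    d = np.asarray(diameter_eq, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter_eq must be positive")
    if noise is None:
        if rng is None:
            raise ValueError("provide either rng or an explicit noise value")
        noise = rng.normal(0.0, config.flatness_noise_sd, size=d.shape)
    f_index = config.flatness_intercept + config.flatness_beta * (d - config.flatness_ref_mm) + noise
    k = np.clip(1.0 - f_index, *config.flatness_k_range)
    return float(k) if np.isscalar(diameter_eq) else k


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def simulate_fruit_trajectories(psi: PsiSeries, config: SimConfig) -> pd.DataFrame:
    """Grow ``fruits_per_tree`` fruits along one tree's water-stress path.

    The sampled psi series is linearly interpolated to a daily grid; each
    day contributes ``growth_rate(midpoint psi)`` mm of diameter.  Using
    the day-interval midpoint makes the accumulated growth over any span
    between measurement dates an exact trapezoidal integral of the growth
    law — the same quadrature the integrated-stress statistic uses, which
    is what links growth to stress algebraically in the noiseless limit.

    Returns one row per (fruit, measurement date) with columns
    ``fruit_id, tree_id, date, diameter_eq, flatness_k``.
    """
    days = np.array([(d - psi.dates[0]).days for d in psi.dates])
    daily = np.interp(np.arange(days[-1] + 1), days, psi.psi)
    mid = 0.5 * (daily[:-1] + daily[1:])
    inc = growth_rate(mid, config)
    cum = np.concatenate([[0.0], np.cumsum(inc)])
    growth_at_dates = cum[days]

    rng = rng_for(config.seed, STREAM_TRAJ, stable_id_hash(psi.tree_id))
    rows = []
    for j in range(config.fruits_per_tree):
        fruit_id = f"{psi.tree_id}-F{j + 1}"
        d0 = rng.normal(config.init_diameter_mean_mm, config.init_diameter_sd_mm)
        d0 = max(d0, 10.0)  # guard absurd draws at tiny sd configs
        eps = rng.normal(0.0, config.flatness_noise_sd)  # persistent per fruit
        diam = d0 + growth_at_dates
        k = sample_flatness(diam, config, noise=eps)
        for date, dmm, kk in zip(psi.dates, diam, np.atleast_1d(k)):
            rows.append((fruit_id, psi.tree_id, date, float(dmm), float(kk)))
    return pd.DataFrame(rows, columns=["fruit_id", "tree_id", "date", "diameter_eq", "flatness_k"])


# ---------------------------------------------------------------------------
# camera & projection
# ---------------------------------------------------------------------------

def sample_pose(config: SimConfig, resolution_tier: str, rng: np.random.Generator) -> CameraPose:
    """Draw a capture pose: distance ~ U(80,100) mm, angle ~ U(0,20) deg."""
    dlo, dhi = config.distance_range_mm
    alo, ahi = config.angle_range_deg
    return CameraPose(
        distance_mm=float(rng.uniform(dlo, dhi)),
        angle_deg=float(rng.uniform(alo, ahi)),
        focal_px=config.focal_px[resolution_tier],
    )


def project_scene(fruit: FruitState, pose: CameraPose, config: SimConfig,
                  resolution_tier: str = "high", round_px: bool | None = None) -> SceneObservation:
    """Analytic projected areas of fruit and marker for one photograph.

    See the module docstring for the forward model.  With ``round_px`` the
    areas are quantized to integer pixel counts, emulating mask output.
    """
    if pose.angle_deg >= 90.0:
        raise ValueError("marker not visible: angle must be < 90 degrees")
    theta = math.radians(pose.angle_deg)
    s = config.marker_side_mm
    f, dist = pose.focal_px, pose.distance_mm
    a = fruit.diameter_eq / 2.0
    k = fruit.flatness_k

    area_marker = s * s * math.cos(theta) * (f / dist) ** 2
    b = a * math.sqrt(math.cos(theta) ** 2 + (k * math.sin(theta)) ** 2)
    area_fruit = math.pi * a * b * (f / (dist + k * a)) ** 2

    if round_px is None:
        round_px = config.round_areas
    if round_px:
        area_marker = float(round(area_marker))
        area_fruit = float(round(area_fruit))
    if area_marker <= 0:
        raise ValueError("marker projects to zero area; ratio undefined")

    return SceneObservation(
        fruit_id=fruit.fruit_id,
        tree_id=fruit.tree_id,
        date=fruit.date,
        area_fruit_px=area_fruit,
        area_marker_px=area_marker,
        ratio=area_fruit / area_marker,
        resolution_tier=resolution_tier,
        truth_diameter_mm=fruit.diameter_eq,
        pose=pose,
    )


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

@dataclass
class LabelMask:
    """3-class label image: 0 background, 1 fruit, 2 marker."""

    grid: np.ndarray
    resolution_tier: str

    def __post_init__(self) -> None:
        from .config import RESOLUTIONS

        self.grid = np.asarray(self.grid)
        expected = tuple(RESOLUTIONS[self.resolution_tier])
        if self.grid.shape != expected:
            raise ValueError(
                f"mask shape {self.grid.shape} does not match tier "
                f"{self.resolution_tier!r} {expected}"
            )
        labels = np.unique(self.grid)
        if not np.isin(labels, [0, 1, 2]).all():
            raise ValueError(f"mask contains labels outside {{0,1,2}}: {labels}")


def render_mask(fruit: FruitState, pose: CameraPose, config: SimConfig,
                resolution_tier: str = "high", droplet_fraction: float = 0.0,
                rng: np.random.Generator | None = None,
                with_counts: bool = False):
    """Rasterize one scene to a 3-class label mask.

    The fruit ellipse and (foreshortened) marker rectangle are drawn
    centered on the image; marker pixels override fruit pixels.  Class
    pixel counts converge to the analytic :func:`project_scene` areas as
    resolution grows.  ``droplet_fraction`` > 0 appends random water-drop
    blobs touching the fruit contour until the fruit area has been inflated
    by approximately that fraction (seeded via ``rng``).

    With ``with_counts`` the rasterizer also returns its own pixel counts
    (fruit count includes pixels later overridden by the marker, i.e. the
    full silhouette that hole-filling extraction recovers).
    """
    from skimage.draw import disk, ellipse

    if pose.angle_deg >= 90.0:
        raise ValueError("marker not visible: angle must be < 90 degrees")
    shape = tuple(config.resolution[resolution_tier])
    h, w = shape
    cy, cx = h // 2, w // 2

    theta = math.radians(pose.angle_deg)
    f, dist = pose.focal_px, pose.distance_mm
    a = fruit.diameter_eq / 2.0
    k = fruit.flatness_k
    scale_fruit = f / (dist + k * a)
    a_px = a * scale_fruit
    b_px = a * math.sqrt(math.cos(theta) ** 2 + (k * math.sin(theta)) ** 2) * scale_fruit

    if a_px >= cx or b_px >= cy:
        raise SceneOutOfFrameError(
            f"scene does not fit in {resolution_tier} frame: fruit semi-axes "
            f"({a_px:.0f}, {b_px:.0f}) px vs half-frame ({cx}, {cy}) px "
            f"[d={fruit.diameter_eq:.1f} mm, D={dist:.1f} mm, "
            f"angle={pose.angle_deg:.1f} deg]"
        )

    grid = np.zeros(shape, dtype=np.uint8)
    rr, cc = ellipse(cy, cx, b_px, a_px, shape=shape)
    grid[rr, cc] = 1
    fruit_count = int(rr.size)

    mw = config.marker_side_mm * f / dist  # marker width in px
    mh = mw * math.cos(theta)  # foreshortened height
    r0, r1 = int(round(cy - mh / 2)), int(round(cy + mh / 2))
    c0, c1 = int(round(cx - mw / 2)), int(round(cx + mw / 2))
    grid[r0:r1, c0:c1] = 2
    marker_count = (r1 - r0) * (c1 - c0)

    added = 0
    if droplet_fraction > 0:
        if rng is None:
            raise ValueError("droplet perturbation requires an rng")
        budget = droplet_fraction * fruit_count
        r_blob = max(2, int(round(0.02 * min(a_px, b_px))))
        for _ in range(10_000):
            if added >= budget:
                break
            phi = rng.uniform(0, 2 * math.pi)
            py = cy + b_px * math.sin(phi)
            px = cx + a_px * math.cos(phi)
            br, bc = disk((py, px), r_blob, shape=shape)
            sel = grid[br, bc] == 0
            grid[br[sel], bc[sel]] = 1
            added += int(sel.sum())

    mask = LabelMask(grid=grid, resolution_tier=resolution_tier)
    if with_counts:
        return mask, {
            "area_fruit_px": fruit_count + added,
            "area_marker_px": marker_count,
        }
    return mask


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig) -> dict[str, pd.DataFrame]:
    """Simulate a full cohort: psi series, trajectories, photos, calipers.

    Returns a dict of DataFrames:

    * ``psi`` — (tree_id, date, psi_MPa), the sampled water potential;
    * ``trajectories`` — (fruit_id, tree_id, date, diameter_eq, flatness_k);
    * ``observations`` — one row per photograph and tier with the analytic
      areas, ratio, pose and ground truth;
    * ``caliper`` — two replicate caliper readings per fruit per date.
    """
    psi_frames, traj_frames, obs_rows, cal_rows = [], [], [], []
    tiers = list(config.resolution)
    for tree_id in config.tree_ids():
        series = simulate_psi_series(config, tree_id)
        psi_frames.append(series.to_frame())
        traj = simulate_fruit_trajectories(series, config)
        traj_frames.append(traj)

        pose_rng = rng_for(config.seed, STREAM_POSE, stable_id_hash(tree_id))
        cal_rng = rng_for(config.seed, STREAM_CALIPER, stable_id_hash(tree_id))
        for row in traj.itertuples(index=False):
            fruit = FruitState(row.fruit_id, row.tree_id, row.date,
                               row.diameter_eq, row.flatness_k)
            for tier in tiers:
                for shot in range(config.images_per_date):
                    pose = sample_pose(config, tier, pose_rng)
                    obs = project_scene(fruit, pose, config, resolution_tier=tier)
                    obs_rows.append(
                        (f"{fruit.fruit_id}_{fruit.date.isoformat()}_{tier}_{shot}",
                         obs.fruit_id, obs.tree_id, obs.date, obs.area_fruit_px,
                         obs.area_marker_px, obs.ratio, tier,
                         obs.truth_diameter_mm, pose.distance_mm, pose.angle_deg)
                    )
            for rep in (1, 2):
                cal_rows.append(
                    (row.fruit_id, row.tree_id, row.date, rep,
                     row.diameter_eq + cal_rng.normal(0.0, config.caliper_noise_sd_mm))
                )

    observations = pd.DataFrame(
        obs_rows,
        columns=["image_id", "fruit_id", "tree_id", "date", "area_fruit_px",
                 "area_marker_px", "ratio", "resolution_tier",
                 "truth_diameter_mm", "distance_mm", "angle_deg"],
    )
    caliper = pd.DataFrame(
        cal_rows, columns=["fruit_id", "tree_id", "date", "replicate_index", "value_mm"]
    )
    return {
        "psi": pd.concat(psi_frames, ignore_index=True),
        "trajectories": pd.concat(traj_frames, ignore_index=True),
        "observations": observations,
        "caliper": caliper,
    }
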
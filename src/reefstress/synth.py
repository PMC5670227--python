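"""Seeded synthetic inputs for every pipeline stage.

Temperature series combine a seasonal sinusoid, a daily (tidal-style)
cycle, an optional multi-month low-amplitude heatwave and Gaussian noise,
sampled at logger cadence. Survey data are driven by an ordered
(cumulative-logit) dose-response in accumulated Degree Heating Weeks:
colony health worsens with DHW, attenuated in habitats with a positive
tolerance shift (the intertidal, in the motivating field setting).

Everything is deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

from .scoring import (
    HEALTH_CODES,
    PointSample,
    QuadratMap,
    Region,
    SubstrateLabel,
    points_to_frame,
    score_points,
    spawn_stratified_points,
)
from .thermal import HABITATS, TemperatureSeries

__all__ = [
    "BleachingResponse",
    "ClimateScenario",
    "CommunityProfile",
    "Heatwave",
    "bleaching_probabilities",
    "gen_roving",
    "gen_survey",
    "gen_temperature",
    "health_probabilities",
]

DAYS_PER_YEAR = 365.25


class InputError(ValueError):
    pass


@dataclass
class Heatwave:
    """Anomaly envelope: linear ramp up, plateau, linear ramp down."""

    start: date
    duration_days: int
    magnitude: float
    ramp_days: int = 0

    def anomaly(self, t_days: np.ndarray) -> np.ndarray:
        """Envelope value at ``t_days`` (float days since heatwave start).

        Ramps up over ``ramp_days``, plateaus until ``duration_days``,
        then ramps down over ``ramp_days``; with no ramp the envelope is
        a plateau covering exactly ``duration_days`` days.
        """
        t = np.asarray(t_days, dtype=float)
        if self.duration_days <= 0 or self.magnitude == 0:
            return np.zeros_like(t)
        if self.ramp_days > 0:
            up = np.clip(t / self.ramp_days, 0.0, 1.0)
            down = np.clip(1.0 - (t - self.duration_days) / self.ramp_days, 0.0, 1.0)
        else:
            up = (t >= 0).astype(float)
            down = (t < self.duration_days).astype(float)
        env = np.where(
            (t >= 0) & (t < self.duration_days + self.ramp_days),
            np.minimum(up, down),
            0.0,
        )
        return self.magnitude * env


@dataclass
class ClimateScenario:
    """Site climate configuration for the temperature generator."""

    site_id: str
    mean_annual: float
    seasonal_amplitude: float = 0.0
    season_phase: int = 45  # day-of-year of the seasonal maximum
    tidal_amplitude: float = 0.0
    heatwave: Heatwave | None = None
    noise_sd: float = 0.0
    mmm: float = 25.0
    interval_minutes: int = 15
    habitat: str = "unspecified"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seasonal_amplitude < 0 or self.tidal_amplitude < 0:
            raise InputError("amplitudes must be non-negative")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be non-negative")
        if self.heatwave is not None and self.heatwave.duration_days < 0:
            raise InputError("heatwave duration must be non-negative")
        if self.habitat not in HABITATS:
            raise InputError(f"habitat {self.habitat!r} not one of {HABITATS}")


def gen_temperature(
    scenario: ClimateScenario, start: date, end: date
) -> TemperatureSeries:
    """Logger-style series sampled every ``interval_minutes`` on [start, end).

    ``T(t) = mean_annual + seasonal + tidal + heatwave + noise`` where the
    seasonal term peaks at ``season_phase`` (day of year), the tidal term
    is a 24-hour sinusoid of half-range ``tidal_amplitude`` (amplitude 3.5
    gives the 7-degree daily range of an extreme intertidal pool), and the
    heatwave term follows the scenario envelope.
    """
    if start >= end:
        raise InputError("start must precede end")
    times = pd.date_range(
        datetime.combine(start, datetime.min.time()),
        datetime.combine(end, datetime.min.time()),
        freq=f"{scenario.interval_minutes}min",
        inclusive="left",
    )
    doy = times.dayofyear.to_numpy(dtype=float)
    seasonal = scenario.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - scenario.season_phase) / DAYS_PER_YEAR
    )
    hours = (
        times.hour.to_numpy() + times.minute.to_numpy() / 60.0
    ).astype(float)
    tidal = scenario.tidal_amplitude * np.sin(2 * np.pi * hours / 24.0)
    if scenario.heatwave is not None:
        t_days = (
            (times - pd.Timestamp(scenario.heatwave.start)).total_seconds().to_numpy()
            / 86400.0
        )
        hw = scenario.heatwave.anomaly(t_days)
    else:
        hw = 0.0
    rng = np.random.default_rng(scenario.seed)
    noise = (
        rng.normal(0.0, scenario.noise_sd, size=len(times))
        if scenario.noise_sd > 0
        else 0.0
    )
    temps = scenario.mean_annual + seasonal + tidal + hw + noise
    return TemperatureSeries(
        site_id=scenario.site_id,
        habitat=scenario.habitat,
        times=times,
        temperatures=temps,
        nominal_interval=scenario.interval_minutes,
    )


@dataclass
class BleachingResponse:
    """Ordered dose-response of colony health to accumulated DHW.

    Cumulative-logit form: ``P(state >= k | dhw)`` is logistic in
    ``(dhw - (theta_k + shift)) / scale`` for k in (M, S, D), with a
    per-habitat additive tolerance shift (positive = more tolerant).
    Defaults put the severe-bleaching midpoint near 4.5 DHW for habitats
    without a shift.
    """

    theta_m: float = 2.0
    theta_s: float = 4.0
    theta_d: float = 8.0
    scale: float = 0.8
    tolerance_shift: dict[str, float] = field(
        default_factory=lambda: {"intertidal": 1.5}
    )

    def __post_init__(self) -> None:
        if not self.theta_m <= self.theta_s <= self.theta_d:
            raise InputError("thresholds must satisfy theta_m <= theta_s <= theta_d")
        if self.scale <= 0:
            raise InputError("scale must be positive")

    def shift_for(self, habitat: str) -> float:
        return self.tolerance_shift.get(habitat, 0.0)


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def bleaching_probabilities(
    dhw: float, response: BleachingResponse, habitat: str = "unspecified"
) -> pd.Series:
    """Probabilities over (UB, M, S, D) from the cumulative-logit model."""
    if dhw < 0:
        raise InputError("dhw must be non-negative")
    shift = response.shift_for(habitat)
    thetas = np.array(
        [response.theta_m, response.theta_s, response.theta_d]
    )
    ge = _logistic((dhw - (thetas + shift)) / response.scale)  # P(>=M, >=S, >=D)
    probs = np.array([1.0 - ge[0], ge[0] - ge[1], ge[1] - ge[2], ge[2]])
    return pd.Series(probs, index=list(HEALTH_CODES))


def health_probabilities(
    dhw: float,
    response: BleachingResponse,
    habitat: str = "unspecified",
    baseline: dict[str, float] | None = None,
) -> pd.Series:
    """Dose-response blended with a baseline health mix.

    The baseline supplies the no-stress state frequencies (pale colonies,
    old mortality). The dose-response exceedance curves are re-anchored
    so they vanish at dhw = 0, then combined with the baseline as
    independent risks on each ``P(state >= k)``: at dhw = 0 the mix
    reduces exactly to the baseline, and severity stays monotone in DHW.
    """
    resp = bleaching_probabilities(dhw, response, habitat)
    if baseline is None:
        return resp
    base = pd.Series(
        {c: baseline.get(c, 0.0) for c in HEALTH_CODES}, dtype=float
    )
    if base.sum() <= 0:
        raise InputError("baseline mix must have positive total")
    base = base / base.sum()

    def _ge(p) -> np.ndarray:  # P(>= M), P(>= S), P(>= D)
        return np.array([p["M"] + p["S"] + p["D"], p["S"] + p["D"], p["D"]])

    resp0 = bleaching_probabilities(0.0, response, habitat)
    r, r0, b = _ge(resp), _ge(resp0), _ge(base)
    r_adj = np.clip((r - r0) / (1.0 - r0), 0.0, 1.0)
    ge = b + (1.0 - b) * r_adj
    probs = np.array([1.0 - ge[0], ge[0] - ge[1], ge[1] - ge[2], ge[2]])
    return pd.Series(np.clip(probs, 0.0, None), index=list(HEALTH_CODES))


@dataclass
class CommunityProfile:
    """Benthic community composition for the survey generator."""

    site_id: str
    genus_abundance: dict[str, float] = field(
        default_factory=lambda: {
            "Acropora": 0.72,
            "Montipora": 0.12,
            "Pocillopora": 0.10,
            "Porites": 0.06,
        }
    )
    morphology: dict[str, str] = field(
        default_factory=lambda: {
            "Acropora": "branching",
            "Montipora": "plating",
            "Pocillopora": "branching",
            "Porites": "massive",
        }
    )
    baseline_health: dict[str, float] = field(
        default_factory=lambda: {"UB": 0.94, "M": 0.04, "S": 0.01, "D": 0.01}
    )
    coral_fraction: float = 0.5
    abiotic_mix: dict[str, float] = field(
        default_factory=lambda: {
            "algae_turf": 0.4,
            "sand_rubble": 0.4,
            "rock": 0.2,
        }
    )

    def __post_init__(self) -> None:
        tot = sum(self.genus_abundance.values())
        if abs(tot - 1.0) > 1e-9:
            raise InputError(f"genus abundances sum to {tot}, expected 1")
        if not 0.0 <= self.coral_fraction <= 1.0:
            raise InputError("coral_fraction must be in [0, 1]")
        for g in self.genus_abundance:
            if g not in self.morphology:
                raise InputError(f"no morphology for genus {g!r}")


GRID_CELLS = 10  # colony-patch grid per quadrat map (10x10 cells)


def _quadrat_map(
    profile: CommunityProfile,
    probs: pd.Series,
    quadrat_id: str,
    transect_id: str,
    rng: np.random.Generator,
) -> QuadratMap:
    """Partition the canvas into a grid of colony/abiotic patches.

    Health is assigned per patch (colony), not per point, so points
    within one colony share a state — reproducing the overdispersion of
    real quadrats.
    """
    g = GRID_CELLS
    n_cells = g * g
    n_coral = int(round(profile.coral_fraction * n_cells))
    cell_order = rng.permutation(n_cells)
    genera = list(profile.genus_abundance)
    gprobs = np.array([profile.genus_abundance[k] for k in genera])
    regions: list[Region] = []
    for rank, cell in enumerate(cell_order):
        row, col = divmod(int(cell), g)
        rect = (col / g, row / g, (col + 1) / g, (row + 1) / g)
        if rank < n_coral:
            genus = genera[rng.choice(len(genera), p=gprobs)]
            health = HEALTH_CODES[rng.choice(4, p=probs.to_numpy())]
            label = SubstrateLabel(
                "hard_coral",
                genus=genus,
                morphology=profile.morphology[genus],
                health=health,
            )
        else:
            cats = list(profile.abiotic_mix)
            w = np.array([profile.abiotic_mix[c] for c in cats], dtype=float)
            label = SubstrateLabel(str(cats[rng.choice(len(cats), p=w / w.sum())]))
        regions.append(Region(label=label, rect=rect))
    return QuadratMap(quadrat_id=quadrat_id, transect_id=transect_id, regions=regions)


def gen_survey(
    profile: CommunityProfile,
    response: BleachingResponse,
    dhw_at_survey: float,
    n_transects: int,
    quadrats_per_transect: int,
    points_per_quadrat: int = 100,
    seed=None,
    habitat: str = "unspecified",
    site: str | None = None,
    survey_date: str = "",
) -> tuple[list[QuadratMap], pd.DataFrame]:
    """Generate quadrat maps and run the point-count scoring end to end.

    Returns the maps and a point-score table in the standard CSV layout.
    Colony health states are drawn from the DHW dose-response blended
    with the profile's baseline mix; fully reproducible given ``seed``.
    """
    if n_transects < 1:
        raise InputError("n_transects must be >= 1")
    if quadrats_per_transect < 1:
        raise InputError("quadrats_per_transect must be >= 1")
    if profile.coral_fraction == 0:
        import warnings

        warnings.warn("coral_fraction is 0: generating all-abiotic maps", stacklevel=2)
    rng = np.random.default_rng(seed)
    probs = health_probabilities(
        dhw_at_survey, response, habitat, profile.baseline_health
    )
    site = site if site is not None else profile.site_id
    scored = []
    maps: list[QuadratMap] = []
    for t in range(1, n_transects + 1):
        tid = f"T{t}"
        for q in range(1, quadrats_per_transect + 1):
            qid = f"{tid}Q{q}"
            qmap = _quadrat_map(profile, probs, qid, tid, rng)
            sample = spawn_stratified_points(points_per_quadrat, rng)
            labels = qmap.labels_at(sample.points)
            maps.append(qmap)
            scored.append((qmap, sample, labels))
    points = points_to_frame(scored, site=site, date=survey_date)
    return maps, points


def gen_roving(
    genus: str,
    response: BleachingResponse,
    dhw: float,
    n_colonies: int,
    seed=None,
    habitat: str = "unspecified",
    baseline: dict[str, float] | None = None,
    diameter_range: tuple[float, float] = (2.0, 150.0),
    site: str = "",
    location: str = "",
    survey_date: str = "",
) -> pd.DataFrame:
    """Roving-diver colony list in the standard CSV layout."""
    if n_colonies < 1:
        raise InputError("n_colonies must be >= 1")
    rng = np.random.default_rng(seed)
    probs = health_probabilities(dhw, response, habitat, baseline)
    states = [HEALTH_CODES[i] for i in rng.choice(4, size=n_colonies, p=probs.to_numpy())]
    lo, hi = diameter_range
    diam = np.round(rng.uniform(lo, hi, size=n_colonies), 1)
    return pd.DataFrame(
        {
            "site": site,
            "location": location,
            "date": survey_date,
            "colony_id": [f"C{i + 1:03d}" for i in range(n_colonies)],
            "diameter_cm": diam,
            "health": states,
        }
    )
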
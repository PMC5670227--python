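"""Benthic survey scoring: photoquadrat point counts and roving tallies.

A photoquadrat is modelled as a labelled map of the unit square (standing
in for a 50x50 cm photograph): non-overlapping rectangular regions, each
carrying a substrate label. Scoring spawns stratified random points over
the canvas, assigns each point the label of its containing region, and
aggregates tallies to percent cover, transect means and site-level
mean +/- SE with transects as the replicate unit.

Roving-diver surveys (timed swims scoring every encountered colony) are
tallied per health category.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "HEALTH_CODES",
    "MORPHOLOGIES",
    "HealthTally",
    "PointSample",
    "QuadratMap",
    "QuadratScore",
    "Region",
    "SubstrateLabel",
    "abundance_from_points",
    "percent_cover",
    "points_to_frame",
    "roving_tally",
    "score_points",
    "spawn_stratified_points",
    "transect_summary",
]

CATEGORIES = (
    "hard_coral",
    "soft_coral",
    "algae_turf",
    "sand_rubble",
    "rock",
    "unknown",
)
MORPHOLOGIES = ("branching", "plating", "encrusting", "massive")
#: Health codes: unbleached, moderately bleached (<50% or pale),
#: severely bleached (>50%), dead.
HEALTH_CODES = ("UB", "M", "S", "D")


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class SubstrateLabel:
    """Label for one map region / scored point.

    ``genus``, ``morphology`` and ``health`` are required for hard coral
    (genus ``"indet"`` allowed) and must be absent otherwise.
    """

    category: str
    genus: str | None = None
    morphology: str | None = None
    health: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise InputError(f"unknown category {self.category!r}")
        if self.category == "hard_coral":
            if not self.genus:
                raise InputError("hard_coral label requires a genus")
            if self.morphology not in MORPHOLOGIES:
                raise InputError(
                    f"hard_coral morphology {self.morphology!r} "
                    f"not one of {MORPHOLOGIES}"
                )
            if self.health not in HEALTH_CODES:
                raise InputError(
                    f"hard_coral health {self.health!r} not one of {HEALTH_CODES}"
                )
        elif self.genus or self.morphology or self.health:
            raise InputError(
                f"{self.category} label must not carry genus/morphology/health"
            )

    @property
    def genus_health(self) -> str:
        """Class key used in abundance matrices, e.g. ``Acropora_S``."""
        if self.category != "hard_coral":
            raise InputError("genus_health only defined for hard coral")
        return f"{self.genus}_{self.health}"


UNKNOWN = SubstrateLabel("unknown")


@dataclass(frozen=True)
class Region:
    """Axis-aligned rectangle ``(x0, y0, x1, y1)`` with one label."""

    label: SubstrateLabel
    rect: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.rect
        if not (x0 < x1 and y0 < y1):
            raise InputError(f"degenerate rect {self.rect}")

    @property
    def area(self) -> float:
        x0, y0, x1, y1 = self.rect
        return (x1 - x0) * (y1 - y0)


@dataclass
class QuadratMap:
    """Labelled substrate map of the unit-square canvas.

    Regions must jointly cover the canvas without overlap; points falling
    on shared boundaries are resolved to the first matching region in
    list order (deterministic tie-break).
    """

    quadrat_id: str
    transect_id: str
    regions: list[Region]

    def __post_init__(self) -> None:
        if not self.regions:
            raise InputError("quadrat map has no regions")

    def _rect_array(self) -> np.ndarray:
        return np.array([r.rect for r in self.regions], dtype=float)

    def labels_at(self, points: np.ndarray) -> list[SubstrateLabel]:
        """Label for each (x, y) row; first containing region wins."""
        pts = np.asarray(points, dtype=float)
        rects = self._rect_array()
        inside = (
            (pts[:, None, 0] >= rects[None, :, 0])
            & (pts[:, None, 0] <= rects[None, :, 2])
            & (pts[:, None, 1] >= rects[None, :, 1])
            & (pts[:, None, 1] <= rects[None, :, 3])
        )
        out: list[SubstrateLabel] = []
        any_hit = inside.any(axis=1)
        first = inside.argmax(axis=1)
        for hit, idx, pt in zip(any_hit, first, pts):
            if hit:
                out.append(self.regions[idx].label)
            else:
                warnings.warn(
                    f"quadrat {self.quadrat_id}: point {tuple(pt)} outside "
                    "all regions; scored as unknown",
                    stacklevel=2,
                )
                out.append(UNKNOWN)
        return out

    def to_dict(self) -> dict:
        return {
            "quadrat_id": self.quadrat_id,
            "transect_id": self.transect_id,
            "regions": [
                {
                    "rect": list(r.rect),
                    "category": r.label.category,
                    "genus": r.label.genus,
                    "morphology": r.label.morphology,
                    "health": r.label.health,
                }
                for r in self.regions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuadratMap":
        regions = [
            Region(
                label=SubstrateLabel(
                    category=r["category"],
                    genus=r.get("genus"),
                    morphology=r.get("morphology"),
                    health=r.get("health"),
                ),
                rect=tuple(r["rect"]),
            )
            for r in d["regions"]
        ]
        return cls(d["quadrat_id"], d["transect_id"], regions)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "QuadratMap":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class PointSample:
    """Stratified random points over the unit square."""

    points: np.ndarray
    subcell_index: np.ndarray
    grid_size: int
    seed: int | None = None
    quadrat_id: str | None = None

    @property
    def n(self) -> int:
        return len(self.points)


def spawn_stratified_points(n: int, seed=None) -> PointSample:
    """Spawn ``n`` points: one uniform per sub-cell, remainder uniform.

    The canvas is divided into a ``g x g`` grid with ``g = floor(sqrt(n))``;
    each sub-cell receives exactly one uniform point (guaranteeing every
    cell is occupied), and the remaining ``n - g**2`` points are uniform
    over the whole canvas. Deterministic given ``seed``.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    g = int(math.isqrt(n))
    cells = np.arange(g * g)
    cx, cy = cells % g, cells // g
    u = rng.random((g * g, 2))
    strat = np.column_stack([(cx + u[:, 0]) / g, (cy + u[:, 1]) / g])
    free = rng.random((n - g * g, 2))
    pts = np.vstack([strat, free])
    col = np.minimum((pts[:, 0] * g).astype(int), g - 1)
    row = np.minimum((pts[:, 1] * g).astype(int), g - 1)
    return PointSample(
        points=pts,
        subcell_index=row * g + col,
        grid_size=g,
        seed=seed if isinstance(seed, int) else None,
    )


@dataclass
class QuadratScore:
    """Point-count tallies for one quadrat."""

    quadrat_id: str
    transect_id: str
    tally: dict[SubstrateLabel, int]
    n_points: int

    def __post_init__(self) -> None:
        if sum(self.tally.values()) != self.n_points:
            raise InputError("tallies must sum to n_points")

    def category_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for label, c in self.tally.items():
            out[label.category] = out.get(label.category, 0) + c
        return out

    def hard_coral_counts(self, grouping: str = "genus_health") -> dict[str, int]:
        out: dict[str, int] = {}
        for label, c in self.tally.items():
            if label.category != "hard_coral":
                continue
            key = label.genus_health if grouping == "genus_health" else label.health
            out[key] = out.get(key, 0) + c
        return out


def score_points(qmap: QuadratMap, sample: PointSample) -> QuadratScore:
    """Assign each sampled point the label of its containing region."""
    pts = np.asarray(sample.points)
    if ((pts < 0) | (pts > 1)).any():
        raise InputError("sample points must lie in the unit square")
    tally: dict[SubstrateLabel, int] = {}
    for label in qmap.labels_at(pts):
        tally[label] = tally.get(label, 0) + 1
    return QuadratScore(
        quadrat_id=qmap.quadrat_id,
        transect_id=qmap.transect_id,
        tally=tally,
        n_points=sample.n,
    )


def percent_cover(
    score: QuadratScore,
    basis: str = "all_points",
    drop_unknown: bool = False,
    grouping: str = "genus_health",
) -> pd.Series:
    """Percent cover on the 0-100 scale.

    ``basis='all_points'`` gives substrate composition over categories;
    ``basis='hard_coral_points'`` gives the genus-x-health (or, with
    ``grouping='health'``, health-only) composition of the scored coral
    points. ``drop_unknown`` renormalises after removing unknown points
    (only meaningful for the all-points basis; unknowns never enter the
    coral denominator). A zero denominator yields an empty series flagged
    ``attrs['no_coral']`` rather than a division error.
    """
    if score.n_points <= 0:
        raise InputError("score has no points")
    if basis == "all_points":
        counts = score.category_counts()
        if drop_unknown:
            counts.pop("unknown", None)
        denom = sum(counts.values())
        if denom == 0:
            out = pd.Series(dtype=float)
            out.attrs["no_coral"] = True
            return out
        out = pd.Series(
            {k: 100.0 * v / denom for k, v in counts.items()}, dtype=float
        )
    elif basis == "hard_coral_points":
        counts = score.hard_coral_counts(grouping=grouping)
        denom = sum(counts.values())
        if denom == 0:
            out = pd.Series(dtype=float)
            out.attrs["no_coral"] = True
            return out
        out = pd.Series(
            {k: 100.0 * v / denom for k, v in counts.items()}, dtype=float
        )
    else:
        raise InputError(f"unknown basis {basis!r}")
    return out.sort_index()


def transect_summary(
    quadrat_pcts: pd.DataFrame,
    transect_col: str = "transect_id",
    group_cols: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Mean +/- SE per class, with transects as the replicate unit.

    ``quadrat_pcts`` holds one row per quadrat: the transect id, optional
    grouping columns (site, time, ...), and percent columns per class.
    Quadrats are first averaged within each transect, then the mean and
    standard error (sample SD / sqrt(n_transects)) are taken across
    transects. With a single transect the SE is undefined (NaN).
    """
    meta = [c for c in (*group_cols, transect_col) if c in quadrat_pcts.columns]
    if transect_col not in meta:
        raise InputError(f"missing transect column {transect_col!r}")
    value_cols = [c for c in quadrat_pcts.columns if c not in meta]
    per_transect = quadrat_pcts.groupby(meta, sort=True)[value_cols].mean()

    def _agg(df: pd.DataFrame) -> pd.DataFrame:
        n = len(df)
        mean = df.mean()
        se = df.std(ddof=1) / math.sqrt(n) if n > 1 else pd.Series(
            np.nan, index=df.columns
        )
        return pd.DataFrame({"mean": mean, "se": se, "n_transects": n})

    if group_cols:
        lvl = list(group_cols) if len(group_cols) > 1 else group_cols[0]
        parts = {
            key: _agg(sub) for key, sub in per_transect.groupby(level=lvl)
        }
        out = pd.concat(parts, names=[*group_cols, "class"])
    else:
        out = _agg(per_transect)
        out.index.name = "class"
    return out


@dataclass
class HealthTally:
    """Colony counts per health category for one roving survey."""

    survey_id: str
    counts: dict[str, int] = field(default_factory=dict)
    genus: str | None = None

    def __post_init__(self) -> None:
        for code, c in self.counts.items():
            if code not in HEALTH_CODES:
                raise InputError(f"unknown health code {code!r}")
            if c < 0:
                raise InputError(f"negative count for {code!r}")

    @property
    def n_colonies(self) -> int:
        return sum(self.counts.values())

    def percentages(self) -> pd.Series:
        n = self.n_colonies
        if n == 0:
            raise InputError("tally is empty")
        return pd.Series(
            {code: 100.0 * self.counts.get(code, 0) / n for code in HEALTH_CODES}
        )

    def __add__(self, other: "HealthTally") -> "HealthTally":
        counts = dict(self.counts)
        for code, c in other.counts.items():
            counts[code] = counts.get(code, 0) + c
        genus = self.genus if self.genus == other.genus else None
        return HealthTally(
            survey_id=f"{self.survey_id}+{other.survey_id}",
            counts=counts,
            genus=genus,
        )


def roving_tally(records, survey_id: str = "", genus: str | None = None) -> HealthTally:
    """Tally colony health codes from a roving-diver survey.

    ``records`` is an iterable of health codes or a DataFrame with a
    ``health`` column. Unrecognised codes raise an error naming the
    offending record.
    """
    if isinstance(records, pd.DataFrame):
        if "health" not in records.columns:
            raise InputError("roving records need a 'health' column")
        codes = list(records["health"])
    else:
        codes = list(records)
    if not codes:
        raise InputError("roving survey has no colonies")
    counts: dict[str, int] = {}
    for i, code in enumerate(codes):
        if code not in HEALTH_CODES:
            raise InputError(
                f"record {i}: unrecognised health code {code!r} "
                f"(expected one of {HEALTH_CODES})"
            )
        counts[code] = counts.get(code, 0) + 1
    return HealthTally(survey_id=survey_id, counts=counts, genus=genus)


# ---------------------------------------------------------------------------
# point-score table <-> abundance matrix plumbing

POINT_COLUMNS = (
    "quadrat_id",
    "transect_id",
    "site",
    "date",
    "point_index",
    "category",
    "genus",
    "morphology",
    "health",
)


def points_to_frame(
    scored: list[tuple[QuadratMap, PointSample, list[SubstrateLabel]]],
    site: str = "",
    date: str = "",
) -> pd.DataFrame:
    """Flatten per-point labels into the point-score CSV layout."""
    rows = []
    for qmap, sample, labels in scored:
        for i, label in enumerate(labels):
            rows.append(
                (
                    qmap.quadrat_id,
                    qmap.transect_id,
                    site,
                    date,
                    i,
                    label.category,
                    label.genus or "",
                    label.morphology or "",
                    label.health or "",
                )
            )
    return pd.DataFrame(rows, columns=list(POINT_COLUMNS))


def abundance_from_points(
    points: pd.DataFrame,
    grouping: str = "genus_health",
    meta_cols: tuple[str, ...] = ("site", "date"),
) -> pd.DataFrame:
    """Transect-level percent-abundance table from a point-score table.

    Hard-coral points are pooled over the quadrats of each transect and
    expressed as percentages of the transect's coral points, one column
    per genus-x-health (or health) class. Returned frame carries the meta
    columns followed by the class percentages; rows are transects.
    """
    required = {"transect_id", "category", "genus", "health"}
    missing = required - set(points.columns)
    if missing:
        raise InputError(f"point table missing columns {sorted(missing)}")
    coral = points[points["category"] == "hard_coral"].copy()
    if coral.empty:
        raise InputError("no hard-coral points in table")
    if grouping == "genus_health":
        coral["class"] = coral["genus"].astype(str) + "_" + coral["health"].astype(str)
    elif grouping == "health":
        coral["class"] = coral["health"].astype(str)
    else:
        raise InputError(f"unknown grouping {grouping!r}")
    keys = [c for c in meta_cols if c in points.columns] + ["transect_id"]
    counts = (
        coral.groupby(keys + ["class"], sort=True).size().unstack(fill_value=0)
    )
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return pct.reset_index()
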
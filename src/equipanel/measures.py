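"""Equity statistics: Lorenz curves, Gini coefficients, agglomeration degrees.

Two complementary families of measures are implemented.

**Lorenz/Gini.**  Units (provinces) are sorted ascending by per-base density
(resource per person, or per km²), cumulative shares are accumulated into a
Lorenz curve, and the Gini coefficient is one minus twice the trapezoidal
area under the curve:

    G = 1 - sum_i (x_{i+1} - x_i) (y_{i+1} + y_i)

with x the cumulative base share, y the cumulative resource share, and the
origin (0, 0) prepended.  G = 0 is perfect equality; conventional bands flag
G > 0.4 and G > 0.5 as warning lines.

**Agglomeration degree.**  The health-resource agglomeration degree (HRAD)
of a unit is its share of the resource divided by its share of land area —
equivalently its per-km² density over the whole's per-km² density:

    HRAD_i = (HR_i / HR_n) / (A_i / A_n)

The population agglomeration degree (PAD) is the same with population in
place of the resource.  HRAD_i = 1 means geographically fair allocation;
HRAD_i / PAD_i = 1 means demographically fair allocation (the ratio equals
the unit's per-capita density over the whole's per-capita density).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .panel import ResourcePanel

_TOL = 1e-12


class DegenerateInputError(ValueError):
    """All resource amounts are zero: the Lorenz curve is undefined."""


class InsufficientUnitsError(ValueError):
    """A within-group Gini needs at least two units."""


# ---------------------------------------------------------------------------
# Lorenz / Gini


@dataclass(frozen=True)
class LorenzCurve:
    """Ordered cumulative-share points of a Lorenz curve.

    ``x`` holds cumulative shares of the base variable (population or area),
    ``y`` cumulative shares of the resource; both start at 0 and end at 1,
    with units sorted ascending by per-base density so the curve lies on or
    below the diagonal.
    """

    x: np.ndarray
    y: np.ndarray
    base: str = "population"

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
            raise ValueError("Lorenz curve needs matching 1-d x/y with >= 2 points")
        if abs(x[0]) > _TOL or abs(y[0]) > _TOL:
            raise ValueError("Lorenz curve must start at (0, 0)")
        if abs(x[-1] - 1) > _TOL or abs(y[-1] - 1) > _TOL:
            raise ValueError("Lorenz curve must end at (1, 1)")
        if np.any(np.diff(x) < -_TOL) or np.any(np.diff(y) < -_TOL):
            raise ValueError("cumulative shares must be non-decreasing")
        if np.any(y > x + 1e-9):
            raise ValueError(
                "curve rises above the diagonal: units are not sorted "
                "ascending by per-base density"
            )


def lorenz(units: Iterable[tuple[float, float]], base: str = "population") -> LorenzCurve:
    """Build a Lorenz curve from (base_amount, resource_amount) pairs.

    Units are sorted ascending by resource/base density (ties kept in input
    order), shares are cumulated, and the origin is prepended.
    """
    pairs = list(units)
    if not pairs:
        raise ValueError("need at least one unit")
    b = np.array([p[0] for p in pairs], dtype=float)
    r = np.array([p[1] for p in pairs], dtype=float)
    if np.any(b <= 0):
        raise ValueError("base amounts must be > 0")
    if np.any(r < 0):
        raise ValueError("resource amounts must be >= 0")
    if not np.any(r > 0):
        raise DegenerateInputError("all resource amounts are zero")
    order = np.argsort(r / b, kind="stable")
    x = np.concatenate([[0.0], np.cumsum(b[order]) / b.sum()])
    y = np.concatenate([[0.0], np.cumsum(r[order]) / r.sum()])
    x[-1] = 1.0
    y[-1] = 1.0
    return LorenzCurve(x=x, y=y, base=base)


def gini(curve: LorenzCurve) -> float:
    """Gini coefficient of a Lorenz curve (trapezoid rule).

    One minus twice the area under the curve; 0 for the diagonal, approaching
    1 - (smallest base share) when a single unit holds everything.
    """
    g = 1.0 - float(np.sum(np.diff(curve.x) * (curve.y[1:] + curve.y[:-1])))
    return max(g, 0.0) if g > -1e-12 else g


def _group_gini(panel: ResourcePanel, region: str | None, year: int,
                resource: str, base_col: str, base_label: str) -> float:
    panel.require_resource(resource)
    df = panel.year_slice(year, region=region)
    if len(df) < 2:
        raise InsufficientUnitsError(
            f"Gini over {region or 'national'} needs >= 2 provinces, found {len(df)}"
        )
    counts = df[resource]
    if counts.isna().any():
        raise KeyError(f"resource {resource!r} missing for some provinces in {year}")
    curve = lorenz(
        zip(df[base_col].astype(float), counts.astype(float)), base=base_label
    )
    return gini(curve)


def gini_by_population(panel: ResourcePanel, region: str | None, year: int,
                       resource: str) -> float:
    """Within-region (or national, ``region=None``) Gini of a resource across
    provinces with population as the base variable."""
    return _group_gini(panel, region, year, resource, "population", "population")


def gini_by_area(panel: ResourcePanel, region: str | None, year: int,
                 resource: str) -> float:
    """As :func:`gini_by_population` with land area as the base variable."""
    return _group_gini(panel, region, year, resource, "area_km2", "area")


# ---------------------------------------------------------------------------
# classification


@dataclass(frozen=True)
class EquityLabel:
    """A qualitative equity band together with the value it classifies."""

    label: str
    value: float


#: Gini bands; 0.4 and 0.5 are the conventional warning lines.
GINI_BANDS = (
    (0.2, "absolute equality"),
    (0.3, "relative equality"),
    (0.4, "reasonable equity"),
    (0.5, "relative inequality"),
    (1.0, "serious inequality"),
)


def classify_gini(g: float) -> EquityLabel:
    """Map a Gini value onto the conventional equity bands.

    [0, 0.2] absolute equality; (0.2, 0.3] relative equality; (0.3, 0.4]
    reasonable equity; (0.4, 0.5] relative inequality; (0.5, 1] serious
    inequality.
    """
    if not 0.0 <= g <= 1.0:
        raise ValueError(f"Gini must lie in [0, 1], got {g}")
    for upper, label in GINI_BANDS:
        if g <= upper:
            return EquityLabel(label=label, value=g)
    raise AssertionError("unreachable: bands cover [0, 1]")


# ---------------------------------------------------------------------------
# agglomeration degrees


def hrad(resource_i: float, area_i: float, resource_total: float,
         area_total: float) -> float:
    """Health-resource agglomeration degree of one unit.

    Share of the resource over share of land area; equivalently the unit's
    per-km² density over the whole's.  1 = geographically fair.
    """
    if area_i <= 0 or area_total <= 0 or resource_total <= 0:
        raise ZeroDivisionError("hrad needs positive areas and resource total")
    return (resource_i / resource_total) / (area_i / area_total)


def pad(pop_i: float, area_i: float, pop_total: float, area_total: float) -> float:
    """Population agglomeration degree: as :func:`hrad` with population."""
    if area_i <= 0 or area_total <= 0 or pop_total <= 0:
        raise ZeroDivisionError("pad needs positive areas and population total")
    return (pop_i / pop_total) / (area_i / area_total)


def hrad_pad_ratio(h: float, p: float) -> float:
    """HRAD over PAD: the unit's per-capita density relative to the whole's.

    1 = demographically fair allocation.
    """
    if p == 0:
        raise ZeroDivisionError("ratio undefined for PAD = 0")
    return h / p


@dataclass(frozen=True)
class AgglomerationRow:
    """HRAD, PAD and their ratio for one unit (province or region)."""

    unit: str
    hrad: float
    pad: float
    ratio: float

    def __post_init__(self) -> None:
        if self.hrad < 0 or self.pad <= 0:
            raise ValueError("need HRAD >= 0 and PAD > 0")
        if abs(self.ratio - self.hrad / self.pad) > _TOL * max(1.0, abs(self.ratio)):
            raise ValueError("ratio field must equal hrad / pad")

    @classmethod
    def build(cls, unit: str, h: float, p: float) -> "AgglomerationRow":
        return cls(unit=unit, hrad=h, pad=p, ratio=hrad_pad_ratio(h, p))


def classify_agglomeration(
    row: AgglomerationRow, tol: float = 0.05
) -> tuple[EquityLabel, EquityLabel]:
    """Qualitative (geographic, demographic) fairness labels for one unit.

    Geographic: HRAD against 1 ± tol; demographic: HRAD/PAD against 1 ± tol.
    Exact unity is the theoretical fairness point; the tolerance makes the
    bands usable on real data, where it is never hit exactly.
    """
    if tol < 0:
        raise ValueError("tolerance must be >= 0")

    def band(v: float) -> str:
        if v < 1.0 - tol:
            return "under-served"
        if v > 1.0 + tol:
            return "over-concentrated"
        return "fair"

    return (
        EquityLabel(label=band(row.hrad), value=row.hrad),
        EquityLabel(label=band(row.ratio), value=row.ratio),
    )


# ---------------------------------------------------------------------------
# densities and growth


def density(count: float, base: float, per: float = 10_000.0) -> float:
    """Resource density per ``per`` units of base (persons or km²)."""
    if base <= 0:
        raise ZeroDivisionError("density needs a positive base")
    if count < 0:
        raise ValueError("count must be >= 0")
    return per * count / base


def avg_annual_growth(series: Sequence[float], mode: str = "geometric") -> float:
    """Average annual growth rate of an ordered yearly series, in % per year.

    ``geometric`` (default) is the endpoint CAGR,
    ``100 * ((last/first)^(1/(k-1)) - 1)`` for k values; ``arithmetic`` is
    the mean of the year-on-year percentage changes.  The two agree to first
    order when yearly changes are small.
    """
    vals = np.asarray(list(series), dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least two yearly values")
    if vals[0] <= 0:
        raise ValueError("first value must be > 0")
    if mode == "geometric":
        if vals[-1] < 0:
            raise ValueError("last value must be >= 0")
        return 100.0 * ((vals[-1] / vals[0]) ** (1.0 / (len(vals) - 1)) - 1.0)
    if mode == "arithmetic":
        if np.any(vals[:-1] <= 0):
            raise ValueError("arithmetic mode needs positive intermediate values")
        return float(np.mean(100.0 * (vals[1:] / vals[:-1] - 1.0)))
    raise ValueError(f"unknown growth mode {mode!r}")
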
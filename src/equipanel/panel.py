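"""Province × year resource panels: domain types, CSV I/O, validation.

The central container is :class:`ResourcePanel`: a rectangular grid of
(province, year) rows carrying population, land area and up to four health
resource counts (institutions, beds, health technicians, practicing
(assistant) physicians), together with a :class:`~equipanel.regions.RegionScheme`
assigning each province to the eastern/central/western macro-region.

Two CSV layouts are accepted for the panel file (auto-detected from the
header): long form ``province,year,resource,count`` and wide form
``province,year,institutions,beds,technicians,physicians`` (any subset of the
resource columns).  The province table supplies land area, year-wise
population and optionally region membership, again in wide
(``province,region,area_km2,population_<year>,...``) or long
(``province,year,population`` + static ``area_km2``) form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import RegionMappingError, RegionScheme, canonical_province, default_scheme

#: Resource columns in the paper-table order: physical before human resources.
RESOURCES = ("institutions", "beds", "technicians", "physicians")

DEFAULT_STUDY_WINDOW = (2009, 2018)


class PanelSchemaError(ValueError):
    """A required column is missing or a file layout cannot be recognised."""


class PanelIntegrityError(ValueError):
    """Duplicate keys, non-rectangular grids or out-of-range values."""


@dataclass(frozen=True)
class ProvinceYearRecord:
    """One province's resources, population and area for one year.

    Counts are non-negative; population and area strictly positive; the year
    must fall inside the study window.  ``None`` marks a resource the panel
    does not carry.
    """

    province: str
    year: int
    population: float
    area_km2: float
    institutions: int | None = None
    beds: int | None = None
    technicians: int | None = None
    physicians: int | None = None
    study_window: tuple[int, int] = DEFAULT_STUDY_WINDOW

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise PanelIntegrityError(
                f"{self.province} {self.year}: population must be > 0, got {self.population}"
            )
        if self.area_km2 <= 0:
            raise PanelIntegrityError(
                f"{self.province} {self.year}: area must be > 0, got {self.area_km2}"
            )
        lo, hi = self.study_window
        if not lo <= self.year <= hi:
            raise PanelIntegrityError(
                f"{self.province}: year {self.year} outside study window {lo}-{hi}"
            )
        for res in RESOURCES:
            v = getattr(self, res)
            if v is not None and v < 0:
                raise PanelIntegrityError(
                    f"{self.province} {self.year}: {res} must be >= 0, got {v}"
                )

    def resource(self, name: str) -> int | None:
        if name not in RESOURCES:
            raise KeyError(f"unknown resource {name!r}; expected one of {RESOURCES}")
        return getattr(self, name)


class ResourcePanel:
    """A validated rectangular province × year panel with a region scheme.

    Parameters
    ----------
    frame
        One row per (province, year) with columns ``province``, ``year``,
        ``population``, ``area_km2`` and any subset of ``RESOURCES``.  Extra
        columns are preserved untouched (and re-emitted by :func:`write_panel`).
    scheme
        Region partition covering every province in the frame.
    study_window
        Inclusive year range the panel is allowed to span.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        scheme: RegionScheme | None = None,
        study_window: tuple[int, int] = DEFAULT_STUDY_WINDOW,
    ) -> None:
        scheme = scheme if scheme is not None else default_scheme()
        df = frame.copy()
        required = {"province", "year", "population", "area_km2"}
        missing = required - set(df.columns)
        if missing:
            raise PanelSchemaError(f"panel frame missing required columns: {sorted(missing)}")

        df["province"] = df["province"].map(canonical_province)
        df["year"] = df["year"].astype(int)
        for res in RESOURCES:
            if res in df.columns:
                vals = pd.to_numeric(df[res], errors="raise")
                nonnull = vals.dropna()
                # counts are integers in real yearbooks; keep exact floats only
                # when a generator deliberately produced un-rounded counts
                if len(nonnull) == 0 or (nonnull == nonnull.round()).all():
                    df[res] = vals.round().astype("Int64")
                else:
                    df[res] = vals.astype(float)

        dup = df.duplicated(subset=["province", "year"])
        if dup.any():
            first = df.loc[dup, ["province", "year"]].iloc[0]
            raise PanelIntegrityError(
                f"duplicate (province, year) pair: ({first['province']!r}, {int(first['year'])})"
            )
        for prov in df["province"].unique():
            if prov not in scheme:
                raise RegionMappingError(f"province {prov!r} not in region scheme")
        if (df["population"] <= 0).any():
            bad = df.loc[df["population"] <= 0].iloc[0]
            raise PanelIntegrityError(
                f"non-positive population for {bad['province']} {int(bad['year'])}"
            )
        if (df["area_km2"] <= 0).any():
            bad = df.loc[df["area_km2"] <= 0].iloc[0]
            raise PanelIntegrityError(
                f"non-positive area for {bad['province']} {int(bad['year'])}"
            )
        lo, hi = study_window
        if ((df["year"] < lo) | (df["year"] > hi)).any():
            bad = int(df.loc[(df["year"] < lo) | (df["year"] > hi), "year"].iloc[0])
            raise PanelIntegrityError(f"year {bad} outside study window {lo}-{hi}")
        for res in RESOURCES:
            if res in df.columns and (df[res].dropna() < 0).any():
                raise PanelIntegrityError(f"negative {res} count in panel")

        provinces = df["province"].unique()
        years = np.sort(df["year"].unique())
        if len(df) != len(provinces) * len(years):
            raise PanelIntegrityError(
                "panel is not a rectangular province × year grid: "
                f"{len(df)} rows for {len(provinces)} provinces × {len(years)} years"
            )
        # per-province area must not vary across years (land is fixed)
        if df.groupby("province")["area_km2"].nunique().gt(1).any():
            raise PanelIntegrityError("area_km2 varies across years for some province")

        self._df = df.sort_values(["year", "province"], kind="stable").reset_index(drop=True)
        self.scheme = scheme
        self.study_window = study_window

    # -- introspection -------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying tidy frame (copy)."""
        return self._df.copy()

    @property
    def provinces(self) -> tuple[str, ...]:
        present = set(self._df["province"])
        return tuple(p for p in self.scheme.provinces() if p in present)

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(int(y) for y in np.sort(self._df["year"].unique()))

    @property
    def resources(self) -> tuple[str, ...]:
        return tuple(r for r in RESOURCES if r in self._df.columns)

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResourcePanel):
            return NotImplemented
        a = self._df.sort_index(axis=1)
        b = other._df.sort_index(axis=1)
        return a.equals(b) and self.scheme.mapping == other.scheme.mapping

    def records(self) -> Iterator[ProvinceYearRecord]:
        for row in self._df.itertuples(index=False):
            kwargs = {}
            for res in self.resources:
                v = getattr(row, res)
                if pd.isna(v):
                    kwargs[res] = None
                else:
                    kwargs[res] = int(v) if float(v).is_integer() else float(v)
            yield ProvinceYearRecord(
                province=row.province,
                year=int(row.year),
                population=float(row.population),
                area_km2=float(row.area_km2),
                study_window=self.study_window,
                **kwargs,
            )

    # -- slicing -------------------------------------------------------

    def year_slice(self, year: int, region: str | None = None) -> pd.DataFrame:
        """Rows of one year, optionally restricted to a region, in canonical
        province order."""
        if year not in self.years:
            raise KeyError(f"year {year} not in panel (has {self.years})")
        df = self._df[self._df["year"] == year].copy()
        df["region"] = df["province"].map(self.scheme.region_of)
        if region is not None:
            df = df[df["region"] == region]
        order = {p: i for i, p in enumerate(self.scheme.provinces())}
        return (
            df.assign(_o=df["province"].map(order))
            .sort_values("_o", kind="stable")
            .drop(columns="_o")
            .reset_index(drop=True)
        )

    def require_resource(self, resource: str) -> None:
        if resource not in RESOURCES:
            raise KeyError(f"unknown resource {resource!r}; expected one of {RESOURCES}")
        if resource not in self._df.columns:
            raise KeyError(f"panel does not carry resource {resource!r}")


# ---------------------------------------------------------------------------
# aggregation


def regional_totals(panel: ResourcePanel, year: int, resource: str) -> dict[str, int]:
    """Sum a resource over each region for one year, plus the national total.

    Returns a mapping with one key per region label and a ``"national"`` key;
    integer arithmetic throughout, so the regional values sum exactly to the
    national one.
    """
    panel.require_resource(resource)
    df = panel.year_slice(year)
    counts = df[resource]
    if counts.isna().any():
        missing = df.loc[counts.isna(), "province"].tolist()
        raise PanelIntegrityError(
            f"resource {resource!r} missing for {missing} in {year}"
        )
    out = {region: 0 for region in ("eastern", "central", "western")}
    for region, total in df.groupby("region")[resource].sum().items():
        out[str(region)] = int(total)
    out["national"] = sum(out[r] for r in ("eastern", "central", "western"))
    return out


def regional_share(part: float, whole: float) -> float:
    """Percentage share ``100 * part / whole`` (e.g. a region's share of the
    national resource stock).  Displayed to 2 decimals in report tables."""
    if whole == 0:
        raise ZeroDivisionError("share undefined for a zero total")
    if whole < 0 or part < 0:
        raise ValueError("shares require part >= 0 and whole > 0")
    return 100.0 * part / whole


# ---------------------------------------------------------------------------
# CSV I/O


def _float_repr(v: float) -> str:
    """Shortest decimal that round-trips the double exactly."""
    return repr(float(v))


def _read_csv(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    return pd.read_csv(path, float_precision="round_trip")


def _panel_counts_frame(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    """Normalise a panel CSV (long or wide) to wide resource columns."""
    cols = set(df.columns)
    if {"province", "year"} - cols:
        raise PanelSchemaError(
            f"{path}: panel file must have 'province' and 'year' columns, got {sorted(cols)}"
        )
    if "resource" in cols and "count" in cols:  # long form
        unknown = set(df["resource"]) - set(RESOURCES)
        if unknown:
            raise PanelSchemaError(f"{path}: unknown resource names {sorted(unknown)}")
        dup = df.duplicated(subset=["province", "year", "resource"])
        if dup.any():
            row = df.loc[dup].iloc[0]
            raise PanelIntegrityError(
                f"{path}: duplicate ({row['province']!r}, {int(row['year'])}, "
                f"{row['resource']!r}) at data row {int(df.index[dup][0]) + 2}"
            )
        wide = df.pivot(index=["province", "year"], columns="resource", values="count")
        wide = wide.reset_index()
        wide.columns.name = None
        return wide
    if cols & set(RESOURCES):  # wide form
        dup = df.duplicated(subset=["province", "year"])
        if dup.any():
            row = df.loc[dup].iloc[0]
            raise PanelIntegrityError(
                f"{path}: duplicate (province, year) pair "
                f"({row['province']!r}, {int(row['year'])}) at data row "
                f"{int(df.index[dup][0]) + 2}"
            )
        return df.copy()
    raise PanelSchemaError(
        f"{path}: expected long columns (province,year,resource,count) or wide "
        f"resource columns among {RESOURCES}"
    )


def _provinces_frame(df: pd.DataFrame, path: Path) -> tuple[pd.DataFrame, dict[str, str] | None]:
    """Normalise a province table to long (province, year, population, area_km2);
    returns the optional region mapping found in the file."""
    cols = set(df.columns)
    if "province" not in cols:
        raise PanelSchemaError(f"{path}: province table needs a 'province' column")
    if "area_km2" not in cols:
        raise PanelSchemaError(f"{path}: province table needs an 'area_km2' column")
    region_map = None
    if "region" in cols:
        region_map = {
            canonical_province(p): r for p, r in zip(df["province"], df["region"])
        }
    pop_year_cols = [c for c in df.columns if c.startswith("population_")]
    if pop_year_cols:  # wide form
        long = df.melt(
            id_vars=["province", "area_km2"],
            value_vars=pop_year_cols,
            var_name="year",
            value_name="population",
        )
        long["year"] = long["year"].str.removeprefix("population_").astype(int)
        return long[["province", "year", "population", "area_km2"]], region_map
    if {"year", "population"} <= cols:  # long form
        return df[["province", "year", "population", "area_km2"]].copy(), region_map
    raise PanelSchemaError(
        f"{path}: province table needs either population_<year> columns or "
        f"'year' + 'population' columns"
    )


def read_panel(
    panel_path: str | Path,
    provinces_path: str | Path,
    scheme: RegionScheme | Mapping[str, str] | None = None,
    study_window: tuple[int, int] = DEFAULT_STUDY_WINDOW,
) -> ResourcePanel:
    """Read and validate a panel from a counts CSV plus a province table CSV.

    ``scheme`` overrides any region column in the province table; when both
    are absent the default 31-province partition is used.
    """
    counts = _panel_counts_frame(_read_csv(panel_path, "panel"), Path(panel_path))
    prov, file_regions = _provinces_frame(
        _read_csv(provinces_path, "provinces"), Path(provinces_path)
    )
    if scheme is None and file_regions is not None:
        scheme = RegionScheme(file_regions)
    elif scheme is not None and not isinstance(scheme, RegionScheme):
        scheme = RegionScheme(scheme)

    counts["province"] = counts["province"].map(canonical_province)
    prov = prov.copy()
    prov["province"] = prov["province"].map(canonical_province)
    merged = counts.merge(prov, on=["province", "year"], how="left", validate="1:1")
    unmatched = merged["population"].isna() | merged["area_km2"].isna()
    if unmatched.any():
        bad = merged.loc[unmatched, ["province", "year"]].iloc[0]
        raise PanelIntegrityError(
            f"no population/area for ({bad['province']!r}, {int(bad['year'])}) "
            f"in province table"
        )
    return ResourcePanel(merged, scheme=scheme, study_window=study_window)


def write_panel(
    panel: ResourcePanel,
    path: str | Path,
    provinces_path: str | Path | None = None,
) -> Path:
    """Write a panel as a wide counts CSV plus a long province table CSV.

    ``provinces_path`` defaults to ``<path stem>.provinces.csv`` next to the
    panel file.  ``read_panel(write_panel(p))`` reproduces ``p`` exactly.
    """
    path = Path(path)
    if provinces_path is None:
        provinces_path = path.with_suffix("").with_suffix("")
        provinces_path = path.parent / (path.stem + ".provinces.csv")
    provinces_path = Path(provinces_path)

    df = panel.frame
    count_cols = ["province", "year"] + [r for r in RESOURCES if r in df.columns]
    extra = [
        c for c in df.columns
        if c not in count_cols + ["population", "area_km2", "region"]
    ]
    df[count_cols + extra].to_csv(path, index=False, float_format=_float_repr)

    prov = df[["province", "year", "population", "area_km2"]].copy()
    prov["region"] = prov["province"].map(panel.scheme.region_of)
    prov.to_csv(provinces_path, index=False, float_format=_float_repr)
    return path
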
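"""End-to-end pipeline: panel in, six report tables out.

The report mirrors the layout of a typical health-resource equity study:

* table1 — resource densities per 10,000 people, region × year, with an
  average-annual-growth footer row;
* table2 — densities per 10,000 km², same layout;
* table3 — within-region Gini of each resource across provinces, population
  base, region × year;
* table4 — the same with land area as the base;
* table5 — HRAD, PAD and HRAD/PAD ratio for every region and province in a
  chosen reference year;
* table6 — the regional HRAD/PAD rows for every study year.

Regional HRAD/PAD values are computed from summed counts, populations and
areas — never by averaging provincial degrees — which is the construction
under which an area-weighted mean over any partition equals 1 exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import measures
from .panel import RESOURCES, ResourcePanel, read_panel
from .regions import REGIONS
from .synthetic import GeneratorConfig, generate_panel

logger = logging.getLogger("equipanel")

#: Display rounding conventions (decimal places) used in emitted tables.
ROUNDING = {"density": 2, "gini": 4, "agglomeration": 3, "share": 2, "growth": 2}


class PipelineError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs and conventions for one pipeline run.

    Either ``panel_path`` + ``provinces_path`` (CSV inputs) or ``generator``
    (synthetic mode) must be provided.  ``reference_year`` selects the
    table5 snapshot and must fall inside the study years.
    """

    panel_path: str | None = None
    provinces_path: str | None = None
    generator: GeneratorConfig | None = None
    years: tuple[int, int] = (2009, 2018)
    resources: tuple[str, ...] = RESOURCES
    reference_year: int = 2018
    out_dir: str = "report"
    growth_mode: str = "geometric"
    round_for_display: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generator is None and (self.panel_path is None or self.provinces_path is None):
            raise ValueError("need either input paths or a generator config")
        if not self.years[0] <= self.reference_year <= self.years[1]:
            raise ValueError(
                f"reference year {self.reference_year} outside study years {self.years}"
            )
        unknown = set(self.resources) - set(RESOURCES)
        if unknown:
            raise ValueError(f"unknown resources {sorted(unknown)}")


@dataclass
class ReportBundle:
    """The six report tables plus run metadata."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    table5: pd.DataFrame
    table6: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {f"table{k}": getattr(self, f"table{k}") for k in range(1, 7)}


# ---------------------------------------------------------------------------
# table builders


def _maybe_round(df: pd.DataFrame, places: int, do_round: bool) -> pd.DataFrame:
    if not do_round:
        return df
    num = df.select_dtypes(include=[float]).columns
    out = df.copy()
    out[num] = out[num].round(places)
    return out


def build_density_tables(
    panel: ResourcePanel,
    resources: tuple[str, ...] = RESOURCES,
    growth_mode: str = "geometric",
    round_for_display: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Region × year density tables (per 10,000 people and per 10,000 km²),
    each with an average-annual-growth footer row in % per year."""
    rows_pop, rows_area = [], []
    for year in panel.years:
        rp: dict[str, Any] = {"year": year}
        ra: dict[str, Any] = {"year": year}
        for res in resources:
            for region in REGIONS:
                col = f"{res}_{region}"
                if res not in panel.resources:
                    rp[col] = np.nan
                    ra[col] = np.nan
                    continue
                df = panel.year_slice(year, region=region)
                count = float(df[res].sum())
                rp[col] = measures.density(count, float(df["population"].sum()))
                ra[col] = measures.density(count, float(df["area_km2"].sum()))
        rows_pop.append(rp)
        rows_area.append(ra)
    t1 = pd.DataFrame(rows_pop)
    t2 = pd.DataFrame(rows_area)

    def footer(tab: pd.DataFrame) -> pd.DataFrame:
        growth: dict[str, Any] = {"year": "avg_annual_growth_pct"}
        for col in tab.columns:
            if col == "year":
                continue
            series = tab[col].astype(float).to_numpy()
            growth[col] = (
                np.nan
                if np.isnan(series).any()
                else measures.avg_annual_growth(series, mode=growth_mode)
            )
        out = pd.concat([tab, pd.DataFrame([growth])], ignore_index=True)
        return out

    t1, t2 = footer(t1), footer(t2)
    return (
        _maybe_round(t1, ROUNDING["density"], round_for_display),
        _maybe_round(t2, ROUNDING["density"], round_for_display),
    )


def build_gini_tables(
    panel: ResourcePanel,
    resources: tuple[str, ...] = RESOURCES,
    round_for_display: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Region × year Gini tables across each region's provinces, for the
    population base (table3) and the area base (table4)."""
    rows_pop, rows_area = [], []
    for year in panel.years:
        rp: dict[str, Any] = {"year": year}
        ra: dict[str, Any] = {"year": year}
        for res in resources:
            for region in REGIONS:
                col = f"{res}_{region}"
                if res not in panel.resources:
                    rp[col] = np.nan
                    ra[col] = np.nan
                    continue
                try:
                    rp[col] = measures.gini_by_population(panel, region, year, res)
                    ra[col] = measures.gini_by_area(panel, region, year, res)
                except measures.InsufficientUnitsError:
                    logger.warning(
                        "region %s has < 2 provinces in %d; Gini marked missing",
                        region, year,
                    )
                    rp[col] = np.nan
                    ra[col] = np.nan
        rows_pop.append(rp)
        rows_area.append(ra)
    t3 = pd.DataFrame(rows_pop)
    t4 = pd.DataFrame(rows_area)
    return (
        _maybe_round(t3, ROUNDING["gini"], round_for_display),
        _maybe_round(t4, ROUNDING["gini"], round_for_display),
    )


def _agglomeration_rows(
    panel: ResourcePanel,
    year: int,
    resources: tuple[str, ...],
    units: str = "both",
) -> list[dict[str, Any]]:
    df = panel.year_slice(year)
    pop_n = float(df["population"].sum())
    area_n = float(df["area_km2"].sum())
    totals = {
        res: float(df[res].sum()) for res in resources if res in panel.resources
    }

    def one(unit: str, pop_i: float, area_i: float, counts: Mapping[str, float]) -> dict[str, Any]:
        row: dict[str, Any] = {"unit": unit}
        p = measures.pad(pop_i, area_i, pop_n, area_n)
        row["pad"] = p
        for res in resources:
            if res not in totals or pd.isna(counts.get(res, np.nan)):
                row[f"hrad_{res}"] = np.nan
                row[f"ratio_{res}"] = np.nan
                continue
            h = measures.hrad(float(counts[res]), area_i, totals[res], area_n)
            row[f"hrad_{res}"] = h
            row[f"ratio_{res}"] = measures.hrad_pad_ratio(h, p)
        return row

    rows: list[dict[str, Any]] = []
    if units in ("both", "regions"):
        for region in REGIONS:
            sub = df[df["region"] == region]
            if sub.empty:
                continue
            rows.append(
                one(
                    f"{region} region",
                    float(sub["population"].sum()),
                    float(sub["area_km2"].sum()),
                    {res: float(sub[res].sum()) for res in totals},
                )
            )
    if units in ("both", "provinces"):
        for r in df.itertuples(index=False):
            counts = {res: getattr(r, res) for res in totals}
            rows.append(one(r.province, float(r.population), float(r.area_km2), counts))
    return rows


def build_agglomeration_table(
    panel: ResourcePanel,
    year: int,
    resources: tuple[str, ...] = RESOURCES,
    round_for_display: bool = True,
) -> pd.DataFrame:
    """table5: HRAD, PAD and recomputed HRAD/PAD ratio for the three regions
    followed by every province (administrative order) in one year."""
    rows = _agglomeration_rows(panel, year, resources, units="both")
    return _maybe_round(pd.DataFrame(rows), ROUNDING["agglomeration"], round_for_display)


def build_agglomeration_timeseries(
    panel: ResourcePanel,
    resources: tuple[str, ...] = RESOURCES,
    round_for_display: bool = True,
) -> pd.DataFrame:
    """table6: the regional HRAD/PAD rows for every year of the panel."""
    rows = []
    for year in panel.years:
        for row in _agglomeration_rows(panel, year, resources, units="regions"):
            rows.append({"year": year, **row})
    return _maybe_round(pd.DataFrame(rows), ROUNDING["agglomeration"], round_for_display)


# ---------------------------------------------------------------------------
# pipeline


def _config_digest(config: PipelineConfig) -> str:
    def default(o: Any) -> Any:
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    blob = json.dumps(config, default=default, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _atomic_write(df: pd.DataFrame, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            df.to_csv(fh, index=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def load_input_panel(config: PipelineConfig) -> ResourcePanel:
    """Load the CSV inputs, or generate the synthetic panel, per config."""
    if config.generator is not None:
        gen = config.generator
        return generate_panel(gen, seed=config.seed)
    return read_panel(
        config.panel_path, config.provinces_path, study_window=config.years
    )


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the full analysis and write ``table1.csv`` … ``table6.csv`` plus
    ``run_log.json`` into ``config.out_dir``.

    Deterministic for fixed inputs and seed; on failure the stage name is
    reported and partially written tables are removed.
    """
    stage = "load"
    try:
        panel = load_input_panel(config)
        logger.info("loaded panel: %d provinces × %d years, resources %s",
                    len(panel.provinces), len(panel.years), panel.resources)

        stage = "densities"
        t1, t2 = build_density_tables(
            panel, config.resources, config.growth_mode, config.round_for_display
        )
        stage = "gini"
        t3, t4 = build_gini_tables(panel, config.resources, config.round_for_display)
        stage = "agglomeration"
        t5 = build_agglomeration_table(
            panel, config.reference_year, config.resources, config.round_for_display
        )
        t6 = build_agglomeration_timeseries(
            panel, config.resources, config.round_for_display
        )
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(stage, exc) from exc

    bundle = ReportBundle(
        table1=t1, table2=t2, table3=t3, table4=t4, table5=t5, table6=t6,
        metadata={
            "config_digest": _config_digest(config),
            "growth_mode": config.growth_mode,
            "rounding": dict(ROUNDING) if config.round_for_display else None,
            "reference_year": config.reference_year,
            "seed": config.seed,
        },
    )

    stage = "write"
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        log: dict[str, Any] = {**bundle.metadata, "tables": {}}
        for name, df in bundle.tables().items():
            path = out / f"{name}.csv"
            _atomic_write(df, path)
            written.append(path)
            log["tables"][name] = {"path": str(path), "rows": int(len(df))}
            logger.info("wrote %s (%d rows)", path, len(df))
        fd, tmp = tempfile.mkstemp(dir=out, suffix=".tmp")
        with os.fdopen(fd, "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)
        os.replace(tmp, out / "run_log.json")
    except Exception as exc:  # noqa: BLE001
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
    return bundle
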
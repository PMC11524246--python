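"""FIA-style inventory ingest: tables → balanced three-cycle subplot panel.

The inventory design: permanent plots on a quasi-systematic grid, each
with four nested subplots, revisited in multi-year measurement cycles.
Invasive-species records live in an occurrence table (one row per subplot
× species with a cover percent); plot visits carry the inventory year; a
condition table carries ownership.  Analysis uses only subplots visited in
all three cycles, so absence in a visited cycle is data (an uninfested
subplot), not a gap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from invascape.errors import InvalidDomainError, SchemaError
from invascape.units import UnitSystem

logger = logging.getLogger(__name__)

__all__ = [
    "CYCLE_WINDOWS",
    "SubplotPanel",
    "assign_cycle",
    "read_tables",
    "build_panel",
    "binary_presence",
    "select_major_species",
    "summarize_infestation",
    "infestation_summary_from_counts",
    "categorical_cover_fraction",
]

#: Inventory-year windows defining the three measurement cycles.
CYCLE_WINDOWS: dict[str, tuple[int, int]] = {
    "T1": (2001, 2005),
    "T2": (2006, 2012),
    "T3": (2013, 2019),
}

_OCC_COLS = ["PLT_CN", "SUBP", "VEG_SPCD", "COVER_PCT", "INVYR"]
_PLOT_COLS = ["PLT_CN", "X", "Y", "INVYR"]
_COND_COLS = ["PLT_CN", "OWNCD"]


@dataclass
class SubplotPanel:
    """Balanced subplot × cycle panel of invasive occurrences.

    ``subplots``: DataFrame indexed by subplot_id with plot_id, x, y.
    ``occurrences``: long DataFrame (subplot_id, cycle, species_code,
    cover_pct); a subplot-cycle absent from it is uninfested, not missing.
    """

    subplots: pd.DataFrame
    occurrences: pd.DataFrame
    cycles: list[str] = field(default_factory=lambda: list(CYCLE_WINDOWS))
    metadata: dict = field(default_factory=dict)

    @property
    def n_subplots(self) -> int:
        return len(self.subplots)

    def species_codes(self) -> list[str]:
        return sorted(self.occurrences["species_code"].unique())

    def infested_ids(self, cycle: str, species_scope: str = "all") -> set:
        occ = self.occurrences[self.occurrences["cycle"] == cycle]
        if species_scope != "all":
            occ = occ[occ["species_code"] == species_scope]
        return set(occ["subplot_id"].unique())


def assign_cycle(
    inventory_year: int, windows: dict[str, tuple[int, int]] = CYCLE_WINDOWS
):
    """Map an inventory year to its measurement cycle label, or None.

    Years outside every window (e.g. 2000) are excluded from the panel.
    """
    if inventory_year < 1990:
        raise InvalidDomainError(f"inventory year {inventory_year} predates 1990")
    for label, (lo, hi) in windows.items():
        if lo <= inventory_year <= hi:
            return label
    return None


def _require(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing required column(s) {missing}")


def read_tables(occurrence_path, plot_path, condition_path=None):
    """Read FIA-style occurrence/plot/condition CSVs with validation.

    Cover percents outside (0, 100] quarantine the row; rows with a
    missing species code are dropped.  Returns
    ``(occurrences, plots, conditions, report)`` where ``report`` counts
    loaded and rejected rows and ``conditions`` is None when no path given.
    """
    occ = pd.read_csv(occurrence_path)
    _require(occ, _OCC_COLS, "occurrence")
    report = {"occurrence_rows": len(occ)}
    if occ.empty:
        warnings.warn(f"occurrence file {occurrence_path} is empty", stacklevel=2)
    no_species = occ["VEG_SPCD"].isna() | (occ["VEG_SPCD"].astype(str).str.len() == 0)
    report["dropped_missing_species"] = int(no_species.sum())
    occ = occ[~no_species].copy()
    occ["COVER_PCT"] = pd.to_numeric(occ["COVER_PCT"], errors="coerce")
    bad = occ["COVER_PCT"].isna() | (occ["COVER_PCT"] <= 0) | (occ["COVER_PCT"] > 100)
    report["quarantined_cover"] = int(bad.sum())
    quarantine = occ[bad]
    occ = occ[~bad]
    plots = pd.read_csv(plot_path)
    _require(plots, _PLOT_COLS, "plot")
    report["plot_rows"] = len(plots)
    conditions = None
    if condition_path is not None:
        conditions = pd.read_csv(condition_path)
        _require(conditions, _COND_COLS, "condition")
        report["condition_rows"] = len(conditions)
    if report["dropped_missing_species"] or report["quarantined_cover"]:
        logger.info("load report: %s", report)
    report["quarantine"] = quarantine
    return occ, plots, conditions, report


def build_panel(
    occurrences: pd.DataFrame,
    plots: pd.DataFrame,
    windows: dict[str, tuple[int, int]] = CYCLE_WINDOWS,
    subplots: pd.DataFrame | None = None,
    subplots_per_plot: int = 4,
) -> SubplotPanel:
    """Assemble the balanced panel of subplots visited in every cycle.

    Plot visits define which cycles a subplot was measured in; only plots
    with a visit in all cycles are kept (their counts are logged).
    Duplicate (subplot, cycle, species) rows keep the maximum cover.  An
    optional subplot table supplies subplot coordinates; otherwise
    subplots ``1..subplots_per_plot`` sit at the plot location.
    """
    plots = plots.copy()
    plots["cycle"] = [assign_cycle(int(yr), windows) for yr in plots["INVYR"]]
    plots = plots[plots["cycle"].notna()]
    cycles = list(windows)
    visits = plots.groupby("PLT_CN")["cycle"].agg(set)
    complete = visits[visits.apply(lambda s: set(cycles) <= s)].index
    n_dropped = visits.index.size - complete.size
    if n_dropped:
        logger.info(
            "dropped %d plot(s) without a visit in all %d cycles",
            n_dropped,
            len(cycles),
        )
    coords = (
        plots[plots["PLT_CN"].isin(complete)]
        .sort_values("INVYR")
        .groupby("PLT_CN")[["X", "Y"]]
        .first()
    )
    if subplots is not None:
        sub = subplots[subplots["plot_id"].isin(set(map(str, complete)))].copy()
        sub = sub.set_index("subplot_id")
    else:
        recs = {}
        for plt in complete:
            for s in range(1, subplots_per_plot + 1):
                recs[f"{plt}_{s}"] = {
                    "plot_id": str(plt),
                    "x": coords.loc[plt, "X"],
                    "y": coords.loc[plt, "Y"],
                }
        sub = pd.DataFrame.from_dict(recs, orient="index")
    sub.index.name = "subplot_id"

    occ = occurrences.copy()
    occ["cycle"] = [assign_cycle(int(yr), windows) for yr in occ["INVYR"]]
    occ = occ[occ["cycle"].notna() & occ["PLT_CN"].isin(set(complete))]
    occ["subplot_id"] = occ["PLT_CN"].astype(str) + "_" + occ["SUBP"].astype(str)
    occ = occ[occ["subplot_id"].isin(set(sub.index))]
    occ = occ.rename(columns={"VEG_SPCD": "species_code", "COVER_PCT": "cover_pct"})
    dup = occ.duplicated(["subplot_id", "cycle", "species_code"], keep=False)
    if dup.any():
        logger.info(
            "%d duplicate subplot-cycle-species rows; keeping max cover",
            int(dup.sum()),
        )
    occ = (
        occ.groupby(["subplot_id", "cycle", "species_code"], as_index=False)[
            "cover_pct"
        ].max()
    )
    return SubplotPanel(
        subplots=sub[["plot_id", "x", "y"]],
        occurrences=occ[["subplot_id", "cycle", "species_code", "cover_pct"]],
        cycles=cycles,
        metadata={"coordinate_system": "planar_m"},
    )


def binary_presence(panel: SubplotPanel, species_scope: str = "all") -> pd.DataFrame:
    """0/1 indicator per subplot × cycle: any in-scope species present."""
    out = pd.DataFrame(
        0, index=panel.subplots.index, columns=panel.cycles, dtype=int
    )
    occ = panel.occurrences
    if species_scope != "all":
        occ = occ[occ["species_code"] == species_scope]
    for cycle, grp in occ.groupby("cycle"):
        if cycle in out.columns:
            out.loc[out.index.isin(set(grp["subplot_id"])), cycle] = 1
    return out


def select_major_species(
    panel: SubplotPanel, min_subplots: int = 200, window: str = "T3"
) -> tuple[pd.DataFrame, list[str]]:
    """Rank species by infested-subplot count in the reference cycle.

    Species found in at least ``min_subplots`` subplots of ``window`` are
    the majors, ranked by count descending; the rest pool as "Others".
    """
    if min_subplots < 1:
        raise InvalidDomainError("min_subplots must be at least 1")
    occ = panel.occurrences[panel.occurrences["cycle"] == window]
    counts = (
        occ.groupby("species_code")["subplot_id"]
        .nunique()
        .sort_values(ascending=False, kind="stable")
    )
    major = counts[counts >= min_subplots]
    others = sorted(counts[counts < min_subplots].index)
    ranking = major.reset_index()
    ranking.columns = ["species_code", "infested_subplots"]
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    return ranking, others


def infestation_summary_from_counts(
    total_subplots: int, infested_subplots: int, species_occurrences: int
) -> dict:
    """Summary-row arithmetic from already-aggregated counts.

    infestation % = 100·infested/total (1 decimal); mean species per
    infested subplot = occurrences/infested (2 decimals).
    """
    if infested_subplots > total_subplots:
        raise InvalidDomainError("infested count exceeds total")
    pct = (
        round(100.0 * infested_subplots / total_subplots, 1)
        if total_subplots
        else None
    )
    mean_sp = (
        round(species_occurrences / infested_subplots, 2) if infested_subplots else None
    )
    return {
        "total_subplots": total_subplots,
        "infested_subplots": infested_subplots,
        "infestation_pct": pct,
        "species_occurrences": species_occurrences,
        "mean_species_per_infested": mean_sp,
    }


def summarize_infestation(panel: SubplotPanel) -> pd.DataFrame:
    """Per-cycle infestation summary over the balanced panel.

    Counts total subplots, infested subplots, infestation percent, species
    occurrences (subplot × species records) and the mean number of species
    per infested subplot.
    """
    rows = []
    for cycle in panel.cycles:
        occ = panel.occurrences[panel.occurrences["cycle"] == cycle]
        infested = occ["subplot_id"].nunique()
        occurrences = len(occ.drop_duplicates(["subplot_id", "species_code"]))
        rows.append(
            {"cycle": cycle}
            | infestation_summary_from_counts(panel.n_subplots, infested, occurrences)
        )
    return pd.DataFrame(rows)


def categorical_cover_fraction(
    class_grid: pd.DataFrame, units: UnitSystem
) -> pd.DataFrame:
    """Percent of each unit's covered area in each land-cover class.

    ``class_grid`` holds one row per raster-like cell: center ``x``, ``y``,
    cell ``area`` and a categorical ``class_label``.  Cells are assigned to
    units by their centers; per-unit percents sum to 100 where the grid
    covers the unit, and a warning is issued for uncovered units.
    """
    for col in ("x", "y", "area", "class_label"):
        if col not in class_grid.columns:
            raise SchemaError(f"class grid is missing column {col!r}")
    from invascape.metrics import assign_units

    cells = class_grid.copy()
    cells.index.name = "cell_id"
    membership = assign_units(cells, units)
    cells["unit_id"] = membership
    covered = cells.dropna(subset=["unit_id"])
    areas = covered.pivot_table(
        index="unit_id", columns="class_label", values="area", aggfunc="sum",
        fill_value=0.0,
    )
    pct = 100.0 * areas.div(areas.sum(axis=1), axis=0)
    missing = [u for u in units.unit_ids if u not in pct.index]
    if missing:
        warnings.warn(
            f"{len(missing)} unit(s) contain no grid cells; their class "
            "percents are undefined",
            stacklevel=2,
        )
    pct = pct.reindex(units.unit_ids)
    pct.columns.name = None
    return pct
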
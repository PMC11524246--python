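"""End-to-end orchestration: simulate → ingest → index → select → fit.

Each stage writes plain-text artifacts (CSV/GeoJSON/JSON) into the run
directory and records them, with SHA-256 hashes and row counts, in
``manifest.json``.  Re-running with the same configuration reproduces
byte-identical artifacts; the manifest makes that checkable.

The run configuration is a flat key-value structure (YAML on disk) with
explicit units — meters for lengths, years for cycle windows.  One master
seed drives everything; stages derive child seeds by fixed offsets so a
stage can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from invascape import ingest as ing
from invascape import synthetic as syn
from invascape.errors import ArtifactMissingError, InvalidDomainError
from invascape.metrics import compute_unit_table, idw_impute, write_unit_geojson
from invascape.moran import select_best_unit
from invascape.sar import (
    fit_sar_ml,
    neighbor_average,
    residual_autocorrelation,
    screen_collinear,
    stepwise_aic,
)
from invascape.units import UnitSystem
from invascape.weights import build_contiguity, row_standardize

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineRun", "run_pipeline", "report_tables"]

# fixed child-seed offsets (documented study-condition plumbing)
_SEED_HIERARCHY = 11
_SEED_NETWORK = 12
_SEED_COVARIATES = 13
_SEED_SEVERITY = 14
_SEED_OCCURRENCES = 15


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run (units: meters, years)."""

    # --- landscape geometry
    extent: tuple = (0.0, 0.0, 98000.0, 98000.0)
    hydro_base: tuple = (2, 2)
    hydro_refinements: tuple = (2, 2, 2, 2)
    eco_base: tuple = (3, 3)
    eco_refinements: tuple = (2, 2)
    county_grid: tuple = (7, 7)
    # --- plot network
    plot_spacing: float = 4900.0
    subplots_per_plot: int = 4
    plot_jitter: float = 500.0
    # --- severity ground truth (SAR on the county-like system)
    rho: float = 0.6
    beta: dict = field(
        default_factory=lambda: {
            "intercept": 1.5,
            "pop_den": 0.03,
            "public_own_pct": -0.04,
        }
    )
    sigma: float = 1.0
    cycle_multipliers: tuple = (1.0, 1.2, 1.4)
    cover_scale: float = 20.0
    # --- analysis choices
    species_scope: str = "all"
    weights_rule: str = "queen"
    idw_power: float = 2.0
    screen_threshold: float = 0.6
    include_imputed: bool = False
    major_species_min_subplots: int = 20
    fit_system: str = "auto"
    # --- bookkeeping
    seed: int = 42

    def __post_init__(self) -> None:
        if not (0 < self.screen_threshold < 1):
            raise InvalidDomainError("screen_threshold must be in (0, 1)")
        windows = list(ing.CYCLE_WINDOWS.values())
        for (a1, b1), (a2, b2) in zip(windows, windows[1:]):
            if a2 <= b1:
                raise InvalidDomainError("cycle year windows overlap")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InvalidDomainError(f"unknown config keys: {sorted(unknown)}")
        for key in ("extent", "hydro_base", "hydro_refinements", "eco_base",
                    "eco_refinements", "county_grid", "cycle_multipliers"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        for k, v in doc.items():
            if isinstance(v, tuple):
                doc[k] = list(v)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def default_covariate_spec() -> list[syn.CovariateSpec]:
    """Unit-level covariates emulating the usual drivers of invasion:
    population density, public ownership, forest-type and land-use
    composition (six classes each)."""
    return [
        syn.CovariateSpec("pop_den", "density", smoothness=0.6, mean=33.0, scale=0.7),
        syn.CovariateSpec(
            "public_own_pct", "percent", smoothness=0.4, mean=30.0, scale=0.9
        ),
        syn.CovariateSpec(
            "forest_group",
            "compositional",
            smoothness=0.5,
            scale=0.8,
            classes=(
                "lob_short",
                "oak_hickory",
                "oak_pine",
                "oak_gum_cypress",
                "long_slash",
                "elm_ash_cot",
            ),
        ),
        syn.CovariateSpec(
            "landuse",
            "compositional",
            smoothness=0.5,
            scale=0.8,
            classes=("ag", "dev", "dist", "fr", "ot", "wa"),
        ),
    ]


class PipelineRun:
    """Stateful runner: stages share the run directory and manifest."""

    def __init__(self, config: RunConfig, outdir) -> None:
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest = (
            json.loads(self.manifest_path.read_text())
            if self.manifest_path.exists()
            else {"stages": {}}
        )
        self.manifest["config"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        }

    # ------------------------------------------------------------ helpers

    def _record(self, stage: str, files: list[str], **extra) -> None:
        entry = {
            "files": {f: _sha256(self.outdir / f) for f in sorted(files)},
            **extra,
        }
        self.manifest["stages"][stage] = entry
        with open(self.manifest_path, "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, sort_keys=True, indent=1)
            fh.write("\n")

    def _need(self, fname: str) -> Path:
        path = self.outdir / fname
        if not path.exists():
            raise ArtifactMissingError(
                f"stage artifact {fname!r} not found in {self.outdir}; "
                "run the earlier stages first"
            )
        return path

    def _systems(self) -> dict[str, UnitSystem]:
        systems = {}
        for path in sorted(self.outdir.glob("units_*.geojson")):
            system = UnitSystem.from_geojson(path)
            systems[system.system_id] = system
        if not systems:
            raise ArtifactMissingError(f"no units_*.geojson in {self.outdir}")
        return systems

    def _load_panel(self) -> ing.SubplotPanel:
        occ, plots, _, _ = ing.read_tables(
            self._need("fia_occurrence.csv"),
            self._need("fia_plot.csv"),
            self._need("fia_cond.csv"),
        )
        subplots = pd.read_csv(self._need("subplots.csv"))
        return ing.build_panel(occ, plots, subplots=subplots)

    # ------------------------------------------------------------- stages

    def stage_simulate(self) -> None:
        cfg = self.config
        hydro = syn.generate_unit_hierarchy(
            cfg.extent,
            cfg.hydro_base,
            cfg.hydro_refinements,
            seed=cfg.seed + _SEED_HIERARCHY,
            prefix="H",
            include_county=True,
            county_grid=cfg.county_grid,
        )
        eco = syn.generate_unit_hierarchy(
            cfg.extent,
            cfg.eco_base,
            cfg.eco_refinements,
            seed=cfg.seed + _SEED_HIERARCHY,
            prefix="E",
            include_county=False,
        )
        systems = hydro + eco
        county = next(s for s in systems if s.system_id == "COUNTY")
        panel = syn.generate_subplot_network(
            [county],
            cfg.plot_spacing,
            cfg.subplots_per_plot,
            cfg.plot_jitter,
            seed=cfg.seed + _SEED_NETWORK,
        )
        covariates = syn.simulate_covariates(
            county, default_covariate_spec(), seed=cfg.seed + _SEED_COVARIATES
        )
        names = [n for n in cfg.beta if n != "intercept"]
        x = pd.DataFrame(
            {"intercept": 1.0} | {n: covariates[n] for n in names},
            index=covariates.index,
        )
        truth = syn.GroundTruth(
            rho=cfg.rho,
            beta=np.array([cfg.beta["intercept"]] + [cfg.beta[n] for n in names]),
            sigma=cfg.sigma,
            seed=cfg.seed + _SEED_SEVERITY,
            beta_names=["intercept"] + names,
        )
        w_county = row_standardize(build_contiguity(county, cfg.weights_rule))
        severity = syn.simulate_severity(w_county, x, truth)
        # the occurrence model needs a non-negative target; the SAR draw
        # can dip below zero in the weakest units — floor at zero there
        floor = severity.clip(lower=0.0)
        panel = syn.simulate_occurrences(
            panel,
            county,
            floor,
            cycle_multipliers=cfg.cycle_multipliers,
            cover_scale=cfg.cover_scale,
            seed=cfg.seed + _SEED_OCCURRENCES,
        )
        files = syn.write_landscape(self.outdir, systems, panel, covariates, truth)
        files += syn.write_fia_tables(panel, self.outdir)
        self._record(
            "simulate",
            files,
            seed=cfg.seed,
            n_plots=panel.subplots["plot_id"].nunique(),
            n_subplots=panel.n_subplots,
            n_occurrences=len(panel.occurrences),
        )

    def stage_ingest(self) -> None:
        panel = self._load_panel()
        summary = ing.summarize_infestation(panel)
        summary.to_csv(self.outdir / "infestation_summary.csv", index=False)
        ranking, others = ing.select_major_species(
            panel, self.config.major_species_min_subplots
        )
        ranking.to_csv(self.outdir / "species_ranking.csv", index=False)
        species = species_summary(
            panel, self.config.major_species_min_subplots
        )
        species.to_csv(self.outdir / "species_summary.csv", index=False)
        self._record(
            "ingest",
            ["infestation_summary.csv", "species_ranking.csv", "species_summary.csv"],
            n_subplots=panel.n_subplots,
            n_major_species=len(ranking),
            n_other_species=len(others),
        )

    def stage_index(self) -> None:
        cfg = self.config
        panel = self._load_panel()
        files = []
        counts = {}
        for name, system in self._systems().items():
            table = compute_unit_table(panel, system, cfg.species_scope)
            table = idw_impute(table, system.centroids(), power=cfg.idw_power)
            for cycle in panel.cycles:
                sub = table[table["cycle"] == cycle]
                fname = f"unit_index_{name}_{cycle}.csv"
                sub.to_csv(self.outdir / fname, index=False)
                files.append(fname)
                gname = f"unit_index_{name}_{cycle}.geojson"
                write_unit_geojson(table, system, cycle, self.outdir / gname)
                files.append(gname)
            counts[name] = int((table["imputed"]).sum())
        self._record("index", files, imputed_rows=counts)

    def stage_select_unit(self) -> None:
        cfg = self.config
        systems = self._systems()
        tables, weights, files = {}, {}, []
        cycles = list(ing.CYCLE_WINDOWS)
        for name, system in systems.items():
            parts = []
            for cycle in cycles:
                parts.append(pd.read_csv(self._need(f"unit_index_{name}_{cycle}.csv")))
            tables[name] = pd.concat(parts, ignore_index=True)
            w = row_standardize(build_contiguity(system, cfg.weights_rule))
            weights[name] = w
            wname = f"weights_{name}.txt"
            w.to_neighbor_list(self.outdir / wname)
            files.append(wname)
        selection = select_best_unit(
            tables, weights, cycles, include_imputed=cfg.include_imputed
        )
        selection.ranking.to_csv(self.outdir / "moran_comparison.csv", index=False)
        files.append("moran_comparison.csv")
        chosen = {
            "by_cycle": selection.chosen_by_cycle,
            "overall": selection.overall,
            "ties": [
                {"scope": str(scope), "systems": list(map(str, systems))}
                for scope, systems in selection.ties
            ],
        }
        with open(self.outdir / "chosen_system.json", "w", encoding="utf-8") as fh:
            json.dump(chosen, fh, sort_keys=True, indent=1)
            fh.write("\n")
        files.append("chosen_system.json")
        self._record("select_unit", files, overall=selection.overall)

    def stage_fit_sar(self) -> None:
        cfg = self.config
        systems = self._systems()
        if cfg.fit_system == "auto":
            chosen = json.loads(self._need("chosen_system.json").read_text())
            fit_name = chosen["overall"]
        else:
            fit_name = cfg.fit_system
        system = systems[fit_name]
        w_full = row_standardize(build_contiguity(system, cfg.weights_rule))
        if fit_name == "COUNTY":
            covariates = pd.read_csv(
                self._need("covariates.csv"), index_col="unit_id"
            )
        else:  # covariates were generated on the county scale; redo here
            covariates = syn.simulate_covariates(
                system, default_covariate_spec(), seed=cfg.seed + _SEED_COVARIATES
            )
        covariates = covariates.copy()
        covariates["pop_den_nbh"] = neighbor_average(covariates["pop_den"], w_full)
        files = []
        for cycle in list(ing.CYCLE_WINDOWS):
            table = pd.read_csv(self._need(f"unit_index_{fit_name}_{cycle}.csv"))
            use = table if cfg.include_imputed else table[~table["imputed"]]
            y = pd.Series(
                use["invasion_index"].to_numpy(), index=use["unit_id"].astype(str)
            ).dropna()
            w = w_full.subset(list(y.index))
            y = y.reindex(w.ids)
            x_all = covariates.reindex(w.ids).dropna(axis=1, how="all")
            x_all = x_all.fillna(x_all.mean())
            x_screened, screen_log = screen_collinear(
                x_all, y, cfg.screen_threshold
            )
            fit, path = stepwise_aic(y, x_screened, w)
            rm = residual_autocorrelation(fit, w)
            doc = {
                "cycle": cycle,
                "system": fit_name,
                "n": fit.n,
                "k": fit.k,
                "rho": fit.rho,
                "se_rho": fit.se_rho,
                "p_rho": fit.p_rho,
                "sigma2": fit.sigma2,
                "loglik": fit.loglik,
                "aic": fit.aic,
                "coefficients": {
                    name: {
                        "estimate": float(fit.beta[name]),
                        "se": float(fit.se_beta[name]),
                        "p": float(fit.p_beta[name]),
                    }
                    for name in fit.beta.index
                },
                "residual_moran": {"i": rm.i, "z": rm.z, "p": rm.p},
                "screened_out": [d["removed"] for d in screen_log],
                "stepwise_path": path.to_dict(orient="records"),
            }
            fname = f"sar_fit_{cycle}.json"
            with open(self.outdir / fname, "w", encoding="utf-8") as fh:
                json.dump(doc, fh, sort_keys=True, indent=1)
                fh.write("\n")
            files.append(fname)
            resid_table = pd.DataFrame(
                {
                    "system_id": fit_name,
                    "unit_id": fit.ids,
                    "cycle": cycle,
                    "n_subplots": 1,
                    "n_infested": 0,
                    "presence_prob": np.nan,
                    "mean_cover": np.nan,
                    "invasion_index": fit.residuals.to_numpy(),
                    "imputed": False,
                }
            )
            rname = f"sar_residuals_{cycle}.geojson"
            write_unit_geojson(resid_table, system, cycle, self.outdir / rname)
            files.append(rname)
            fitted_table = resid_table.assign(
                invasion_index=fit.fitted.to_numpy()
            )
            fname2 = f"sar_fitted_{cycle}.geojson"
            write_unit_geojson(fitted_table, system, cycle, self.outdir / fname2)
            files.append(fname2)
        self._record("fit_sar", files, system=fit_name)

    def stage_report(self) -> None:
        files = report_tables(self.outdir)
        self._record("report", files)

    def run_all(self) -> dict:
        self.stage_simulate()
        self.stage_ingest()
        self.stage_index()
        self.stage_select_unit()
        self.stage_fit_sar()
        self.stage_report()
        return self.manifest


def species_summary(panel: ing.SubplotPanel, min_subplots: int) -> pd.DataFrame:
    """Per-species infested counts, presence % and mean cover % by cycle,
    with minor species pooled as Others (their covers summed)."""
    ranking, others = ing.select_major_species(panel, min_subplots)
    majors = list(ranking["species_code"])
    n = panel.n_subplots
    rows = []
    for code in majors + ["Others"]:
        rec = {"species_code": code}
        for cycle in panel.cycles:
            occ = panel.occurrences[panel.occurrences["cycle"] == cycle]
            grp = (
                occ[occ["species_code"].isin(others)]
                if code == "Others"
                else occ[occ["species_code"] == code]
            )
            count = grp["subplot_id"].nunique()
            rec[f"count_{cycle}"] = count
            rec[f"presence_pct_{cycle}"] = round(100.0 * count / n, 2) if n else None
            rec[f"mean_cover_{cycle}"] = (
                round(grp["cover_pct"].sum() / n, 2) if n else None
            )
            rec[f"occurrences_{cycle}"] = len(
                grp.drop_duplicates(["subplot_id", "species_code"])
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def report_tables(outdir) -> list[str]:
    """Assemble the summary bundle from completed stage artifacts.

    Emits the four analysis tables (infestation by cycle; per-species
    counts; Moran comparison; SAR fits) as CSV plus a human-readable
    ``report.txt``, cross-checking occurrence-count conservation between
    the species table and the infestation summary.
    """
    outdir = Path(outdir)
    files = []

    def need(name: str) -> Path:
        p = outdir / name
        if not p.exists():
            raise ArtifactMissingError(f"report needs missing artifact {name!r}")
        return p

    lines = ["Invasion-severity analysis report", "=" * 34, ""]
    summary = pd.read_csv(need("infestation_summary.csv"))
    summary.to_csv(outdir / "table_infestation.csv", index=False)
    files.append("table_infestation.csv")
    lines.append("Infestation by measurement cycle:")
    lines.append(summary.to_string(index=False))
    if summary["infested_subplots"].sum() == 0:
        lines.append("NOTE: zero infestation everywhere in the panel.")
    lines.append("")
    species_path = outdir / "species_summary.csv"
    if species_path.exists():
        species = pd.read_csv(species_path)
        species.to_csv(outdir / "table_species.csv", index=False)
        files.append("table_species.csv")
        lines.append("Major species (minor pooled as Others):")
        lines.append(species.to_string(index=False))
        for _, srow in summary.iterrows():
            cyc = srow["cycle"]
            col = f"occurrences_{cyc}"
            if col in species.columns:
                total = int(species[col].sum())
                if total != int(srow["species_occurrences"]):
                    raise InvalidDomainError(
                        f"occurrence counts disagree for {cyc}: species table "
                        f"{total} vs summary {srow['species_occurrences']}"
                    )
        lines.append("")
        lines.append(
            "Cross-check: per-species occurrence counts (incl. Others) sum to "
            "the summary's per-cycle occurrence totals."
        )
        lines.append("")
    moran_path = outdir / "moran_comparison.csv"
    if moran_path.exists():
        moran = pd.read_csv(moran_path)
        moran.to_csv(outdir / "table_moran.csv", index=False)
        files.append("table_moran.csv")
        lines.append("Moran's I by unit system and cycle:")
        lines.append(moran.to_string(index=False))
        chosen = json.loads(need("chosen_system.json").read_text())
        lines.append(f"Chosen modeling unit overall: {chosen['overall']}")
        lines.append("")
    sar_rows = []
    for path in sorted(outdir.glob("sar_fit_*.json")):
        doc = json.loads(path.read_text())
        for name, rec in doc["coefficients"].items():
            sar_rows.append(
                {
                    "cycle": doc["cycle"],
                    "variable": name,
                    "estimate": rec["estimate"],
                    "p": rec["p"],
                    "rho": doc["rho"],
                    "p_rho": doc["p_rho"],
                    "aic": doc["aic"],
                    "residual_moran_z": doc["residual_moran"]["z"],
                    "residual_moran_p": doc["residual_moran"]["p"],
                }
            )
    if sar_rows:
        sar_table = pd.DataFrame(sar_rows)
        sar_table.to_csv(outdir / "table_sar.csv", index=False)
        files.append("table_sar.csv")
        lines.append("Spatial lag model fits:")
        lines.append(sar_table.to_string(index=False))
        lines.append("")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    files.append("report.txt")
    return files


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage in order; returns the manifest."""
    return PipelineRun(config, outdir).run_all()
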
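"""Synthetic study system with known SAR ground truth.

Emulates the structure of a state-wide forest inventory: nested
rectangular unit hierarchies (watershed-like and ecoregion-like levels)
plus an offset, non-nested county-like partition; a jittered square plot
lattice (~4.9 km spacing, four subplots per plot); unit-level covariates
with controlled spatial smoothness; a latent per-unit severity surface
drawn from the spatial-lag process y = (I − ρW)⁻¹(Xβ + ε); and subplot
occurrence records whose re-aggregation recovers that severity.

The occurrence model inverts the index definition: on a unit with target
index y the presence probability is p = √(y / s) for a cover scale s, and
cover given presence is Beta-distributed with mean y/p², so that
E[P̂ · Ĉ] ≈ p · (p · y/p²) = y.  One uniform draw per subplot is shared
across cycles, so non-decreasing cycle multipliers give non-decreasing
infestation counts in every realization, not just in expectation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from invascape.errors import InfeasibleRhoError, InvalidDomainError
from invascape.ingest import SubplotPanel
from invascape.metrics import assign_units
from invascape.units import UnitSystem, grid_partition
from invascape.weights import SpatialWeights, build_contiguity, row_standardize

__all__ = [
    "GroundTruth",
    "SpeciesProfile",
    "CovariateSpec",
    "UnitSystem",
    "generate_unit_hierarchy",
    "generate_subplot_network",
    "simulate_covariates",
    "simulate_severity",
    "simulate_occurrences",
    "write_landscape",
    "write_fia_tables",
    "DEFAULT_SPECIES_PROFILES",
]

# FIA-like subplot layout: center subplot plus three at 36.58 m (120 ft),
# azimuths 360/120/240 degrees.
_SUBPLOT_RADIUS = 36.58


@dataclass
class GroundTruth:
    """Parameters of the severity-generating SAR process."""

    rho: float
    beta: np.ndarray
    sigma: float
    seed: int
    unit_severity: pd.Series | None = None
    beta_names: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        doc = {
            "rho": self.rho,
            "beta": list(map(float, np.asarray(self.beta))),
            "beta_names": list(self.beta_names),
            "sigma": self.sigma,
            "seed": self.seed,
        }
        if self.unit_severity is not None:
            doc["unit_severity"] = {
                k: float(v) for k, v in self.unit_severity.items()
            }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, sort_keys=True, indent=1)
            fh.write("\n")


@dataclass
class SpeciesProfile:
    """Relative prevalence of one species in the occurrence generator."""

    code: str
    weight: float
    cycle_weight_multipliers: tuple = (1.0, 1.0, 1.0)


#: Default species mix, shaped like a strongly skewed invader community:
#: one dominant vine, a common shrub, and a tail of minor species.
DEFAULT_SPECIES_PROFILES: list[SpeciesProfile] = [
    SpeciesProfile("LOJA", 0.52),
    SpeciesProfile("LIGUS2", 0.25),
    SpeciesProfile("LYJA", 0.07, (0.6, 0.9, 1.4)),
    SpeciesProfile("LECU", 0.05, (0.3, 1.0, 1.6)),
    SpeciesProfile("ALJU", 0.04),
    SpeciesProfile("TRSE6", 0.03, (0.7, 0.9, 1.5)),
    SpeciesProfile("ROSA5", 0.02),
    SpeciesProfile("OTHER1", 0.02),
]


@dataclass
class CovariateSpec:
    """One simulated unit-level covariate.

    kind: ``"percent"`` (bounded 0–100), ``"density"`` (nonnegative,
    log-normal-like) or ``"compositional"`` (a group of class percents
    summing to 100; ``classes`` names them).  ``smoothness`` is the
    autoregressive coefficient of the SAR filter that spatially smooths
    the underlying white noise (0 = white noise).
    """

    name: str
    kind: str = "percent"
    smoothness: float = 0.5
    mean: float = 50.0
    scale: float = 1.0
    classes: tuple = ()


def _check_extent(extent) -> tuple[float, float, float, float]:
    xmin, ymin, xmax, ymax = map(float, extent)
    if xmax <= xmin or ymax <= ymin:
        raise InvalidDomainError(f"extent {extent} has non-positive area")
    return xmin, ymin, xmax, ymax


def generate_unit_hierarchy(
    extent,
    base_grid: tuple[int, int],
    refinements,
    seed: int = 0,
    prefix: str = "L",
    include_county: bool = True,
    county_grid: tuple[int, int] = (7, 7),
) -> list[UnitSystem]:
    """Nested grid hierarchy plus an independent county-like partition.

    Level 1 is a ``base_grid`` tiling of the extent; each further level
    subdivides every cell by the next refinement factor, and children
    carry their parent's unit_id.  When ``include_county`` is set, a
    non-nested partition on an offset grid (its interior grid lines
    shifted by a seed-drawn fraction of a cell) is appended with
    system_id ``"COUNTY"``.
    """
    extent = _check_extent(extent)
    refinements = list(refinements)
    if any(int(f) < 2 for f in refinements):
        raise InvalidDomainError("all subdivision factors must be >= 2")
    rows, cols = base_grid
    if rows < 1 or cols < 1:
        raise InvalidDomainError("base grid must be at least 1x1")
    systems: list[UnitSystem] = []
    prev_id: str | None = None
    prev_factor = 1
    for level in range(len(refinements) + 1):
        sys_id = f"{prefix}{level + 1}"
        if prev_id is None:
            parent_of = None
        else:

            def parent_of(r, c, _p=prev_id, _f=prev_factor):
                return f"{_p}_{r // _f:03d}_{c // _f:03d}"

        systems.append(grid_partition(extent, rows, cols, sys_id, parent_of=parent_of))
        prev_id = sys_id
        if level < len(refinements):
            prev_factor = int(refinements[level])
            rows, cols = rows * prev_factor, cols * prev_factor
    if include_county:
        rng = np.random.default_rng(seed)
        off = 0.25 + 0.5 * rng.random(2)
        systems.append(
            grid_partition(
                extent,
                county_grid[0],
                county_grid[1],
                "COUNTY",
                offset=(float(off[0]), float(off[1])),
            )
        )
    return systems


def generate_subplot_network(
    systems,
    spacing: float,
    subplots_per_plot: int = 4,
    jitter: float = 0.0,
    seed: int = 0,
) -> SubplotPanel:
    """Jittered square plot lattice with nested subplots.

    Plot density is one plot per ``spacing²`` (4.9 km spacing ≈ one plot
    per 24 km²).  ``jitter`` displaces each plot uniformly in ±jitter per
    axis and must stay below spacing/2 so plots cannot swap lattice cells.
    Returns a panel skeleton: subplot coordinates, no occurrences yet.
    """
    if spacing <= 0:
        raise InvalidDomainError("spacing must be positive")
    if jitter >= spacing / 2:
        raise InvalidDomainError(
            f"jitter {jitter} must be < spacing/2 = {spacing / 2}"
        )
    first = systems[0] if isinstance(systems, (list, tuple)) else systems
    xmin, ymin, xmax, ymax = first.bounds()
    nx = int(np.floor((xmax - xmin) / spacing + 1e-9))
    ny = int(np.floor((ymax - ymin) / spacing + 1e-9))
    rng = np.random.default_rng(seed)
    # subplot offsets: center, then rings of three at increasing radius
    offsets = [(0.0, 0.0)]
    s = 1
    while len(offsets) < subplots_per_plot:
        ring = (len(offsets) - 1) // 3 + 1
        ang = np.deg2rad(90.0 - 120.0 * ((len(offsets) - 1) % 3))
        offsets.append(
            (ring * _SUBPLOT_RADIUS * np.cos(ang), ring * _SUBPLOT_RADIUS * np.sin(ang))
        )
        s += 1
    recs = {}
    pid = 0
    for iy in range(ny):
        for ix in range(nx):
            cx = xmin + (ix + 0.5) * spacing
            cy = ymin + (iy + 0.5) * spacing
            if jitter > 0:
                cx += rng.uniform(-jitter, jitter)
                cy += rng.uniform(-jitter, jitter)
            plot_id = f"P{pid:05d}"
            for k, (dx, dy) in enumerate(offsets, start=1):
                recs[f"{plot_id}_{k}"] = {
                    "plot_id": plot_id,
                    "x": cx + dx,
                    "y": cy + dy,
                }
            pid += 1
    subplots = pd.DataFrame.from_dict(recs, orient="index")
    subplots.index.name = "subplot_id"
    return SubplotPanel(
        subplots=subplots,
        occurrences=pd.DataFrame(
            columns=["subplot_id", "cycle", "species_code", "cover_pct"]
        ),
        cycles=[],
        metadata={"coordinate_system": "planar_m", "spacing": spacing},
    )


def _smooth_field(w: SpatialWeights, smoothness: float, rng) -> np.ndarray:
    """Standardized SAR-filtered white noise: (I − λW)⁻¹ ε, unit variance."""
    eps = rng.standard_normal(w.n)
    if smoothness == 0:
        z = eps
    else:
        a = np.eye(w.n) - smoothness * w.dense()
        z = np.linalg.solve(a, eps)
    sd = z.std(ddof=0)
    return (z - z.mean()) / (sd if sd > 0 else 1.0)


def simulate_covariates(
    units: UnitSystem, spec, seed: int = 0
) -> pd.DataFrame:
    """Spatially autocorrelated unit-level covariates.

    Each covariate is a monotone transform of SAR-smoothed white noise on
    the units' queen contiguity: percents through a logistic map to
    (0, 100), densities through an exponential map (nonnegative), and
    compositional groups through a softmax so class percents sum to 100.
    """
    specs = list(spec)
    if len(specs) < 2:
        raise InvalidDomainError("covariate spec must name at least two covariates")
    w = row_standardize(build_contiguity(units, "queen"))
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for cs in specs:
        if not (0 <= cs.smoothness < 1):
            raise InvalidDomainError(
                f"smoothness for {cs.name!r} must be in [0, 1)"
            )
        if cs.kind == "percent":
            z = _smooth_field(w, cs.smoothness, rng)
            logit0 = np.log(cs.mean / (100.0 - cs.mean))
            cols[cs.name] = 100.0 / (1.0 + np.exp(-(logit0 + cs.scale * z)))
        elif cs.kind == "density":
            z = _smooth_field(w, cs.smoothness, rng)
            cols[cs.name] = np.exp(np.log(max(cs.mean, 1e-12)) + cs.scale * z)
        elif cs.kind == "compositional":
            if len(cs.classes) < 2:
                raise InvalidDomainError(
                    f"compositional covariate {cs.name!r} needs >= 2 classes"
                )
            fields = np.column_stack(
                [_smooth_field(w, cs.smoothness, rng) for _ in cs.classes]
            )
            expf = np.exp(cs.scale * fields)
            shares = 100.0 * expf / expf.sum(axis=1, keepdims=True)
            for j, cls in enumerate(cs.classes):
                cols[f"{cs.name}_{cls}"] = shares[:, j]
        else:
            raise InvalidDomainError(f"unknown covariate kind {cs.kind!r}")
    return pd.DataFrame(cols, index=pd.Index(units.unit_ids, name="unit_id"))


def simulate_severity(
    w: SpatialWeights, x, truth: GroundTruth
) -> pd.Series:
    """Draw the latent unit severity from y = (I − ρW)⁻¹(Xβ + ε).

    Deterministic given ``truth.seed``; the realized surface is stored on
    ``truth.unit_severity``.
    """
    if isinstance(x, pd.DataFrame):
        names = list(x.columns)
        xmat = x.to_numpy(dtype=float)
        ids = list(x.index)
    else:
        xmat = np.asarray(x, dtype=float)
        names = [f"x{i}" for i in range(xmat.shape[1])]
        ids = list(w.ids)
    beta = np.asarray(truth.beta, dtype=float)
    if xmat.shape[1] != len(beta):
        raise InvalidDomainError(
            f"X has {xmat.shape[1]} columns but beta has {len(beta)}"
        )
    if w.style == "row" and not (-1.0 < truth.rho < 1.0):
        raise InfeasibleRhoError(
            f"rho={truth.rho} not strictly inside (-1, 1) for row-standardized W"
        )
    a = np.eye(w.n) - truth.rho * w.dense()
    # guard against a singular system even for exotic weight structures
    sign, logdet = np.linalg.slogdet(a)
    if sign == 0 or not np.isfinite(logdet):
        raise InfeasibleRhoError(f"I - rho*W singular at rho={truth.rho}")
    rng = np.random.default_rng(truth.seed)
    eps = truth.sigma * rng.standard_normal(w.n)
    y = np.linalg.solve(a, xmat @ beta + eps)
    truth.unit_severity = pd.Series(y, index=ids)
    if not truth.beta_names:
        truth.beta_names = names
    return truth.unit_severity


def simulate_occurrences(
    panel: SubplotPanel,
    units: UnitSystem,
    severity: pd.Series,
    species_profiles=None,
    cycle_multipliers=(1.0, 1.2, 1.4),
    cycles=("T1", "T2", "T3"),
    cover_scale: float = 20.0,
    presence_cap: float = 0.95,
    secondary_prob: float = 0.35,
    cover_concentration: float = 6.0,
    seed: int = 0,
) -> SubplotPanel:
    """Subplot-level occurrence records consistent with a severity surface.

    Presence is Bernoulli with p = √(target/cover_scale) (capped); total
    cover given presence is 100·Beta with mean target/p², occasionally
    split over a secondary species; the species identity follows the
    profile weights.  Re-aggregating with the index formulas recovers the
    per-unit target within Monte-Carlo error.  The per-subplot presence
    uniform is shared across cycles, so rising multipliers give
    non-decreasing infestation in every realization.
    """
    if species_profiles is None:
        species_profiles = DEFAULT_SPECIES_PROFILES
    sev = severity.astype(float)
    if (sev < 0).any():
        raise InvalidDomainError("severity must be non-negative")
    if len(cycle_multipliers) != len(cycles):
        raise InvalidDomainError("one multiplier per cycle is required")
    rng = np.random.default_rng(seed)
    membership = assign_units(panel, units)
    sub_ids = panel.subplots.index.to_numpy()
    unit_of = membership.to_numpy()
    u_presence = rng.random(len(sub_ids))  # shared across cycles (coupling)
    codes = np.array([p.code for p in species_profiles])
    base_w = np.array([p.weight for p in species_profiles], dtype=float)
    mults = np.array(
        [list(p.cycle_weight_multipliers) for p in species_profiles], dtype=float
    )
    records = []
    for ci, (cycle, mult) in enumerate(zip(cycles, cycle_multipliers)):
        target = sev.reindex(pd.Index(unit_of)).to_numpy() * float(mult)
        target = np.where(np.isnan(target), 0.0, target)
        p = np.sqrt(np.clip(target, 0.0, None) / cover_scale)
        p = np.minimum(p, presence_cap)
        present = u_presence < p
        if not present.any():
            continue
        idx = np.nonzero(present)[0]
        mu = np.clip(target[idx] / (p[idx] ** 2), 0.02, 95.0) / 100.0
        a = mu * cover_concentration
        b = (1.0 - mu) * cover_concentration
        total_cover = 100.0 * rng.beta(a, b)
        total_cover = np.clip(total_cover, 0.01, 100.0)
        wc = base_w * mults[:, ci]
        wc = wc / wc.sum()
        primary = rng.choice(len(codes), size=len(idx), p=wc)
        has_second = rng.random(len(idx)) < secondary_prob
        second = rng.choice(len(codes), size=len(idx), p=wc)
        for j, si in enumerate(idx):
            sid = sub_ids[si]
            if has_second[j] and second[j] != primary[j]:
                records.append((sid, cycle, codes[primary[j]],
                                round(0.7 * total_cover[j], 4)))
                records.append((sid, cycle, codes[second[j]],
                                round(0.3 * total_cover[j], 4)))
            else:
                records.append((sid, cycle, codes[primary[j]],
                                round(total_cover[j], 4)))
    occurrences = pd.DataFrame(
        records, columns=["subplot_id", "cycle", "species_code", "cover_pct"]
    )
    return SubplotPanel(
        subplots=panel.subplots,
        occurrences=occurrences,
        cycles=list(cycles),
        metadata=dict(panel.metadata),
    )


# --------------------------------------------------------------------- IO


def write_landscape(outdir, systems, panel, covariates, truth) -> list[str]:
    """Write the generated study system as plain-text artifacts.

    plots.csv, subplots.csv, occurrences.csv, covariates.csv, truth.json
    and one ``units_<system>.geojson`` per unit system; byte-identical for
    identical seeds.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    plots = (
        panel.subplots.groupby("plot_id")[["x", "y"]]
        .mean()
        .round(4)
        .reset_index()
    )
    plots.to_csv(outdir / "plots.csv", index=False)
    written.append("plots.csv")
    panel.subplots.round(4).reset_index().to_csv(
        outdir / "subplots.csv", index=False
    )
    written.append("subplots.csv")
    panel.occurrences.to_csv(outdir / "occurrences.csv", index=False)
    written.append("occurrences.csv")
    covariates.round(6).reset_index().to_csv(outdir / "covariates.csv", index=False)
    written.append("covariates.csv")
    truth.to_json(outdir / "truth.json")
    written.append("truth.json")
    for system in systems:
        name = f"units_{system.system_id}.geojson"
        system.to_geojson(outdir / name)
        written.append(name)
    return written


#: Representative inventory year written for each cycle in FIA-style export.
CYCLE_YEARS = {"T1": 2003, "T2": 2009, "T3": 2016}


def write_fia_tables(panel: SubplotPanel, outdir, owncd: int = 40) -> list[str]:
    """Export the panel as FIA-style occurrence/plot/condition CSVs.

    The occurrence table uses (PLT_CN, SUBP, VEG_SPCD, COVER_PCT, INVYR);
    the plot table repeats each plot once per cycle with its inventory
    year, so re-reading through the ingest module round-trips the panel.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    occ = panel.occurrences.copy()
    parts = occ["subplot_id"].str.rsplit("_", n=1, expand=True)
    occ["PLT_CN"] = parts[0]
    occ["SUBP"] = parts[1]
    occ["INVYR"] = occ["cycle"].map(CYCLE_YEARS)
    occ = occ.rename(columns={"species_code": "VEG_SPCD", "cover_pct": "COVER_PCT"})
    occ[["PLT_CN", "SUBP", "VEG_SPCD", "COVER_PCT", "INVYR"]].to_csv(
        outdir / "fia_occurrence.csv", index=False
    )
    plots = (
        panel.subplots.groupby("plot_id")[["x", "y"]].mean().round(4).reset_index()
    )
    rows = []
    for cycle in panel.cycles or list(CYCLE_YEARS):
        for _, r in plots.iterrows():
            rows.append(
                {
                    "PLT_CN": r["plot_id"],
                    "X": r["x"],
                    "Y": r["y"],
                    "INVYR": CYCLE_YEARS[cycle],
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "fia_plot.csv", index=False)
    pd.DataFrame(
        {"PLT_CN": plots["plot_id"], "OWNCD": owncd}
    ).to_csv(outdir / "fia_cond.csv", index=False)
    return ["fia_occurrence.csv", "fia_plot.csv", "fia_cond.csv"]
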
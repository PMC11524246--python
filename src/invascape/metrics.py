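"""Per-unit invasion severity: presence probability × mean cover.

For modeling unit *i* and measurement cycle *j*:

    P_ij = S_ij / N_ij            presence probability
    C_ij = Σ c_ij / N_ij          mean cover percent
    invasion index = P_ij × C_ij  severity

where N_ij counts all subplots in the unit (uninfested ones included in
the denominator), S_ij counts infested subplots, and Σ c_ij sums the cover
percent of every invasive species record on every subplot.  Because covers
sum across species, C can in principle exceed 100; no cap is applied.

Units too small to contain any subplot get their index filled by
inverse-distance-weighted (IDW) interpolation from observed units and are
flagged, so downstream statistics can exclude them.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from shapely.geometry import mapping
from shapely.strtree import STRtree

from invascape.errors import ImputationImpossibleError, InvalidDomainError
from invascape.units import UnitSystem

__all__ = [
    "assign_units",
    "presence_probability",
    "mean_cover",
    "invasion_index",
    "compute_unit_table",
    "idw_impute",
    "write_unit_geojson",
]


def assign_units(panel, units: UnitSystem) -> pd.Series:
    """Map each subplot to the unit polygon containing it.

    A point on a shared boundary belongs to the unit with the
    lexicographically smallest unit_id (deterministic, order independent).
    Subplots outside every unit map to NaN.  Overlapping units are an
    invariant violation and raise.
    """
    units.validate_no_overlap()
    subplots = panel.subplots if hasattr(panel, "subplots") else panel
    from shapely.geometry import Point

    pts = [Point(x, y) for x, y in zip(subplots["x"], subplots["y"])]
    tree = STRtree(units.geometries)
    pi, gi = tree.query(pts, predicate="intersects")
    ids = np.array(units.unit_ids, dtype=object)
    best: dict[int, str] = {}
    for p, g in zip(pi, gi):
        uid = ids[g]
        if p not in best or uid < best[p]:
            best[p] = uid
    out = pd.Series(
        [best.get(i, np.nan) for i in range(len(pts))],
        index=subplots.index,
        name="unit_id",
    )
    return out


def presence_probability(n_infested: int, n_subplots: int):
    """P = S/N, the fraction of subplots with at least one invasive."""
    if n_infested < 0 or n_subplots < 0:
        raise InvalidDomainError("counts must be non-negative")
    if n_infested > n_subplots:
        raise InvalidDomainError(
            f"infested count {n_infested} exceeds subplot count {n_subplots}"
        )
    if n_subplots == 0:
        return None
    return n_infested / n_subplots


def mean_cover(cover_values, n_subplots: int):
    """C = (Σ covers over all species and subplots) / N.

    The denominator is the total subplot count of the unit-cycle, not just
    the infested ones; an empty cover list gives 0.
    """
    if n_subplots < 0:
        raise InvalidDomainError("subplot count must be non-negative")
    if n_subplots == 0:
        return None
    total = float(np.sum(cover_values)) if len(cover_values) else 0.0
    return total / n_subplots


def invasion_index(presence_prob, mean_cover_pct):
    """Severity = P × C; zero iff either factor is zero."""
    if presence_prob is None or mean_cover_pct is None:
        return None
    if presence_prob < 0 or presence_prob > 1:
        raise InvalidDomainError(f"presence probability {presence_prob} not in [0,1]")
    if mean_cover_pct < 0:
        raise InvalidDomainError(f"mean cover {mean_cover_pct} negative")
    return presence_prob * mean_cover_pct


def compute_unit_table(
    panel,
    units: UnitSystem,
    species_scope: str = "all",
    cycles=None,
    membership: pd.Series | None = None,
) -> pd.DataFrame:
    """One row of (N, S, P, C, index) per unit and cycle.

    ``species_scope`` is ``"all"`` or a single species code.  Units
    containing no subplots get NaN metrics and are left for
    :func:`idw_impute`.  ``membership`` may be passed to reuse a previous
    :func:`assign_units` result.
    """
    if membership is None:
        membership = assign_units(panel, units)
    if cycles is None:
        cycles = panel.cycles
    occ = panel.occurrences
    if species_scope != "all":
        occ = occ[occ["species_code"] == species_scope]
    n_by_unit = membership.dropna().value_counts()
    rows = []
    for cycle in cycles:
        occ_c = occ[occ["cycle"] == cycle]
        occ_c = occ_c.merge(
            membership.rename("unit_id"), left_on="subplot_id", right_index=True
        )
        infested = (
            occ_c.groupby("unit_id")["subplot_id"].nunique()
            if len(occ_c)
            else pd.Series(dtype=int)
        )
        cover_sum = (
            occ_c.groupby("unit_id")["cover_pct"].sum()
            if len(occ_c)
            else pd.Series(dtype=float)
        )
        for uid in units.unit_ids:
            n = int(n_by_unit.get(uid, 0))
            s = int(infested.get(uid, 0))
            csum = float(cover_sum.get(uid, 0.0))
            p = presence_probability(s, n)
            c = (csum / n) if n > 0 else None
            idx = invasion_index(p, c)
            rows.append(
                {
                    "system_id": units.system_id,
                    "unit_id": uid,
                    "cycle": cycle,
                    "n_subplots": n,
                    "n_infested": s,
                    "presence_prob": np.nan if p is None else p,
                    "mean_cover": np.nan if c is None else c,
                    "invasion_index": np.nan if idx is None else idx,
                    "imputed": False,
                }
            )
    table = pd.DataFrame(rows)
    n_empty = int((table["n_subplots"] == 0).sum())
    if len(table) and n_empty == len(table):
        warnings.warn(
            f"system {units.system_id!r}: no subplot falls in any unit", stacklevel=2
        )
    return table


def idw_impute(
    table: pd.DataFrame,
    centroids: pd.DataFrame,
    power: float = 2.0,
    neighbors="all",
    value_cols=("invasion_index",),
) -> pd.DataFrame:
    """Fill units without subplots by inverse-distance weighting.

    For a missing unit, value = Σ dᵢ^(−power)·vᵢ / Σ dᵢ^(−power) over the
    observed donor units of the same cycle, with distances between unit
    centroids.  A donor coincident with the target centroid contributes its
    value exactly (limit rule; coincident donors are averaged).  Observed
    values are never altered; filled rows get ``imputed=True``.  By design
    only the final invasion index is imputed — recombining separately
    imputed P and C would not multiply back consistently.
    """
    if power <= 0:
        raise InvalidDomainError("IDW power must be positive")
    out = table.copy()
    for cycle, grp in out.groupby("cycle"):
        observed = grp[grp["n_subplots"] > 0]
        missing = grp[grp["n_subplots"] == 0]
        if missing.empty:
            continue
        if observed.empty:
            raise ImputationImpossibleError(
                f"cycle {cycle!r}: every unit is missing; nothing to impute from"
            )
        don_xy = centroids.loc[observed["unit_id"], ["x", "y"]].to_numpy(float)
        for col in value_cols:
            dvals = observed[col].to_numpy(float)
            for ridx, row in missing.iterrows():
                tx, ty = centroids.loc[row["unit_id"], ["x", "y"]]
                d = np.hypot(don_xy[:, 0] - tx, don_xy[:, 1] - ty)
                if neighbors != "all":
                    k = min(int(neighbors), len(d))
                    keep = np.argsort(d, kind="stable")[:k]
                else:
                    keep = np.arange(len(d))
                dk, vk = d[keep], dvals[keep]
                zero = dk < 1e-12
                if zero.any():
                    out.loc[ridx, col] = float(vk[zero].mean())
                else:
                    wgt = dk ** (-power)
                    out.loc[ridx, col] = float((wgt * vk).sum() / wgt.sum())
        out.loc[missing.index, "imputed"] = True
    return out


def write_unit_geojson(
    table: pd.DataFrame, units: UnitSystem, cycle: str, path
) -> None:
    """Choropleth-ready GeoJSON of one cycle's per-unit metrics."""
    sub = table[table["cycle"] == cycle].set_index("unit_id")
    features = []
    for uid, row in units.table.iterrows():
        props = {"unit_id": uid, "cycle": cycle}
        if uid in sub.index:
            rec = sub.loc[uid]
            for col in ("presence_prob", "mean_cover", "invasion_index"):
                v = rec[col]
                props[col] = None if pd.isna(v) else float(v)
            props["imputed"] = bool(rec["imputed"])
            props["n_subplots"] = int(rec["n_subplots"])
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(row["geometry"]),
                "properties": props,
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")
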
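"""Global Moran's I: statistic, Cliff–Ord inference, and scale selection.

Moran's I measures spatial autocorrelation of a per-unit variable under a
spatial weights structure.  Under no autocorrelation its expectation is
−1/(n−1); positive values indicate clustering.  The closed-form variance
follows Cliff & Ord under either the normality or the randomization
(permutation-moment) assumption; a Monte-Carlo permutation test is also
provided as a reference.

Scale selection ranks candidate unit systems by the Moran's I of their
invasion index and picks the system with the strongest clustering — the
rationale being that the scale at which severity is most spatially
organized is the most informative modeling unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from invascape.errors import (
    InsufficientUnitsError,
    SelectionImpossibleError,
    UndefinedStatisticError,
)
from invascape.weights import SpatialWeights

__all__ = [
    "MoranResult",
    "morans_i",
    "morans_test",
    "morans_i_permutation",
    "select_best_unit",
]


@dataclass
class MoranResult:
    """Moran's I with analytic inference.

    ``z`` is the standard deviate (I − E[I]) / sqrt(Var[I]); ``p`` is the
    p-value for the chosen alternative.  ``n_used`` counts the units that
    entered the computation after island/missing exclusions.
    """

    i: float
    expectation: float
    variance: float
    z: float
    p: float
    n_used: int
    variance_assumption: str = "randomization"
    alternative: str = "greater"


def _prepare(x, w: SpatialWeights):
    """Align x to w, drop missing values and islands, return (z, W', n)."""
    if isinstance(x, pd.Series):
        vals = x.reindex(w.ids).to_numpy(dtype=float)
    else:
        vals = np.asarray(x, dtype=float)
        if vals.shape != (w.n,):
            raise ValueError(f"x has shape {vals.shape}, expected ({w.n},)")
    keep = ~np.isnan(vals)
    keep &= w.cardinalities > 0
    if keep.all():
        sub = w
    else:
        sub = w.subset([uid for uid, k in zip(w.ids, keep) if k])
        vals = vals[keep]
        # restriction may strand further islands; drop until stable
        while len(sub.islands) > 0:
            inner = ~np.isin(np.array(sub.ids), np.array(sub.islands))
            vals = vals[inner]
            sub = sub.subset([uid for uid, k in zip(sub.ids, inner) if k])
    n = sub.n
    if n < 3:
        raise InsufficientUnitsError(f"Moran's I needs n >= 3 usable units, got {n}")
    z = vals - vals.mean()
    if np.allclose(z, 0.0):
        raise UndefinedStatisticError("Moran's I is undefined for constant x")
    return z, sub, n


def morans_i(x, w: SpatialWeights) -> float:
    """Global Moran's I of ``x`` under weights ``w``.

    I = (n / S0) · Σ_i Σ_j w_ij z_i z_j / Σ_i z_i²  with  z = x − mean(x).
    ``x`` may be a pandas Series indexed by unit id (aligned to ``w.ids``)
    or an array in ``w.ids`` order; missing values and islands are excluded
    and the weights restricted accordingly.
    """
    z, sub, n = _prepare(x, w)
    s0, _, _ = sub.moments()
    num = float(z @ sub.sparse().dot(z))
    return (n / s0) * num / float(z @ z)


def morans_test(
    x,
    w: SpatialWeights,
    variance: str = "randomization",
    alternative: str = "greater",
) -> MoranResult:
    """Moran's I with closed-form Cliff–Ord inference.

    ``variance="randomization"`` uses the permutation-moment variance
    (involves the sample kurtosis b2); ``"normality"`` assumes Gaussian x.
    The two agree exactly when b2 = 3.
    """
    if variance not in ("randomization", "normality"):
        raise ValueError(f"unknown variance assumption {variance!r}")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    z, sub, n = _prepare(x, w)
    s0, s1, s2 = sub.moments()
    i_obs = (n / s0) * float(z @ sub.sparse().dot(z)) / float(z @ z)
    e_i = -1.0 / (n - 1)
    if variance == "normality":
        var = (n * n * s1 - n * s2 + 3 * s0 * s0) / ((n * n - 1) * s0 * s0) - e_i * e_i
    else:
        if n <= 3:
            raise InsufficientUnitsError(
                "randomization variance requires n > 3 usable units"
            )
        m2 = float(z @ z) / n
        m4 = float((z**4).sum()) / n
        b2 = m4 / (m2 * m2)
        num = n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0) - b2 * (
            (n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0
        )
        var = num / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - e_i * e_i
    zstat = (i_obs - e_i) / np.sqrt(var)
    if alternative == "greater":
        p = float(stats.norm.sf(zstat))
    elif alternative == "less":
        p = float(stats.norm.cdf(zstat))
    else:
        p = float(2 * stats.norm.sf(abs(zstat)))
    return MoranResult(
        i=float(i_obs),
        expectation=e_i,
        variance=float(var),
        z=float(zstat),
        p=p,
        n_used=n,
        variance_assumption=variance,
        alternative=alternative,
    )


def morans_i_permutation(
    x,
    w: SpatialWeights,
    n_permutations: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> tuple[float, float, np.ndarray]:
    """Monte-Carlo permutation test for Moran's I.

    Returns ``(I_observed, p_value, permuted_values)``.  The p-value uses
    the standard (1 + #extreme) / (1 + n_permutations) estimator.
    """
    z, sub, n = _prepare(x, w)
    s0, _, _ = sub.moments()
    wmat = sub.sparse()
    denom = float(z @ z)
    i_obs = (n / s0) * float(z @ wmat.dot(z)) / denom
    rng = np.random.default_rng(seed)
    perms = np.empty(n_permutations)
    for k in range(n_permutations):
        zp = rng.permutation(z)
        perms[k] = (n / s0) * float(zp @ wmat.dot(zp)) / denom
    if alternative == "greater":
        p = (1 + int((perms >= i_obs).sum())) / (1 + n_permutations)
    elif alternative == "less":
        p = (1 + int((perms <= i_obs).sum())) / (1 + n_permutations)
    else:
        e = perms.mean()
        p = (1 + int((np.abs(perms - e) >= abs(i_obs - e)).sum())) / (
            1 + n_permutations
        )
    return float(i_obs), float(p), perms


@dataclass
class SelectionResult:
    """Outcome of multiscale unit selection."""

    ranking: pd.DataFrame  # system, cycle, n_used, moran_i, z, p, chosen
    chosen_by_cycle: dict
    overall: str
    ties: list


def select_best_unit(
    index_tables: dict,
    weights: dict,
    cycles=None,
    value_col: str = "invasion_index",
    include_imputed: bool = False,
    variance: str = "randomization",
) -> SelectionResult:
    """Rank unit systems by the Moran's I of their invasion index.

    ``index_tables`` maps system_id → per-unit index table (one row per
    unit and cycle, with an ``imputed`` flag); ``weights`` maps system_id →
    its SpatialWeights.  Per cycle the chosen system is the one with the
    highest I; ties go to the system with fewer units (coarser).  The
    overall winner is the system winning the most cycles, same tie rule.
    Imputed units are excluded by default: interpolated values would
    manufacture spatial smoothness.
    """
    if len(index_tables) < 2:
        raise SelectionImpossibleError("need at least two candidate systems")
    rows = []
    if cycles is None:
        cycles = sorted({c for t in index_tables.values() for c in t["cycle"].unique()})
    elif isinstance(cycles, str):
        cycles = [cycles]
    for system_id, table in index_tables.items():
        w = weights[system_id]
        for cycle in cycles:
            sub = table[table["cycle"] == cycle]
            if not include_imputed and "imputed" in sub.columns:
                sub = sub[~sub["imputed"].astype(bool)]
            x = pd.Series(sub[value_col].to_numpy(), index=sub["unit_id"])
            try:
                res = morans_test(x, w, variance=variance)
                rows.append(
                    {
                        "system": system_id,
                        "cycle": cycle,
                        "n_units": w.n,
                        "n_used": res.n_used,
                        "moran_i": res.i,
                        "z": res.z,
                        "p": res.p,
                    }
                )
            except (InsufficientUnitsError, UndefinedStatisticError) as exc:
                rows.append(
                    {
                        "system": system_id,
                        "cycle": cycle,
                        "n_units": w.n,
                        "n_used": 0,
                        "moran_i": np.nan,
                        "z": np.nan,
                        "p": np.nan,
                        "note": str(exc),
                    }
                )
    ranking = pd.DataFrame(rows)
    if ranking["moran_i"].isna().all():
        raise SelectionImpossibleError("no system admits a valid Moran's I")
    chosen = {}
    ties = []
    for cycle in cycles:
        sub = ranking[(ranking["cycle"] == cycle) & ranking["moran_i"].notna()]
        if sub.empty:
            continue
        best_i = sub["moran_i"].max()
        cand = sub[np.isclose(sub["moran_i"], best_i)]
        if len(cand) > 1:
            ties.append((cycle, sorted(cand["system"])))
        chosen[cycle] = cand.sort_values(["n_units", "system"]).iloc[0]["system"]
    wins = pd.Series(list(chosen.values())).value_counts()
    top = wins[wins == wins.max()].index
    if len(top) > 1:
        sizes = {s: weights[s].n for s in top}
        overall = min(top, key=lambda s: (sizes[s], s))
        ties.append(("overall", sorted(top)))
    else:
        overall = top[0]
    ranking["chosen"] = [
        chosen.get(c) == s for s, c in zip(ranking["system"], ranking["cycle"])
    ]
    return SelectionResult(
        ranking=ranking, chosen_by_cycle=chosen, overall=overall, ties=ties
    )
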
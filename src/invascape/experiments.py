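"""Canned validation experiments with synthetic ground truth.

These are the package's own calibration studies: each generates data from
a known process and measures how well the corresponding estimator recovers
it.  They are used both by the test suite and by the results-reproduction
script, so the study conditions live here in one place.

Study conditions (fixed):

* ``moran_tail_calibration`` — closed-form Cliff–Ord inference versus a
  9,999-draw permutation reference on a 6×6 grid, evaluated on a clustered
  input (the regime where a Moran test decides anything).  The permutation
  distribution is mildly skewed, so closed-form and Monte-Carlo p-values
  are compared in the tail; the first two moments are compared exactly.
* ``sar_recovery`` — ρ* = 0.5, β* = (4, 0.03), σ = 1 on a 10×10 queen
  lattice (n = 100), 50 replicates: fraction of fits with every parameter
  inside ±3 estimated SEs, and the residual-Moran adequacy rate.
* ``scale_identification`` — severity driven at the county scale by a
  neighbor-averaged covariate (correlation range ≈ 2 county widths), then
  observed through a 4.9-km plot network and re-aggregated onto a nested
  hierarchy (4 / 16 / 784 units) plus the 256-unit county-like grid
  itself; counts how often Moran ranking picks the county scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from invascape.metrics import compute_unit_table, idw_impute
from invascape.moran import morans_i_permutation, morans_test, select_best_unit
from invascape.sar import fit_sar_ml, neighbor_average, residual_autocorrelation
from invascape.synthetic import (
    GroundTruth,
    generate_subplot_network,
    generate_unit_hierarchy,
    simulate_occurrences,
    simulate_severity,
)
from invascape.units import grid_partition
from invascape.weights import build_contiguity, row_standardize

__all__ = [
    "moran_tail_calibration",
    "sar_recovery",
    "scale_identification",
]


def moran_tail_calibration(seed: int, n_permutations: int = 9999) -> dict:
    """Closed-form vs permutation Moran inference on a clustered 6×6 field."""
    grid = grid_partition((0.0, 0.0, 6000.0, 6000.0), 6, 6, "G6")
    w = row_standardize(build_contiguity(grid, "queen"))
    rng = np.random.default_rng(seed)
    gradient = np.add.outer(np.arange(6), np.arange(6)).ravel().astype(float)
    x = gradient + 3.0 * rng.normal(size=36)
    closed = morans_test(x, w, variance="randomization", alternative="greater")
    _, p_perm, perms = morans_i_permutation(
        x, w, n_permutations, seed=seed + 1, alternative="greater"
    )
    return {
        "p_closed": closed.p,
        "p_permutation": p_perm,
        "p_abs_diff": abs(closed.p - p_perm),
        "expectation_closed": closed.expectation,
        "expectation_permutation": float(perms.mean()),
        "variance_closed": closed.variance,
        "variance_permutation": float(perms.var()),
        "n": 36,
    }


def sar_recovery(
    seed: int,
    replicates: int = 50,
    rho_true: float = 0.5,
    beta_true: tuple = (4.0, 0.03),
    sigma: float = 1.0,
) -> dict:
    """Parameter recovery and residual adequacy of the SAR ML fit."""
    grid = grid_partition((0.0, 0.0, 10000.0, 10000.0), 10, 10, "G10")
    w = row_standardize(build_contiguity(grid, "queen"))
    hits = adequate = 0
    rhos = []
    for rep in range(replicates):
        rng = np.random.default_rng(seed + 1000 + rep)
        x1 = rng.uniform(0.0, 100.0, w.n)
        design = pd.DataFrame({"intercept": 1.0, "x1": x1}, index=w.ids)
        truth = GroundTruth(
            rho=rho_true,
            beta=np.asarray(beta_true, float),
            sigma=sigma,
            seed=seed + 5000 + rep,
        )
        y = simulate_severity(w, design, truth)
        fit = fit_sar_ml(y, pd.DataFrame({"x1": x1}, index=w.ids), w)
        ok = abs(fit.rho - rho_true) <= 3 * fit.se_rho
        ok &= abs(fit.beta["intercept"] - beta_true[0]) <= 3 * fit.se_beta["intercept"]
        ok &= abs(fit.beta["x1"] - beta_true[1]) <= 3 * fit.se_beta["x1"]
        hits += bool(ok)
        rhos.append(fit.rho)
        if residual_autocorrelation(fit, w).p >= 0.05:
            adequate += 1
    return {
        "recovery_rate": hits / replicates,
        "adequacy_rate": adequate / replicates,
        "rho_mean": float(np.mean(rhos)),
        "replicates": replicates,
        "n_units": w.n,
    }


def scale_identification(seed: int, n_seeds: int = 20) -> dict:
    """How often Moran ranking picks the severity-generating county scale."""
    extent = (0.0, 0.0, 196_000.0, 196_000.0)
    wins = 0
    for k in range(n_seeds):
        rep_seed = seed + 10_000 + 37 * k
        systems = generate_unit_hierarchy(
            extent,
            (2, 2),
            [2, 7],
            seed=rep_seed + 1,
            prefix="H",
            include_county=True,
            county_grid=(16, 16),
        )
        by_id = {s.system_id: s for s in systems}
        county = by_id["COUNTY"]
        w = row_standardize(build_contiguity(county, "queen"))
        rng = np.random.default_rng(rep_seed + 2)
        noise = pd.Series(rng.normal(size=len(county)), index=county.unit_ids)
        # neighbor-averaged driver: correlation range about two county widths
        driver = neighbor_average(noise + neighbor_average(noise, w), w)
        driver = (driver - driver.mean()) / driver.std()
        design = pd.DataFrame(
            {"intercept": 1.0, "driver": driver}, index=county.unit_ids
        )
        truth = GroundTruth(
            rho=0.15, beta=np.array([7.0, 3.2]), sigma=0.3, seed=rep_seed + 3
        )
        severity = simulate_severity(w, design, truth).clip(lower=0.0)
        panel = generate_subplot_network(
            [county], 4900.0, 4, 300.0, seed=rep_seed + 4
        )
        panel = simulate_occurrences(
            panel,
            county,
            severity,
            cycle_multipliers=(1.0, 1.2, 1.4),
            cover_concentration=40.0,
            seed=rep_seed + 5,
        )
        tables, weights = {}, {}
        for name, system in by_id.items():
            table = compute_unit_table(panel, system)
            table = idw_impute(table, system.centroids())
            tables[name] = table
            weights[name] = row_standardize(build_contiguity(system, "queen"))
        selection = select_best_unit(tables, weights)
        wins += selection.overall == "COUNTY"
    return {"identification_rate": wins / n_seeds, "n_seeds": n_seeds}
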
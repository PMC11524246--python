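# invascape

Multiscale mapping and modeling of nonnative invasive plant species (NNIPS)
severity on forest-inventory plot networks.

National forest inventories (FIA-style) record invasive presence and percent
cover on a grid of permanent plots, each with four nested subplots, revisited
in multi-year measurement cycles.  Managers need to know *at which spatial
scale* invasion is organized — watershed, ecoregion, or county — and *what
drives it*.  `invascape` implements that workflow end to end for analysts of
such inventories, together with a synthetic-landscape generator with known
ground truth so every stage can be validated without restricted plot
coordinates.

## The statistics at the core

For modeling unit *i* and measurement cycle *j*, with N_ij subplots of which
S_ij are infested and per-record cover percents c:

    P_ij = S_ij / N_ij                    presence probability
    C_ij = Σ c_ij / N_ij                  mean cover percent (sums species)
    invasion index_ij = P_ij × C_ij       severity

Units too small to contain a subplot are filled by inverse-distance-weighted
(IDW) interpolation and flagged.  Candidate unit systems (nested hierarchies
and a county-like partition) are ranked per cycle by global Moran's I of the
invasion index,

    I = (n / S0) · Σ_i Σ_j w_ij z_i z_j / Σ_i z_i²,   z = x − x̄,

with Cliff–Ord closed-form inference (randomization or normality variance)
and a permutation reference.  On the chosen scale, severity is explained by
a spatial-lag (SAR) model

    Y = ρ W Y + X β + ε,   ε ~ N(0, σ² I),

fitted by concentrated maximum likelihood with an exact eigenvalue
log-determinant, covariate screening at |r| > 0.6, stepwise AIC search
(k = p + 2, counting ρ and σ²), Wald inference, and a Moran diagnostic on
the residuals.

## Worked example

```sh
invascape run-all --outdir run --seed 42
```

generates a 98 × 98 km synthetic landscape (nine unit systems: five
watershed-like levels, three ecoregion-like levels, one offset county-like
grid; 400 plots / 1,600 subplots; severity drawn from a SAR process on the
county-like scale), ingests it as FIA-style tables, and runs the full
analysis.  From `run/report.txt`:

```
Infestation by measurement cycle:
cycle  total_subplots  infested_subplots  infestation_pct  species_occurrences  mean_species_per_infested
   T1            1600                675             42.2                  825                       1.22
   T2            1600                751             46.9                  929                       1.24
   T3            1600                821             51.3                 1032                       1.26
```

Infestation rises across cycles because the generator's per-cycle severity
multipliers rise (1.0, 1.2, 1.4).  The Moran comparison
(`run/moran_comparison.csv`, cycle T3 shown) ranks the aggregation scales:

```
system  n_used  moran_i      z      p
COUNTY      49   0.3861 5.2540 0.0000
    E2      36   0.3677 4.3810 0.0000
    H3      64   0.3582 5.6262 0.0000
    H1       4  -0.3333 0.0000 0.5000
...
```

and `run/sar_fit_T3.json` holds the spatial-lag fit on the chosen scale —
here ρ̂ = 0.56 (SE 0.18, p = 0.002) against a generating ρ = 0.6, a
population-density coefficient of 0.035 (truth 0.03), and a residual
Moran p of 0.31, i.e. the lag term absorbed the spatial structure.

Every stage is also exposed separately (`simulate`, `ingest`, `index`,
`select-unit`, `fit-sar`, `report`) over a YAML config, and the whole
library can be driven from Python:

```python
from invascape import fit_sar_ml, morans_test
fit = fit_sar_ml(y, X, weights)      # y: Series by unit, X: DataFrame
print(fit.summary())
```

## Layout

| module | contents |
| --- | --- |
| `invascape.synthetic` | landscape generator: hierarchies, plot network, covariates, SAR severity, occurrences |
| `invascape.ingest` | FIA-style table reading, cycle coding, balanced panel, summaries |
| `invascape.metrics` | presence/cover/index per unit and cycle, IDW imputation |
| `invascape.weights` / `invascape.moran` | contiguity weights, Moran's I and inference, scale selection |
| `invascape.sar` | spatial-lag ML, screening, stepwise AIC, residual diagnostics |
| `invascape.pipeline` / `invascape.cli` | orchestration, manifest, reporting, CLI |
| `invascape.experiments` | canned calibration studies used by tests and the reproduction script |

See `docs/methods.md` for the modeling assumptions, generator design and
numerical choices.
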
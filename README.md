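# plelscape

Landscape ecological security analysis for oasis cities in arid regions,
built around the production–living–ecological land (PLEL) view of land use.
The package is aimed at landscape ecologists and land-use modellers who want
a scriptable, fully seeded version of the standard grid-based risk /
coupling-coordination / multi-scenario simulation workflow, runnable
end-to-end on synthetic rasters without any data download.

## What it computes

Land-use rasters are reclassified into 8 PLEL classes (APL, IPL, ULL, RLL,
FEL, GEL, WEL, OEL, grouped into production / living / ecological tiers).
The study area is tiled into square evaluation units; for each unit *k* and
class *i* present in it the landscape ecological risk index is

```
ERI_k = Σ_i (A_ki / A_k) · E_ki · F_i
E_ki  = 0.5·C_ki + 0.3·S_ki + 0.2·D_i          (disturbance)
C_ki  = n_ki / A_ki                             (fragmentation)
S_ki  = (A_k / 2A_ki) · sqrt(n_ki / A_k)        (separation)
D_i   = (Q_i + M_i)/4 + L_i/2                   (dominance)
```

with areas in hm² and F the normalized vulnerability ranks
(0.03 … 0.22).  Unit values are interpolated by ordinary kriging and cut
into five security levels (thresholds 0.0061 / 0.0079 / 0.0096 / 0.012);
spatial clustering is measured by global Moran's I with a permutation test.
Tier risks U1/U2/U3 feed a coupling coordination degree model
(C, T = Σ αU, D = √(C·T)) with five coordination levels.  Future land
demand comes from a Markov projection (NLD scenario) and from linear
programs maximizing economic (ECD), ecological (ELD) or blended (EED)
objectives under box, total-area and population constraints, with a GM(1,1)
grey-forecasting utility; a patch-growing cellular automaton allocates a
demand vector in space and is validated by confusion-matrix kappa against a
persistence baseline.

## Worked example

The whole pipeline runs from one command on a seeded synthetic oasis
landscape (a 300×300-cell, 30 m corridor-structured mosaic, three epochs):

```
plelscape --outdir demo --seed 1 run-all
```

This writes CSV tables and ESRI ASCII rasters under `demo/`.  With seed 1
the run log reports a hindcast kappa of **0.956** (overall accuracy 96.8 %)
against a persistence-baseline kappa of 0.918: the allocator reproduces the
held-out third epoch better than assuming no change.  `morans_i.csv` lists
the per-epoch mean unit ERI (0.0175, 0.0194, 0.0185 here — the magnitude
the hm²-based formulas produce on an 8-class mosaic), and
`scenario_demand.csv` holds the four 2030-style demand vectors; the ECD
column reproduces the scenario-program optima below.  Each stage is also
available as its own subcommand (`simulate-data`, `reclass`, `risk`,
`surface`, `ccd`, `demand`, `allocate`, `validate`).

As a library:

```python
from plelscape import risk_index as rk, scenarios as scn

rk.vulnerability_weights()          # ULL 0.03 ... OEL 0.22
demand, value = scn.solve_scenario_lp(scn.load_default_spec("economic"))
demand.round(2)
# APL    144917.10
# IPL      3319.02
# ULL      4424.58
# RLL      9719.19
# FEL     22562.69
# GEL    357380.01
# WEL     49388.31
# OEL    140649.88
```

## Layout

```
src/plelscape/
  synthetic_data.py    seeded oasis landscapes, epoch series, driver stacks
  plel_core.py         rasters, reclassification, areas, transition matrices
  risk_index.py        evaluation grid, landscape metrics, ERI
  security_surface.py  ordinary kriging, security levels, Moran's I
  coupling.py          coupling coordination degree model
  scenarios.py         Markov, GM(1,1), scenario linear programs
  allocation.py        suitability learning + CA spatial allocator
  cli_pipeline.py      orchestration and the `plelscape` CLI
docs/methods.md        model assumptions, parameters, limitations
```
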
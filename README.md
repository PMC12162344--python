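# wapmelt

Analysis toolkit for the question of how sea-surface glacial meltwater
(sGMW) relates to phytoplankton biomass along the Western Antarctic
Peninsula (WAP). The WAP is warming rapidly; its glaciers discharge
increasing amounts of buoyant, nutrient-bearing meltwater into one of the
Southern Ocean's most productive shelf ecosystems, while the winter sea-ice
season shortens. `wapmelt` implements the full computational chain needed
to study that interplay from gridded satellite/reanalysis fields, bottle
samples and hydrographic profiles — and ships seeded synthetic-data
generators so the whole chain is testable without downloading anything.

Intended users: polar marine ecologists and remote-sensing analysts who
want a tested, reusable version of these standard reductions rather than
one-off notebook code.

## What it computes

**Water-mass decomposition** (`wapmelt.watermass`). Each near-surface
sample with measured salinity and δ¹⁸O is treated as a mixture of sea-ice
meltwater (sim), meteoric water (met = precipitation + glacial meltwater)
and ocean water (ow), solving

```
F_sim + F_met + F_ow                       = 1
S_sim·F_sim + S_met·F_met + S_ow·F_ow      = S_total
δ¹⁸O_sim·F_sim + δ¹⁸O_met·F_met + δ¹⁸O_ow·F_ow = δ¹⁸O_total
```

for the fractions F, given end-member signatures (S, δ¹⁸O) of the three
source waters. Fractions are reported unclipped with an out-of-range flag;
F_met is the usual sGMW proxy where local precipitation is small.
End-member values must be supplied explicitly — they are a calibration
choice, and the package refuses to decompose without them
(`wapmelt example-config` prints an illustrative set).

**Sea-ice phenology** (`wapmelt.icepheno`). From (quasi-)daily sea-ice
concentration, within an annual search window from Julian day 46 to 410
(411 in a leap anchor year): the advance date is the first day
concentration exceeds 15 % for at least 5 consecutive days, the retreat
date the first day it stays below 15 % through the window end, and
duration is their difference. Perennially ice-covered cells take the
window limits as sentinels; ice-free cells get a no-ice marker. Interannual
trends are ordinary least-squares slopes with p-values.

**Mixed-layer depth** (`wapmelt.mld`). MLD is the depth of the maximum
buoyancy frequency N² = (g/ρ₀)·Δρ/Δz, graded by a quality index
QI = 1 − rms(ρ deviation, surface→MLD)/rms(ρ deviation, surface→1.5·MLD):
certain (QI > 0.8), uncertain (0.5 < QI ≤ 0.8), undetermined (QI ≤ 0.5).

**Climatology** (`wapmelt.climatology`). cos(latitude)-weighted regional
means over the Palmer-LTER-grid ROI polygon, austral years (1 Sep → 31
Aug), day-weighted DJF summer means, percent anomalies
(summer − climatology)/climatology × 100, 8-day composites, and
period-mean maps with standard errors.

**Statistics** (`wapmelt.stats`). Pearson correlation (optionally on
log₁₀ chl-a), Shapiro–Wilk and Levene screening, and Welch's
unequal-variance t-test comparing the 2002–2018 and 2019-onward climate
periods.

**Synthetic data** (`wapmelt.synth`). Seeded generators for every input:
forward-mixed bottle samples, sea-ice seasons with known advance/retreat,
two-layer density profiles with known MLD, and coupled gridded
chl-a/sGMW/SST/SAT fields with a prescribed correlation, shared seasonal
cycle and winter ocean-colour gaps — each with a machine-readable truth
table.

## Worked example

Run the whole pipeline on self-generated synthetic inputs:

```sh
wapmelt run-all --seed 0 --outdir demo
```

which prints

```
report written to demo/report.json
sGMW vs chl-a (log10-y): r=0.687, p=0.00e+00, n=4603
```

and writes per-stage outputs under `demo/`. From `demo/report.json`:

* `ice_index`: advance J.D. 120, retreat J.D. 330, duration 210 days —
  exactly the season the generator embedded in the noisy concentration
  series.
* `mld`: 41.0 m, QI 1.0, "certain" — the generator's 40 m two-layer
  interface recovered to within the 2 m level spacing.
* `correlation`: r = 0.687 over n = 4603 observed days against a
  generating correlation of 0.70 (sampling error at this n is ≈ 0.008, so
  a deviation of ~0.013 is unremarkable).
* `comparisons.sgmw`: Welch t = 1.20, p = 0.23 on n = (1475, 240) DJF
  days — correctly finding no shift, since this synthetic run generates
  both periods from one distribution.

The same stages are available individually (`simulate`, `decompose`,
`ice-index`, `mld`, `climatology`, `compare`), reading and writing CSV,
CF-style netCDF and JSON; see `wapmelt <cmd> --help`.

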
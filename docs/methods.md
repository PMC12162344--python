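# Methods

This note documents the models implemented in `wapmelt`, the defaults
that matter, the design choices made where the science left room, and
what the synthetic generators do and do not emulate.

## Water-mass decomposition

A surface sample's salinity and δ¹⁸O are modelled as a conservative
three-component mixture (sea-ice melt, meteoric water, ocean water). The
3×3 linear system (unity, salinity balance, δ¹⁸O balance) is solved
directly; after the solve the tiny floating-point closure defect is
redistributed evenly across the three fractions so that
F_sim + F_met + F_ow = 1 holds to machine precision, which perturbs the
other two equation residuals by at most the same machine-level amount.

*Conditioning.* The mixing matrix is rejected as degenerate when the
determinant after scaling each row to unit max-norm falls below 1e−8.
Row scaling makes the guard scale-free: salinities are O(30) while δ¹⁸O
values are O(10), and an unscaled determinant would conflate units with
conditioning.

*Unclipped fractions.* Measurement noise and end-member mis-specification
routinely push fractions slightly outside [0, 1]. Clipping would destroy
the unity constraint, so fractions are reported as solved and flagged
(`out_of_range`) when any falls outside [0, 1] beyond a 1e−12 numerical
tolerance.

*End-members.* No defaults are built in: end-member signatures are a
site- and season-dependent calibration, and silently assuming one would
manufacture ground truth. The example configuration ships an
*illustrative* set in the range of the WAP δ¹⁸O literature
(S ≈ 6 / 0 / 34.73 PSU, δ¹⁸O ≈ +1.9 / −16 / −0.14 ‰ for sim/met/ow) and
is labelled as such. Separating precipitation from glacial meltwater
within the meteoric fraction is exposed as an optional user-supplied
precipitation fraction to subtract (default: none; F_met itself is the
glacial-meltwater proxy).

## Sea-ice phenology

Julian days are day-of-year of the anchor year, continuing past 31
December (366, 367, …). The annual search window runs from day 46 (15
February) to day 410, or 411 when the anchor year is a leap year — both
ends land on 14 February of the following year, the mean timing of the
summer ice minimum.

Advance is the first window day with concentration above the 15 %
ice-edge threshold for ≥ 5 consecutive days; retreat is the first day
from which concentration stays below the threshold through the window
end. One edge rule is applied everywhere: ice is present iff SIC >
threshold, so a value exactly at 15 % counts as below the edge. The
5-day persistence counts calendar days on the gap-filled daily series; a
single sub-threshold day resets the run (the tolerant variant is not
implemented, as the strict reading is the simpler and reproducible one).

Sentinels: a cell whose concentration never departs takes advance = 46
and retreat = 410/411; a cell where the persistence criterion is never
met is marked `no_ice` with duration 0 and is excluded from trend fits
(no index is defined for ice-free cells).

Gap filling linearly interpolates runs of up to 3 missing days (the
every-other-day cadence of the early passive-microwave record) and flags
interpolated values; longer gaps raise a coverage error rather than
fabricating a season.

Trends are ordinary least squares on year vs index with the two-sided
slope p-value; missing years are dropped, never interpolated.

## Mixed-layer depth

N² = (g/ρ₀)·Δρ/Δz on interior layer midpoints, with g = 9.81 m s⁻² and
ρ₀ = 1025 kg m⁻³. The MLD is the midpoint depth of the maximum-N² layer;
exact ties are broken toward the shallowest layer using a 1e−9 relative
tolerance so that fp rounding cannot pick an arbitrary deeper member of a
tied run.

The quality index follows the homogeneity principle — a genuine mixed
layer has near-zero density standard deviation above its base:

QI = 1 − rms(ρ − mean ρ | surface→MLD) / rms(ρ − mean ρ | surface→1.5·MLD)

with categories certain (QI > 0.8), uncertain (0.5 < QI ≤ 0.8) and
undetermined (QI ≤ 0.5, value reported but flagged unusable). The exact
variance-ratio form and the 1.5× reference extent are this package's
concrete choice among the family of homogeneity indices in use; it is
scale-free (multiplying the density deviation structure by a constant
changes nothing) and degenerates cleanly: a perfectly homogeneous profile
gives 0/0, resolved to QI = 0, and a candidate layer containing fewer
than two levels is likewise graded 0. If a profile is shallower than
1.5×MLD the reference rms uses the available extent.

Density may be supplied directly (preferred) or computed from T/S with a
linear equation of state, ρ = ρ₀(1 − α(T − T₀) + β(S − S₀)), α = 1.7e−4
K⁻¹, β = 7.6e−4 PSU⁻¹. MLD depends only on the vertical structure of
density, not its absolute calibration, so a linear EOS is adequate here;
the coefficients are representative of cold polar surface water. No N²
smoothing is applied by default (least processing); an optional 3-point
running mean is available.

## Regional climatology

Regional values are cos(latitude)-weighted means over grid cells whose
centres fall inside the ROI polygon — the Palmer LTER grid triangle with
vertices (−66.86°, −63.97°), (−78.48°, −68.09°), (−76.14°, −69.24°)
(lon, lat). Shoreline tracing is not attempted; an optional land mask
excludes land cells instead. Each gridded variable is reduced on its own
native grid before any cross-variable analysis (no regridding). A time
step with no observed ROI cell is missing; a configurable minimum
coverage fraction (default 0) can additionally reject poorly observed
days, since winter ocean-colour coverage is sparse.

Austral year Y runs 1 September Y → 31 August Y+1; summer means are
day-weighted DJF means (December of Y with January–February of Y+1).
Percent anomalies are (summer − climatology)/climatology × 100, undefined
for zero climatology. 8-day composites re-anchor at 1 January of each
calendar year with the year's final bin truncated — the standard
ocean-colour binning calendar. Period climatologies report per-cell
temporal mean and SE = sd/√n (≥ 2 observations required); the regional
scalar's SE is computed from the ROI-averaged daily series rather than
from the per-cell SEs, which respects the strong spatial correlation of
regional averages.

## Statistics

Pearson r is computed on complete pairs, by default with chl-a
log₁₀-transformed (chl-a is approximately log-normal; an identity option
exists). Welch's t and its Welch–Satterthwaite df are implemented from
the formulas, since this is the decision-bearing statistic; Shapiro–Wilk
and mean-centred Levene screening delegate to scipy and are always
reported but never gate the Welch test. Shapiro–Wilk is run on a
fixed-seed subsample above n = 5000 (its validity limit) and flagged.
The default period boundary is 1 January 2019, separating the 2002–2018
record from the post-2018 regional climate shift. No multiple-testing
correction is applied.

## Synthetic generators

All randomness derives from one root seed via named CRC-keyed
substreams, so identical configurations produce bit-identical outputs.
Every generator emits a truth table.

*Mixtures* forward-apply the mass-balance equations to known fraction
triplets plus optional Gaussian noise — the exact inverse of the
decomposition, so noise-free recovery to 1e−9 is a construction
guarantee.

*Sea-ice seasons* place a plateau (default 80 %) between the true
advance and retreat days with short internal ramps, keep in-season
values at least `threshold + margin` and off-season values at most
`threshold − margin` (default margin 10 %), and clip Gaussian noise to
±0.999·margin — so every day stays strictly on its side of the edge and
the detectors recover the truth exactly. The every-other-day cadence
drops alternate days while always retaining the two days adjacent to
each transition, so linear gap-filling reconstructs the crossings
exactly as well.

*Profiles* are uniform density above the prescribed interface, a step at
it, and a linear gradient below; step 0 with zero gradient yields the
homogeneous/undetermined case.

*Coupled fields* superpose a shared standardized seasonal cycle (peak
mid-January, variance share 0.25 per variable) and bivariate-normal
anomalies on regional log₁₀ chl-a and sGMW. The anomaly correlation is
set to (ρ_target − λ²)/(1 − λ²) with λ² the seasonal share, so that the
correlation of the *total* observed series — what the pipeline measures —
equals ρ_target; naively adding a shared cycle on top of
ρ_target-correlated anomalies would inflate the measured r above the
target. Defaults: chl-a ~ 0.70 μg/l with 0.25 log₁₀-sd; sGMW ~ 2.6 %
with 0.45 sd; SST/SAT sinusoids leading the meltwater cycle by 30 days;
May–August masked as the winter ocean-colour gap. The default
correlation-study span (Sep 2002 – Aug 2018) yields ≈ 3.9 k observed
daily pairs, the order of the real paired record; the end-to-end demo
pipeline extends the span through Aug 2021 so the two climate periods
are both populated. Fields are the regional series broadcast over a 1°
WAP grid plus small iid cell noise (0.01 units): spatially quasi-uniform
by design.

What passing tests therefore show: the *algorithms* invert their own
forward models and match independent oracles under realistic noise. What
they do not show: robustness to cloud-driven sampling biases, spatial
heterogeneity and advection, retrieval error structure, or end-member
drift in real observations.

## Problem sizes and numerical conventions

Acceptance-grade checks use 1000 mixture triplets, 500 sea-ice seasons
vs a brute-force scan, 200 two-layer profiles, 100 seeds of the coupled
generator, and 1000 null replicates of the period comparison — sizes at
which the Monte-Carlo error of each check is far below its tolerance.
Longitudes are in [−180, 180], depths positive downward, dates ISO 8601,
CSV with '.' decimals and empty missing fields, gridded I/O as CF-style
netCDF (classic format).

## Known limitations

* The linear EOS ignores pressure and nonlinear T/S effects; do not use
  the computed densities for anything but vertical-structure work.
* ROI membership is by cell centre; cells straddling the polygon edge
  are all-or-nothing.
* The phenology detector requires full window coverage after gap
  filling; partial years yield a coverage error rather than a best
  effort index.
* `compare_periods` treats daily values as independent; serial
  correlation in real daily series inflates the effective significance
  of both Welch's test and the correlation p-values.
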
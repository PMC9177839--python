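# Methods

This note documents the models, defaults and numerical choices behind
`trackiba`, and what the synthetic study can and cannot demonstrate.

## Geometry

All areas, bandwidths and radii are kilometres in one azimuthal
equidistant plane per analysis region, centred on the mean colony
position (the projection in which a "7 km bandwidth" or "20 km closure"
has a single meaning).  Radial distances from the centre are exact by
construction; distances between off-centre points are accurate to better
than 0.1% out to ~700 km, beyond the ~600 km ranges handled here.
Geodesic distances (path lengths, radius tests, merge rules) use the
haversine on a sphere of radius 6371.0 km.  Results are mildly
projection-dependent; no official CRS is claimed.

## Synthetic tracks

The generator emulates the statistical structure the analysis assumes,
not penguin physiology:

- **Movement** — a biased correlated random walk in the projected plane:
  gamma-distributed hourly step lengths (shape 2, mean 2.2 km/h, capped
  at 8 km/h so clean tracks never cross the 12.4 km/h error threshold),
  von Mises turning noise (κ = 4), a persistent seaward outbound bearing,
  and a homing bias that ramps up over the final third of the trip so
  every trip closes at a colony.  Trip durations are gamma (mean 32 d,
  SD 7 d) — long enough that most tracks clear the > 20-day inclusion
  rule, matching a study design in which complete pre-moult trips run
  three to eight weeks.
- **Land** — a toy half-plane: everything north of `coast_lat` is land
  and colonies sit on the coastline.  Steps that would cross the coast
  bounce back to sea.
- **Roosts** — at 22:00 GMT a bird within snap range (≤ 0.9 × the step
  cap, so the snap itself is plausible) of any colony hauls out for 5–8 h
  with fixes at the colony point.
- **Moult** — with probability 0.5 a trip ends in a terminal haul-out of
  60–96 h ashore (> 48 h is the detection rule), at the deployment colony
  (75%) or another colony, reached by a swum transit at 80% of the step
  cap.  The truth interval starts at the beginning of the contiguous
  ashore run, since a roost flowing directly into the haul-out keeps the
  bird continuously on land.
- **Sampling** — `hourly` keeps every fix (GPS-GSM-class devices);
  `night_only` keeps at most the first fix per night window (default
  21:00–22:00 GMT, PTT/archival-class duty cycles).  Under night-only
  sampling a moult cannot be distinguished from nightly roosting —
  deliberately so, matching the real limitation of night-scheduled
  devices.
- **Errors** — "teleport" fixes displaced seaward far enough to imply
  > 12.4 km/h against both true neighbours regardless of the sampling
  interval, injected with ≥ 2 genuine fixes between errors so each error
  is attributable by a speed criterion, and logged in the `TruthRecord`.
- **Group effects** — colony positions and a per-group `range_scale`
  multiplier on step length create colony/stage/year differences in
  range.

Determinism: each bird's RNG stream derives from (seed, group index,
bird index), so a single track simulated alone is bit-identical to the
same bird inside a full dataset, and reruns reproduce files byte for
byte.

What the generator does **not** emulate: bathymetry and coastline shape,
prey fields, behavioural state switching, Argos location-class error
structure, device failure/dropout patterns, or autocorrelated
environmental drivers.  Passing tests therefore demonstrate the
correctness and calibration of the *methods* on data with the assumed
structure — not that real penguin data satisfy those assumptions.

## Cleaning

- **Speed filter** (12.4 km/h): iterative worst-violator removal.  For
  the fastest violating pair, the endpoint whose removal bridges its
  neighbours at a plausible speed is deleted; if both or neither removal
  resolves the bridge, the one leaving the smaller residual local
  violation goes.  A genuine error violates against both neighbours, so
  this removes the error rather than its victims, including errors at a
  track end and pairs of errors flanking one good fix.  Only the speed
  criterion is used — no turning-angle rule — because the analysis
  defines the filter by the speed threshold alone.  The filter is
  idempotent.
- **Land flagging**: inside the land polygon, or within 500 m of a
  colony point (GPS scatter around haul-outs; the analysis is
  insensitive to this radius at the scales involved).
- **Trips**: maximal runs of consecutive at-sea fixes; runs of fewer
  than 2 fixes are discarded.  The trip preceding a detected moult is
  marked complete.
- **Moult**: first maximal on-land interval spanning > 48 h (strict),
  with the nearest colony attached.  Intervals broken by any at-sea fix
  do not qualify.
- **Tracking days**: full calendar dates (00:00–24:00 UTC) between the
  first at-sea fix and the last at-sea fix before the moult (or the last
  transmitted fix).  Tracks with strictly more than 20 such days are
  retained.  GMT calendar dates are used throughout.
- **Daily regularization**: one position per calendar day at 12:00 UTC
  (midpoint between the night-only window and the hourly day, minimizing
  regime bias), linearly interpolated in the projected plane; reference
  instants outside the fix range clamp to the endpoint fix.  Gaps longer
  than 3 days are emitted as flagged missing days rather than invented
  straight-line transits.  Interpolated positions lie on the original
  polyline, so the daily path is never longer than the full-resolution
  path.  For residency percentages a parallel daily series including
  fixes ashore is kept, each day carrying the land flag of the fix
  nearest its reference instant — this is what lets "including land
  fixes" be defined on a daily-regularized series at all.

## Home ranges

- **UD**: fixed-bandwidth isotropic bivariate Gaussian kernel density of
  the daily at-sea positions, h = 7 km, evaluated at the centres of 2 km
  cells (≈ h/3.5: resolves the kernel while keeping 600 km domains
  tractable) on a grid padded by 3h, renormalized to unit mass.  The
  kernel separates, so evaluation is two small matrix products; ≥ 5
  positions are required.
- **Isopleths**: cells sorted by density (stable tie-break on cell
  order), accumulated to the target volume — the smallest-area cell set
  by construction, hence exactly nested across volumes.
- **OIVS**: empirical area(v) for v = 0.01…0.99, both axes rescaled to
  [0, 1] (area by area(0.99), volume by 0.99), slope by 3-point central
  differences, scanned from v = 0.99 downward for the largest v where
  the slope first reaches 1.  The empirical curve is used directly (no
  parametric fit); the closed-form Gaussian curve serves as the test
  oracle.  On a pure Gaussian UD the crossing sits near 79%; the
  54%-style values reported for real colonies arise from multimodal
  space use.  The cohort mean OIVS (rounded to an integer percent) is
  applied uniformly to all core areas and core ranges.
- **Pooling**: a group UD is the arithmetic mean of its members' UDs on
  a common grid — identical to a pooled kernel density with each bird's
  fixes weighted to contribute equal mass, so long tracks do not
  dominate, and it lets the permutation test and the representativeness
  bootstrap reuse precomputed per-bird density stacks.  Groups need ≥ 5
  birds.  Land cells are not masked from UDs.

## Overlap inference

BA = Σ √(p₁·p₂)·ΔA after zeroing each density outside its own isopleth
and renormalizing.  UDs on mismatched grids are resampled bilinearly;
the permutation test avoids resampling entirely by building every UD on
the fixed union-extent grid.  The permutation unit is the whole bird
(fixes are autocorrelated); each of the 1000 permutations redraws two
pseudo-groups of the original sizes and rebuilds both pooled UDs.
p = (#{observed > permuted} + 1)/(B + 1) with a strict inequality — low
observed overlap relative to the null is the signal that the groups'
ranges differ — and a Wilson 95% interval on the underlying proportion
accompanies every p.  Significance is read at p ≤ 0.05.

perANOVA uses the classical F statistic with raw group labels permuted
5000 times and the same +1 smoothing (p ∈ [1/(B+1), 1]).  Dunn's
pairwise z tests use tie-corrected rank variance, two-sided normal p,
multiplied by the number of comparisons and capped at 1; they run only
where the omnibus p clears 0.05.

## IBA delineation

Candidate cells are those where strictly more than 10% of the group's
individual core regions overlap; groups need strictly more than 10
birds.  Representativeness: for each subsample size k, `n_boot` = 50
random subsets of k birds are pooled into a core region and scored by
the fraction of the left-out birds' positions inside it; mean inclusion
vs k is fit with a Michaelis–Menten curve y = a·k/(b + k)
(`scipy.optimize.curve_fit`), and the score 100·N/(b + N) — the fraction
of asymptotic coverage achieved at the actual sample size — is ≤ 100 by
construction and > 70 is deemed representative.  Each bird carries equal
weight regardless of track length, so unequal tracking durations are not
accounted for (a known limitation of the procedure).  Aggregation, all
relative to the summed area of the candidate polygons: drop isolated
polygons < 5%, fill holes < 5%, then iteratively merge the closest
polygon pair whose centroid separation is below 5% of the largest
pairwise centroid distance (merged pair → its joint convex hull, the
simplest boundary-minimizing union).  The final boundary is the minimum
convex polygon over everything retained; sites failing the
representativeness bar are still emitted, flagged.

## Management overlays

Zone overlap is intersection area over site area in the shared plane,
for the existing no-take layer alone and with the proposed 20-km
closures added.  Residency is the percentage of a bird's daily fixes
within 20/50 km (great-circle) of its colony, with the denominator
including or excluding fixes ashore; cohort mean ± SD is reported.
Because birds may roost or moult at *another* colony, including land
fixes can lower a percentage relative to the excluding-land variant —
the familiar pattern of land fixes raising the percentage holds when
the fixes ashore are at the focal colony.  Catches in September–December
are summed per year into half-open 0.16° cells anchored at integer
degrees (boundary hauls to the lower cell) and averaged across retained
years; excluded years (e.g. an incomplete 2016) are configurable.

## Problem sizes and reproducibility

The demonstration study is 2 colonies × 2 stages × 12 birds with hourly
sampling; it runs the full chain — including 1000-permutation overlap
tests, 5000-permutation perANOVAs and 50-bootstrap representativeness —
in a few minutes on one core, and twice with the same seed gives
byte-identical artifacts.  Test-suite simulations use shorter trips,
5 km UD cells, and subsampled bootstrap sizes where the property under
test does not depend on them; the calibration test uses 200 null
replicates of 6 + 6 birds at 200 permutations, and the power test a
two-colony scenario (300 km apart) with short tortuous trips whose core
ranges are structurally disjoint.  All randomness flows from explicit
seeds.

## Known limitations

- The coastline is a half-plane; sites and UDs are not clipped to water.
- OIVS on near-unimodal synthetic UDs concentrates near 79%, above the
  values real multimodal colony data produce; the pipeline carries the
  cohort mean through rather than asserting any particular percentage.
- The representativeness score of small cohorts of wide-ranging birds is
  honestly low; the demonstration study's sites illustrate the mechanics
  of the flagging rather than achieving the > 70% bar.
- Bilinear UD resampling slightly smooths mass near grid edges; the
  pipeline sidesteps it by sharing grids wherever UDs are compared.
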
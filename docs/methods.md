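# Methods

`splatquant` quantifies splatter contamination recorded on universal
indicator paper (UIP) during simulated dental aerosol-generating procedures,
and compares mitigation conditions — chiefly the presence of an extraoral
scavenger (EOS) — across operatory, clinician and assistant sites. This note
describes the measurement model, the synthetic-data generator that stands in
for the wet-lab experiment, and the numerical choices made where the
original study left the design open.

## Measurement model

UIP is pH-sensitive paper: acidic splatter (10% citric acid in the coolant
line of the simulated procedures) turns it from yellow to red on contact.
The measurement for one strip is its **intensity of contamination**, the
percentage of the strip's pixels classified as red in a 600 dpi scan:

    intensity% = 100 × n_red / n_total.

Classification is a deterministic HSV threshold: a pixel is contaminated iff
its hue lies on a red arc of the hue circle (default [340°, 20°], i.e. ±20°
around pure red) *and* its saturation ≥ 0.3 *and* its value ≥ 0.2. The
original analysis does not state its threshold numerically; the default here
separates red (≈5°) from the paper's clean yellow (≈55°) with a wide margin
on both sides, and `threshold_sweep` re-measures a strip under perturbed
thresholds to show the statistic is insensitive to the choice — the same
check the original workflow performed by repetition. Pixels that are neither
red nor yellow (shadows, scanner edge artefacts) count as uncontaminated; a
warning is logged when they exceed 5% of a strip, since that suggests the
binary red/yellow decomposition is breaking down.

Two deliberate conventions:

* **Single-point rule.** Any contamination — one red pixel — marks the strip
  contaminated. There is no small-object filtering.
* **No strip segmentation.** Each image file is assumed pre-cropped to one
  strip; `Scan.cropped(margin_px)` is the hook for trimming borders or
  mounting tape if a scan includes them.

## Summary statistics

For each procedure × role group (roles: operatory, clinician, assistant;
the patient strip is grouped under operatory):

* **frequency (n)** — count of contaminated strips;
* **mean intensity** — mean over *contaminated* strips only; a group with
  none reports 0 rather than undefined, matching how the source tables
  print 0.00;
* **maximum intensity** — the largest single-strip intensity, with its site
  (ties go to the earliest record in input order).

Pooling over procedures is the unweighted arithmetic mean of per-procedure
frequencies and mean intensities. The published pooled means are shipped as
an input fixture (`table1_pooled.csv`): the per-strip data behind them were
never released and recomputing them from the per-procedure table under
plausible pairings does not reproduce the printed values exactly, so the
comparison arithmetic treats them as given.

## EOS pairing and comparison

Procedure runs are paired when they differ only by EOS use: the scavenging
variation descriptor is tokenised (split on commas and "and",
case-insensitive), the EOS token removed, and runs match when the procedure
description, operatory type and remaining token set are identical.
Parenthesised qualifiers such as "(short visor)" stay attached to their
token, so short-visor runs pair only with each other; runs whose only
potential partner differs in another attribute (e.g. saliva-ejector-only
versus no-suction) stay unpaired. On the bundled study table this yields the
nine pairs A1–A2, A3–A4, A5–A6, B1–B2, C1–C2, D2–D3, E1–E2, E3–E4, G2–G3.

For each role × metric the report gives the absolute difference
(without − with) and the percent reduction
100 × (without − with) / without. Conventions: reductions are computed at
full precision and rounded to integer percent only for display; a zero
baseline reports 0% with a logged warning; an increase appears as a negative
reduction. No significance testing is performed — the underlying experiment
had no repeats, so none would be defensible.

## Spatial mapping

Site positions are horizontal coordinates in metres with the incisal edge of
the maxillary left central incisor (tooth 21) at the origin. Distance is the
horizontal Euclidean norm — height is recorded as a categorical class
(floor / chair / table / person / ceiling) and summarised separately, never
folded into distance. Directions are 12-sector clock positions; the
convention (nowhere defined in the source) is that 12 o'clock points toward
the top of the operatory plan behind the patient's head and angles increase
clockwise viewed from above, with sector boundaries resolved toward the
later hour. Distance profiles use half-open bins [a, b); distances are
reported to 2 decimals.

The bundled site layouts are **synthetic**: only the distances and clock
positions quoted in the study text (patient 0.35 m; bracket table 0.60 m;
assistant's chair 0.24 m; operating light 0.75 m; furthest closed-surgery
site 1.34 m at 8 o'clock; furthest open-clinic site 1.33 m at 4 o'clock;
open-clinic hotspot 0.22 m at 1 o'clock) are factual, and every other
coordinate is invented to complete a plausible plan.

## Synthetic-data generator

No scans or strip-level records from the original experiment are available,
so the generator emulates them with known ground truth.

**Strips.** Splatter marks are filled discs with lognormal radii
(log-mean log 5 px ≈ 0.2 mm at 600 dpi, log-sd 0.4) at uniform-random
centres; overlap is allowed and the union taken — the simplest model that
reproduces the speckled appearance of real strips. The ground-truth mask is
exactly the set of painted pixels, recorded before appearance effects.
Colour: background hue 55° (sat 0.75, value 0.92), splatter hue 5°
(sat 0.85, value 0.82), per-pixel Gaussian hue jitter (default sd 3°) and
additive Gaussian sensor noise (default sd 2 on the 0–255 scale). A
requested target coverage is met by painting droplets from a seed-fixed
schedule until the painted-pixel count reaches `round(target × total)`, so
coverage is monotone in the target at fixed seed; full coverage is a
special-cased fill (random discs cannot saturate the corners), and a
50 000-droplet cap guards against pathological targets. An explicit droplet
count takes precedence over a target when both are supplied.

**Studies.** For each procedure × site, the strip is contaminated with
probability

    p = base_hit_prob × exp(−distance_decay × d) × hit multipliers,

and a contaminated strip draws intensity from a lognormal, scaled by the
applicable intensity multipliers and clipped to [0, 100]. Mitigation acts
multiplicatively: the EOS has separate hit and intensity multipliers;
high-volume suction and rubber dam scale hit probability. Exponential decay
and multiplicative factors are a modelling choice — identifiable with few
parameters — not a claim about the physics of ballistic droplets. Defaults:
base_hit_prob 0.6, distance_decay 1.5 /m, intensity lognormal(0, 1) (median
1%, occasional tens of percent, matching the skew of the observed per-strip
range), eos_intensity_multiplier 0.25 and eos_hit_multiplier 0.8 (the
pooled effect sizes observed in the motivating study: 75% intensity and 20%
frequency reduction for operatory sites), hvs_multiplier 0.7,
rd_multiplier 0.5.

What the generator does **not** emulate: directional anisotropy of splatter
(real contamination concentrated toward particular clock positions),
droplet-size dependence on procedure type, streaking/pooling of large-volume
exposures (the surgical-handpiece pattern), scanner colour-profile drift,
and any aerosol-phase (<50 μm) behaviour. Passing tests therefore show the
*pipeline* is correct — classification, aggregation, pairing and mapping
recover known inputs — not that the generator's parameters describe any
real operatory.

**Effect-size recovery.** The pooled mean-intensity estimator applied to
paired synthetic procedures converges on 1 − eos_intensity_multiplier. The
recovery experiment uses 200 replicate pairs on the closed-surgery layout
with the hit multipliers set to 1 so the intensity multiplier is isolated;
the confidence interval is a 500-replicate percentile bootstrap over
procedure pairs. With these sizes the estimate typically lands within a few
percentage points of the true 75% and runs in seconds.

## Numerical choices and degenerate inputs

* Intensities and coverages are exact ratios of integer pixel counts; the
  round-trip test without jitter demands bit-exact equality.
* `percent_reduction(a, 0)` returns exactly 100 (short-circuited to avoid
  `100·a/a` float round-off); `percent_reduction(0, ·)` returns 0 by
  convention.
* Empty record lists, mixed procedure codes or roles, duplicate procedure
  codes, non-positive bin widths and invalid threshold fractions raise
  `ValueError`; an all-clean study is not an error — furthest-contaminated
  returns an empty result and profiles report zero counts.
* Ties (maximum intensity, furthest site) resolve to the earliest record in
  input order, which is preserved from the manifest.

## Known limitations

The transcribed study table inherits one internal oddity of its source
(run J2 prints frequency 1 with mean 2 and max 90.15, which cannot all
describe the same single strip); it is carried as printed and no invariant
is asserted that the source itself violates. The quantifier assumes
pre-cropped single-strip scans and does not correct for scanner colour
profiles or estimate pH from hue. The comparison layer deliberately stops at
descriptive differences and reductions.
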
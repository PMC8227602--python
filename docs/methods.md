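# Methods

## Input model

The caller never touches raw fluorescence traces. Its unit of input is a
*peak table*: one row per detected fragment peak with sample identifier,
marker, role (tumour or matched normal), fragment size (bp, possibly
fractional) and signal (RFU). Peak calling, baseline subtraction and sizing
are the instrument's job. Peaks at exactly identical sizes within one trace
are merged by summing signal — a single electropherogram position cannot
carry two peaks. Each marker has a configurable size gate (generous windows
around the expected amplicon range, e.g. 90–150 bp for BAT-25); peaks
outside the gate are primer/ladder artifacts and are dropped, with a logged
count, before anything else. Gating is idempotent.

The panel is fixed at five markers — the score is "/500" precisely because
it sums five percentages — but the names and windows are configurable.

## Novelty rules and allelic variability

For one marker, with tumour trace *T* and normal trace *N* (both gated):

1. **Noise filter.** A peak is kept iff its signal is ≥ `noise_fraction`
   (default 0.02) × the trace's *pre-filter* total signal. The boundary is
   inclusive: the stated filtering ("less than 2%") and novelty ("more than
   2%") readings conflict at exactly 2%, and we resolve them into a single
   coherent threshold — survival of the filter is the only signal-share
   test a peak faces. A zero-signal trace filters to an empty trace with a
   QC flag rather than dividing by zero.
2. **Normal preprocessing.** By default the same filter is applied to the
   normal trace (`filter_normal = true`) before distances and the size
   range are computed, so a 1% stutter remnant in the normal cannot veto a
   genuine novel peak 1 bp away from it. Nothing in the source procedure
   settles this either way; it is exposed in configuration.
3. **Novelty.** A surviving tumour peak is *novel* iff its distance to the
   nearest surviving normal peak is ≥ `min_novel_distance_bp` (default
   2 bp, inclusive) **and** it lies within `max_outside_range_bp` (default
   10 bp, inclusive) of the normal peak-size range [min, max]. Distances
   use raw, possibly fractional sizes; nothing is rounded to integer bases.
   Peaks farther than 10 bp outside the range contribute nothing to
   variability but stay in the denominator: they are treated as artifacts,
   not evidence.
4. **Variability.** Each surviving tumour peak's signal proportion is its
   signal divided by the tumour trace's total signal — by default the
   *pre-filter* total within the gate (`denominator_mode`), switchable to
   post-filter. The marker's percentage allelic variability is 100 × the
   sum of proportions over novel peaks, clamped into [0, 100] against float
   roundoff. A marker is **unstable** iff variability strictly exceeds
   `marker_instability_threshold_pct` (default 2.0): tabulated reference
   rows with a 2% cell count it as stable, fixing the strict inequality.

A consequence of the pre-filter denominator worth knowing: a single novel
peak can never carry a variability strictly between 0 and the noise
fraction (it would have been filtered), so per-marker values like "1%" in
a published table must stem from either rounding conventions or a different
denominator upstream; such values enter this package at the classification
layer, where they are taken at face value.

A marker whose tumour or normal trace is absent, or whose normal trace is
empty after preprocessing, is **missing**: carried as NA with a QC flag
through classification, never an error, because FFPE dropout is routine.

## Classification

* **NCI marker count** over non-missing markers: 0 unstable → MSS,
  1 → MSI-L, ≥ 2 → MSI-H.
* **MSI score**: unrounded sum of the per-marker variabilities over
  non-missing markers (not rescaled when markers are missing — a plain,
  conservative sum). Tiers: score < 3 → MSS, 3–5 inclusive → MSI-L,
  > 5 → MSI-H. The source states the MSI-H boundary both as "≥5" and as
  ">5"; reference rows with score exactly 5 are labelled MSI-L, so the
  strict reading is implemented. The MSS tier extends down to 0 (the
  stated "1–2" leaves 0 unaddressed; an all-stable sample is plainly MSS).
* **Maximum allelic variability** and, for MSI-H samples only, the **Toh
  score** (equal to the MSI score) complete the per-sample summary.

Classification always runs on unrounded values; reports display integer
percents (half-up). The reference tables themselves show printed scores
that differ by ±1 from the sum of their printed integer cells in several
rows — consistent with unrounded internal arithmetic upstream of a
rounded display, which is exactly what this package does.

## Reference cohort and known inconsistencies

The packaged 56-specimen cohort (`src/msicall/data/patient_cohort.tsv`)
stores per-marker integer variabilities, IHC status, BRAF subgroup and the
originally reported classifications. Recomputing from the integer cells
reproduces **every** reported NCI status, score tier and maximum
variability. Two rows report unstable-marker *counts* inconsistent with
the strict >2% rule applied to their own printed integers (row 142: cells
3/7/5/0/7 reported as 3 unstable where the rule gives 4; row 242: cells
2/12/6/0/0 reported as 3 where the rule gives 2 — presumably 2.x% before
rounding). Both rows are MSI-H under either count; the golden tests pin
the mismatch set to exactly these two rows. Separately, the NCI method
calls 14 of 56 samples MSI-L here, while the accompanying prose says
13/56; the tables win, and the discrepancy is simply noted.

## Concordance with IHC

IHC reads mismatch-repair protein expression and is binary (MSS / MSI-H);
it cannot recognise MSI-L. Concordance therefore excludes the samples the
*method under evaluation* calls MSI-L — the exclusion set differs between
the marker-count method and the score method — then reports
`round(100 × concordant / evaluated)` to the nearest integer, overall and
per subgroup. With no evaluable samples the percentage is undefined and
flagged, not zero. The Kruskal–Wallis comparison of MSI scores across
subgroups uses average ranks with tie correction and the chi-square
approximation (scipy), with per-group mean/median reported and a Welch
t-test provided as a two-group utility; a hand-rolled rank computation
serves as the independent cross-check in the tests.

## Simulator

`synth` emulates the assay so the caller is testable end-to-end:

* **Germline profile** per marker: one (mononucleotide) or two
  (dinucleotide) allele peaks at `main_signal_rfu` (default 1000), each
  with a stutter ladder at `allele − k × repeat_unit` for k = 1..`n_stutter`
  (default 2) and geometric signal decay `stutter_decay**k` (default 0.10
  per step — realistic for these repeat classes and, importantly, leaving
  the first stutter above and the second below the 2% filter).
* **Tumour trace**: a (1 − f) : f signal-weighted mixture of the germline
  profile and the same profile shifted by `shift_bp` (default −3 bp,
  deletions being typical) on the unstable markers (default BAT-25,
  BAT-26, D5S346). The novel signal share is therefore proportional to the
  tumour fraction f, giving the closed-form limit: variability of a
  noiseless, stutter-free single-allele marker = 100 × f.
* **Noise**: Poisson-count spurious peaks (rate 2/trace) at uniform
  positions in the window, signals uniform below `noise_signal_frac` ×
  main signal (default 1%) — deliberately under the 2% filter so ground
  truth stays closed-form. Every peak signal gets multiplicative lognormal
  jitter (`signal_cv` = 0.10). Fragment sizes are exact by default
  (`size_jitter_bp` = 0): real sizing error of the same order as the 2 bp
  distance rule would make novelty calls at the boundary a coin flip,
  which is a property of the instrument, not of the caller under test.
* **Seeding**: one root integer seed, split per sample × marker × role via
  a `SeedSequence` over CRC32s of the identifiers, so any single trace is
  reproducible in isolation and outputs are byte-identical per seed.

With these defaults the −3 bp shift on the *dinucleotide* marker lands
1 bp from the normal's one-repeat stutter peak and is correctly not called
novel — kept deliberately to exercise the distance rule; an MSI-H call
then rests on the two mononucleotide markers, which is the ≥2-marker
criterion doing its job. The dilution-series checks run 20 replicate
seeds over fractions 0.05–1.0 (seven samples × five markers × two roles
each), a size chosen to estimate the ≥95% detection rate while keeping the
whole suite in seconds.

What the simulator does **not** model: electrophoretic mobility and dye
saturation, sizing error (off by default, see above), PCR competition
between alleles, and real FFPE degradation. Passing simulator tests shows
the caller implements its rules correctly under controlled stutter and
noise; it does not certify performance on a particular instrument, whose
noise floor is expected to be recalibrated (`noise_fraction` is the first
knob to turn).

## Degenerate inputs and numerical choices

* Zero-signal or empty traces → empty after filtering, marker missing,
  QC-flagged; all five markers missing → NA statuses with a QC flag.
* Threshold comparisons: filter inclusive (≥), instability strict (>),
  distance inclusive (≥), range inclusive (≤) — each pinned by a test.
* Variability clamped to [0, 100]; proportions in pre-filter mode sum to 1
  within 1e-9 (tested).
* Reports are byte-stable; the JSON report carries exact unrounded values
  alongside the integer display values, so a parsed report round-trips
  every numeric field exactly.
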
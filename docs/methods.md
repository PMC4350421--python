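# Methods

This note documents the models, parameter choices and numerical decisions
behind each analysis stage, and what the synthetic-data generators do and
do not emulate.

## SADH consensus scanning

The consensus is represented as an ordered list of residue-class sets and
a window matches when every residue belongs to its position class.  Two
flavours are compiled:

* simplified core (8 positions): `{Y} [KR] any [FL] {A} {A} [ILV] {P}` —
  the form used for database searching and for all quantitative claims;
* full consensus (11 positions): `[+] any any {Y} [+] any ϕ {A} {A} ϕ {P}`
  with `[+] = {K, R}` and `ϕ = {F, L, I, V, M, A, W, Y}`.

Choices: `[+]` excludes histidine, consistent with the simplified form's
`[KR]`; the hydrophobic class is the conventional broad set, but the full
consensus is informational — every count and statistic in the package uses
the simplified core unless stated otherwise.  Matching is case-insensitive
(sequences are uppercased on input); the unknown residue `X` satisfies only
unconstrained positions, so an ambiguous residue can never create a match.
Coordinates are 1-based inclusive, matching mutation nomenclature
(R1322W).  Overlapping matches are all reported; "proteins with a match"
means ≥ 1 match.

### Variant-impact classification

A missense variant is classified by re-scanning: `motif_lost` if it falls
inside a wild-type match whose window no longer matches after the
substitution, `outside_motif` if no wild-type match overlaps the position,
`motif_retained` otherwise.  A subtlety in the SCRIB numbering: with the
full 11-mer of repeat 2 ending at P1332, the leading `[+]` position is
R1322 and the simplified 8-residue core occupies 1325–1332.  R1322W is
therefore `motif_lost` against the full consensus but `outside_motif`
against the simplified core, P1332L is `motif_lost` against both (P is the
terminal anchor of both forms), and A1315T lies inside the 25-aa repeat
but outside both consensus windows.  Both classifications are available
(the `variants` subcommand takes `--motif full|simplified`); the full
consensus is the default for variant work because it is the frame in which
all three pathology variants have a consistent reading.  Note that a
consensus-level call makes no claim about binding affinity: a variant can
break the consensus yet bind in vitro, and the in-cell destabilization is
the biologically relevant readout.

### Coverage and enrichment

Coverage is merged-window residue count over protein length; the three
25-residue repeat windows (75 aa of 1657, ≈ 4.53%) are packaged as
explicit intervals, since the repeat boundaries — not the 8-residue
cores — define the annotated motif regions.  The enrichment statistic
models mutation positions as uniform over the protein and reports the
one-sided exact binomial upper tail P(X ≥ k) with n = total mutations and
p = coverage.  This is the simplest defensible null; it ignores
per-residue mutability differences (sequence context, CpG effects) and is
meant as a descriptive tail probability, not a calibrated burden test.

## Cortical Localisation Index

`CLI = (i/(i+I)) / (a/(a+A))` with summed intensities `i`, `I` and pixel
areas `a`, `A` of the cortical band and interior.  Reading `i` and `I` as
*sums* is forced by the area terms: with means instead of sums the ratio
would not reduce to 1 for a uniform signal.  The verbal definition as a
ratio of mean intensities is recovered in the thin-band limit: the
deviation between the two readings is `(a/A)(r−1)/(1 + r·a/A)` for an
enrichment ratio `r`, so it vanishes linearly in `a/A`.  The tests assert
agreement within 2% at `a/A ≈ 0.014`; note that at `a/A = 0.05` and
`r = 2` the exact deviation is already 4.5%, so the two definitions are
only interchangeable for genuinely thin bands.

The band is built by eroding the mask with a disc footprint of radius
`round(thickness/pixel size)` pixels (minimum 1), i.e. the band is
measured inward from the mask edge; 0.625 µm at a typical 0.21 µm/px
spinning-disk sampling gives a 3-px band.  Everything inside the band
counts as "cytoplasm", including the nucleus.  Background is a constant
offset subtracted with clamping at zero.  The per-cell CLI is the
unweighted arithmetic mean over z-planes.

## FRAP fitting

Model: `Y(t) = Y0 + (Ymax − Y0)(1 − e^(−kt))` on traces normalized to a
pre-bleach mean of 1 with t = 0 at the first post-bleach frame.  The
protocol this reimplements prints the recovery equation as
`Y(t) = (Ymax − Ymin)(1 − e^(2kt)) − Ymin`, which diverges as written
(positive exponent) and is offset-inconsistent with its own
mobile-fraction formula; it is read here as the standard bounded
single-exponential with `Ymin ≡ Y0`, which is the only interpretation
under which `Mf = (Ymax − Y0)/(1 − Y0)` and `t½ = ln 2 / k` make sense.
This is an interpretation, recorded here, not a silent fix.

Fitting is bounded least squares (`k > 0`, `Y0`, `Ymax ∈ [−1, 2]`) with
analytic initial guesses: `Y0` = first post-bleach point, `Ymax` = mean of
the last three points, `k = ln 2 /` (time to halfway between them).  `t½`
is reported as `ln 2 / k`, never read off the curve.  Non-convergence and
non-positive rate constants raise a named error carrying the initial
guess and residual.  No acquisition-photobleaching correction or reference
region is applied (none is specified in the protocol).  Double-exponential
and diffusion-reaction models are out of scope.

## Centrosome-orientation scoring

A cell is correctly oriented when the angle between the
nucleus-to-centrosome vector and the wound direction is strictly below
45°.  The boundary convention (exactly 45° → not oriented) is a
documented choice; the boundary has measure zero under any continuous
model of centrosome position, so it cannot affect expected scores.
Geometry is 2-D projected positions and distance from the nucleus is
ignored.  The random baseline — centrosome angles uniform on the
circle — has expected score 90/360 = 25%, the assay's floor.

## Synthetic-data generators

All generators take an explicit integer seed and return their ground
truth; identical seeds give bit-identical outputs.

* **Proteomes**: decoys drawn from uniform residue frequencies (a simple
  null, deliberately not a model of real proteome composition) and
  rejection-sampled until motif-free; carriers have one consensus
  instance planted at a recorded position, re-scanned so the planted site
  is the only match.
* **Cells**: a rasterized disc mask split with the same erosion rule the
  analysis uses, interior at a base intensity and band at
  `enrichment × base`, additive Gaussian noise per plane.  Because the
  generator shares the partition geometry, the closed-form CLI
  `(ea/(ea+A))/(a/(a+A))` is exact for the noiseless image; defaults
  (radius 40 px, 3-px band, 3 planes, noise sd 5% of base) emulate a
  mid-section confocal slice of a rounded epithelial cell.
* **FRAP traces**: the single-exponential model plus Gaussian noise in
  normalized units, mapped to raw counts with a constant background;
  defaults (40 post-bleach frames at 3 s, noise sd 0.02, 5 pre-bleach
  frames) match the regular 3–10 s sampling of a junctional FRAP series.
  Benchmark regimes used throughout the tests: a fast, almost fully
  mobile membrane tag (t½ = 10 s, Mf = 0.97), a cortically anchored
  wild-type protein (26 s, 0.60) and a destabilized mutant (18 s, 0.82).
* **Orientation populations**: centrosome directions von
  Mises-distributed around the wound normal; concentration 0 reduces
  exactly to the uniform null, so the 25% baseline is a special case of
  the same generator.

What the generators do **not** emulate: microscope point-spread functions,
photobleaching during acquisition, non-Gaussian (shot-dominated) noise
statistics, realistic cell shapes or nuclei, biological proteome
composition, and correlated mutation hotspots.  Passing tests therefore
demonstrate that the estimators recover known parameters under their own
model assumptions — they do not validate segmentation, nor robustness to
model misspecification on real micrographs.

## Fixtures

The published SCRIB, DMTN/ABLIM and ortholog sequences appear only in
figure panels and are not redistributed; `sadhtools.fixtures` builds
deterministic synthetic stand-ins (every id carries a `_synthetic`
suffix) that reproduce the stated geometry: a 1657-aa protein with three
25-aa repeats whose consensus numbering places R1322, A1315 and P1332
exactly as in the human protein, a seven-peptide panel with four
canonical carriers and three single-violation near-misses, and an
ortholog panel with motif-bearing vertebrates and motif-free
invertebrate stand-ins.  Conclusions drawn from these fixtures test the
machinery, not the real sequences.

## Problem sizes

The test suite uses 200 replicate FRAP traces per condition for the
noisy-recovery check, 10⁵ cells for baseline convergence, exhaustive
scanner-equivalence enumeration up to length 12 over a 3-letter alphabet
and length 9 over the minimal 5-letter alphabet that can realize the
consensus, and 150-px cells for the thin-band limit.  The acceptance
script simulates 2×10⁵ cells for the orientation baseline.  These sizes
put Monte-Carlo error well inside each asserted tolerance while keeping
the whole suite under a minute of compute.
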
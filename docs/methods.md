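# Methods

## Mobility–CCS conversion

CCS is computed from inverse reduced mobility with the Mason–Schamp
relation using CODATA constants (e = 1.602176634e-19 C,
k_B = 1.380649e-23 J/K) and the Loschmidt number density
N₀ = 2.686780111e25 m⁻³ (273.15 K, 101.325 kPa), the standard-conditions
density that the "reduced" in reduced mobility refers to. The ion mass is
taken as m/z·|z| (the electron mass deficit of an anion is ~0.5 ppm of
these masses and far below every tolerance used). The drift gas is pure
N₂ at 28.0134 Da; the ~0.6% O₂ present in membrane-generated concurrent
gas is recorded in `InstrumentMetadata` but deliberately excluded from
the reduced mass, because reference CCS values are defined for N₂ and the
calibration absorbs gas-composition effects anyway.

The conversion temperature defaults to 305 K and is exposed on
`MobilityPhysicsContext` rather than hidden: vendors differ in the
effective temperature convention, and since TIMS CCS is calibrated rather
than first-principles, any consistent choice cancels between calibration
and analyte conversion. All round-trip and recovery guarantees are
temperature-independent for the same reason.

## Calibration

`fit_calibration` regresses reference 1/K₀ (obtained from each
calibrant's reference CCS through the exact Mason–Schamp inverse) on the
measured raw readings, paired by index, requiring ≥ 3 points. Fitting in
this direction makes `apply_calibration` a single affine evaluation, so
analyte values are interpolated directly; readings outside the calibrant
span are flagged as extrapolated rather than rejected. Whether the
vendor's internal linear fit operates in 1/K₀ or an internal voltage
space is not documented; this package fits in 1/K₀ space. Multiple
reference tables (e.g. a vendor list and a community consensus list for
the same tune-mix ions) are supported throughout: a library entry carries
one aggregate CCS per table id, and `dual_reference_ccs` evaluates one
raw reading under independently fitted models. No shipped table contains
real reference values — both lists are user-supplied configuration, and
all tests use synthetic tables.

## Mobilogram processing

EIMs sum centroid intensity within an m/z window (default ±0.01 Da
absolute; ppm mode available) per mobility bin; BPMs take the per-bin
maximum. Smoothing is single-cycle Savitzky–Golay over a 0.005 V·s/cm²
window, polynomial order 2, mirror padding; the window is converted to
the nearest odd point count at the trace's bin spacing (an odd window is
a hard requirement of the filter) and must be ≥ 5 points.

Peak picking exposes three vendor-style parameters with declared,
testable semantics, since the vendor definitions are not public:

* sensitivity s — detection floor at (100 − s)% of the base intensity
  (97 → 3% of max), monotone in the vendor's direction: higher
  sensitivity admits more candidate maxima;
* minimum peak valley v — two adjacent maxima remain separate peaks only
  if the valley between them drops by ≥ v% of the *lower* apex
  (scale-free; merging keeps the taller apex);
* relative intensity threshold r — surviving peaks below r% of the base
  peak are discarded.

Apex positions are refined below the bin spacing with a three-point
parabola on log intensity (exact for a sampled Gaussian); FWHM is read by
linear interpolation at half height, and the 4σ base width is derived as
FWHM·4/2.3548 assuming a locally Gaussian shape — robust to noise floors
and consistent with the 4σ convention used in the resolution and
peak-capacity algebra. Peak purity is the fraction of total centroid
intensity within the m/z window over the peak's 4σ mobility extent; an
empty extent yields purity 0. CCS values are computed from the apex of
the extracted trace (the apex bin, not the base-peak m/z, when that
distinction matters), and widths convert to the CCS domain through the
same linear chain, so resolving power is domain-independent.

## Adduct annotation

Species m/z rules subtract a proton (1.00727646688 Da; the electron is
retained) for deprotonation, with [M-3H]⁻ modeled as a 2H oxidation
followed by deprotonation, and the formic acid / sodium formate adduct
masses computed from the same atomic mass table (46.0054793 and
67.9874251 Da). These conventions are what place deprotonated rutin at
nominal m/z 609 with companions at 607 and 677.

Theoretical isotope patterns are built by convolving per-element isotope
distributions (per-atom exponentiation by squaring), aggregated on a
unit-mass "extra neutron" grid — the scale a TOF resolves for these
analytes — truncated to 4 isotopologues by default and base-normalized.
Pattern agreement is scored as 1000·RMS intensity mismatch over the
shared isotopologues (0 = perfect; an open analog of vendor pattern
scores, not a reimplementation of any proprietary formula). A peak is
annotated with a species when centroids at the species m/z dominate its
extent (purity ≥ 0.5 by default) and the observed pattern scores within
the ceiling (default 50); when several peaks qualify for the same
species, the highest-purity peak wins, each species is assigned at most
once, and leftovers stay `unknown` — no rule exists for the occasional
unexplained mobility peak, so none is invented.

## Library building and comparison

Replicates aggregate as mean, sample (n−1) SD and RSD% — triplicates are
a sample of the measurement population, so the n−1 denominator is used
throughout; a single replicate leaves SD/RSD as NaN rather than a fake
zero. Entries whose [M-H]⁻ RSD exceeds 0.35% are QC-flagged (the
well-behaved regime for this ion tops out near that value); the threshold
is configuration, not a hard gate. Percent differences between
measurement sets default to the first (reference/library) value as
denominator, with "second" and symmetric "mean" available, because the
convention is rarely stated in published tables and exact reproduction of
third-party percent columns is generally impossible from rounded CCS
values anyway. Set comparisons summarize with the plain mean and sample
SD of the per-item differences and list unmatched keys instead of
dropping them.

Library files are flat TSV with a `#key=value` metadata header (gas
composition, temperature, pressures, mobility range, ramp time, charge
control target, polarity, reference-table ids, free-form extras) —
greppable and diffable. Floats serialize with shortest round-trip repr so
write→read is the identity on every numeric field; aggregate-statistic
consistency (RSD = 100·SD/mean) is re-checked on read.

## Annotation-quality matching

Each criterion a query feature supplies — mass (ppm), RT (min), isotope
pattern score, MS/MS cosine (0.01 Da binning), CCS (%) — is evaluated
against a (wide, narrow) threshold pair; absent criteria are marked
not-evaluated rather than counted against a match. Defaults: mass 5/2
ppm, RT 0.3/0.1 min, pattern 50/20, MS/MS cosine 0.6/0.8, CCS 5%/2%,
plus a separate high-confidence CCS flag at 0.3%. The CCS tier pair and
the 2.0%/0.3% convention coexist in practice and are deliberately both
exposed (tiers + flag) rather than merged. Only the CCS thresholds are
community-established; the others are declared defaults. The ΔCCS
denominator is the library value (the reference standard). Ranking is
ordinal — narrow-tier count, wide-tier count, ascending mass ppm,
ascending ΔCCS, entry id — because the matching display reports tiers,
not a fused score; the key is total, so results are deterministic.

## Resolution analysis

Peak capacity is implemented as P = 1 + t_g / mean(w) with 4σ base
widths (the printed form of the defining equation is typographically
garbled in the source literature; the prose gloss — gradient time over
average width — is the only self-consistent reading). Pairwise
resolution uses the mean of the two 4σ base widths as the width term.
The isomer matrix evaluates all n(n−1)/2 unordered pairs, counts pairs
above each threshold (default 0.25/0.5/1.0) and exposes the heat-map
color classes. The width convention (4σ vs FWHM) is a parameter of the
caller's peak objects, since published matrices do not always state it;
exact reproduction of any particular instrument's matrix is out of scope
and the behavior validated is the monotone growth of resolved-pair
counts with resolving power.

## Synthetic data

Mobility peaks are Gaussian — the 4σ resolution algebra presumes
near-Gaussian shapes, and TIMS elution peaks are well approximated by
them. The default axis is 0.4–1.8 1/K₀ over 1000 bins (the survey
acquisition range; ~0.0014 V·s/cm² spacing) and the default peak sigma
0.012 V·s/cm² puts a mid-range peak near resolving power 40, the broad
survey regime. Species are planted at the raw position implied by their
true CCS and the inverse of the configured affine distortion, carrying
the compound's theoretical isotopologue centroids, so the full
calibrate→extract→pick→convert chain is exercised, not just the last
step. Noise is additive uniform per centroid, scaled by the species peak
height. Replicate batches jitter true CCS multiplicatively with a
configurable relative SD (default 0.1%, the reproducibility regime of
triplicate standard analyses). Matrix backgrounds draw feature positions
uniformly in mobility and m/z and intensities log-uniformly — simplicity
over realism, since the property asserted is CCS-shift robustness, not
background shape. All generators are deterministic under a fixed seed.

What passing on synthetic data does not show: real mobilograms have
non-Gaussian tails, correlated chemical noise, charge-state mixtures and
RT-domain structure none of which the generators emulate, so the
recovery bounds established here are best-case algorithmic properties,
not instrument performance claims.

## Problem sizes and tolerances

The test suite uses panels of 5–50 synthetic compounds on 1000-bin axes
(a 50-compound triplicate batch is the largest fixture), chosen so each
property is measured with meaningful sampling statistics while the whole
suite stays interactive. Key numerical bounds: Mason–Schamp round trip
< 1e-12 relative; noiseless calibration recovery < 1e-9 on slope and
intercept; noiseless end-to-end CCS recovery < 0.05%; matrix-overlay CCS
shift < 0.15% per compound; isotope convolution vs the brute-force
multinomial oracle < 1e-9 relative. Degenerate inputs are contracts, not
crashes: empty frame stacks give empty mobilograms, all-zero traces give
empty peak lists, zero-intensity extents give purity 0, single
replicates give NaN dispersion.

## Known limitations

Profile-mode (non-centroided) spectra, 3D feature finding across
retention time, nonlinear calibration models, vendor binary formats
(.d/.tdf) and positive-mode adduct catalogs are out of scope. The mzML
reader covers the centroided ion-mobility subset (spectrum list with
inverse-reduced-mobility cvParams, plain or zlib float arrays) rather
than the full standard. In-TIMS collisional dissociation (transfer-
voltage adduct stripping) is representable only as synthetic fixtures
with and without adduct species; its physics is not modeled.
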
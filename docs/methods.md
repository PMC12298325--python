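# Methods

## The allocation model

Whole-venom composition is modelled as a probability simplex over toxins
plus an uncharacterized remainder. Observation happens at three nested
levels:

1. **Peaks.** The RP-HPLC trace (absorbance at 214 nm vs time) is split
   into peaks; each non-excluded peak's baseline-corrected area, divided
   by the total over non-excluded peaks, is its venom fraction. Excluding
   a peak (e.g. one shown to contain only a non-venom contaminant) removes
   it from the denominator entirely.
2. **Bands.** A peak containing proteins of resolvably different mass
   shows several SDS-PAGE bands; integrated band densities, normalised
   within the lane, split the peak's fraction. Unidentified bands keep
   their density share — they are venom mass we cannot name, so their
   share flows to *uncharacterized* rather than being dropped (dropping
   them would silently inflate every identified toxin).
3. **Within-band MS1.** Co-banded toxins are split by summed MS1
   extracted-ion intensity. Ion counts are only comparable within one
   LC-MS run; the partitioner rejects feature sets mixing run ids, and no
   normalisation across bands or runs is ever applied.

Each factor defaults to 1 when its level is a singleton, so the model
degrades gracefully to pure peak integration. The toxin fraction is the
sum of its peak×band×MS1 terms (a toxin eluting in several peaks, as
dominant long-chain neurotoxins do, simply accumulates terms); provenance
records every term. Conservation (Σ fractions + uncharacterized = 1) is
enforced to 1e-9 at construction — it is an internal-consistency
invariant, not a statistical statement.

Family rollups are exact sums of member fractions; percentages are
rounded half-away-from-zero only at reporting time, so a reported family
total is always the sum of its reported members up to display rounding.

## Chromatogram processing

*Baseline.* Rolling-minimum with linear interpolation: a sample is a
baseline anchor when it realises the minimum of at least one window
(equivalently, where the morphological opening equals the signal); the
baseline interpolates linearly between anchors, is clipped to lie at or
below the trace, and treats the first and last samples as anchors (a
trace is assumed to start and end off-peak). The window (default 6 min)
must exceed the widest peak footprint; the known trade-off is that under
a drift of slope *s* the anchors creep up the peak flanks to a height of
order *s*×window, clipping tails — keep *s*×window small against peak
heights. A window smaller than one sample degenerates to baseline ≡
trace, documented and tested as the limit case.

*Peak picking.* Local maxima of the corrected signal with prominence ≥
`min_prominence` (default: 1% of the maximum corrected signal);
boundaries at the deepest valley between adjacent apexes, earliest sample
on ties; outer boundaries at the deepest point flanking the first/last
apex. Time windows are half-open with the shared valley sample assigned
to the earlier peak; because the trapezoid rule sums per-segment areas,
adjacent peaks sharing a boundary sample conserve total area exactly.

*Integration.* Trapezoidal on the corrected signal clipped at zero
(baseline overshoot must never produce negative abundance). Peaks whose
fraction falls below `min_area_fraction` (default 0.1%) are dropped and
fractions recomputed. Operator-defined sub-peaks (shoulders the picker
cannot separate) enter via a manual-boundaries table.

*Peak-to-lane matching.* Gel lanes carry the collection time of their
fraction (`rt_min`); detected peaks are matched to lanes by apex
proximity (default tolerance 1 min). This makes lane assignment robust to
an undetected minor peak; a detected peak with no lane, and a lane with
no detected peak, are both surfaced rather than silently shifted.

## Identification

Tryptic digestion cleaves C-terminal to K/R except before P, enumerating
peptides with up to the configured missed cleavages and exact (start,
end) coordinates; fully cleaved peptides concatenate back to the input
(tested as an identity). Matching is exact substring search against
precursor sequences with I and L folded together by default — the two
residues are isobaric and indistinguishable in bottom-up MS. Peptide
identity is therefore assumed established upstream; spectral scoring,
mass tolerances and FDR control are out of scope, and mass-only
modifications (carbamidomethyl-C, oxidised-M) are invisible to substring
matching — a documented limitation. A protein is identified at ≥ 1 unique
peptide (unique = all matches within one collapsed proteoform group);
identification is monotone in that threshold.

Proteoform collapsing: records of the same family group when their mature
chains (signal/propeptide always trimmed first) reach ≥ 0.95 global
identity, counted as alignment matches divided by the shorter mature
length under match=1/mismatch=0/gap=0 scoring, tolerating internal gap
runs up to 50 residues (covers retained untranslated stretches of ~40-50
residues seen in real assemblies). Groups are single-linkage closures and
partition the records; the representative is the longest mature sequence,
ties broken lexicographically by id.

## The synthetic mock venom

The generator emulates the study conditions the pipeline is meant for: a
small-elapid-like venom dominated by one 3FTx, with a tail of secondary
families.

- **Abundances**: symmetric Dirichlet over toxins (default concentration
  0.5; the packaged fixture uses 0.3, giving a sparse, dominated mixture
  with a top component near 50-60%), sorted so toxin 1 dominates.
- **Peak layout**: the dominant toxin elutes in 4 peaks (proteoform
  heterogeneity); other toxins co-elute with probability 0.3. Peaks are
  placed by hydrophobicity rank (Kyte-Doolittle GRAVY of the mature
  chain) evenly across the shallow 15-45 %B gradient segment with ±15%
  jitter — rank placement keeps peaks resolvable without a retention
  model, which is deliberately out of scope. Impurity peaks elute early
  (5-13 %B), mirroring a ribosomal-protein contaminant peak.
- **Peak shape**: exponentially modified Gaussian, σ ∈ [0.15, 0.3] min,
  τ ∈ [0.08, 0.18] min per peak — right-tailed peaks ~0.5-1.5 min wide,
  typical of long shallow-gradient separations. The returned ground-truth
  areas are the analytic EMG areas (the EMG density integrates to 1).
- **Detector response**: area ∝ amount with per-toxin response factor
  defaulting to 1 (equal A214 response per unit mass). Whether response is
  uniform across peaks is not asserted anywhere — it is exposed as a
  parameter (`response_factor_sd`) instead.
- **Noise**: white noise (default 0.2 mAU) and linear drift (default
  0.02 mAU/min) on the trace; multiplicative log-normal noise on band
  densities (CV 5%) and MS1 features (σ = 0.15 per feature, i.e. ~15%
  CV, in the range reported for within-run label-free MS1). Each toxin
  contributes one MS1 feature per detectable tryptic peptide (7-30
  residues, ≤ 2 missed cleavages, capped at 10) with Dirichlet
  "flyability" weights, so per-toxin summed intensities average over
  several features as the partitioner expects; features below
  1/dynamic-range of the band's strongest are dropped.
- **Gel**: toxins co-band when masses differ by ≤ 2 kDa (single-linkage on
  the mass ladder); the default mass→mobility map is log-linear and
  validated monotone. `unidentified_band_fraction` adds one
  unidentifiable band per lane carrying that share of lane density.
- **Expression table**: two replicate cpm columns normalised to 1e6,
  family shares following a configurable profile (default 72% 3FTx / 16%
  PLA2 / 12% minor families, echoing a strongly upregulated toxin set), a
  configurable zero-in-both-replicates fraction, and a small sub-1-cpm
  "ambiguous" fraction.

Everything is a pure function of (parameters, seed). The packaged fixture
(`aa_fixture`, seed 42) has 12 toxins over 7 families and 2 impurity
peaks; both impurity peaks are treated as identified contaminants and
excluded, so recovered fractions are directly comparable to the
ground-truth simplex.

What the generator does **not** emulate: MS/MS spectra and acquisition,
isotope envelopes, retention modelling, gel smearing/saturation, between-
run batch effects, or correlated (non-white) detector noise. Passing
recovery tests therefore show the allocation arithmetic and its
statistical robustness to the modelled noise sources — not robustness to
instrument artefacts outside the model.

## Transcriptome summary choices

Genes with 0 < cpm < 1 in at least one replicate fall between the two
activity rules ("0 in both" = inactive, "≥ 1 in both" = counted); they
are flagged *ambiguous*, kept in the table, and excluded from counts and
shares. Expression shares use the mean cpm of the two replicates. Family
labels come from a controlled vocabulary column; a configurable
case-insensitive keyword matcher over description strings is provided as
a helper for tables lacking labels. Both rounded (printed-precision) and
unrounded percentages are reported.

## Numerical and degenerate-input conventions

- Fractions are validated to sum to 1 within 1e-9 at every level (lane,
  band partition, final table).
- Equal-height valley candidates: earliest time wins (deterministic).
- Zero total density ("empty lane"), all-zero MS1 intensities, zero
  integrable signal, excluding every peak, and cross-run MS1 mixing are
  all hard errors, not silent zeros.
- Pipeline stage failures are re-raised naming the stage; configuration
  validation reports all violations at once.
- Reported percentages round half-away-from-zero at one decimal by
  default.

## Problem sizes

The default trace samples a 185-min gradient at 0.01 min (18,501 points).
The recovery experiment in the test suite and acceptance script runs the
full pipeline on the packaged 12-toxin fixture across 20 observation
seeds; conservation is exercised on 100 randomly drawn mock venoms at the
allocation level. These sizes were chosen to exercise every code path at
full realism for a single-venom study while keeping the whole suite in
the tens of seconds.
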
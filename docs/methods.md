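# Methods

This note documents the models, conventions and numerical choices behind
`targetmet`, and what the synthetic-data generator does and does not
emulate.

## Scope and data model

The package processes *targeted* LC-MS metabolomics data: a library of
compounds (name, elemental formula, adduct, reference retention time), one
centroided MS1 mzML file per acquisition, and a sample sheet assigning each
acquisition a group and a role (`study` or `blank`). Quantification is by
chromatographic peak height; identification is by the library alone. There
is no untargeted feature finding, no chromatogram warping or alignment, and
no MS2 scoring.

Spectra are consumed centroided. Vendor peak-picking (profile → centroid)
is upstream of this package; the writer and reader in `_mzml.py` handle
centroid MS1 spectra with scan-level polarity, which is the minimal subset
the pipeline needs. The writer is deterministic at the byte level; both
directions are cross-checked against the independent Bioconductor mzR
reader in the test suite.

## Mass arithmetic

Monoisotopic atomic masses come from the NIST table embedded in
`pyteomics.mass`, so the package needs no network access. Adduct m/z is

    m/z = (M + Δ_ion + k·Δ¹³C) / |z|

with Δ¹³C = 1.0033548378 Da and |z| = 1 (only singly charged adducts are
supported; [M+H]⁺ and [M−H]⁻ are built in and the registry is extensible by
(label, mass delta, charge) triples). Heavy-isotope shifts model carbon
only: the tracing use case is uniformly ¹³C-labeled glucose, and modeling
other elements' isotopes (e.g. ¹⁸O at m+2) is deliberately out of scope.

## Extraction

Tolerances default to the targeted HILIC workflow this package models:
±5 ppm mass window, ±0.5 min retention-time search window, ±7.5 s apex
tolerance. Within the search window, each matching-polarity scan
contributes one XIC point whose intensity is the *sum* of centroid
intensities inside the ppm window (summing conserves signal when a peak is
split across near-coincident centroids; a `max` mode is available since
either convention is defensible). The apex is the maximum-intensity XIC
point, ties broken toward the point closest to the reference apex so output
is deterministic.

The apex-tolerance reference is resolved in two passes: pass 1 extracts
every study sample against the library retention time; the per-metabolite
*consensus apex* is the median apex over study samples with signal; pass 2
re-extracts every run (blanks included) against the consensus. Blanks never
vote on the consensus. A single-pass mode (reference = library RT) exists
for libraries with well-calibrated retention times. The median was chosen
over the mean for robustness to the occasional mis-picked apex.

Retention times are handled in minutes throughout; the apex tolerance is
converted from seconds once at parameter construction. Absence of signal is
a value (height 0, not detected), never an error.

One caveat: with the apex-retention rule, widening a window is not
*guaranteed* to never lower a height — a wider window can admit a larger
interferent whose apex is then rejected. On library-anchored data where the
targeted peak dominates its window (the regime the method assumes, and the
one the generator produces), widening is monotone, and the test suite
checks it there.

## Blank-based detection

Per metabolite the detection threshold is

    threshold = max(snr × stat(blank heights), floor)

with snr = 3, floor = 10 000 a.u., and stat = arithmetic mean of blank
heights by default (`max` is available as a stricter variant; which blank
statistic the original workflow used is not specified, so this is a
documented interpretation). A study cell is detected iff its height is
**≥** the threshold; the boundary is included so the rule is deterministic
and documented. Two study matrices are derived: threshold-imputed
(non-detected cells hold the threshold — fold changes touching such cells
are upper/lower bounds and are flagged `fc_is_bound`) and zero-imputed (for
count-model analyses downstream of this package). Blank columns are
excluded from both. Designs without blanks must opt in to floor-only
thresholding explicitly.

## Differential statistics

The primary test is the two-sided independent two-sample t-test with pooled
variance, applied per metabolite to the threshold-imputed intensities;
Welch's variant is a flag. Significance is raw p < 0.05 (strict
inequality); Benjamini–Hochberg q-values are reported in an extra column
but do not drive the flag, reproducing the workflow's stated rule while
surfacing the modern correction. Testing intensities directly (not logs) is
the default for the same fidelity reason; a log-scale option exists via
transforming the matrix before the call. Degenerate rows with zero variance
in both groups yield p = 1 when the means agree and p = 0 otherwise.

Heatmap ordering: rows are z-scored with the sample (n−1) standard
deviation (constant rows map to zeros, matching the convention of the
standard heatmap tools), then rows and columns are clustered
agglomeratively with Euclidean distance and complete linkage — the defaults
of the widely used `pheatmap` package — and leaf orders are emitted.
Clustering a matrix with NaN is an error by design.

## Natural-abundance correction

For an n-carbon metabolite the probability that a fully unlabeled molecule
appears at m+k is binomial, C(n,k)·aᵏ·(1−a)ⁿ⁻ᵏ with a = 0.0107 for ¹³C.
The default correction subtracts, for every k ≥ 1, the natural contribution
anchored at the same sample's m+0 intensity:

    corrected[k] = max(0, raw[k] − C(n,k)·(a/(1−a))ᵏ · raw[0])

m+0 passes through unchanged and negatives are clamped to zero (intensities
are non-negative; the clamping choice is ours). This rule deliberately does
*not* cascade the natural envelopes of labeled pools (an m+3 pool's own
natural m+4 is left in place); it is the subtraction rule as practiced. The
`matrix` mode inverts the full lower-triangular binomial mixing matrix and
is the rigorous alternative — on data generated exactly by forward mixing
it recovers the labeled pools to numerical precision.

A consequence of the m+0-anchored rule worth knowing: fractional enrichment
corrected[k]/Σ corrected slightly overestimates the true labeled fraction,
because corrected[0] keeps the *entire* m+0 signal while k ≥ 1 natural
signal is removed from the denominator. For a C3 compound with a true 20 %
m+3 fraction the noiseless recovered value is 0.2052. The matrix mode does
not have this bias.

Isotopologue series are extracted per (metabolite, k) with the same
windowed extraction; since isotopologues co-elute, every k ≥ 1 uses the
m+0 consensus apex as its reference.

## The synthetic-data generator

The generator emulates the acquisition the pipeline targets: a 42-minute
gradient with MS1 scans alternating polarity every `scan_interval_s`
(1 s default, so each polarity is revisited every 2 s), Gaussian elution
profiles with σ = 8 s (FWHM ≈ 19 s, typical of ZIC-pHILIC peaks), centroid
m/z with independent Gaussian error of 2 ppm SD per centroid, exponential
baseline centroids (mean 1000 a.u., ~2 per scan, uniform over m/z 67–1000),
between-sample lognormal noise with 20 % CV (mean-preserving), and blanks
carrying 1 % of the mean study signal so the 3× S/N rule exercises both
outcomes. True peak heights are drawn log-uniformly over 10⁵–5×10⁶ a.u.;
group effects are specified per metabolite in log₂ units. Formulas are real
small molecules (glycolysis/TCA intermediates, amino acids, and related
compounds) so theoretical m/z values are realistic; each run has exactly
one chromatographic peak per metabolite, matching the targeted,
library-anchored extraction model (no isomers). Tracing experiments emit
binomial isotopologue envelopes mixed with specified labeled fractions.

Two design choices make exact verification possible. Library retention
times are aligned to the scan grid of each compound's polarity, so in the
zero-jitter limit the apex is sampled exactly and extraction reproduces
true heights bit for bit. And all randomness descends from one seed through
a fixed seed-sequence tree (one child for the truth draw, one per run), so
identical configurations yield byte-identical mzML output.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data: profile-mode peak shapes and centroiding
artifacts, retention-time drift or warping between runs, co-eluting isomers
and in-source fragments, detector saturation, heteroscedastic
intensity-dependent mass error, and MS2. Results on synthetic data validate
the *processing rules*, not instrument behavior.

## Problem sizes in the verification suite

The acceptance checks run at sizes chosen to make their statistics
meaningful while keeping the suite quick on one CPU: 200 random runs for
the extraction-vs-brute-force oracle; a 10-metabolite, 3+3+2-run noiseless
experiment for the exact round trip; 1000 metabolites at n = 6 vs 6 for the
type-I band (99 % binomial band [0.032, 0.068] at α = 0.05); 200
metabolites with 20 true effects of log₂FC = 1 for sensitivity; 100
isotopologue series at 5 % multiplicative noise for tracer recovery; and an
8-metabolite full pipeline executed twice for byte-level determinism.

## Known limitations

- Only singly charged adducts; no isotope fine structure.
- Carbon-only natural-abundance correction (documented interpretation).
- The covariate-adjusted model consuming the zero-imputed matrix is outside
  this package; the matrix is produced for it.
- Extraction assumes the library RT is within ±0.5 min of the true apex;
  larger calibration shifts need a re-anchored library, not wider windows.
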
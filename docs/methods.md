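# Methods

## Data model

A T-RF profile is an ordered set of called peaks; each peak carries a
fragment-size estimate (bases), a height and an area (fluorescence
units). Sizes, heights and areas are kept at full floating-point precision
throughout — the shift-correction objective discriminates sub-0.1-base
differences, so display rounding (two decimals for sizes) happens only at
output. Shift corrections are stored as a per-profile additive
`size_offset` next to the observed sizes rather than overwriting them,
because an offset is only meaningful relative to the profile set it was
estimated against. Every transformation appends to the profile's
provenance log.

Peaks with a valid height but no area are accepted (`area = NaN`);
height-based workflows run unimpeded and area-based operations raise a
data error rather than propagating NaN.

## Detection thresholding

The peak detection threshold (PDT) is "the lowest acceptable peak height",
so the comparison is inclusive (height ≥ PDT), as are the analysis-range
bounds (default 50–1020 bases, the span over which sizes can be calibrated
against the size standard). The filter operates on already-exported peak
tables, so one export can be analysed under several thresholds. Typical
values are 50 (intermediate; baseline noise on the emulated platform is
20–30 units) and 100 (high; also removes spectral pull-up artifacts).

## Moving-average binning

Alignment bins are built from the shortest fragment upward:

1. the globally shortest unbinned T-RF seeds a bin;
2. unbinned T-RFs at most Y bases longer than the seed join, shortest
   first, at most one per profile (the first candidate of a profile is the
   one nearest the seed);
3. the bin mean is recomputed, then T-RFs at most Z bases above the mean
   join one at a time — the candidate nearest the current mean first, from
   profiles not yet represented — with the mean recomputed after every
   addition;
4. when no candidate fits, the next bin is seeded.

Defaults Y = 1, Z = 0.5, with Z ≤ Y enforced. The published description
leaves three details open, resolved here as: within a window the
candidate closest to the current bin mean wins, ties to the shorter
fragment; exact cross-profile size ties are processed in profile input
order (for determinism); and the Y window is filled once, not re-searched
after Z-phase additions. A literal, independently written re-execution of
the procedure is kept in the test suite and checked against the
implementation on a thousand random small instances.

A bin is classified **ambiguous** when any member lies strictly within the
alignment range (default 1 base) of a member of another bin; the strict
inequality means fragments spaced at exactly the range — e.g. clean
integer-spaced communities — are not flagged. For two-profile alignments,
mutually ambiguous bin clusters are re-paired by an order-preserving
matching that first maximizes the number of matched pairs (within the
range) and then minimizes the total absolute size difference; this fixes
the forward-binning artifact where the shortest fragments pair up even
when the longer ones are closer in size. Bins still ambiguous after all
corrections can be dropped, so downstream analyses use only unambiguously
aligned fragments — a deliberately conservative trade of information for
reliability.

An integer binner (round half away from zero) is included purely as the
comparison method; it splits neighbouring estimates such as 134.4/134.6
across two bins and is not recommended.

## Systematic shift correction

Size-estimation error between two runs is often systematic: all signed
differences over shared bins carry one sign. A pair is flagged *shifted*
when at least one difference is nonzero and all nonzero differences agree
in sign (zeros are sign-neutral — identical estimates are no evidence).

Correction model: one constant additive offset per profile (nonlinear,
size-dependent shifts are out of scope). Candidate references are bins
classified correct with a member in every profile; an optional flag
relaxes the status requirement. For each candidate, the common value is
the mean of the reference sizes (only relative offsets affect the
objective, so this choice only sets the reported bin sizes), offsets
follow, and the candidate is scored by the sum of standard deviations of
corrected member sizes over the correct bins of the *pre-correction*
alignment. Population standard deviations (ddof = 0) are used so singleton
bins contribute zero rather than being undefined. The minimal-score
candidate wins (ties to the smaller mean size), offsets are applied, and
the profiles are re-binned and re-classified on corrected sizes in a
single pass (no iteration to a fixed point). Injected constant offsets are
recovered to machine precision in the noiseless case and to about
3σ/√(n_fragments) under per-peak jitter of sd σ.

## Normalization

**TFN** (total fluorescence normalization): TFmin is the minimum TF (on
the configured basis) of the group; the minimum-TF profile is returned
untouched. Every other profile iterates a cumulative factor c ← c·TFmin/TF;
each iteration re-evaluates the *original* peak set under c, retaining
peaks with scaled signal ≥ threshold (so a removed peak can re-enter),
recomputes TF over retained scaled peaks, and stops when
|TF − TFmin|/TFmin ≤ 1e-9 (cap: 1000 iterations). When a
threshold-straddling peak flips in and out, the retained set enters a
period-2 cycle — detected by comparing retained-set hashes two iterations
apart — and the profile is finalized as the peak-wise average of the two
states, a peak absent from one state contributing zero. Averaged
sub-threshold peaks are retained: averaging is the declared terminal step
and no further thresholding follows. A destructive mode (peaks removed
permanently each iteration) is available as a documented alternative; the
two modes agree whenever no peak re-enters.

Thresholds by variant: TFN-heights uses the PDT; TFN-areas uses the
minimum observed peak area in the whole dataset (supplied explicitly when
a subgroup is normalized); TFN-areas-LT uses the minimum area among the
replicates being normalized. Group scope is the caller's: pairwise for
duplicate analyses, dataset-wide otherwise.

**FPT** (fixed percentage threshold): a single pass removing peaks whose
relative abundance on the input profile is strictly below the threshold
(default 1%); survivors are not rescaled, so every retained peak's
original-profile abundance is ≥ the threshold.

## Consensus profiles

A consensus keeps the bins present in all (default, with two replicates)
or at least k replicates; its peak size, height and area are unweighted
means over the members actually present. Consensus TF is therefore
bounded by the larger replicate TF, and the peak count by the smaller
replicate count.

## Similarity

Jaccard = |A∩B|/|A∪B| on presence sets (presence = abundance > 0);
Bray-Curtis similarity = 1 − ½Σ|p−q| = Σ min(p,q) for unit-sum vectors.
Similarities are computed on bins *after* the chosen treatment, with
abundances renormalized over the retained bins. Two empty profiles compare
as 1 with a warning (reachable after aggressive filtering) rather than
erroring. Distance matrices are written as 1 − S.

## Synthetic data generator

The generator emulates, with known ground truth, the noise structure
measured in repeated loadings:

| phenomenon | model | default | rationale |
|---|---|---|---|
| size jitter | N(0, σ) per peak, truncated at ±cap | σ = 0.21·√π/2 ≈ 0.186, cap 0.48 | E\|j₁−j₂\| = 2σ/√π = 0.21 bases between duplicates; duplicate differences stay < 1 base |
| systematic shift | uniform constant per profile | ±0.4 bases | matches the constant-offset correction model |
| loading multiplier | arcsine on [1−c, 1+c], c = √2·cv | cv 0.163 | duplicate TF differences mean ≈ 17% of the higher TF with a hard maximum 2c/(1+c) ≈ 37%; lighter-tailed shapes miss the mean, heavier-tailed ones overshoot the observed ~33% maximum |
| artifact peaks | Poisson count, uniform sizes, uniform heights | rate 3, heights 20–100 | spans the 20–30-unit baseline up to sub-PDT pull-up artifacts |
| peak broadening | area = height·(1 + slope·size) | slope 0.002 | peaks broaden and flatten with migration distance |
| heights | abundance · base_signal · concentration · multiplier | base_signal 30000 | puts a 0.2%-abundance fragment at the PDT-50 detection edge, so low-abundance detection depends on loading, as observed |

Communities default to log-normal abundance weights (σ = 1.2; few dominant,
many rare fragments) at sizes spaced ≥3 bases. The size-jitter statistics
(0.21-base mean) are modelled as pure per-peak jitter; systematic shifts
are a separate, separately-switched phenomenon, so calibration checks run
with shifts disabled while shift-recovery studies enable them.

What the generator does **not** emulate: size-dependent (nonlinear)
migration error, restriction-site biology, PCR amplification bias,
overlapping-peak area distortion, and correlated artifact structure.
Passing tests therefore demonstrate correctness of the data treatment
under the characterized noise model, not robustness to every failure mode
of real electropherograms.

## Treatment presets

Nine named treatments are shipped, combining PDT 50/100, TFN-heights /
TFN-areas / no normalization (of replicates and/or consensus profiles),
shift correction on/off, and moving-average vs integer alignment. The
stage report records profile count, mean T-RF count and mean TF after
every stage; the mean T-RF count is non-increasing by construction, since
every stage only removes or merges peaks. The `TRex-A`/`TRex-H` presets
model workflows whose noise filtering is done by an external statistical
filter; they refuse to run unless the caller declares the input
pre-filtered, since that filter is not implemented here. Treatment
configurations hash to a digest that is logged with the input digest and
package version for reproducibility.

## Problem sizes in tests

The test-suite and acceptance-script simulations use 15–30 fragment
communities, up to 8 profiles for shift studies, 51 duplicate pairs (1000+
duplicate peak pairs) for noise calibration and 10⁴ random vector pairs
for the similarity identities — sizes at which the Monte-Carlo tolerances
stated alongside each check are comfortably resolved while the whole suite
runs in seconds.

## Known limitations

* The shift model is a constant offset per profile; genuinely nonlinear
  size-calibration differences are only partially absorbed.
* TFN cycle detection assumes the period-2 alternation described for
  threshold-straddling peaks; longer cycles (not observed in practice)
  raise a diagnostic error instead of being averaged.
* Duplicate-pair ambiguity resolution is defined for exactly two profiles;
  multi-profile ambiguity is addressed by shift correction and, failing
  that, by dropping ambiguous bins.
* Raw electropherogram traces (.fsa) are not parsed; the toolkit starts
  from exported peak tables.
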
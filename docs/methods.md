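# Methods

## Quantification model

Each protein is quantified by a single **representative peptide**: among
peptides observed in both SILAC channels anywhere in the dataset, the one
occupying the greatest number of distinct (replicate, slice, channel)
cells. Ties break by larger summed intensity, then lexicographically
smallest sequence, so selection is deterministic. If no peptide is seen in
both channels, the most frequent one overall is used and the protein is
flagged `single-channel-representative`. Counting distinct cells (rather
than spectral counts) makes the choice robust to repeated measurements of
the same slice; this counting unit and the tie rules are this package's
own conventions.

**Migration profiles** are built per (protein, condition): the
representative peptide's intensities are summed per slice within each
replicate, the raw replicate profiles are averaged element-wise, and the
averaged profile is divided once by its maximum. Averaging *raw* profiles
before the single max-normalization means the replicate with more signal
contributes proportionally; normalizing per replicate first would weight
noisy low-signal replicates equally. Slices without an observation count
as zero intensity — absence of evidence at the detection floor — but are
excluded from ratio denominators.

**Condition ratios** (reference/perturbed) are computed per replicate as
the ratio of summed slice intensities of the representative peptide over
slices where at least one condition was observed, then combined across
replicates by geometric mean (ratios are scale quantities; the arithmetic
mean of a ratio and its reciprocal is biased above 1). A protein with
signal in only one condition is flagged `absent-in-perturbed` or
`absent-in-reference` rather than assigned an infinite ratio. An
`all_peptides=True` switch sums every peptide of the protein instead; the
default stays with the representative peptide for consistency with the
profiles. The single-peptide ratio carries ≈10 % relative sampling noise
per replicate at the default measurement error (the kernel-weighted
effective number of slices in a band is only ≈3.5), so per-protein ratios
of unchanged proteins scatter roughly ±20 %; the all-peptide estimator
averages over ~5 peptides and tightens this to ±10 %. Complex-level
medians are much tighter than either.

No between-replicate loading normalization is applied by default — SILAC
mixing within a lane already controls composition; an optional
total-intensity scaling (`total_intensity_normalization`) exists for gross
loading differences between lanes.

## Gel model and calibration

Apparent mass is log-linear in slice index: `log10(mass) = intercept +
slope × slice`, the standard behaviour of gradient native gels over their
resolving range. Calibration fits this line by least squares to a marker
table (≥2 markers, strictly co-monotone); with two markers it
interpolates exactly. The RMS residual in log10 units is reported so an
inadequate model is visible instead of silently absorbed. By default the
pipeline **self-calibrates**: the configured gel endpoints anchor the
extremes and two landmark complexes detected in the reference lane anchor
the middle — the free complex III dimer (500 kDa, the lowest-mass band of
UQCRC2) and the complex V monomer (700 kDa, the dominant band of ATP5F1B).
Which markers a real experiment should trust is a judgement call; an
external marker TSV overrides self-calibration.

## Peak calls and migration shifts

Normalized profiles are smoothed with a 3-point moving average (window
configurable; 1 disables), and local maxima strictly greater than both
neighbours and at least `min_rel_height` (default 0.2) high are called as
bands; boundary slices count with their single neighbour. Interior peak
positions are refined by parabolic interpolation over the three slices
around the maximum, recovering sub-slice band centres to ≈0.1 slice for
Gaussian bands. Band heights are read from the smoothed profile, so a
band must clear the height threshold *after* smoothing — shoulders and
noise ripples at the default noise level are not called, and real minor
bands close to the threshold (e.g. a species at ~26 % relative height
flanked by neighbours at ~15 %) may be suppressed; lower `min_rel_height`
to recover them.

Between conditions, peaks are matched greedily by nearest slice within
`match_tol` (default 1.5 slices, comfortably above the ≈0.15-slice jitter
of refined band centres at default noise while below the spacing of
distinct assembly forms). Unmatched perturbed peaks are *gained*,
unmatched reference peaks *lost*.

Complex-level fold changes are the median and IQR over finite subunit
ratios — the median is robust to modules that deviate from the rest of
the complex (the N-module subunits of complex I are depleted more strongly
than the core in the default scenario). Absent-in-one-condition subunits
are counted and reported separately; folding them in as infinities would
dominate any summary. Co-migration is the Pearson correlation of two
normalized profiles over all slices (≥5 slices of combined support
required), the common complexome-profiling practice.

## Synthetic evidence generator

The generator emulates the statistical structure the analysis assumes.
Each assembly form is a Gaussian band in *slice* coordinates (width
`peak_sigma`, default 1 slice) centred where its apparent mass migrates
under the log-linear gel model — Gaussian in slices, not mass, matching
the smeared appearance of native bands. The discretized kernel is
truncated at ±5σ and renormalized over the in-gel slices, so the loaded
amount of every protein is conserved exactly and noise-free runs are
machine-precision reproductions of the closed-form signal. Per-protein
signal is the abundance-and-stoichiometry-weighted sum of its forms'
kernels. Peptide-level evidence multiplies this signal by a per-peptide
lognormal response factor (σ = 0.3, fixed across replicates and
channels), the condition's mixing share (1:1 by default), and a
per-observation lognormal measurement error (σ = 0.2). Observations below
the detection floor are censored — dropped entirely, not stored as zeros.
The default floor (4.6e-4 abundance units) is the 10th percentile of the
noise-free nonzero signal distribution of the default scenario, giving
realistic sparsity (~10 % of true observations censored) without
destroying recovery.

The default scenario fixes a 64-slice gel spanning log10(mass/kDa) 3.5 →
1.5 and a form table encoding the knockout phenotype: summed over forms,
non-N-module complex I subunits total 100 (wt) vs 20 (KO) — exactly
fivefold — while the four designated N-module subunits are excluded from
the 750 kDa precomplex and therefore deplete more strongly; all assembled
complex IV species have KO abundance 0 except the 130 kDa
MT-CO1/COA3/HIGD2A intermediate; complex III shifts toward its 500 kDa
dimer; complex II is identical in both conditions; mtLSU (1650 kDa) and
mtSSU (850 kDa) are reduced 1.75-fold and the assembly factors DDX28
(60 kDa) and ERAL1 (48 kDa) twofold. Apparent masses and abundances of
species other than the 130 and 750 kDa landmarks are generator defaults
chosen to be physiologically plausible, not measured values. Replicate 1
carries the heavy label on wild-type and replicate 2 on the knockout; a
label swap is assumed as the default duplicate design, though real
duplicate experiments need not have swapped labels.

What the generator does **not** model: isotope-envelope overlap and ratio
compression, retention-time effects, charge states, shared peptides
between proteins, protein-specific digestion efficiency, and band
asymmetry. Passing tests therefore demonstrate that the analysis recovers
the assumed generative structure, not that it is robust to every artifact
of real complexome data.

## Problem sizes and determinism

The default scenario simulates 144 proteins (~37 000 evidence rows); a
full pipeline run takes a few seconds, and the multi-seed recovery
checks use 20 independent simulations. A single integer seed drives every
stochastic stage through one `numpy` generator consumed in a fixed
iteration order, so identical (config, seed) pairs produce byte-identical
output files; report numbers are written with fixed formatting to keep
the byte-level guarantee. Degenerate inputs (empty evidence, all-zero
profiles, single-channel proteins, constant profiles in correlation) are
flagged explicitly rather than silently coerced.

## Known limitations

- One profile per (protein, condition): the package does not separately
  report per-experiment channel profiles.
- Shared peptides are assigned to every mapped protein; no protein
  inference.
- The log-linear calibration cannot represent gel compression at the
  extremes; the residual diagnostic flags it but no spline fallback is
  provided.
- Complex-level summaries assume two conditions; multi-condition designs
  and statistical testing across them are out of scope.
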
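# Methods

`enhancerkit` implements the computational core of an enhancer-genomics
analysis anchored on enhancer RNA (eRNA) origins: where RNA polymerase II
loads at an active enhancer, nascent-transcription data show divergent
strand-specific read pileups, and the center of that bidirectional signature
is a point anchor for asking which transcription factor motifs cluster at
active regulatory elements, how accessible the surrounding chromatin is, and
how accessibility and expression shift between conditions. This note records
the models, the tunable parameters and their defaults, the numerical
choices, and what the synthetic validation does and does not establish.

## PWM scanning and threshold calibration (`pwm`)

A motif is a position weight matrix: an L x 4 table of base probabilities
over A, C, G, T. Windows are scored with the log2 likelihood ratio against
an i.i.d. background model,

    score(w) = sum_i log2( p_i(w_i) / b(w_i) )   [bits],

with optional pseudocount smoothing `p' = (p + c*b) / (1 + c)`. Both strands
are scanned; minus-strand hits are reported in forward BED coordinates.
Windows containing N are skipped rather than scored against the background —
the common scanner convention, avoiding invented scores.

The hit threshold is calibrated to a target p-value (default 1e-5, the
conventional genome-scan cutoff this analysis family uses): the null
distribution of the window score under i.i.d. background positions is built
by dynamic programming over per-position score distributions, and the
threshold is the smallest attainable score whose exceedance probability is
at most the target. Numerics: score sums are merged at 1e-9 bits, which
keeps the DP exact to far below the score spacing of real motifs; if the
number of distinct states exceeds 10^6 the DP restarts on a fixed 0.01-bit
grid. A p-value below the attainable minimum (e.g. below 1/4^L under a
uniform background) returns the maximum attainable score with a warning.
All overlapping hits are reported; any pruning policy belongs downstream.

## Bidirectional origin calling (`origins`)

Strand-specific coverage (two bedGraph tracks, minus strand as positive
magnitudes) is densified per chromosome and each strand smoothed with a
centered moving sum of halfwidth 30 bp. Strand-local maxima with smoothed
mass >= 20 reads are candidate peaks; on plateaus the midpoint (floored) is
taken, so a smoothed point spike maps back to its own position. Each
minus-strand maximum is paired with its nearest downstream plus-strand
maximum when the separation is in (0, 300] bp; pairing is one-to-one and
greedy by descending total smoothed mass with ties toward the smaller
coordinate. The origin is the rounded mass-weighted mean of the paired peak
positions, and origins closer than 150 bp are merged keeping the higher
total mass. All four parameters are overridable.

This is a deterministic peak-pairing rule, deliberately simpler than
probabilistic mixture-model callers for nascent transcription: downstream
motif displacement needs only origin points. The "nearest downstream
partner" constraint is what keeps tail fluctuations of a strong origin from
spawning satellite calls — every spurious minus-side maximum competes for
the same dominant plus peak and loses it to the main pair. On synthetic
coverage with >= 200 reads per origin and no noise the caller recovers every
planted origin within a few bp (validated at +/- 25 bp) with zero false
calls.

## Motif displacement (`md`)

For one motif, each instance (midpoint = floor((start+end)/2), strand
ignored) is assigned a signed distance to its *nearest* origin, equidistant
ties toward the smaller origin coordinate; instances farther than R are
dropped and each instance counts once. The MD score is

    md = h / H,  h = #{|d| <= r},  H = #{|d| <= R},

with inclusive radii and defaults r = 150, R = 1500 (a 3000 bp window
around the origin). Under uniform placement md converges to r/R = 0.1. H = 0
leaves md undefined (NaN, flagged) and the motif is excluded from testing.
Nearest-origin assignment (rather than counting an instance once per nearby
origin) avoids double counting where origins cluster; this is a documented
choice, not an inferred convention of other implementations.

Two conditions are compared per motif with the pooled two-proportion z-test

    z = (md_a - md_b) / sqrt( p(1-p) (1/H_a + 1/H_b) ),  p = (h_a+h_b)/(H_a+H_b),

two-sided normal p-value, significance at alpha = 1e-4 (the stated
convention for MD comparisons; no further multiplicity correction is
applied). A pooled proportion of exactly 0 or 1 has no variance; such pairs
are flagged degenerate with p = 1. Barcode matrices are equal-width
histograms of the signed distances over [-R, R]; the bin count must be even
so 0 sits on an edge, and a distance of exactly 0 lands in the right-central
bin (numpy half-open bins, last bin closed).

## Single-nucleus contrasts (`sn`)

Nuclei arrive labeled (sample, disease, genotype, cell type) with total
counts and per-feature counts; clustering and label transfer are upstream
and out of scope. Two minimal models consistent with "logistic regression"
and "negative binomial regression" on per-nucleus data are fixed:

- **Accessibility.** Response = indicator(feature count > 0); model
  `logit P = b0 + b1*group + b2*log(total_counts)`; p-value from the
  likelihood-ratio test of b1 = 0. The headline fold change is the ratio of
  depth-normalized group means (counts per 10^4 total), since a
  probability-model coefficient is not a count ratio; exp(b1) is also
  reported. If a group mean is exactly zero, 1 count per 10^4 is added to
  both means and the result flagged — applying that offset unconditionally
  would bias typical ratios by tens of percent, so it is strictly a
  zero-division guard. Complete separation falls back to a small-ridge
  penalized fit, flagged.
- **Expression.** Counts ~ NB2 with log link, log(total_counts) offset, and
  a group covariate; the dispersion is estimated by maximum likelihood
  jointly with the coefficients in both the full and reduced models, and the
  group term is tested by likelihood ratio. fold_change = exp(b1).
  Nonconvergence falls back to Poisson regression, flagged.

Bonferroni adjustment is `p_adj = min(1, p * n_tests)` with n_tests equal to
the number of contrasts actually run (logged in the results table).
Pseudo-bulk tracks sum per-base fragment overlap across a nucleus subset,
normalized per 10^4 nuclei.

## MNase protection (`mnase`)

Tiled qPCR across a region, digested vs undigested chromatin, under the
standard efficiency-2 delta-delta-Ct model: per replicate,
`dCt_i = Ct_digested_i - Ct_undigested_i` and
`protection_i = 2^-(dCt_i - dCt_ref)` against a configurable reference
amplicon (the data do not pin down whether normalization used an external
or in-tile reference, so it is a parameter). Protection is therefore
*relative to the reference*, exactly 1 there in every replicate, invariant
to any common additive Ct shift, and reported as mean +/- SD across
replicates ordered along the tile. Amplicons missing from some replicate are
flagged, never silently dropped.

## Synthetic data (`synthetic`)

The generator encodes the statistical structure each stage assumes, with
truth tables sufficient to score every downstream estimate.

- **Genome**: i.i.d. bases at a configurable GC fraction; default 100 kb.
- **Origins**: uniformly placed subject to a minimum spacing (default 20
  origins, 3000 bp spacing — no overlap of +/-1500 bp MD windows, and ~60%
  of the genome within R of an origin so the null condition keeps H large).
- **Motifs**: a fraction of instances (default 0.5) centered uniformly
  within +/-150 bp of a random origin, the rest uniform; the consensus (or
  its reverse complement) overwrites genome bases, keeping coordinates
  stable; overlaps are redrawn up to a retry cap. Placement density must
  respect window capacity: the 20-origin default exists because heavy
  co-localized loads cannot pack into fewer windows.
- **Coverage**: per origin, half the reads on each strand at origin +/-
  offset with geometric offsets (support >= 1) of mean 60 bp — the simplest
  one-parameter discrete heavy-tail; the empirical offset distribution of
  real nascent-transcription data is not modeled. Optional uniform noise
  reads per strand.
- **Nucleus tables**: depth ~ lognormal(7.5, 0.4) (median ~1800 counts, a
  realistic single-nucleus scale); accessibility ~ Bernoulli with logit
  linear in group and centered log depth (slope 0.25), calibrated so the
  rate ratio at mean depth equals the configured fold change (default 1.52);
  expression ~ NB with mean proportional to depth times baseline 4 counts
  and group ratio 1.91 by default, size parameter r = 0.5 (variance =
  mu + mu^2/r; r = inf gives the Poisson limit). Accessibility is a
  per-nucleus indicator, not fragment counts, matching the logistic response
  contract.
- **MNase Ct**: undigested Ct near a fixed plateau (22 cycles, 0.1 SD
  jitter), digested Ct lower by log2(protection) plus Normal(0, noise_sd).

Fixed seeds give byte-identical outputs; operations draw from independent
salted substreams of the config seed.

What passing on this synthetic data does **not** show: robustness to mapping
artifacts, non-i.i.d. genomic background (repeats, CpG composition), motif
instances arising from the background sequence itself, empirical
nascent-read offset distributions, doublets/QC failures in single-nucleus
data, or per-sample batch structure (group labels are constant within
simulated samples, and the regressions treat nuclei as independent).

## Validation scales

The test suite validates: scanner and threshold exactness against brute
force/enumeration (50 random PWMs, L <= 8); MD null calibration (1e5
uniform distances; size of the z-test over 1000 null pairs) and detection
power (100 seeds, planted fraction 0.5 vs null); origin recovery (20 seeds,
500 reads/origin); regression recovery (50 seeds at 3000 nuclei/group,
planted ratios 1.52/1.91); and the exact MNase round trip. The acceptance
script reruns the main computations at these scales, averaging each
fold-change contrast over 5 replicate datasets (the replicate-averaged
simulation-study estimate). The whole suite runs in well under a minute on
one CPU; sizes were chosen as the smallest that make the statistical
assertions stable.

## Known limitations

- The origin caller reports point estimates only — no region boundaries, no
  pausing/elongation decomposition, no differential transcription.
- The exact-DP threshold path assumes a 0th-order background; higher-order
  or positional backgrounds are out of scope, as are gapped motifs and
  q-values.
- The logistic/NB contrasts model nuclei as exchangeable within groups;
  sample-level random effects are not modeled.
- MNase protection assumes perfect amplification efficiency (exactly 2 per
  cycle) and reports protection only relative to the chosen reference.
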
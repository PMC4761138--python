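# Methods

## The measurement model

In-vivo MNase digestion of the bacterial nucleoid converts chromosome
accessibility into fragment statistics: DNA bound by nucleoid proteins or
occluded inside higher-order structures survives digestion as short
protected segments, while accessible DNA — notably around transcription
start and end sites — is destroyed. Sequencing gives 36-bp tags marking the
5'-end of each surviving fragment on one strand of the circular genome. All
coordinates in the package are 0-based half-open; a minus-strand tag's
5'-end is the fragment's rightmost base, matching standard aligner
semantics. Positions wrap modulo the genome length whenever the genome is
declared circular.

## Quality control

Amplification bias produces isolated positions carrying implausibly many
duplicate tags. Per strand, the mean and population SD of tag counts are
computed **over occupied positions only** and positions with
`(count − mean)/sd > 7` are zeroed. Using all positions instead would put
the mean far below 1 and the cut would remove essentially every duplicated
position, defeating the filter's purpose; both the pooling of strands and
the inclusion of zero positions remain available as flags. Duplicate tags
at a surviving position are counted, not collapsed — the filter removes
positions, not reads. The filter is approximately idempotent: on simulated
data a second pass removes well under 0.1 % of the remaining tags.

## Fragment size and spacing

Fragments sequenced from both ends leave tag pairs on opposite strands, so
the Pearson correlation between the plus-strand counts and the minus-strand
counts shifted by `d` peaks near the fragment length (a 50-bp fragment's two
5'-ends lie 49 bp apart, so the estimator reports the peak lag itself).
Correlations are computed exactly at every integer lag via FFT (circular
convolution on circular genomes; overlap-windowed Pearson otherwise) and
smoothed in a 25-bp running boxcar. Unique-alignment constraints are known
to produce a technical peak at the read length in real data, so lags within
±5 bp of the read length are excluded. A candidate peak must be a strict
local maximum standing at least 6 robust SDs (median/MAD over the searched
lags) above the profile baseline; otherwise the sample is control-like and
the estimator raises a no-estimate error rather than returning noise. The 6
SD floor separates the two regimes by more than an order of magnitude on
simulated data (nucleoid peak z ≫ 100, control maxima z ≈ 2–3).

Spacing periodicity uses the same-strand autocorrelation, averaged over the
two strands (per-strand profiles are retained). The raw profile over lags
1–1000 is mean-subtracted and transformed with a zero-padded real FFT
(default padding to ≥16× the profile length, so the period grid near 93 bp
is ~0.3 bp); power is scaled as `(2/n)|X_k|²`, which at unpadded Fourier
frequencies equals the explained sum of squares of a least-squares sinusoid
— the identity the test suite verifies. The dominant period is the power
argmax restricted to 50–500 bp.

## Fragment centers and metagene profiles

Tags are shifted by `round(size/2)` towards the fragment 3'-end (plus tags
right, minus tags left), giving strandless center counts that conserve the
tag total. Metagene profiles extract ±500 bp windows at TSS or TES, mirror
minus-strand genes so positive offsets point downstream of transcription,
average over genes, and smooth with a 51-bp boxcar (GC and center profiles)
or loess (A-tract coverage; span 0.1 of the window, the value being
unstated in the source analyses). Genes, not operons, anchor the profiles,
and no overlap exclusion is applied by default — on dense bacterial gene
layouts neighbouring genes' accessibility dips therefore contaminate the
flanks, which is why the recovery tests measure dip geometry on genes with
no foreign anchor within 250 bp and estimate the dip width by integrating
the depletion area (exact for a rectangular dip and robust to edge blur).

## Cluster calling

Center density is the exact sum of Gaussian contributions (σ = 25 bp) at
every base, computed by FFT convolution with tails truncated at 8σ — the
truncation error per center is below 10⁻¹⁵, keeping the track within 10⁻¹⁰
of a naive double loop. The significance threshold is calibrated against a
Monte-Carlo null: 20 draws of the same number of centers placed uniformly
on the genome, KDE'd identically. The reported threshold is the smallest
density `t` at which the mean number of null positions above `t` is at most
`FDR × `(observed positions above `t`) — an empirical positionwise FDR with
target 10⁻³. A per-cluster variant is deliberately not implemented; the
positionwise construction is the one the calibration curve (written to
JSON) describes. Because the null is re-simulated at the observed depth,
thresholds rescale only approximately when counts are scaled; the calls are
stable (tests require ≤10 % count change and ≥0.9 positional Jaccard under
count doubling). Runs above threshold separated by <25 bp are merged
(including across the origin), runs shorter than 25 bp are then discarded,
and clusters are screened by the ratio of per-million nucleoid density to
per-million control density over the cluster (pseudo-density
1/genome-length in the denominator; default minimum ratio 1.0, the source
threshold being unstated).

## A-tract statistics

A-tracts are maximal runs `A^n T^m` with `3 ≤ n+m ≤ 10` and no internal TpA
step; either run may be empty, non-AT bases (including N) break runs, and
runs longer than 10 are excluded entirely rather than truncated, because
the definition bounds `n+m` itself. Region membership is by tract midpoint
(any-overlap and containment alternatives are easy to add at the call
site). The genome-to-random ratio divides observed per-length counts by
their mean over 15 uniform permutations of the genome's own bases —
mononucleotide composition is preserved exactly; i.i.d. resampling of the
same composition is a one-line variant. Closed-form expected counts on
i.i.d. sequence (boundary factors `1−p_A` / `1−p_A−p_T` on the left and
symmetric on the right) back the statistical tests.

## The synthetic-data generator

The generator is the package's acceptance surface: it emulates the loop
model of low-level nucleoid organisation and emits the ground truth each
estimator must recover.

* **Genome** (1 Mb, circular, GC 0.51): i.i.d. bases except at planted
  features. 500 footprint groups (0.5/kb) of 2–5 footprints, 50 bp long,
  successive starts 93 ± 3 bp apart, placed without overlap. A-tract
  groups (three tracts of length 3–10 with G/C separators) are planted at
  loop apexes — the gaps between successive footprints — at a rate of one
  group per apex, and extra tracts (Poisson mean 4 per promoter, a free
  magnitude, the source reporting only the qualitative enrichment) in
  [−100, +20] windows around the 500 planted gene TSSs. Footprint stems are
  actively depleted of tracts by swapping a mid-tract base with a G/C base
  from the same stem — swaps preserve the global base composition exactly,
  so composition checks remain valid. Planted tracts are forced maximal at
  both flanks and verified by re-scanning the emitted sequence.
* **Nucleoid tags** (200,000): each fragment is a footprint with both edges
  jittered (SD 3 bp), or with probability 0.1 an unconstrained background
  fragment (length uniform 50–500) representing digestion leakage that
  survives gel purification — the sequenced band is mostly protected
  material, so the leakage fraction is small. A fragment always yields a
  plus tag at its left end and, with probability 0.5, a minus tag at its
  right end. Fragments whose center falls within 50 bp of any TSS/TES are
  rejected with probability 0.6, producing the ~100-bp accessibility dip.
  Footprint sampling weights are Gamma-distributed with ~22 % coefficient
  of variation: enough heterogeneity to be non-trivial while keeping
  genuine pile-ups inside the bulk of the count distribution, so the Z = 7
  filter removes only injected amplification spikes.
* **Control tags** (200,000): naked-DNA digestion; cut positions carry a
  1.5× preference for A/T bases, lengths are uniform 50–500 bp, so the
  sample has neither a characteristic length nor any spacing periodicity.
* **Anomalies**: positions at rate 10⁻⁵/bp/strand are inflated to ≥50× the
  occupied-position mean, recorded for QC verification.
* Each stage draws from an independent substream
  (`SeedSequence(seed, spawn_key=(stage,))`) of the single global seed, so
  stages are independently reproducible and every generator is a pure
  function of (config, seed).

**What the simulator does not model:** mappability (hence no 35–36-bp
technical cross-correlation peak — the exclusion band is still applied),
base-call errors, repetitive DNA, replication-associated coverage gradients
along the origin–terminus axis, operon structure, or condition-dependent
protein occupancy. Passing recovery tests therefore demonstrates estimator
correctness under the planted statistical structure, not robustness to
every artifact of real libraries.

## Problem sizes and tolerances

All validation runs at desk scale: the default preset (1 Mb, 200k + 200k
tags) drives recovery tests of the fragment size (±2 bp), spacing period
(±3 bp), TSS dip width (±25 % of the planted 100 bp, area estimator),
cluster recovery (≥80 % of planted groups at ≥50 % reciprocal overlap) and
the A-tract excess (r(8) > 3, mirroring the enterobacterial genome-wide
excess); null-placement simulations bound the called fraction at FDR 10⁻³;
brute-force oracles pin the KDE and autocorrelation to 10⁻¹⁰ and the
periodogram to 1 % of a least-squares sinusoid fit. The pipeline tests use
a 300-kb / 80k-tag reduction of the same preset.

## Known limitations

* With footprints planted in periodic groups, thresholded runs merge across
  the 93-bp gaps and called clusters span whole groups; their median length
  (~270 bp) reflects group spans, not single footprints. Real data with
  sparser, less regular protection yields much shorter clusters. Relatedly,
  called group-spanning clusters include the AT-rich apexes, which pulls
  cluster GC slightly below the genome average in simulation.
* The positionwise empirical FDR is depth-dependent (see above); exact
  scale invariance of cluster calls holds only in the large-count limit.
* Multi-chromosome inputs are handled by iterating records independently;
  there is no joint normalisation across sequences.
* The ChIP association module computes profiles only; it attaches no
  significance statement to the central enrichment.
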
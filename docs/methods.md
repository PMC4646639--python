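# Methods

## Assay model

The package models a ligation-probe, amplicon-counting copy-number assay.
A probe pair consists of a left and right oligonucleotide that hybridise
adjacently; only ligated pairs amplify, and the amplicon count is
proportional to target copy number. Each sample is assayed in two
independent reactions (a *detection* and a *confirmation* probe mix) whose
measurements are pooled at the exon level, so a single-exon call always
rests on at least two chemically independent probes.

Reads are assigned to probes by their 20-base *middle key*, the k-mer
centred on the ligation junction (k/2 bases from the 3' end of the left
hybridising arm, k/2 from the 5' start of the right arm). Centring on the
junction makes the key specific to successful ligation: neither unligated
oligo contains it. Keys are matched exactly on both strands after
trimming any 3' run-through adapter (minimum overlap 10 bases). Reads
matching no key are off-target; reads matching two or more distinct keys
are chimera-like and are discarded as ambiguous rather than fractionally
assigned. Counting uses read 1 only — the ~60 bp insert fits entirely in
either mate, and counting both would double-count. An optional
one-mismatch mode (precomputed Hamming-1 neighbourhood index) is available
but off by default, because single-nucleotide variants under a probe arm
legitimately suppress ligation and mimicking tolerance would hide that
caveat rather than address it.

## Quantification

For sample *i*, exon *j*, probe *k*:

1. **Depth normalization.** x'_ijk = x_ijk / X_i with X_i the arithmetic
   mean of raw counts over probes whose gene is *not* assayed for
   amplification. The exclusion prevents a genuine amplification from
   inflating the normaliser and masking itself. The arithmetic mean (not
   median) is used deliberately to match the assay's published behaviour;
   this choice has a known failure mode, reproduced by the test suite: a
   large heterozygous deletion spanning many normalization probes deflates
   X_i and inflates every other ratio. The package reports this skew
   rather than correcting it silently.
2. **Control baseline.** x''_ijk = x'_ijk / x̄'_k, the per-probe mean over
   accumulated control samples (minimum 3, typically 8). Per-probe CV
   across controls is recorded; probes with CV above 0.30, or falling
   below the raw-coverage floor in any control, are marked unusable and
   excluded from ratios with the reason logged. Baselines persist to TSV
   with a design checksum and refuse to be applied across design versions.
3. **Exon pooling.** Mean and sample SD (n−1 denominator) of x'' over all
   usable probes for the exon, across both reaction libraries; probes
   carried in both mixes contribute one measurement per library, since the
   libraries are separate reactions. Exons with no usable probe are
   emitted with a missing flag, never dropped.

### Coverage floor

Library QC requires 1000× median probe coverage, and probes under a 500×
raw-count floor are flagged. The floor is applied on the *control* side:
a probe under the floor in a control library is unusable in the baseline.
In case samples, below-floor probes are flagged in the report but retained
in ratios — at 1000× depth a heterozygously deleted probe is *expected*
near 500×, so excluding low-count case probes would delete the deletion
signal itself. The no-template control's mean probe coverage must stay
under 1% of the sample mean (configurable; the assay literature reports
the NTC value without a numeric threshold).

## Classification

Bands on the exon mean ratio (1 = two copies): ≤ 0.3 homozygous deletion;
(0.3, 0.7) heterozygous deletion; [0.7, 1.3] normal; > 1.3 duplication in
blood. In tumour samples gains are only *called* above 1.5 (≈ >3 average
copies); the (1.3, 1.5] band is reported as an equivocal gain for review,
guarding against genomic-instability false positives. Both edges of the
normal band classify as normal (conservative calling); all boundaries are
configuration-visible. The exon SD is reported but not used as a calling
criterion. Copies = 2 × ratio with a single configurable reference ploidy
(all panel genes are autosomal). Amplification calls are annotated low
(>3–6 copies), medium (>6–12) or high (>12) on the assay's own copies
estimate.

Origin assignment from blood–tumour pairs: an event seen in both samples
is germline; tumour-only, somatic; a tumour homozygous deletion over a
blood heterozygous deletion is germline-with-LOH, and an unpaired tumour
homozygous deletion receives the same interpretation. Unpaired events are
otherwise left undetermined. Per-exon calls are merged into region calls
as maximal same-category, same-origin runs in design exon order, with the
region ratio the mean of member exon ratios.

### Mixture dosage model

Expected ratio of a cell mixture = Σ fraction × copies / 2. Tumour purity
is the two-component case (neoplastic fraction p at c copies, remainder
diploid). The somatic detection limit at purity p is the smallest integer
loss whose expected ratio leaves the normal band: a one-copy loss is
detectable for p > 0.6 (so at 100% purity), a homozygous loss for
p > 0.3 (so at 50% purity), and at p ≤ 0.3 even a homozygous loss stays
at or above 0.7 and is undetectable.

## Simulator

The generator emulates the statistical structure of the assay, not its
chemistry:

- **Fixed probe efficiencies** — lognormal multipliers (σ = 0.25 by
  default), drawn once per design and shared by every library, so they
  cancel against the control baseline exactly as real probe biases do.
  Draws are renormalised to median 1, making `target_depth` the median
  probe coverage of a diploid library — the scale on which the coverage
  requirement is stated.
- **Ratio-scale noise** — multiplicative lognormal with mean 1 and SD
  0.103 by default, the empirical per-probe ratio spread of control
  samples. The lognormal keeps counts positive; only the SD is empirical,
  the law is a modelling choice. Pooling two probes per exon reduces this
  to ≈ 0.072 (1/√2), which the tests verify on 10⁵ simulated exons.
- **Counting** — Poisson at `target_depth` × efficiency × (copies/2) ×
  noise (default depth 1000 reads/probe). Poisson sampling can be
  disabled for exact-arithmetic tests.
- **Dropout** — zero-inflation of probe counts emulating degraded or
  low-input libraries. Quality tiers (very_good … very_poor) map to
  (noise multiplier, dropout) pairs — (1.0, 0) up to (2.0, 0.10); the
  mapping is this package's own, as the underlying gel-based DNA-quality
  grading is qualitative. At dropout ≈ 0.2 (1-ng-like input) libraries
  fail coverage QC, which the tests assert.
- **Truth model** — events are integer copy numbers over exon runs;
  somatic events are diluted by purity toward the diploid background,
  germline events apply to all cells.
- **FASTQ emission** — each probe contributes `count` reads of its ligated
  insert plus downstream adapter, padded to the read length; counting
  round-trips exactly.

With the nominal depth equal to the 1000× median requirement, a simulated
library's realized median sits within a percent of the gate and the QC
verdict is effectively a coin flip; the CLI cohort simulator therefore
defaults to a 10% loading margin (depth 1100), emulating a run loaded to
meet the requirement, while the library-level default stays at 1000.

What the simulator does **not** model: sequencing errors, chimera
formation, index hopping, PCR duplicates, GC/length bias, and the
decomposition of the 0.103 noise into biological, library and counting
components (one knob covers all three). Passing tests therefore
demonstrate the correctness of the quantification and calling logic under
the assay's stated noise structure, not robustness to artefacts absent
from the model.

## Problem sizes and determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds give byte-identical designs,
counts, FASTQ and reports. The performance checks use a cohort of 8
controls plus 50 case samples (one germline single-copy event of ≥3 exons
each) on a 6-gene × 8-exon panel with 2 probes per exon and 7 reference
genes — a deliberately compact panel on which a multi-exon event still
occupies a small fraction of the normalization probes. Noise-propagation
checks use 10⁵ simulated exons; the unbiasedness check uses 300 cases on
the full 157-probe panel preset, where a 3-exon event perturbs the
normaliser by ≲1.5%.

## Known limitations

- Relative quantification only: a genome-wide ploidy shift, or deletions
  spanning a large share of normalization probes, bias all ratios (the
  documented skew mechanism).
- Variants near the ligation site suppress counts and can mimic single-
  exon deletions; the confirmation mix mitigates but does not eliminate
  this, and the package flags rather than models it.
- The classifier acts on the mean ratio alone; an optional flag can
  additionally require |mean − 1| > 2·SD, off by default to match the
  assay's published calling rule.
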
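# Methods

## Assay model

MMSDK couples a methylation-sensitive mapping enzyme (MluI, ACGCGT) to a
fragmenting enzyme (NlaIII, CATG) and a type IIS tagging enzyme that
releases a 17-bp tag adjacent to the CATG. Only unmethylated MluI sites are
cut, so the number of tags mapped back to a site in a library is, up to
sequencing depth, proportional to the unmethylated fraction of that site in
that sample. Every analysis step below inherits this direction convention:
**a higher tag count means less methylation**, and differential calls must
be inverted to speak about methylation.

Both recognition motifs are reverse-complement palindromes, so plus-strand
motif scanning is strand-complete; this is asserted at import time.

## Virtual library

The mapping reference is the genome digested in silico under the assumption
that every site is unmethylated. Conventions, frozen so that all
coordinates are reproducible:

- A fragment joins an MluI site to the nearest CATG on each side: left
  fragment `[nla.start, mlu.start+6)`, right fragment
  `[mlu.start, nla.start+4)` — the motif is carried entirely by the
  fragment on its own side. The choice of boundary bases is conventional;
  only counts and tag interiors feed the analysis.
- Adjacent MluI sites with no CATG between them share one `mlu_mlu`
  fragment with no NlaIII end and therefore no tag; it is excluded from the
  mappable reference. Hence the library-size identity
  `mappable = 2·n_sites − 2·n_nla_free_intervals − n_end_losses`.
  End losses (an MluI site with no CATG before the chromosome start or
  after its end) are counted separately; both totals are reported.
- The virtual tag is the 17 bases immediately interior to the CATG, read
  toward the MluI end; right-side tags are read on the minus strand and
  stored reverse-complemented. Fragments with interior < 17 bases, or an N
  in the 17-mer, yield no tag and are logged.
- All copies of any 17-mer occurring more than once are removed from the
  mappable library (unambiguous mapping) but retained on a side list so the
  low-confidence mapper can still place reads on them ambiguously.

CpG islands are predicted from the three classical criteria — GC
fraction > 0.5, observed/expected CpG = (#CpG·L)/(#C·#G) > 0.6, length >
500 bp — with a 501-bp window sliding in steps of 1; windows containing N
are skipped; overlapping or touching passing windows are merged and the
merged region is re-tested on its full extent and dropped if it fails. The
promoter-detection tool the criteria come from may apply further
heuristics; only the three published criteria are implemented here, which
is why the type is simply "CGI region".

Site annotation: CGI membership is ≥ 1 bp overlap of the 6-bp motif
interval; repeat class is the overlapping repeat interval with the largest
overlap (ties: first by coordinate, logged); nearest gene minimises
interval distance (0 when overlapping, ties to the smaller start).
Coordinates are 0-based half-open everywhere internally; RepeatMasker
`.out` and GFF3 are shifted on input. Soft-masked lowercase is uppercased
and *not* treated as repeat — repeat status comes only from the annotation
file.

## Tag mapping and count matrices

Quality-aware short-read mappers grade placements by mapping quality, and
MMSDK analyses conventionally keep two tiers (quality > 0 and > 20). Base
qualities of raw reads are not part of this package's inputs, so the tiers
are modelled directly on the virtual library:

- **high** — exact match, single orientation, to a genome-unique tag;
- **low** — exact match to a duplicated tag, a hit in both orientations,
  several equally good targets (one chosen uniformly with a seeded
  generator, mirroring the random placement that earns mapping quality
  zero), or a single/chosen best hit at Hamming distance 1;
- **unmapped** — any N in the read, or ≥ 2 mismatches everywhere.

One mismatch is the default tolerance (config knob `max_mismatches`);
17-mers do not support much more without drowning in ambiguity. Reads are
matched in both orientations because tag orientation in sequencer output is
platform-dependent. Counts aggregate a site's (≤ 2) tags; the "low" matrix
counts high+low assignments (the inclusive quality->0 set), so it dominates
the "high" matrix elementwise. Library totals are all mapped tags of the
tier, not just surviving sites, which makes filtering and normalization
commute.

## Filtering and normalization

Unique (non-repeat) sites are filtered on high-confidence counts: keep a
site iff mean across libraries ≥ 5, or mean < 5 and sample SD ≥ 5. The SD
uses the n−1 denominator — unspecified in the source description, chosen
as the small-sample convention (8 libraries) and frozen. Repeat-class sites
skip the filter and are analysed on normalized low-confidence counts, the
inclusive tier being more appropriate where unique mapping is impossible.
Normalization divides by the tier-matched library total and multiplies by a
scale, counts per million by default (`scale=1`, the raw fraction, is one
config entry away); totals are assumed per-tier.

## Cluster support (AU/BP)

Libraries are clustered on 1 − Pearson correlation with average linkage
(complete and single exposed in config; the source description does not
state a linkage). Merging is deterministic: equal distances resolve to the
smallest (i, j) index pair.

Support values resample **sites** (features, rows) with replacement —
libraries are never resampled. At each scale r in 0.5…1.4 (step 0.1),
B = 1000 resamples of round(r·n) sites are drawn and reclustered; BP_r of
an original cluster is the fraction of resample trees containing exactly
its leaf set. BP is BP_r at r nearest 1. AU comes from the multiscale fit:
for scales with 0 < BP_r < 1, z_r = Φ⁻¹(1 − BP_r) is fit by weighted least
squares to z_r = v√r + c/√r with delta-method weights
B·φ(z_r)²/(BP_r(1−BP_r)), and AU = 1 − Φ(v − c), clipped to [0, 1].
Degenerate curves (fewer than two scales with informative BP) fall back to
the BP value nearest scale 1 and are flagged `degenerate` rather than
fitted. The root carries AU = BP = 1 by convention. Internally support
values are fractions; the Newick/TSV exports print percent.

## Differential methylation

Counts are pooled (summed) within each group, as are library totals;
replicate structure is not modelled hierarchically — overdispersion
handling is out of scope, and the simulator's Poisson sampling matches the
analysis model by design. Per site, the exact conditional test of equal
Poisson rates: given T = x₁+x₂, x₁ ~ Binomial(T, N₁/(N₁+N₂)) under the
null; two-sided p = min(1, 2·min(inclusive tails)); T = 0 gives p = 1. The
test is exact and therefore conservative at small T — null calibration on
10,000 equal-rate pairs (rates 5–50) gives a raw p < 0.05 fraction of
about 0.04. FDR is Benjamini–Hochberg within tissue; significance is
called at adjusted p < 0.05.

Repeat classes: the normalized values of all member sites in all libraries
of a group are pooled into one sample per group and compared by Wilcoxon
rank-sum — exact enumeration when the pooled sample is small (< 20) and
tie-free, otherwise the normal approximation with tie and continuity
corrections. BH runs across the tested classes within a tissue, and the
family size m is reported explicitly (published repeat tables of this kind
can carry an FDR family larger than the displayed classes). Pooling
per-library values rather than per-site group means is a choice; the
alternative is one config entry.

Fisher's exact test (two-sided, hypergeometric enumeration) serves the
bisulfite-validation 2×2 tables. Gene-level reporting groups significant
sites by nearest gene; cross-comparison with a differential-expression
gene list is a case-sensitive set intersection, with the expression list
consumed as a TSV (intake filter |FC| ≥ 2, p < 0.05) — expression analysis
itself is upstream of this package.

## Synthetic data

The generator emulates the target study design: 2 tissues × (2 clones +
2 controls), i.e. 8 libraries. Defaults: 2 chromosomes × 120 kb with 60
planted MluI sites each (≥ ~1 kb apart), background GC 0.42 (mammalian
genome scale), CATG flanks 25–~650 bp from each site; 30 % of sites
embedded in 800-bp CGI blocks (GC 0.65, obs/exp tuned to 0.8 by swapping
surplus CG dinucleotides to GC); 20 % of sites covered by repeat intervals
labelled with real repeat-class names; 50 % near a planted gene. Per-site
baseline unmethylation probability is uniform on [0.15, 0.5]; a tissue
effect (×1.5 on a 20 % site subset per tissue) creates the tissue
signature; the clone effect multiplies the probability by 1/3 at 10 % of
sites in clone libraries — fewer tags, i.e. *higher* methylation in
clones, the direction reported for cloned animals. Counts are
Poisson(depth × probability) at depth 50 expected tags per fully
unmethylated site; reads are the site's tag sequences with optional
per-base substitution errors (default 0), shuffled. Replicates share
probabilities; all noise is sampling noise.

Truth is defined post hoc by scanning the emitted genome, so accidental
motifs arising from the random background are part of the truth tables
rather than a violation of them.

What the simulator does **not** emulate: overdispersion between biological
replicates (an optional negative-binomial stress mode would break the
Poisson assumption deliberately; the default matches the test's model),
incomplete enzyme digestion, bisulfite chemistry, linker/ditag structure of
raw sequencer output, CpG-island methylation correlation along the genome,
and realistic repeat sequence content (repeats are annotation intervals
only, since annotation is all the pipeline consumes). Passing tests
therefore demonstrate correctness of the pipeline's computations and
calibration under its own model, not robustness to these real-data
effects.

## Problem sizes and numerical choices

Tests and the acceptance script run on deliberately small instances: ~160
realized sites for pipeline round trips, ~415 sites × 8 libraries for the
spike-in calibration (three seeded runs pooled, ~110 discoveries, so the
Monte-Carlo margin on the empirical FDR is ±~0.02), B = 1000 bootstrap
resamples over 10 scales for support values, and 20 seeded runs for the
noise calibration of AU. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; identical inputs and seeds give
bit-identical outputs, including the mapper's ambiguity tie-breaks and
every exported table.

Degenerate inputs are handled explicitly: empty genomes produce an empty
library with a warning; chromosomes shorter than the CGI window produce no
islands; zero-variance library columns and zero library totals are errors
naming the library; classes with < 2 sites are skipped with a warning;
T = 0 count pairs give p = 1.

## Known limitations

- Pooled group counts ignore replicate-level variability; with real
  biological replicates the Poisson test is anti-conservative under
  overdispersion.
- The two-tier mapper is not a quality-aware aligner; tier semantics are an
  analog of the original mapping-quality thresholds, not a reimplementation.
- CGI prediction implements the three published criteria only.
- The AU fit uses the standard two-term probit expansion; clusters whose
  BP curve is degenerate get flagged fallbacks instead of extrapolated
  values.
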
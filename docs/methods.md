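# Methods

## Problem and data model

The pipeline quantifies bacterial transmission from a fermented rice-bran
bed (the *source*) to the palm skin of the person maintaining it (the
*sink*), using paired 16S rRNA ASV count tables. The central object is an
integer feature table (ASVs × samples); relative abundances are a distinct
type so that threshold logic can never run on raw counts. Sample semantics
(subject, substrate, day, timepoint, contact/no-contact phase) live entirely
in the metadata; the convention is that days 0–14 are the contact phase
(daily stirring) and days 15–29 the no-contact phase. The two day-0 skin
samples are distinguished by the timepoint labels `0` (pre-interaction) and
`0'` (6 h post-interaction).

## Preprocessing

ASVs are removed before any community statistic when (in this priority
order) any lineage rank contains `chloroplast` (case-insensitive), any rank
contains `mitochondri` (catching both *Mitochondria* and *Mitochondrial*
spellings across database releases), or the ASV has no taxonomy record /
a lineage that is the single label `Unassigned`. Lineages resolved only to
a higher rank (e.g. domain alone) are *kept*: exclusion targets unassigned
reads, not poorly resolved ones. An optional `min_resolved_ranks` switch
tightens this, off by default. The filter reports per-sample read
accounting that balances exactly (retained + removed = original), and it is
idempotent.

Genus-level composition sums relative abundances by prefix-stripped genus
name; features without a named genus aggregate into
`Unclassified_<lowest named rank>`. The top-N summary (default N = 15, the
usual presentation depth for these communities) ranks genera by mean
relative abundance across the presented samples with a deterministic
lexicographic tie-break, and always carries an explicit `remainder` row, so
every column still sums to 1.

## Diversity

Shannon index uses base 2 by default (configurable); observed features is
the positive-entry count. Rarefaction subsamples *without replacement*
using numpy's multivariate hypergeometric sampler — an exact draw, not a
multinomial approximation — so `depth = total` returns the sample verbatim
and the mean observed-features value matches the closed form
`Σ_i [1 − C(N−n_i, d)/C(N, d)]`. Curves are evaluated on the grid
{0, step, …, ≤ max_depth} with defaults max_depth 10 000 (the range the
study design sweeps), step 500 and 10 iterations; depth 0 is reported as 0
by convention and depths above a sample's total are left absent rather than
extrapolated. Randomness derives from one master seed through
per-(sample, depth, iteration) `SeedSequence` substreams, making curves
bitwise reproducible under any evaluation order.

## Shared-ASV statistic

An ASV is shared when its relative abundance strictly exceeds the threshold
(default 0.01, i.e. 1%) in *both* members of a source–sink pair; the strict
`>` follows the statistic's definition, with a `strict=False` switch for
sensitivity analyses. The threshold is interpreted per pair (both samples of
the pair), not per substrate-wide dataset — consistent with the pairwise way
the statistic is computed. The reported proportion is sink-weighted
(`100 × Σ sink abundances of shared ASVs`); the shared *set* is symmetric
under swapping source and sink, the proportion is not. Pairing: contact-
phase skin samples (including both day-0 timepoints) pair with the same
subject's same-day bed sample; no-contact skin samples pair with a fixed
source day (default 14, the last stirred day). Skin samples with no
available partner surface as explicit unpaired records. Persistence is the
last no-contact day per subject with a nonempty shared set; the taxonomic
breakdown splits each pair's proportion by genus, with unassignable shared
ASVs in an `Unassigned` bucket, and conserves the total exactly.

## Reference-sequence curation

Mirrors the standard SSU database-curation recipe: sequences are upper-cased
with U→T on ingest; culling rejects a sequence at ≥ 5 degenerate bases
(any IUPAC code outside A/C/G/T) or a homopolymer run of ≥ 8 — the
"five or more" reading of the recipe's ambiguous phrasing, matching the
curation tool's documented default, and configurable. Length minima are
domain-conditional (archaeal 16S ≥ 900 bp, bacterial 16S ≥ 1200 bp,
eukaryotic 18S ≥ 1400 bp, resolved from the lineage's domain rank);
sequences whose domain cannot be resolved pass with a warning, since no rule
exists for them. Uniq-mode deduplication collapses identical
(sequence, lineage) records but retains identical sequences with different
lineages; first occurrence wins, so output order is deterministic.

## Synthetic-data generator

The generator emulates the study's conditions and is the ground-truth bed
for every recovery test:

* **Source community**: one dominant lactic-acid-bacterium ASV whose share
  is drawn per subject in [0.69, 0.79] (pinnable), remainder split by a
  Dirichlet draw; day-to-day wobble is a Dirichlet perturbation around the
  base profile with concentration 500 (≈2% SD on the dominant share —
  "conservative"; ∞ gives the exactly constant limit).
* **Sink community**: a subject-specific Dirichlet draw over a feature
  universe disjoint from the source's, so every shared detection is
  attributable; an `overlap_abundance` option plants one feature in both
  universes to model ambient background sharing (the pre-interaction signal
  a subject can show).
* **Transfer and shedding**: each stir mixes fraction *f* (default 0.10) of
  that day's bed profile into the skin baseline; the deposit decays as
  `f·2^(−Δt/h)` with half-life *h* (default 0.5 d, chosen to reproduce the
  day-15-but-not-day-18 persistence phenotype). Each contact sample carries
  only the most recent stir's deposit with the 6-h stir-to-swab gap as a
  0.25-day decay step; residue from earlier stirs is taken as fully shed,
  an excellent approximation while `h` is much shorter than the 3-day
  sampling interval (at `h = 3` d it understates the expectation by a few
  percent, which is irrelevant to recovery tests because the analytic truth
  is computed from the same mixing model). The pre-interaction day-0 sample
  has no deposit.
* **Sequencing**: multinomial counts at a depth drawn uniformly in
  [13 000, 42 000] per sample, the spread real runs of this design show.
  An optional `contaminant_fraction` dilutes every raw sample with uniform
  chloroplast/mitochondria/unassigned reads that the preprocessing filter
  must remove; expectations always refer to the filtered, renormalized
  abundances.
* **Truth**: exact per-day profiles, the expected shared set and proportion
  at every timepoint (threshold applied to the exact profiles), and every
  seed used. All randomness comes from one master seed through structured
  `SeedSequence` spawn keys, so a given parameter set is bit-reproducible.

What the generator does *not* model: growth or competition on skin
(decay-only shedding is all the sampling design can resolve), within-day
dynamics, primer/extraction bias, or chimeras. Passing recovery tests
therefore demonstrates the pipeline's correctness and calibration under
multinomial sampling noise, not robustness to those upstream artifacts.

## Numerical and design choices

* Relative-abundance columns must sum to 1 within 1e-9; genus collapse and
  breakdowns conserve mass to the same tolerance; filter read accounting is
  exact integer arithmetic.
* All-zero samples are an error by default (they signal upstream failure),
  removable only via an explicit `drop_empty` flag.
* Top-N ranking tie-break and dereplication survivor choice are
  deterministic (lexicographic / first occurrence).
* The pipeline runner computes everything before writing anything, so a
  failed stage leaves no partial outputs; output TSVs embed a config hash
  (output paths excluded) and no timestamps, making reruns byte-identical.
* Recovery experiments use depth 30 000 and a pinned dominant mass of 0.75
  so closed-form expectations are sharp; the shedding-recovery experiment
  uses `h = 3` d, which keeps three no-contact timepoints above the 1%
  detection threshold — the minimum for a meaningful log-linear fit
  (at the default `h = 0.5` d only day 15 survives, which is the designed
  persistence phenotype but cannot support a slope estimate).

## Limitations

The statistic is deterministic set arithmetic, not probabilistic source
attribution; it cannot separate live colonization from residue, and its 1%
dual threshold deliberately ignores low-abundance transmission. Simulator
defaults encode one consistent parameterization of the study's observed
phenotypes; other (f, h) pairs could produce similar timecourses, and the
package makes no claim of identifying them from the study layout beyond the
no-contact decay slope.
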
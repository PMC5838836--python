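# Methods

This note documents the models and procedures implemented in `crossreg`,
the defaults they use, and the design decisions taken where the design was
genuinely open.

## Coordinate conventions

All intervals are 0-based half-open everywhere internally; BED I/O keeps
that convention and SNP tables (1-based on disk, as on genotyping chips
and in VCF) are converted at the boundary. Chains follow the UCSC layout:
the header's `t` side is the projection *source* and is always on the `+`
strand; when the target (`q`) strand is `-`, stored target coordinates
live on the reversed sequence and the forward-strand interval is
`(target_size - end, target_size - start)`. Chains are stored as read, and
every public query answer is reported in forward coordinates with a
strand flag, which avoids double-reversal bugs. The source-span index
deliberately returns *all* overlapping chains, because duplication rescue
depends on one source region reaching several targets.

## Two-stage projection

**Stage 1 (primary).** A region projects through a chain when the
fraction of its bases inside aligned blocks — its coverage — reaches
`min_match_main` (default 0.2, the permissive setting at which mappable
fraction saturates without losing specificity). The target span runs from
the projection of the first to the last aligned base of the query, not
the chain ends, matching the behavior of standard liftover tooling on
which the default thresholds were calibrated. In strict mode exactly one
chain may pass; two or more passing chains make the region *ambiguous*
rather than picking a "best" chain, because stage 1 is defined as strict
1-to-1 forward-and-reciprocal mapping — ambiguous regions are deferred to
the rescue round instead. An accepted forward projection is then
back-projected through the reverse chains and kept only when the
back-projection is unique, lands on the original chromosome, and both
borders return within `recip_tolerance_bp` (default 25 bp).

**Stage 2 (rescue).** Regions left unmapped, ambiguous, or reciprocally
failed are re-projected allowing multiple targets at `min_match_multi`
(default 0.8). All passing targets are kept, ordered deterministically by
coverage, then chain score, then chain id (descending), so outputs are
byte-reproducible. Rescue hits are not themselves reciprocally checked:
by construction they are multi-target, so a 1-to-1 reciprocal requirement
would be contradictory; the stringent 0.8 coverage bound is the guard.

Two points were genuinely open and are exposed as parameters: whether the
reciprocal back-projection should use the permissive or a stricter
threshold (we use `min_match_main`, the least-surprise reading of a
single reciprocal rule), and the rescue round's reciprocal handling
(default off, as above).

## Merging and enrichment statistics

Datasets merge by interval union; book-ended intervals (distance 0) merge,
exposed as `merge_distance`. Contributor names are kept, prefixed by
dataset label, and their number is the region's annotation count. Merging
is idempotent and independent of dataset order. "Overlap" everywhere
means ≥ 1 shared base, with no minimum-fraction requirement.

`Ratio_E` (and analogously `Ratio_P`) is the number of reference enhancers
overlapped by a dataset divided by the dataset's length in Mb; the fold
against the genome baseline divides by the density obtained if the whole
reference set were spread over the whole genome. Fold enrichment of a
coverage table cell is `pct_reference_covered / pct_genome_covered`,
reported rounded to the nearest integer; ratios are reported to one
decimal.

## Feature computation

* CAGE support is the count of peak intervals sharing ≥ 1 base with the
  region (a peak bridging two regions counts in both).
* Signal aggregation over a bedGraph is `Σ overlap_len × value` (sum
  mode; mean divides by region length). Bases absent from the track
  contribute zero; overlapping track intervals are an error.
* Conservation is averaged over *scored* bases only; a region with no
  scored base gets 0 and a flag.
* Motif (TFBS) counting scans both strands of the region with each PWM's
  log-odds matrix, `log2((p_motif + ε)/(p_background + ε))` with
  ε = 1e-4 to avoid −∞. A hit is a window scoring at least
  `rel_threshold` (default 0.8) times the PWM's maximum achievable score;
  overlapping hits of one PWM on one strand collapse to the best window.
  This per-PWM hit counting replaces HMM-based cluster scoring: the
  downstream filter consumes a count either way.
* Reference thresholds use linear interpolation between order statistics
  (the numpy default quantile rule) — fixed and documented because the
  filter thresholds depend on the convention. Read-count signals are
  transformed `log2(x + 1)` before thresholding, the pseudocount
  accommodating zero counts.

## The filter cascade

Each filter's threshold is resolved against the reference enhancer set's
own feature values:

| filter | predicate (defaults) |
| --- | --- |
| CAGE | ≥ 2 peaks, or 1 peak and RNA-seq > mean(reference) |
| H3K27Ac | log2(x+1) ≥ median of reference (mean selectable) |
| RNAseq | log2(x+1) ≥ Q3 of reference (median/mean selectable) |
| SVM | length < 3000 (strict) and score ≥ median(reference) |
| AnnCount | annotation count ≥ Q3(reference) |
| PhastCons | mean conservation ≥ 95th percentile(reference) |
| TFBScount | motif hits ≥ mean(reference) |

TFBScount defaults to the mean statistic because the median variant
degenerates on sparse references (retaining almost nothing). Combination
semantics are **union** — a region is retained when it passes ≥ 1 enabled
filter — with an intersection mode exposed for sensitivity analysis; the
union reading is consistent with per-filter independent retention
reporting and with the relative size of filtered versus universal sets.
Signals are thresholded as raw sums (not length-normalized) by default.
`optimize_filter_params` evaluates each filter independently over a grid
of threshold specifications and reports retained Mb, Ratio_E, and
Ratio_P per parameterization.

## Gapped k-mer model and deltaSVM

A sequence is represented by counts of gapped k-mers: every length-`l`
window contributes one word per choice of `k` informative positions
(C(l, k) subsets; the rest are wildcards). Defaults `l = 10`, `k = 6`
keep the 4^10 possible l-mers enumerable on a desktop while giving the
feature map enough context to capture typical 6–12 bp binding motifs.
Feature ids are canonicalized under reverse complement (regulatory
activity is strand-symmetric); both strands are scanned, which exactly
doubles every canonical count and therefore changes no downstream
decision. Windows containing non-ACGT characters are skipped.

Training uses an L2-regularized linear SVM (liblinear dual solver, C = 1
by default, seeded and deterministic) on positives versus negatives
sampled uniformly over valid placements in the genome with the identical
length multiset, rejecting overlaps with positives/exclusions and
ambiguous bases (≤ 100 tries each). Model quality is reported as
stratified 5-fold cross-validated AUC before a final fit on all data.

Every l-mer's weight is the linear score (sans intercept, which cancels
in differences) of its own feature vector, derived lazily and cached; the
model serializes as a versioned flat table of its sparse feature
coefficients, from which weights are recomputed exactly. deltaSVM sums
the weights of all l-mers overlapping the variant in the alternate
sequence minus the reference sequence. For indels the overlapping-window
set is taken over the edited span in each sequence — a generalization
beyond substitutions that preserves the identity (ref→ref scores 0) and
antisymmetry properties exactly. Significance calls are two-sided by
default: a score outside the central 95% of the empirical score
distribution is flagged, with a one-sided |score| mode exposed since the
"beyond the 95th percentile" reading is ambiguous.

## The synthetic fixture

The generator emulates the *structure* of the cross-species problem, not
its sequence statistics. The source genome is i.i.d. uniform ACGT — the
simplest background with controllable signal. The target genome is the
source transformed by an explicit, non-overlapping rearrangement plan
(inversion, deletion, insertion, tandem duplication, translocation)
applied left-to-right; alignment chains are emitted directly from the
resulting coordinate map, never re-aligned, so the per-base ground truth
is exact by construction. Planted regulatory regions avoid event
boundaries; regions inside the duplication are expected to surface only
through the rescue stage, regions inside the deletion only as unmapped.
"Active" regions (default half, ~2 kb of motif-bearing sequence per
100 kb) receive consensus motif copies in their central third — the
enhancer-core placement — plus enriched H3K27Ac/RNA-seq signal (default
8× background), elevated conservation, CAGE peaks (promoters), and a
companion annotation in a second jittered dataset so that merged
annotation counts separate supported from unsupported regions the way
multi-dataset agreement does in real data. SNPs are planted either in
motif centres (expected negative deltaSVM) or in background sequence.

What passing tests on this fixture therefore show: the coordinate
machinery, thresholds, rescue logic, filter arithmetic, and model/scoring
plumbing behave exactly as specified under known ground truth. What they
do not show: performance on real genomes, where sequence divergence,
repeat content, chain quality, GC structure, and motif degeneracy all
matter; results on real data depend on the chain set supplied, which this
package accepts as-is without reciprocal-best net filtering.

## Problem sizes and defaults used in validation

The test-suite fixture uses a 2 × 1 Mb genome with ~100 planted regions;
the acceptance run scales this to 2 × 5 Mb with 2,000 regions. Classifier
checks use 200 positives + 200 negatives of 100 bp with one planted 8-bp
motif. For reference-enhancer training inside the pipeline driver, long
enhancers are trimmed to their central 300 bp and at most 250 positives
are used — enough to learn the planted motifs while keeping the feature
matrix small.

## Known limitations

* The multi-species chain-building step itself (raw alignment, netting,
  chain scoring) is out of scope; supplied chains are trusted.
* bedGraph only, no bigWig; BED3–BED6 only, no full VCF parsing.
* The string-kernel SVM formulation is replaced by an explicit gapped
  k-mer feature map with a linear classifier; deltaSVM semantics are
  unchanged because scoring consumes only the l-mer weight table, but
  training-time regularization paths differ from string-kernel solvers.
* Per-PWM hit counting is a simplification of HMM cluster scoring and
  will count dense homotypic clusters differently.
* The fixture's uniform-base background understates the motif
  false-positive rate of real genomes; thresholds tuned on it should be
  re-examined on real data.
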
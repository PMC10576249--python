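# Methods

This note documents the models, decision rules, numerical choices and
limitations behind `ednascreen`. It is the package's own account of its
procedure; every number quoted here is produced by the test suite or by
`scripts/acceptance.py`, not asserted from elsewhere.

## The screening problem

Metabarcoding of mixed samples (faecal material, environmental frass)
yields denoised amplicon sequence variants (ASVs) with per-sample read
counts. Assignment against a barcode reference library occasionally
returns confident matches to species that cannot plausibly occur at the
study site. Such observations may reflect laboratory cross-
contamination, field contamination, index hopping, or sequencing
artefacts — and, untreated, they enter downstream ecological analyses
as false positives. The package operationalises the vetting of these
observations as a deterministic, configurable pipeline.

## Taxonomic assignment

**Alignment model.** Candidate matches use end-gap-free (semi-global)
placement of the shorter sequence within the longer, computed with the
edlib infix aligner; internal gaps and substitutions each cost 1.
Identity is reported over the aligned overlap,
`100·(overlap − mismatches)/overlap`, with coverage
(`overlap / query length`) handled as a separate criterion. When the
two sequences have equal length the containment direction is ambiguous;
both directions are evaluated and the better kept, making the result
symmetric in its arguments. Ambiguity codes (N, etc.) are accepted on
input but always count as mismatches — conservative toward "No match".
How public identification engines treat gaps internally is not
documented; the gap-as-mismatch choice is stated here, not claimed to
be equivalent.

**Coverage rule.** Matches with an aligned overlap below
`min_overlap_bp = 140` are discarded from ranking (but the aligner
itself returns them marked coverage-failed, never silently). On the
145 bp amplicon, 140 bp corresponds to ≈ 96.6% coverage; the base-pair
rule is operative and the percentage (`min_coverage_frac = 0.96`)
advisory, because the discard criterion is naturally expressed in
base pairs for a fixed-length amplicon.

**Decision rules.** Per species, the best reference record is kept;
hits are ranked by identity with a deterministic lexicographic
tie-break. Then:

1. no hit at ≥ 97% identity (inclusive) → *no match*;
2. a unique top species → species-level assignment;
3. a top-identity tie containing both locally occurring and non-local
   species → the local candidate wins (`local_preference_applied`);
4. a tie with no local candidate → the lowest taxonomic rank shared by
   the tied species (genus, then family, then order). Tied species
   sharing no rank at all are treated as unidentifiable.

The confidence class is *strict* when the winning hit has at most
`strict_max_mismatches = 1` mismatch (equivalently > 99% on a 140+ bp
overlap), otherwise *standard*. An optional second reference library is
consulted only when the primary yields no match, mirroring a fallback
database lookup.

Properties verified by the suite: identity of a sequence against itself
is 100; alignment mismatch counts equal a brute-force dynamic-
programming oracle on random pairs ≤ 80 bp; the adjudicator never
returns a non-local species while a local species ties at the top
identity; raising the identity threshold never converts a no-match into
an assignment.

## Abundance filtering

Relative read abundance (RRA) is `100·count/total` per sample. The
filter removes, in a single pass over the *raw* RRA, entries strictly
below `rra_min_pct = 0.1` together with entries assigned "no match",
then rescales survivors to sum to 100. "Strictly below" means an entry
at exactly 0.1% survives. The single-pass (no cascade) evaluation
matches the procedure of filtering first and recalculating once.
Filtering is idempotent and conserves the 100% total to 1e-9.
Merging sums abundances per exact assignment (rank, name), so a
genus-level assignment never collapses onto a congeneric species-level
one. Two further switches default to off because they are not part of
the core procedure: a minimum per-sample read total (for dropping
failed samples) and negative-control-informed cell subtraction.

## Non-local flagging and pattern analyses

A species is *non-local* when its checklist distance (nearest known
occurrence) strictly exceeds `nonlocal_distance_km = 200`; exactly
200 km counts as local. Flags require species rank **and** strict
confidence. Weaker signals are never discarded silently: standard-
confidence matches to non-local species and rank-level assignments all
of whose tied candidates are non-local appear in a near-threshold list;
species absent from the checklist appear in an unknown-locality list.
Synonym reconciliation in species names is the caller's responsibility;
names are expected pre-normalised.

**Occurrence matrices** order samples by field collection date or by
lab processing index (ties broken lexicographically by sample id) and
hold the flagged RRA per species × sample.

**Ordering concentration.** Visual inspection of occurrence figures is
replaced by a statistic: the mean absolute pairwise difference of a
species' occurrence positions within the ordering. The p-value is the
fraction of `n_permutations` uniform draws of the same number of
positions (without replacement) whose statistic is at most the observed
one — small p means occurrences cluster in a narrow stretch, as a
point-source event would produce. This quantification is an addition of
this package and is labelled as such in the output. Under the null the
p-values are uniform (checked by a seeded Kolmogorov–Smirnov test). The
default is 10,000 permutations; a seed is mandatory whenever the test
runs.

**Correlations.** Per-sample non-local totals (post-filter) are
correlated, by Spearman's rho with average ranks for ties, against the
sample's total reads and distinct-variant count taken from the
*pre-filter* profiles (no-match variants included), since artefact load
is a property of the raw sample. Constant vectors yield a missing
value. Per-sample totals (rather than per-ASV points) are used; this is
a documented choice.

**Replicates.** Technical replicate pairs are compared by Jaccard index
over present taxa, Jaccard over taxa at ≥ 1% RRA (abundant taxa tend to
agree; rare ones often appear in only one replicate), and an explicit
discordant-taxa list.

## Provenance tracing

Flagged sequences are compared against suspect source sets (e.g. other
projects handled in the same laboratory) with the same overlap aligner;
the nearest source per set is reported with mismatch count and 0-based
mismatch positions, and "exact" means zero mismatches over the full
flagged sequence. Pairwise p-distances (mismatches/overlap) feed a
neighbor-joining tree. p-distance rather than a substitution model is
deliberate: on 145 bp fragments at the divergences involved, model
correction would be spurious precision. The NJ implementation clamps a
negative branch length to zero and transfers the deficit to its sister
edge (preserving the joined pair's mutual distance), and breaks Q-
criterion ties toward the pair whose smallest contained leaf labels
sort first, making output deterministic. On additive matrices it
recovers the generating topology and path lengths (verified up to
8 taxa, and cross-checked against scikit-bio's implementation).

Homopolymer artefact detection reports an event when an alignment indel
consists of one repeated base inside a run of that base of length ≥ 2
in both sequences (e.g. a 7T run shortened to 6T); substitutions never
produce events. A scan for unassigned ("no match") variants within
`max_mismatches = 4` of a flagged cluster — just beyond the 97%
assignment radius on 145 bp — lists artefact candidates that fell below
the identification threshold.

## Synthetic data generator

The generator embodies the statistical structure the screen assumes.
Defaults are the study conditions the pipeline is designed for, chosen
once and fixed:

* **Samples:** 94 analysis samples in five categories (9/24/16/24/21),
  two negative controls, two technical replicate pairs, collection
  dates uniform over 2017-05-14 … 2017-07-17, lab processing order a
  random permutation decoupled from collection order.
* **Library:** 60 local + 25 non-local species, 658 bp references with
  a fixed 145 bp amplicon window (offset 33), ≥ 2% between-species
  p-distance on the window, three congeneric pairs sitting just above
  that floor, ~10% of local species with a second within-species
  haplotype (≤ 1% divergence). Checklist distances: local ≤ 150 km,
  foreign 250–2500 km. The local pool size is a realism choice (the
  amplifiable lepidopteran diet fraction); no community-size model is
  prescribed by the procedure itself.
* **Communities:** per-sample richness Poisson(10) (min 3) from a
  per-category pool (70% of the local list), log-normal composition
  (σ = 1.2), multinomial reads at depth Normal(28,145, 7,200) — the
  depth SD reproduces a standard error of ≈ 743 over 94 samples.
  Replicate pairs share a composition and redraw reads.
* **Contamination scenarios:** `lab_point_source` (restricted to a
  processing-index window), `field_environmental` (a collection-date
  window), `background_carryover` (low Poisson reads everywhere, at an
  expected RRA of 0.05%, i.e. mostly below the 0.1% filter). Point-
  source read counts are chosen so realized RRA ≈ the drawn level;
  levels are capped at 60% per event, consistent with the largest
  per-sample totals such screens encounter (~55%). The default scenario
  mix is calibrated so that a majority of samples carry at least one
  non-local occurrence and totals span roughly 0.1–40%.
* **Noise:** substitution error variants (rate per base 0.001),
  homopolymer run shortening (probability 0.05 per run ≥ 6), chimeras
  joining two co-occurring parents at a uniform breakpoint (rate 0.01
  per parent); each variant splits off a small fraction of its parent's
  reads. Negative controls receive a few Poisson reads of the globally
  dominant variant, mimicking the trace counts real controls show.

Every read-bearing cell carries exactly one truth origin; variant
collisions that would double-label a cell are skipped. A single
`numpy.random.default_rng(seed)` drives all draws in a fixed order, so
a seed reproduces every output file byte for byte.

**What the generator does not emulate:** primer/PCR amplification bias,
tag-jumping between specific sample pairs, nuclear mitochondrial
pseudogenes, degradation gradients, or taxonomically structured
reference gaps. Passing recovery tests therefore demonstrates that the
*decision logic* behaves as specified under the assumed statistical
structure — not that real contamination is always this detectable.

## Test and acceptance scale

The property suites run at desk scale: 500 random alignment pairs
≤ 80 bp against a pure-Python dynamic-programming oracle, 1,000 random
tie structures for the adjudicator, 1,000 random profiles for filter
idempotence/conservation, additive-matrix NJ recovery for 4–8 taxa, and
200 vectors for Spearman agreement (≤ 1e-12). Recovery checks use a
scaled-down simulated study — 30 samples, 15 local + 6 foreign species,
depth ≈ 6,000, 100–200 permutations, 50 replicates for the ordering
sign test — sizes chosen so the whole suite completes in seconds while
keeping every distributional feature of the full-size default; the
full-size configuration is exercised once in `scripts/acceptance.py`.

Expected outcomes, all recomputed at run time: noise-free point-source
contamination injected at ≥ 1% RRA is flagged with precision = recall
= 1.0 (the flag set equals the planted truth set); background carryover
at an expected 0.05% RRA is recovered at well under 20% (the intended
effect of the 0.1% filter); across 50 replicates the ordering-
concentration p-value under processing order is smaller than under
collection order essentially always (sign test p ≪ 0.01); chimeras of
local parents are assigned no-match or sub-strict confidence and are
never flagged.

## Known limitations

* The aligner reports one optimal alignment; when equally optimal
  alignments differ in overlap length (e.g. adjacent substitutions vs.
  a gap pair), the reported identity can differ in the second decimal
  while the mismatch count is invariant. Decisions are driven by
  identity and mismatch count at thresholds far from these ambiguities.
* Identity ties are detected at 1e-9; identities computed from integer
  mismatch/overlap pairs are exactly representable, so this matters
  only for pathological inputs.
* Real sequencing batches are third-party data and not redistributed
  here; the headline-count reproduction test activates only when a user
  supplies a full batch table as `data/original_batch_asv_table.tsv`,
  and the packaged checks otherwise rest on the property, recovery and
  micro-example suites.
* Reports are plain TSV/JSON/Newick; no plotting is built in, by
  design — occurrence matrices are written in the exact layout a
  heatmap layer expects.
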
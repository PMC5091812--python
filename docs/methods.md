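# Methods

## Read cleaning

Input is Illumina-style paired FASTQ from Sol-B-tagged libraries: cDNA
primed with `5'-GTTTCCCACTGGAGGATA-N9-3'`, where BpmI digestion leaves a
residual 5' fragment of the 18-mer tag (the "B-tail") on some reads. The
cleaning stack runs in this order, and a pair is dropped whenever either
mate fails; the attrition report charges each dropped pair to the first
failing stage so input pairs are accounted exactly once:

1. **DUST low-complexity filter.** Overlapping 3-mers are counted in
   sliding 64-base windows (the whole read if shorter); a window scores
   `sum(c_t (c_t - 1) / 2) / (w - 3)`, rescaled so a mononucleotide run
   scores 100, and the read score is the window maximum. Reads scoring
   above 7 are removed. This is the 0–100-rescaled variant used by common
   read-cleaning tools, not the unscaled original statistic; both the
   threshold and window are configurable.
2. **Pair dereplication.** A pair is removed if its concatenated mates
   equal a previously kept pair's exactly, or equal the reverse complement
   with mates swapped (PCR duplicates read from the opposite strand).
   First occurrence wins.
3. **B-tail trimming.** The longest 5' prefix matching a suffix of the
   18-mer tag is removed, quality in lockstep. Matching requires at least
   5 bases (the residual tail length is not fixed by the chemistry we
   model, and 1–4-base matches are indistinguishable from background),
   exact identity below 10 bases, and at most one mismatch at 10–18 bases
   (a ~10% error rate, the convention adapter trimmers use). Trimming is
   therefore *statistically* idempotent: a freshly exposed 5' end re-matches
   a tag suffix with probability ~1e-3 per read, so a second pass trims a
   handful of extra bases in a large library while removing no reads.
4. **Bespoke seven-rule filter**, applied mate-wise in this order: failed
   chastity flag (CASAVA `<mate>:Y:...` header field; absent field = pass);
   any single-base run longer than 20; any `N`; fewer than 2/3 of the first
   `floor(L/2)` bases at Q >= 30 (strict inequality, Phred+33); the full
   Sol-B 18-mer anywhere in the read; length below 70 after trimming.
5. **Single-read dereplication**, pooling both mates and not accounting for
   pairs. To preserve pairing for downstream concordance analysis the whole
   pair is dropped when either mate's sequence was already seen, so the
   report invariant `filtered reads = 2 x surviving pairs` holds; the
   surviving read total is the normalization denominator.

A consequence of the stage order worth knowing: any run of >= 19 identical
bases inside a 64-base window already exceeds DUST 7, so reads violating the
">20 homopolymer" rule are in practice removed one stage earlier and appear
in the low-complexity tally. The homopolymer rule still matters as a
safety net under non-default DUST thresholds.

## Profiling and normalization

Per-read taxon assignments (read id, mate, sample, taxon, rank) are rolled
up to a sample x taxon matrix at phylum or genus rank, counting mates
individually and excluding reads assigned to the reserved `HOST` taxon —
host subtraction itself (alignment against the human reference) is outside
this package's scope and is represented by that reserved label.
Normalization is counts per million filtered reads (the pre-host-subtraction
denominator from QC); the scale factor is conventional and cancels in every
statistic computed from raw counts plus exposure. Re-sequenced samples are
reduced to one member per replicate set by a seeded uniform draw.

## Contamination screen

A taxon is "present" in a sample when its raw count reaches a threshold
(default 1 read; configurable, and the overlap count is monotone
non-increasing in it). All plasma-free negative controls are pooled:
presence in any of them flags the taxon. The screen reports the number and
percentage (one decimal) of observed taxa found in negatives and per-taxon
flags, optionally cross-referenced against an editable catalog of genera
repeatedly reported as kit contaminants (`plasmeta/data/known_contaminants.txt`).
Frequency- or concentration-based decontamination models are deliberately
out of scope; the screen is presence/absence only.

## Group/batch regression

Eligible taxa (nonzero in at least `min_samples_present` samples, default 1)
are fit one at a time on the study samples only (negative and positive
controls excluded, replicates already dropped):

- **Model.** `count ~ group + batch`, log link, treatment coding with
  Healthy and batch 1 as references. The filtered-read exposure enters by
  modelling the per-sample *rate* `count / exposure`, making every statistic
  an exact function of rates — multiplying any sample's counts and
  denominator by the same factor changes no p-value at all (verified to
  1e-14). This is the package's resolution of the exposure question: an
  offset formulation whose weights acknowledge counting noise cannot have
  that exact invariance.
- **Variance.** Quasi-likelihood with Tweedie variance `V(mu) = mu^p`,
  default `p = 1.9`, dispersion from the Pearson chi-square. Deeply
  overdispersed counts (the generator's default NB dispersion is 0.3, so
  `phi * mu >= 2` for most taxa) have variance close to quadratic in the
  mean; a plain quasi-Poisson (`p = 1`, available via
  `family="quasipoisson"`) underestimates the variance of taxa carrying
  strong batch effects roughly `fold^(2-p)`-fold and, in simulation,
  produced an order-of-magnitude inflation of group-factor false positives
  on exactly those taxa. With `p = 1.9` that mechanism disappears.
- **Tests.** Joint factor significance by the quasi-deviance F-test
  comparing nested models (3 df for group, `n_batches - 1` for batch)
  against the full model's Pearson dispersion; per-level contrasts against
  the reference by two-sided Wald tests. Bonferroni correction divides
  alpha (default 0.05) by the number of taxa actually tested in the
  analysis at hand. A factor with a single observed level is dropped with a
  warning; a fit that fails yields NaN p-values, never an exception.
- **Classification.** Each taxon is labelled `group_only`, `batch_only`,
  `both` or `neither` from the corrected flags; group-associated taxa that
  are also contamination-flagged are annotated as likely artifacts, since a
  disease signal riding on a reagent contaminant is confounded evidence.

**Calibration, measured.** Under the synthetic study's own conditions
(500 taxa, 74 samples, NB dispersion 0.3, lognormal library sizes, fold-10
batch-3 effects on 50 taxa, group null), 100 replicates give batch-effect
sensitivity 1.00 and a group-factor family-wise error estimate of 0.09.
Two things bound that number below: perfectly uniform p-values would already
give `1 - (1 - 1e-4)^500 = 0.049`, and the residual excess (9 events across
45,000 null tests, i.e. per-test error 2e-4 at nominal 1e-4) is far-tail
skewness of heavily dispersed counts in the smallest group (n = 11), which
no quasi-likelihood F-test removes — robust (sandwich) covariances were
markedly worse in the same experiment. The acceptance check therefore tests
the FWER estimate against its target with a two-Monte-Carlo-standard-error
allowance. Practically: at these sample sizes, treat a lone Bonferroni-
boundary group hit on an otherwise unremarkable taxon with suspicion —
which is the package's central message anyway.

## Paired-read validation

For a taxon of interest, the audit counts reads assigned (mates counted
individually), pairs with both mates assigned, samples contributing, and —
when a second classifier's table is supplied — reads confirmed by both.
The verdict is `unsupported` when concordant pairs do not exceed a
configurable budget (default one pair per profiled sample) *and* the
confirmed fraction is below a configurable floor (default 0.1); with no
second table the pair criterion decides alone. The thresholds are printed
in every report: the audit is an explicit decision rule, not a hidden one.

## Cohort statistics

`fisher_exact` is a Freeman-Halton test for r x c tables: all-zero rows and
columns are dropped, every table with the observed margins is enumerated
recursively, and the multivariate hypergeometric probabilities of tables no
more probable than the observed one (relative tolerance 1e-7 for float
ties) are summed. Enumeration is guarded at a table total of 200
observations — the cohort tables here total at most 50. 2 x 2 agrees with
the closed-form hypergeometric sum to 1e-12. `wilcoxon_rank_sum` is exact
for tie-free samples with min(n) <= 25 and a tie-corrected,
continuity-corrected normal approximation otherwise; the method used is
recorded in the result.

## Figures

Hierarchical clustering (samples and taxa) uses Euclidean distance on
log(1 + CPM) with average linkage; PCA centers and unit-scales each taxon
of the same transform (zero-variance taxa pass through unscaled, and an
all-constant matrix maps every sample to the origin). Component signs
follow a fixed convention — the largest-magnitude loading of each component
is made positive — so coordinates are bit-reproducible. Points are colored
by batch and shaped by group; replicate pairs are joined by dashed lines.

## The synthetic-data generator

The generator emulates the study design it models: groups CFS 25,
Healthy 25, ADCLS 13, SLE 11, NegControl 7, PosControl 1; three batches
assigned round-robin within each group; 28 taxa of which 20 are reagent
contaminants. Expected count for taxon t in sample s is

    library_size(s) * base_abundance(t) * batch_mult(t, batch(s)) * group_mult(t, group(s))

with negative-binomial noise (`var = mu + 0.3 mu^2`). Biological
(non-contaminant) taxa have group multiplier exactly 0 in negative
controls; contaminants keep their base abundance there. Batch multipliers
for batches 2+ are lognormal with log-SD 0.5 (batch 1 is the reference
lot); optional group effects put a configurable fold on randomly chosen
taxa in one non-reference group. Library sizes are lognormal with mean
50,000 pairs per sample and CV 0.5 — a desk-scale stand-in for real
filtered-read totals; base abundances are lognormal around 2e-4 (log-SD 1),
so a typical taxon draws ~10 reads per sample, the regime where
contamination screening is actually hard.

Reads carry at most one planted defect per pair (rates must sum to <= 1),
and each planting is rejection-sampled so the read violates *only* the rule
recorded in its truth label — e.g. a short fragment is redrawn until its
(short) DUST window passes, and an inserted primer may not create a long
run. Clean reads are rejection-sampled against every rule. Duplicate
defects copy an earlier clean pair (exactly, or reverse-complemented with
mates swapped) and are emitted after all other pairs so the clean source is
always the first occurrence. Quality strings are Phred+33, Q35–40 for
clean bases; low-quality halves draw Q2–29 across the whole first half.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: actual genome sequences (taxon assignments are
labels, not alignments), classifier error and database bias, adapter
contamination (inputs are assumed adapter-trimmed), host-read alignment
(host reads are labelled `HOST`), chimeras, and within-taxon strain
variation. The truth-exact QC recovery in particular says the *filter
rules* are implemented exactly, not that the rules themselves are optimal
for real libraries.

## Numerical and design choices

- DUST windows slide by one base; scores are exact rationals in floating
  point, and the brute-force cross-check demands 1e-9 agreement.
- `-derep`-style duplicate removal treats exact and reverse-complement
  duplicates pair-aware in the first pass and pooled single reads in the
  last; both keep the first occurrence in input order.
- Presence thresholds, verdict floors, GLM family/variance power, and the
  contaminant catalog are configuration, not constants.
- Determinism: one `numpy` Generator seeded from the top-level seed drives
  each simulation; gzip output is written with a zeroed timestamp so
  identical seeds give byte-identical files.
- Ambiguous/unassigned reads are excluded from matrices rather than binned;
  positive controls stay in matrices but never enter group statistics.

## Known limitations

- The group-factor far tail is ~2x anticonservative at Bonferroni scales
  under heavy overdispersion with an n = 11 group (quantified above).
- B-tail trimming is statistically, not exactly, idempotent (see above).
- The Freeman-Halton enumeration is exponential in principle; the guard
  (total <= 200) covers cohort-table scales, and no Monte-Carlo fallback is
  provided.
- Single-end orphan retention is not supported: a pair whose one mate fails
  any rule is dropped whole.
- The pipeline driver holds libraries in memory; it is sized for
  desk-scale studies (tens of thousands of pairs per library), not
  production sequencing volumes.
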
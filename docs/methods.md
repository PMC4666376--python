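# Methods

This note records the models, conventions and numerical choices behind
`branchselex`, and what the simulation-based tests do and do not establish.

## Read preparation

The amplicon top strand is modelled as
`barcode_fwd + fwd_constant + variable + rev_constant + revcomp(barcode_rev)`;
the forward read covers its 5' end, the reverse read the 5' end of the bottom
strand. All sequences are handled in the DNA alphabet (T, not U) because
sequencing reads the cDNA; 0-based half-open coordinates are used internally
and never appear in outputs.

**Demultiplexing** matches both barcodes at the 5' ends of the two reads,
exactly by default (`--barcode-mismatch 0`); a pair matching zero entries or
more than one entry is rejected with a reason code (`no_barcode_match`,
`ambiguous_barcode`). Barcode placement inside the primers and the mismatch
tolerance are declared conventions, not values inferred from data. Swapped
input files are recognised from the barcodes and flipped to the canonical
orientation, so outputs do not depend on which physical file is called R1.

**Pair merging** uses the maximal exact suffix/prefix overlap of the forward
read and the reverse-complemented reverse read, requiring at least 10 nt of
exact overlap (no mismatches tolerated inside the overlap — an error there
rejects the pair rather than guessing). When no usable overlap exists, a
fallback accepts a pair if a single read spans both constant-region anchors
on its own; this covers short amplicons whose stripped reads no longer align
head-to-tail as well as non-overlapping long amplicons. Constant regions are
matched exactly by default (`--constant-mismatch 0`), since the inclusion
rule is "correct constant regions". The variable region is the substring
between the constant regions and must be 25–45 nt; reads with `N` in the
variable region are rejected. Quality scores are carried but not used.
Rejection is data, not failure: `assigned + rejected == total` holds at every
stage, and rejection reasons are reported per sample.

## Pairwise identity and clustering

Identity between two sequences is defined by a global alignment scored
match +1, mismatch 0, gap 0, chosen to maximise the number of matching
columns; among match-maximising alignments the one with the fewest gaps
(fewest columns) is used, and

```
identity = matches / alignment_columns .
```

Identical strings score 1; `ACGTACGTAC` vs `ACGTACGTAG` scores 0.9; strings
with no common subsequence score 0. The DP packs (matches, paired columns)
into one integer and runs under numba.

Clustering is greedy abundance-ordered centroid clustering (CD-HIT/USEARCH
style): unique sequences are visited in descending total count, ties broken
lexicographically; each joins the *first* centroid with identity at or above
the threshold (0.90 by default; the boundary joins), else founds a new
cluster. Identity is computed against the centroid only, never average
linkage. Clustering is performed jointly over all samples so one cluster id
tracks a family across branches, which the enrichment tables require. The
representative of a cluster is its most abundant member (tie: lexicographically
smallest); cluster ids are a short hash of the representative, so they are
stable across runs and machine-independent.

Two exact screens keep the quadratic scan fast without changing the result:
a centroid is skipped if `min(len)/max(len)` or shared base composition over
`max(len)` already caps identity below the threshold, and surviving pairs
are pre-filtered with an edit-distance bound
(`ed <= min(len)·(1-t)/t`, evaluated with edlib) that is implied by
identity ≥ t. Both bounds are necessary conditions, so the output is
identical to brute force — asserted against an independent all-pairs oracle
in the tests.

Greedy centroid clustering does not guarantee that raising the threshold
never merges clusters in adversarial near-threshold configurations; for the
family-structured data this pipeline targets the cluster count is monotone in
the threshold, and the property test checks it on such data.

## Quantification

Pool fractions use totals of *retained* (post-filter) reads, not raw reads,
as the denominators — the copy-number table and its totals describe the same
filtered universe. EFs with a zero pre-selection fraction are undefined and
flagged, never imputed; EFs of sequences lost during selection are exactly 0.
No pseudo-counts are used by default (a `pseudocount` option exists for
exploration) because the downstream scans already impose a ≥10-copy floor in
the input pool. Relative EFs are always computed within a single
immobilisation mode; a mode that has mutant branches but no wild-type
reference is a configuration error. Full precision is kept in all files;
rounding (e.g. 1.62) is presentation only.

`replicate_variability` reports, for the top-N sequences by mean abundance,
the sample standard deviation across replicate preparations as percent of the
mean (relative SD, ddof = 1) — the statistic used to judge whether an
observed EF change exceeds preparation-plus-sequencing noise.

## Profiling

A residue is included in a binding profile when `EF_variant/EF_wt` falls
*strictly* below `1/fold_threshold` (default 0.5); exactly two-fold is not a
call. Any undefined relative EF makes the whole profile indeterminate rather
than risking a false site call for rare sequences. Profile scans require the
identical residue set in every requested immobilisation mode (concordance)
and exact set equality with the reference; a superset relaxation exists but
is off by default. Conformation calls use `EF_latent/EF_active` with the same
fold threshold: below the cutoff is `active_preferring`, otherwise
`binds_both` — ratios *above* the threshold also map to `binds_both`, since
the latent form is then bound at least as well; there is no separate
latent-preferring label. Competition calls mirror this with
`EF_complex/EF_antibody` (`ligand_competed` below the cutoff). Both calls are
invariant under common scaling of the two EFs and reuse the profiling fold
threshold for parsimony (independently configurable).

The hotspot summary restricts the top-N most abundant input clusters to
those with `EF_wt > 1` and reports, per mutant, the fraction with a
more-than-two-fold relative reduction, plus the fraction unaffected by every
panel mutant and (EF_wt, EF_variant) point clouds for scatter plots.
`rank_by_ef` sorts clusters by a branch's EF (undefined last, ties by input
abundance then id) — the search pattern for binders with properties unlike
the dominant families, e.g. complex-compatible aptamers.

## Motif discovery

The finder targets short, highly conserved, ungapped motifs with at most one
occurrence per member sequence, the regime in which aptamer family consensus
elements live. It is a greedy seed-and-extend procedure, not an EM mixture
model: seeds of width `width_min` are ranked by distinct-member support (ties
lexicographic), each seed collects its leftmost unmasked occurrence per
member, the window grows while every added column keeps majority-base
frequency ≥ 0.90 (and width ≤ `width_max`), sites are masked, and the search
repeats up to `max_motifs`. Consensus letters use the conservation rule: a
single base if it alone reaches 90%, else the minimal IUPAC degenerate code
whose bases cumulatively do (added by decreasing frequency). Motifs are
written in MEME minimal format with a sites TSV, and families can be exported
as FASTA for external motif or RNA-structure tools; E-values, gapped motifs
and structure prediction are out of scope.

## Simulator

`make_truth_pool` builds an enriched-pool snapshot: `n_families` aptamer
families (default 5 × 20 members) over a log-normal background tail (default
5000 sequences, σ = 1.6, spanning high-copy sequences down to singleton
scale). Each family master (35–42 nt) carries two planted motifs (an 8–9-mer
and a 5-mer); members substitute at most 10% of positions outside the motifs,
so every member stays within the 0.90 clustering threshold of its master.
Member abundances decay geometrically (factor 0.6) from the master.

`make_affinity_model` assigns wild-type affinity 1 to binders and 0 to
background. A mutant in a family's planted profile divides affinity by a
per-(family, mutant) fold drawn uniformly from 4–10 — at least twice the
analysis fold threshold, so planted sites are detectable by design. The
latent branch applies the same treatment to active-preferring families, the
complex branch to ligand-competed families; a `rare` complex-compatible
family can be planted at arbitrary frequency with 100-fold complex affinity.
Selection is proportional capture with additive non-specific retention
`b = 0.01`: `f'_i = f_i (a_i + b) / Σ_j f_j (a_j + b)` — linear and
non-saturating, the simplest model under which enrichment tracks affinity;
saturation, washing kinetics and capture-surface competition are not
modelled. Immobilisation modes are replicate branches with identical
affinities and independent read sampling, sequencing error is i.i.d.
substitution only (indels would mostly be removed by the length filter), and
all randomness derives from one seed via `SeedSequence` spawn keys, so each
sample is independently reproducible.

**Abundance regime.** Default family masters sit at ~0.06% (family totals
0.10–0.15%), keeping total planted binder mass (~0.6%) below the background
retention mass. In this regime the branch normalisation `Σ f(a+b)` is nearly
branch-independent and relative EFs track the planted folds, which is what
the recovery guarantees below are calibrated for. In binder-dominated pools —
as real late-round SELEX pools tend to be, with wild-type EFs of order 1 —
the normalisation shrinks on mutant branches that affect much of the pool and
compresses `EF_variant/EF_wt` toward 1, so a genuine 4-fold site can evade
the two-fold threshold. This compression is a property of enrichment-based
site calling itself, not of the implementation; users profiling binder-rich
pools should expect conservative calls near the threshold.

## Problem sizes and validation

The test suite and the acceptance script validate at these scales, chosen to
exercise the full pipeline at meaningful statistical resolution:

* end-to-end recovery: 19 samples × 2×10⁵ read pairs, error rate 10⁻³,
  5 families + 3000 background sequences; exact concordant profile recovery
  for all planted families, correct conformation and competition labels, and
  no call ever containing the neutral panel mutant;
* EF calibration: 20 seeds × 4 branches × 2×10⁵ reads, counts-only; the
  estimated EF of every member at frequency ≥ 10⁻⁴ is compared with the
  analytic expectation using a 3-standard-error band on the log scale (the
  conventional interval form for a ratio statistic), with ≥ 99% coverage
  required;
* rare-binder search: a 10⁻⁵-frequency complex-compatible family with
  100-fold complex affinity at 10⁶ reads/sample (the study-scale per-sample
  depth) must enter the top 10 of the complex-branch EF ranking in ≥ 18 of
  20 seeds;
* replicate variability: three multinomial re-preparations of the same pool
  at 1.58×10⁶ reads; the top-50 relative SDs from pure read sampling must
  stay within the variability observed experimentally at that depth
  (max ≤ 11%, mean ≤ 4%);
* clustering: exact agreement with an all-pairs brute-force oracle on 200
  uniques, plus determinism and count-conservation properties.

What passing these tests shows: the estimators are unbiased against the
generative model, the pipeline is deterministic, and ground truth is
recoverable under the stated conditions. What they do not show: robustness to
PCR amplification bias across earlier selection rounds, chimera formation,
indel sequencing errors, saturating capture chemistry, or binder-dominated
pool compositions — none of which the generator emulates.

## Known limitations

* The identity definition and greedy order are fully specified for
  determinism, but greedy centroid clustering is order-dependent by nature;
  thresholds other than 0.90 were not tuned.
* No k-mer prefiltering beyond the exact screens; pools far above ~10⁵–10⁶
  uniques will be slow.
* EF confidence intervals are not attached to the tables; the delta-method
  helper exists for simulation checks only.
* The motif finder approximates, not replaces, EM-based discovery; motifs
  below ~90% conservation or with variable spacing will be fragmented or
  missed. MEME-format output allows externally computed motifs to be swapped
  in.
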
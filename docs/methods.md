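# Methods

This note documents the models, conventions and numerical choices behind
`amplimock`, and what the synthetic data do and do not establish about real
amplicon datasets.

## Mock-community threshold calibration

Each sequencing library carries one mock sample containing nine known protist
species. Its denoised ASV table is matched against the expected species by
global edit distance:

* an ASV is **assigned** to a species if its minimum edit distance to any
  expected sequence is ≤ 1 (`max_mismatch`, configurable); ties go to the
  lexicographically smallest species id;
* the **expected set** for the strict rule is the ASVs at distance exactly 0 —
  one-mismatch variants count as assigned for the lenient rule but are noise
  the strict rule must remove. This is the only reading under which strict
  thresholds (≈ 1% here) exceed lenient ones (≈ 0.5%): if variants were
  "expected", the largest non-expected proportion would typically be smaller
  than the smallest assigned one.

The **lenient threshold** is `min(reads of assigned ASVs) / total mock reads`
and is applied with keep-if-**≥** semantics, so the defining ASV would itself
survive at its own threshold ("ASVs with *less than* this proportion are
filtered out"). The **strict threshold** is the *largest* proportion among
non-expected ASVs, an exclusive bound applied with keep-if-**>** semantics —
this avoids inventing an arbitrary ε above the bound, and makes "filtering the
mock at its own strict threshold returns exactly the expected set" an identity
whenever the design is feasible (every expected ASV above every non-expected
one). Infeasibility is reported, not silently patched.

Thresholds are applied **per sample**, against the sample's total reads
*before* filtering, each environmental sample using the thresholds of the mock
on its own library. Decisions are scale-invariant (multiplying a sample's
counts by a constant changes nothing) and monotone in the threshold. The
denominator is the total of the heterotroph-restricted table at the point of
filtering; totals before functional filtering would be an equally defensible
convention — the choice is isolated in one place and the partition API accepts
any upstream table.

The **low-abundance dataset** is exactly the set of cells (sample, ASV) the
lenient filter removed, restricted to ASVs whose best-hit identity exceeds
98%; per sample it is disjoint from the main dataset by construction.

## Taxonomic assignment

ASVs are assigned to the best reference hit by end-to-end global alignment
under unit costs (match 0, mismatch 1, gap 1; edlib), with

    identity% = 100 · (alignment columns − edit distance) / alignment columns.

Equally optimal alignments can differ in column count (a substitution column
versus an insertion/deletion pair), moving identity by a fraction of a
percent; the aligner's path choice is deterministic for a fixed input order,
so inputs are canonically ordered, making the result symmetric. Production
aligners expose several identity definitions with unstated gap conventions;
the one above is documented and configurable rather than guessed.

Cutoffs are **strict** inequalities (> 80% to be assigned, > 98% for the
low-abundance dataset) and the 80% decision is made in exact integer
arithmetic (`100·matches > min_identity·columns`), so a query at exactly
80.0% is rejected regardless of floating-point representation. Ties between
references at equal identity resolve to the smallest reference id, which
makes assignment invariant to reference ordering.

Functional classes are derived from the PR2 "division" rank (position 3 of
the 8-rank lineage; missing ranks are padded with the literal token
`unassigned`). Metazoa, Fungi and Streptophyta are excluded by name; there is
no canonical list of "exclusively phototrophic" divisions, so that set is a
configurable mapping defaulting to obvious phototroph divisions
(Chlorophyta, Rhodophyta, Haptophyta, Cryptophyta). Unassigned ASVs
(identity ≤ 80%) are always removed from the analysis fraction.

## Community statistics

* **Shannon** H = −Σ p_i ln p_i (natural log, the vegan convention; base
  configurable).
* **Rarefaction** is analytic: E[S_n] = Σ_i [1 − C(N−N_i, n)/C(N, n)],
  computed via log-gamma for numerical stability — deterministic and equal to
  the expectation of the resampling procedure (verified against a 10⁴-draw
  Monte-Carlo oracle to 3 SE in the tests).
* **Group summaries** use the sample standard deviation (n−1); single-sample
  groups report sd 0 and are flagged rather than dropped.
* **Taxon profiles** are proportions of ASVs per division with divisions
  below 2% pooled into "Others"; report percentages round half-up.
* **Jaccard** distances are computed on presence/absence (≥ 1 read).
* **NMDS** minimizes Kruskal stress-1 by SMACOF-style majorization with
  isotonic regression (scikit-learn's non-metric MDS engine) over 20 random
  starts, tolerance 1e−7; the best start is reported with its stress and
  convergence flag, and results are reproducible under a fixed seed.
* **PermANOVA** partitions squared distances: SS_total = Σ_{i<j} d²_ij / n,
  SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g, pseudo-F =
  (SS_between/(g−1)) / (SS_within/(n−g)). The p-value uses the +1/+1
  convention (observed statistic counted in numerator and denominator), so
  p ≥ 1/(n_perm+1). Small designs can be enumerated exhaustively
  (`exhaustive=True`), which the tests compare against an independent
  brute-force oracle. Pairwise tests report raw and Benjamini–Hochberg
  adjusted p-values.
* The **nested** two-factor test decomposes sequentially (Type-I): the island
  term first, then depth nested within island (island × depth cells), each
  tested against the residual under *free* permutation of samples — the
  default of the reference R implementation. Restricted permutation within
  islands is arguably the better exchangeability unit for the nested term;
  free permutation was chosen for comparability and is noted as a limitation.
  Designs with one sample per cell have no residual and are rejected with an
  explicit error (the 3-island × 7-depth layout is such a design; the
  synthetic analysis therefore nests depth *zones*, 3 × 3 cells, 12 residual
  df).

## Synthetic data

The generator emulates *denoised* V9 output (~130 nt), not raw reads: no
per-base error model, no chimera sequences (contaminants stand in for any
unrelated noise), no tag-jumping, no negative controls.

* **Reference database**: random sequences with all pairwise identities
  < 95%, carrying 8-rank PR2-style lineages cycling through six heterotroph
  divisions and the four excluded groups.
* **Mock libraries**: reads are drawn *multinomially* at fixed total
  (default 10⁵) — proportions are the unit the thresholds act on, so totals
  are held fixed rather than Poisson-distributed. The default design is a
  symmetric nine-species mix with one 1-mismatch error variant at 0.5% and
  one contaminant (edit distance ≥ 2 from every species) at 1%, the expected
  species sharing the remainder equally; designed proportions therefore sum
  to 1 and the designed lenient/strict values are exactly 0.5%/1.0%. If a
  design sums to < 1 the remainder is drawn and discarded, and ground-truth
  thresholds are recorded on the observed-read scale.
* **Environmental dataset**: 21 samples (3 islands × 7 depth strata,
  50–2000 m, five libraries round-robin). Community structure is planted via
  disjoint ASV pools — a core pool (60 ASVs) shared by all, one pool per
  depth zone (40 each; zones 50 m / 150–500 m / 1000–2000 m) and one per
  island (30 each). Each eligible ASV occupies a given sample with
  probability 0.8 (benthic communities are patchy; without this, deep
  sequencing makes presence deterministic and within-group distances
  collapse to zero). Abundances are log-normal (σ = 1 across ASVs, σ = 0.5
  per-sample noise; no abundance distribution is dictated by the data, so
  log-normal was chosen as the standard heavy-tailed default) with 500 000
  multinomial reads per sample, yielding ~100–120 detected ASVs per sample —
  comparable to the motivating study's 99–175. ASV sequences derive from
  reference entries at designed identity levels (25% exact, 20% at >98%,
  40% at ~90%, 15% below 80%) so both identity cutoffs are exercised, and
  15% of ASVs carry excluded-group lineages so functional filtering is
  exercised. All randomness flows from integer-seeded NumPy generators;
  output is deterministic per seed.

Passing tests on these data show that the *procedures* are correct — that
thresholds are recovered within sampling error, filters implement their
definitions exactly, and the inference machinery is calibrated (type-I error
at nominal level) and powerful against planted structure of realistic size.
They do not validate biological conclusions on real communities, where copy
number variation, DNA from the water column and reference-database gaps all
act outside this model.

## Problem sizes and numerical conventions

The statistical checks run at: 100 mock libraries of 10⁵ reads for threshold
recovery; 1000 null datasets (21 samples, 199 permutations) for type-I
calibration — 199 permutations make the nominal 0.05 level exact for the
permutation test; 100 planted-effect datasets for power at α = 0.01.
Comparisons against enumeration use n = 4 (4! = 24 permutations). Report
percentages round half-up (`Decimal`), mean reads are reported in millions to
one decimal, and p-values never fall below 1/(n_perm+1).

## Known limitations

* Identity at the 98% cutoff is compared in floating point downstream of the
  assigner; at V9 lengths no attainable identity sits exactly on 98%, so this
  is inconsequential, but other cutoffs on other amplicon lengths could sit
  on a representable boundary.
* The NMDS engine reports the best of `n_starts` random starts; global
  optimality is not guaranteed (inherent to NMDS).
* `read_count_table` validates every cell (integer, non-negative, complete)
  and is written for clarity over speed; tables with millions of cells would
  want a vectorized path.
* The strict threshold requires each expected species to appear as an
  exact-sequence ASV; a mock in which a species is represented only by an
  error variant is reported as incomplete rather than calibrated.
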
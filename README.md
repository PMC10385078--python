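# amplimock

Mock-community-calibrated ASV filtering and community-structure statistics for
18S V9 amplicon metabarcoding of benthic protists.

## The problem

Denoised amplicon tables (ASVs — amplicon sequence variants — by samples)
still contain low-level noise: PCR/sequencing error variants and cross-talk.
When a known **mock community** (here: nine cultured protist species) is
sequenced on every library, its output calibrates objective, per-library
read-proportion thresholds:

* **lenient threshold** `t_len(L)` — the read proportion of the mock ASV with
  the smallest read count still assigned to one of the nine species (allowing
  one base mismatch). Environmental samples on library *L* keep an ASV iff its
  within-sample proportion is **≥ t_len(L)**.
* **strict threshold** `t_str(L)` — the largest proportion among mock ASVs
  that are *not* one of the nine expected (exact-sequence) ASVs; keeping only
  cells with proportion **> t_str(L)** leaves exactly the expected set.
* the cells removed by the lenient filter form a **low-abundance** dataset,
  restricted to ASVs with > 98% identity to a reference sequence.

Around this calibration the package implements the full analysis a
metabarcoding study of community structure needs: global-alignment taxonomic
assignment with a strict > 80% identity cutoff and functional filtering
(removing metazoans, fungi, streptophytes and exclusively phototrophic taxa),
Shannon diversity, analytic (hypergeometric) rarefaction
`E[S_n] = Σ_i [1 − C(N−N_i, n)/C(N, n)]`, Jaccard presence/absence distances,
non-metric multidimensional scaling (Kruskal stress-1), one-factor, pairwise
and two-factor nested PermANOVA with permutation p-values
`p = (1 + #{F* ≥ F}) / (1 + n_perm)`, exact-genotype rediscovery, and
UpSet-style unique/shared ASV partitions across depth groups and islands.

A synthetic-data module generates mock libraries and a 21-sample
environmental design (3 islands × 7 depth strata, 50–2000 m) with known
ground truth — designed thresholds, ASV pool memberships, lineages and
identity levels — so every stage is testable without any download.

## Worked example

```python
import amplimock as am

study = am.generate_study(seed=42)          # refs, env data, 5 mock libraries
cal = am.MockThresholdCalibrator().fit(
    {lib: (cm, seqs) for lib, (cm, seqs, _) in study["mocks"].items()},
    study["mock_species"])
print(cal.thresholds_.per_library.round(5))

table = am.assign_all(study["env_seqs"], study["refs"])   # best hit > 80% id
het = am.filter_functional(table)                         # heterotrophs only
env_het = study["env_counts"].subset_asvs(sorted(het)).drop_empty_asvs()
part = am.partition_datasets(env_het, study["meta"], cal.thresholds_, table)

d = am.jaccard_matrix(part.main)
meta = study["meta"]
zones = [am.DEPTH_ZONES[int(meta.table.loc[s, "depth_m"])] for s in d.ids]
res = am.permanova(d, zones, n_perm=999, seed=42)
rep = am.intersections(am.group_presence(part.main, meta, "island"))
```

Output:

```
            t_lenient  t_strict  feasible_strict
library_id
L1            0.00486   0.00999             True
L2            0.00501   0.00991             True
L3            0.00496   0.00988             True
L4            0.00538   0.01085             True
L5            0.00505   0.01041             True
main: 166 ASVs, strict: 128, low-abundance: 57
depth zones: pseudo-F = 5.21, R2 = 0.367, p = 0.001
island-unique ASVs: 67 (40%), shared by all three: 82 (49%)
```

The five libraries recover their designed calibration (lenient 0.5%, strict
bound 1.0%) up to multinomial sampling error, every strict threshold is
feasible (filtering the mock at it leaves exactly the nine expected ASVs),
and the planted three-zone depth structure (50 m / 150–500 m / 1000–2000 m)
is detected by PermANOVA on Jaccard distances at the permutation floor
p = 1/(999+1) + sampling.

A command-line interface mirrors the stages:
`amplimock simulate | assign | calibrate | filter | diversity | ordinate |
permanova | sets` (see `amplimock --help`).

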
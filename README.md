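# famburden

Family-based candidate-gene risk-allele burden analysis for small
multi-generation pedigrees, with APOE ε-diplotype calling and gene-level
DNA-methylation summaries.

## The problem

Population polygenic risk scores transfer poorly to single families: effect
sizes estimated in large (mostly European-ancestry) cohorts are not
calibrated for within-family comparison, and a family of seven cannot
validate them. `famburden` instead implements the simple, interpretable
statistic used in family-based multi-omics case studies of late-onset
Alzheimer's disease: an unweighted **Genetic Burden Score** over a fixed
candidate-gene panel,

```
GBS_i = Σ_j  G_ij ,    G_ij ∈ {0, 1, 2}
```

where `G_ij` is the number of risk alleles individual *i* carries at panel
SNP *j*. The default panel covers six AD-associated genes (*APOE*, *PICALM*,
*CLU*, *CR1*, *BIN1*, *ABCA7*; GRCh37 coordinates built in), with SNPs
extracted from gene regions ± 50 kb. GBS is a **within-family comparative
score only** — it is not a disease probability and has no population
percentile interpretation.

Around that core the package provides:

* **pedigree** handling (PLINK PED/FAM dialect), ordinal generation
  assignment, consanguinity subsetting (marry-in spouses excluded), and
  per-SNP Mendelian-consistency checking by gamete-pair enumeration;
* **variant QC** in a fixed, reported order: multi-allelic → missing risk
  designation → monomorphic-in-family → any missing genotype;
* **APOE ε-diplotype calling** from rs429358/rs7412 with the canonical
  ε-haplotype table, ambiguity flagging for the double heterozygote, and
  ε4-carrier classification;
* **within-family statistics**: mean ± sample SD summaries, per-generation
  summaries, sibling discordance (Δ and percent of the smaller total),
  per-gene contribution percentages, carrier vs non-carrier comparison,
  one-way random-effects ICC, and an ordinal generation trend;
* **methylation summaries**: β = M/(M+U), probe filtering (detection-p,
  SNP-overlap, cross-reactive, sex-chromosome), gene-region ± 10 kb mean β
  per individual, genotype–methylation Pearson correlations, and
  complete-linkage hierarchical clustering with a deterministic tie-break;
* a fully seeded **synthetic family generator** (LD-structured founder
  haplotypes, meiosis with recombination, optional missingness and
  Mendelian-error injection, genotype-coupled β values) so the whole
  pipeline is testable without restricted subject-level data.

## Worked example

The package bundles the published per-individual summary data of a
seven-member, three-generation family (three grandparents, two parents, two
offspring; one affected grandparent):

```python
import famburden as fb

core = fb.core_family()
print(fb.summarize(list(core.totals.values()), "family").display())

bt = fb.BurdenTable.from_totals(core.totals)
for g in fb.generation_summary(bt, core.pedigree):
    print(g.display())

a, b = core.sibling_pair
delta, rel = fb.relative_discordance(core.totals[a], core.totals[b])
print(f"sibling discordance: delta={delta:.0f} ({fb.round_half_up(rel)}%)")

cc = fb.carrier_comparison(bt, core.carrier_flags)
print(cc.carriers.display())
print(cc.non_carriers.display())
```

prints

```
family: n=7, mean 46.9 ± 8.8, range: 37-61
Generation 1: n=3, mean 48.0 ± 7.9, range: 39-54
Generation 2: n=2, mean 43.0 ± 2.8, range: 41-45
Generation 3: n=2, mean 49.0 ± 17.0, range: 37-61
sibling discordance: delta=24 (64.9%)
e4 carriers: n=3, mean 48.3 ± 11.4, range: 39-61
non-carriers: n=4, mean 45.8 ± 8.1, range: 37-54
```

Read: the affected grandparent has the *lowest* burden in her generation
(39 of 39–54), the two brothers differ by 24 alleles (64.9 % of the smaller
total) despite identical parents, and ε4 carriers exceed non-carriers by
only 2.6 alleles on average — the burden score and ε4 status dissociate in
this family.

## Command line

```sh
famburden simulate --seed 7 --out data/          # synthetic inputs + truth.json
famburden score --ped data/pedigree.ped --vcf data/genotypes.vcf \
    --panel data/panel.tsv --regions data/regions.tsv --out scores/
famburden apoe --vcf data/genotypes.vcf --out apoe.tsv
famburden methylation --beta data/beta.tsv --manifest data/manifest.tsv \
    --regions data/regions.tsv --detp data/detection_p.tsv --out meth/
famburden report --config run.yaml --out report.json
```

`report` runs the full pipeline (pedigree → blood relatives → region
extraction → QC → GBS → ε calling → methylation → statistics) and writes a
single JSON document with full-precision values and provenance checksums;
`docs/report.schema.json` describes its structure.

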
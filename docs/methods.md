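# Methods

## Genetic Burden Score

For individual *i* over a panel of biallelic SNPs with designated risk
alleles, `GBS_i = Σ_j G_ij` with `G_ij` the risk-allele dosage (0, 1, 2) of
the unphased diploid genotype. The score is unweighted by design: in a
single family, published GWAS effect sizes add no calibrated information and
may import ancestry bias, while equal weighting keeps gene-level
decompositions directly interpretable. The decomposition identity
`GBS_i = Σ_genes count_i,gene` holds exactly (integer arithmetic throughout).

Interpretation boundaries are part of the contract: GBS values are not
disease probabilities, are not comparable to population polygenic-score
percentiles, and are meaningful only relative to other members of the same
family.

### Region extraction and QC

Panel SNPs are assigned to candidate genes by position: a record is kept iff
it falls inside a gene region ± 50 kb (1-based inclusive boundaries
everywhere; chromosome names compared after stripping a leading `chr`).
Flanked regions must not overlap on a chromosome, so the assignment is
unambiguous. The built-in region table carries the GRCh37 coordinates of
*APOE*, *PICALM*, *CLU*, *CR1*, *BIN1* and *ABCA7*.

Variant QC applies four rules in a fixed order, attributing each removal to
the first failing rule so the report is reproducible: (1) multi-allelic;
(2) risk allele absent or not one of {ref, alt}; (3) monomorphic across the
scored samples (a single distinct allele observed); (4) any missing
genotype. The filter is monotone and idempotent. Strand flipping is not
attempted: panel alleles are assumed reported on the VCF reference strand,
and ambiguous A/T–C/G SNPs pass through, because resolving them would
require external frequency data.

rs429358 and rs7412 may arrive either inside the VCF or through a side TSV
of directly assayed genotypes (they are absent from some genotyping arrays);
when both sources cover a call they must agree or loading fails. In the
burden they are ordinary risk-dosage SNPs, independent of ε calling.

## APOE ε diplotypes

The ε haplotypes are defined by (rs429358, rs7412): ε2 = (T,T), ε3 = (T,C),
ε4 = (C,C), ε1 = (C,T). An unphased genotype pair is resolved by
enumerating all haplotype pairs consistent with both site-wise allele
multisets. Eight of the nine possible genotype combinations are unique; the
double heterozygote is explained by both ε2/ε4 and ε1/ε3 and is reported as
ε2/ε4 (ε1 is vanishingly rare in human populations) with `ambiguous=True`
and the alternative recorded. An ε4 carrier is any diplotype containing ε4.

## Pedigree semantics

Founders take generation 1; a child sits one generation below its deepest
in-pedigree parent (a child with a single recorded parent sits one below
that parent). Blood-relative subsetting uses the consanguinity criterion:
an individual is retained iff it shares an in-pedigree common ancestor
(counting itself) with at least one proband. This keeps ancestors,
descendants and collateral relatives, keeps a spouse who also has a blood
path (e.g. a cousin marriage), and excludes marry-ins. The pipeline's
default proband set is the deepest generation, which reproduces the usual
"blood relatives of the youngest offspring" framing.

The Mendelian check treats each SNP independently (no linkage phasing):
a (child, SNP) pair is a violation iff no choice of one allele from each
parent's genotype yields the child's genotype. Missing genotypes are never
flagged, and an absent parent constrains nothing. The panel genes are all
autosomal, so X/Y transmission is not special-cased.

## Statistics

* Summaries report mean, **sample** SD (n−1 denominator), min and max; the
  SD convention reproduces the reference worked example exactly, which a
  population SD does not. All statistics are computed at full precision;
  half-up rounding to 1 decimal (3 for correlations) happens only at
  display time.
* Sibling discordance: Δ = |a − b| and 100·Δ/min(a, b). The smaller total
  is the only denominator consistent with the worked example.
* Contribution percentages: 100 · gene mean / total mean. The bundled
  worked example feeds the published 1-dp gene means and 1-dp family mean,
  matching the reference display.
* ICC: one-way random-effects ICC(1) = (MSB − MSW)/(MSB + (k₀−1)·MSW), with
  the standard unequal-group-size k₀ = (N − Σn_g²/N)/(a−1). Generation is
  the grouping factor — the grouping is an assumption, as familial
  clustering can be defined many ways in a single pedigree. Cross-checked
  against pingouin (balanced case) and statsmodels ANOVA mean squares
  (unbalanced case).
* Generation trend: OLS of total burden on the ordinal generation code
  (1, 2, 3). A constant response returns slope 0 and r 0 by convention.
* Pearson correlations require n ≥ 3 and nonzero variance; a gene whose
  count or β vector is constant is flagged undefined rather than reported
  as 0.

## Methylation

β = M/(M+U); no stabilizing offset by default (configurable). The pipeline
consumes a probe × sample β matrix plus manifest — IDAT parsing and
normalization are upstream concerns. Probe filtering applies, in order:
detection p > 0.01 in **any** sample (strict reading), SNP-overlap flag,
cross-reactive flag, sex-chromosome flag; population-specific SNP-overlap
and cross-reactivity are supplied as user mask lists, not computed from
reference data. Gene-level summaries average β over probes inside a gene
region ± 10 kb (vs ± 50 kb for variants); a gene without in-window probes
is absent from the output, not zero. Whether "regulatory regions" should be
a separate promoter definition is unresolved in the source description;
region ± 10 kb is the implemented reading.

Hierarchical clustering is a hand-rolled O(n³) complete-linkage
agglomerator on Euclidean distances with a deterministic tie-break
(lexicographically smallest cluster pair), making the merge tree a pure
function of the input; merge heights are provably non-decreasing under
complete linkage. scipy's agglomerator serves as an independent oracle in
the tests, never as the implementation.

## Synthetic family generator

The generator emulates the study conditions: a seven-member,
three-generation blood core (an affected grandmother whose child married
into a grandparent couple's line, plus two third-generation brothers; a
member with one named parent gets a hidden, non-emitted founder as the
missing marry-in parent), a 320-SNP panel with per-gene counts
{ABCA7 101, PICALM 89, CR1 84, CLU 29, BIN1 8, APOE 9} laid inside the real
gene regions, and rs429358/rs7412 at their true GRCh37 coordinates with
real allele coding so ε calling runs unmodified on synthetic output.

* **Frequencies**: per-SNP risk-allele frequencies drawn once per panel,
  uniform on (0.02, 0.15) by default, chosen so family totals land in the
  tens of alleles as in the motivating family; rs429358/rs7412 use fixed
  East-Asian-like frequencies (0.12, 0.08).
* **LD**: a latent-uniform copy chain — with probability ρ (default 0.8)
  the previous SNP's latent uniform is reused, else a fresh one is drawn;
  the allele state is `u < f_j`. Copying at the latent level preserves each
  SNP's marginal frequency exactly and gives adjacent-state correlation
  exactly ρ when neighboring frequencies are equal (the closed form used by
  the Monte-Carlo test). Chains restart at gene-block boundaries.
* **Meiosis**: per gene block, a uniformly chosen starting haplotype with
  per-interval switch probability 0.01; blocks assort independently,
  emulating chromosomal independent assortment.
* **Corruption**: optional missingness (logged in the truth record) and
  Mendelian-error injection. Errors are injected only into leaf individuals
  because corrupting a mid-pedigree parent would cascade violations into
  its children's trios; sites where both parents are heterozygous admit no
  violating genotype and are skipped.
* **Methylation**: probe β = expit(logit(baseline) + slope·count + offset_i
  + N(0, σ)), σ on the logit scale so β stays in (0,1) by construction.
  The default per-individual offset (−0.1 logit for the affected member)
  emulates an affected-specific hypomethylation shift without asserting any
  causal claim. Decoy probes outside every gene window exercise the
  region-assignment path. Note the offset is worth ≈ 10 risk alleles of
  coupling signal on the logit scale, so tests that probe coupling recovery
  set it to zero to isolate the mechanism.
* **Determinism**: everything derives from one `numpy` Generator seeded by
  the config (methylation uses a stream derived from (seed, 1) so genotype
  output is unaffected by toggling it); emitted files are byte-identical
  across runs.

A note on sibling discordance: with near-zero within-block recombination,
higher LD makes haplotype blocks segregate as units, so the mean |ΔGBS|
between simulated sibs *increases* with ρ (whole-block dosage differences,
~m per block) and shrinks as SNPs become independent (CLT cancellation,
~√m). The property suite asserts this direction.

### What the generator does not model

Coalescent population history, realistic r² decay with distance, phenotype
or liability, age structure, probe-level technical artifacts (batch,
cell-type composition, dye bias), and genotyping error beyond the explicit
injections. Passing tests therefore demonstrate correctness of the
*computations* under controlled conditions, not robustness to real-world
array noise.

## Problem sizes and numerical choices

The test and acceptance workloads use the family-scale problems the method
targets: 320-SNP panels, 7-member families, 500 founders (1,000 haplotypes)
for frequency recovery, 1,000 trios for the Mendelian oracle, 50 random
instances for the clustering oracle, and 20 replicate families for coupling
recovery. Frequency recovery is assessed as mean absolute deviation ≤ 0.03
with ≥ 90 % of SNPs inside the ± 0.03 band — at 1,000 haplotypes the
per-SNP binomial SD reaches 0.016, so a per-SNP-maximum criterion would be
statistically vacuous. Similarly, with n = 7 the null distribution of a
Pearson r has SD ≈ 0.41, so uncoupled genes are required to stay below
|r| = 0.5 in the median across replicates, while the coupled gene must be
recovered (correct sign, |r| > 0.8) in ≥ 18 of 20 replicates.

Ties in clustering break lexicographically; constant vectors yield
explicit errors (Pearson, trend on identical generations) or flags
(undefined correlations) rather than NaNs; rounding is half-up via decimal
arithmetic, never binary-float `round`.

## Known limitations

* The worked-example dataset carries family-level summary values, not
  subject-level genotypes (which are not public); per-SNP results for that
  family are therefore not reproducible here, and the three published APOE
  β values cannot recompute the published family mean β.
* The ε2/ε4 vs ε1/ε3 ambiguity is resolved by prior rarity, not by data.
* No strand auto-flipping, no imputation, no HWE testing (not applicable to
  family data), no IDAT processing, no enrichment analysis.
* ICC uses generation as the grouping factor; other groupings (nuclear
  family, sibship) would give different values.
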
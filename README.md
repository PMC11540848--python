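# xqtl

Integrative genetic analysis of a proteome/transcriptome cohort: map
cis- and trans-QTLs for protein and mRNA abundance, colocalize eQTL and
pQTL signals, classify pQTLs as transcript-mediated or SNP-direct, test
causal/pleiotropic control of GWAS traits with SMR + HEIDI, and rank
candidate genes by multi-evidence order statistics — with a synthetic-data
generator that reproduces the statistical structure every stage assumes, so
the whole pipeline is testable end-to-end with no external data.

It is written for statistical geneticists and proteogenomics analysts who
want the full chain — TMT reporter-ion quantification through candidate
prioritization — as composable, tested library functions rather than a
patchwork of external tools.

## The statistics at the core

* **Permutation-calibrated QTL mapping.** Per trait, variants in the cis
  window (TSS ± 1 Mb) are scanned by linear regression on dosage; the
  minimum nominal p over R = 10,000 sample-label permutations is fit with a
  Beta(a, b) by maximum likelihood, and the *adjusted p* is the Beta CDF at
  the observed minimum. Genome-wide FDR uses Storey q-values
  (q < 0.05); trans scans use Bonferroni α /(#variants × #traits).
* **Colocalization.** Wakefield log-ABF per variant,
  `0.5[log(V/(V+W)) + z²W/(V+W)]`, summed over single-causal-variant
  configurations into posteriors PP0–PP4 for the five hypotheses
  (no signal / trait-1 only / trait-2 only / two variants / one shared
  variant).
* **Mediation.** A pQTL is transcript-dependent when conditioning on mRNA
  collapses it: z = (x − mean(x_perm))/sd(x_perm) with x = −log10(p_cond)
  and the mRNA labels permuted 1000 times; call at z ≤ −4.26
  (the normal quantile at p = 1e-5).
* **SMR + HEIDI.** b_xy = b_GWAS/b_QTL at the top QTL;
  T_SMR = z₁²z₂²/(z₁²+z₂²) ~ χ²(1); HEIDI rejects the single-shared-variant
  model when b_xy is heterogeneous across LD partners of the instrument
  (delta-method covariance with second-order ratio corrections,
  Satterthwaite tail).
* **Prioritization.** Per-gene rank ratios across five evidence sources
  aggregated by the joint order-statistic tail probability
  Q = k!·V_k, V_i = Σ_j (−1)^(j−1) V_{i−j} q_{i−j+1}^j / j!.

## Worked example

Run the end-to-end pipeline on a simulated cohort (268 samples, 20 genes,
one LD block per gene; ~79% of proteins transcript-mediated):

```python
from xqtl import PipelineConfig, SimConfig, run_pipeline

cfg = PipelineConfig(
    out_dir="demo", seed=7,
    sim=SimConfig(n_samples=268, n_variants=400, n_blocks=20, seed=7),
    n_permutations=2000,
)
manifest = run_pipeline(cfg)
```

This writes genotypes, phenotype BEDs, GWAS summaries, a PSM table and all
stage outputs under `demo/`, with a `manifest.json` listing the 8 stages,
their parameters and output checksums. On this configuration it prints
(via the result tables):

```
pGenes at q<0.05: 15 of 20
  trait_id variant_id    slope    nominal_p   adjusted_p       qvalue
gene1_prot chr1_snp11 0.284463 1.422309e-02 2.379572e-01 2.614090e-01
gene2_prot chr2_snp18 0.451872 6.468239e-04 1.168654e-02 1.797929e-02
gene3_prot chr3_snp11 1.113681 1.552984e-18 1.887590e-16 1.887590e-15
colocalized (PP4>0.8): 7 of 20
mediation: {'dependent': 7}
evaluation: {'mediation_accuracy': 1.0, 'quantify_pearson_r': 0.967}
```

Reading the numbers: 15 of the 20 simulated proteins reach a significant
cis-pQTL at FDR 5% (the adjusted p is the beta-approximated empirical p
from 2000 permutations; the q-value column is the Storey/BH FDR across
traits). Seven genes show strong eQTL–pQTL colocalization (PP4 > 0.8) —
by design only transcript-mediated genes can, since SNP-direct proteins
carry no eQTL — and all seven are classified transcript-dependent by the
conditional-mapping z-test, matching the generator's truth table
(`mediation_accuracy: 1.0`). The TMT chain recovered the simulated protein
abundances from PSM-level reporter intensities with r = 0.967.

The same stages are exposed on the command line:

```bash
xqtl simulate --out demo --seed 7
xqtl map --genotypes demo/genotypes.tsv --bed demo/mrna.corrected.bed \
         --out demo/eqtl.tsv --mode cis --permutations 10000
xqtl coloc --assoc1 pqtl.ma --assoc2 eqtl.ma --out coloc.tsv
xqtl run --out demo --seed 7          # full pipeline
```

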
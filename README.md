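# adiponet

Cross-population weighted gene co-expression network analysis (WGCNA) for
adipose expression studies of serum triglycerides (TG).

High serum TG is an established coronary-heart-disease risk factor, and
adipose tissue — where TGs are stored and hydrolyzed — is the natural place
to look for transcriptional programs that track serum TG. `adiponet`
implements the full multi-cohort workflow for that question:

1. **Per-cohort preparation** — detection-call filtering, collapsing
   multiple microarray probes per gene to the most variable probe,
   residualizing expression on covariates (age, sex) and twin-pair
   structure, and adjusting log-TG for significant covariates by
   bidirectional stepwise regression.
2. **Network inference** — unsigned weighted networks with adjacency
   `a_ij = |cor(x_i, x_j)|^β`, topological-overlap dissimilarity
   `d = 1 − ω`, where

       ω_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

   average-linkage clustering with a static merge-height cut, minimum
   module size, and eigengene-based module merging. Each module is
   summarized by its eigengene (ME, the first principal component of
   standardized member expression); every gene gets a module membership
   kME = cor(gene, ME). Module eigengenes are correlated with traits under
   Bonferroni control over (modules × traits).
3. **Module preservation** — permutation Zsummary between a reference and a
   test cohort: density and connectivity statistics are compared against
   random gene sets of matched size; `Zsummary > 10` is strong evidence of
   preservation, `< 2` none.
4. **Cross-cohort comparison** — gene-symbol harmonization, Fisher exact
   tests of module overlap over the shared expressed-gene background,
   Monte-Carlo empirical p-values for joint hub-gene overlap, kME
   cross-correlation, Welch-t differential expression with top-N list
   overlap, hypergeometric over-representation (GMT gene sets), and
   SNP-dosage association with eigengenes.
5. **Synthetic studies** — a latent-factor generator that plants partially
   preserved, TG-coupled modules across cohorts (with twin-pair correlation
   and multi-probe redundancy), so every stage is testable end to end
   without external data.

## Worked example

```python
import numpy as np
import adiponet as a

cfg = a.SyntheticStudyConfig(
    n_cohorts=2, samples_per_cohort=(53, 70), n_genes=600,
    module_sizes=(60, 50), tg_module_index=0, tg_effect=0.6, seed=42,
    rnaseq_cohort=1)
study = a.generate_multi_cohort_study(cfg)
cohorts = [a.CohortInput(name=c.name, expression=c.expression,
                         phenotypes=c.phenotypes, annotation=c.annotation)
           for c in study.cohorts]
result = a.run_all(cohorts, network_config=a.NetworkConfig(min_module_size=25),
                   n_permutations=50, seed=42)

for c in result.cohorts:
    row = c.trait_result.table.query("module == @c.tg_module").iloc[0]
    print(f"{c.name}: TG module = {c.tg_module} "
          f"({len(c.tg_module_genes)} genes, r = {row.pearson_r:.2f}, "
          f"p = {row.p_value:.1e})")
pres = result.preservation["cohort1_vs_cohort2"].to_frame()
print(pres[["module", "size", "Zsummary", "flag"]].to_string(index=False))
ov = result.tg_overlaps["cohort1_vs_cohort2"]
print(f"TG-module overlap: {ov.shared_count}/{ov.set_b_size} genes "
      f"({ov.percentage:.1f}%), Fisher p = {ov.fisher_p:.2e}")
```

prints

```
cohort1: TG module = turquoise (115 genes, r = 0.54, p = 2.7e-05)
cohort2: TG module = turquoise (97 genes, r = 0.80, p = 1.0e-16)
   module  size  Zsummary   flag
turquoise   115 16.059990 strong
     blue    79 12.382023 strong
TG-module overlap: 63/97 genes (64.9%), Fisher p = 4.89e-29
```

Read: in each cohort the trait-coupled planted module is recovered as the
top TG-associated module (eigengene–TG correlation with its p-value); both
modules of cohort 1 are strongly preserved in cohort 2 (Zsummary > 10);
and the two cohorts' TG modules share 63 of 97 genes — far more than
expected over a 600-gene background (Fisher exact test).

The same pipeline is scriptable from a shell:

```bash
adiponet simulate --seed 42 --out study/
adiponet run-all --config study.yaml --seed 42 --out results/
```

with subcommands `simulate, preprocess, network, preservation, compare,
enrich, run-all` (see `adiponet --help`). Every command writes a JSON run
log with the resolved configuration, seeds and input digests.

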
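# intbias

Integration-site bias analysis for transposon and retroviral systems.

Transposons (Sleeping Beauty, piggyBac) and retroviruses (e.g. MMTV) do not
insert into host DNA uniformly: target-site selection is shaped by sequence
motifs (TA, TTAA), chromatin state, gene activity and genome topology.  In
insertional-mutagenesis (IM) cancer screens this intrinsic bias is a
confounder — a cluster of integrations recurring across tumors (a common
integration site, CIS) may mark a selected cancer gene, or may simply be a
hotspot of the delivery system.  `intbias` implements the statistical
machinery to measure such biases against matched random controls and to
separate selection from bias in tumor screens:

- **Matched random controls** — every integration is matched to *m* (default
  10) random loci sharing its integration motif, its distance to the nearest
  upstream restriction site (library-recovery constraint), and unique
  mappability; all downstream statistics are observed-vs-control.
- **Annotation bias** — meta-gene alignment profiles, gene/transcript region
  enrichments with orientation tests (binomial, BH-FDR), expression-quantile
  trends (Cochran–Armitage), and TAD-boundary interface profiles
  (Cochran–Mantel–Haenszel between systems).
- **Scale-resolved association** — for each genomic feature *f* and scale
  *s*, window-mean scores at integration sites are compared with scores at
  ±*s* bp by a two-sample t on rank-normalized values; the control-adjusted
  statistic

  ```
  T(s, f) = Z_I − mean_j Z_Cj,      T ~ N(0, sqrt(1 + 1/m)) under the null
  ```

  gives analytic p-values (BH-FDR over the feature × scale matrix) and a
  macro/micro-feature classification by smallest significant scale.
- **Markov-blanket feature selection** — tertile-discretized locus features
  plus a binary integration indicator enter bootstrapped discrete
  Bayesian-network structure learning (annealed hill-climb, BDeu/BIC); each
  feature is summarized by the fraction of bootstraps it enters the
  indicator's Markov blanket and its mean conditional mutual information.
- **CIS calling** — Gaussian-kernel convolution (30 kb kernel, 1 kb grid)
  with a Monte-Carlo genome-wide null and Bonferroni control; called CISs
  are filtered against an unselected profile by a one-sided binomial test
  (success probability N_tumor / (N_tumor + N_unselected), BH-FDR): CISs
  without tumor excess are flagged spurious.  Calls are further classified
  activating/repressing by orientation homogeneity and annotated with the
  nearest TSS.
- **Synthetic data** — a first-class generator (assemblies, annotations,
  feature tracks, log-linear biased integration profiles, tumor screens with
  planted CIS loci) with serialized ground truth, so every stage has a
  parameter-recovery test with no external downloads.

## Worked example

```python
import numpy as np
from intbias import (BiasModel, FeatureCoupling, FeatureSpec,
                     make_assembly, make_annotation, make_feature_tracks,
                     simulate_integrations, sample_matched_controls,
                     find_motif_sites, find_restriction_sites,
                     region_bias, filter_overlapping_genes)

assembly = make_assembly({"chr1": 1_000_000}, gc=0.42, seed=11)
annotation = make_annotation(assembly, n_genes=40, seed=7)
tracks, truth = make_feature_tracks(
    assembly, annotation,
    [FeatureSpec(name="tssness", noise_sd=0.0, bumps=[("tss", 1.0, 400)])],
    seed=30)

# a TA-constrained profile biased toward TSSs (e^2 ~ 7.4x at full bump height)
model = BiasModel(motif="TA",
                  coefficients=[FeatureCoupling("tssness", 2.0, 0)])
rmap = find_restriction_sites(assembly, "GATC")
ints = simulate_integrations(assembly, model, n=4000, tracks={"tssness": tracks[0]},
                             restriction_map=rmap, seed=31)
controls = sample_matched_controls(ints, find_motif_sites(assembly, "TA"),
                                   rmap, m=5, seed=32)
genes = filter_overlapping_genes(annotation.genes)
print(region_bias(ints, controls, genes)[
    ["region_class", "obs", "expected", "log2_ratio", "q"]].round(3))
```

prints

```
     region_class   obs  expected  log2_ratio      q
0           genic  2255    2282.2      -0.017  0.388
1    TSS_upstream   425     156.0       1.446  0.000
2  TSS_downstream   401     166.0       1.272  0.000
3           other  1326    1565.8      -0.240  0.000
```

The planted TSS bias appears as a strong, significant enrichment of
integrations within 1 kb of TSSs relative to matched controls (log2 ratio
≈ 1.3–1.4, i.e. ~2.5–2.7x after dilution of the Gaussian bump across the
windows); the mass drawn into TSS regions comes at the expense of loci far
from genes ("other" significantly depleted), while genic counts stay at
their control expectation.

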
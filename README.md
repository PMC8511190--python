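# pcenet

Protein co-expression network analysis for spectral-count proteomics.

`pcenet` is a tested, reusable implementation of the network-analysis
chain used to profile small two-subtype tumor cohorts from label-free
shotgun proteomics — e.g. lung squamous cell carcinoma (SqCC) against
papillary predominant adenocarcinoma (PPA), a few thousand proteins
quantified by spectral counts in ~15 laser-microdissected samples. From a
protein × sample count matrix and a binary trait table it derives:

1. **Weighted co-expression modules** (WGCNA-style): Pearson similarity
   `s_ij`, soft-threshold adjacency `a_ij = |s_ij|^β`, topological overlap

   `T_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`,

   average-linkage clustering of `1 − T`, and a deep-split tree cut with a
   minimum module size; unassigned proteins get the "grey" label 0.
2. **Module–trait association**: each module is summarized by its
   eigenprotein (first principal component of the standardized module
   submatrix); the point-biserial correlation `r` of the eigenprotein with
   each 0/1 subtype indicator is tested via
   `t = r·√(n−2)/√(1−r²)` and gated at `|r| > 0.5` with
   Benjamini–Hochberg `q < 0.05`.
3. **Hub ranking** by Maximal Clique Centrality,
   `MCC(v) = Σ_{C ∋ v} (|C|−1)!` over maximal cliques of an induced
   STRING-style interaction subgraph (confidence ≥ 0.400).
4. **Over-representation analysis** with one-sided hypergeometric tests,
   BH control, and the Strength effect size `log10(observed/expected)`.
5. **Multivariate correlation clustering** of key proteins (eigenprotein
   representatives and hubs) after quantile normalization.
6. **Master-regulator activation calls** from a signed regulator→target
   network: `z = (N_consistent − N_inconsistent)/√N` over informative
   targets, a one-sided Fisher overlap test, and the conventional bands
   (`|z| ≥ 2` activated/inhibited, `1.5 < |z| < 2` up-/downregulated, at
   overlap `p < 0.005`).

A synthetic-data module generates study-scale datasets (2000 proteins,
7 + 8 samples, 30 planted modules of ≥ 15 proteins, 3 trait-linked,
negative-binomial spectral counts) with full ground truth, so every stage
is testable by parameter recovery without downloading anything.

## Worked example

```python
from pcenet.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    out_dir="demo_out",
    simulate={"n_proteins": 2000, "n_modules": 30, "n_trait_modules": 3},
    seed=1,
)
bundle = run_pipeline(config)
print(f"modules detected: {bundle.metadata['n_modules']}")
print(f"significant modules: {bundle.significant_modules}")
mt = bundle.module_trait
print(mt[mt.significant & (mt.trait == "SqCC")]
      [["module", "trait", "r", "p", "q"]].to_string(index=False))
```

prints

```
modules detected: 26
significant modules: [1]
 module trait       r            p        q
      1  SqCC 0.95135 5.110796e-08 0.000001
```

The generator planted 30 modules; the tree cut recovered 26 of them
(adjusted Rand index ≈ 0.89 against the planted partition, with grey
noise proteins rejected). The three planted trait-linked modules share
one latent driver — the subtype indicator — so their factors are mutually
correlated and the unsigned network merges them into the single recovered
module 1, whose eigenprotein correlates `r = 0.95` with the SqCC
indicator at BH `q ≈ 1e−6`: clearly past the `|r| > 0.5`, `q < 0.05`
gate. Result tables (partition, eigenproteins, kME, module–trait, hubs,
enrichment, MVA clusters, regulator calls) are written to `demo_out/`.

The same run is available from the shell:

```bash
pcenet simulate --seed 1 --out data/
pcenet run --config run.yaml       # or: pcenet wgcna / hubs / enrich / mva / regulators
```

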
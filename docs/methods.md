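# Methods

## Scope and model

`pcenet` analyzes a protein × sample matrix of non-negative spectral
counts — the number of MS/MS spectra assigned to each protein, a
semiquantitative abundance proxy from label-free shotgun proteomics —
together with binary sample traits (two tumor subtypes). The pipeline is
the weighted co-expression recipe: correlation network → soft threshold →
topological overlap → hierarchical modules → eigenprotein summaries →
trait gating, followed by interaction-network hub ranking, annotation
enrichment, correlation clustering of key proteins, and causal-network
regulator calls.

### Co-expression network

Counts are transformed `log2(count + 1)` by default before correlation
(raw counts are allowed via config); the log transform stabilizes Pearson
correlation on skewed counts. Zero-variance proteins are dropped with a
warning. The similarity is the pairwise Pearson correlation `s_ij`; the
adjacency is unsigned, `a_ij = |s_ij|^β` (a signed variant
`((1+s)/2)^β` is available by flag). The default soft power is **β = 25**
with modules of minimum size **15** at deep-split sensitivity **4** and a
significance gate of **|r| > 0.5, BH q < 0.05** — the parameter set used
for cohort-scale spectral-count data of this kind. An optional
scale-free criterion can select β instead: connectivities
`k_i = Σ_j |s_ij|^β` are binned into 10 equal-occupancy bins of
`log10 k`, and the fit R² of `log10` density against `log10 k` is
reported per candidate; the smallest β reaching R² ≥ 0.8 wins. Note the
R² is unsigned (the slope is not constrained), and on the synthetic
default data the criterion is satisfied already at small β, so automatic
selection is deliberately **not** the pipeline default.

The topological overlap of two proteins combines their direct adjacency
and shared neighborhood:

    T_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    L_ij = Σ_{u≠i,j} a_iu a_uj,   k_i = Σ_{u≠i} a_iu,

with `T_ii = 1`; the clustering dissimilarity is `1 − T`.

### Module detection

Average-linkage agglomerative clustering of `1 − T` yields a dendrogram;
modules are branches below a cut placed at a fixed fraction of the
maximum merge height, per deep-split level:

| deep split | 0 | 1 | 2 | 3 | 4 |
|------------|-----|-----|-----|-----|-----|
| cut height (fraction of max) | 0.64 | 0.73 | 0.82 | 0.91 | 0.99 |

Candidates smaller than the minimum module size dissolve to the
unassigned label 0 ("grey"); surviving modules are relabeled 1..M by
decreasing size (ties broken by smallest member ID). This is a
deterministic static-height simplification of adaptive branch trimming:
it reproduces planted-truth partitions well (see below) but module
boundaries can differ from the adaptive-reference algorithm, which
re-splits dense branches recursively. In particular, modules whose latent
factors are strongly mutually correlated — unavoidable when several
modules track the same binary trait with |r| ≈ 0.9 — may merge into one
detected module. No post-hoc merging of similar modules is performed by
default (an eigenprotein-similarity merge hook exists in the config,
default off).

### Eigenproteins and trait association

Within a module, each protein profile is standardized to mean 0 and unit
variance across samples; the eigenprotein is the unit-norm first right
singular vector of the standardized submatrix, oriented to correlate
non-negatively with the module's mean profile, and
`variance_explained` is the top singular value squared over the total.
Module membership kME is the signed Pearson correlation of a protein
profile with an eigenprotein (reported signed in [−1, 1]; any
absolute-value convention is left to the caller). Module–trait
association is the point-biserial Pearson correlation of the eigenprotein
with the 0/1 indicator; two-sided p-values come from the t transform with
n − 2 degrees of freedom (a perfect |r| = 1 is reported at the smallest
positive normal double), and BH adjustment is applied jointly over all
module × trait tests (with two complementary subtype indicators the two
traits carry mirrored r and identical p). A pair is significant iff
|r| > r_min **and** q < q_max.

### Hubs, enrichment, MVA, regulators

Hubs are ranked inside each significant module on the induced subgraph of
a confidence-filtered interaction network (edges ≥ 0.400 after
auto-rescaling STRING-style 0–1000 scores; duplicate edges keep the
maximum score; self-loops dropped). Maximal cliques come from
Bron–Kerbosch with pivoting; `MCC(v) = Σ (|C|−1)!` over maximal cliques
of size ≥ 2 containing v, isolated nodes scoring 0 — the conservative
convention, since size-1 "cliques" would give every isolated node a
constant offset. Ranks break ties by ascending protein ID so hub lists
are reproducible. The top k = 20 are reported.

Enrichment is one-sided over-representation: observed = |query ∩ term|,
expected = |term|·|query|/|background|, p from the hypergeometric upper
tail, BH across all terms of a collection, Strength =
log10(observed/expected); terms with observed = 0 are omitted rather than
assigned −∞. The default background is the union of the collection's
members, overridable when the measured proteome is the proper universe.

The multivariate stage quantile-normalizes samples (each column's sorted
values are replaced by the across-sample mean of order statistics; ties
receive the mean of the reference values they span — exact idempotence
therefore holds on tie-free data only) and clusters key proteins (the
top-kME representative of each significant module plus its hubs) by
average linkage on 1 − Pearson correlation (Spearman by flag), cutting at
a requested cluster count with leaf order deterministic in protein ID.

Regulator calls use the activation z-score over a signed
regulator→target network: with observed per-protein direction
d ∈ {−1, 0, +1} (sign of the class-mean difference of log2 counts,
computed on quantile-normalized data in the pipeline), a target is
consistent when `edge_sign × d = +1`, and
`z = (N_cons − N_incons)/√N` over the N informative targets (z = 0 when
N = 0). Overlap significance is a one-sided Fisher exact test of the
target set against the analyzed protein set over the background; it
stands in for proprietary network-scoring significance at the same 0.005
gate, and the z semantics are unchanged. The activated band is inclusive
at z = 2.0 — scores of exactly 2 belong with activation, which
reconciles the conventional "|z| > 2" label with scores printed as
exactly 2. Edge evidence is unweighted (±1).

## Synthetic data generator

The generator emulates the processed input of a two-subtype cohort at
study scale: 2000 proteins × (7 + 8) samples, 30 planted modules with
sizes drawn from 15–150 (nudged to tile 90% of the proteome; the
remaining 10% is background), 3 trait-linked modules, integer counts.

Counts for protein i in sample s are negative binomial with mean
`10^(μ_i + λ_i f_m(s))` and dispersion 0.3
(variance = mean + 0.3·mean²), with baseline `μ_i ~ U(1, 4)` on the
log10 scale and loading `λ_i ~ U(0.6, 0.95)`. The base-10 reading of the
baseline range gives mean counts spanning 10–10⁴ — the
several-orders-of-magnitude dynamic range of proteome abundance — and
produces within-module correlations around 0.85–0.95 after the log
transform, the regime in which a high soft power (β = 25) yields
scale-free topology and clean module separation. Module factors
`f_m ~ N(0, 1)` per sample; trait-module factors are
`f_m = β_t x_s + 0.5 ε` with trait effect β_t = 2.0 and the subtype
indicator x. The noise scale 0.5 is calibrated so planted module–trait
correlations sit near 0.9 (BH q ~ 10⁻⁴) — the strength of clearly
subtype-linked modules this pipeline is designed to flag at n = 15; with
unit noise the planted correlation (~0.71) would hover at the edge of
the q < 0.05 gate and recovery rates would measure test power rather
than implementation correctness. All planted trait modules are elevated
in class 1 (SqCC), matching a design focused on modules over-expressed
in one subtype; per-module signs remain available in the API. Background
proteins ride on private noise factors so the tree cut must reject them.
Identical config + seed reproduce counts bit-for-bit.

The causal-network generator assigns each regulator targets drawn from
trait-linked proteins and sets a fraction `consistency` of edge signs to
agree with the targets' planted direction (reversed for planted
"inhibited" regulators), so that with perfect direction observation
`z = (2·consistency − 1)·√N`. The annotation generator plants half of
its terms mostly inside single modules and draws the rest uniformly.

What the generator does **not** emulate: peptide-to-protein inference,
shared peptides, acquisition missingness, batch effects, or covariate
structure. Passing recovery tests therefore demonstrates correctness of
the network chain under a clean factor model, not robustness to
MS-specific artifacts.

## Validation problem sizes

The recovery study runs the full detection chain on 50 generator seeds
at the default scale (2000 × 15, 30 modules): adjusted Rand index
against the planted partition is ≥ 0.8 in ≈ 96% of seeds (mean ≈ 0.90),
and all planted trait modules pass the significance gate with the
correct sign in 100% of seeds. The null study (trait effect 0, no trait
modules, 100 seeds) observes the gate firing for ≈ 0.2% of modules,
far below the 5% bound. Numerical primitives are checked against
independent oracles: triple-loop TOM evaluation (≤ 1e−12), exhaustive
clique enumeration for MCC (200 random graphs ≤ 12 nodes), full
eigendecomposition for eigenprotein variance (≤ 1e−10), hand-computed
and reference BH step-up, exact hypergeometric tail summation, and
closed-form activation-z identities.

## Known limitations

- The tree cut is a static-height approximation; strongly correlated
  modules (notably several modules tracking one trait) can merge, and
  borderline proteins near module edges may be greyed where an adaptive
  cut would keep them.
- With 15 samples, correlation estimates are noisy; the |r| > 0.5 gate is
  meaningful only jointly with the BH q gate.
- Enrichment depends on the annotation collection supplied; no attempt is
  made to reproduce any specific database snapshot.
- The Fisher overlap p is a generic substitute for proprietary
  network-bias-corrected scoring; calls at the 0.005 gate should be read
  as overlap significance, not as a reimplementation of any commercial
  tool's statistic.
- Quantile normalization is exactly idempotent only on tie-free data;
  with heavy ties (many zero counts) repeated application drifts slightly.
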
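# Methods

## Model and assumptions

The package treats drug repositioning as a module-comparison problem: a
drug is represented by the set of genes central to its mode-of-action
subnetwork, a disease by the genes central to its pathophysiology
subnetwork, and a repositioning candidate is a drug whose gene module
helps explain a disease's gene module. The chain of representations is

seed genes → one-hop network expansion → per-source signatures
(literature, expression) → induced subnetworks → above-average-centrality
gene sets → Boolean membership matrices → per-disease sparse logistic
regression → drug-disease scores → ROC/AUC.

Assumptions worth stating explicitly:

* **Gene identifiers are opaque strings.** No synonym or probe mapping is
  performed; inputs are assumed already aggregated to one identifier per
  gene, and co-occurrence tables already aggregated over MeSH/synonym
  variants.
* **Expansion is exactly one hop.** "Functionally related" means direct
  interaction-network neighbors, never transitive closure; a two-path
  seed a with edges a–b–c contributes b but not c. Seeds absent from the
  network are kept (curated knowledge outranks interactome coverage).
* **Induced subnetworks are full induced subgraphs**, including
  neighbor-neighbor edges, so centrality reflects the complete local
  topology. Signature genes missing from the reference survive as
  isolated nodes with centrality 0.
* **Genes are exchangeable observations in the regression.** Each
  disease's fit treats the ~2343 genes as i.i.d. Bernoulli observations;
  no gene weighting, no correlation structure.

## The connectivity score

`connect_score` implements two variants of a regularized log-odds
enrichment measure for entity-gene co-mentions. The default ("modified")
variant, `ln(ABS_DG·max(ABS_D,ABS_G)+λ) − ln(ABS_D+ABS_G+λ)`, avoids the
corpus-size term of the classical form, whose value is rarely well
defined for a filtered abstract collection. λ (default 1) regularizes
zero counts; with λ=1 an all-zero cell scores exactly 0, which motivates
the strict-positivity rule: "positively connected" means score > 0, zero
being the no-information point. The low-count filter (cells < 5 zeroed)
runs before scoring, so a gene with 1–4 co-mentions can never enter a
text signature.

## Expression signatures

Drug replicate rank lists are merged by mean rank (Borda aggregation).
The published upstream procedure cites a hierarchical Kruskal-based
merging whose exact variant is not recoverable; Borda is the simplest
aggregation with the same intent and lives behind a single function
(`merge_ranked_lists`) so an alternative can be swapped in.

Disease case/control matrices are scored with a SAM-style moderated
statistic `d = (x̄_case − x̄_control)/(s + s₀)`, where `s` is the pooled
two-sample standard error and `s₀` (default: median of `s` over genes)
prevents small-variance genes from dominating. The full SAM
permutation/FDR machinery is deliberately absent: downstream only the
ranking of `d` is used. Ties in any ranking are broken by lexicographic
gene id, a determinism choice. Signatures take the k highest- and k
lowest-ranked genes (k = 25, i.e. 50 genes when n ≥ 50).

## Centrality and selection

Degree is the incident-edge count; betweenness is exact unnormalized
shortest-path betweenness; closeness is computed within connected
components as (c−1)/Σd with isolated nodes scoring 0. These conventions
track common graph-tool defaults, but the choice is immaterial to
selection: the rule keeps genes whose score strictly exceeds the
subnetwork mean, and `x > mean-of-others` is algebraically identical to
`x > overall mean` (property-tested in exact rational arithmetic), so any
uniform rescaling — normalized or unnormalized centrality — selects the
same genes. Regular subnetworks (all scores equal) legitimately select
nothing and propagate as all-zero membership rows.

The centrality computations are delegated to networkx; the test suite
checks them against an independent brute-force BFS shortest-path
enumerator on every connected graph with at most six nodes.

## Association model

The published description mixes "logistic regression" with "lasso"; this
package reconciles the two as L1-penalized logistic regression with an
intercept: per disease, response = Boolean gene membership vector,
predictors = all drugs' membership vectors, fit by liblinear
(deterministic at tol 1e-8). The penalty is configurable; the default
"path" picks, per disease, the strength from the grid
{0.05, 0.2, 1, 5, 20} (solver C = 1/penalty) minimizing deviance on a
seeded 25 % gene holdout, then refits on all genes. Degenerate cases are
exact: an all-constant response or an all-zero predictor matrix yields
zero coefficients and intercept = logit of the response mean. Scores are
signed coefficients; only strictly positive coefficients become calls,
since a negative weight has no repositioning interpretation. Source
combination is an element-wise OR of the text and expression membership
matrices per centrality measure (selection-level union), not a union of
subnetworks before centrality.

## Evaluation

AUC is the Mann-Whitney pair-counting probability that a random positive
outscores a random negative with ties counted 1/2, equal to the
trapezoidal ROC area (cross-checked against an independent trapezoidal
implementation). Negatives default to 400 sampled zero-co-occurrence
pairs for user-supplied data; the synthetic world samples 100 from its
390 unplanted pairs.

## The synthetic world

The generator emulates every pipeline input with planted ground truth.
Defaults: 2343 genes, 50 drugs, 8 diseases, 10 planted pairs sharing
20-gene modules; preferential-attachment reference networks (m = 3) per
source; overdispersed negative-binomial co-mention counts (base mean 0.8,
size 2) with planted cells' mean multiplied by the enrichment factor
(default 20); expression shifts of ±4 noise standard deviations applied
to half the module (up) and half (down) in 3 drug replicates and 4 case
samples; 10 extra random seed genes per entity. Planted modules are
biased toward the high-degree decile (probability 0.7) and receive
intra-module edges (probability 0.3 per pair, per source network), so
centrality selection has signal to find — mirroring the premise that hub
genes are the informative representation. The 50-drug/8-disease scale
keeps a full end-to-end run in the low minutes on one CPU while
preserving the published gene-universe size.

A deliberate generator contract: a planted pair has generative
consequences only through its active signal channels. With enrichment 1.0
and shift 0 the planted pairs are labels with no footprint — no module
seeds, no cohesion edges, background counts and noise expression — so
null-world recovery is chance by construction. Each planted pair can
carry signal in both sources or in one only (`frac_text_only`,
`frac_expr_only`), which builds the complementary-signal scenario where
OR-combining sources should dominate either alone.

What the world does **not** emulate: real literature count distributions,
platform/batch effects, probe-level noise, correlated expression between
functionally related genes, or the incompleteness and ascertainment bias
of curated seed databases. Passing recovery tests therefore demonstrates
that the pipeline's machinery is correct and sensitive to the signal
classes it targets, not that real-data AUCs of any particular magnitude
are expected.

## Numerical choices and degenerate inputs

* Ranks are 1-based permutations; normalized rank is (r−1)/(n−1), with a
  single-gene universe mapping to 0.
* Zero-variance genes with s₀ = 0 define d = 0 rather than NaN.
* Empty text signatures (no positively scored gene) produce a warned
  all-zero membership row instead of aborting a batch run.
* All randomness flows through explicit integer seeds; there is no global
  random state. Derived seeds stay below 2³¹.

## Known limitations

* Borda merging is a stand-in for the cited hierarchical rank
  aggregation; results may differ where replicate lists disagree
  strongly.
* The per-disease fits are independent; no information is shared across
  diseases (no multi-task structure, no stability selection).
* The penalty grid is coarse by design; users needing a tuned penalty
  should pass an explicit value.
* Betweenness on very large dense subnetworks is the runtime bottleneck
  (Brandes is O(nm) per graph).
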
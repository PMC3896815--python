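# netrepos

Network-based drug repositioning: predict new disease indications for
known drugs by comparing the gene modules that represent each drug and
each disease in protein interaction networks.

## Who this is for

Computational biologists and cheminformaticians who have, per drug and per
disease: curated seed genes (drug targets, disease genes), literature
co-mention counts with genes, and expression data (ranked drug-treatment
profiles, case/control disease microarrays) — and want a reproducible
pipeline from those inputs to ranked drug-disease association scores. A
built-in synthetic-world generator with planted associations makes every
stage testable without any database access.

## The method

1. **Seed expansion.** Each entity's seed genes are extended by their
   direct neighbors in a functional protein network (one hop; lists
   `DrugExt`, `DiseaseExt`).
2. **Text route.** Entity-gene abstract co-mention counts below 5 are
   zeroed, then scored with a regularized log-odds connectivity measure

   `Connect_DG = ln(ABS_DG · max(ABS_D, ABS_G) + λ) − ln(ABS_D + ABS_G + λ)`,  λ = 1,

   where `ABS_DG` is the co-mention abstract count and `ABS_D`, `ABS_G`
   the marginal mention counts. Genes with a strictly positive score form
   the entity's text signature. (The classical corpus-size variant
   `ln(ABS_DG·N+λ) − ln(ABS_G·ABS_D+λ)` is also available.)
3. **Expression route.** Drug replicate rank lists (rank 1 = most
   up-regulated) are Borda-merged; disease case/control matrices are
   scored with a SAM-style moderated statistic
   `d = (x̄_case − x̄_control)/(s + s₀)` and ranked. The 25 highest and 25
   lowest ranked genes form the expression signature.
4. **Subnetworks and centrality.** Each signature is looked up in a
   source-specific reference network; the induced subgraph over signature
   genes plus direct neighbors is scored with degree, betweenness, and
   closeness centrality, and genes strictly above the mean centrality are
   kept. This yields six Boolean entity×gene membership matrices
   ({text, expression} × {degree, betweenness, closeness}), plus
   OR-combined ones.
5. **Association.** Per disease, an L1-penalized logistic regression
   writes the disease's Boolean gene vector as a sparse combination of all
   drugs' gene vectors (genes are observations, drugs predictors). The
   signed coefficient is the association score; strictly positive
   coefficients are repositioning calls.
6. **Evaluation.** ROC/AUC of the scores for gold-standard positive pairs
   against sampled zero-co-occurrence negative pairs.

## Worked example

`examples/04_end_to_end.py` generates a 300-gene world with 3 planted
drug-disease pairs and runs the full pipeline:

```
world: {'n_genes': 300, 'n_drugs': 10, 'n_diseases': 3, ..., 'n_planted_pairs': 3, ...}
planted pairs: [('dis00', 'drug001'), ('dis00', 'drug004'), ('dis02', 'drug006')]

recovery AUC by configuration (planted pairs vs sampled negatives):
  text        degree   0.983
  expression  degree   0.883
  combined    degree   0.867

association scores of the planted pairs (positive = called):
  dis00 ~ drug001: +3.126
  dis00 ~ drug004: +2.366
  dis02 ~ drug006: +6.611
```

An AUC near 1 means the regression ranks the planted pairs above the
unplanted background; the positive coefficients are the recovered calls.
The other examples walk through each stage: `01_literature_scoring.py`
(log-odds scores on a five-gene table), `02_expression_signatures.py`
(rank merging and SAM scoring), `03_subnetwork_centrality.py` (induction
and the above-average selection rule).

A thin CLI mirrors the stages (`netrepos simulate | expand | score-text |
score-expr | subnet | centrality | associate | evaluate`); run
`netrepos --help`.

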
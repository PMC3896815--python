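"""End-to-end drug repositioning on a synthetic world.

Generates a small world with planted drug-disease associations, runs the
full pipeline (seed expansion, text and expression signatures, subnetwork
centrality, sparse logistic association), and evaluates recovery by AUC.
"""

import logging

import netrepos as nr
from netrepos.pipeline import run_pipeline

logging.disable(logging.WARNING)

world = nr.generate(
    nr.WorldConfig(
        n_genes=300, n_drugs=10, n_diseases=3, n_planted_pairs=3,
        module_size=10, n_negatives=20, rng_seed=1,
    )
)
print("world:", nr.world_report(world))
print("planted pairs:", sorted(world.planted))

result = run_pipeline(world, nr.PipelineConfig(seed=1), measures=("degree",))

print("\nrecovery AUC by configuration (planted pairs vs sampled negatives):")
for (source, measure), auc in result.aucs.items():
    print(f"  {source:11s} {measure:8s} {auc:.3f}")

assoc = result.associations[("combined", "degree")]
print("\nassociation scores of the planted pairs (positive = called):")
for dis, drg in sorted(world.planted):
    print(f"  {dis} ~ {drg}: {assoc.score_of(dis, drg):+.3f}")
# An AUC near 1 means the regression coefficients rank the planted pairs
# above the unplanted background pairs almost perfectly.
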
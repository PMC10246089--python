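"""Multilayer community detection with significance and specialist calls.

Runs the full detection stack on the default planted scenario (4 tissues,
60 genes, three generalist blocks, one pancreas-specialist block): supra-
modularity matrix at resolution 1, consensus over seeded GenLouvain runs,
closed-form Z scores for each community's intralayer weight, and the
specialist fraction per community.
"""

from sklearn.metrics import adjusted_rand_score

from coexmux import (
    build_multilayer,
    build_supra_modularity,
    community_summary,
    detect_communities,
    fit_configuration_model,
    planted_multilayer_expression,
    significance_table,
)

dataset = planted_multilayer_expression(seed=0)
mlc = build_multilayer(dataset.layers)
nulls = [
    fit_configuration_model(mlc.rho[a], layer_name=name)
    for a, name in enumerate(mlc.layer_names)
]
supra = build_supra_modularity(mlc, nulls, gamma=1.0)
partition = detect_communities(supra, n_runs=50, seed=0)

ari = adjusted_rand_score(dataset.truth_partition.labels, partition.labels)
print(f"{partition.n_communities} communities; "
      f"adjusted Rand index vs planted truth: {ari:.3f}")
records = {r.label: r for r in significance_table(partition, mlc, nulls)}
print("community  nodes  specialist_fraction  tissue     class       Z")
for label, nodes in sorted(partition.communities().items()):
    s = community_summary(label, nodes)
    z = records[label].z
    z_text = f"{z:.1f}" if z is not None else "undefined"
    print(f"{label:>9}  {s.n_nodes:>5}  {s.specialist_fraction:>19.3f}  "
          f"{(s.specialist_tissue or 'N/A'):<9}  {s.klass:<10}  {z_text}")
# The three generalist blocks appear as 48-node communities spanning all
# four tissues (fraction 0), the specialist block as a 10-node pancreas
# community with fraction 1, and the background genes as one diffuse
# community; all planted communities carry Z far above 5.
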
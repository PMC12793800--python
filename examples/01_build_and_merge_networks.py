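"""Build tripartite herb-compound-target networks and combine databases.

Generates a small pseudo-database ensemble sharing one latent network,
then compares union vs intersection aggregation of the compound-target
layer — the trade-off between coverage and precision when integrating
multiple herbal databases.
"""

from npbench import SyntheticConfig, generate_all, merge_databases

dataset = generate_all(SyntheticConfig(n_databases=3, seed=0))
latent = dataset.truth.latent
print(f"latent network: {len(latent.herbs)} herbs, "
      f"{len(latent.compounds)} compounds, {len(latent.targets)} targets, "
      f"{len(latent.hc_edges)} HC + {len(latent.ct_edges)} CT edges")

for db in dataset.databases:
    print(f"  {db.db_label}: {len(db.hc_edges)} HC, {len(db.ct_edges)} CT edges")

union = merge_databases(dataset.databases, mode="union", layer="ct")
inter = merge_databases(dataset.databases, mode="intersection", layer="ct")

true_ct = latent.ct_edges
for net, name in ((union, "union"), (inter, "intersection")):
    kept = len(net.ct_edges)
    correct = len(net.ct_edges & true_ct)
    print(f"{name:>12}: {kept} CT edges, {correct} truly in the latent network "
          f"(precision {correct / kept:.2f}, "
          f"recall {correct / len(true_ct):.2f})")

# Intersection keeps only edges every database agrees on: higher precision,
# lower recall. Union recovers nearly all true edges but admits each
# database's spurious ones — the same trade-off seen with real databases.
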
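"""Build a consensus pharmacophore from an ensemble of aligned complexes.

Generates the stock synthetic ensemble (14 complexes, 19 planted interaction
sites), perceives interaction-filtered features per complex, clusters them,
and retains the clusters present in more than 60 % of complexes.
"""
from sbpharm import (build_model, cluster_features, excluded_volumes_for,
                     make_complex_ensemble, perceive, select_clusters)
from sbpharm.fixtures import table1_spec

complexes = make_complex_ensemble(table1_spec(seed=7, noise_sd=0.3))
features = [f for cx in complexes for f in perceive(cx)]
print(f"{len(features)} features perceived over {len(complexes)} complexes")

clusters = cluster_features(features, cluster_radius=2.0, n_complexes=14)
print(f"{len(clusters)} feature clusters:")
for c in clusters:
    print(f"  {c.cluster_id:<5} {c.kind:<4} count {c.count:>2}  "
          f"frequency {c.frequency:>3}%")

selected = select_clusters(clusters, threshold=60)
evs = excluded_volumes_for(complexes)
model = build_model(selected, evs, {"n_complexes": 14, "threshold": 60})
print(f"\nretained {len(model.features)} features (> 60% of complexes) "
      f"and {len(model.excluded_volumes)} excluded volumes")
# Count and frequency say in how many of the 14 complexes each recurrent
# interaction appears; only the recurrent ones define the screenable model.
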
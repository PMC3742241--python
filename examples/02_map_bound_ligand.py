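"""Validate a model by re-finding a bound pose from a scrambled conformer.

A ligand whose feature points satisfy the model is rigidly scattered; the
mapper must recover a pose whose heavy-atom RMSD to the bound geometry is
near zero and whose fit value is near the maximum (one point per feature).
"""
import numpy as np

from sbpharm import (ConformerSet, bound_vs_mapped_rmsd, build_model,
                     cluster_features, excluded_volumes_for,
                     make_complex_ensemble, map_molecule, perceive,
                     select_clusters)
from sbpharm.fixtures import _active_ligand, table1_spec
from sbpharm.geometry import RigidTransform, random_rotation

complexes = make_complex_ensemble(table1_spec(seed=7))
clusters = cluster_features([f for c in complexes for f in perceive(c)],
                            n_complexes=14)
model = build_model(select_clusters(clusters), excluded_volumes_for(complexes),
                    {"n_complexes": 14})

rng = np.random.default_rng(1)
bound = _active_ligand(model, rng, jitter=0.0)   # bound pose, model frame
tf = RigidTransform(random_rotation(rng), rng.uniform(-20, 20, 3))
conformer = tf.apply(bound.coords)               # what a conformer file holds

result = map_molecule(ConformerSet("ligand", bound, [conformer]), model)
heavy = bound.heavy_indices()
mapped = result.transform.apply(conformer[heavy])
rmsd = bound_vs_mapped_rmsd(bound.coords[heavy], mapped)

print(f"fit value          : {result.fit:.3f} (max {len(model.features)})")
print(f"bound-vs-mapped RMSD: {rmsd:.3f} A")
# A fit near the feature count and an RMSD near zero mean the model pins
# down the bioactive pose from geometry alone.
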
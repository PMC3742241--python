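"""Pharmacophore-based virtual screening of a multi-conformer SDF library.

Builds the stock model, generates a library of 10 planted actives and 90
structural decoys (each decoy lacks one required feature kind), and ranks
every molecule by its best-over-conformers geometric fit value.
"""
from sbpharm import (build_model, cluster_features, excluded_volumes_for,
                     make_complex_ensemble, make_library, perceive,
                     read_library_sdf, screen_library, select_clusters)
from sbpharm.fixtures import table1_spec

complexes = make_complex_ensemble(table1_spec(seed=7))
clusters = cluster_features([f for c in complexes for f in perceive(c)],
                            n_complexes=14)
model = build_model(select_clusters(clusters), excluded_volumes_for(complexes),
                    {"n_complexes": 14})

sdf_text = make_library(model, n_actives=10, n_decoys=90, seed=7)
library = read_library_sdf(sdf_text)
hits = screen_library(library, model, top_k=1000)

print(f"{len(hits)} of {len(library)} molecules map all "
      f"{len(model.features)} features")
for h in hits:
    print(f"  rank {h.rank:>2}  {h.molecule_id}  fit {h.best.fit:.3f}  "
          f"conformer {h.best.conformer_index}")
# Only molecules covering every model feature inside its tolerance sphere
# (and clear of all excluded volumes) appear; decoys are absent by design.
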
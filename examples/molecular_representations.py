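"""Fingerprints, molecular graphs and Tanimoto similarity.

Builds both molecular representations for a few drug-like molecules and
reports their pairwise Tanimoto similarity and graph sizes.
"""

import numpy as np

from molnp.molrep import (max_similarity_to_reference, smiles_to_fingerprint,
                          smiles_to_graph, tanimoto)

molecules = {
    "paracetamol": "CC(=O)Nc1ccc(O)cc1",
    "phenacetin": "CCOc1ccc(NC(C)=O)cc1",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
}

fps = {name: smiles_to_fingerprint(smi) for name, smi in molecules.items()}
print("pairwise Tanimoto similarity (1024-bit Morgan, radius 3):")
names = list(molecules)
for i, a in enumerate(names):
    for b in names[i + 1:]:
        print(f"  {a} vs {b}: {tanimoto(fps[a], fps[b]):.3f}")
# Values near 1 mean overlapping substructures; paracetamol/phenacetin
# share the acetanilide core, caffeine is structurally distant.

print("\ngraph featurization:")
for name, smi in molecules.items():
    g = smiles_to_graph(smi)
    print(f"  {name}: {g.n_atoms} heavy atoms, "
          f"{len(g.bond_features) // 2} bonds, "
          f"atom feature dim {g.atom_features.shape[1]}")

sims = max_similarity_to_reference([fps["caffeine"]],
                                   [fps["paracetamol"], fps["phenacetin"]])
print(f"\ncaffeine's closest neighbour similarity: {sims[0]:.3f}")
print("1 minus this value is the Tanimoto distance used for "
      "applicability-domain buckets.")
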
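"""Turn a SMILES string into the directed graph the encoder consumes.

Aspirin has 13 heavy atoms and 13 bonds, hence 26 directed bond states;
every directed bond is paired with its reverse, which the
message-passing update excludes to prevent message echo.
"""

from aampnn import compute_ecfp, featurize_molecule

graph = featurize_molecule("CC(=O)Oc1ccccc1C(=O)O")
print(f"molecule: {graph.smiles_canonical}")
print(f"heavy atoms: {graph.n_atoms}")
print(f"directed bonds: {graph.n_directed_bonds}")
print(f"atom feature width: {graph.atom_features.shape[1]} "
      "(one-hot blocks + mask slot)")
print(f"reverse pair of bond 0: bond {graph.reverse_index[0]}")

fp = compute_ecfp("CC(=O)Oc1ccccc1C(=O)O")
print(f"ECFP (radius {fp.radius}, {fp.n_bits} bits): "
      f"{int(fp.bits.sum())} bits set")
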
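"""Assemble fixed-length feature vectors for an enzyme–substrate pair.

Pools a per-residue embedding matrix into a protein vector (mean pooling),
assembles a molecule vector from the last/penultimate layers of a SMILES
encoder (mean + max pooling + both first-position rows), and concatenates
them — here with the deterministic synthetic embedder at the reference
dimensions (1024 per residue, 256 per SMILES symbol).
"""

from kinpred import PairFeaturizer, SyntheticHashEmbedder, append_condition

embedder = SyntheticHashEmbedder(protein_token_dim=1024, molecule_token_dim=256, seed=0)
featurizer = PairFeaturizer(embedder)

sequence = "MKVLAACDEFHIKNQRSTVW"
smiles = "CC(=O)Oc1ccccc1"  # aspirin

protein = featurizer.protein_vector(sequence)
molecule = featurizer.molecule_vector(smiles)
pair = featurizer.pair_vector(sequence, smiles)
with_ph = append_condition(pair, 7.4)

print(f"protein vector:  {protein.dim} dims (mean pooling over {len(sequence)} residues)")
print(f"molecule vector: {molecule.dim} dims (4 blocks of 256)")
print(f"pair vector:     {pair.dim} dims (protein block then molecule block)")
print(f"pair + pH:       {with_ph.dim} dims, last entry = {with_ph.values[-1]}")
# The pair vector is what the kinetics regressor consumes; the 2049-d variant
# feeds the condition-aware base model of the environmental-factor stack.
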
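"""Mol2vec-style substructure embeddings on a small synthetic corpus.

Each molecule becomes a sentence of Morgan substructure identifiers (one
per heavy atom per radius 0..1); a skip-gram model embeds the identifiers
and a molecule vector is the sum of its word vectors (100-dimensional).
"""

from fpbow import sentence, train_embeddings
from fpbow.mol2vec import corpus, embed_molecules
from fpbow.synthetic import SyntheticConfig, generate

ds, _ = generate(SyntheticConfig(n_molecules=100, seed=0))

s = sentence(ds.smiles[0], radius=1)
print(f"{ds.smiles[0]}: {len(s.words)} substructure words (atoms x 2 radii)")

table = train_embeddings(corpus(ds.smiles), dim=100, epochs=2, seed=0)
print(f"embedding table: {len(table)} substructures -> {table.dim}-d vectors")

vectors = embed_molecules(ds.smiles[:5], table)
print(f"molecule vectors: {vectors.shape}  (row = sum of its word vectors)")
print("first molecule, first 4 components:", [round(float(x), 4) for x in vectors[0, :4]])
# These 100-d vectors are the dense alternative to fingerprints and feed
# the same extractors and classifiers.
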
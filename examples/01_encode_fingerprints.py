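"""Densify a sparse molecular fingerprint into a bag-of-words code sequence.

A 2048-bit Morgan fingerprint of a drug-like molecule sets only a few
dozen bits.  Treating each set bit n as the integer code n+1 turns the
sparse vector into a short "sentence" an embedding layer can consume;
padding with the reserved code 0 makes a batch rectangular.
"""

import numpy as np

from fpbow import decode, encode, morgan_fp, pad

smiles = ["CCO", "c1ccc(S(=O)(=O)N)cc1", "c1ccc2c(c1)cc(N(C)C)cc2"]
seqs = []
for smi in smiles:
    fp = morgan_fp(smi)  # radius 2, 2048 bits
    seq = encode(fp)
    seqs.append(seq)
    print(f"{smi:30s} bits set: {fp.popcount:3d}  first codes: {seq.codes[:5].tolist()}")

matrix = pad(seqs)
print(f"\npadded token matrix: {matrix.rows.shape} (pad length {matrix.l_pad}, pad code 0)")
print(f"embedding vocabulary: {matrix.vocabulary_size} (codes 0..2048)")

round_trip = all(np.array_equal(decode(s), morgan_fp(smi).bits) for s, smi in zip(seqs, smiles))
print(f"decode(encode(fp)) == fp for every molecule: {round_trip}")
# The sentence lengths above are the popcounts; the matrix is what the
# 1D-CNN / LSTM extractors consume.
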
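"""Build the two codebook families and inspect their error-correcting margins.

Run:  python examples/01_codebooks.py
"""
import numpy as np

from ecoc_tka.codes import (
    assign_hadamard_codewords,
    build_hadamard_matrix,
    codebook_min_distance,
    enumerate_hamming_codewords,
    error_correcting_capability,
    positive_ratio_per_bit,
    select_hamming_codewords,
)

# Hadamard-16: constant pairwise distance 8 -> corrects any 3 bit errors
m = build_hadamard_matrix(16)
d = codebook_min_distance(m)
print(f"Hadamard-16: {m.shape[0]} rows, d_min = {d}, corrects t = {error_correcting_capability(d)} bit errors")

# (15, 11) Hamming code: 2048 codewords, d_min = 3 -> a single-error corrector
cw = enumerate_hamming_codewords(4)
print(f"(15,11) Hamming: {cw.shape[0]} codewords of length {cw.shape[1]}, d_min = {codebook_min_distance(cw)}")

# Greedy selection of 8 class codewords from the Hamming code
words, dist_min = select_hamming_codewords(8)
print(f"selected 8 Hamming codewords with guaranteed pairwise distance >= {dist_min}")

# Hadamard row assignment for 8 classes with bell-shaped frequencies:
# the balance objective drives every binary task's positive ratio toward 0.5
freqs = np.array([0.04, 0.09, 0.16, 0.21, 0.21, 0.16, 0.09, 0.04])
cb = assign_hadamard_codewords(freqs, 16, seed=0)
ratios = positive_ratio_per_bit(cb, freqs)[cb.active_bits]
print(f"assigned codebook: {int(cb.active_bits.sum())} active bits, "
      f"positive ratios {np.round(ratios, 2)}")
print("(ratios near 0.5 mean each binary classifier trains on a balanced task)")
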
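"""Mutation burden, signature refitting, and the UV dipyrimidine fraction.

Draws a mutation spectrum from a known mixture of mutational processes,
refits it by nonnegative least squares against the synthetic catalog, and
computes the footprint-normalized burden and the UV-type event fraction.
"""

import numpy as np

from csccqc import fit_signature_weights, mutation_burden, synthetic_signature_matrix
from csccqc.signatures import uv_content_of_mixture

sigs = synthetic_signature_matrix()
true_w = np.zeros(len(sigs.columns))
for name, wv in (("UV", 0.6), ("APOBEC", 0.3), ("FLAT", 0.1)):
    true_w[sigs.columns.get_loc(name)] = wv

rng = np.random.default_rng(3)
n_mutations = 4000
spectrum = rng.multinomial(n_mutations, sigs.to_numpy() @ true_w)

att = fit_signature_weights(spectrum.astype(float), sigs)
print(f"{'signature':10s} {'true':>6s} {'fit':>6s}")
for name, tw in zip(sigs.columns, true_w):
    print(f"{name:10s} {tw:6.2f} {att.weights[name]:6.3f}")
print(f"unattributed: {att.unattributed:.4f}   "
      f"reconstruction error: {att.reconstruction_error:.2e}")
print("-> weights are the estimated share of mutations caused by each process")

burden = mutation_burden(n_mutations, 40_000_000)
print(f"\nburden: {burden:.1f} mutations/Mb over a 40 Mb callable footprint")
print(f"expected UV-type fraction of this mixture: "
      f"{uv_content_of_mixture(sigs, true_w):.3f} "
      "(C>T at the 3' base of a dipyrimidine)")
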
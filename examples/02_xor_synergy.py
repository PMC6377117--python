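"""Measure pairwise synergy that no single-gene statistic can see.

Builds the XOR construction -- two genes carrying latent bits whose XOR is
the class label -- and compares each gene's individual mutual information
with the class against the pair's interaction information, both computed
on the three-state (mu +/- sigma) discretized values.
"""

import numpy as np

from igisplus import SyntheticSpec, generate, interaction_information, mutual_information
from igisplus.data_io import discretize

# exact, noiseless case: the uniform 4-point XOR distribution
x1 = np.array([0, 0, 1, 1])
x2 = np.array([0, 1, 0, 1])
c = x1 ^ x2
print("noiseless XOR:")
print(f"  I(x1; c) = {mutual_information(x1, c):.3f} bits (individually useless)")
print(f"  II(x1; x2; c) = {interaction_information(x1, x2, c):.3f} bits "
      "(the pair determines the class)")

# generated construction: bits + Gaussian noise, discretized at mu +/- sigma
mis, iis = [], []
for seed in range(20):
    spec = SyntheticSpec(n_samples=200, n_genes=10, xor_pairs=((0, 1),), seed=seed)
    data, _ = generate(spec)
    states = discretize(data).states
    mis.append(mutual_information(states[:, 0], data.labels))
    iis.append(interaction_information(states[:, 0], states[:, 1], data.labels))

print("generated construction (noise SD 0.1, M=200, 20 seeds):")
print(f"  mean individual MI      = {np.mean(mis):.3f} bits")
print(f"  mean pair interaction   = {np.mean(iis):.3f} bits")
print("A candidate-ranking criterion that adds interaction information "
      "can therefore surface a gene whose value only shows with a partner.")
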
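"""Unique peak matching with the discrete genetic algorithm.

Generates two related synthetic spectra, evolves a unique peak-to-peak
matching with the medium preset, and compares the evolved cost with the
exact assignment optimum.
"""

import numpy as np

from hsqcmatch import GAConfig, Spectrum, dga_similarity, optimal_assignment

rng = np.random.default_rng(7)
n = 12
h = rng.uniform(0.5, 9.0, n)
c = rng.uniform(10.0, 160.0, n)
p = Spectrum.from_shifts("parent", h, c)
# a "derivative": same peaks with small chemical-shift perturbations
q = Spectrum.from_shifts(
    "derivative", h + rng.normal(0, 0.03, n), c + rng.normal(0, 0.3, n)
)

cfg = GAConfig(preset="medium", seed=42)
res = dga_similarity(p, q, cfg)
_, optimum = optimal_assignment(p, q)

print(f"DGA similarity (three-level metric): {res.final_score:.4f}")
print(f"evolved raw cost: {res.evaluation.epsilon_s:.6f}  "
      f"exact optimum: {optimum:.6f}")
print(f"cost evaluations (NFE): {res.nfe}   generations: {res.generations}")
print(f"outliers rejected: {int(res.evaluation.outlier_flags.sum())}")
print("\nbest matching (p peak -> q peak):",
      " ".join(f"{i}->{j}" for i, j in enumerate(res.matching.assignment)))
print("\nA score near 0 with the evolved cost at the optimum means the GA")
print("recovered the true peak correspondence despite the shift jitter.")
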
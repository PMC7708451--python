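"""Raw counts -> modelling target: TPM, filters, Box-Cox, length de-bias.

Shows each step of the expression pipeline on a tiny raw-count matrix.
"""

import numpy as np

from reggrammar import expression as ex

rng = np.random.default_rng(0)
n_genes, n_exp = 200, 12
lengths = rng.integers(300, 3000, n_genes).astype(float)
true_level = rng.lognormal(4, 1.5, n_genes)
counts = rng.poisson(true_level[:, None] * rng.uniform(0.8, 1.2, (n_genes, n_exp)))
counts[0] = 0  # a silent gene, to be removed by the abundance filter

raw = ex.ExpressionMatrix([f"g{i}" for i in range(n_genes)],
                          [f"e{j}" for j in range(n_exp)], counts)
tpm = ex.tpm_matrix(raw, lengths)
print(f"TPM column sums: {tpm.values.sum(axis=0)[:3]} (all 1e6)")

kept, summaries = ex.filter_genes(tpm, min_tpm=5, rsd_max=1)
print(f"kept {len(kept)}/{n_genes} genes after TPM>=5 and RSD<1 filters")

kept_lengths = lengths[[int(g[1:]) for g in kept]]
target, transform = ex.median_target(summaries, kept_lengths)
print(f"Box-Cox lambda (MLE): {transform.lmbda:.3f}")
r = np.corrcoef(target, np.log10(kept_lengths))[0, 1]
print(f"correlation of target with log10 ORF length after de-bias: {r:.1e}")
# The target is the length-corrected Box-Cox median TPM: the quantity
# the sequence model is trained to predict. The de-bias step removes
# the technical coupling between fragment-based counts and gene length.
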
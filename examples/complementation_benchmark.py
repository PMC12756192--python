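"""Predict which candidate ortholog complements a deleted gene.

Builds a synthetic cross-species complementation benchmark (50 cases; per
case one "yeast" protein and two candidate orthologs, the functionally
nearer of which is the true complementer), then predicts the complementer
from cosine similarity of pooled residue embeddings, for mean pooling and
sliced-Wasserstein (SWE) pooling, across increasing residue noise.
"""

from plmsim import (
    SyntheticCaseSpec,
    gen_complementation_benchmark,
    make_swe_config,
    run_complementation_benchmark,
)

swe_cfg = make_swe_config(d=16, L=64, M=128, seed=0)

print("accuracy of complementer prediction (50 cases per condition)")
print(f"{'noise SD':>9}  {'mean pooling':>13}  {'SWE pooling':>12}")
for sigma in (0.0, 0.5, 2.0, 10.0):
    spec = SyntheticCaseSpec(n_cases=50, sigma_noise=sigma, delta_func=1.0, seed=1)
    cases, embeddings = gen_complementation_benchmark(spec)
    row = []
    for method in ("mean", "swe"):
        res = run_complementation_benchmark(cases, embeddings, method=method, swe_cfg=swe_cfg)
        row.append(f"{res.n_correct}/{res.n_total}")
    print(f"{sigma:>9}  {row[0]:>13}  {row[1]:>12}")

print(
    "\nWith no residue noise the geometry forces a perfect score; accuracy"
    "\ndecays toward chance (25/50) as noise swamps the functional shift."
)
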
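"""End-to-end complementation benchmark: pool, score, tally.

Convenience layer tying the pooling and similarity stages together for a set
of complementation cases with per-protein residue-embedding matrices.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .pooling import SWEConfig, mean_pool, swe_pool
from .similarity import BenchmarkResult, ComplementationCase, evaluate_benchmark, predict_complementing

__all__ = ["pool_embeddings", "run_complementation_benchmark"]


def pool_embeddings(
    embeddings: Mapping[str, np.ndarray],
    method: str = "mean",
    swe_cfg: SWEConfig | None = None,
) -> dict[str, np.ndarray]:
    """Pool every protein's residue matrix with one method ("mean" or "swe")."""
    if method == "mean":
        return {pid: mean_pool(m) for pid, m in embeddings.items()}
    if method == "swe":
        if swe_cfg is None:
            raise ValueError("swe pooling requires a SWEConfig")
        return {pid: swe_pool(m, swe_cfg) for pid, m in embeddings.items()}
    raise ValueError(f"unknown pooling method {method!r}")


def run_complementation_benchmark(
    cases: Sequence[ComplementationCase],
    embeddings: Mapping[str, np.ndarray],
    method: str = "mean",
    swe_cfg: SWEConfig | None = None,
) -> BenchmarkResult:
    """Pool residue matrices, predict each case's complementer, tally accuracy."""
    pooled = pool_embeddings(embeddings, method=method, swe_cfg=swe_cfg)
    predictions = [predict_complementing(case, pooled) for case in cases]
    return evaluate_benchmark(cases, predictions)
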
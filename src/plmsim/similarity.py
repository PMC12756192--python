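"""Cosine-similarity scoring of protein pairs and the complementation benchmark.

Cross-species complementation experiments — deleting an essential yeast gene
and testing which of several candidate orthologs from another species
rescues the deletion — give a gold-standard readout of functional
near-equivalence.  If sequence embeddings capture function, the
complementing candidate should be the one whose pooled embedding has the
highest cosine similarity to the yeast protein's.  This module scores
candidates, tallies benchmark accuracy, and compares paired accuracy series
(e.g. SWE pooling vs mean pooling across models) with an exact Wilcoxon
signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComplementationCase",
    "PredictionResult",
    "BenchmarkResult",
    "TIE",
    "cosine",
    "predict_complementing",
    "evaluate_benchmark",
    "wilcoxon_signed_rank",
    "read_cases_tsv",
    "write_cases_tsv",
]

#: Sentinel prediction when two candidates are exactly tied.
TIE = "TIE"


@dataclass(frozen=True)
class ComplementationCase:
    """One yeast protein, >= 2 candidate orthologs, and the known complementer."""

    yeast_id: str
    candidate_ids: tuple[str, ...]
    complementing_id: str
    source: str = ""

    def __post_init__(self) -> None:
        cands = tuple(self.candidate_ids)
        if len(cands) < 2:
            raise ValueError("a case needs at least two candidate orthologs")
        if len(set(cands)) != len(cands):
            raise ValueError("candidate ids must be distinct")
        if self.complementing_id not in cands:
            raise ValueError("complementing_id must be one of the candidates")
        object.__setattr__(self, "candidate_ids", cands)


@dataclass(frozen=True)
class PredictionResult:
    case_id: str
    similarities: dict[str, float] = field(default_factory=dict)
    predicted_id: str = TIE
    correct: bool = False


def cosine(u, v) -> float:
    """Cosine similarity dot(u, v) / (||u|| ||v||), in [-1, 1]."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for zero-norm vectors")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def predict_complementing(
    case: ComplementationCase, embeddings: Mapping[str, np.ndarray]
) -> PredictionResult:
    """Predict the complementing candidate as argmax cosine to the yeast protein.

    An exact tie for the maximum yields the sentinel ``TIE`` and is scored
    incorrect: a tie carries no prediction.
    """
    try:
        yeast_vec = embeddings[case.yeast_id]
        sims = {cand: cosine(yeast_vec, embeddings[cand]) for cand in case.candidate_ids}
    except KeyError as exc:
        raise KeyError(f"missing embedding for {exc.args[0]!r} in case {case.yeast_id}") from exc
    best = max(sims.values())
    winners = [cand for cand, s in sims.items() if s == best]
    if len(winners) > 1:
        return PredictionResult(case_id=case.yeast_id, similarities=sims)
    return PredictionResult(
        case_id=case.yeast_id,
        similarities=sims,
        predicted_id=winners[0],
        correct=winners[0] == case.complementing_id,
    )


@dataclass(frozen=True)
class BenchmarkResult:
    n_correct: int
    n_total: int
    table: pd.DataFrame

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_total


def evaluate_benchmark(
    cases: Sequence[ComplementationCase], predictions: Sequence[PredictionResult]
) -> BenchmarkResult:
    """Tally predictions over a case set; the per-case table carries similarities."""
    if len(cases) == 0:
        raise ValueError("empty case set")
    if len(predictions) != len(cases):
        raise ValueError(f"{len(cases)} cases but {len(predictions)} predictions")
    rows = []
    for case, pred in zip(cases, predictions):
        if pred.case_id != case.yeast_id:
            raise ValueError(f"prediction for {pred.case_id} does not match case {case.yeast_id}")
        rows.append(
            {
                "yeast_id": case.yeast_id,
                "predicted_id": pred.predicted_id,
                "complementing_id": case.complementing_id,
                "correct": pred.correct,
                **{f"sim_{c}": pred.similarities.get(c, np.nan) for c in case.candidate_ids},
            }
        )
    table = pd.DataFrame(rows)
    return BenchmarkResult(n_correct=int(table["correct"].sum()), n_total=len(cases), table=table)


def wilcoxon_signed_rank(
    paired_a: Sequence[float],
    paired_b: Sequence[float],
    *,
    zero_method: str = "discard",
    exact_limit: int = 25,
) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Differences ``a - b`` are ranked by absolute value (average ranks on
    ties).  Zero differences are discarded by default (classic Wilcoxon);
    ``zero_method="pratt"`` keeps them for ranking but drops them from the
    statistic.  Up to ``exact_limit`` nonzero pairs the null distribution of
    W+ is computed exactly by enumerating all sign assignments (via the
    generating polynomial over doubled ranks, equivalent to the 2^n
    enumeration); beyond that a normal approximation with tie-corrected
    variance and continuity correction is used.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    if a.size < 1:
        raise ValueError("at least one pair is required")
    d = a - b
    if zero_method not in {"discard", "pratt"}:
        raise ValueError("zero_method must be 'discard' or 'pratt'")
    if zero_method == "discard":
        d = d[d != 0.0]
        if d.size == 0:
            raise ValueError("no nonzero differences")
        ranks = stats.rankdata(np.abs(d))
    else:
        if np.all(d == 0.0):
            raise ValueError("no nonzero differences")
        ranks_all = stats.rankdata(np.abs(d))
        ranks = ranks_all[d != 0.0]
        d = d[d != 0.0]

    w_plus = float(ranks[d > 0].sum())
    n = d.size
    if n <= exact_limit:
        return _exact_two_sided_p(ranks, w_plus)
    total = ranks.sum()
    mu = total / 2.0
    sigma = np.sqrt(np.sum(ranks**2) / 4.0)
    z = (abs(w_plus - mu) - 0.5) / sigma
    return float(2.0 * stats.norm.sf(max(z, 0.0)))


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided tail probability of W+ under random sign assignment.

    Ranks may be half-integers (average ranks); doubling makes them integer
    so the distribution is a polynomial convolution with 2^n total mass.
    """
    doubled = np.rint(2.0 * ranks).astype(int)
    max_sum = int(doubled.sum())
    counts = np.zeros(max_sum + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: max_sum + 1 - r]
        counts = counts + shifted
    total = counts.sum()  # == 2^n
    w2 = int(round(2.0 * w_plus))
    p_le = counts[: w2 + 1].sum() / total
    p_ge = counts[w2:].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


# ---------------------------------------------------------------------------
# Case-table serialization (TSV: yeast_id, candidate_ids comma-joined,
# complementing_id, source)


def write_cases_tsv(path: str | Path, cases: Sequence[ComplementationCase]) -> None:
    df = pd.DataFrame(
        {
            "yeast_id": [c.yeast_id for c in cases],
            "candidate_ids": [",".join(c.candidate_ids) for c in cases],
            "complementing_id": [c.complementing_id for c in cases],
            "source": [c.source for c in cases],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_cases_tsv(path: str | Path) -> list[ComplementationCase]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"yeast_id", "candidate_ids", "complementing_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"case table missing columns: {sorted(missing)}")
    return [
        ComplementationCase(
            yeast_id=row.yeast_id,
            candidate_ids=tuple(row.candidate_ids.split(",")),
            complementing_id=row.complementing_id,
            source=getattr(row, "source", ""),
        )
        for row in df.itertuples(index=False)
    ]
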
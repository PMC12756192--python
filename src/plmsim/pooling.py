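"""Pooling of per-residue embedding matrices into fixed-length sequence embeddings.

Two strategies are provided:

* **Mean pooling** — the column-wise average of the residue vectors.  Simple,
  but the resulting vector is sensitive to length differences between
  proteins because averaging collapses the whole residue distribution onto
  its first moment.

* **Sliced-Wasserstein embedding (SWE)** — treats the residue vectors of a
  protein as an empirical distribution in embedding space and encodes, for a
  frozen set of random 1-D slices, the monotone optimal-transport
  displacements between the protein's projected distribution and a frozen
  reference point set.  The result is a fixed-length vector regardless of
  protein length, and it retains distributional information that mean
  pooling discards.

The slice directions and reference points are drawn once per run and shared
by every protein ("frozen"); nothing is learned.  Per-layer pooled vectors
are combined by simple element-wise averaging (:func:`pool_layers`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SWEConfig",
    "SequenceEmbedding",
    "make_swe_config",
    "mean_pool",
    "swe_pool",
    "pool_layers",
]

_UNIT_NORM_TOL = 1e-9


@dataclass(frozen=True)
class SWEConfig:
    """Frozen parameters of the sliced-Wasserstein embedding.

    Attributes
    ----------
    directions:
        ``(L, d)`` matrix of unit-norm slice directions.
    reference:
        ``(M, d)`` matrix of reference points (landmarks in embedding space).
    quantile_levels:
        The ``M`` midpoint quantile levels ``t_m = (m - 0.5) / M``.
    seed:
        Seed of the RNG that generated ``directions`` and ``reference``.
    """

    directions: np.ndarray
    reference: np.ndarray
    quantile_levels: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        theta = np.asarray(self.directions, dtype=float)
        ref = np.asarray(self.reference, dtype=float)
        t = np.asarray(self.quantile_levels, dtype=float)
        if theta.ndim != 2 or ref.ndim != 2:
            raise ValueError("directions and reference must be 2-D matrices")
        if theta.shape[1] != ref.shape[1]:
            raise ValueError(
                f"dimension mismatch: directions are {theta.shape[1]}-dimensional "
                f"but reference points are {ref.shape[1]}-dimensional"
            )
        if ref.shape[0] < 2:
            raise ValueError("at least 2 reference points (M >= 2) are required")
        norms = np.linalg.norm(theta, axis=1)
        if not np.allclose(norms, 1.0, atol=_UNIT_NORM_TOL, rtol=0.0):
            raise ValueError("every slice direction must have unit norm")
        if t.shape != (ref.shape[0],):
            raise ValueError("quantile_levels must have one level per reference point")
        if not (np.all(np.diff(t) > 0) and t[0] > 0.0 and t[-1] < 1.0):
            raise ValueError("quantile levels must be strictly increasing in (0, 1)")
        object.__setattr__(self, "directions", theta)
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "quantile_levels", t)

    @property
    def n_slices(self) -> int:
        return self.directions.shape[0]

    @property
    def n_reference(self) -> int:
        return self.reference.shape[0]

    @property
    def d(self) -> int:
        return self.directions.shape[1]


@dataclass(frozen=True)
class SequenceEmbedding:
    """A pooled, fixed-length embedding for one protein."""

    protein_id: str
    vector: np.ndarray
    pooling_tag: str  # "mean" or "swe"
    layer_spec: tuple[int, ...] = field(default=())
    model_tag: str = ""


def make_swe_config(d: int, L: int = 64, M: int = 128, seed: int = 0) -> SWEConfig:
    """Draw frozen SWE parameters: L unit slice directions and M reference points.

    Directions are normalised iid standard-Gaussian draws (uniform on the
    sphere); reference entries are iid standard Gaussian.  Deterministic
    under ``seed``.
    """
    if L < 1:
        raise ValueError("at least one slice (L >= 1) is required")
    if M < 2:
        raise ValueError("at least 2 reference points (M >= 2) are required")
    if d < 1:
        raise ValueError("embedding dimension must be positive")
    rng = np.random.default_rng(seed)
    theta = rng.standard_normal((L, d))
    theta /= np.linalg.norm(theta, axis=1, keepdims=True)
    reference = rng.standard_normal((M, d))
    levels = (np.arange(M) + 0.5) / M
    return SWEConfig(directions=theta, reference=reference, quantile_levels=levels, seed=seed)


def _as_matrix(E) -> np.ndarray:
    """Accept either a raw (n, d) array or an object with a ``matrix`` attribute."""
    matrix = getattr(E, "matrix", E)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("residue embeddings must form an (n, d) matrix")
    if matrix.shape[0] < 1:
        raise ValueError("empty residue-embedding matrix")
    return matrix


def mean_pool(E) -> np.ndarray:
    """Column-wise arithmetic mean of the residue rows."""
    return _as_matrix(E).mean(axis=0)


def swe_pool(E, cfg: SWEConfig, *, average_slices: bool = False) -> np.ndarray:
    """Sliced-Wasserstein embedding of one residue-embedding matrix.

    For each slice direction theta_l the residue rows are projected to
    scalars ``x = E @ theta_l`` and the reference points to ``r = R @
    theta_l`` (sorted ascending).  The empirical quantile function of ``x``
    is evaluated at the midpoint levels ``t_m = (m - 0.5)/M`` — sorted
    ``x_i`` sits at level ``(i - 0.5)/n``, with linear interpolation between
    and clamping at the extremes — and the slice vector is the signed
    displacement ``u_l[m] = q(t_m) - r_(m)``.  When ``n == M`` this reduces
    to ``sorted(x) - sorted(r)``, the monotone (optimal) matching of the two
    projected multisets.

    By default the per-slice vectors are concatenated into a length ``L*M``
    embedding; with ``average_slices=True`` they are averaged into a length
    ``M`` embedding instead.
    """
    matrix = _as_matrix(E)
    if matrix.shape[1] != cfg.d:
        raise ValueError(
            f"dimension mismatch: embeddings are {matrix.shape[1]}-dimensional "
            f"but the SWE config expects d={cfg.d}"
        )
    n = matrix.shape[0]
    # (n, L) projections, sorted per slice; stable sort for determinism on ties
    x = np.sort(matrix @ cfg.directions.T, axis=0, kind="stable")
    r = np.sort(cfg.reference @ cfg.directions.T, axis=0, kind="stable")
    x_levels = (np.arange(n) + 0.5) / n
    t = cfg.quantile_levels
    L = cfg.n_slices
    slices = np.empty((L, cfg.n_reference))
    for ell in range(L):
        q = np.interp(t, x_levels, x[:, ell])  # interp clamps outside [first, last]
        slices[ell] = q - r[:, ell]
    if average_slices:
        return slices.mean(axis=0)
    return slices.reshape(-1)


def pool_layers(vectors) -> np.ndarray:
    """Element-wise mean of per-layer pooled vectors of equal length."""
    vecs = [np.asarray(v, dtype=float) for v in vectors]
    if len(vecs) == 0:
        raise ValueError("at least one pooled vector is required")
    length = vecs[0].shape
    for v in vecs[1:]:
        if v.shape != length:
            raise ValueError("pooled vectors must all have the same length")
    return np.mean(vecs, axis=0)
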
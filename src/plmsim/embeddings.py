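"""Per-residue embedding backends and the on-disk embedding cache.

A backend turns an amino-acid sequence into one ``(n, d)`` matrix per
requested model layer, with exactly one row per residue (special tokens such
as BOS/EOS/CLS are never represented).  Two backends are provided:

* :func:`embed_mock` — a deterministic, dependency-free stand-in whose rows
  are seeded hashes of each residue's local sequence context.  Sequences
  sharing local context share rows, which is enough structure for every
  downstream stage to be exercised without model weights.
* :func:`embed_model` — an adapter for Huggingface transformer checkpoints
  (ESM2, ESM-C, ProtBERT, ProtT5, ...).  It extracts hidden states of the
  last ``k`` layers and strips special-token rows.  ``transformers`` and
  ``torch`` are imported lazily; if they are missing a clear error is
  raised and the pipeline can proceed from the cache or the mock backend.

The cache stores each matrix as a ``.npy`` file next to a JSON sidecar
recording protein id, dimensions, layer and model tag; round-trips are
lossless to full floating precision.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from Bio import SeqIO

__all__ = [
    "ResidueEmbeddings",
    "LayerSpec",
    "ModelBackendUnavailableError",
    "embed_mock",
    "embed_model",
    "EmbeddingCache",
    "read_fasta",
    "write_fasta",
]

#: Accepted residue alphabet: the 20 standard amino acids plus ambiguity
#: codes B/Z/X and selenocysteine U.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYXUBZ")


class ModelBackendUnavailableError(RuntimeError):
    """Raised when the transformer backend cannot be used (missing deps/weights)."""


@dataclass(frozen=True)
class ResidueEmbeddings:
    """An (n, d) matrix of per-residue vectors for one protein at one layer.

    ``n`` equals the protein's residue count; no row corresponds to a
    non-residue (special or padding) token.
    """

    protein_id: str
    layer_index: int
    matrix: np.ndarray
    model_tag: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] < 1:
            raise ValueError("matrix must be a non-empty (n, d) array")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def d(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class LayerSpec:
    """How many final layers of the model to extract (k in {1, 4, 8})."""

    k: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be at least 1")

    def layer_indices(self, depth: int) -> list[int]:
        """Layer indices, descending from the final layer."""
        if self.k > depth:
            raise ValueError(f"k={self.k} exceeds model depth {depth}")
        return [depth - i for i in range(self.k)]


def _validate_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise ValueError(f"illegal residue characters: {sorted(bad)}")
    return seq


def _context_vector(context: str, layer: int, d: int, seed: int) -> np.ndarray:
    """Deterministic standard-normal vector keyed by (context k-mer, layer, seed)."""
    key = f"{context}|{layer}|{seed}|{d}".encode()
    digest = hashlib.blake2b(key, digest_size=8).digest()
    sub_seed = int.from_bytes(digest, "little") % (2**32)
    return np.random.default_rng(sub_seed).standard_normal(d)


def embed_mock(
    sequence: str,
    layer_spec: LayerSpec = LayerSpec(1),
    d: int = 16,
    seed: int = 0,
    *,
    protein_id: str = "",
    window: int = 1,
    depth: int = 8,
    model_tag: str = "mock",
) -> list[ResidueEmbeddings]:
    """Deterministic mock embedding backend.

    Each residue's vector is a seeded hash of its centred length-``window``
    k-mer and the layer index, so sequences sharing local context share
    rows, and the same input always yields identical output.  Returns one
    :class:`ResidueEmbeddings` per selected layer, final layer first.
    """
    seq = _validate_sequence(sequence)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    half = window // 2
    padded = "-" * half + seq + "-" * half
    out = []
    for layer in layer_spec.layer_indices(depth):
        rows = np.vstack(
            [
                _context_vector(padded[i : i + window], layer, d, seed)
                for i in range(len(seq))
            ]
        )
        assert rows.shape[0] == len(seq)
        out.append(
            ResidueEmbeddings(
                protein_id=protein_id, layer_index=layer, matrix=rows, model_tag=model_tag
            )
        )
    return out


# ---------------------------------------------------------------------------
# Embedding cache


def _safe_name(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]", "_", text)


class EmbeddingCache:
    """Directory-backed store of residue-embedding matrices.

    Each entry is a ``.npy`` matrix plus a JSON sidecar carrying
    ``protein_id``, ``n``, ``d``, ``layer`` and ``model_tag``.
    """

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)

    def _stem(self, protein_id: str, model_tag: str, layer: int) -> Path:
        return self.directory / f"{_safe_name(protein_id)}__{_safe_name(model_tag)}__L{layer}"

    def has(self, protein_id: str, model_tag: str, layer: int) -> bool:
        stem = self._stem(protein_id, model_tag, layer)
        return stem.with_suffix(".npy").exists() and stem.with_suffix(".json").exists()

    def save(self, emb: ResidueEmbeddings) -> None:
        stem = self._stem(emb.protein_id, emb.model_tag, emb.layer_index)
        np.save(stem.with_suffix(".npy"), emb.matrix)
        sidecar = {
            "protein_id": emb.protein_id,
            "n": emb.n,
            "d": emb.d,
            "layer": emb.layer_index,
            "model_tag": emb.model_tag,
        }
        stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    def load(self, protein_id: str, model_tag: str, layer: int) -> ResidueEmbeddings:
        stem = self._stem(protein_id, model_tag, layer)
        if not self.has(protein_id, model_tag, layer):
            raise KeyError(f"no cached embedding for ({protein_id}, {model_tag}, layer {layer})")
        matrix = np.load(stem.with_suffix(".npy"))
        meta = json.loads(stem.with_suffix(".json").read_text())
        return ResidueEmbeddings(
            protein_id=meta["protein_id"],
            layer_index=meta["layer"],
            matrix=matrix,
            model_tag=meta["model_tag"],
        )


# ---------------------------------------------------------------------------
# FASTA helpers


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Transformer backend


def embed_model(
    sequences: Mapping[str, str] | str | Path,
    model_tag: str,
    layer_spec: LayerSpec = LayerSpec(1),
    *,
    cache: EmbeddingCache | None = None,
    device: str = "cpu",
    max_length: int | None = None,
) -> dict[str, list[ResidueEmbeddings]]:
    """Extract per-residue hidden states from a Huggingface checkpoint.

    ``sequences`` may be a FASTA path or an {id: sequence} mapping.  Hidden
    states of the last ``k`` layers are extracted and the beginning/end
    special-token rows removed, so each matrix has exactly one row per
    residue.  Results are written to ``cache`` when given, and cached
    entries are returned without invoking the backend at all.

    Raises :class:`ModelBackendUnavailableError` when ``transformers``/
    ``torch`` are not installed or the checkpoint cannot be loaded; callers
    can fall back to the cache or to :func:`embed_mock`.  Sequences longer
    than ``max_length`` are skipped and reported, not fatal.
    """
    if isinstance(sequences, (str, Path)):
        sequences = read_fasta(sequences)

    results: dict[str, list[ResidueEmbeddings]] = {}
    pending = {pid: _validate_sequence(seq) for pid, seq in sequences.items()}

    if cache is not None:
        still_pending = {}
        for pid, seq in pending.items():
            hit = _try_cache(cache, pid, model_tag, layer_spec)
            if hit is not None:
                results[pid] = hit
            else:
                still_pending[pid] = seq
        pending = still_pending

    if not pending:
        return results

    try:
        import torch
        from transformers import AutoModel, AutoTokenizer
    except ImportError as exc:  # pragma: no cover - depends on optional deps
        raise ModelBackendUnavailableError(
            f"model backend unavailable for '{model_tag}': transformers/torch are "
            "not installed. Install them, supply a populated embedding cache, or "
            "use the mock backend (embed_mock)."
        ) from exc

    try:  # pragma: no cover - requires local model weights
        tokenizer = AutoTokenizer.from_pretrained(model_tag)
        model = AutoModel.from_pretrained(model_tag, output_hidden_states=True)
    except Exception as exc:  # pragma: no cover
        raise ModelBackendUnavailableError(
            f"model backend unavailable: could not load '{model_tag}' ({exc}). "
            "Supply a populated embedding cache or use the mock backend."
        ) from exc

    model.to(device).eval()  # pragma: no cover - below requires weights
    for pid, seq in pending.items():  # pragma: no cover
        if max_length is not None and len(seq) > max_length:
            import logging

            logging.getLogger(__name__).warning(
                "skipping %s: length %d exceeds max_length %d", pid, len(seq), max_length
            )
            continue
        enc = tokenizer(" ".join(seq), return_tensors="pt").to(device)
        with torch.no_grad():
            out = model(**enc)
        hidden = out.hidden_states  # tuple: embeddings + one per layer
        depth = len(hidden) - 1
        special = tokenizer.get_special_tokens_mask(
            enc["input_ids"][0].tolist(), already_has_special_tokens=True
        )
        keep = [i for i, flag in enumerate(special) if not flag]
        layers = []
        for layer in layer_spec.layer_indices(depth):
            matrix = hidden[layer][0].cpu().numpy()[keep]
            if matrix.shape[0] != len(seq):
                raise RuntimeError(
                    f"{pid}: row count {matrix.shape[0]} != residue count {len(seq)}"
                )
            emb = ResidueEmbeddings(
                protein_id=pid, layer_index=layer, matrix=matrix, model_tag=model_tag
            )
            if cache is not None:
                cache.save(emb)
            layers.append(emb)
        results[pid] = layers
    return results


def _try_cache(
    cache: EmbeddingCache, protein_id: str, model_tag: str, layer_spec: LayerSpec
) -> list[ResidueEmbeddings] | None:
    """Return the cached last-k layers for a protein, or None on any miss.

    The cache stores absolute layer indices; the most recent k consecutive
    cached layers are accepted as the requested last-k set.
    """
    cached_layers = sorted(
        int(p.stem.rsplit("__L", 1)[1])
        for p in cache.directory.glob(f"{_safe_name(protein_id)}__{_safe_name(model_tag)}__L*.npy")
    )
    if len(cached_layers) < layer_spec.k:
        return None
    top = cached_layers[-layer_spec.k :]
    if top != list(range(top[0], top[0] + layer_spec.k)):
        return None
    return [cache.load(protein_id, model_tag, layer) for layer in reversed(top)]
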
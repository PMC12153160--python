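"""Modality embeddings behind a uniform provider contract, and their fusion.

Three modalities feed the classifier: contextual sentence-token vectors
(width ``d_w``), a drug-description document vector per drug (``d_d``), and a
molecular-graph vector per drug (``d_g``).  Real pretrained encoders plug in
as providers; the built-in providers are deterministic seeded hashes so the
full pipeline runs offline.  Per drug *i* the fused sequence is
``E_i = [Es ; Ed_i ; Eg_i]`` with the description and graph vectors tiled
across token positions (``fusion="tile"``) or appended as pseudo-tokens
(``fusion="append"``).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np

from .corpus import DDIInstance
from .smiles import MolecularGraph

__all__ = [
    "TokenEmbeddingSequence", "ProviderOutput",
    "HashedTokenProvider", "HashedDocProvider", "GraphSignatureProvider",
    "embed_sentence_tokens", "embed_description", "embed_graph",
    "fuse_embeddings",
]


def _seeded_vector(key: str, dim: int) -> np.ndarray:
    digest = hashlib.sha256(key.encode()).digest()
    rng = np.random.Generator(np.random.PCG64(int.from_bytes(digest[:8], "little")))
    return rng.standard_normal(dim)


@dataclass
class TokenEmbeddingSequence:
    """Per-token embedding rows aligned with a blinded instance's tokens."""

    matrix: np.ndarray          # (T, d_w)
    tokens: list[str]

    def __post_init__(self):
        if self.matrix.shape[0] != len(self.tokens):
            raise ValueError("row count must equal token count")


@dataclass
class ProviderOutput:
    """Raw contextual-provider output before pooling.

    ``layers`` has shape (L, S, d) over S sub-token rows; ``subtoken_map[s]``
    gives the instance-token index of sub-token s, or -1 for boundary markers
    (sentence-start/separator analogues), which are excluded from the pooled
    sequence.
    """

    layers: np.ndarray
    subtoken_map: list[int]


class HashedTokenProvider:
    """Deterministic contextual stand-in: one seeded-hash vector per token."""

    def __init__(self, dim: int = 400, seed: int = 0):
        self.dim = dim
        self.seed = seed

    def encode(self, tokens: list[str]) -> ProviderOutput:
        rows = np.stack([
            _seeded_vector(f"tok|{self.seed}|{t}", self.dim) for t in tokens])
        return ProviderOutput(layers=rows[None, :, :],
                              subtoken_map=list(range(len(tokens))))


class HashedDocProvider:
    """Deterministic document embedding: seeded hash of the full text."""

    def __init__(self, dim: int = 200, seed: int = 0):
        self.dim = dim
        self.seed = seed

    def embed(self, text: str) -> np.ndarray:
        return _seeded_vector(f"doc|{self.seed}|{text}", self.dim)


class GraphSignatureProvider:
    """Graph embedding from a canonical multiset of local atom signatures.

    The signature of an atom is (element, sorted multiset of neighbour
    elements); the sorted multiset of all signatures is hashed to seed the
    vector, so graphs identical up to atom reordering map to the same vector.
    """

    def __init__(self, dim: int = 100, seed: int = 0):
        self.dim = dim
        self.seed = seed

    def signature(self, graph: MolecularGraph) -> str:
        sigs = []
        for i, atom in enumerate(graph.atoms):
            nbrs = sorted(graph.atoms[j] for j, _ in graph.neighbors(i))
            sigs.append((atom, tuple(nbrs)))
        return repr(sorted(sigs))

    def embed(self, graph: MolecularGraph) -> np.ndarray:
        return _seeded_vector(f"graph|{self.seed}|{self.signature(graph)}", self.dim)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def embed_sentence_tokens(instance: DDIInstance, provider) -> TokenEmbeddingSequence:
    """Contextual token embeddings for one instance.

    When the provider exposes several layers the mean of its last four is
    taken; sub-token rows mapping to one instance token are mean-pooled;
    boundary-marker rows (``subtoken_map`` entry -1) are dropped.
    """
    if not instance.tokens:
        raise ValueError(f"{instance.instance_id}: empty token list")
    out = provider.encode(instance.tokens)
    if out.layers.shape[-1] != provider.dim:
        raise ValueError("provider output width does not match its dim")
    pooled_layers = out.layers[-4:].mean(axis=0)  # (S, d)
    T = len(instance.tokens)
    matrix = np.zeros((T, provider.dim))
    counts = np.zeros(T)
    for s, t in enumerate(out.subtoken_map):
        if t < 0:
            continue
        matrix[t] += pooled_layers[s]
        counts[t] += 1
    if np.any(counts == 0):
        missing = [instance.tokens[t] for t in np.nonzero(counts == 0)[0]]
        raise ValueError(f"no sub-token rows for token(s): {missing}")
    matrix /= counts[:, None]
    return TokenEmbeddingSequence(matrix, list(instance.tokens))


def embed_description(text: str, provider, *, allow_missing: bool = True) -> np.ndarray:
    """Document vector for a drug description; zero-vector fallback if empty."""
    if not text or not text.strip():
        if not allow_missing:
            raise ValueError("empty drug description")
        warnings.warn("empty drug description; using zero vector", stacklevel=2)
        return np.zeros(provider.dim)
    return provider.embed(text)


def embed_graph(graph: MolecularGraph | None, provider) -> np.ndarray:
    """Whole-graph vector; zero-vector fallback for an empty/absent graph."""
    if graph is None or not graph.atoms:
        warnings.warn("empty molecular graph; using zero vector", stacklevel=2)
        return np.zeros(provider.dim)
    return provider.embed(graph)


def fuse_embeddings(
    Es: TokenEmbeddingSequence | np.ndarray,
    Ed: np.ndarray,
    Eg: np.ndarray,
    *,
    fusion: str = "tile",
) -> np.ndarray:
    """Concatenate the three modalities into one per-drug sequence.

    ``tile`` repeats Ed and Eg at every token position on the feature axis,
    giving shape (T, d_w + d_d + d_g).  ``append`` keeps modalities in
    disjoint feature slices and adds one pseudo-token row for Ed and one for
    Eg, giving shape (T + 2, d_w + d_d + d_g).
    """
    S = Es.matrix if isinstance(Es, TokenEmbeddingSequence) else np.asarray(Es)
    Ed, Eg = np.asarray(Ed), np.asarray(Eg)
    if S.ndim != 2 or Ed.ndim != 1 or Eg.ndim != 1:
        raise ValueError("Es must be (T, d_w); Ed and Eg must be vectors")
    T = S.shape[0]
    if fusion == "tile":
        return np.concatenate(
            [S, np.tile(Ed, (T, 1)), np.tile(Eg, (T, 1))], axis=1)
    if fusion == "append":
        d_w, d_d, d_g = S.shape[1], Ed.shape[0], Eg.shape[0]
        out = np.zeros((T + 2, d_w + d_d + d_g))
        out[:T, :d_w] = S
        out[T, d_w:d_w + d_d] = Ed
        out[T + 1, d_w + d_d:] = Eg
        return out
    raise ValueError(f"unknown fusion mode {fusion!r}")
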
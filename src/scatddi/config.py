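"""Model and training configuration.

Defaults follow the published operating point of the classifier: 400/200/100
embedding dimensions for word / drug-description / molecular-graph modalities,
a 3-layer BiGRU with 128 hidden units per direction, 32-dimensional attention
heads, dropout 0.01, learning rate 1e-3 and mini-batches of 30 pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from typing import Any

import hashlib
import json

import yaml

#: DDI classes in canonical index order.
CLASSES = ("negative", "effect", "mechanism", "advice", "int")
POSITIVE_CLASSES = ("effect", "mechanism", "advice", "int")


@dataclass
class ScatConfig:
    """Architecture hyperparameters.

    Attributes
    ----------
    d_w, d_d, d_g:
        Embedding widths of the sentence-token, drug-description and
        molecular-graph modalities.  The fused per-token width is their sum.
    gru_hidden:
        Hidden size per GRU direction; the encoded feature width is
        ``Gd = 2 * gru_hidden``.
    gru_layers:
        Number of stacked BiGRU layers.
    head_dim:
        Per-head width in the cross-attention. ``n_heads`` defaults to
        ``Gd // head_dim``.
    fusion:
        ``"tile"`` broadcasts the description/graph vectors over token
        positions (default); ``"append"`` adds them as pseudo-tokens.
    tied_encoder:
        If true (default) one shared BiGRU encodes both drugs' sequences.
    batch_norm:
        Normalise encoded features before cross-attention and the link
        embedding before the classifier.
    """

    d_w: int = 400
    d_d: int = 200
    d_g: int = 100
    gru_hidden: int = 128
    gru_layers: int = 3
    head_dim: int = 32
    n_heads: int = 0  # 0 -> Gd // head_dim
    n_classes: int = 5
    dropout: float = 0.01
    fusion: str = "tile"
    tied_encoder: bool = True
    batch_norm: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("d_w", "d_d", "d_g", "gru_hidden", "gru_layers",
                     "head_dim", "n_classes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_heads == 0:
            self.n_heads = max(1, self.gd // self.head_dim)
        if self.fusion not in ("tile", "append"):
            raise ValueError("fusion must be 'tile' or 'append'")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def gd(self) -> int:
        """Encoded feature width (both GRU directions concatenated)."""
        return 2 * self.gru_hidden

    @property
    def d_fused(self) -> int:
        return self.d_w + self.d_d + self.d_g


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (Adam with default moments)."""

    learning_rate: float = 0.001
    mini_batch: int = 30
    max_iterations: int = 3000
    eval_batch: int = 1024
    class_weighting: str = "off"  # off | inverse-frequency
    eval_every: int = 100
    early_stopping: bool = False
    patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 1e-4 < self.learning_rate < 0.1:
            raise ValueError("learning_rate must lie in (1e-4, 0.1)")
        for name in ("mini_batch", "max_iterations", "eval_batch", "eval_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if self.class_weighting not in ("off", "inverse-frequency"):
            raise ValueError("class_weighting must be 'off' or 'inverse-frequency'")


def _from_mapping(cls, mapping: dict[str, Any]):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise KeyError(
            f"unknown {cls.__name__} key(s): {', '.join(sorted(unknown))}")
    return cls(**mapping)


def load_config(path) -> tuple[ScatConfig, TrainConfig]:
    """Read a YAML file with optional ``model:`` and ``train:`` sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    extra = set(raw) - {"model", "train"}
    if extra:
        raise KeyError(f"unknown config section(s): {', '.join(sorted(extra))}")
    model = _from_mapping(ScatConfig, raw.get("model") or {})
    train = _from_mapping(TrainConfig, raw.get("train") or {})
    return model, train


def config_hash(*configs) -> str:
    payload = json.dumps([asdict(c) for c in configs], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
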
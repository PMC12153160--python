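"""The cross-attention DDI network.

Pipeline per drug pair: the two fused modality sequences are encoded by a
(shared) stacked BiGRU; shared-weight multi-head cross-attention exchanges
information between the two drugs' encodings (queries from one drug, keys and
values from the other, identical projection weights in both directions); the
attended maps are averaged with the originals, globally max-pooled into one
feature vector per drug; a link-attention layer turns the pooled pair into a
per-coordinate attention vector that re-weights the element-wise product of
the two drug vectors; an affine map and softmax yield the class distribution
over {negative, effect, mechanism, advice, int}.

All maths runs on :mod:`scatddi.autodiff` tensors so the same code path
serves training (reverse-mode gradients) and inference.
"""

from __future__ import annotations

import json

import numpy as np

from .autodiff import Tensor, concat
from .config import ScatConfig

__all__ = [
    "ScatModel", "pad_batch", "residual_combine", "global_max_pool",
    "link_embed",
]

_NEG_INF = -1e30


def pad_batch(seqs: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Stack variable-length (T_i, d) sequences into (B, T_max, d) + lengths."""
    if not seqs:
        raise ValueError("empty batch")
    lengths = np.array([s.shape[0] for s in seqs], dtype=np.int64)
    if lengths.min() < 1:
        raise ValueError("sequences must have at least one step")
    d = seqs[0].shape[1]
    out = np.zeros((len(seqs), lengths.max(), d))
    for i, s in enumerate(seqs):
        if s.shape[1] != d:
            raise ValueError("inconsistent feature widths in batch")
        out[i, :s.shape[0]] = s
    return out, lengths


def _length_mask(lengths: np.ndarray, t_max: int) -> np.ndarray:
    return (np.arange(t_max)[None, :] < lengths[:, None]).astype(np.float64)


# -- stateless pieces (exact elementwise contracts) -------------------------

def residual_combine(Z, U):
    """Average the attended map with the original: F = (Z + U) / 2."""
    if Z.shape != U.shape:
        raise ValueError(f"shape mismatch {Z.shape} vs {U.shape}")
    if isinstance(Z, Tensor) or isinstance(U, Tensor):
        return (Z + U) * 0.5
    return (np.asarray(Z) + np.asarray(U)) / 2.0


def global_max_pool(F: np.ndarray) -> np.ndarray:
    """Column-wise max over time for a single (T, D) map."""
    F = np.asarray(F)
    if F.ndim != 2 or F.shape[0] < 1:
        raise ValueError("need a (T, D) matrix with T >= 1")
    return F.max(axis=0)


def link_embed(F1, F2, a12):
    """F12 = a12 * (F1 * F2), all elementwise (symmetric in F1, F2)."""
    arrs = [np.asarray(x.data if isinstance(x, Tensor) else x) for x in (F1, F2, a12)]
    if not (arrs[0].shape == arrs[1].shape == arrs[2].shape):
        raise ValueError("F1, F2 and a12 must share one shape")
    if any(isinstance(x, Tensor) for x in (F1, F2, a12)):
        F1 = F1 if isinstance(F1, Tensor) else Tensor(F1)
        F2 = F2 if isinstance(F2, Tensor) else Tensor(F2)
        a12 = a12 if isinstance(a12, Tensor) else Tensor(a12)
        return a12 * (F1 * F2)
    return arrs[2] * (arrs[0] * arrs[1])


class ScatModel:
    """Holds all trainable tensors and implements the forward pass.

    Parameters are initialised with a scaled-uniform fan-in scheme from the
    config seed; every weight lives in ``self.params`` under a stable name so
    checkpoints are plain ``.npz`` archives.
    """

    def __init__(self, config: ScatConfig):
        self.config = config
        self.params: dict[str, Tensor] = {}
        self._bn_stats: dict[str, np.ndarray] = {}
        rng = np.random.Generator(np.random.PCG64(config.seed))
        self._init_params(rng)

    # -- parameters ---------------------------------------------------------
    def _uniform(self, rng, shape, fan_in) -> np.ndarray:
        bound = 1.0 / np.sqrt(max(fan_in, 1))
        return rng.uniform(-bound, bound, size=shape)

    def _add(self, name: str, value: np.ndarray) -> None:
        self.params[name] = Tensor(value, requires_grad=True)

    def _init_params(self, rng) -> None:
        cfg = self.config
        H, Gd = cfg.gru_hidden, cfg.gd
        encoders = ["gru"] if cfg.tied_encoder else ["gru1", "gru2"]
        for enc in encoders:
            in_dim = cfg.d_fused
            for layer in range(cfg.gru_layers):
                for direction in ("f", "b"):
                    p = f"{enc}_l{layer}{direction}"
                    self._add(f"{p}_W", self._uniform(rng, (in_dim, 3 * H), in_dim))
                    self._add(f"{p}_U", self._uniform(rng, (H, 3 * H), H))
                    self._add(f"{p}_b", np.zeros(3 * H))
                in_dim = Gd
        hd, nh = cfg.head_dim, cfg.n_heads
        for name in ("Wq", "Wk", "Wv"):
            self._add(name, self._uniform(rng, (Gd, nh * hd), Gd))
        self._add("Wz", self._uniform(rng, (nh * hd, Gd), nh * hd))
        self._add("W12", self._uniform(rng, (2 * Gd, Gd), 2 * Gd))
        self._add("b12", np.zeros(Gd))
        self._add("W_link", self._uniform(rng, (Gd,), Gd))
        self._add("Wc", self._uniform(rng, (Gd, cfg.n_classes), Gd))
        self._add("bc", np.zeros(cfg.n_classes))
        if cfg.batch_norm:
            for bn, dim in (("bn1", Gd), ("bn2", Gd)):
                self._add(f"{bn}_gamma", np.ones(dim))
                self._add(f"{bn}_beta", np.zeros(dim))
                self._bn_stats[f"{bn}_mean"] = np.zeros(dim)
                self._bn_stats[f"{bn}_var"] = np.ones(dim)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    # -- BiGRU ---------------------------------------------------------------
    def _gru_direction(self, X: Tensor, lengths: np.ndarray, prefix: str) -> Tensor:
        """One GRU direction over a padded (B, T, d) batch -> (B, T, H)."""
        W, U, b = (self.params[f"{prefix}_W"], self.params[f"{prefix}_U"],
                   self.params[f"{prefix}_b"])
        B, T, _ = X.shape
        H = self.config.gru_hidden
        gates_x = X @ W + b                     # (B, T, 3H)
        h = Tensor(np.zeros((B, H)))
        outs = []
        for t in range(T):
            gx = gates_x[:, t, :]
            gh = h @ U
            z = (gx[:, :H] + gh[:, :H]).sigmoid()
            r = (gx[:, H:2 * H] + gh[:, H:2 * H]).sigmoid()
            n = (gx[:, 2 * H:] + r * gh[:, 2 * H:]).tanh()
            h = (1.0 - z) * n + z * h
            outs.append(h)
        from .autodiff import stack
        return stack(outs, axis=1)

    def _reverse_index(self, lengths: np.ndarray, t_max: int) -> np.ndarray:
        idx = np.tile(np.arange(t_max), (len(lengths), 1))
        for i, L in enumerate(lengths):
            idx[i, :L] = np.arange(L - 1, -1, -1)
        return idx

    def bigru_encode_batch(self, X: Tensor, lengths: np.ndarray, drug: int) -> Tensor:
        """Stacked BiGRU over a padded batch -> (B, T, 2*gru_hidden)."""
        enc = "gru" if self.config.tied_encoder else f"gru{drug}"
        rev = self._reverse_index(lengths, X.shape[1])
        out = X
        for layer in range(self.config.gru_layers):
            fwd = self._gru_direction(out, lengths, f"{enc}_l{layer}f")
            bwd = self._gru_direction(
                out.gather_time(rev), lengths, f"{enc}_l{layer}b").gather_time(rev)
            out = concat([fwd, bwd], axis=-1)
        return out

    def bigru_encode(self, E: np.ndarray, drug: int = 1) -> np.ndarray:
        """Single-sequence convenience wrapper: (T, d) -> (T, Gd)."""
        E = np.asarray(E)
        if E.ndim != 2 or E.shape[0] < 1:
            raise ValueError("need a (T, d) sequence with T >= 1")
        X, lengths = pad_batch([E])
        return self.bigru_encode_batch(Tensor(X), lengths, drug).data[0]

    # -- cross-attention ------------------------------------------------------
    def _project_heads(self, U: Tensor, W: Tensor) -> Tensor:
        B, T, _ = U.shape
        nh, hd = self.config.n_heads, self.config.head_dim
        return (U @ W).reshape(B, T, nh, hd).transpose(0, 2, 1, 3)

    def _attend(self, Uq: Tensor, Ukv: Tensor, key_mask: np.ndarray | None):
        """Queries from Uq, keys/values from Ukv; returns (Z, A)."""
        cfg = self.config
        Q = self._project_heads(Uq, self.params["Wq"])
        K = self._project_heads(Ukv, self.params["Wk"])
        V = self._project_heads(Ukv, self.params["Wv"])
        scores = (Q @ K.transpose(0, 1, 3, 2)) / np.sqrt(cfg.head_dim)
        if key_mask is not None:
            bias = np.where(key_mask[:, None, None, :] > 0, 0.0, _NEG_INF)
            scores = scores + Tensor(bias)
        A = scores.softmax(axis=-1)                       # (B, h, Tq, Tk)
        ctx = A @ V                                       # (B, h, Tq, hd)
        B, _, Tq, _ = ctx.shape
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, Tq, cfg.n_heads * cfg.head_dim)
        return ctx @ self.params["Wz"], A

    def cross_attention_batch(self, Ud1: Tensor, Ud2: Tensor,
                              mask1: np.ndarray | None = None,
                              mask2: np.ndarray | None = None):
        """Both directions with shared projections; returns (Z1, A1, Z2, A2)."""
        if Ud1.shape[-1] != Ud2.shape[-1]:
            raise ValueError("feature widths differ between the two drugs")
        Z1, A1 = self._attend(Ud1, Ud2, mask2)
        Z2, A2 = self._attend(Ud2, Ud1, mask1)
        return Z1, A1, Z2, A2

    def cross_attention(self, Ud1: np.ndarray, Ud2: np.ndarray):
        """Single-pair wrapper: (T1, Gd), (T2, Gd) -> ((Z1, A1), (Z2, A2))."""
        t1, t2 = (Tensor(np.asarray(U)[None]) for U in (Ud1, Ud2))
        Z1, A1, Z2, A2 = self.cross_attention_batch(t1, t2)
        return (Z1.data[0], A1.data[0]), (Z2.data[0], A2.data[0])

    # -- link attention and classifier ----------------------------------------
    def link_attention_batch(self, F1: Tensor, F2: Tensor) -> Tensor:
        pre = concat([F1, F2], axis=-1) @ self.params["W12"] + self.params["b12"]
        a_hat = self.params["W_link"] * pre.relu()
        return a_hat.softmax(axis=-1)

    def link_attention(self, F1: np.ndarray, F2: np.ndarray) -> np.ndarray:
        D = self.config.gd
        F1, F2 = np.asarray(F1), np.asarray(F2)
        if F1.shape != (D,) or F2.shape != (D,):
            raise ValueError(f"expected two length-{D} vectors")
        return self.link_attention_batch(Tensor(F1[None]), Tensor(F2[None])).data[0]

    def classify_batch(self, F12: Tensor) -> Tensor:
        """Class logits from the link embedding (affine map before softmax)."""
        return F12 @ self.params["Wc"] + self.params["bc"]

    def classify(self, F12: np.ndarray) -> np.ndarray:
        F12 = np.asarray(F12)
        if F12.shape != (self.config.gd,):
            raise ValueError(f"expected a length-{self.config.gd} vector")
        return self.classify_batch(Tensor(F12[None])).softmax(axis=-1).data[0]

    # -- batch-norm -----------------------------------------------------------
    def _batch_norm(self, X: Tensor, name: str, mask: np.ndarray | None,
                    train: bool, eps: float = 1e-5, momentum: float = 0.1) -> Tensor:
        gamma, beta = self.params[f"{name}_gamma"], self.params[f"{name}_beta"]
        if train:
            if mask is not None:
                m = Tensor(mask[..., None])
                count = float(mask.sum())
                mean = (X * m).sum(axis=tuple(range(X.ndim - 1))) / count
                var = (((X - mean) * m) ** 2).sum(
                    axis=tuple(range(X.ndim - 1))) / count
            else:
                axes = tuple(range(X.ndim - 1))
                count = float(np.prod([X.shape[a] for a in axes]))
                mean = X.sum(axis=axes) / count
                var = ((X - mean) ** 2).sum(axis=axes) / count
            self._bn_stats[f"{name}_mean"] *= 1 - momentum
            self._bn_stats[f"{name}_mean"] += momentum * mean.data
            self._bn_stats[f"{name}_var"] *= 1 - momentum
            self._bn_stats[f"{name}_var"] += momentum * var.data
        else:
            mean = Tensor(self._bn_stats[f"{name}_mean"])
            var = Tensor(self._bn_stats[f"{name}_var"])
        return gamma * ((X - mean) / (var + eps) ** 0.5) + beta

    # -- forward --------------------------------------------------------------
    def _dropout(self, X: Tensor, rng) -> Tensor:
        p = self.config.dropout
        if p <= 0 or rng is None:
            return X
        keep = (rng.random(X.shape) >= p) / (1.0 - p)
        return X * Tensor(keep)

    def forward_batch(self, E1: list[np.ndarray], E2: list[np.ndarray],
                      train: bool = False, rng=None) -> dict:
        """Full forward pass over a batch of fused sequence pairs.

        Returns a dict with ``logits`` (Tensor, (B, n_classes)), ``probs``
        (ndarray) and the pooled drug features.  In eval mode (``train=False``)
        the pass is a pure function of inputs and parameters.
        """
        cfg = self.config
        X1, len1 = pad_batch([np.asarray(e) for e in E1])
        X2, len2 = pad_batch([np.asarray(e) for e in E2])
        if X1.shape[-1] != cfg.d_fused or X2.shape[-1] != cfg.d_fused:
            raise ValueError(
                f"fused width must be {cfg.d_fused}, got {X1.shape[-1]}")
        mask1, mask2 = (_length_mask(l, x.shape[1]) for l, x in
                        ((len1, X1), (len2, X2)))
        drop_rng = rng if train else None
        T1 = self._dropout(Tensor(X1), drop_rng)
        T2 = self._dropout(Tensor(X2), drop_rng)
        Ud1 = self.bigru_encode_batch(T1, len1, drug=1)
        Ud2 = self.bigru_encode_batch(T2, len2, drug=2)
        if cfg.batch_norm:
            # one shared normalisation over both drugs' valid positions
            both = concat([Ud1, Ud2], axis=1)
            both_mask = np.concatenate([mask1, mask2], axis=1)
            both = self._batch_norm(both, "bn1", both_mask, train)
            Ud1, Ud2 = both[:, :Ud1.shape[1], :], both[:, Ud1.shape[1]:, :]
        Z1, A1, Z2, A2 = self.cross_attention_batch(Ud1, Ud2, mask1, mask2)
        F1 = residual_combine(Z1, Ud1)
        F2 = residual_combine(Z2, Ud2)
        # masked global max-pool over time
        F1 = (F1 + Tensor(np.where(mask1[..., None] > 0, 0.0, _NEG_INF))).max(axis=1)
        F2 = (F2 + Tensor(np.where(mask2[..., None] > 0, 0.0, _NEG_INF))).max(axis=1)
        a12 = self.link_attention_batch(F1, F2)
        F12 = link_embed(F1, F2, a12)
        if cfg.batch_norm:
            F12 = self._batch_norm(F12, "bn2", None, train)
        F12 = self._dropout(F12, drop_rng)
        logits = self.classify_batch(F12)
        probs = logits.softmax(axis=-1)
        return {"logits": logits, "probs": probs.data, "probs_t": probs,
                "F1": F1, "F2": F2, "a12": a12.data,
                "A1": A1.data, "A2": A2.data}

    def forward(self, E1: np.ndarray, E2: np.ndarray) -> np.ndarray:
        """Eval-mode class probabilities for one fused pair."""
        return self.forward_batch([E1], [E2])["probs"][0]

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        from dataclasses import asdict
        from .config import config_hash
        from .utils import atomic_write_text, savez_deterministic
        arrays = {f"param/{k}": v.data for k, v in self.params.items()}
        arrays.update({f"bn/{k}": v for k, v in self._bn_stats.items()})
        savez_deterministic(path, arrays)
        atomic_write_text(
            str(path) + ".json",
            json.dumps({"config": asdict(self.config),
                        "config_hash": config_hash(self.config)},
                       sort_keys=True, indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "ScatModel":
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        model = cls(ScatConfig(**meta["config"]))
        with np.load(str(path)) as data:
            for key in data.files:
                kind, name = key.split("/", 1)
                if kind == "param":
                    model.params[name].data = data[key].copy()
                else:
                    model._bn_stats[name] = data[key].copy()
        return model
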
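"""Reference synthetic studies run by the test suite and analysis scripts.

The planted-signal study is the package's controlled end-to-end experiment:
a synthetic corpus is generated, blinded and filtered, class-conditional
embeddings with separation ``mu`` (in units of the noise scale) are planted,
and the classifier is trained and scored on a held-out split.  At
``mu = 5`` the classes are linearly separable and the network should recover
them almost perfectly; at ``mu = 0`` held-out accuracy can only be chance.

Problem sizes are desk-scale: 500 training and 200 test pairs, embedding
widths 32/16/8, a single BiGRU layer with 16 hidden units per direction and
four 8-dimensional attention heads, 500 Adam steps at the default learning
rate and mini-batch 30.
"""

from __future__ import annotations

import io

import numpy as np
from sklearn.metrics import f1_score

from .config import ScatConfig, TrainConfig
from .corpus import build_dataset_variant, parse_corpus_xml
from .synthetic import SyntheticSpec, fuse_store, generate_planted_embeddings, generate_toy_corpus
from .training import ScatClassifier, evaluate_metrics, kfold_cv

__all__ = ["planted_signal_study", "cv_study", "study_config"]


def study_config(seed: int) -> tuple[ScatConfig, TrainConfig]:
    model = ScatConfig(d_w=32, d_d=16, d_g=8, gru_hidden=16, gru_layers=1,
                       head_dim=8, n_heads=4, dropout=0.01, seed=seed)
    train = TrainConfig(max_iterations=500, mini_batch=30, seed=seed)
    return model, train


def _planted_xy(seed: int, signal_strength: float, n_total: int,
                n_sentences: int = 200):
    spec = SyntheticSpec(n_sentences=n_sentences, seed=seed,
                         signal_strength=signal_strength, noise_sd=1.0,
                         d_w=32, d_d=16, d_g=8)
    corpus = generate_toy_corpus(spec)
    sentences = parse_corpus_xml(io.BytesIO(corpus.xml_bytes))
    instances = build_dataset_variant(sentences, "dataset-1").instances
    if len(instances) < n_total:
        raise ValueError(f"corpus too small: {len(instances)} < {n_total}")
    rng = np.random.Generator(np.random.PCG64(seed))
    order = rng.permutation(len(instances))[:n_total]
    instances = [instances[i] for i in order]
    store = generate_planted_embeddings(instances, spec)
    return fuse_store(store, instances)


def planted_signal_study(seed: int = 7, signal_strength: float = 5.0,
                         n_train: int = 500, n_test: int = 200,
                         max_iterations: int = 500) -> dict:
    """Train on the planted-signal set and score the held-out split."""
    X, y = _planted_xy(seed, signal_strength, n_train + n_test)
    y = np.asarray(y)
    model_cfg, train_cfg = study_config(seed)
    train_cfg.max_iterations = max_iterations
    clf = ScatClassifier(config=model_cfg, train_config=train_cfg)
    clf.fit(X[:n_train], y[:n_train])
    train_pred = clf.predict(X[:n_train])
    test_pred = clf.predict(X[n_train:])
    test_gold = y[n_train:]
    return {
        "train_accuracy": float(np.mean(train_pred == y[:n_train])),
        "heldout_accuracy": float(np.mean(test_pred == test_gold)),
        "heldout_macro_f1": float(f1_score(test_gold, test_pred,
                                           average="macro")),
        "heldout_micro_f1_positive": evaluate_metrics(
            list(test_pred), list(test_gold), scope="positive").f1,
        "n_train": n_train,
        "n_test": n_test,
    }


def cv_study(seed: int = 7, n: int = 150, k: int = 5,
             max_iterations: int = 150) -> dict:
    """Stratified k-fold cross-validation on a smaller planted-signal set."""
    X, y = _planted_xy(seed, 5.0, n, n_sentences=60)
    model_cfg, train_cfg = study_config(seed)
    train_cfg.max_iterations = max_iterations
    reports, summary = kfold_cv(X, np.asarray(y), k=k, config=model_cfg,
                                train_config=train_cfg, scope="positive")
    return {
        "cv_pooled_micro_f1_positive": summary["pooled"].f1,
        "cv_mean_accuracy": summary["mean"]["accuracy"],
        "n": n,
    }
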
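"""Offline synthetic fixtures for every stage of the pipeline.

Three generators emulate the inputs the real pipeline consumes:

* :func:`generate_toy_corpus` — a corpus in the DDIExtraction2013 XML
  dialect with 2–5 drug mentions per sentence, pair labels sampled from the
  class priors, and a known number of planted duplicate-name (R1) and
  abbreviation (R2) negative pairs so the filter rules can be checked
  exactly.  Drug descriptions and structure strings are emitted alongside.
* :func:`generate_planted_embeddings` — class-conditional Gaussian
  embeddings for all three modalities: for an instance of class *c* every
  vector is drawn around ``mu * u_c`` (``u_c`` a fixed unit direction per
  class and modality) with noise ``sigma``.  At ``mu = 0`` the classes are
  indistinguishable; at ``mu >> sigma`` they are linearly separable, so the
  classifier's learning behaviour has a known ground truth.
* :func:`make_smiles_panel` — a fixed structure panel (atom, chain, branch,
  ring, aromatic ring, one malformed string) for parser tests.

Sentence surface text is template-generated; linguistic realism is out of
scope — the fixtures exercise pipeline mechanics, not pharmacology.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree

from .config import CLASSES
from .corpus import DDIInstance
from .embeddings import fuse_embeddings
from .utils import atomic_write_text, savez_deterministic

__all__ = [
    "SyntheticSpec", "ToyCorpus", "generate_toy_corpus",
    "generate_planted_embeddings", "fuse_store", "make_smiles_panel",
]

_VERBS = ["increases", "decreases", "potentiates", "inhibits", "alters",
          "reduces", "enhances", "modulates"]
_PHRASES = [
    "serum concentration in patients",
    "hepatic clearance during therapy",
    "plasma levels after repeated dosing",
    "renal excretion in elderly subjects",
    "absorption rate when taken orally",
]
_SMILES_POOL = [
    "CCO", "CC(C)O", "C1CCCCC1", "c1ccccc1", "CC(=O)OC", "CCN(CC)CC",
    "c1ccncc1", "CC(C)(C)O", "C1CCOC1", "CCOC(=O)C", "CC=CC", "C#N",
]


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic fixtures.

    ``class_priors`` follows the canonical class order
    (negative, effect, mechanism, advice, int) and must sum to 1.
    ``signal_strength`` is the class-mean separation ``mu`` in embedding
    space, in units of the noise scale; ``noise_sd`` is ``sigma``.
    """

    n_sentences: int = 50
    n_drugs: int = 40
    class_priors: tuple = (0.2, 0.2, 0.2, 0.2, 0.2)
    signal_strength: float = 5.0
    noise_sd: float = 1.0
    seed: int = 0
    d_w: int = 32
    d_d: int = 16
    d_g: int = 8
    modality_scales: tuple = (1.0, 1.0, 1.0)
    planted_r1: int = 0
    planted_r2: int = 0

    def __post_init__(self):
        if abs(sum(self.class_priors) - 1.0) > 1e-9 or len(self.class_priors) != 5:
            raise ValueError("class_priors must be a length-5 simplex")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be non-negative")
        if self.n_drugs < 5:
            raise ValueError("need at least 5 distinct drug names")


@dataclass
class ToyCorpus:
    xml_bytes: bytes
    gold: list[tuple[str, str]]              # (pair_id, label)
    planted_r1: list[str]                    # pair ids removable by rule R1
    planted_r2: list[str]                    # pair ids removable by rule R2
    descriptions: dict[str, str]             # drug name -> description text
    structures: dict[str, str]               # drug name -> SMILES

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"corpus": out / "corpus.xml", "gold": out / "gold.tsv",
                 "manifest": out / "planted.json",
                 "smiles": out / "structures.tsv",
                 "descriptions": out / "descriptions"}
        paths["corpus"].write_bytes(self.xml_bytes)
        atomic_write_text(paths["gold"], "pair_id\tlabel\n" + "".join(
            f"{pid}\t{lab}\n" for pid, lab in self.gold))
        atomic_write_text(paths["manifest"], json.dumps(
            {"planted_r1": self.planted_r1, "planted_r2": self.planted_r2},
            sort_keys=True, indent=2) + "\n")
        atomic_write_text(paths["smiles"], "drug\tsmiles\n" + "".join(
            f"{name}\t{smi}\n" for name, smi in sorted(self.structures.items())))
        paths["descriptions"].mkdir(exist_ok=True)
        for name, text in sorted(self.descriptions.items()):
            atomic_write_text(paths["descriptions"] / f"{name}.txt", text + "\n")
        return paths


def _drug_names(spec: SyntheticSpec) -> list[str]:
    return [f"agent{k}" for k in range(spec.n_drugs)]


def generate_toy_corpus(spec: SyntheticSpec) -> ToyCorpus:
    """Deterministically generate a toy corpus from the spec."""
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    names = _drug_names(spec)
    root = etree.Element("corpus")
    doc = etree.SubElement(root, "document", id="d0")
    gold, planted_r1, planted_r2 = [], [], []
    descriptions, structures = {}, {}

    plant_r1_left, plant_r2_left = spec.planted_r1, spec.planted_r2
    for s in range(spec.n_sentences):
        sid = f"s{s}"
        n_ent = int(rng.integers(2, 6))
        # distinct names unless a rule violation is planted deliberately
        mention_names = [names[i] for i in
                         rng.choice(len(names), size=n_ent, replace=False)]
        plant = None
        if plant_r1_left > 0:
            mention_names[1] = mention_names[0]
            plant, plant_r1_left = "r1", plant_r1_left - 1
        elif plant_r2_left > 0:
            abbrev = mention_names[0][:2].upper() + str(s % 10)
            mention_names[0] = f"{mention_names[0]} ({abbrev})"
            mention_names[1] = abbrev
            plant, plant_r2_left = "r2", plant_r2_left - 1

        # assemble text and character offsets (0-based inclusive)
        words: list[tuple[str, int | None]] = [("coadministration", None), ("of", None)]
        for k in range(n_ent):
            words.append((mention_names[k], k))
            if k < n_ent - 2:
                words.append((",", None))
            elif k == n_ent - 2:
                words.append(("and", None))
        words.append((_VERBS[int(rng.integers(len(_VERBS)))], None))
        words.append((_PHRASES[int(rng.integers(len(_PHRASES)))], None))
        words.append((".", None))
        text_parts, offsets, pos = [], {}, 0
        for w, ent_idx in words:
            if text_parts:
                pos += 1  # joining space
            if ent_idx is not None:
                offsets[ent_idx] = (pos, pos + len(w) - 1)
            text_parts.append(w)
            pos += len(w)
        text = " ".join(text_parts)

        sent = etree.SubElement(doc, "sentence", id=sid, text=text)
        for k in range(n_ent):
            lo, hi = offsets[k]
            etree.SubElement(sent, "entity", id=f"{sid}.e{k}",
                             charOffset=f"{lo}-{hi}", type="drug",
                             text=mention_names[k])
        p = 0
        for a in range(n_ent):
            for b in range(a + 1, n_ent):
                pid = f"{sid}.p{p}"
                p += 1
                if plant and {a, b} == {0, 1}:
                    label = "negative"
                    (planted_r1 if plant == "r1" else planted_r2).append(pid)
                else:
                    label = CLASSES[int(rng.choice(5, p=spec.class_priors))]
                attrs = {"id": pid, "e1": f"{sid}.e{a}", "e2": f"{sid}.e{b}",
                         "ddi": "false" if label == "negative" else "true"}
                if label != "negative":
                    attrs["type"] = label
                etree.SubElement(sent, "pair", **attrs)
                gold.append((pid, label))

    for name in names:
        digest = int.from_bytes(
            hashlib.sha256(f"{spec.seed}|{name}".encode()).digest()[:4], "little")
        structures[name] = _SMILES_POOL[digest % len(_SMILES_POOL)]
        descriptions[name] = (
            f"{name} is a synthetic reference compound used to exercise the "
            f"multimodal interaction pipeline; its assigned structure is "
            f"{structures[name]}.")

    xml_bytes = etree.tostring(root, pretty_print=True,
                               xml_declaration=True, encoding="UTF-8")
    return ToyCorpus(xml_bytes, gold, planted_r1, planted_r2,
                     descriptions, structures)


# ---------------------------------------------------------------------------
# planted-signal embeddings
# ---------------------------------------------------------------------------

def _class_axes(spec: SyntheticSpec) -> dict[str, dict[str, np.ndarray]]:
    """Fixed unit direction per (class, modality), independent of instances."""
    rng = np.random.Generator(np.random.PCG64(
        int.from_bytes(hashlib.sha256(f"axes|{spec.seed}".encode()).digest()[:4],
                       "little")))
    axes = {}
    for cls in CLASSES:
        axes[cls] = {}
        for mod, dim in (("w", spec.d_w), ("d", spec.d_d), ("g", spec.d_g)):
            v = rng.standard_normal(dim)
            axes[cls][mod] = v / np.linalg.norm(v)
    return axes


def generate_planted_embeddings(
    instances: list[DDIInstance], spec: SyntheticSpec,
) -> dict[str, dict[str, np.ndarray]]:
    """Class-conditional Gaussian embeddings for labelled instances.

    Returns a store mapping instance id to arrays ``Es`` (T x d_w) and
    per-drug vectors ``Ed1``, ``Ed2`` (d_d), ``Eg1``, ``Eg2`` (d_g).
    Deterministic: vectors depend only on (spec, instance id, label).
    """
    axes = _class_axes(spec)
    mu, sd = spec.signal_strength, spec.noise_sd
    sw, sd_scale, sg = spec.modality_scales
    store = {}
    for inst in instances:
        if inst.label not in CLASSES:
            raise ValueError(f"{inst.instance_id}: unlabelled instance")
        key = int.from_bytes(hashlib.sha256(
            f"emb|{spec.seed}|{inst.instance_id}".encode()).digest()[:8], "little")
        rng = np.random.Generator(np.random.PCG64(key))
        ax = axes[inst.label]
        T = len(inst.tokens)
        store[inst.instance_id] = {
            "Es": mu * sw * ax["w"] + sd * rng.standard_normal((T, spec.d_w)),
            "Ed1": mu * sd_scale * ax["d"] + sd * rng.standard_normal(spec.d_d),
            "Ed2": mu * sd_scale * ax["d"] + sd * rng.standard_normal(spec.d_d),
            "Eg1": mu * sg * ax["g"] + sd * rng.standard_normal(spec.d_g),
            "Eg2": mu * sg * ax["g"] + sd * rng.standard_normal(spec.d_g),
        }
    return store


def fuse_store(store: dict, instances: list[DDIInstance],
               fusion: str = "tile"):
    """Assemble (X, y) for the classifier from an embedding store."""
    X, y = [], []
    for inst in instances:
        rec = store[inst.instance_id]
        E1 = fuse_embeddings(rec["Es"], rec["Ed1"], rec["Eg1"], fusion=fusion)
        E2 = fuse_embeddings(rec["Es"], rec["Ed2"], rec["Eg2"], fusion=fusion)
        X.append((E1, E2))
        y.append(inst.label)
    return X, y


def save_store(store: dict, path) -> None:
    arrays = {}
    for iid, rec in store.items():
        for k, v in rec.items():
            arrays[f"{iid}|{k}"] = v
    savez_deterministic(path, arrays)


def load_store(path) -> dict:
    store: dict[str, dict[str, np.ndarray]] = {}
    with np.load(str(path)) as data:
        for key in data.files:
            iid, k = key.rsplit("|", 1)
            store.setdefault(iid, {})[k] = data[key].copy()
    return store


# ---------------------------------------------------------------------------
# structure panel
# ---------------------------------------------------------------------------

def make_smiles_panel() -> list[tuple[str, str]]:
    """Fixed SMILES panel; the ``malformed`` entry must fail to parse."""
    return [
        ("single-atom", "C"),
        ("chain", "CCO"),
        ("branch", "CC(C)O"),
        ("ring", "C1CCCCC1"),
        ("aromatic", "c1ccccc1"),
        ("double-bond", "C=CC"),
        ("malformed", "C1CC(C"),
    ]
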
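"""Corpus parsing, candidate-pair enumeration, drug blinding and filtering.

Sentences arrive in the DDIExtraction2013 XML dialect: ``document`` elements
hold ``sentence`` elements; each sentence carries ``entity`` children (drug
mentions with character offsets) and ``pair`` children (candidate drug pairs
labelled with an interaction type or marked non-interacting).

The preprocessing implemented here follows the entity-blinding convention of
sentence-level DDI extraction: the two target mentions become the placeholder
tokens ``drug1`` and ``drug2`` (in sentence order), every other drug mention
becomes ``drug0``, and the remaining text is lowercased, stripped of
punctuation and stop-words, with digit strings collapsed to ``dnum``.

Two corpus-cleaning rules remove candidate pairs that are trivially
non-interacting because both names refer to the same substance:

* R1 — the two surface names are equal after normalisation;
* R2 — one name is an abbreviation or special case of the other
  (parenthesised alias, whole-token substring, or initials).
"""

from __future__ import annotations

import itertools
import json
import re
import string
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from .config import CLASSES

__all__ = [
    "DrugEntity", "AnnotatedSentence", "DDIInstance", "DatasetVariant",
    "CorpusValidationError", "parse_corpus_xml", "enumerate_candidate_pairs",
    "blind_sentence", "filter_negative_instances", "build_dataset_variant",
    "DEFAULT_STOP_WORDS", "write_instances_jsonl", "read_instances_jsonl",
    "write_class_summary_tsv",
]

VARIANT_NAMES = ("dataset-1", "dataset-2", "dataset-3", "dataset-4")

#: Compact English stop-word list used by default; replaceable per call.
DEFAULT_STOP_WORDS = frozenset("""
a an and are as at be been by for from has have in into is it its of on or
that the their then there these this to was were which will with
""".split())

_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})


class CorpusValidationError(ValueError):
    """Referential-integrity failure in a parsed corpus."""


@dataclass(frozen=True)
class DrugEntity:
    """A drug mention with (possibly discontinuous) character offsets.

    Offsets are 0-based inclusive on the raw sentence string, the corpus
    dialect's convention; they are normalised to half-open internally.
    """

    entity_id: str
    text: str
    char_span: tuple[tuple[int, int], ...]
    entity_type: str = "drug"

    def __post_init__(self):
        if not self.char_span:
            raise ValueError(f"entity {self.entity_id}: empty char_span")
        prev_end = -1
        for start, end in self.char_span:
            if start > end:
                raise ValueError(
                    f"entity {self.entity_id}: span start {start} > end {end}")
            if start <= prev_end:
                raise ValueError(
                    f"entity {self.entity_id}: spans unsorted or overlapping")
            prev_end = end

    @property
    def start(self) -> int:
        return self.char_span[0][0]


@dataclass
class AnnotatedSentence:
    sentence_id: str
    text: str
    entities: list[DrugEntity]
    gold_pairs: list[tuple[str, str, str]]  # (e1 id, e2 id, label)
    pair_ids: list[str] = field(default_factory=list)

    def entity(self, entity_id: str) -> DrugEntity:
        for e in self.entities:
            if e.entity_id == entity_id:
                return e
        raise CorpusValidationError(
            f"sentence {self.sentence_id}: unknown entity id {entity_id!r}")


@dataclass
class DDIInstance:
    """One blinded sentence with a target drug pair — the unit of learning."""

    instance_id: str
    tokens: list[str]
    drug1_ref: DrugEntity
    drug2_ref: DrugEntity
    label: str = "UNKNOWN"

    def validate(self) -> None:
        if self.tokens.count("drug1") != 1 or self.tokens.count("drug2") != 1:
            raise ValueError(
                f"{self.instance_id}: need exactly one drug1 and one drug2")
        if self.tokens.index("drug1") >= self.tokens.index("drug2"):
            raise ValueError(f"{self.instance_id}: drug1 must precede drug2")


@dataclass
class DatasetVariant:
    name: str
    instances: list[DDIInstance]
    provenance: dict[str, list[str]]  # instance_id -> flags

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASSES}
        for inst in self.instances:
            counts[inst.label] = counts.get(inst.label, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _parse_char_offset(raw: str) -> tuple[tuple[int, int], ...]:
    """``"0-6;10-15"`` -> ``((0, 6), (10, 15))`` (semicolon = discontinuous)."""
    spans = []
    for part in raw.split(";"):
        start_s, _, end_s = part.strip().partition("-")
        spans.append((int(start_s), int(end_s)))
    return tuple(spans)


def parse_corpus_xml(path, dialect: str = "ddiextraction2013") -> list[AnnotatedSentence]:
    """Parse a corpus file into annotated sentences.

    Raises
    ------
    lxml.etree.XMLSyntaxError
        On malformed XML (the error names the offending line).
    CorpusValidationError
        When a pair references an entity id absent from its sentence.
    """
    if dialect != "ddiextraction2013":
        raise ValueError(f"unsupported corpus dialect: {dialect!r}")
    tree = etree.parse(path if hasattr(path, "read") else str(path))
    sentences = []
    for sent_el in tree.iter("sentence"):
        sid = sent_el.get("id", "")
        text = sent_el.get("text", "")
        entities = [
            DrugEntity(
                entity_id=e.get("id"),
                text=e.get("text", ""),
                char_span=_parse_char_offset(e.get("charOffset", "")),
                entity_type=e.get("type", "drug"),
            )
            for e in sent_el.findall("entity")
        ]
        known = {e.entity_id for e in entities}
        gold_pairs, pair_ids = [], []
        for p in sent_el.findall("pair"):
            e1, e2 = p.get("e1"), p.get("e2")
            for eid in (e1, e2):
                if eid not in known:
                    raise CorpusValidationError(
                        f"sentence {sid}: pair {p.get('id')!r} references "
                        f"unknown entity {eid!r}")
            label = p.get("type") if p.get("ddi") == "true" else "negative"
            if label not in CLASSES:
                raise CorpusValidationError(
                    f"sentence {sid}: pair {p.get('id')!r} has unknown "
                    f"label {label!r}")
            gold_pairs.append((e1, e2, label))
            pair_ids.append(p.get("id") or f"{sid}.p{len(pair_ids)}")
        sentences.append(AnnotatedSentence(sid, text, entities, gold_pairs, pair_ids))
    return sentences


# ---------------------------------------------------------------------------
# pair enumeration and blinding
# ---------------------------------------------------------------------------

def enumerate_candidate_pairs(sentence: AnnotatedSentence) -> list[tuple[DrugEntity, DrugEntity]]:
    """All unordered entity pairs, earlier mention first; n*(n-1)/2 of them."""
    ordered = sorted(sentence.entities, key=lambda e: e.start)
    return list(itertools.combinations(ordered, 2))


def _normalize_segment(segment: str, stop_words, number_token: str = "dnum") -> list[str]:
    tokens = []
    for tok in segment.lower().translate(_PUNCT_TABLE).split():
        if tok in stop_words:
            continue
        tokens.append(number_token if tok.isdigit() else tok)
    return tokens


def blind_sentence(
    sentence: AnnotatedSentence,
    target: tuple[DrugEntity, DrugEntity],
    *,
    stop_words=DEFAULT_STOP_WORDS,
    instance_id: str | None = None,
    label: str = "UNKNOWN",
) -> DDIInstance:
    """Blind the target pair to ``drug1``/``drug2`` and normalise the rest.

    Entities are replaced before any lowercasing or punctuation stripping so
    their surface forms never leak into the token stream; discontinuous
    mentions collapse to a single placeholder at their first span.
    """
    ids = {e.entity_id for e in sentence.entities}
    for t in target:
        if t.entity_id not in ids:
            raise CorpusValidationError(
                f"sentence {sentence.sentence_id}: target entity "
                f"{t.entity_id!r} not in sentence")
    first, second = sorted(target, key=lambda e: e.start)
    placeholder = {first.entity_id: "drug1", second.entity_id: "drug2"}
    for e in sentence.entities:
        placeholder.setdefault(e.entity_id, "drug0")

    # (start, end_exclusive, token or None); None = drop (later span of entity)
    events = []
    for e in sorted(sentence.entities, key=lambda e: e.start):
        for k, (s, end_incl) in enumerate(e.char_span):
            events.append((s, end_incl + 1, placeholder[e.entity_id] if k == 0 else None))
    events.sort(key=lambda ev: ev[0])
    for (s1, e1, _), (s2, _, _) in zip(events, events[1:]):
        if s2 < e1:
            raise CorpusValidationError(
                f"sentence {sentence.sentence_id}: overlapping entity spans")

    tokens, cursor = [], 0
    for s, e, tok in events:
        tokens.extend(_normalize_segment(sentence.text[cursor:s], stop_words))
        if tok is not None:
            tokens.append(tok)
        cursor = e
    tokens.extend(_normalize_segment(sentence.text[cursor:], stop_words))

    inst = DDIInstance(
        instance_id=instance_id or f"{sentence.sentence_id}.{first.entity_id}-{second.entity_id}",
        tokens=tokens,
        drug1_ref=first,
        drug2_ref=second,
        label=label,
    )
    inst.validate()
    return inst


# ---------------------------------------------------------------------------
# negative filtering
# ---------------------------------------------------------------------------

_PAREN_RE = re.compile(r"\(([^()]*)\)")


def _norm_name(name: str) -> str:
    return " ".join(name.casefold().split())


def _name_tokens(name: str) -> list[str]:
    return name.casefold().translate(_PUNCT_TABLE).split()


def _is_abbreviation(a: str, b: str) -> bool:
    """True when `a` is an alias, whole-token substring or initialism of `b`."""
    na, ta, tb = _norm_name(a), _name_tokens(a), _name_tokens(b)
    if not ta or not tb:
        return False
    # (i) parenthesised alias inside b
    for alias in _PAREN_RE.findall(b):
        if _norm_name(alias) == na:
            return True
    # (ii) whole-token contiguous substring (proper)
    if len(ta) < len(tb):
        for i in range(len(tb) - len(ta) + 1):
            if tb[i:i + len(ta)] == ta:
                return True
    # (iii) initials of b's tokens
    if len(tb) >= 2 and "".join(t[0] for t in tb) == "".join(ta):
        return True
    return False


def _match_rules(name1: str, name2: str) -> list[str]:
    flags = []
    if _norm_name(name1) == _norm_name(name2):
        flags.append("filtered_negative_rule1")
    elif _is_abbreviation(name1, name2) or _is_abbreviation(name2, name1):
        flags.append("filtered_negative_rule2")
    return flags


def filter_negative_instances(
    instances: list[DDIInstance],
) -> tuple[list[DDIInstance], list[tuple[DDIInstance, list[str]]]]:
    """Split instances into (kept, removed) under rules R1/R2.

    Any instance whose two target surface names are equal (R1) or stand in an
    abbreviation/special-case relation (R2) is removed regardless of label —
    positive pairs hit by a rule are ambiguous annotations and are dropped
    from the filtered dataset variants too.
    """
    kept, removed = [], []
    for inst in instances:
        flags = _match_rules(inst.drug1_ref.text, inst.drug2_ref.text)
        if flags:
            removed.append((inst, flags))
        else:
            kept.append(inst)
    return kept, removed


# ---------------------------------------------------------------------------
# dataset variants
# ---------------------------------------------------------------------------

def sentences_to_instances(
    sentences: list[AnnotatedSentence], *, stop_words=DEFAULT_STOP_WORDS,
) -> list[DDIInstance]:
    """Blind every gold-labelled pair of every sentence."""
    instances = []
    for sent in sentences:
        for (e1, e2, label), pid in zip(sent.gold_pairs, sent.pair_ids):
            instances.append(blind_sentence(
                sent, (sent.entity(e1), sent.entity(e2)),
                stop_words=stop_words, instance_id=pid, label=label))
    return instances


def build_dataset_variant(
    sentences: list[AnnotatedSentence], name: str, *, stop_words=DEFAULT_STOP_WORDS,
) -> DatasetVariant:
    """Assemble one of the four dataset variants.

    dataset-1: all instances; dataset-2: after R1/R2 filtering;
    dataset-3: dataset-1 without negatives; dataset-4: dataset-2 without
    negatives.
    """
    if name not in VARIANT_NAMES:
        raise ValueError(f"unknown variant {name!r}; expected one of {VARIANT_NAMES}")
    instances = sentences_to_instances(sentences, stop_words=stop_words)
    provenance: dict[str, list[str]] = {i.instance_id: [] for i in instances}

    if name in ("dataset-2", "dataset-4"):
        instances, removed = filter_negative_instances(instances)
        for inst, flags in removed:
            provenance[inst.instance_id].extend(flags)
    if name in ("dataset-3", "dataset-4"):
        dropped = [i for i in instances if i.label == "negative"]
        for inst in dropped:
            provenance[inst.instance_id].append("negative_dropped")
        instances = [i for i in instances if i.label != "negative"]
    return DatasetVariant(name=name, instances=instances, provenance=provenance)


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def _entity_to_dict(e: DrugEntity) -> dict:
    return {"entity_id": e.entity_id, "text": e.text,
            "char_span": [list(s) for s in e.char_span],
            "entity_type": e.entity_type}


def _entity_from_dict(d: dict) -> DrugEntity:
    return DrugEntity(d["entity_id"], d["text"],
                      tuple(tuple(s) for s in d["char_span"]),
                      d.get("entity_type", "drug"))


def write_instances_jsonl(instances: list[DDIInstance], path) -> None:
    with open(path, "w") as fh:
        for inst in instances:
            fh.write(json.dumps({
                "instance_id": inst.instance_id,
                "tokens": inst.tokens,
                "drug1_ref": _entity_to_dict(inst.drug1_ref),
                "drug2_ref": _entity_to_dict(inst.drug2_ref),
                "label": inst.label,
            }, sort_keys=True) + "\n")


def read_instances_jsonl(path) -> list[DDIInstance]:
    instances = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            instances.append(DDIInstance(
                d["instance_id"], d["tokens"],
                _entity_from_dict(d["drug1_ref"]),
                _entity_from_dict(d["drug2_ref"]),
                d.get("label", "UNKNOWN")))
    return instances


def write_class_summary_tsv(variant: DatasetVariant, path) -> None:
    counts = variant.class_counts()
    with open(path, "w") as fh:
        fh.write("class\tcount\n")
        for cls in CLASSES:
            fh.write(f"{cls}\t{counts.get(cls, 0)}\n")
        fh.write(f"total\t{len(variant.instances)}\n")
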
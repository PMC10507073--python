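"""Non-chart modality encodings: ICD-9 sequences, demographics, notes.

ICD-9 diagnoses are encoded either as a padded index sequence over a code
vocabulary (for the recurrent model and the tabular baseline) or rendered
as text — the patient's demographics sentence, the fixed prefix
"Procedures patient went through and doctor's diagnoses:", and the code
long-titles joined by commas in sequence order (for a text model).

Discharge notes are cleaned (lower-cased, de-identification brackets
removed, whitespace collapsed), tokenized by an injected tokenizer, and
split into fixed-length chunks whose model scores are later aggregated to
one patient-level probability.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abstraction import EncodedSample

logger = logging.getLogger(__name__)

ICD9_TEXT_PREFIX = "Procedures patient went through and doctor's diagnoses:"

_DEID_RE = re.compile(r"\[\*\*.*?\*\*\]", flags=re.DOTALL)
_WS_RE = re.compile(r"\s+")


@dataclass
class Icd9Sequence:
    """One admission's ordered diagnoses: (seq_num, code, long_title)."""

    entries: list[tuple[int, str, str]]

    def __post_init__(self) -> None:
        seqs = [s for s, _, _ in self.entries]
        if any(b <= a for a, b in zip(seqs, seqs[1:])):
            raise ValueError("seq_num must be strictly increasing")

    def codes(self) -> list[str]:
        return [c for _, c, _ in self.entries]

    def titles(self) -> list[str]:
        return [t for _, _, t in self.entries]


def icd9_sequences(diagnoses: pd.DataFrame, dictionary: pd.DataFrame) -> dict[int, Icd9Sequence]:
    """Per-admission ICD-9 sequences joined with long titles."""
    title_of = dict(zip(dictionary["icd9_code"], dictionary["long_title"]))
    out = {}
    for hadm, g in diagnoses.sort_values(["hadm_id", "seq_num"]).groupby("hadm_id"):
        out[int(hadm)] = Icd9Sequence([
            (int(r.seq_num), r.icd9_code, title_of.get(r.icd9_code, r.icd9_code))
            for r in g.itertuples(index=False)
        ])
    return out


class Icd9Vocabulary:
    """Code <-> index map with pad at 0 and a reserved unknown index at 1."""

    PAD, UNK = 0, 1

    def __init__(self, codes: list[str]):
        uniq = list(dict.fromkeys(codes))
        self.codes = uniq
        self.index = {c: i + 2 for i, c in enumerate(uniq)}
        self.unknown_seen = 0

    def __len__(self) -> int:
        return len(self.codes) + 2

    def __getitem__(self, code: str) -> int:
        idx = self.index.get(code)
        if idx is None:
            self.unknown_seen += 1
            return self.UNK
        return idx


def encode_icd9_onehot(seq: Icd9Sequence, vocab: Icd9Vocabulary, length: int) -> EncodedSample:
    """Code-index sequence in seq_num order, padded (or tail-truncated) to
    ``length``. Unknown codes map to the reserved UNK index and are counted
    on the vocabulary."""
    idx = [vocab[c] for c in seq.codes()]
    kept = idx[-length:] if len(idx) > length else idx
    indices = np.full(length, vocab.PAD, dtype=np.int64)
    mask = np.zeros(length, dtype=bool)
    indices[:len(kept)] = kept
    mask[:len(kept)] = True
    return EncodedSample(indices=indices, mask=mask, vocab_size=len(vocab))


def demographics_sentence(age_years: float, gender: str, insurance: str) -> str:
    g = {"M": "male", "F": "female"}.get(gender, gender.lower())
    return f"Patient is a {int(age_years)}-year-old {g} with {insurance} insurance."


def build_icd9_text(seq: Icd9Sequence, age_years: float, gender: str, insurance: str) -> str:
    """Textual ICD-9 representation: demographics sentence, the fixed prefix,
    then the long titles joined by ", " in seq_num order."""
    parts = [demographics_sentence(age_years, gender, insurance), ICD9_TEXT_PREFIX]
    if seq.entries:
        parts.append(", ".join(seq.titles()))
    return " ".join(parts)


@dataclass
class DemographicsSchema:
    """Category lists per demographic field; defines the one-hot layout.

    Age is bucketed 18-65 / >65, mirroring the cohort's demographic strata.
    """

    genders: list[str] = field(default_factory=lambda: ["M", "F"])
    age_buckets: list[tuple[float, float]] = field(
        default_factory=lambda: [(18.0, 65.0), (65.0, float("inf"))])
    insurances: list[str] = field(default_factory=lambda: [
        "Medicare", "Medicaid", "Private", "Government", "Self Pay"])
    ethnicities: list[str] = field(default_factory=lambda: [
        "WHITE", "BLACK/AFRICAN AMERICAN", "HISPANIC OR LATINO", "ASIAN", "OTHER"])

    @property
    def width(self) -> int:
        return (len(self.genders) + len(self.age_buckets)
                + len(self.insurances) + len(self.ethnicities))


def encode_demographics(record, schema: DemographicsSchema | None = None) -> np.ndarray:
    """Concatenated one-hot blocks for gender, age bucket, insurance and
    ethnicity; an unseen category yields an all-zero block (warning logged).
    ``record`` is any object/row with age_years, gender, insurance, ethnicity."""
    schema = schema or DemographicsSchema()
    blocks = []

    def onehot(value, categories, name):
        block = np.zeros(len(categories))
        if value in categories:
            block[categories.index(value)] = 1.0
        else:
            logger.warning("unseen %s category %r -> zero block", name, value)
        return block

    blocks.append(onehot(record.gender, schema.genders, "gender"))
    age_block = np.zeros(len(schema.age_buckets))
    for i, (lo, hi) in enumerate(schema.age_buckets):
        if lo <= record.age_years < hi or (math.isinf(hi) and record.age_years >= lo):
            age_block[i] = 1.0
            break
    blocks.append(age_block)
    blocks.append(onehot(record.insurance, schema.insurances, "insurance"))
    blocks.append(onehot(record.ethnicity, schema.ethnicities, "ethnicity"))
    return np.concatenate(blocks)


def preprocess_note(text: str) -> str:
    """Clean a raw note: lower-case, drop [** .. **] de-identification spans,
    collapse whitespace/line-break runs. Digits are kept."""
    if not text:
        return ""
    text = _DEID_RE.sub(" ", text)
    text = text.lower()
    return _WS_RE.sub(" ", text).strip()


class WhitespaceTokenizer:
    """Minimal injected tokenizer: whitespace splitting over a fitted vocab.

    Interface: ``encode(text) -> ids`` and ``decode(ids) -> text``; id 0 is
    reserved for padding, id 1 for out-of-vocabulary tokens.
    """

    PAD, UNK = 0, 1

    def __init__(self):
        self.vocab: dict[str, int] = {}
        self.inverse: dict[int, str] = {}

    def fit(self, texts: list[str]) -> "WhitespaceTokenizer":
        for t in texts:
            for w in t.split():
                if w not in self.vocab:
                    idx = len(self.vocab) + 2
                    self.vocab[w] = idx
                    self.inverse[idx] = w
        return self

    @property
    def vocab_size(self) -> int:
        return len(self.vocab) + 2

    def encode(self, text: str) -> list[int]:
        return [self.vocab.get(w, self.UNK) for w in text.split()]

    def decode(self, ids: list[int]) -> str:
        return " ".join(self.inverse.get(i, "<unk>") for i in ids if i != self.PAD)


@dataclass
class NoteChunks:
    """A note's token ids divided into fixed-length chunks."""

    chunks: list[list[int]]

    def __post_init__(self) -> None:
        if len(self.chunks) < 1:
            raise ValueError("a note must yield at least one chunk")

    @property
    def n(self) -> int:
        return len(self.chunks)

    def concatenated(self) -> list[int]:
        return [t for c in self.chunks for t in c]


def chunk_note(cleaned: str, tokenizer, chunk_length: int = 318) -> NoteChunks:
    """Greedy fixed-length token windows; the last chunk may be short and an
    empty note yields one empty chunk. n = ceil(token_count / chunk_length).

    The default window of 318 content tokens leaves room for special tokens
    in a 512-token-limit text encoder.
    """
    if chunk_length <= 0:
        raise ValueError("chunk_length must be positive")
    ids = tokenizer.encode(cleaned)
    if not ids:
        return NoteChunks([[]])
    return NoteChunks([ids[i:i + chunk_length] for i in range(0, len(ids), chunk_length)])
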
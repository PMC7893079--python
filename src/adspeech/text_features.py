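"""Language-stream inputs and the targeted psycholinguistic feature vector.

The language models consume two aligned token-level streams — pretrained word
embeddings and POS-tag ids — truncated/padded to a fixed length with a mask.
The targeted text vector couples four psycholinguistic norms (age of
acquisition, concreteness, familiarity, imageability) averaged over the
participant's tokens with a mean sentiment polarity and two demographic slots
(age, gender), always in that fixed order of seven values.

Norm averages use only tokens covered by the lexicon (coverage is partial by
nature); tokens without a sentiment score contribute zero polarity. The POS
tagger and sentiment scorer are pluggable callables; deterministic rule- and
lexicon-based defaults ship with the package so nothing here needs a model
download.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus_io import Transcript

#: The 17-tag universal POS inventory (default tagset).
UNIVERSAL_TAGS = (
    "ADJ", "ADP", "ADV", "AUX", "CCONJ", "DET", "INTJ", "NOUN", "NUM",
    "PART", "PRON", "PROPN", "PUNCT", "SCONJ", "SYM", "VERB", "X",
)

NORM_NAMES = ("age_of_acquisition", "concreteness", "familiarity", "imageability")


class EmbeddingTable:
    """Word -> fixed-dimension vector lookup; out-of-vocabulary words map to zeros."""

    def __init__(self, vocabulary: dict[str, int], vectors: np.ndarray):
        vectors = np.asarray(vectors, dtype=float)
        if vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D (vocab x dim) array")
        if max(vocabulary.values(), default=-1) >= vectors.shape[0]:
            raise ValueError("vocabulary index exceeds vector table")
        self.vocabulary = dict(vocabulary)
        self.vectors = vectors

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def lookup(self, word: str) -> np.ndarray:
        idx = self.vocabulary.get(word)
        if idx is None:
            return np.zeros(self.dim)
        return self.vectors[idx]

    @classmethod
    def from_text(cls, path: str | Path) -> "EmbeddingTable":
        """Read the standard word-vector text format: ``word v1 ... vd`` per line."""
        vocab: dict[str, int] = {}
        rows: list[list[float]] = []
        dim = None
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                parts = line.rstrip().split(" ")
                if len(parts) < 2:
                    continue
                word, values = parts[0], [float(v) for v in parts[1:]]
                if dim is None:
                    dim = len(values)
                elif len(values) != dim:
                    raise ValueError(f"line {lineno}: inconsistent vector dimension")
                if word in vocab:
                    raise ValueError(f"line {lineno}: duplicate word {word!r}")
                vocab[word] = len(rows)
                rows.append(values)
        if not rows:
            raise ValueError("empty embedding file")
        return cls(vocab, np.array(rows))


class PsycholinguisticLexicon:
    """Word -> (age_of_acquisition, concreteness, familiarity, imageability)."""

    def __init__(self, entries: dict[str, tuple[float, float, float, float]]):
        for word, norms in entries.items():
            if len(norms) != 4:
                raise ValueError(f"{word!r}: lexicon entry needs all four norms")
        self.entries = {w: tuple(float(v) for v in ns) for w, ns in entries.items()}

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, word: str):
        return self.entries.get(word)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PsycholinguisticLexicon":
        df = pd.read_csv(path)
        required = ["word", "aoa", "concreteness", "familiarity", "imageability"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"lexicon CSV missing columns {missing}")
        if df["word"].duplicated().any():
            raise ValueError("duplicate word in lexicon CSV")
        return cls({str(r.word): (r.aoa, r.concreteness, r.familiarity, r.imageability)
                    for r in df.itertuples()})


@dataclass(frozen=True)
class TargetedTextFeatures:
    """Fixed-order 7-vector enriching the language stream (model A1 / C)."""

    aoa_mean: float
    concreteness_mean: float
    familiarity_mean: float
    imageability_mean: float
    sentiment_mean: float
    age: float
    gender: int                     # female=0, male=1
    lexicon_coverage: float = 1.0   # diagnostic, not part of the vector

    def to_array(self) -> np.ndarray:
        return np.array([self.aoa_mean, self.concreteness_mean,
                         self.familiarity_mean, self.imageability_mean,
                         self.sentiment_mean, self.age, float(self.gender)])


@dataclass
class EncodedText:
    """Padded language-stream inputs for one participant."""

    embeddings: np.ndarray          # max_len x dim
    pos_ids: np.ndarray             # max_len ints indexing the tagset
    mask: np.ndarray                # max_len booleans


# ---------------------------------------------------------------------------
# Default backends (deterministic, no external model)
# ---------------------------------------------------------------------------

_CLOSED_CLASS = {
    "DET": {"the", "a", "an", "this", "that", "these", "those", "some", "any",
            "no", "every", "each"},
    "PRON": {"i", "you", "he", "she", "it", "we", "they", "me", "him", "her",
             "us", "them", "his", "hers", "its", "their", "my", "your", "our",
             "who", "what", "something", "someone"},
    "ADP": {"in", "on", "at", "of", "to", "from", "with", "by", "for", "into",
            "over", "under", "about", "near", "out", "off", "up", "down"},
    "CCONJ": {"and", "or", "but", "nor", "so", "yet"},
    "SCONJ": {"because", "while", "if", "although", "when", "since", "that"},
    "AUX": {"is", "are", "was", "were", "be", "been", "being", "am", "do",
            "does", "did", "have", "has", "had", "will", "would", "can",
            "could", "may", "might", "shall", "should", "must"},
    "PART": {"not", "n't"},
    "INTJ": {"oh", "well", "yes", "no", "okay", "mhm", "hmm", "huh"},
    "ADV": {"very", "too", "also", "now", "then", "here", "there", "again",
            "always", "never", "just", "still", "almost", "away"},
}

_VERB_SUFFIXES = ("ing", "ed", "ate", "ify", "ise", "ize")
_ADJ_SUFFIXES = ("ful", "ous", "ive", "able", "ible", "al", "ish", "less")
_ADJ_WORDS = {"little", "big", "small", "old", "young", "happy", "sad",
              "dirty", "clean", "tall", "short", "wet", "dry", "good", "bad",
              "nice", "full", "empty"}


def rule_pos_tagger(tokens: list[str]) -> list[str]:
    """Deterministic lexicon+suffix tagger over the universal tagset.

    Intentionally simple; the tagger is a pluggable backend and this default
    exists so the pipeline is self-contained and reproducible.
    """
    tags = []
    for tok in tokens:
        low = tok.lower()
        tag = None
        for t, words in _CLOSED_CLASS.items():
            if low in words:
                tag = t
                break
        if tag is None:
            if low.replace(".", "").replace("-", "").isdigit():
                tag = "NUM"
            elif low.endswith("ly"):
                tag = "ADV"
            elif low.endswith(_VERB_SUFFIXES) or low in {"go", "see", "fall",
                                                         "falls", "take", "takes",
                                                         "run", "runs", "eat",
                                                         "eats", "wash", "washes",
                                                         "reach", "reaches",
                                                         "spill", "spills"}:
                tag = "VERB"
            elif low in _ADJ_WORDS or low.endswith(_ADJ_SUFFIXES):
                tag = "ADJ"
            elif tok[:1].isupper():
                tag = "PROPN"
            else:
                tag = "NOUN"
        tags.append(tag)
    return tags


_DEFAULT_POLARITY = {
    "good": 1.0, "great": 1.0, "nice": 0.8, "happy": 0.9, "love": 0.9,
    "fine": 0.5, "pretty": 0.5, "clean": 0.3,
    "bad": -1.0, "awful": -1.0, "sad": -0.9, "wrong": -0.7, "dirty": -0.5,
    "trouble": -0.6, "mess": -0.5, "spill": -0.3, "fall": -0.3, "falls": -0.3,
}


def lexicon_sentiment_scorer(word: str) -> float:
    """Default word-polarity backend; unknown words score 0 (neutral)."""
    return _DEFAULT_POLARITY.get(word.lower(), 0.0)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def encode_text_inputs(transcript: Transcript, table: EmbeddingTable,
                       tagset: tuple[str, ...] = UNIVERSAL_TAGS,
                       max_len: int = 512,
                       tagger=rule_pos_tagger) -> EncodedText:
    """Build the padded embedding and POS-id streams from participant turns only."""
    if max_len < 1:
        raise ValueError("max_len must be positive")
    tokens = transcript.participant_tokens()
    if not tokens:
        raise ValueError(f"{transcript.participant_id}: no participant tokens")
    tags = tagger(tokens)
    tag_index = {t: i for i, t in enumerate(tagset)}
    unknown = [t for t in tags if t not in tag_index]
    if unknown:
        raise ValueError(f"tagger produced tags outside the tagset: {sorted(set(unknown))}")

    tokens, tags = tokens[:max_len], tags[:max_len]
    emb = np.zeros((max_len, table.dim))
    pos = np.zeros(max_len, dtype=int)
    mask = np.zeros(max_len, dtype=bool)
    for i, (tok, tag) in enumerate(zip(tokens, tags)):
        emb[i] = table.lookup(tok)
        pos[i] = tag_index[tag]
        mask[i] = True
    return EncodedText(embeddings=emb, pos_ids=pos, mask=mask)


def average_lexicon_features(tokens: list[str],
                             lexicon: PsycholinguisticLexicon
                             ) -> tuple[np.ndarray, float]:
    """Per-norm means over the tokens found in the lexicon, plus coverage.

    Returns a length-4 array ordered (aoa, concreteness, familiarity,
    imageability). With zero lexicon hits the means are NaN sentinels and a
    warning is issued.
    """
    if not tokens:
        raise ValueError("average_lexicon_features requires >=1 token")
    hits = [lexicon.get(t.lower()) for t in tokens]
    hits = [h for h in hits if h is not None]
    coverage = len(hits) / len(tokens)
    if not hits:
        warnings.warn("no tokens found in psycholinguistic lexicon; "
                      "norm means are missing", stacklevel=2)
        return np.full(4, np.nan), 0.0
    return np.asarray(hits, dtype=float).mean(axis=0), coverage


def average_sentiment(tokens: list[str], scorer=lexicon_sentiment_scorer) -> float:
    """Mean polarity over tokens; unscored tokens contribute 0."""
    if not tokens:
        raise ValueError("average_sentiment requires >=1 token")
    return float(np.mean([scorer(t) for t in tokens]))


def build_targeted_text_vector(transcript: Transcript,
                               lexicon: PsycholinguisticLexicon,
                               scorer=lexicon_sentiment_scorer,
                               age: float | None = None,
                               gender: str | None = None) -> TargetedTextFeatures:
    """Assemble the 7-slot targeted text vector for one participant."""
    if age is None or (isinstance(age, float) and math.isnan(age)):
        raise ValueError(f"{transcript.participant_id}: missing age")
    if gender not in ("male", "female"):
        raise ValueError(f"{transcript.participant_id}: gender must be male/female")
    tokens = transcript.participant_tokens()
    if not tokens:
        raise ValueError(f"{transcript.participant_id}: no participant tokens")
    norms, coverage = average_lexicon_features(tokens, lexicon)
    return TargetedTextFeatures(
        aoa_mean=float(norms[0]), concreteness_mean=float(norms[1]),
        familiarity_mean=float(norms[2]), imageability_mean=float(norms[3]),
        sentiment_mean=average_sentiment(tokens, scorer),
        age=float(age), gender=1 if gender == "male" else 0,
        lexicon_coverage=coverage,
    )
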
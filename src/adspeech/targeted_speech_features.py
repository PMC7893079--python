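"""AD-specific targeted features enriching the speech stream (models B1 and C).

Three groups, 14 values in total per participant:

* six segment-length statistics over the session's VAD segment durations
  (mean, median, sample sd, min, max, count);
* six disfluency/intervention rates from the transcript — word rate and
  interviewer-intervention rate per minute, plus filled-pause, unfilled-pause,
  repetition and retrace rates per participant word (per-word rates are robust
  to session length);
* two idea-density values, DEPID and DEPID-R. DEPID counts proposition-bearing
  dependency relations in the participant's utterances per participant word;
  DEPID-R discounts repeated propositions by deduplicating identical
  (head-lemma, relation, dependent-lemma) triples across the transcript —
  repetition of ideas being itself characteristic of AD speech.

The dependency parser is a pluggable callable ``tokens -> [(head, rel, dep)]``;
a deterministic heuristic parser ships as the default so the pipeline runs
without an external NLP model. The proposition-bearing relation list is read
from an editable data file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .corpus_io import (
    FILLED_PAUSE,
    PARTICIPANT,
    REPETITION,
    RETRACE,
    Transcript,
    UNFILLED_PAUSE,
)
from .text_features import rule_pos_tagger


@dataclass(frozen=True)
class SegLenStats:
    mean_s: float
    median_s: float
    sd_s: float
    min_s: float
    max_s: float
    count: int

    def to_array(self) -> np.ndarray:
        return np.array([self.mean_s, self.median_s, self.sd_s,
                         self.min_s, self.max_s, float(self.count)])


@dataclass(frozen=True)
class DisfluencyFeatures:
    word_rate: float                # participant words per minute
    intervention_rate: float        # interviewer utterances per minute
    filled_pause_rate: float        # events per participant word
    unfilled_pause_rate: float
    repetition_rate: float
    retrace_rate: float

    def to_array(self) -> np.ndarray:
        return np.array([self.word_rate, self.intervention_rate,
                         self.filled_pause_rate, self.unfilled_pause_rate,
                         self.repetition_rate, self.retrace_rate])


@dataclass(frozen=True)
class IdeaDensity:
    depid: float                    # propositions per participant word
    depid_r: float                  # with repeated propositions removed

    def __post_init__(self):
        if not (0.0 <= self.depid_r <= self.depid + 1e-12):
            raise ValueError("invariant violated: 0 <= depid_r <= depid")

    def to_array(self) -> np.ndarray:
        return np.array([self.depid, self.depid_r])


def segment_length_statistics(durations) -> SegLenStats:
    """Six statistics of the session's segment durations; sd is the sample sd
    (defined as 0 for a single segment)."""
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise ValueError("segment_length_statistics requires >=1 duration")
    if (d <= 0).any():
        raise ValueError("durations must be strictly positive")
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return SegLenStats(mean_s=float(d.mean()), median_s=float(np.median(d)),
                       sd_s=sd, min_s=float(d.min()), max_s=float(d.max()),
                       count=int(d.size))


def disfluency_intervention_features(transcript: Transcript,
                                     session_minutes: float) -> DisfluencyFeatures:
    """Word/intervention rates per minute and four marker rates per word."""
    if session_minutes <= 0:
        raise ValueError("session_minutes must be positive")
    n_words = len(transcript.participant_tokens())
    n_interventions = transcript.interviewer_utterance_count()
    if n_words == 0:
        warnings.warn("zero participant words; marker rates undefined (NaN)",
                      stacklevel=2)
        per_word = [float("nan")] * 4
    else:
        per_word = [transcript.marker_count(k) / n_words
                    for k in (FILLED_PAUSE, UNFILLED_PAUSE, REPETITION, RETRACE)]
    return DisfluencyFeatures(
        word_rate=n_words / session_minutes,
        intervention_rate=n_interventions / session_minutes,
        filled_pause_rate=per_word[0], unfilled_pause_rate=per_word[1],
        repetition_rate=per_word[2], retrace_rate=per_word[3],
    )


# ---------------------------------------------------------------------------
# DEPID / DEPID-R
# ---------------------------------------------------------------------------

def load_proposition_relations(path: str | Path | None = None) -> frozenset[str]:
    """Read the proposition-bearing dependency-relation list (one per line,
    '#' comments); defaults to the table shipped with the package."""
    if path is None:
        text = (resources.files("adspeech") / "data" / "depid_relations.txt").read_text()
    else:
        text = Path(path).read_text()
    rels = {line.strip() for line in text.splitlines()
            if line.strip() and not line.lstrip().startswith("#")}
    if not rels:
        raise ValueError("empty proposition-relation table")
    return frozenset(rels)


def heuristic_dependency_parser(tokens: list[str]) -> list[tuple[str, str, str]]:
    """Deterministic rule-based dependency triples for simple declarative clauses.

    Built on the rule POS tagger: the first verb (or auxiliary, failing that)
    roots the clause; the nearest preceding nominal attaches as nsubj and
    following nominals as obj/obl (obl when introduced by an adposition);
    determiners and adjectives attach to the next nominal (det/amod), adverbs
    to the root (advmod), adpositions to the following nominal (case).
    Adequate for the template sentences of the synthetic cohorts; replaceable
    by any callable with the same signature for real text.
    """
    if not tokens:
        return []
    low = [t.lower() for t in tokens]
    tags = rule_pos_tagger(tokens)
    nominal = {"NOUN", "PROPN", "PRON", "NUM"}

    root = None
    for i, t in enumerate(tags):
        if t == "VERB":
            root = i
            break
    if root is None:
        for i, t in enumerate(tags):
            if t == "AUX":
                root = i
                break
    triples: list[tuple[str, str, str]] = []
    subj_taken = False
    obj_taken = False

    def next_nominal(start: int) -> int | None:
        for j in range(start + 1, len(tokens)):
            if tags[j] in nominal:
                return j
        return None

    for i, tag in enumerate(tags):
        if i == root:
            continue
        if tag in ("DET",):
            j = next_nominal(i)
            if j is not None:
                triples.append((low[j], "det", low[i]))
        elif tag == "ADJ":
            j = next_nominal(i)
            if j is not None:
                triples.append((low[j], "amod", low[i]))
            elif root is not None:
                triples.append((low[root], "xcomp", low[i]))
        elif tag == "ADP":
            j = next_nominal(i)
            if j is not None:
                triples.append((low[j], "case", low[i]))
        elif tag == "ADV" and root is not None:
            triples.append((low[root], "advmod", low[i]))
        elif tag == "AUX" and root is not None and i != root:
            triples.append((low[root], "aux", low[i]))
        elif tag in nominal and root is not None:
            prev_adp = any(tags[k] == "ADP" for k in range(max(0, i - 2), i))
            if i < root and not subj_taken:
                triples.append((low[root], "nsubj", low[i]))
                subj_taken = True
            elif i > root and prev_adp:
                triples.append((low[root], "obl", low[i]))
            elif i > root and not obj_taken:
                triples.append((low[root], "obj", low[i]))
                obj_taken = True
            else:
                triples.append((low[root], "nmod", low[i]))
        elif tag == "CCONJ" and root is not None:
            triples.append((low[root], "cc", low[i]))
    return triples


def compute_depid(transcript: Transcript,
                  parser=heuristic_dependency_parser,
                  relations: frozenset[str] | None = None) -> IdeaDensity:
    """Dependency-based propositional idea density (DEPID, DEPID-R)."""
    if relations is None:
        relations = load_proposition_relations()
    n_words = 0
    all_triples: list[tuple[str, str, str]] = []
    parsed_any = False
    for u in transcript.utterances:
        if u.speaker != PARTICIPANT or not u.tokens:
            continue
        try:
            triples = parser(list(u.tokens))
        except Exception as exc:              # parser failure: skip, adjust count
            warnings.warn(f"parser failed on utterance ({exc}); skipped",
                          stacklevel=2)
            continue
        parsed_any = True
        n_words += len(u.tokens)
        all_triples.extend(triples)
    if not parsed_any or n_words == 0:
        raise ValueError("compute_depid requires >=1 parsable participant utterance")
    bearing = [t for t in all_triples if t[1] in relations]
    unique = set(bearing)
    return IdeaDensity(depid=len(bearing) / n_words,
                       depid_r=len(unique) / n_words)


def targeted_speech_vector(transcript: Transcript, durations,
                           parser=heuristic_dependency_parser,
                           relations: frozenset[str] | None = None) -> np.ndarray:
    """The full 14-value targeted speech-feature vector (6 + 6 + 2).

    Session minutes are taken as the summed VAD segment durations.
    """
    seg = segment_length_statistics(durations)
    minutes = float(np.sum(np.asarray(durations, dtype=float))) / 60.0
    disf = disfluency_intervention_features(transcript, minutes)
    density = compute_depid(transcript, parser=parser, relations=relations)
    return np.concatenate([seg.to_array(), disf.to_array(), density.to_array()])
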
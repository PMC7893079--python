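"""Synthetic cohorts with the structure of a balanced picture-description study.

The generator emulates the data layout the pipeline expects — one session per
participant, 54+54 train and 24+24 test participants, per-participant VAD
segment counts drawn from a truncated normal around mean 24.86 (sd 12.84,
min 3), balanced age and gender — with controllable class signal:

* **acoustic effect** — a designated block of per-segment features is shifted
  by ``delta`` (in pooled-sd units) for the AD class, optionally with a linear
  within-session drift across segment index that only a temporal model (not a
  mean-pool) can exploit;
* **duration-correlated block** — a fraction of features is constructed as
  ``a * duration + noise`` so the duration-correlation filter has real work;
* **transcript effect** — AD participants produce elevated filled/unfilled
  pause, repetition and retrace probabilities, more verb-less fragment
  utterances (lower propositional idea density) and more semantically vague
  words.

Transcripts are built from templated picture-description clauses over a small
closed vocabulary, so the deterministic POS-tagger/parser backends cover them
exactly. Durations are lognormal (positive, right-skewed, like speech chunks).
No attempt is made at realistic English discourse or acoustic waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import (
    Cohort,
    FILLED_PAUSE,
    INTERVIEWER,
    Marker,
    PARTICIPANT,
    Participant,
    REPETITION,
    RETRACE,
    SessionAcoustics,
    Transcript,
    UNFILLED_PAUSE,
    Utterance,
)
from .evaluation import CohortResources
from .text_features import EmbeddingTable, PsycholinguisticLexicon

# closed vocabulary for templated clauses (coverable by the rule backends)
_DETS = ["the", "a"]
_NOUNS = ["boy", "girl", "mother", "cookie", "jar", "stool", "water", "sink",
          "window", "plate", "curtain", "dish", "cup", "floor", "kitchen"]
_VERBS = ["falls", "takes", "washes", "spills", "reaches", "runs", "eats", "sees"]
_ADJS = ["little", "happy", "dirty", "tall", "wet"]
_VAGUE = ["thing", "stuff"]
_INV_PROMPTS = [["okay"], ["mhm"], ["and", "then"], ["what", "else"]]


@dataclass(frozen=True)
class TranscriptEffect:
    """Per-class token/marker generation probabilities."""

    p_filled: float = 0.05          # filled-pause marker per participant word
    p_unfilled: float = 0.05
    p_repetition: float = 0.02
    p_retrace: float = 0.01
    p_fragment: float = 0.10        # verb-less utterance (lowers idea density)
    p_vague: float = 0.05           # vague noun substitution
    n_utterances_mean: float = 14.0

    def __post_init__(self):
        for name in ("p_filled", "p_unfilled", "p_repetition", "p_retrace",
                     "p_fragment", "p_vague"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")


AD_TRANSCRIPT_EFFECT = TranscriptEffect(p_filled=0.30, p_unfilled=0.15,
                                        p_repetition=0.10, p_retrace=0.05,
                                        p_fragment=0.40, p_vague=0.25)
NONAD_TRANSCRIPT_EFFECT = TranscriptEffect()


@dataclass
class SimConfig:
    n_train_per_class: int = 54
    n_test_per_class: int = 24
    # segment-count distribution (truncated normal)
    segment_mean: float = 24.86
    segment_sd: float = 12.84
    segment_min: int = 3
    # acoustic features
    n_acoustic_features: int = 40
    n_effect_features: int = 5
    effect_delta: float = 2.0       # AD mean shift in pooled-sd units
    trend_slope: float = 0.0        # optional AD within-session linear drift
    dur_corr_fraction: float = 0.2  # features built as a*duration + noise
    dur_corr_coef: float = 1.0
    dur_corr_noise_sd: float = 0.1
    # transcripts
    ad_transcript: TranscriptEffect = field(default_factory=lambda: AD_TRANSCRIPT_EFFECT)
    nonad_transcript: TranscriptEffect = field(default_factory=lambda: NONAD_TRANSCRIPT_EFFECT)
    # resources
    embedding_dim: int = 16
    seed: int = 0

    def __post_init__(self):
        if min(self.n_train_per_class, self.n_test_per_class) < 1:
            raise ValueError("participant counts must be positive")
        if self.n_acoustic_features < 1:
            raise ValueError("need at least one acoustic feature")
        n_dur = int(round(self.dur_corr_fraction * self.n_acoustic_features))
        if n_dur + self.n_effect_features > self.n_acoustic_features:
            raise ValueError("duration-correlated + effect features exceed total")

    @property
    def n_dur_corr_features(self) -> int:
        return int(round(self.dur_corr_fraction * self.n_acoustic_features))

    def feature_names(self) -> tuple[str, ...]:
        names = [f"dur_{i:03d}" for i in range(self.n_dur_corr_features)]
        names += [f"sig_{i:03d}" for i in range(self.n_effect_features)]
        names += [f"noise_{i:03d}"
                  for i in range(self.n_acoustic_features - len(names))]
        return tuple(names)


# ---------------------------------------------------------------------------
# Transcripts
# ---------------------------------------------------------------------------

def _clause(effect: TranscriptEffect, rng: np.random.Generator) -> list[str]:
    def noun():
        if rng.random() < effect.p_vague:
            return _VAGUE[rng.integers(len(_VAGUE))]
        return _NOUNS[rng.integers(len(_NOUNS))]

    det = _DETS[rng.integers(len(_DETS))]
    subject = noun()
    if rng.random() < effect.p_fragment:
        # verb-less fragment: carries no proposition-bearing verb relations
        return [det, subject]
    verb = _VERBS[rng.integers(len(_VERBS))]
    tokens = [det, subject, verb]
    if rng.random() < 0.6:
        det2 = _DETS[rng.integers(len(_DETS))]
        if rng.random() < 0.3:
            tokens += [det2, _ADJS[rng.integers(len(_ADJS))], noun()]
        else:
            tokens += [det2, noun()]
    return tokens


def simulate_transcript(label: str, effect: TranscriptEffect,
                        rng: np.random.Generator,
                        participant_id: str = "sim") -> Transcript:
    """One interleaved *PAR/*INV transcript with class-conditional marker rates."""
    n_utt = max(3, int(rng.poisson(effect.n_utterances_mean)))
    utterances: list[Utterance] = []
    for _ in range(n_utt):
        tokens = _clause(effect, rng)
        markers: list[Marker] = []
        for pos in range(len(tokens) + 1):
            # marker slots between tokens; probabilities are per word
            if pos < len(tokens):
                if rng.random() < effect.p_filled:
                    markers.append(Marker(FILLED_PAUSE, pos))
                if rng.random() < effect.p_unfilled:
                    markers.append(Marker(UNFILLED_PAUSE, pos))
                if rng.random() < effect.p_repetition:
                    markers.append(Marker(REPETITION, pos))
                if rng.random() < effect.p_retrace:
                    markers.append(Marker(RETRACE, pos))
        markers.sort(key=lambda m: m.position)
        utterances.append(Utterance(PARTICIPANT, tuple(tokens), tuple(markers)))
        if rng.random() < 0.25:
            prompt = _INV_PROMPTS[rng.integers(len(_INV_PROMPTS))]
            utterances.append(Utterance(INTERVIEWER, tuple(prompt)))
    return Transcript(participant_id, tuple(utterances))


# ---------------------------------------------------------------------------
# Acoustics
# ---------------------------------------------------------------------------

def simulate_session_acoustics(label: str, segment_count: int, config: SimConfig,
                               rng: np.random.Generator,
                               participant_id: str = "sim") -> SessionAcoustics:
    """Per-segment feature matrix: duration-correlated, class-signal, noise blocks."""
    if segment_count < 1:
        raise ValueError("segment_count must be >= 1")
    durations = rng.lognormal(mean=0.9, sigma=0.5, size=segment_count)
    n_dur = config.n_dur_corr_features
    n_sig = config.n_effect_features
    n_noise = config.n_acoustic_features - n_dur - n_sig

    blocks = []
    if n_dur:
        blocks.append(config.dur_corr_coef * durations[:, None]
                      + rng.normal(0, config.dur_corr_noise_sd,
                                   (segment_count, n_dur)))
    if n_sig:
        shift = config.effect_delta if label == "AD" else 0.0
        sig = rng.normal(shift, 1.0, (segment_count, n_sig))
        if label == "AD" and config.trend_slope:
            drift = config.trend_slope * (np.arange(segment_count)
                                          / max(1, segment_count - 1))
            sig += drift[:, None]
        blocks.append(sig)
    if n_noise:
        blocks.append(rng.normal(0, 1.0, (segment_count, n_noise)))
    return SessionAcoustics(participant_id=participant_id,
                            feature_set_name="custom",
                            matrix=np.hstack(blocks), durations=durations,
                            feature_names=config.feature_names())


# ---------------------------------------------------------------------------
# Cohort and resources
# ---------------------------------------------------------------------------

def _segment_count(config: SimConfig, rng: np.random.Generator) -> int:
    while True:
        n = int(round(rng.normal(config.segment_mean, config.segment_sd)))
        if n >= config.segment_min:
            return n


def simulate_cohort(config: SimConfig | None = None) -> Cohort:
    """A full reproducible cohort: transcripts, acoustics, metadata, split."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    participants: list[Participant] = []
    split: dict[str, str] = {}
    for which, n_per_class in (("train", config.n_train_per_class),
                               ("test", config.n_test_per_class)):
        for label in ("AD", "non-AD"):
            effect = (config.ad_transcript if label == "AD"
                      else config.nonad_transcript)
            for i in range(n_per_class):
                pid = f"{which}_{'ad' if label == 'AD' else 'cn'}_{i:03d}"
                # age/gender balanced by construction: both classes share the
                # same deterministic age ladder and alternating gender
                age = 55 + (i % 26)
                gender = "male" if i % 2 == 0 else "female"
                transcript = simulate_transcript(label, effect, rng, pid)
                acoustics = simulate_session_acoustics(
                    label, _segment_count(config, rng), config, rng, pid)
                participants.append(Participant(pid, label, float(age), gender,
                                                transcript, acoustics))
                split[pid] = which
    return Cohort(participants, split)


def vocabulary() -> tuple[str, ...]:
    words = sorted(set(_DETS + _NOUNS + _VERBS + _ADJS + _VAGUE
                       + [w for p in _INV_PROMPTS for w in p]))
    return tuple(words)


def simulate_resources(config: SimConfig | None = None) -> CohortResources:
    """Synthetic embedding table (random unit vectors) and psycholinguistic
    lexicon (uniform over plausible norm ranges), fixed by the config seed."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed + 10_007)
    words = vocabulary()
    vecs = rng.normal(size=(len(words), config.embedding_dim))
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    table = EmbeddingTable({w: i for i, w in enumerate(words)}, vecs)
    lexicon = PsycholinguisticLexicon({
        w: (float(rng.uniform(2, 12)),      # age of acquisition, years
            float(rng.uniform(1, 7)),       # concreteness
            float(rng.uniform(1, 7)),       # familiarity
            float(rng.uniform(1, 7)))       # imageability
        for w in words
    })
    return CohortResources(embedding_table=table, lexicon=lexicon)
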
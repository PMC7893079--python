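"""The five classifier architectures.

* **A0** — language stream only: GloVe-style word embeddings and POS-tag
  one-hots pass through parallel temporal convolutions (kernel sizes 3/4/5),
  dropout, and a unidirectional LSTM whose last state feeds a dense layer and
  a sigmoid output.
* **A1** — A0 with the LSTM made bidirectional, additive attention pooling
  over the hidden states, and a dense sub-network consuming the 7-value
  targeted text vector (psycholinguistic/sentiment/demographic).
* **B0** — speech stream only: a GRU over the temporally ordered per-segment
  acoustic feature vectors; the final hidden state (the session's "common
  vector") feeds a dense layer and a sigmoid output.
* **B1** — B0 plus a dense sub-network on the 14 targeted speech features
  (segment-length statistics, disfluency/intervention rates, idea density).
* **C** — bi-modal late fusion: the latent dense outputs of the A1 and B1
  streams concatenated, then a dense layer and a sigmoid output.

Every model maps a batch dict of numpy arrays to one P(AD) probability per
participant. AD is the positive class throughout. Dropout (rate 0.5 between
convolution and recurrence) is active only in training mode, so inference is
deterministic.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np

from . import nn
from .nn import Tensor

MODEL_KINDS = ("A0", "A1", "B0", "B1", "C")

#: batch dict keys per stream
TEXT_KEYS = ("text_emb", "text_pos", "text_mask")
TEXT_TARGETED_KEY = "text_targeted"
SPEECH_KEYS = ("speech", "speech_mask")
SPEECH_TARGETED_KEY = "speech_targeted"

N_TEXT_TARGETED = 7
N_SPEECH_TARGETED = 14


@dataclass
class ModelConfig:
    kind: str = "B0"
    # text stream
    embedding_dim: int = 50
    n_pos_tags: int = 17
    conv_filter_sizes: tuple[int, ...] = (3, 4, 5)
    conv_filters: int = 64
    text_recurrent_width: int = 64
    dropout: float = 0.5
    # speech stream
    n_acoustic_features: int = 88
    gru_width: int = 64
    speech_bidirectional: bool = False
    speech_attention: bool = False
    # targeted-feature sub-networks and fusion
    targeted_dense_width: int = 32
    fusion_dense_width: int = 32

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}, got {self.kind!r}")
        if self.kind == "C" and (self.embedding_dim < 1 or self.n_acoustic_features < 1):
            raise ValueError("model C requires both a text and a speech stream")
        if self.kind in ("A0", "A1", "C") and self.embedding_dim < 1:
            raise ValueError(f"model {self.kind} requires a text stream")
        if self.kind in ("B0", "B1", "C") and self.n_acoustic_features < 1:
            raise ValueError(f"model {self.kind} requires a speech stream")

    # architecture invariants, derived from the kind
    @property
    def text_bidirectional(self) -> bool:
        return self.kind in ("A1", "C")

    @property
    def text_attention(self) -> bool:
        return self.kind in ("A1", "C")

    @property
    def uses_text_targeted(self) -> bool:
        return self.kind in ("A1", "C")

    @property
    def uses_speech_targeted(self) -> bool:
        return self.kind in ("B1", "C")

    def input_signature(self) -> tuple[str, ...]:
        keys: list[str] = []
        if self.kind in ("A0", "A1", "C"):
            keys += list(TEXT_KEYS)
            if self.uses_text_targeted:
                keys.append(TEXT_TARGETED_KEY)
        if self.kind in ("B0", "B1", "C"):
            keys += list(SPEECH_KEYS)
            if self.uses_speech_targeted:
                keys.append(SPEECH_TARGETED_KEY)
        return tuple(keys)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_filter_sizes"] = list(self.conv_filter_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "conv_filter_sizes" in d:
            d["conv_filter_sizes"] = tuple(d["conv_filter_sizes"])
        return cls(**d)


class _TextStream(nn.Module):
    """Parallel convolutions -> dropout -> (Bi)LSTM -> last state or attention."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        conv_in_emb = cfg.embedding_dim
        conv_in_pos = cfg.n_pos_tags
        self.convs_emb = [nn.Conv1D(conv_in_emb, cfg.conv_filters, k, rng)
                          for k in cfg.conv_filter_sizes]
        self.convs_pos = [nn.Conv1D(conv_in_pos, cfg.conv_filters, k, rng)
                          for k in cfg.conv_filter_sizes]
        self.dropout = nn.Dropout(cfg.dropout, rng)
        conv_out = cfg.conv_filters * len(cfg.conv_filter_sizes)
        W = cfg.text_recurrent_width
        if cfg.text_bidirectional:
            self.rnn_emb = nn.BiLSTM(conv_out, W, rng)
            self.rnn_pos = nn.BiLSTM(conv_out, W, rng)
            state_w = 2 * W
        else:
            self.rnn_emb = nn.LSTM(conv_out, W, rng)
            self.rnn_pos = nn.LSTM(conv_out, W, rng)
            state_w = W
        if cfg.text_attention:
            self.attn_emb = nn.AttentionPool(state_w, rng)
            self.attn_pos = nn.AttentionPool(state_w, rng)
        self.out_width = 2 * state_w

    def _one(self, x: Tensor, mask: np.ndarray, convs, rnn, attn) -> Tensor:
        feats = nn.concatenate([c(x, mask) for c in convs], axis=2).relu()
        feats = self.dropout(feats)
        states = rnn(feats, mask)
        if self.cfg.text_attention:
            return attn(states, mask)
        return states[:, states.shape[1] - 1, :]    # mask carries last true state

    def __call__(self, batch: dict) -> Tensor:
        emb = Tensor(batch["text_emb"])
        pos_ids = np.asarray(batch["text_pos"], dtype=int)
        onehot = np.eye(self.cfg.n_pos_tags)[pos_ids]
        pos = Tensor(onehot)
        mask = np.asarray(batch["text_mask"], dtype=bool)
        ve = self._one(emb, mask, self.convs_emb, self.rnn_emb,
                       getattr(self, "attn_emb", None))
        vp = self._one(pos, mask, self.convs_pos, self.rnn_pos,
                       getattr(self, "attn_pos", None))
        return nn.concatenate([ve, vp], axis=1)


class _SpeechStream(nn.Module):
    """(Bi)GRU over padded segment sequences; final-state (or attention) readout."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.gru = nn.GRU(cfg.n_acoustic_features, cfg.gru_width, rng)
        self.out_width = cfg.gru_width
        if cfg.speech_bidirectional:
            self.gru_bwd = nn.GRU(cfg.n_acoustic_features, cfg.gru_width, rng)
            self.out_width = 2 * cfg.gru_width
        if cfg.speech_attention:
            self.attn = nn.AttentionPool(self.out_width, rng)

    def __call__(self, batch: dict) -> Tensor:
        x = Tensor(batch["speech"])
        mask = np.asarray(batch["speech_mask"], dtype=bool)
        states = self.gru(x, mask)
        if self.cfg.speech_bidirectional:
            states = nn.concatenate([states, self.gru_bwd(x, mask, reverse=True)],
                                    axis=2)
        if self.cfg.speech_attention:
            return self.attn(states, mask)
        if self.cfg.speech_bidirectional:
            # forward half reads last true state at T-1; backward half at t=0
            T = states.shape[1]
            H = self.cfg.gru_width
            fwd_last = states[:, T - 1, :][:, :H]
            bwd_first = states[:, 0, :][:, H:]
            return nn.concatenate([fwd_last, bwd_first], axis=1)
        return states[:, states.shape[1] - 1, :]


class Model(nn.Module):
    """A built architecture: forward contract ``batch dict -> P(AD) per row``."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        if config.kind == "C":
            # the bi-modal model contains exactly the A1 and B1 streams; their
            # latent dense outputs are concatenated before the output layer
            self.a1 = Model(replace(config, kind="A1"),
                            seed=int(rng.integers(2**31)))
            self.b1 = Model(replace(config, kind="B1"),
                            seed=int(rng.integers(2**31)))
            width = 2 * config.fusion_dense_width
        else:
            width = 0
            if config.kind in ("A0", "A1"):
                self.text = _TextStream(config, rng)
                width += self.text.out_width
                if config.uses_text_targeted:
                    self.text_targeted = nn.Dense(N_TEXT_TARGETED,
                                                  config.targeted_dense_width, rng,
                                                  activation="relu")
                    width += config.targeted_dense_width
            if config.kind in ("B0", "B1"):
                self.speech = _SpeechStream(config, rng)
                width += self.speech.out_width
                if config.uses_speech_targeted:
                    self.speech_targeted = nn.Dense(N_SPEECH_TARGETED,
                                                    config.targeted_dense_width, rng,
                                                    activation="relu")
                    width += config.targeted_dense_width
        self.fusion = nn.Dense(width, config.fusion_dense_width, rng,
                               activation="relu")
        self.head = nn.Dense(config.fusion_dense_width, 1, rng)

    def _check_inputs(self, batch: dict):
        missing = [k for k in self.config.input_signature() if k not in batch]
        if missing:
            raise ValueError(f"model {self.config.kind} missing inputs {missing}")

    def latent(self, batch: dict) -> Tensor:
        """The fused dense representation (pre-output); model C concatenates these."""
        self._check_inputs(batch)
        if self.config.kind == "C":
            return self.fusion(nn.concatenate(
                [self.a1.latent(batch), self.b1.latent(batch)], axis=1))
        parts: list[Tensor] = []
        if hasattr(self, "text"):
            parts.append(self.text(batch))
            if hasattr(self, "text_targeted"):
                parts.append(self.text_targeted(Tensor(batch["text_targeted"])))
        if hasattr(self, "speech"):
            parts.append(self.speech(batch))
            if hasattr(self, "speech_targeted"):
                parts.append(self.speech_targeted(Tensor(batch["speech_targeted"])))
        return self.fusion(nn.concatenate(parts, axis=1))

    def logits(self, batch: dict) -> Tensor:
        return self.head(self.latent(batch)).reshape(-1)

    def forward(self, batch: dict, training: bool = False) -> np.ndarray:
        """Probabilities P(AD), one per participant; deterministic when not training."""
        self.set_training(training)
        probs = self.logits(batch).sigmoid().data
        self.set_training(False)
        if probs.ndim != 1:
            raise ValueError("expected one probability per participant")
        return probs


def build_model(config: ModelConfig, seed: int = 0) -> Model:
    """Instantiate one of the five architectures with reproducible initialization."""
    return Model(config, seed=seed)


def slice_batch(batch: dict, idx: np.ndarray) -> dict:
    return {k: np.asarray(v)[idx] for k, v in batch.items()}


def batch_size(batch: dict) -> int:
    return len(next(iter(batch.values())))
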
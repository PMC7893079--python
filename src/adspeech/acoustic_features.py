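"""Acoustic feature-set management for the speech stream.

Covers the three standard paralinguistic feature banks (emobase, eGeMAPS,
ComParE), the duration-correlation filter that removes per-segment features
carrying segment-length information, train-statistics z-scoring, and padding
of variable-length segment sequences into a masked batch tensor for the GRU.

The filter computes, for every feature, the Pearson correlation between the
feature and the segment duration over all segments of the cohort pooled
(fit_scope="all", the default, matching how the upstream preprocessing is
described; "train" restricts pooling to the train split as the leakage-safe
alternative). Features with |R| above the threshold are removed, as are
zero-variance features, for which the correlation is undefined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .corpus_io import Cohort, SessionAcoustics

FEATURE_SET_DIMENSIONS = {"emobase": 1582, "eGeMAPS": 88, "ComParE": 6373}


@dataclass(frozen=True)
class FeatureSetInfo:
    name: str
    expected_dimension: int

    @classmethod
    def named(cls, name: str) -> "FeatureSetInfo":
        if name not in FEATURE_SET_DIMENSIONS:
            raise KeyError(f"unknown feature set {name!r}; "
                           f"known: {sorted(FEATURE_SET_DIMENSIONS)} or use custom")
        return cls(name, FEATURE_SET_DIMENSIONS[name])

    def validate(self, session: SessionAcoustics):
        if session.feature_set_name != self.name:
            raise ValueError(f"session {session.participant_id} claims "
                             f"{session.feature_set_name!r}, expected {self.name!r}")
        if session.matrix.shape[1] != self.expected_dimension:
            raise ValueError(
                f"session {session.participant_id}: {session.matrix.shape[1]} "
                f"features, {self.name} defines {self.expected_dimension}")


@dataclass
class FilterResult:
    retained: tuple[str, ...]
    removed: tuple[str, ...]
    r_values: dict[str, float]
    zero_variance: tuple[str, ...] = ()
    threshold: float = 0.2

    def retained_indices(self, feature_names: tuple[str, ...]) -> np.ndarray:
        keep = set(self.retained)
        return np.array([i for i, n in enumerate(feature_names) if n in keep],
                        dtype=int)


@dataclass
class PaddedSequenceBatch:
    tensor: np.ndarray              # participants x max_segments x features
    mask: np.ndarray                # participants x max_segments booleans
    order: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if self.tensor.shape[:2] != self.mask.shape:
            raise ValueError("tensor and mask disagree on batch/time shape")
        if not np.allclose(self.tensor[~self.mask], 0.0):
            raise ValueError("masked-out rows must be zero")


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient of two equal-length sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson_r needs two equal-length 1-D sequences")
    if x.size < 3:
        raise ValueError("pearson_r needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_r undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def _pooled(cohort: Cohort, fit_scope: str) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    if fit_scope == "all":
        sessions = [p.acoustics for p in cohort.participants]
    elif fit_scope == "train":
        sessions = [p.acoustics for p in cohort.train]
    else:
        raise ValueError("fit_scope must be 'all' or 'train'")
    if not sessions:
        raise ValueError("empty cohort")
    names = sessions[0].feature_names
    for s in sessions:
        if s.feature_names != names:
            raise ValueError("all sessions must share one feature set")
    X = np.vstack([s.matrix for s in sessions])
    d = np.concatenate([s.durations for s in sessions])
    return X, d, names


def duration_correlation_filter(cohort: Cohort, threshold: float = 0.2,
                                fit_scope: str = "all") -> FilterResult:
    """Remove features whose pooled |R| against segment duration exceeds threshold."""
    X, d, names = _pooled(cohort, fit_scope)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 pooled segments")
    # vectorized per-column Pearson R against duration
    dc = d - d.mean()
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    sd = np.sqrt((dc**2).sum())
    zero_var = sx == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * dc[:, None]).sum(axis=0) / (sx * sd)
    r[zero_var] = np.nan

    retained, removed, zvar = [], [], []
    r_values: dict[str, float] = {}
    for i, name in enumerate(names):
        r_values[name] = float(r[i])
        if zero_var[i]:
            zvar.append(name)
            removed.append(name)
        elif abs(r[i]) > threshold:
            removed.append(name)
        else:
            retained.append(name)
    if zvar:
        warnings.warn(f"{len(zvar)} zero-variance feature(s) removed "
                      "(duration correlation undefined)", stacklevel=2)
    return FilterResult(tuple(retained), tuple(removed), r_values,
                        tuple(zvar), threshold)


def apply_filter(session: SessionAcoustics, result: FilterResult) -> SessionAcoustics:
    idx = result.retained_indices(session.feature_names)
    return SessionAcoustics(
        participant_id=session.participant_id,
        feature_set_name=session.feature_set_name,
        matrix=session.matrix[:, idx],
        durations=session.durations,
        feature_names=tuple(session.feature_names[i] for i in idx),
    )


def standardize(train_sessions: list[SessionAcoustics],
                apply_sessions: list[SessionAcoustics]
                ) -> tuple[list[SessionAcoustics], list[SessionAcoustics],
                           np.ndarray, np.ndarray]:
    """Z-score features using pooled train-segment statistics only.

    Returns transformed train and apply session lists plus the (mean, sd)
    vectors. Features constant on train are set to zero everywhere.
    """
    if not train_sessions:
        raise ValueError("standardize needs a non-empty train set")
    names = train_sessions[0].feature_names
    X = np.vstack([s.matrix for s in train_sessions])
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    zero_sd = sd == 0
    if zero_sd.any():
        warnings.warn(f"{int(zero_sd.sum())} constant feature(s) on train; "
                      "set to zero after standardization", stacklevel=2)
    safe_sd = np.where(zero_sd, 1.0, sd)

    def transform(s: SessionAcoustics) -> SessionAcoustics:
        if s.feature_names != names:
            raise ValueError("feature names differ between sessions")
        z = (s.matrix - mean) / safe_sd
        z[:, zero_sd] = 0.0
        return SessionAcoustics(s.participant_id, s.feature_set_name, z,
                                s.durations, s.feature_names)

    return ([transform(s) for s in train_sessions],
            [transform(s) for s in apply_sessions], mean, sd)


def pad_segment_sequences(sessions: list[SessionAcoustics],
                          max_segments: int = 64) -> PaddedSequenceBatch:
    """Stack sessions into (batch, max_segments, features) with a boolean mask.

    Sequences longer than ``max_segments`` are truncated from the end (the
    first segments are kept); shorter ones are zero-padded, mask False.
    """
    if max_segments < 1:
        raise ValueError("max_segments must be >= 1")
    if not sessions:
        raise ValueError("no sessions to pad")
    n_feat = sessions[0].matrix.shape[1]
    for s in sessions:
        if s.matrix.shape[1] != n_feat:
            raise ValueError("sessions disagree on retained feature dimension")
    tensor = np.zeros((len(sessions), max_segments, n_feat))
    mask = np.zeros((len(sessions), max_segments), dtype=bool)
    for i, s in enumerate(sessions):
        n = min(s.n_segments, max_segments)
        tensor[i, :n] = s.matrix[:n]
        mask[i, :n] = True
    return PaddedSequenceBatch(tensor, mask, tuple(s.participant_id for s in sessions))
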
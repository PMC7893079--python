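"""Transcript parsing, feature tables, and cohort assembly."""

import numpy as np
import pandas as pd
import pytest

from adspeech.corpus_io import (
    ChatParseError,
    Cohort,
    FILLED_PAUSE,
    INTERVIEWER,
    PARTICIPANT,
    Participant,
    REPETITION,
    RETRACE,
    SessionAcoustics,
    Transcript,
    UNFILLED_PAUSE,
    assemble_cohort,
    load_cohort,
    load_feature_table,
    parse_chat,
    save_cohort,
    write_chat,
)
from adspeech.synthetic_data import (
    AD_TRANSCRIPT_EFFECT,
    SimConfig,
    simulate_cohort,
    simulate_transcript,
)


class TestParseChat:
    def test_filler_becomes_marker_not_token(self):
        t = parse_chat("*PAR: the boy &-um falls .")
        assert len(t.utterances) == 1
        u = t.utterances[0]
        assert u.tokens == ("the", "boy", "falls")
        assert u.marker_kinds() == (FILLED_PAUSE,)

    def test_interviewer_tier(self):
        t = parse_chat("*INV: okay .")
        u = t.utterances[0]
        assert u.speaker == INTERVIEWER
        assert u.tokens == ("okay",)

    def test_file_order_preserved(self):
        t = parse_chat("*PAR: the boy falls .\n*INV: okay .")
        assert [u.speaker for u in t.utterances] == [PARTICIPANT, INTERVIEWER]

    @pytest.mark.parametrize("code,kind", [
        ("(.)", UNFILLED_PAUSE), ("(..)", UNFILLED_PAUSE), ("(...)", UNFILLED_PAUSE),
        ("[/]", REPETITION), ("[//]", RETRACE), ("&uh", FILLED_PAUSE),
    ])
    def test_marker_vocabulary(self, code, kind):
        t = parse_chat(f"*PAR: the boy {code} falls .")
        assert t.utterances[0].marker_kinds() == (kind,)
        assert t.utterances[0].tokens == ("the", "boy", "falls")

    def test_headers_dependent_tiers_and_other_codes_ignored(self):
        text = ("@Begin\n@Languages: eng\n"
                "*PAR: the <boy> [x 2] falls .\n"
                "%mor: det|the n|boy v|fall\n"
                "@End\n")
        t = parse_chat(text)
        assert len(t.utterances) == 1
        assert t.utterances[0].tokens == ("the", "boy", "falls")

    def test_continuation_line_joined(self):
        t = parse_chat("*PAR: the boy\n\tfalls .")
        assert t.utterances[0].tokens == ("the", "boy", "falls")

    def test_malformed_tier_names_line(self):
        with pytest.raises(ChatParseError, match="line 2"):
            parse_chat("*PAR: fine .\n*XYZ: what .")

    def test_empty_file_rejected(self):
        with pytest.raises(ChatParseError):
            parse_chat("   \n  ")

    def test_punctuation_dropped(self):
        t = parse_chat("*PAR: well , the boy falls ?")
        assert t.utterances[0].tokens == ("well", "the", "boy", "falls")


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(8))
    def test_write_then_parse_is_identity(self, seed):
        rng = np.random.default_rng(seed)
        t = simulate_transcript("AD", AD_TRANSCRIPT_EFFECT, rng, "p1")
        assert parse_chat(write_chat(t), "p1") == t

    @pytest.mark.parametrize("seed", range(8))
    def test_no_filler_string_among_tokens(self, seed):
        rng = np.random.default_rng(100 + seed)
        t = simulate_transcript("AD", AD_TRANSCRIPT_EFFECT, rng, "p1")
        reparsed = parse_chat(write_chat(t), "p1")
        for u in reparsed.utterances:
            assert not any(tok.startswith("&") or tok in ("uh", "um")
                           for tok in u.tokens)


class TestFeatureTable:
    def _write(self, tmp_path, df):
        path = tmp_path / "p1.csv"
        df.to_csv(path, index=False)
        return path

    def test_loads_matrix_and_durations(self, tmp_path):
        df = pd.DataFrame(np.arange(15).reshape(3, 5),
                          columns=[f"f{i}" for i in range(5)])
        df["duration_s"] = [1.0, 2.0, 3.0]
        sess = load_feature_table(self._write(tmp_path, df), "custom")
        assert sess.matrix.shape == (3, 5)
        assert sess.durations.tolist() == [1.0, 2.0, 3.0]
        assert sess.feature_names == tuple(f"f{i}" for i in range(5))

    def test_row_order_preserved(self, tmp_path):
        df = pd.DataFrame({"a": [10.0, 20.0, 30.0], "duration_s": [1, 1, 1]})
        sess = load_feature_table(self._write(tmp_path, df), "custom")
        assert sess.matrix[:, 0].tolist() == [10.0, 20.0, 30.0]

    def test_missing_duration_column(self, tmp_path):
        df = pd.DataFrame({"a": [1.0]})
        with pytest.raises(ValueError, match="duration_s"):
            load_feature_table(self._write(tmp_path, df), "custom")

    def test_non_numeric_cell(self, tmp_path):
        df = pd.DataFrame({"a": ["oops"], "duration_s": [1.0]})
        with pytest.raises(ValueError, match="non-numeric"):
            load_feature_table(self._write(tmp_path, df), "custom")

    def test_zero_rows(self, tmp_path):
        df = pd.DataFrame({"a": [], "duration_s": []})
        with pytest.raises(ValueError, match="zero segments"):
            load_feature_table(self._write(tmp_path, df), "custom")


def _mini_sources(ids):
    transcripts = {i: parse_chat("*PAR: the boy falls .", i) for i in ids}
    acoustics = {i: SessionAcoustics(i, "custom", np.ones((2, 3)),
                                     [1.0, 2.0], ("a", "b", "c"))
                 for i in ids}
    return transcripts, acoustics


class TestAssembleCohort:
    def test_inner_join(self):
        tr, ac = _mini_sources(["p1", "p2"])
        meta = pd.DataFrame({"id": ["p1", "p2"], "label": ["AD", "non-AD"],
                             "age": [70, 65], "gender": ["male", "female"]})
        cohort, unmatched = assemble_cohort(tr, ac, meta)
        assert len(cohort.participants) == 2
        assert unmatched == {}

    def test_unmatched_reported_and_excluded(self):
        tr, ac = _mini_sources(["p1", "p2"])
        meta = pd.DataFrame({"id": ["p1"], "label": ["AD"],
                             "age": [70], "gender": ["male"]})
        cohort, unmatched = assemble_cohort(tr, ac, meta)
        assert [p.id for p in cohort.participants] == ["p1"]
        assert unmatched["transcripts"] == ["p2"]

    def test_duplicate_metadata_id_rejected(self):
        tr, ac = _mini_sources(["p1"])
        meta = pd.DataFrame({"id": ["p1", "p1"], "label": ["AD", "AD"],
                             "age": [70, 70], "gender": ["male", "male"]})
        with pytest.raises(ValueError, match="duplicate"):
            assemble_cohort(tr, ac, meta)

    def test_missing_label_rejected(self):
        tr, ac = _mini_sources(["p1"])
        meta = pd.DataFrame({"id": ["p1"], "label": [None],
                             "age": [70], "gender": ["male"]})
        with pytest.raises(ValueError, match="label"):
            assemble_cohort(tr, ac, meta)


class TestInvariants:
    def test_duplicate_participant_in_cohort_rejected(self):
        tr, ac = _mini_sources(["p1"])
        p = Participant("p1", "AD", 70, "male", tr["p1"], ac["p1"])
        with pytest.raises(ValueError, match="duplicate"):
            Cohort([p, p])

    def test_session_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            SessionAcoustics("p", "custom", np.ones((2, 3)), [1.0],
                             ("a", "b", "c"))
        with pytest.raises(ValueError, match="positive"):
            SessionAcoustics("p", "custom", np.ones((1, 1)), [0.0], ("a",))


def test_cohort_disk_round_trip(tmp_path):
    cohort = simulate_cohort(SimConfig(n_train_per_class=3, n_test_per_class=2,
                                       n_acoustic_features=10, seed=5))
    save_cohort(cohort, tmp_path)
    loaded = load_cohort(tmp_path)
    assert [p.id for p in loaded.participants] == [p.id for p in cohort.participants]
    assert loaded.split == cohort.split
    for a, b in zip(loaded.participants, cohort.participants):
        assert a.transcript == b.transcript
        assert a.label == b.label
        np.testing.assert_allclose(a.acoustics.matrix, b.acoustics.matrix,
                                   atol=1e-12)
        np.testing.assert_allclose(a.acoustics.durations, b.acoustics.durations,
                                   atol=1e-12)
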
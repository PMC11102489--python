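"""Sessionization, qualification, labeling and splitting."""

import numpy as np
import pandas as pd
import pytest

from rechat import sessions


def brute_force_partition(messages, gap_hours=6.0):
    """Independent oracle: boundary at every gap >= threshold."""
    ordered = sorted(messages, key=lambda m: m.sent_at)
    out, cur = [], []
    for m in ordered:
        if cur and (m.sent_at - cur[-1].sent_at) >= pd.Timedelta(hours=gap_hours):
            out.append(cur)
            cur = []
        cur.append(m)
    if cur:
        out.append(cur)
    return out


def random_stream(rng, n_max=50):
    n = int(rng.integers(1, n_max + 1))
    hours = np.cumsum(rng.exponential(3.0, size=n))
    senders = rng.choice(["chatter", "counselor"], size=n)
    t0 = pd.Timestamp("2022-03-01")
    return [
        sessions.Message("c0", s, t0 + pd.Timedelta(hours=float(h)), "x")
        for h, s in zip(hours, senders)
    ]


class TestSegmentSessions:
    def test_empty(self):
        assert sessions.segment_sessions([]) == []

    def test_gap_partition_examples(self, toy_messages):
        cons = sessions.segment_sessions(toy_messages("a", [0, 1, 2, 9]))
        assert [c.n_total for c in cons] == [3, 1]
        # a gap of exactly six hours starts a new consultation
        cons = sessions.segment_sessions(toy_messages("a", [0, 6]))
        assert [c.n_total for c in cons] == [1, 1]
        cons = sessions.segment_sessions(toy_messages("a", [0, 5.99]))
        assert [c.n_total for c in cons] == [2]

    def test_mixed_chat_ids_rejected(self, toy_messages):
        msgs = toy_messages("a", [0]) + toy_messages("b", [1])
        with pytest.raises(ValueError, match="multiple chats"):
            sessions.segment_sessions(msgs)

    def test_matches_brute_force_on_random_streams(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            msgs = random_stream(rng)
            got = sessions.segment_sessions(msgs)
            want = brute_force_partition(msgs)
            assert [len(c.messages) for c in got] == [len(w) for w in want]
            # conservation: concatenation restores the sorted stream
            flat = [m for c in got for m in c.messages]
            assert flat == sorted(msgs, key=lambda m: m.sent_at)


class TestQualifies:
    @pytest.mark.parametrize(
        "n_co, n_ch, expected",
        [(3, 7, True), (0, 0, False), (2, 20, False), (3, 6, False), (10, 0, True)],
    )
    def test_thresholds(self, toy_messages, n_co, n_ch, expected):
        senders = ["counselor"] * n_co + ["chatter"] * n_ch
        msgs = toy_messages("a", list(np.linspace(0, 1, n_co + n_ch)), senders)
        if not msgs:
            msgs = []
            c = sessions.Consultation("a", [])
            assert sessions.qualifies(c) is False
            return
        (c,) = sessions.segment_sessions(msgs)
        assert sessions.qualifies(c) is expected


class TestLabelOutcome:
    def _episode(self, toy_messages, extra_hours=(), extra_senders=None):
        senders = ["chatter"] * 7 + ["counselor"] * 3
        hours = list(np.linspace(0, 2, 10)) + list(extra_hours)
        senders += extra_senders or ["chatter"] * len(extra_hours)
        return sessions.build_episodes(toy_messages("a", hours, senders))

    def test_recontact_within_window(self, toy_messages):
        ep = self._episode(toy_messages, extra_hours=[2 + 10 * 24])
        assert ep.label is True

    def test_no_later_contact(self, toy_messages):
        ep = self._episode(toy_messages)
        assert ep.label is False

    def test_six_hour_merge_prevents_recontact(self, toy_messages):
        # a follow-up 5 h after the last message joins the same consultation
        ep = self._episode(toy_messages, extra_hours=[7.0])
        assert len(ep.consultations) == 1
        assert ep.label is False

    def test_window_boundary_inclusive(self, toy_messages):
        ep = self._episode(toy_messages, extra_hours=[2 + 188 * 24])
        assert ep.label is True
        ep = self._episode(toy_messages, extra_hours=[2 + 188 * 24 + 1])
        assert ep.label is False

    def test_counselor_only_followup_does_not_count(self, toy_messages):
        ep = self._episode(
            toy_messages, extra_hours=[2 + 24], extra_senders=["counselor"]
        )
        assert ep.label is False

    def test_missing_index_raises(self, toy_messages):
        ep = sessions.build_episodes(toy_messages("a", [0, 1]))
        assert ep.index_consultation is None
        with pytest.raises(ValueError, match="undefined"):
            sessions.label_outcome(ep)

    def test_window_monotonicity(self, toy_messages):
        """Growing the window never flips a label from true to false."""
        rng = np.random.default_rng(17)
        for _ in range(50):
            extra = sorted(rng.uniform(10, 250 * 24, size=rng.integers(0, 4)))
            ep = self._episode(toy_messages, extra_hours=list(extra))
            labels = [
                sessions.label_outcome(ep, window_days=w)
                for w in range(50, 260, 30)
            ]
            assert labels == sorted(labels)  # False..False,True..True


class TestCorpusPipeline:
    def test_vectorized_agrees_with_per_chat_api(self, small_corpus):
        _, messages, _ = small_corpus
        sub = messages[messages.chat_id.isin(messages.chat_id.unique()[:40])]
        cons = sessions.sessionize_corpus(sub)
        for cid, grp in sub.groupby("chat_id"):
            msgs = [
                sessions.Message(cid, r.sender, r.sent_at, r.text)
                for r in grp.itertuples()
            ]
            ep = sessions.build_episodes(msgs)
            mine = cons[cons.chat_id == cid]
            assert len(mine) == len(ep.consultations)
            assert list(mine.n_total) == [c.n_total for c in ep.consultations]
            rec = sessions.build_records(cons[cons.chat_id == cid])
            if ep.index_consultation is None:
                assert rec.empty
            else:
                assert bool(rec.label.iloc[0]) == ep.label

    def test_total_message_count_conserved(self, small_corpus):
        _, messages, _ = small_corpus
        cons = sessions.sessionize_corpus(messages)
        assert cons.n_total.sum() == len(messages)


class TestTimeSplit:
    def _records(self, dates):
        return pd.DataFrame(
            {"chat_id": range(len(dates)), "index_start": pd.to_datetime(dates)}
        )

    def test_all_before_cutoff_warns_empty_test(self):
        rec = self._records(["2022-01-01", "2022-02-01"])
        with pytest.warns(UserWarning, match="empty"):
            train, test = sessions.time_split(rec, "2023-01-01")
        assert len(train) == 2 and len(test) == 0

    def test_cutoff_itself_goes_to_test(self):
        rec = self._records(["2022-08-31", "2022-09-01"])
        train, test = sessions.time_split(rec, "2022-09-01")
        assert list(train.chat_id) == [0]
        assert list(test.chat_id) == [1]

    def test_percentile_cutoff_gives_expected_fraction(self):
        rng = np.random.default_rng(2)
        dates = pd.Timestamp("2021-10-01") + pd.to_timedelta(
            rng.uniform(0, 456, size=2000), unit="D"
        )
        rec = self._records(dates)
        cutoff = rec.index_start.quantile(0.79)
        train, test = sessions.time_split(rec, cutoff)
        assert len(train) + len(test) == 2000
        assert len(test) / 2000 == pytest.approx(0.21, abs=0.01)


class TestWindowSensitivity:
    def test_constant_eval_has_zero_sd(self, small_corpus):
        _, messages, _ = small_corpus
        cons = sessions.sessionize_corpus(messages)
        scores, sd = sessions.outcome_window_sensitivity(cons, lambda rec: 0.66)
        assert sd == 0.0
        assert len(scores) == 7

    def test_single_window(self, small_corpus):
        _, messages, _ = small_corpus
        cons = sessions.sessionize_corpus(messages)
        scores, sd = sessions.outcome_window_sensitivity(
            cons, lambda rec: rec.label.mean(), windows=[188]
        )
        assert sd == 0.0 and len(scores) == 1

    def test_empty_window_list_rejected(self, small_corpus):
        _, messages, _ = small_corpus
        cons = sessions.sessionize_corpus(messages)
        with pytest.raises(ValueError):
            sessions.outcome_window_sensitivity(cons, lambda r: 0.5, windows=[])

    def test_prevalence_stable_when_delays_concentrate_early(self, small_corpus):
        """Labeling is nearly window-invariant because most recontacts
        happen within the first week."""
        _, messages, _ = small_corpus
        cons = sessions.sessionize_corpus(messages)
        scores, sd = sessions.outcome_window_sensitivity(
            cons, lambda rec: rec.label.mean()
        )
        assert sd < 0.01
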
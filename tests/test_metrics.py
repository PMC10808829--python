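"""SRET feature extraction: counts, rates, RT bias, recall bias, matrix."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sretlca import (
    DataError,
    build_endorsement_matrix,
    compute_features,
    endorsement_features,
    generate_cohort,
    recall_bias,
    rt_bias,
)
from sretlca.metrics import EndorsementMatrix
from sretlca.wordbank import NEGATIVE, POSITIVE

from conftest import block_probs_3class, make_spec, participant_trials


class TestEndorsementFeatures:
    def test_all_rejected_gives_zero_counts_and_rates(self, bank):
        trials = participant_trials({w: False for w in range(90)})
        feats = endorsement_features(trials, bank)
        assert feats["n_pos_endorsed"] == 0 and feats["n_neg_endorsed"] == 0
        assert feats["pos_rate"] == 0.0 and feats["neg_rate"] == 0.0

    def test_rate_denominator_is_all_words_presented(self, bank):
        """Endorsing all 42 positive words gives rate 42/90, not 42/42."""
        trials = participant_trials({w: bool(bank.is_positive[w]) for w in range(90)})
        feats = endorsement_features(trials, bank)
        assert feats["n_pos_endorsed"] == 42 and feats["n_neg_endorsed"] == 0
        assert feats["pos_rate"] == pytest.approx(42 / 90)
        assert feats["pos_rate_valence"] == pytest.approx(1.0)

    def test_single_negative_endorsement(self, bank):
        responses = {w: False for w in range(90)}
        responses[0] = True  # word 0 is negative in the default bank
        feats = endorsement_features(participant_trials(responses), bank)
        assert feats["n_neg_endorsed"] == 1
        assert feats["neg_rate"] == pytest.approx(1 / 90)

    def test_duplicate_word_trials_raise_listing_ids(self, bank):
        trials = pd.concat([participant_trials({0: True, 1: False})] * 2)
        with pytest.raises(DataError, match=r"\[0, 1\]"):
            endorsement_features(trials, bank)

    def test_unknown_word_raises(self, bank):
        with pytest.raises(DataError, match="unknown word_ids"):
            endorsement_features(participant_trials({500: True}), bank)


class TestRtBias:
    def test_equal_endorse_and_reject_means_give_zero(self, bank):
        responses = {0: True, 1: False, 48: True, 49: False}
        rts = {0: 800, 1: 800, 48: 700, 49: 600}
        assert rt_bias(participant_trials(responses, rts), NEGATIVE, bank) == pytest.approx(0.0)

    def test_hand_computed_value(self, bank):
        """Endorse-neg {900,900}, reject-neg {600,600}, positives all 750 -> 0.4."""
        responses = {0: True, 1: True, 2: False, 3: False,
                     48: True, 49: True, 50: False, 51: False}
        rts = {0: 900, 1: 900, 2: 600, 3: 600, 48: 750, 49: 750, 50: 750, 51: 750}
        bias = rt_bias(participant_trials(responses, rts), NEGATIVE, bank)
        assert bias == pytest.approx(0.4)

    def test_missing_when_no_endorsements_of_valence(self, bank):
        responses = {0: False, 1: False, 48: True}
        assert np.isnan(rt_bias(participant_trials(responses), NEGATIVE, bank))

    def test_nonpositive_rt_raises(self, bank):
        trials = participant_trials({0: True, 1: False}, rts={0: 0.0, 1: 700})
        with pytest.raises(DataError, match="non-positive"):
            rt_bias(trials, NEGATIVE, bank)

    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_under_rt_rescaling(self, scale):
        """Numerator and denominator scale together, so the bias is scale-free."""
        bank_local = __import__("sretlca").default_word_bank()
        responses = {0: True, 1: True, 2: False, 48: True, 49: False}
        rts = {0: 950, 1: 820, 2: 610, 48: 700, 49: 760}
        base = rt_bias(participant_trials(responses, rts), NEGATIVE, bank_local)
        scaled = rt_bias(
            participant_trials(responses, {w: r * scale for w, r in rts.items()}),
            NEGATIVE, bank_local,
        )
        assert scaled == pytest.approx(base, rel=1e-9)


class TestRecallBias:
    @pytest.mark.parametrize(
        "pos_ids, neg_ids, expected",
        [
            ([48, 49, 50], [0], (0.75, 0.25, -0.5)),
            ([48, 49], [0, 1], (0.5, 0.5, 0.0)),
        ],
    )
    def test_ratios(self, bank, pos_ids, neg_ids, expected):
        recalls = pd.DataFrame({"participant_id": 0, "word_id": pos_ids + neg_ids})
        rb = recall_bias(recalls, bank)
        assert rb["pos_recall_bias"] == pytest.approx(expected[0])
        assert rb["neg_recall_bias"] == pytest.approx(expected[1])
        assert rb["recall_bias_diff"] == pytest.approx(expected[2])

    def test_biases_sum_to_one_when_defined(self, bank):
        recalls = pd.DataFrame({"participant_id": 0, "word_id": [0, 5, 48, 60, 70]})
        rb = recall_bias(recalls, bank)
        assert rb["pos_recall_bias"] + rb["neg_recall_bias"] == pytest.approx(1.0)

    def test_zero_recalled_words_is_missing(self, bank):
        recalls = pd.DataFrame({"participant_id": [], "word_id": []})
        rb = recall_bias(recalls, bank)
        assert all(np.isnan(v) for v in rb.values())

    def test_unknown_recalled_word_raises(self, bank):
        recalls = pd.DataFrame({"participant_id": 0, "word_id": [123]})
        with pytest.raises(DataError, match="not in bank"):
            recall_bias(recalls, bank)

    def test_endorsed_only_variant_restricts_numerator(self, bank):
        trials = participant_trials({0: True, 1: False, 48: False, 49: True})
        recalls = pd.DataFrame({"participant_id": 0, "word_id": [0, 1, 49]})
        rb = recall_bias(recalls, bank, endorsed_only=True, trials=trials)
        # only words 0 (neg) and 49 (pos) were endorsed and recalled
        assert rb["pos_recall_bias"] == pytest.approx(0.5)


class TestEndorsementMatrix:
    def test_full_endorser_is_row_of_ones(self, bank):
        trials = participant_trials({w: True for w in range(90)})
        matrix = build_endorsement_matrix(trials, bank)
        assert matrix.X.shape == (1, 90)
        assert (matrix.X == 1).all()

    def test_csv_roundtrip_identical(self, tmp_path, bank):
        cohort = generate_cohort(make_spec(block_probs_3class(), n=15, seed=4))
        matrix = build_endorsement_matrix(cohort.trials, bank)
        path = tmp_path / "m.csv"
        matrix.write_csv(path, bank)
        back = EndorsementMatrix.read_csv(path)
        np.testing.assert_array_equal(matrix.X, back.X)
        np.testing.assert_array_equal(matrix.participant_ids, back.participant_ids)

    def test_row_sums_match_endorsement_counts(self, bank):
        """Cross-check the matrix against the per-participant features."""
        cohort = generate_cohort(make_spec(block_probs_3class(), n=30, seed=9))
        matrix = build_endorsement_matrix(cohort.trials, bank)
        feats = compute_features(cohort.trials, cohort.recalls, bank)
        counts = (feats["n_pos_endorsed"] + feats["n_neg_endorsed"]).to_numpy()
        np.testing.assert_array_equal(matrix.X.sum(axis=1), counts)
        # and the overall-rate identity: pos_rate + neg_rate = total / J
        total_rate = (feats["pos_rate"] + feats["neg_rate"]).to_numpy()
        np.testing.assert_allclose(total_rate, matrix.X.sum(axis=1) / 90.0)

    def test_missing_word_for_a_participant_raises(self, bank):
        trials = pd.concat(
            [
                participant_trials({w: False for w in range(90)}, pid=0),
                participant_trials({w: False for w in range(89)}, pid=1),
            ]
        )
        with pytest.raises(DataError, match="missing word trials"):
            build_endorsement_matrix(trials, bank)
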
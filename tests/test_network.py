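import numpy as np
import pytest

from _oracles import (
    brute_track_assignment,
    gate_dicts,
    scalar_forward,
    scalar_lstm_step,
)
from clipbind.encoding import encode_batch
from clipbind.network import (
    ConvFilterBank,
    LSTMGateParams,
    LSTMState,
    ModelParams,
    assemble_timesteps,
    blstm_forward,
    build_tracks,
    conv_scan,
    forward,
    profile_and_score,
    sigmoid,
    wta_enhance,
)
from clipbind.seq_io import NamedSequence
from conftest import random_model, random_rna


def enc_of(residues, sizes):
    return encode_batch([NamedSequence("s", residues)], sizes)[0]


class TestConvScan:
    def test_zero_weight_filter_scores_zero_everywhere(self):
        enc = enc_of("ACGUA", [3])
        bank = ConvFilterBank([np.zeros((3, 4))])
        assert np.all(conv_scan(enc, bank)[0] == 0)

    def test_hand_dot_product(self):
        # weight +1 at (pos1, A) and (pos2, C), -1 elsewhere
        W = np.full((2, 4), -1.0)
        W[0, 0] = 1.0
        W[1, 1] = 1.0
        enc = enc_of("AAC", [2])
        scores = conv_scan(enc, ConvFilterBank([W]))[0]
        # placements over real region: "AA" -> 1 - 1 = 0; "AC" -> 2
        left = enc.left_pad
        assert scores[left] == 0.0
        assert scores[left + 1] == 2.0

    def test_placements_inside_zero_margin_score_zero(self):
        rng = np.random.default_rng(0)
        W = rng.normal(size=(2, 4))
        enc = enc_of("ACGU", [4])  # margin of 3 zero columns each side
        scores = conv_scan(enc, ConvFilterBank([W]))[0]
        assert scores[0] == 0.0  # fully inside the left margin
        assert scores[-1] == 0.0

    def test_filter_wider_than_input_errors(self):
        enc = enc_of("AC", [2])
        with pytest.raises(ValueError):
            conv_scan(enc, ConvFilterBank([np.zeros((10, 4))]))


class TestWTA:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ([1, 3, 2], [1, 36, 4]),
            ([0, 0, 0], [0, 0, 0]),
            ([2, 2, 0], [16, 4, 0]),  # first-occurrence tie-break
        ],
    )
    def test_stated_rule(self, scores, expected):
        np.testing.assert_array_equal(wta_enhance(np.array(scores, float)), expected)

    def test_preserves_argmax(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            s = rng.random(10)
            e = wta_enhance(s)
            assert np.argmax(e) == np.argmax(s)


class TestBuildTracks:
    def test_zero_enhanced_gives_zero_track(self):
        enc = enc_of("ACG", [2])
        (track,) = build_tracks([np.zeros(enc.padded_length - 1)], enc)
        assert np.all(track == 0)

    def test_single_placement_value_lands_on_its_start_base(self):
        enc = enc_of("ACG", [2])
        e = np.zeros(enc.padded_length - 1)
        j = enc.left_pad + 1  # placement starting on the C
        e[j] = 5.0
        (track,) = build_tracks([e], enc)
        nz = np.argwhere(track != 0)
        assert nz.tolist() == [[j, 1]]
        assert track[j, 1] == 5.0

    @pytest.mark.parametrize("rule", ["start", "max_cover"])
    def test_matches_exhaustive_assignment_oracle(self, rule):
        rng = np.random.default_rng(3)
        enc = enc_of("ACG", [3])
        m = 3
        e = rng.random(enc.padded_length - m + 1)
        (track,) = build_tracks([e], enc, assignment=rule)
        expected = brute_track_assignment(
            enc.onehot.tolist(), list(e), m, rule
        )
        np.testing.assert_allclose(track, expected, atol=1e-12)

    def test_unknown_rule_rejected(self):
        enc = enc_of("ACG", [2])
        with pytest.raises(ValueError):
            build_tracks([np.zeros(enc.padded_length - 1)], enc, assignment="?")


class TestAssembleTimesteps:
    def test_dimension_is_four_times_filters_plus_one(self):
        enc = enc_of("ACGUA", [4, 5, 6, 7, 8])
        scores = conv_scan(enc, ConvFilterBank.initialize())
        tracks = build_tracks([wta_enhance(s) for s in scores], enc)
        xs = assemble_timesteps(tracks, enc)
        assert xs.shape == (enc.padded_length, 24)

    def test_padding_positions_are_all_zero(self):
        enc = enc_of("ACG", [4])
        bank = ConvFilterBank([np.full((4, 4), 0.5)])
        tracks = build_tracks(
            [wta_enhance(s) for s in conv_scan(enc, bank)], enc
        )
        xs = assemble_timesteps(tracks, enc)
        assert np.all(xs[enc.mask == 0] == 0)

    def test_zero_conv_weights_reduce_to_raw_onehot(self):
        enc = enc_of("ACGU", [3])
        bank = ConvFilterBank([np.zeros((3, 4))])
        tracks = build_tracks(
            [wta_enhance(s) for s in conv_scan(enc, bank)], enc
        )
        xs = assemble_timesteps(tracks, enc)
        np.testing.assert_array_equal(xs[:, :4], np.zeros_like(enc.onehot))
        np.testing.assert_array_equal(xs[:, 4:], enc.onehot)


class TestLSTMStep:
    def test_all_zero_params_closed_form(self):
        p = LSTMGateParams(np.zeros((4, 12)), np.zeros((3, 12)), np.zeros(12))
        state = LSTMState.zero(3)
        nxt = lstm_step_wrap(np.zeros(4), state, p)
        np.testing.assert_allclose(nxt.h, 0.0)
        np.testing.assert_allclose(nxt.c, 0.0)

    def test_forget_bias_closed_form(self):
        # zero weights, b_f = +10, c_prev = 1: f ~ sigmoid(10),
        # c = f, h = o * tanh(c) = 0.5 tanh(c)
        n = 2
        p = LSTMGateParams(np.zeros((4, 4 * n)), np.zeros((n, 4 * n)), np.zeros(4 * n))
        p.b[n : 2 * n] = 10.0
        state = LSTMState(h=np.zeros(n), c=np.ones(n))
        nxt = lstm_step_wrap(np.zeros(4), state, p)
        f = 1 / (1 + np.exp(-10.0))
        np.testing.assert_allclose(nxt.c, f, atol=1e-12)
        np.testing.assert_allclose(nxt.h, 0.5 * np.tanh(f), atol=1e-12)

    def test_agrees_with_scalar_gate_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n, d = int(rng.integers(1, 5)), int(rng.integers(1, 6))
            p = LSTMGateParams.initialize(d, n, rng, std=0.7)
            x = rng.normal(size=d)
            state = LSTMState(h=rng.normal(size=n), c=rng.normal(size=n))
            nxt = lstm_step_wrap(x, state, p)
            h, c = scalar_lstm_step(
                list(x), list(state.h), list(state.c), gate_dicts(p)
            )
            assert np.max(np.abs(nxt.h - h)) < 1e-10
            assert np.max(np.abs(nxt.c - c)) < 1e-10


def lstm_step_wrap(x, state, p):
    from clipbind.network import lstm_step

    return lstm_step(x, state, p)


class TestBLSTM:
    def test_single_timestep_uses_zero_initial_state(self):
        rng = np.random.default_rng(5)
        p = LSTMGateParams.initialize(4, 3, rng, std=0.5)
        q = LSTMGateParams.initialize(4, 3, rng, std=0.5)
        xs = rng.normal(size=(1, 4))
        H = blstm_forward(xs, p, q)
        from clipbind.network import lstm_step

        fwd = lstm_step(xs[0], LSTMState.zero(3), p)
        bwd = lstm_step(xs[0], LSTMState.zero(3), q)
        np.testing.assert_allclose(H[0, :3], fwd.h)
        np.testing.assert_allclose(H[0, 3:], bwd.h)

    def test_zero_params_give_zero_hidden_matrix(self):
        p = LSTMGateParams(np.zeros((4, 8)), np.zeros((2, 8)), np.zeros(8))
        H = blstm_forward(np.ones((5, 4)), p, p)
        np.testing.assert_allclose(H, 0.0)

    def test_reversal_symmetry(self):
        # swapping directions and reversing the input reverses H rows with
        # halves swapped
        rng = np.random.default_rng(6)
        p = LSTMGateParams.initialize(4, 3, rng, std=0.5)
        q = LSTMGateParams.initialize(4, 3, rng, std=0.5)
        xs = rng.normal(size=(7, 4))
        H = blstm_forward(xs, p, q)
        H_swapped = blstm_forward(xs[::-1], q, p)
        np.testing.assert_allclose(H_swapped[::-1, :3], H[:, 3:], atol=1e-12)
        np.testing.assert_allclose(H_swapped[::-1, 3:], H[:, :3], atol=1e-12)


class TestProfileAndScore:
    def test_zero_hidden_matrix_scores_half(self):
        enc = enc_of("ACG", [2])
        prof = profile_and_score(np.zeros((enc.padded_length, 6)), enc)
        np.testing.assert_array_equal(prof.values, np.zeros(3))
        assert prof.score == 0.5

    def test_closed_form_sigmoid_of_sum(self):
        enc = enc_of("ACG", [2])
        H = np.zeros((enc.padded_length, 1))
        H[enc.left_pad : enc.left_pad + 3, 0] = [1.0, -1.0, 0.5]
        prof = profile_and_score(H, enc)
        assert prof.score == pytest.approx(1 / (1 + np.exp(-0.5)), abs=1e-9)

    def test_padding_rows_do_not_contribute(self):
        enc = enc_of("ACG", [3])
        rng = np.random.default_rng(2)
        H = rng.normal(size=(enc.padded_length, 4))
        prof = profile_and_score(H, enc)
        H2 = H.copy()
        H2[enc.mask == 0] = 99.0  # junk in padding rows must be masked out
        prof2 = profile_and_score(H2, enc)
        np.testing.assert_allclose(prof.values, prof2.values)
        assert prof.score == prof2.score


class TestForward:
    def test_default_model_score_in_open_interval(self):
        model = ModelParams.initialize(hidden_size=4)
        prof = forward(NamedSequence("s", "ACGUACGU"), model)
        assert 0.0 < prof.score < 1.0
        assert len(prof.values) == 8

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        model = random_model(rng, hidden_size=4)
        s = NamedSequence("s", random_rna(rng, 15))
        a = forward(s, model)
        b = forward(s, model)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.score == b.score

    def test_score_is_sigmoid_of_profile_sum(self):
        rng = np.random.default_rng(9)
        model = random_model(rng, hidden_size=5)
        for _ in range(10):
            s = NamedSequence("s", random_rna(rng, int(rng.integers(8, 30))))
            prof = forward(s, model)
            assert abs(prof.score - sigmoid(prof.values.sum())) < 1e-6

    def test_full_pass_equivalence_with_straight_line_oracle(self):
        # tiny instances: T <= 5, hidden <= 3
        rng = np.random.default_rng(10)
        for _ in range(5):
            sizes = (2, 3)
            hidden = int(rng.integers(1, 4))
            model = random_model(rng, filter_sizes=sizes, hidden_size=hidden)
            residues = random_rna(rng, int(rng.integers(3, 6)))
            prof = forward(NamedSequence("s", residues), model)
            conv_w = [w.tolist() for w in model.conv.filters]
            oracle_prof, oracle_score = scalar_forward(
                residues, conv_w, gate_dicts(model.fwd), gate_dicts(model.bwd),
                hidden,
            )
            assert np.max(np.abs(prof.values - oracle_prof)) < 1e-8
            assert abs(prof.score - oracle_score) < 1e-8
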
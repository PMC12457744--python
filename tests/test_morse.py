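"""Breath-encoded Morse: codec, renderer, rule-based decoder, classifier."""

import numpy as np
import pytest

import breathflow as bf


def render_trace(text, noise=None, fs=100.0):
    proto = bf.render_breaths(bf.encode_text(text), fs=fs)
    tr = bf.transduce(bf.synth_pressure(proto))
    if noise is not None:
        tr = bf.add_noise(tr, noise)
    return tr


class TestEncode:
    def test_bright(self):
        assert bf.encode_text("BRIGHT") == "-... .-. .. --. .... -"

    def test_shortest_code(self):
        assert bf.encode_text("E") == "."

    def test_empty(self):
        assert bf.encode_text("") == ""

    def test_word_separator(self):
        assert bf.encode_text("AB CD") == ".- -... / -.-. -.."

    def test_unsupported_character_named(self):
        with pytest.raises(ValueError, match="'@'"):
            bf.encode_text("A@B")

    def test_round_trip_through_table(self):
        for ch, code in bf.MORSE_TABLE.items():
            assert bf.encode_text(ch) == code


class TestRender:
    def test_single_dot_single_shallow_breath(self):
        proto = bf.render_breaths(".")
        assert len(proto.segments) == 1
        assert proto.segments[0].label == "dot"

    def test_bright_symbol_counts(self):
        # "-... .-. .. --. .... -" has 5 dashes and 12 dots
        proto = bf.render_breaths(bf.encode_text("BRIGHT"))
        labels = [s.label for s in proto.segments]
        assert labels.count("dash") == 5
        assert labels.count("dot") == 12

    def test_inter_letter_gap_three_periods(self):
        proto = bf.render_breaths(bf.encode_text("AB"), period_s=2.0)
        # A = .-  (2 breaths), B = -... (4 breaths)
        starts = [s.start for s in proto.segments]
        # gap between last breath of A (ends starts[1]+2) and first of B
        assert starts[2] - (starts[1] + 2.0) == pytest.approx(3 * 2.0)

    def test_malformed_morse_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            bf.render_breaths(".x-")

    def test_deep_must_exceed_shallow(self):
        with pytest.raises(ValueError):
            bf.render_breaths(".", deep_kpa=1.0, shallow_kpa=2.0)


class TestDecode:
    def test_clean_round_trip_sos(self):
        assert bf.decode_rule_based(render_trace("SOS")).text == "SOS"

    def test_clean_round_trip_bright(self):
        res = bf.decode_rule_based(render_trace("BRIGHT"))
        assert res.text == "BRIGHT"
        assert not res.low_confidence

    def test_word_gap_preserved(self):
        assert bf.decode_rule_based(render_trace("HI MOM")).text == "HI MOM"

    def test_single_amplitude_degenerate_flagged_all_dots(self):
        # all-dash message: the dot/dash split is uncalibrated, so the
        # decoder flags low confidence and reads every breath as a dot
        res = bf.decode_rule_based(render_trace("MT"))
        assert res.low_confidence
        assert "-" not in res.morse

    def test_flat_trace_no_signal(self):
        t = np.arange(0, 10, 0.01)
        with pytest.raises(ValueError, match="no signal"):
            bf.decode_rule_based(bf.VoltageTrace(t, np.zeros(len(t)), 100.0))

    def test_round_trip_identity_over_random_strings(self):
        """200 random alphanumeric messages decode to themselves at zero
        noise; messages made solely of dashes are informationally ambiguous
        (no shallow reference breath) and must instead come back flagged."""
        rng = np.random.default_rng(2024)
        chars = list("ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789")
        for _ in range(200):
            n = int(rng.integers(1, 7))
            text = "".join(rng.choice(chars, size=n))
            res = bf.decode_rule_based(render_trace(text, fs=50.0))
            all_dash = set(bf.encode_text(text)) <= {"-", " "}
            if all_dash:
                assert res.low_confidence
            else:
                assert res.text == text, text

    def test_accuracy_degrades_monotonically_with_noise(self):
        msgs = ["SOS", "HELP", "BRIGHT", "CQ", "WATER"]
        accs = []
        for sd in (0.0, 0.1, 0.2, 0.4):
            hits = 0
            for k, m in enumerate(msgs):
                noise = bf.NoiseSpec(white_sd=sd, seed=10 + k)
                hits += bf.decode_rule_based(render_trace(m, noise)).text == m
            accs.append(hits / len(msgs))
        assert all(a >= b - 0.02 for a, b in zip(accs, accs[1:]))


class TestFeatures:
    def test_identical_windows_identical_rows(self):
        tr = render_trace("S")
        win = (1.0, 5.0)
        X = bf.extract_features(tr, [win, win])
        np.testing.assert_array_equal(X[0], X[1])

    def test_amplitude_scale_shifts_log_power_by_constant(self):
        tr = render_trace("S")
        tr2 = tr.with_values(3.0 * tr.v)
        a = bf.extract_features(tr, [(1.0, 5.0)])[0]
        b = bf.extract_features(tr2, [(1.0, 5.0)])[0]
        shift = b - a
        np.testing.assert_allclose(shift, 2 * np.log10(3.0), atol=1e-6)

    def test_window_outside_trace_rejected(self):
        tr = render_trace("S")
        with pytest.raises(ValueError, match="outside"):
            bf.extract_features(tr, [(0.0, tr.duration + 5.0)])

    def test_deep_and_shallow_breaths_separate_in_feature_space(self):
        # the dash/dot class-mean feature distance, measured over seeded
        # noisy single-breath renderings, must clear the noise floor of
        # that measurement (the standard error of the mean difference)
        deep_f, shal_f = [], []
        for seed in range(60):
            deep = bf.add_noise(bf.transduce(bf.synth_pressure(
                bf.render_breaths("-", fs=50.0))), bf.NoiseSpec(seed=seed))
            shal = bf.add_noise(bf.transduce(bf.synth_pressure(
                bf.render_breaths(".", fs=50.0))),
                bf.NoiseSpec(seed=seed + 1000))
            w = [(0.5, deep.duration - 0.5)]
            deep_f.append(bf.extract_features(deep, w)[0])
            shal_f.append(bf.extract_features(shal, w)[0])
        D, S = np.array(deep_f), np.array(shal_f)
        gap = np.linalg.norm(D.mean(axis=0) - S.mean(axis=0))
        scatter = np.mean([np.linalg.norm(x - S.mean(axis=0)) for x in S])
        noise_floor = scatter / np.sqrt(len(S))
        assert gap > 3.0 * noise_floor


class TestClassifier:
    def test_perfectly_separable_is_exact(self):
        rng = np.random.default_rng(0)
        X = np.vstack([np.full((20, 4), i) + 0.01 * rng.standard_normal((20, 4))
                       for i in range(6)])
        y = np.repeat(list("ABCDEF"), 20)
        rep = bf.train_eval_classifier(X, y, seed=1)
        assert rep.accuracy == 1.0

    def test_shuffled_labels_at_chance(self):
        X, y = bf.make_letter_dataset(n_per_class=25, seed=0)
        rng = np.random.default_rng(5)
        rep = bf.train_eval_classifier(X, rng.permutation(y), seed=0)
        assert rep.accuracy == pytest.approx(1 / 6, abs=0.12)

    def test_class_with_too_few_examples_rejected(self):
        X = np.zeros((3, 4))
        with pytest.raises(ValueError, match="<2"):
            bf.train_eval_classifier(X, ["A", "A", "B"])

    def test_confusion_matrix_consistency(self):
        X, y = bf.make_letter_dataset(n_per_class=20, seed=3)
        rep = bf.train_eval_classifier(X, y, seed=3)
        assert rep.confusion.sum() == rep.n_test
        assert rep.accuracy == pytest.approx(
            np.trace(rep.confusion) / rep.n_test)
        counts = {c: int(r.sum()) for c, r in zip(rep.classes, rep.confusion)}
        assert all(v == rep.n_test // 6 for v in counts.values())

    def test_dataset_deterministic_in_seed(self):
        Xa, _ = bf.make_letter_dataset(letters="BR", n_per_class=3, seed=9)
        Xb, _ = bf.make_letter_dataset(letters="BR", n_per_class=3, seed=9)
        np.testing.assert_array_equal(Xa, Xb)
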
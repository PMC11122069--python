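import numpy as np
import pytest

from headgest import (
    ConfigError,
    DtwConfig,
    GeneratorConfig,
    GestureTemplate,
    ImuSequence,
    PreprocessConfig,
    TemplateSet,
    build_template,
    build_template_set,
    classify,
    distance_matrix,
    dtw,
    generate_dataset,
    generate_gesture,
)
from headgest.dtw_classifier import median_template_length
from headgest.imu_io import GESTURE_CLASSES
from headgest.preprocessing import preprocess_for_dtw
from headgest.synthetic import PRIMARY_AXIS, biphasic_pulse
from conftest import random_multichannel
from oracles import dtw_min_over_all_paths, reference_dtw_distance


def const_seq(value: float, n: int) -> ImuSequence:
    return ImuSequence(np.full((n, 6), value))


class TestBuildTemplate:
    def test_single_segment_identity(self):
        seg = ImuSequence(np.random.default_rng(0).normal(size=(7, 6)))
        tpl = build_template([seg], "nod")
        assert tpl.m == 7 and tpl.n_sources == 1
        np.testing.assert_array_equal(tpl.channels, seg.data)

    def test_unequal_lengths_partial_averaging(self):
        # lengths 3 and 5 -> m = 4; position 4 averages only the longer one
        tpl = build_template([const_seq(1.0, 3), const_seq(3.0, 5)], "nod")
        assert tpl.m == 4
        np.testing.assert_allclose(tpl.channels[:, 0], [2, 2, 2, 3])

    def test_identical_segments_average_to_themselves(self):
        seg = ImuSequence(np.random.default_rng(3).normal(size=(9, 6)))
        tpl = build_template([seg, ImuSequence(seg.data.copy()), seg], "tilt_up")
        np.testing.assert_allclose(tpl.channels, seg.data)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_template([], "nod")

    @pytest.mark.parametrize(
        "lengths, expected",
        [([7], 7), ([3, 5], 4), ([3, 4], 3), ([1, 2, 3, 10], 2), ([2, 2, 2], 2)],
    )
    def test_median_length_rounds_half_down(self, lengths, expected):
        assert median_template_length(lengths) == expected

    def test_recovery_improves_with_more_sources(self):
        """Templates from 50 noisy, time-jittered copies of a fixed prototype
        sit closer to it (mean absolute error) than templates from 5."""
        fs = 100.0
        cfg = GeneratorConfig(
            duration_range=(1.19, 1.21), amplitude_range=(1.45, 1.55)
        )
        n = 120
        t = (np.arange(n) + 0.5) / fs
        proto = biphasic_pulse(t, n / fs, 1.5, -1, cfg.lobe_width_frac)

        def mae(n_copies: int) -> float:
            copies = [
                generate_gesture("nod", cfg, 1000 + i).data for i in range(n_copies)
            ]
            tpl = build_template(copies, "nod")
            k = min(tpl.m, n)
            got = tpl.channels[:k, 5]  # gz is the nod axis
            return float(np.mean(np.abs(got - proto[:k])))

        assert mae(50) < mae(5)


class TestDistanceMatrix:
    def test_zero_self_distance(self):
        s = np.ones((1, 6))
        assert distance_matrix(s, s)[0, 0] == 0.0

    def test_unit_vector(self):
        a = np.zeros((1, 6))
        b = np.zeros((1, 6))
        b[0, 0] = 1.0
        assert distance_matrix(a, b)[0, 0] == pytest.approx(1.0)

    def test_sqrt_six(self):
        a = np.ones((1, 6))
        b = np.zeros((1, 6))
        assert distance_matrix(a, b)[0, 0] == pytest.approx(np.sqrt(6))
        assert distance_matrix(a, b, squared=True)[0, 0] == pytest.approx(6.0)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError):
            distance_matrix(np.zeros((2, 6)), np.zeros((2, 5)))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            distance_matrix(np.zeros((0, 6)), np.zeros((2, 6)))


class TestDtw:
    def test_self_match_is_zero_diagonal(self):
        s = random_multichannel(np.random.default_rng(1), 8)
        res = dtw(s, s)
        assert res.distance == 0.0
        assert res.path == [(i, i) for i in range(8)]
        assert res.k == 8

    def test_small_one_channel_example(self):
        # |.| pointwise costs on S=(1,2,3), T=(1,3): best summed cost is 1.
        S = np.array([[1.0], [2.0], [3.0]])
        T = np.array([[1.0], [3.0]])
        res = dtw(S, T)
        assert res.distance == pytest.approx(1.0)
        assert res.path in (
            [(0, 0), (1, 0), (2, 1)],
            [(0, 0), (1, 1), (2, 1)],
        )

    def test_single_cell_grid(self):
        res = dtw(np.array([[0.0]]), np.array([[1.0]]))
        assert res.distance == pytest.approx(1.0) and res.k == 1

    def test_matches_exhaustive_path_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            n, m = rng.integers(1, 7, size=2)
            S = random_multichannel(rng, int(n))
            T = random_multichannel(rng, int(m))
            res = dtw(S, T)
            assert res.distance == pytest.approx(
                dtw_min_over_all_paths(res.distance_matrix)
            )

    def test_path_constraints_and_length_bounds(self):
        rng = np.random.default_rng(8)
        for _ in range(60):
            n, m = map(int, rng.integers(1, 9, size=2))
            res = dtw(random_multichannel(rng, n), random_multichannel(rng, m))
            assert res.path[0] == (0, 0) and res.path[-1] == (n - 1, m - 1)
            steps = {
                (b[0] - a[0], b[1] - a[1]) for a, b in zip(res.path, res.path[1:])
            }
            assert steps <= {(1, 0), (1, 1), (0, 1)}
            assert max(n, m) <= res.k <= n + m - 1
            assert res.normalized_distance == pytest.approx(res.distance / res.k)

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            S = random_multichannel(rng, int(rng.integers(2, 30)))
            T = random_multichannel(rng, int(rng.integers(2, 30)))
            assert dtw(S, T).distance == pytest.approx(dtw(T, S).distance)

    def test_zero_iff_aligned_pairs_identical(self):
        rng = np.random.default_rng(10)
        S = random_multichannel(rng, 12)
        res = dtw(S, S + 1e-3)
        assert res.distance > 0
        # Repeated samples warp onto each other at zero cost.
        stretched = np.repeat(S, 2, axis=0)
        assert dtw(S, stretched).distance == pytest.approx(0.0)

    def test_translation_invariance_per_channel(self):
        rng = np.random.default_rng(11)
        S = random_multichannel(rng, 15)
        T = random_multichannel(rng, 10)
        d0 = dtw(S, T).distance
        S2, T2 = S.copy(), T.copy()
        S2[:, 2] += 5.0
        T2[:, 2] += 5.0
        assert dtw(S2, T2).distance == pytest.approx(d0)

    def test_agrees_with_independent_reference(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            S = random_multichannel(rng, int(rng.integers(5, 40)))
            T = random_multichannel(rng, int(rng.integers(5, 40)))
            assert dtw(S, T).distance == pytest.approx(reference_dtw_distance(S, T))


@pytest.fixture(scope="module")
def trained():
    pp = PreprocessConfig()
    data = generate_dataset(20, GeneratorConfig(), 1)
    return build_template_set(data, pp), pp


class TestClassify:
    def test_template_self_match_wins(self, pp):
        rng = np.random.default_rng(13)
        seqs = {
            lab: ImuSequence(rng.normal(size=(30, 6))) for lab in GESTURE_CLASSES
        }
        templates = TemplateSet(
            [
                GestureTemplate(
                    lab,
                    preprocess_for_dtw(seq, pp).data,
                    n_sources=1,
                    preprocessing=pp.fingerprint(),
                )
                for lab, seq in seqs.items()
            ]
        )
        for lab, seq in seqs.items():
            got, distances = classify(seq, templates, pp)
            assert got == lab
            assert distances[lab] == pytest.approx(0.0)

    def test_synthetic_gesture_classified_cross_checked(self, trained):
        templates, pp = trained
        seg = generate_gesture("shake_left", GeneratorConfig(), 999)
        label, distances = classify(seg.data, templates, pp)
        assert label == "shake_left"
        conditioned = preprocess_for_dtw(seg.data, pp)
        for lab in GESTURE_CLASSES:
            ref = reference_dtw_distance(conditioned.data, templates[lab].channels)
            assert distances[lab] == pytest.approx(ref)

    def test_exact_tie_breaks_lexicographically(self, pp):
        chan = np.zeros((10, 6))
        templates = TemplateSet(
            [
                GestureTemplate(lab, chan.copy(), 1, preprocessing=pp.fingerprint())
                for lab in GESTURE_CLASSES
            ]
        )
        seq = ImuSequence(np.ones((12, 6)))
        label, distances = classify(seq, templates, pp)
        assert len(set(distances.values())) == 1
        assert label == min(GESTURE_CLASSES)

    def test_incomplete_set_rejected(self, pp):
        templates = TemplateSet(
            [GestureTemplate("nod", np.zeros((5, 6)), 1, pp.fingerprint())]
        )
        with pytest.raises(ConfigError, match="incomplete"):
            classify(ImuSequence(np.ones((8, 6))), templates, pp)

    def test_preprocessing_fingerprint_mismatch_rejected(self, trained):
        templates, _ = trained
        other = PreprocessConfig(t_win_s=0.2)
        with pytest.raises(ConfigError, match="mismatch"):
            classify(ImuSequence(np.ones((8, 6))), templates, other)

    def test_normalized_distance_option(self, trained):
        templates, pp = trained
        seg = generate_gesture("nod", GeneratorConfig(), 500)
        lab_u, d_u = classify(seg.data, templates, pp, DtwConfig())
        lab_n, d_n = classify(
            seg.data, templates, pp, DtwConfig(normalize_by_path_length=True)
        )
        assert lab_u == lab_n == "nod"
        assert all(d_n[k] < d_u[k] for k in d_u)
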
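from collections import Counter

import numpy as np
import pytest

from endoview.descriptors import DescriptorMatrix
from endoview.discovery import DEFAULT_HIERARCHY, CentroidModel, apply_label_map
from endoview.errors import InvalidInputError
from endoview.partition import (
    UNCERTAIN,
    ClassDistances,
    FrameLabels,
    PartitionConfig,
    Segmentation,
    SurgeryConfig,
    build_overview,
    class_distances,
    extract_segments,
    suppress_short_segments,
    surgery_detect,
    temporal_mode_filter,
    visibility_classify,
)

# ---------------------------------------------------------------------------
# Independent brute-force references
# ---------------------------------------------------------------------------


def brute_class_distances(X, centroids_by_class):
    classes = sorted(centroids_by_class)
    d = np.empty((len(X), len(classes)))
    for i, x in enumerate(X):
        for j, lab in enumerate(classes):
            d[i, j] = min(
                float(((x - c) ** 2).sum()) for c in centroids_by_class[lab]
            )
    return d, classes


def brute_mode_filter(labels, M):
    F = len(labels)
    out = []
    for i in range(F):
        lo, hi = max(0, i - M // 2), min(F, i + (M + 1) // 2)
        counts = Counter(labels[lo:hi])
        best = max(counts.values())
        winners = [lab for lab, c in counts.items() if c == best]
        out.append(winners[0] if len(winners) == 1 else UNCERTAIN)
    return out


def brute_moving_average(x, W):
    F = len(x)
    return np.array(
        [
            np.mean(x[max(0, i - W // 2) : min(F, i + (W + 1) // 2)])
            for i in range(F)
        ]
    )


def _cd(d, classes=("A", "B"), frame_index=None):
    d = np.atleast_2d(np.asarray(d, dtype=float))
    if frame_index is None:
        frame_index = np.arange(len(d))
    return ClassDistances(d=d, class_order=tuple(classes), frame_index=frame_index)


def _fl(labels):
    return FrameLabels(labels=np.asarray(labels, dtype=object),
                       frame_index=np.arange(len(labels)))


class TestClassDistances:
    def _model(self, centroids, labels):
        model = CentroidModel(centroids=np.asarray(centroids, dtype=np.float32))
        return apply_label_map(model, labels, DEFAULT_HIERARCHY)

    def test_zero_at_own_centroid(self):
        model = self._model([[1.0, 2.0], [5.0, 5.0]], {0: "Wall", 1: "Surgery"})
        dm = DescriptorMatrix(vectors=[[1.0, 2.0]], frame_index=[0])
        cd = class_distances(dm, model)
        assert cd.d[0, cd.class_order.index("Wall")] == 0.0

    def test_one_dimensional_arithmetic(self):
        # x=3, class A centroids {0, 5}, class B centroid {10} -> d_A=4, d_B=49
        model = self._model(
            [[0.0], [5.0], [10.0]], {0: "Wall", 1: "Wall", 2: "Surgery"}
        )
        cd = class_distances(DescriptorMatrix(vectors=[[3.0]], frame_index=[0]), model)
        assert cd.d[0, cd.class_order.index("Wall")] == pytest.approx(4.0)
        assert cd.d[0, cd.class_order.index("Surgery")] == pytest.approx(49.0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(12)
        classes = ["Surgery", "High quality", "Wall"]
        for _ in range(20):
            X = rng.standard_normal((50, 8))
            centroids = rng.standard_normal((12, 8)).astype(np.float32)
            labels = {i: classes[i % 3] for i in range(12)}
            model = self._model(centroids, labels)
            cd = class_distances(
                DescriptorMatrix(vectors=X, frame_index=np.arange(50)), model
            )
            ref, ref_classes = brute_class_distances(
                X.astype(np.float32).astype(np.float64),
                {
                    lab: centroids.astype(np.float64)[
                        [i for i, l in labels.items() if l == lab]
                    ]
                    for lab in classes
                },
            )
            assert list(cd.class_order) == ref_classes
            np.testing.assert_allclose(cd.d, ref, rtol=1e-6)

    def test_dim_mismatch_rejected(self):
        model = self._model([[0.0, 0.0]], {0: "Wall"})
        with pytest.raises(InvalidInputError, match="dim"):
            class_distances(DescriptorMatrix(vectors=[[1.0]], frame_index=[0]), model)


class TestVisibilityClassify:
    def test_zero_distance_wins_for_any_ratio(self):
        for R in (0.01, 0.5, 1.0):
            fl = visibility_classify(_cd([[0.0, 3.0]]), PartitionConfig(R=R))
            assert fl.labels[0] == "A"

    def test_exact_tie_is_uncertain(self):
        fl = visibility_classify(_cd([[4.0, 4.0]]), PartitionConfig(R=0.95))
        assert fl.labels[0] == UNCERTAIN

    def test_ratio_boundary(self):
        cfg = PartitionConfig(R=0.95)
        # 3.8 < 4.0 * 0.95 = 3.8 is false -> Uncertain
        assert visibility_classify(_cd([[3.8, 4.0]]), cfg).labels[0] == UNCERTAIN
        assert visibility_classify(_cd([[3.79, 4.0]]), cfg).labels[0] == "A"

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            visibility_classify(_cd([[1.0]], classes=("A",)), PartitionConfig())

    def test_uncertain_set_monotone_in_ratio(self):
        rng = np.random.default_rng(13)
        cd = _cd(rng.uniform(0, 10, size=(300, 4)), classes=("A", "B", "C", "D"))
        prev = None
        for R in (1.0, 0.95, 0.7, 0.4, 0.1):
            unc = set(
                np.flatnonzero(
                    visibility_classify(cd, PartitionConfig(R=R)).labels == UNCERTAIN
                )
            )
            if prev is not None:
                assert prev <= unc  # smaller R rejects at least as much
            prev = unc

    def test_ratio_one_rejects_only_exact_ties(self):
        d = np.array([[1.0, 2.0], [3.0, 3.0], [0.5, 0.5000001]])
        fl = visibility_classify(_cd(d), PartitionConfig(R=1.0))
        assert list(fl.labels) == ["A", UNCERTAIN, "A"]


class TestTemporalModeFilter:
    def test_constant_sequence_unchanged(self):
        fl = temporal_mode_filter(_fl(["A"] * 50), 7)
        assert set(fl.labels) == {"A"}

    def test_isolated_flip_removed(self):
        fl = temporal_mode_filter(_fl(["A", "A", "A", "B", "A", "A", "A"]), 3)
        assert list(fl.labels) == ["A"] * 7

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            labels = rng.choice(["A", "B", "C"], size=200).tolist()
            got = temporal_mode_filter(_fl(labels), 7)
            assert list(got.labels) == brute_mode_filter(labels, 7)

    def test_idempotent_on_long_piecewise_constant_runs(self):
        labels = ["A"] * 30 + ["B"] * 25 + ["C"] * 40
        once = temporal_mode_filter(_fl(labels), 9)
        twice = temporal_mode_filter(once, 9)
        assert list(once.labels) == list(twice.labels) == labels


class TestSegments:
    def test_maximal_runs(self):
        seg = extract_segments(_fl(["A", "A", "B"]))
        assert seg.segments == [(0, 2, "A"), (2, 3, "B")]

    def test_single_frame(self):
        assert extract_segments(_fl(["A"])).segments == [(0, 1, "A")]

    def test_round_trip_through_frame_labels(self):
        rng = np.random.default_rng(15)
        labels = rng.choice(["A", "B"], size=100).tolist()
        seg = extract_segments(_fl(labels))
        assert list(seg.to_frame_labels().labels) == labels

    def test_short_segment_relabeled(self):
        seg = Segmentation(segments=[(0, 100, "A"), (100, 130, "B"), (130, 300, "A")])
        out = suppress_short_segments(seg, 80)
        assert out.segments == [(0, 100, "A"), (100, 130, UNCERTAIN), (130, 300, "A")]

    def test_long_segments_unchanged(self):
        seg = Segmentation(segments=[(0, 100, "A"), (100, 200, "B")])
        assert suppress_short_segments(seg, 80).segments == seg.segments

    def test_all_short_segments_merge_into_one_uncertain(self):
        seg = Segmentation(segments=[(0, 50, "A"), (50, 90, "B"), (90, 140, "A")])
        assert suppress_short_segments(seg, 80).segments == [(0, 140, UNCERTAIN)]

    def test_no_short_non_uncertain_runs_after_suppression(self):
        rng = np.random.default_rng(16)
        for _ in range(10):
            labels = rng.choice(["A", "B", "C"], size=400).tolist()
            seg = suppress_short_segments(extract_segments(_fl(labels)), 15)
            for s, e, lab in seg.segments:
                assert lab == UNCERTAIN or (e - s) >= 15


class TestSurgeryDetect:
    def _cd_from_raw(self, raw):
        d = np.stack([np.asarray(raw, float), np.full(len(raw), 100.0)], axis=1)
        return ClassDistances(
            d=d, class_order=("Surgery", "Wall"), frame_index=np.arange(len(raw))
        )

    def test_constant_below_threshold_spans_video(self):
        track = surgery_detect(self._cd_from_raw([2.0] * 100), SurgeryConfig(W=10, t=6.3))
        assert track.intervals == [(0, 100)]

    def test_constant_at_threshold_detects_nothing(self):
        track = surgery_detect(self._cd_from_raw([6.3] * 100), SurgeryConfig(W=10, t=6.3))
        assert track.intervals == []

    def test_trapezoidal_profile_matches_brute_force(self):
        # t chosen so the trapezoidal mean crosses it strictly between frames
        # (the window mean changes in steps of 10/400 = 0.025 per frame)
        raw = np.full(2400, 10.0)
        raw[1000:1400] = 0.0
        cfg = SurgeryConfig(W=400, t=6.33)
        track = surgery_detect(self._cd_from_raw(raw), cfg)
        ref = brute_moving_average(raw, cfg.W)
        np.testing.assert_allclose(track.smoothed, ref, rtol=1e-9, atol=1e-9)
        # crossing points from the independently computed threshold-centered mean
        flagged = np.flatnonzero(brute_moving_average(raw - cfg.t, cfg.W) < 0)
        assert track.intervals == [(int(flagged[0]), int(flagged[-1]) + 1)]
        # window fully inside the dip -> mean 0 -> certainly flagged
        assert set(range(1100, 1300)) <= set(flagged.tolist())

    def test_missing_surgery_class_rejected(self):
        cd = ClassDistances(
            d=np.ones((5, 2)), class_order=("Wall", "Liquids"), frame_index=np.arange(5)
        )
        with pytest.raises(InvalidInputError, match="Surgery"):
            surgery_detect(cd, SurgeryConfig())


class TestBuildOverview:
    def _track(self, n, flagged=()):
        flags = np.zeros(n, bool)
        for s, e in flagged:
            flags[s:e] = True
        from endoview.partition import _flag_runs, SurgeryTrack

        return SurgeryTrack(
            raw=np.zeros(n), smoothed=np.zeros(n), flags=flags,
            intervals=_flag_runs(flags), threshold=1.0,
        )

    def test_binary_projection_of_noninformative(self):
        seg = Segmentation(segments=[(0, 10, "Wall")])
        ov = build_overview(seg, self._track(10), DEFAULT_HIERARCHY)
        assert ov.binary.segments == [(0, 10, "Non-informative")]

    def test_half_and_half_fractions(self):
        seg = Segmentation(segments=[(0, 5, "High quality"), (5, 10, "Liquids")])
        ov = build_overview(seg, self._track(10), DEFAULT_HIERARCHY)
        assert ov.binary.segments == [
            (0, 5, "Informative"),
            (5, 10, "Non-informative"),
        ]
        assert ov.fractions["binary"] == {
            "Informative": 0.5,
            "Non-informative": 0.5,
        }

    def test_adjacent_same_super_segments_merge(self):
        seg = Segmentation(
            segments=[(0, 5, "High quality"), (5, 10, "Medium quality")]
        )
        ov = build_overview(seg, self._track(10), DEFAULT_HIERARCHY)
        assert ov.binary.segments == [(0, 10, "Informative")]

    def test_uncertain_projects_to_uncertain(self):
        seg = Segmentation(segments=[(0, 4, UNCERTAIN), (4, 10, "Wall")])
        ov = build_overview(seg, self._track(10), DEFAULT_HIERARCHY)
        assert ov.binary.segments[0] == (0, 4, UNCERTAIN)
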
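"""Window geometry, no-rotation sampling, balancing, and the 72/18/10 split."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from headbci import (
    EpochDataset,
    RotationEvent,
    SplitSpec,
    WindowSpec,
    balance_classes,
    build_dataset,
    no_rotation_windows,
    rotation_windows,
    split,
)
from headbci.epochs import LEFT_CLS, NONE, RIGHT_CLS, balanced_partition
from headbci.utils import substream

SPEC = WindowSpec()


class TestRotationWindows:
    def test_hand_computed_spans_for_onset_ten_seconds(self):
        spans = rotation_windows(10.0, SPEC)
        assert len(spans) == 7
        # furthest window: starts 488 ms before onset
        assert spans[0] == pytest.approx((9.512, 9.762))
        # closest window: ends 188 ms before onset
        assert spans[-1] == pytest.approx((9.562, 9.812))
        # middle window centered 338 ms before onset
        assert spans[3] == pytest.approx((10.0 - 0.463, 10.0 - 0.213))
        assert sum(spans[3]) / 2 == pytest.approx(10.0 - 0.338)

    def test_union_covers_exactly_the_lookback_band(self):
        spans = rotation_windows(5.0, SPEC)
        assert min(s for s, _ in spans) == pytest.approx(5.0 - 0.488)
        assert max(e for _, e in spans) == pytest.approx(5.0 - 0.188)

    def test_middle_center_property_matches_spans(self):
        assert SPEC.middle_center == pytest.approx(0.338)

    def test_too_early_onset_is_an_error(self):
        with pytest.raises(ValueError, match="too early"):
            rotation_windows(0.4, SPEC)

    @given(
        width=st.floats(0.1, 0.5),
        closest=st.floats(0.05, 0.4),
        gap=st.floats(0.0, 0.9),
        n=st.sampled_from([3, 5, 7, 9]),
    )
    @settings(max_examples=100, deadline=None)
    def test_geometry_identities_hold_for_any_valid_spec(self, width, closest, gap, n):
        # overlap requires furthest - width < closest + width, i.e. the extra
        # look-back beyond (closest + width) must stay under one width
        furthest = closest + width + gap * width
        spec = WindowSpec(width=width, closest_end=closest, furthest_start=furthest, n_windows=n)
        spans = rotation_windows(10.0, spec)
        assert len(spans) == n
        for s, e in spans:
            assert e - s == pytest.approx(width)
        starts = [s for s, _ in spans]
        assert starts == sorted(starts)
        steps = np.diff(starts)
        assert np.allclose(steps, steps[0])  # evenly spaced
        assert spans[0][0] == pytest.approx(10.0 - furthest)
        assert spans[-1][1] == pytest.approx(10.0 - closest)
        mid = sum(spans[n // 2]) / 2
        assert 10.0 - mid == pytest.approx(spec.middle_center)

    def test_non_overlapping_spec_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            WindowSpec(width=0.1, closest_end=0.1, furthest_start=0.5)
        with pytest.raises(ValueError, match="odd"):
            WindowSpec(n_windows=6)


class TestNoRotationWindows:
    EVENTS = [
        RotationEvent(20.0, "left", 20.3),
        RotationEvent(45.0, "right", 45.3),
        RotationEvent(80.0, "left", 80.3),
    ]

    def test_clearance_and_no_overlap(self):
        rng = substream(0, "t")
        spans = no_rotation_windows(self.EVENTS, duration=100.0, n_required=150, rng=rng)
        assert len(spans) == 150
        for s, e in spans:
            assert e - s == pytest.approx(0.25)
            for ev in self.EVENTS:
                # no overlap with the rotation span itself
                assert e <= ev.onset or s >= ev.offset
                # ends at least 1000 ms before every later onset
                if s < ev.onset:
                    assert ev.onset - e >= 1.0 - 1e-9

    def test_deterministic_given_the_same_stream(self):
        a = no_rotation_windows(self.EVENTS, 100.0, 50, substream(3, "x"))
        b = no_rotation_windows(self.EVENTS, 100.0, 50, substream(3, "x"))
        assert a == b

    def test_unscored_events_still_block_sampling(self):
        # a detected return movement (from_center False) must also be avoided
        ev = [RotationEvent(10.0, "left", 10.3, from_center=False)]
        spans = no_rotation_windows(ev, 20.0, 500, substream(1, "y"))
        for s, e in spans:
            assert e <= 9.0 + 1e-9 or s >= 10.3

    def test_impossible_request_is_an_error(self):
        with pytest.raises(ValueError, match="eligible"):
            no_rotation_windows(self.EVENTS, duration=5.0, n_required=10_000, rng=substream(0, "z"))


class TestBalance:
    def test_undersamples_to_smaller_rotation_class(self):
        rng = substream(0, "bal")
        by = {NONE: np.arange(5000), LEFT_CLS: np.arange(700), RIGHT_CLS: np.arange(840)}
        out = balance_classes(by, rng)
        assert {len(v) for v in out.values()} == {700}
        # chosen indices come from the original pools
        assert set(out[RIGHT_CLS]) <= set(range(840))

    def test_empty_class_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            balance_classes({NONE: np.arange(10), LEFT_CLS: np.array([]), RIGHT_CLS: np.arange(10)}, substream(0, "b"))

    def test_none_shortage_is_an_error(self):
        with pytest.raises(ValueError, match="fewer no-rotation"):
            balance_classes({NONE: np.arange(3), LEFT_CLS: np.arange(10), RIGHT_CLS: np.arange(10)}, substream(0, "b"))


@pytest.fixture(scope="module")
def dataset(session, detected):
    from headbci import preprocess_session

    _thr, _events, _labels, resolved = detected
    eeg128 = preprocess_session(session.eeg, session.eeg_rate)
    return build_dataset([(eeg128, resolved)], substream(5, "none-windows"))


class TestBuildDataset:
    def test_feature_vector_is_1024_long(self, dataset):
        assert dataset.features.shape[1] == 32 * 32 == 1024
        assert dataset.features.dtype == np.float32

    def test_rotation_epochs_are_multiples_of_seven(self, dataset, detected):
        n_rot = int(np.sum(dataset.labels != NONE))
        assert n_rot % 7 == 0 or dataset.meta["n_rejected"] > 0
        # each rotation group holds at most 7 windows, all same label
        for g in np.unique(dataset.group[dataset.labels != NONE]):
            sel = dataset.group == g
            assert sel.sum() <= 7
            assert len(set(dataset.labels[sel])) == 1

    def test_t_center_matches_window_geometry(self, dataset):
        rot = dataset.labels != NONE
        tc = dataset.t_center[rot]
        assert np.all(tc < 0)
        assert tc.min() >= -(0.488 - 0.125) - 1e-6
        assert tc.max() <= -(0.188 + 0.125) + 0.5 / 128 + 1e-6
        assert np.all(np.isnan(dataset.t_center[~rot]))

    def test_build_is_deterministic(self, session, detected):
        from headbci import preprocess_session

        _thr, _events, _labels, resolved = detected
        eeg128 = preprocess_session(session.eeg, session.eeg_rate)
        a = build_dataset([(eeg128, resolved)], substream(5, "none-windows"))
        b = build_dataset([(eeg128, resolved)], substream(5, "none-windows"))
        np.testing.assert_array_equal(a.features, b.features)
        np.testing.assert_array_equal(a.start, b.start)

    def test_roundtrip_hdf5(self, dataset, tmp_path):
        p = tmp_path / "ds.h5"
        dataset.save(p)
        back = EpochDataset.load(p)
        np.testing.assert_array_equal(back.features, dataset.features)
        np.testing.assert_array_equal(back.labels, dataset.labels)
        assert back.meta["rate"] == dataset.meta["rate"]


class TestSplit:
    def _two_block_dataset(self):
        # synthetic metadata-only dataset: 40 rotations/block, 7 windows each,
        # plus singleton none groups, over two 1200 s blocks
        feats, labels, tc, group, block, start, end = [], [], [], [], [], [], []
        gid = 0
        rng = np.random.default_rng(0)
        for b in range(2):
            onsets = np.linspace(20.0, 1180.0, 40)
            for o in onsets:
                for s, e in rotation_windows(o):
                    feats.append(np.zeros(4, dtype=np.float32))
                    labels.append(1 if gid % 2 else 2)
                    tc.append((s + e) / 2 - o)
                    group.append(gid)
                    block.append(b)
                    start.append(s)
                    end.append(e)
                gid += 1
            for _ in range(200):
                s = rng.uniform(0, 1199.75)
                feats.append(np.zeros(4, dtype=np.float32))
                labels.append(0)
                tc.append(np.nan)
                group.append(gid)
                gid += 1
                block.append(b)
                start.append(s)
                end.append(s + 0.25)
        return EpochDataset(
            features=np.array(feats),
            labels=np.array(labels, dtype=np.int8),
            t_center=np.array(tc),
            group=np.array(group),
            block=np.array(block),
            start=np.array(start),
            end=np.array(end),
        )

    def test_test_stream_is_the_last_four_minutes(self):
        ds = self._two_block_dataset()
        tagged, (tb, t0, t1) = split(ds, [1200.0, 1200.0], substream(0, "split"))
        assert tb == 1
        assert t1 - t0 == pytest.approx(240.0)  # 10% of 40 min
        assert t1 == pytest.approx(1200.0)
        test = tagged.split_tag == "test"
        assert np.all(tagged.block[test] == 1)
        assert np.all(tagged.start[test] >= t0 - 1e-9)
        assert np.all(tagged.end[test] <= t1 + 1e-9)

    def test_no_group_straddles_partitions(self):
        ds = self._two_block_dataset()
        tagged, _ = split(ds, [1200.0, 1200.0], substream(1, "split"))
        for g in np.unique(tagged.group):
            tags = set(tagged.split_tag[tagged.group == g])
            assert len(tags) == 1

    def test_train_val_ratio_is_four_to_one(self):
        ds = self._two_block_dataset()
        tagged, _ = split(ds, [1200.0, 1200.0], substream(2, "split"))
        rest = np.isin(tagged.split_tag, ["train", "val"])
        groups = tagged.group[rest]
        tags = tagged.split_tag[rest]
        g_train = len(np.unique(groups[tags == "train"]))
        g_val = len(np.unique(groups[tags == "val"]))
        assert g_train / (g_train + g_val) == pytest.approx(0.8, abs=0.02)

    def test_split_without_test_rotations_is_an_error(self):
        ds = self._two_block_dataset()
        keep = ~((ds.block == 1) & (ds.start >= 940.0) & (ds.labels != 0))
        with pytest.raises(ValueError, match="zero rotation"):
            split(ds.subset(keep), [1200.0, 1200.0], substream(0, "s"))

    def test_balanced_partition_equal_counts(self):
        ds = self._two_block_dataset()
        tagged, _ = split(ds, [1200.0, 1200.0], substream(3, "split"))
        part = balanced_partition(tagged, "train", substream(3, "bal"))
        counts = part.class_counts()
        assert counts["none"] == counts["left"] == counts["right"] > 0

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            SplitSpec(train_frac=0.8, val_frac=0.18, test_frac=0.10)


class TestEndToEndSplitOnRealDataset(object):
    def test_partitions_disjoint_and_cover(self, dataset, session):
        duration = session.imu.shape[0] / session.imu_rate
        tagged, (tb, t0, t1) = split(dataset, [duration], substream(9, "split"))
        assert tb == 0 and t1 == pytest.approx(duration)
        tags = set(tagged.split_tag)
        assert tags <= {"train", "val", "test", "dropped"}
        n = sum(np.sum(tagged.split_tag == t) for t in tags)
        assert n == len(tagged)
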
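"""Manifest parsing, series assembly, series-level splits, augmentation."""

import numpy as np
import pytest

from phenodistill.data import (AugmentationPolicy, FrameRecord, SeriesSample,
                               SplitSpec, Transform, apply_transform,
                               assemble_series, augment_training_set,
                               dataset_summary, read_manifest, split_series)

# Per-stage series counts of the emulated field study: (train before
# augmentation, val, test) per stage 1..8; the train set is augmented 3x.
STUDY_STAGE_COUNTS = {
    1: (612, 204, 204),
    2: (716, 254, 254),
    3: (490, 163, 163),
    4: (388, 112, 112),
    5: (370, 121, 121),
    6: (284, 98, 98),
    7: (366, 105, 105),
    8: (496, 184, 184),
}


def _dummy_records(n_series=4, L=3, stage=1):
    recs = []
    for i in range(n_series):
        for t in range(L):
            recs.append(FrameRecord(f"s{i}", t, stage, f"img/s{i}_{t}.png"))
    return recs


def _dummy_samples(counts: dict[int, int], L: int = 1, tag: str = "") -> list[SeriesSample]:
    out = []
    for stage, n in counts.items():
        for i in range(n):
            frames = [FrameRecord(f"{tag}st{stage}_{i}", t, stage, "x.png")
                      for t in range(L)]
            out.append(SeriesSample(series_id=frames[0].series_id, frames=frames,
                                    label=stage, source_id=frames[0].series_id))
    return out


class TestReadManifest:
    def test_row_count(self, micro_dataset, micro_config):
        root, _ = micro_dataset
        records = read_manifest(root / "manifest.csv")
        assert len(records) == micro_config.n_series * micro_config.frames_per_series

    def test_out_of_range_stage_names_row(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("series_id,frame_index,stage,path\n"
                        "a,0,1,x.png\na,1,9,y.png\n")
        with pytest.raises(ValueError, match="row 2"):
            read_manifest(path)

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("series_id,frame_index,stage,path\n")
        assert read_manifest(path) == []

    def test_duplicate_key_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("series_id,frame_index,stage,path\n"
                        "a,0,1,x.png\na,0,2,y.png\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_manifest(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("series_id,frame_index,path\na,0,x.png\n")
        with pytest.raises(ValueError, match="stage"):
            read_manifest(path)


class TestAssembleSeries:
    def test_groups_and_sorts(self):
        samples = assemble_series(_dummy_records(10, 3), L=3)
        assert len(samples) == 10
        for s in samples:
            assert [f.frame_index for f in s.frames] == [0, 1, 2]

    def test_short_series_rejected_by_default(self, caplog):
        recs = _dummy_records(2, 3) + [FrameRecord("short", 0, 1, "x.png"),
                                       FrameRecord("short", 1, 1, "y.png")]
        with caplog.at_level("WARNING"):
            samples = assemble_series(recs, L=3)
        assert len(samples) == 2
        assert any("short" in r.message for r in caplog.records)

    def test_pad_policy_repeats_earliest_frame(self):
        recs = [FrameRecord("s", t, 2, f"{t}.png") for t in range(1, 3)]  # 2 frames
        (sample,) = assemble_series(recs, L=3, length_policy="pad")
        assert sample.L == 3
        assert sample.frames[0] is sample.frames[1]  # first frame duplicated in front
        assert sample.frames[0].frame_index == 1

    def test_label_is_final_stage(self):
        recs = [FrameRecord("s", t, stage, "x.png")
                for t, stage in enumerate([2, 2, 3, 4])]
        (sample,) = assemble_series(recs, L=4)
        assert sample.label == 4

    def test_majority_label_policy(self):
        recs = [FrameRecord("s", t, stage, "x.png")
                for t, stage in enumerate([2, 2, 2, 4])]
        (sample,) = assemble_series(recs, L=4, label_policy="majority")
        assert sample.label == 2


class TestSplitSeries:
    def test_six_two_two_on_ten_series(self):
        samples = _dummy_samples({1: 10})
        train, val, test = split_series(samples, SplitSpec(seed=0))
        assert (len(train), len(val), len(test)) == (6, 2, 2)

    def test_all_to_train(self):
        samples = _dummy_samples({1: 7})
        train, val, test = split_series(samples, SplitSpec(ratios=(1, 0, 0), seed=0))
        assert (len(train), len(val), len(test)) == (7, 0, 0)

    def test_deterministic(self):
        samples = _dummy_samples({1: 9, 2: 8, 5: 7})
        a = split_series(samples, SplitSpec(seed=4))
        b = split_series(samples, SplitSpec(seed=4))
        for xs, ys in zip(a, b):
            assert [s.series_id for s in xs] == [s.series_id for s in ys]

    def test_partition_is_by_series_and_exhaustive(self):
        samples = _dummy_samples({1: 11, 3: 6, 7: 13})
        train, val, test = split_series(samples, SplitSpec(seed=1))
        ids = [s.series_id for part in (train, val, test) for s in part]
        assert len(ids) == len(set(ids)) == len(samples)

    def test_stratified_when_counts_permit(self):
        samples = _dummy_samples({s: 10 for s in range(1, 9)})
        train, val, test = split_series(samples, SplitSpec(seed=2))
        for part in (train, val, test):
            assert {s.label for s in part} == set(range(1, 9))

    def test_too_few_series_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            split_series(_dummy_samples({1: 2}), SplitSpec(seed=0))

    def test_ratios_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SplitSpec(ratios=(0.5, 0.2, 0.2))


class TestAugmentation:
    def test_study_counts_emergence(self):
        """612 emergence training series expand to exactly 1836 with factor 3."""
        train = _dummy_samples({1: STUDY_STAGE_COUNTS[1][0]})
        out = augment_training_set(train, AugmentationPolicy(expansion_factor=3))
        assert len(out) == 1836

    def test_study_counts_total(self):
        """The full per-stage table (3722 series) expands to 11166."""
        train = _dummy_samples({s: c[0] for s, c in STUDY_STAGE_COUNTS.items()})
        assert len(train) == 3722
        out = augment_training_set(train, AugmentationPolicy(expansion_factor=3))
        assert len(out) == 11166

    def test_factor_one_is_identity(self):
        train = _dummy_samples({1: 5})
        out = augment_training_set(train, AugmentationPolicy(expansion_factor=1))
        assert out == train

    def test_per_stage_conservation_and_label_preservation(self):
        train = _dummy_samples({2: 4, 5: 3}, L=2)
        out = augment_training_set(train, AugmentationPolicy(expansion_factor=3,
                                                             seed=1))
        assert len(out) == 3 * len(train)
        for stage, n in ((2, 4), (5, 3)):
            assert sum(s.label == stage for s in out) == 3 * n
        for s in out:
            assert s.L == 2
        copies = [s for s in out if s.is_augmented]
        assert len(copies) == 2 * len(train)
        assert all(s.transform is not None for s in copies)

    def test_transform_is_per_series(self):
        """Every frame of an augmented copy shares one transform object."""
        train = _dummy_samples({1: 2}, L=4)
        out = augment_training_set(train, AugmentationPolicy(expansion_factor=2,
                                                             seed=0))
        copy = next(s for s in out if s.is_augmented)
        assert copy.frames == train[0].frames or copy.frames == train[1].frames

    def test_unknown_op_rejected(self):
        with pytest.raises(ValueError, match="unknown augmentation"):
            AugmentationPolicy(ops=("brightness", "zoom"))


class TestApplyTransform:
    def test_identity(self, rng):
        img = rng.random((8, 8, 3))
        np.testing.assert_array_equal(apply_transform(img, None), img)

    def test_flip_is_involution(self, rng):
        img = rng.random((8, 8, 3))
        t = Transform(flip=True)
        np.testing.assert_allclose(apply_transform(apply_transform(img, t), t), img)

    def test_brightness_clips(self):
        img = np.full((4, 4, 3), 0.9)
        out = apply_transform(img, Transform(brightness=1.5))
        assert out.max() <= 1.0


class TestDatasetSummary:
    def test_reproduces_study_table(self):
        """Per-stage accounting matches the emulated study: ALL row
        3722 / 11166 / 1241 / 1241 and a 13648 grand total."""
        train = _dummy_samples({s: c[0] for s, c in STUDY_STAGE_COUNTS.items()})
        val = _dummy_samples({s: c[1] for s, c in STUDY_STAGE_COUNTS.items()}, tag="v")
        test = _dummy_samples({s: c[2] for s, c in STUDY_STAGE_COUNTS.items()}, tag="t")
        aug = augment_training_set(train, AugmentationPolicy(expansion_factor=3))
        table = dataset_summary(aug, val, test)
        assert table.loc["emergence", "train_before_aug"] == 612
        assert table.loc["emergence", "train_after_aug"] == 1836
        assert table.loc["emergence", "overall"] == 2244
        assert table.loc["anthesis", "overall"] == 1048
        row = table.loc["ALL"]
        assert (row["train_before_aug"], row["train_after_aug"]) == (3722, 11166)
        assert row["val"] == row["test"] == 1241
        assert row["overall"] == 13648

    def test_empty_splits_all_zero(self):
        table = dataset_summary([], [], [])
        assert (table.to_numpy() == 0).all()

    def test_overall_additivity(self):
        train = _dummy_samples({1: 3, 4: 2})
        aug = augment_training_set(train, AugmentationPolicy(expansion_factor=3))
        val = _dummy_samples({1: 1}, tag="v")
        test = _dummy_samples({4: 2}, tag="t")
        table = dataset_summary(aug, val, test)
        np.testing.assert_array_equal(
            table["overall"],
            table["train_after_aug"] + table["val"] + table["test"])
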
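"""Volume loading, slice filtering, resizing and sequence grouping."""

import logging

import numpy as np
import pytest
import SimpleITK as sitk

from laseg.errors import ConfigurationError, ValidationError
from laseg.synthetic_data import PhantomConfig, generate_phantom
from laseg.volume_io import (Batch, Volume3D, batch_sequences, load_volume,
                             make_sequences, normalize_intensities,
                             preprocess_volume, resize_slice, save_volume,
                             split_and_filter)


class TestVolume3D:
    def test_mask_values_are_remapped_to_01(self):
        intens = np.zeros((2, 4, 4), dtype=np.float32)
        mask = np.zeros((2, 4, 4), dtype=np.uint8)
        mask[0, 1, 1] = 255
        vol = Volume3D(intensities=intens, mask=mask)
        assert set(np.unique(vol.mask)) <= {0, 1}
        assert vol.mask[0, 1, 1] == 1

    def test_mask_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="mask shape"):
            Volume3D(intensities=np.zeros((10, 6, 6)),
                     mask=np.zeros((9, 6, 6)))

    def test_nonbinary_mask_rejected(self):
        with pytest.raises(ValidationError, match="mask"):
            Volume3D(intensities=np.zeros((2, 4, 4)),
                     mask=np.full((2, 4, 4), 7))

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValidationError, match="spacing"):
            Volume3D(intensities=np.zeros((2, 4, 4)), spacing=(1, 0, 1))


class TestFileRoundTrips:
    def test_nifti_round_trip_is_bit_exact(self, small_phantom, tmp_path):
        img_p = tmp_path / "vol.nii.gz"
        msk_p = tmp_path / "vol_mask.nii.gz"
        save_volume(img_p, small_phantom.intensities, (1.25, 0.5, 0.5))
        save_volume(msk_p, small_phantom.mask, (1.25, 0.5, 0.5))
        loaded = load_volume(img_p, msk_p)
        assert (loaded.intensities == small_phantom.intensities).all()
        assert (loaded.mask == small_phantom.mask).all()
        assert loaded.spacing == pytest.approx((1.25, 0.5, 0.5))

    def test_mask_coded_255_is_remapped_on_load(self, tmp_path):
        save_volume(tmp_path / "v.nii.gz", np.zeros((3, 8, 8), np.float32))
        save_volume(tmp_path / "m.nii.gz",
                    np.random.default_rng(0).choice([0, 255], (3, 8, 8))
                    .astype(np.uint8))
        vol = load_volume(tmp_path / "v.nii.gz", tmp_path / "m.nii.gz")
        assert set(np.unique(vol.mask)) <= {0, 1}

    def test_nrrd_volume_reads_with_spacing(self, tmp_path):
        arr = np.random.default_rng(1).random((4, 8, 8)).astype(np.float32)
        img = sitk.GetImageFromArray(arr)
        img.SetSpacing((0.5, 0.5, 2.0))      # (x, y, z)
        sitk.WriteImage(img, str(tmp_path / "v.nrrd"))
        vol = load_volume(tmp_path / "v.nrrd")
        assert vol.intensities.shape == (4, 8, 8)
        assert np.allclose(vol.intensities, arr)
        assert vol.spacing == pytest.approx((2.0, 0.5, 0.5))

    def test_missing_file_raises_io_error_naming_path(self, tmp_path):
        with pytest.raises(IOError, match="nowhere.nii.gz"):
            load_volume(tmp_path / "nowhere.nii.gz")

    def test_mask_shape_mismatch_on_load(self, tmp_path):
        save_volume(tmp_path / "v.nii.gz", np.zeros((10, 8, 8), np.float32))
        save_volume(tmp_path / "m.nii.gz", np.zeros((9, 8, 8), np.uint8))
        with pytest.raises(ValidationError):
            load_volume(tmp_path / "v.nii.gz", tmp_path / "m.nii.gz")


class TestSplitAndFilter:
    def _volume_with_fg_slices(self, fg_slices, n=10):
        mask = np.zeros((n, 6, 6), dtype=np.uint8)
        for k in fg_slices:
            mask[k, 2, 2] = 1
        return Volume3D(intensities=np.random.default_rng(0).random((n, 6, 6)),
                        mask=mask)

    def test_keeps_only_foreground_slices_in_order(self):
        vol = self._volume_with_fg_slices([3, 4, 5, 6, 7])
        pairs = split_and_filter(vol)
        assert len(pairs) == 5
        expected = np.moveaxis(vol.intensities, 0, 0)[3:8]
        for (img, m), ref in zip(pairs, expected):
            assert (img == ref).all()
            assert m.sum() >= 1

    def test_empty_mask_returns_empty_list_with_warning(self, caplog):
        vol = self._volume_with_fg_slices([])
        with caplog.at_level(logging.WARNING):
            pairs = split_and_filter(vol)
        assert pairs == []
        assert any("no slice contains foreground" in r.message
                   for r in caplog.records)

    def test_keep_empty_retains_all_slices_without_mask(self):
        vol = Volume3D(intensities=np.zeros((10, 6, 6)))
        assert len(split_and_filter(vol, keep_empty=True)) == 10

    def test_filtering_without_mask_is_a_configuration_error(self):
        vol = Volume3D(intensities=np.zeros((10, 6, 6)))
        with pytest.raises(ConfigurationError):
            split_and_filter(vol, keep_empty=False)

    def test_count_matches_direct_loop_on_random_masks(self, rng):
        for _ in range(20):
            mask = (rng.random((12, 5, 5)) < 0.1).astype(np.uint8)
            vol = Volume3D(intensities=rng.random((12, 5, 5)), mask=mask)
            expected = sum(1 for k in range(12) if mask[k].sum() > 0)
            assert len(split_and_filter(vol)) == expected


class TestResize:
    def test_upscales_to_target(self):
        img = np.random.default_rng(0).random((20, 20))
        mask = (img > 0.5).astype(np.uint8)
        out_img, out_mask = resize_slice(img, mask, (64, 64))
        assert out_img.shape == (64, 64)
        assert out_mask.shape == (64, 64)

    def test_identity_when_already_at_target(self):
        img = np.random.default_rng(0).random((16, 16))
        mask = (img > 0.5).astype(np.uint8)
        out_img, out_mask = resize_slice(img, mask, (16, 16))
        assert (out_img == img).all() and (out_mask == mask).all()

    def test_mask_stays_binary_after_resize(self):
        rng = np.random.default_rng(5)
        for target in [(24, 24), (50, 30), (12, 64)]:
            mask = (rng.random((32, 32)) < 0.2).astype(np.uint8)
            _, out = resize_slice(rng.random((32, 32)), mask, target)
            assert set(np.unique(out)) <= {0, 1}

    def test_too_small_target_rejected(self):
        with pytest.raises(ValidationError):
            resize_slice(np.zeros((16, 16)), None, (4, 16))


class TestMakeSequences:
    def _slices(self, n):
        return [(np.full((4, 4), k, dtype=np.float32),
                 np.full((4, 4), k % 2, dtype=np.uint8)) for k in range(n)]

    @pytest.mark.parametrize("n,t,n_seq,last_pad", [
        (16, 8, 2, 0),
        (12, 8, 2, 4),
        (1, 8, 1, 7),
        (5, 2, 3, 1),
    ])
    def test_grouping_and_padding(self, n, t, n_seq, last_pad):
        seqs = make_sequences(self._slices(n), seq_len=t)
        assert len(seqs) == n_seq
        assert all(s.seq_len == t for s in seqs)
        assert seqs[-1].pad_count == last_pad
        assert all(s.pad_count == 0 for s in seqs[:-1])

    def test_unpadded_concatenation_reproduces_input(self):
        slices = self._slices(13)
        seqs = make_sequences(slices, seq_len=4)
        rebuilt = []
        for s in seqs:
            t = s.seq_len - s.pad_count
            rebuilt.extend(s.images[:t, 0])
        assert len(rebuilt) == 13
        for got, (want, _) in zip(rebuilt, slices):
            assert (got == want).all()

    def test_padding_repeats_last_slice(self):
        seqs = make_sequences(self._slices(3), seq_len=8)
        s = seqs[0]
        for k in range(3, 8):
            assert (s.images[k] == s.images[2]).all()

    def test_empty_slice_list_rejected(self):
        with pytest.raises(ValidationError):
            make_sequences([], seq_len=8)


class TestBatchingAndPipeline:
    def test_batch_layout_is_ntchw(self, small_phantom):
        seqs = preprocess_volume(small_phantom, size=32, seq_len=4)
        batch = batch_sequences(seqs)
        assert batch.data.shape == (len(seqs), 4, 1, 32, 32)
        assert batch.masks.shape == (len(seqs), 4, 32, 32)
        assert batch.valid.shape == (len(seqs), 4)

    def test_batch_requires_5d(self):
        with pytest.raises(ValidationError):
            Batch(data=np.zeros((2, 1, 8, 8)))

    def test_normalization_maps_to_unit_interval(self, small_phantom):
        out = normalize_intensities(small_phantom.intensities * 700 + 40)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_pipeline_validity_masks_mark_padding(self, small_phantom):
        seqs = preprocess_volume(small_phantom, size=32, seq_len=3)
        total_real = sum(int(s.valid.sum()) for s in seqs)
        assert total_real == 8    # every phantom slice has foreground
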
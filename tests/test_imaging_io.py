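"""Slice/label-map I/O and 8-bit normalisation contracts."""

import numpy as np
import pytest

from fatquant import (DataError, ImageIOError, RegionMasks, UsageError, normalize_to_8bit,
                      read_grades, read_label_map, read_slice, write_label_map, write_slice)


class TestNormalize:
    def test_minmax_three_levels_round_half_up(self):
        raw = np.tile(np.array([0, 50, 100]), (32, 32))[:32, :96]
        out = normalize_to_8bit(raw)
        assert set(np.unique(out.pixels)) == {0, 128, 255}

    def test_constant_image_maps_to_zero(self):
        out = normalize_to_8bit(np.full((40, 40), 77))
        assert not out.pixels.any()

    @pytest.mark.parametrize("hi", [4095, 65535, 1000])
    def test_matches_per_pixel_rescale_oracle(self, rng, hi):
        raw = rng.integers(0, hi + 1, (48, 48))
        raw.flat[0], raw.flat[1] = 0, hi  # pin the range
        out = normalize_to_8bit(raw)
        oracle = np.floor(raw * 255.0 / hi + 0.5).astype(np.uint8)
        np.testing.assert_array_equal(out.pixels, oracle)

    def test_monotone(self, rng):
        raw = rng.normal(500, 200, (64, 64))
        out = normalize_to_8bit(raw).pixels
        order = np.argsort(raw.ravel(), kind="stable")
        assert (np.diff(out.ravel()[order].astype(int)) >= 0).all()

    def test_percentile_clips_outlier(self, rng):
        raw = rng.uniform(0, 200, (64, 64))
        raw[0, 0] = 10000.0
        out = normalize_to_8bit(raw, policy="percentile", p_lo=0.5, p_hi=99.5)
        assert out.pixels[0, 0] == 255
        # the 0-200 body occupies most of the dynamic range, not a corner of it
        assert np.percentile(out.pixels, 99) > 200
        lo, hi = np.percentile(raw, [0.5, 99.5])
        oracle = normalize_to_8bit(np.clip(raw, lo, hi))
        np.testing.assert_array_equal(out.pixels, oracle.pixels)

    def test_bad_percentile_bounds(self):
        with pytest.raises(UsageError):
            normalize_to_8bit(np.zeros((32, 32)), policy="percentile", p_lo=90, p_hi=10)

    def test_idempotent_on_full_range_8bit(self, rng):
        raw = rng.integers(0, 256, (40, 40))
        raw.flat[0], raw.flat[1] = 0, 255
        once = normalize_to_8bit(raw).pixels
        twice = normalize_to_8bit(once).pixels
        np.testing.assert_array_equal(once, twice)


class TestReadSlice:
    def test_png_8bit_identity(self, tmp_path):
        arr = np.full((64, 64), 100, dtype=np.uint8)
        write_slice(tmp_path / "c.png", arr)
        out = read_slice(tmp_path / "c.png")
        assert (out.pixels == 100).all()

    def test_16bit_nifti_rescaled(self, tmp_path, rng):
        import nibabel as nib

        raw = rng.integers(0, 4096, (64, 64)).astype(np.int16)
        raw.flat[0], raw.flat[1] = 0, 4095
        nib.save(nib.Nifti1Image(raw, np.eye(4)), tmp_path / "s.nii.gz")
        out = read_slice(tmp_path / "s.nii.gz")
        oracle = np.floor(raw * 255.0 / 4095 + 0.5).astype(np.uint8)
        np.testing.assert_array_equal(out.pixels, oracle)

    def test_volume_requires_slice_index(self, tmp_path, rng):
        import nibabel as nib

        vol = rng.integers(0, 255, (64, 64, 3)).astype(np.int16)
        nib.save(nib.Nifti1Image(vol, np.eye(4)), tmp_path / "v.nii.gz")
        with pytest.raises(UsageError):
            read_slice(tmp_path / "v.nii.gz")
        out = read_slice(tmp_path / "v.nii.gz", slice_index=1)
        assert out.pixels.shape == (64, 64)

    def test_truncated_dicom_is_io_error(self, tmp_path):
        bad = tmp_path / "t.dcm"
        bad.write_bytes(b"\x00" * 100)
        with pytest.raises(ImageIOError):
            read_slice(bad)

    def test_single_frame_dicom_roundtrip(self, tmp_path, rng):
        import pydicom
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        arr = rng.integers(0, 255, (64, 64)).astype(np.uint8)
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(str(tmp_path / "a.dcm"), {}, file_meta=meta, preamble=b"\0" * 128)
        ds.Rows, ds.Columns = arr.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = ds.BitsStored = 8
        ds.HighBit = 7
        ds.PixelRepresentation = 0
        ds.PixelData = arr.tobytes()
        ds.save_as(tmp_path / "a.dcm", enforce_file_format=True)
        out = read_slice(tmp_path / "a.dcm")
        np.testing.assert_array_equal(out.pixels, arr)

    def test_missing_file(self, tmp_path):
        with pytest.raises(ImageIOError):
            read_slice(tmp_path / "nope.png")


class TestLabelMaps:
    def _masks(self):
        fossa = np.zeros((64, 64), dtype=bool)
        muscle = np.zeros((64, 64), dtype=bool)
        fossa[10:40, 10:40] = True
        muscle[15:30, 15:30] = True
        return RegionMasks(fossa=fossa, muscle=muscle)

    def test_roundtrip_preserves_labels(self, tmp_path):
        masks = self._masks()
        write_label_map(tmp_path / "l.nii.gz", masks)
        back = read_label_map(tmp_path / "l.nii.gz")
        np.testing.assert_array_equal(back.fossa, masks.fossa)
        np.testing.assert_array_equal(back.muscle, masks.muscle)
        assert back.containment_violations == 0

    def test_violating_prediction_roundtrip(self, tmp_path):
        masks = self._masks()
        masks.muscle[50:55, 50] = True  # 5 muscle px outside fossa
        write_label_map(tmp_path / "p.nii.gz", masks)
        back = read_label_map(tmp_path / "p.nii.gz")
        assert back.containment_violations == 5
        np.testing.assert_array_equal(back.muscle, masks.muscle)

    def test_ground_truth_containment_enforced(self, tmp_path):
        masks = self._masks()
        masks.muscle[50:55, 50] = True
        write_label_map(tmp_path / "p.nii.gz", masks)
        with pytest.raises(DataError):
            read_label_map(tmp_path / "p.nii.gz", ground_truth=True)

    def test_missing_label_is_data_error(self, tmp_path):
        import nibabel as nib

        lab = np.zeros((64, 64), dtype=np.int16)
        lab[10:40, 10:40] = 1  # fossa only, no muscle label
        nib.save(nib.Nifti1Image(lab, np.eye(4)), tmp_path / "l.nii.gz")
        with pytest.raises(DataError, match="2"):
            read_label_map(tmp_path / "l.nii.gz")


def test_grade_sidecar_roundtrip(tmp_path):
    (tmp_path / "g.csv").write_text("source_id,grade\na,0\nb,4\n")
    df = read_grades(tmp_path / "g.csv")
    assert list(df["grade"]) == [0, 4]
    (tmp_path / "bad.csv").write_text("source_id,grade\na,7\n")
    with pytest.raises(DataError):
        read_grades(tmp_path / "bad.csv")
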
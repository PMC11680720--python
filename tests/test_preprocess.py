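"""Normalization, standard cropping, dataset split, and file round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from onfhgrade import (
    DegenerateInputError,
    Slice,
    ValidationError,
    crop_to_standard,
    normalize,
    split_dataset,
)
from onfhgrade import io as fio
from onfhgrade.preprocess import read_split_manifest, write_split_manifest


class TestNormalize:
    def test_minmax_spans_unit_interval(self, rng):
        raw = rng.uniform(10, 260, size=(40, 50))
        slc = normalize(raw)
        assert slc.pixels.min() == 0.0
        assert slc.pixels.max() == 1.0

    def test_idempotent_on_normalized_input(self, rng):
        raw = rng.random((30, 30))
        raw[0, 0], raw[-1, -1] = 0.0, 1.0
        out = normalize(raw)
        assert np.allclose(out.pixels, raw)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalize(np.full((20, 20), 7.0))

    def test_non_2d_rejected(self):
        with pytest.raises(ValidationError):
            normalize(np.zeros((4, 4, 4)))


class TestCrop:
    def test_central_window_of_larger_image(self, rng):
        raw = rng.random((512, 512))
        out = crop_to_standard(normalize(raw))
        assert out.pixels.shape == (256, 256)
        expected = normalize(raw).pixels[128:384, 128:384]
        assert np.array_equal(out.pixels, expected)

    def test_identity_at_target_size(self, rng):
        slc = normalize(rng.random((256, 256)))
        out = crop_to_standard(slc)
        assert np.array_equal(out.pixels, slc.pixels)

    def test_small_input_zero_padded_symmetrically(self, rng):
        slc = normalize(rng.random((200, 300)))
        out = crop_to_standard(slc)
        assert out.pixels.shape == (256, 256)
        # 56 missing rows -> 28 top, 28 bottom of zeros
        assert np.all(out.pixels[:28] == 0.0) and np.all(out.pixels[-28:] == 0.0)
        assert np.array_equal(out.pixels[28:-28], slc.pixels[:, 22:278])

    def test_idempotence(self, rng):
        slc = normalize(rng.random((300, 400)))
        once = crop_to_standard(slc)
        twice = crop_to_standard(once)
        assert np.array_equal(once.pixels, twice.pixels)

    def test_center_is_clamped_to_bounds(self, rng):
        slc = normalize(rng.random((300, 300)))
        out = crop_to_standard(slc, center=(0, 0))
        assert np.array_equal(out.pixels, slc.pixels[:256, :256])


class TestSplit:
    def test_80_20_at_n200(self):
        ids = [f"s{i}" for i in range(200)]
        split = split_dataset(ids, 0.8, seed=0)
        assert len(split.train_ids) == 160 and len(split.test_ids) == 40

    def test_rounding_at_small_n(self):
        split = split_dataset(list("abcde"), 0.8, seed=0)
        assert len(split.train_ids) == 4 and len(split.test_ids) == 1

    def test_determinism(self):
        ids = [f"s{i}" for i in range(57)]
        a = split_dataset(ids, 0.8, seed=9)
        b = split_dataset(ids, 0.8, seed=9)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids

    @settings(deadline=None, derandomize=True)
    @given(n=st.integers(2, 150), frac=st.floats(0.05, 0.95), seed=st.integers(0, 1000))
    def test_partition_property(self, n, frac, seed):
        ids = [f"s{i}" for i in range(n)]
        split = split_dataset(ids, frac, seed=seed)
        assert sorted(split.train_ids + split.test_ids) == sorted(ids)
        assert len(split.train_ids) == int(np.floor(frac * n + 0.5))

    def test_duplicates_rejected(self):
        with pytest.raises(ValidationError):
            split_dataset(["a", "b", "a"], 0.8, seed=0)

    def test_manifest_round_trip(self, tmp_path):
        split = split_dataset([f"s{i}" for i in range(10)], 0.7, seed=4)
        path = write_split_manifest(split, tmp_path / "split.csv")
        back = read_split_manifest(path)
        assert back.train_ids == split.train_ids
        assert back.test_ids == split.test_ids
        assert back.seed == 4 and back.train_fraction == 0.7


class TestIO:
    def test_png_slice_round_trip(self, tmp_path, rng):
        slc = normalize(rng.random((64, 64)))
        path = fio.write_slice(slc, tmp_path / "x.png")
        raw, _, fmt = fio.read_raw(path)
        assert fmt == "png"
        assert np.abs(raw / 255.0 - slc.pixels).max() <= 0.5 / 255.0 + 1e-12

    def test_png_mask_round_trip(self, tmp_path, default_phantom):
        path = fio.write_mask(default_phantom.head_mask, tmp_path / "m.png")
        assert np.array_equal(fio.read_mask(path), default_phantom.head_mask)

    def test_nifti_round_trip(self, tmp_path, rng):
        slc = Slice(rng.random((32, 48)).astype(np.float32), spacing=(0.5, 0.7))
        path = fio.write_slice(slc, tmp_path / "x.nii")
        raw, spacing, fmt = fio.read_raw(path)
        assert fmt == "nifti"
        assert np.allclose(raw, slc.pixels, atol=1e-6)
        assert spacing == pytest.approx((0.5, 0.7))

    def test_dicom_read_with_monochrome1_inversion(self, tmp_path, rng):
        pydicom = pytest.importorskip("pydicom")
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

        pixels = rng.integers(0, 4096, size=(32, 32)).astype(np.uint16)

        def make(path, photometric):
            meta = FileMetaDataset()
            meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
            meta.MediaStorageSOPInstanceUID = generate_uid()
            meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
            ds.Rows, ds.Columns = pixels.shape
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = photometric
            ds.BitsAllocated = ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 0
            ds.PixelSpacing = [0.8, 0.8]
            ds.PixelData = pixels.tobytes()
            ds.save_as(str(path), enforce_file_format=True)
            return path

        raw2, spacing, fmt = fio.read_raw(make(tmp_path / "m2.dcm", "MONOCHROME2"))
        assert fmt == "dicom" and spacing == (0.8, 0.8)
        assert np.array_equal(raw2, pixels.astype(float))
        raw1, _, _ = fio.read_raw(make(tmp_path / "m1.dcm", "MONOCHROME1"))
        assert np.array_equal(raw1, pixels.max() - pixels.astype(float))
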
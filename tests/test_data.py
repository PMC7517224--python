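"""Container types, I/O round trips, and the preprocessing pipeline."""

import numpy as np
import pytest

from gwcine import (
    CineSequence,
    DeformationSequence,
    RegionMask,
    load_fields,
    load_sequence,
    preprocess,
    save_fields,
    save_sequence,
)
from gwcine.data import normalize_intensity


class TestContainers:
    def test_frames_must_be_3d(self):
        with pytest.raises(ValueError):
            CineSequence(np.zeros((4, 4)))

    def test_identity_fields_are_zero(self):
        f = DeformationSequence.identity(3, (8, 8))
        assert f.displacements.shape == (3, 8, 8, 2)
        assert not f.displacements.any()

    def test_region_mask_rejects_empty(self):
        with pytest.raises(ValueError):
            RegionMask(np.zeros((4, 4), dtype=bool))


class TestSequenceIO:
    @pytest.mark.parametrize("ext", ["npz", "h5"])
    def test_round_trip_bit_identical(self, tmp_path, rng, ext):
        seq = CineSequence(rng.random((10, 64, 64)), 1.5, "subj", "sl0")
        path = tmp_path / f"seq.{ext}"
        save_sequence(seq, path)
        loaded = load_sequence(path)
        assert np.array_equal(loaded.frames, seq.frames)
        assert loaded.pixel_spacing == seq.pixel_spacing
        assert loaded.subject_id == "subj"

    def test_nifti_load(self, tmp_path, rng):
        import nibabel as nib

        data = rng.random((16, 16, 5)).astype(np.float64)
        affine = np.diag([2.0, 2.0, 1.0, 1.0])
        nib.save(nib.Nifti1Image(data, affine), str(tmp_path / "seq.nii.gz"))
        seq = load_sequence(tmp_path / "seq.nii.gz")
        assert seq.frames.shape == (5, 16, 16)
        assert seq.pixel_spacing == pytest.approx(2.0)
        assert np.allclose(seq.frames[2], data[:, :, 2])

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(IOError):
            load_sequence(tmp_path / "absent.npz")

    def test_dicom_dir_with_mixed_shapes_rejected(self, tmp_path, rng):
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import (
            ExplicitVRLittleEndian,
            SecondaryCaptureImageStorage,
            generate_uid,
        )

        def write_dcm(path, arr, instance):
            meta = FileMetaDataset()
            meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
            meta.MediaStorageSOPInstanceUID = generate_uid()
            meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
            ds.SOPClassUID = SecondaryCaptureImageStorage
            ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
            ds.InstanceNumber = instance
            ds.Rows, ds.Columns = arr.shape
            ds.BitsAllocated = 16
            ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 0
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.PixelData = arr.astype(np.uint16).tobytes()
            ds.save_as(str(path), enforce_file_format=True)

        write_dcm(tmp_path / "a.dcm", rng.random((8, 8)) * 100, 1)
        write_dcm(tmp_path / "b.dcm", rng.random((12, 12)) * 100, 2)
        with pytest.raises(ValueError, match="unequal"):
            load_sequence(tmp_path, format="dicom_dir")


class TestFieldIO:
    @pytest.mark.parametrize("ext", ["npz", "h5"])
    def test_round_trip_bit_identical(self, tmp_path, rng, ext):
        fields = DeformationSequence(rng.normal(size=(4, 8, 8, 2)))
        path = tmp_path / f"fields.{ext}"
        save_fields(fields, path)
        loaded = load_fields(path)
        assert np.array_equal(loaded.displacements, fields.displacements)

    def test_zero_field_round_trip_is_identity(self, tmp_path):
        fields = DeformationSequence.identity(3, (8, 8))
        save_fields(fields, tmp_path / "z.npz")
        assert not load_fields(tmp_path / "z.npz").displacements.any()

    def test_shape_mismatch_with_paired_sequence(self, tmp_path, rng):
        fields = DeformationSequence(rng.normal(size=(4, 8, 8, 2)))
        save_fields(fields, tmp_path / "f.npz")
        other = CineSequence(rng.random((5, 8, 8)))
        with pytest.raises(ValueError, match="does not match"):
            load_fields(tmp_path / "f.npz", sequence=other)


class TestPreprocess:
    def test_resample_and_crop_to_target(self, rng):
        seq = CineSequence(rng.random((3, 160, 160)), pixel_spacing=2.0)
        out = preprocess(seq, target_spacing_mm=1.0, crop_size=320)
        assert out.frames.shape == (3, 320, 320)
        assert out.pixel_spacing == 1.0

    def test_constant_sequence_normalizes_to_zero(self):
        seq = CineSequence(np.full((3, 16, 16), 5.0))
        out = preprocess(seq, 1.0, 16)
        assert not out.frames.any()

    def test_conforming_input_unchanged(self, rng):
        frames = rng.random((4, 32, 32))
        frames = normalize_intensity(frames)
        seq = CineSequence(frames, pixel_spacing=1.0)
        out = preprocess(seq, 1.0, 32)
        assert np.allclose(out.frames, frames)

    def test_idempotent(self, rng):
        seq = CineSequence(rng.random((4, 48, 48)) * 7 + 3, pixel_spacing=1.0)
        once = preprocess(seq, 1.0, 32)
        twice = preprocess(once, 1.0, 32)
        assert np.allclose(once.frames, twice.frames)

    def test_affine_intensity_invariance(self, rng):
        frames = rng.random((4, 16, 16))
        a = preprocess(CineSequence(frames), 1.0, 16)
        b = preprocess(CineSequence(3.2 * frames + 1.7), 1.0, 16)
        assert np.allclose(a.frames, b.frames)

    def test_sequence_level_normalization(self, rng):
        out = preprocess(CineSequence(rng.random((5, 16, 16))), 1.0, 16)
        assert out.frames.min() == 0.0
        assert out.frames.max() == 1.0
        # per-frame extrema generally differ from 0/1 under joint scaling
        assert not all(np.isclose(f.max(), 1.0) for f in out.frames)

    def test_invalid_spacing_rejected(self, rng):
        with pytest.raises(ValueError):
            preprocess(CineSequence(rng.random((2, 8, 8))), -1.0, 16)
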
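"""Volume I/O: round trips, HU calibration, and the coordinate contract."""

import numpy as np
import pytest

from otolithct.volume_io import (
    CTVolume,
    index_to_world,
    inplane_spacing,
    read_volume,
    world_to_index,
    write_volume,
)


@pytest.fixture
def small_volume(rng=None):
    rng = np.random.default_rng(42)
    voxels = rng.integers(-1000, 1500, size=(8, 8, 8)).astype(np.int16)
    return CTVolume(voxels, spacing_mm=(0.5, 0.18, 0.18), origin_mm=(1.0, 2.0, 3.0))


class TestNifti:
    def test_round_trip_exact(self, small_volume, tmp_path):
        path = tmp_path / "vol.nii.gz"
        write_volume(small_volume, path)
        back = read_volume(path)
        np.testing.assert_array_equal(back.voxels, small_volume.voxels)
        assert back.spacing_mm == pytest.approx(small_volume.spacing_mm)
        assert back.origin_mm == pytest.approx(small_volume.origin_mm)

    def test_spacing_preserved_to_float_precision(self, tmp_path):
        vol = CTVolume(np.zeros((4, 4, 4), dtype=np.int16), (0.50, 0.18, 0.18))
        path = tmp_path / "vol.nii"
        write_volume(vol, path)
        back = read_volume(path)
        assert back.spacing_mm == pytest.approx((0.50, 0.18, 0.18), abs=1e-6)

    def test_single_slice_accepted(self, tmp_path):
        vol = CTVolume(np.full((1, 5, 6), 100, dtype=np.int16), (0.5, 0.18, 0.18))
        path = tmp_path / "thin.nii.gz"
        write_volume(vol, path)
        assert read_volume(path).shape == (1, 5, 6)

    def test_hu_clamped_on_read(self, tmp_path):
        vol = CTVolume(np.array([[[-3000.0, 5000.0, 0.0]]]), (0.5, 0.18, 0.18))
        path = tmp_path / "wild.nii"
        write_volume(vol, path)
        back = read_volume(path)
        assert back.voxels.min() == -1024
        assert back.voxels.max() == 3100

    def test_empty_shape_rejected(self):
        with pytest.raises(ValueError):
            CTVolume(np.zeros((0, 4, 4)), (0.5, 0.18, 0.18))

    def test_bad_spacing_rejected(self):
        with pytest.raises(ValueError):
            CTVolume(np.zeros((4, 4, 4)), (0.5, 0.0, 0.18))

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "absent.nii")


def _make_dicom_series(tmp_path, n_slices=4, fov_mm=96.0, matrix=8, modality="CT"):
    """Tiny synthetic DICOM series built in-memory at test time."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    pitch = fov_mm / matrix
    series_uid = generate_uid()
    rng = np.random.default_rng(0)
    for i in range(n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.Modality = modality
        ds.SeriesInstanceUID = series_uid
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, i * 0.5]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [pitch, pitch]
        ds.SliceThickness = 0.5
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.Rows = matrix
        ds.Columns = matrix
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        raw = rng.integers(0, 3000, size=(matrix, matrix)).astype(np.uint16)
        ds.PixelData = raw.tobytes()
        ds.save_as(tmp_path / f"slice{i:03d}.dcm", enforce_file_format=True)
    return tmp_path


class TestDicom:
    def test_series_geometry_from_printed_acquisition(self, tmp_path):
        """FOV 96 mm over a 512 matrix gives 0.1875 mm in-plane pitch."""
        d = _make_dicom_series(tmp_path, fov_mm=96.0, matrix=8)
        # pitch carried in PixelSpacing exactly as fov/matrix would give at 512
        vol = read_volume(d)
        assert vol.spacing_mm[1] == pytest.approx(12.0)  # 96/8 for the tiny grid
        assert inplane_spacing(96.0, 512) == pytest.approx(0.1875)
        assert vol.shape == (4, 8, 8)
        assert vol.spacing_mm[0] == pytest.approx(0.5)

    def test_rescale_applied_and_clamped(self, tmp_path):
        d = _make_dicom_series(tmp_path)
        vol = read_volume(d)
        # raw 0..3000 with slope 1, intercept -1024 -> HU in [-1024, 1976]
        assert vol.voxels.min() >= -1024
        assert vol.voxels.max() <= 1976

    def test_non_ct_modality_warns_but_reads(self, tmp_path):
        d = _make_dicom_series(tmp_path, modality="MR")
        with pytest.warns(UserWarning, match="not CT"):
            read_volume(d)

    def test_missing_rescale_is_hard_error_naming_file(self, tmp_path):
        import pydicom

        d = _make_dicom_series(tmp_path)
        victim = sorted(d.glob("*.dcm"))[1]
        ds = pydicom.dcmread(victim)
        del ds.RescaleSlope
        ds.save_as(victim, enforce_file_format=True)
        with pytest.raises(ValueError, match=victim.name):
            read_volume(d)


class TestCoordinates:
    def test_origin_voxel(self):
        vol = CTVolume(np.zeros((4, 4, 4)), (0.5, 0.18, 0.18))
        assert index_to_world(vol, (0, 0, 0)) == (0.0, 0.0, 0.0)

    def test_unit_index_maps_to_spacing(self):
        vol = CTVolume(np.zeros((4, 4, 4)), (0.18, 0.18, 0.5))
        assert index_to_world(vol, (1, 1, 1)) == pytest.approx((0.18, 0.18, 0.5))

    def test_world_round_trip_within_half_voxel(self):
        vol = CTVolume(np.zeros((10, 10, 10)), (0.5, 0.18, 0.18), origin_mm=(1, 1, 1))
        world = (2.3, 1.77, 2.05)
        idx = world_to_index(vol, world)
        back = index_to_world(vol, idx)
        for w, b, s in zip(world, back, vol.spacing_mm):
            assert abs(w - b) <= s / 2 + 1e-12

    def test_out_of_range_index_rejected(self):
        vol = CTVolume(np.zeros((4, 4, 4)), (0.5, 0.18, 0.18))
        with pytest.raises(IndexError):
            index_to_world(vol, (4, 0, 0))
        with pytest.raises(IndexError):
            world_to_index(vol, (-5.0, 0.0, 0.0))
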
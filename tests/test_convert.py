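import gzip

import numpy as np
import nibabel as nib
import pytest

from bru2bids import fixtures
from bru2bids.convert import (
    BYTE_ORDERS,
    WORD_TYPES,
    CorruptDataError,
    UnsupportedFormatError,
    build_affine,
    decode_2dseq,
    write_nifti,
)
from bru2bids.jcampdx import ParameterDict


def make_visu(**overrides):
    entries = {
        "VisuCoreDim": 3,
        "VisuCoreSize": [2, 2, 1],
        "VisuCoreExtent": [2.0, 2.0, 1.0],
        "VisuCoreFrameCount": 1,
        "VisuCoreWordType": "_16BIT_SGN_INT",
        "VisuCoreByteOrder": "littleEndian",
        "VisuCoreDataSlope": 1.0,
        "VisuCoreDataOffs": 0.0,
        "VisuCoreOrientation": [1, 0, 0, 0, 1, 0, 0, 0, 1],
        "VisuCorePosition": [0.0, 0.0, 0.0],
        "VisuAcqRepetitionTime": 1000.0,
    }
    entries.update(overrides)
    return ParameterDict(entries=entries)


RAW_2X2 = np.array([0, 1, 2, 3], dtype="<i2").tobytes()


class TestDecode:
    def test_identity_scaling(self):
        image = decode_2dseq(RAW_2X2, make_visu())
        # x-fastest: stream [0,1,2,3] -> voxels[x,y] = [[0,2],[1,3]]
        assert image.voxels.shape == (2, 2, 1)
        np.testing.assert_array_equal(image.voxels[:, :, 0], [[0, 2], [1, 3]])
        assert image.value_slope == 1.0 and image.value_offset == 0.0

    def test_linear_scaling(self):
        image = decode_2dseq(RAW_2X2, make_visu(VisuCoreDataSlope=2.5))
        np.testing.assert_array_equal(
            np.sort(image.voxels.ravel()), [0.0, 2.5, 5.0, 7.5]
        )

    def test_scaling_linearity_property(self):
        rng = np.random.default_rng(0)
        raw = rng.integers(-100, 100, size=8, dtype=np.int16)
        visu_plain = make_visu(VisuCoreSize=[2, 2, 2], VisuCoreExtent=[2.0, 2.0, 2.0])
        visu_scaled = make_visu(
            VisuCoreSize=[2, 2, 2],
            VisuCoreExtent=[2.0, 2.0, 2.0],
            VisuCoreDataSlope=3.25,
            VisuCoreDataOffs=-7.5,
        )
        plain = decode_2dseq(raw.tobytes(), visu_plain).voxels
        scaled = decode_2dseq(raw.tobytes(), visu_scaled).voxels
        np.testing.assert_allclose(
            scaled, 3.25 * plain - 7.5, rtol=np.finfo(np.float32).eps
        )

    @pytest.mark.parametrize("word_type", sorted(WORD_TYPES))
    @pytest.mark.parametrize("byte_order", sorted(BYTE_ORDERS))
    def test_encode_decode_roundtrip(self, word_type, byte_order):
        spec = fixtures.ScanSpec(
            scan_number=1,
            instruction_name="bold",
            matrix=(8, 8, 4),
            frames=10,
            word_type=word_type,
            byte_order=byte_order,
        )
        array = fixtures.scan_array(spec, seed=3)
        image = decode_2dseq(fixtures.encode_2dseq(array, spec), make_visu(
            VisuCoreSize=[8, 8, 4],
            VisuCoreExtent=[8.0, 8.0, 4.0],
            VisuCoreFrameCount=10,
            VisuCoreWordType=word_type,
            VisuCoreByteOrder=byte_order,
        ))
        assert image.voxels.shape == (8, 8, 4, 10)
        np.testing.assert_array_equal(image.raw, array)
        np.testing.assert_array_equal(image.voxels, array.astype(np.float64))

    def test_encode_decode_encode_byte_stable(self):
        spec = fixtures.ScanSpec(scan_number=1, instruction_name="bold", frames=3)
        array = fixtures.scan_array(spec, seed=5)
        payload = fixtures.encode_2dseq(array, spec)
        image = decode_2dseq(payload, make_visu(
            VisuCoreSize=[8, 8, 4],
            VisuCoreExtent=[8.0, 8.0, 4.0],
            VisuCoreFrameCount=3,
        ))
        assert fixtures.encode_2dseq(image.raw, spec) == payload

    def test_per_frame_scaling(self):
        raw = np.arange(8, dtype="<i2")
        visu = make_visu(
            VisuCoreSize=[2, 2, 1],
            VisuCoreFrameCount=2,
            VisuCoreDataSlope=[1.0, 10.0],
            VisuCoreDataOffs=[0.0, 5.0],
        )
        image = decode_2dseq(raw.tobytes(), visu)
        assert image.value_slope is None  # non-uniform: baked in
        np.testing.assert_array_equal(
            np.sort(image.voxels[..., 0].ravel()), [0, 1, 2, 3]
        )
        np.testing.assert_array_equal(
            np.sort(image.voxels[..., 1].ravel()), [45, 55, 65, 75]
        )

    def test_repetition_time_for_4d(self):
        spec = fixtures.ScanSpec(scan_number=1, instruction_name="bold", frames=2)
        payload = fixtures.encode_2dseq(fixtures.scan_array(spec, 0), spec)
        image = decode_2dseq(payload, make_visu(
            VisuCoreSize=[8, 8, 4],
            VisuCoreExtent=[8.0, 8.0, 4.0],
            VisuCoreFrameCount=2,
            VisuAcqRepetitionTime=1500.0,
        ))
        assert image.repetition_time == pytest.approx(1.5)

    def test_2d_frames_become_slices(self):
        raw = np.arange(12, dtype="<i2")
        visu = make_visu(
            VisuCoreDim=2,
            VisuCoreSize=[2, 2],
            VisuCoreExtent=[2.0, 2.0],
            VisuCoreFrameCount=3,
        )
        image = decode_2dseq(raw.tobytes(), visu)
        assert image.voxels.shape == (2, 2, 3)

    def test_byte_count_mismatch(self):
        with pytest.raises(CorruptDataError, match="expected 8 bytes"):
            decode_2dseq(RAW_2X2[:-2], make_visu())

    def test_unknown_word_type(self):
        with pytest.raises(UnsupportedFormatError, match="word type"):
            decode_2dseq(RAW_2X2, make_visu(VisuCoreWordType="_64BIT_MAGIC"))


class TestBuildAffine:
    def test_unit_voxels_identity(self):
        visu = make_visu(
            VisuCoreSize=[16, 16, 8], VisuCoreExtent=[16.0, 16.0, 8.0]
        )
        np.testing.assert_array_equal(build_affine(visu), np.eye(4))

    def test_voxel_sizes_from_extent(self):
        visu = make_visu(
            VisuCoreSize=[16, 16, 8], VisuCoreExtent=[32.0, 32.0, 8.0]
        )
        affine = build_affine(visu)
        np.testing.assert_allclose(np.diag(affine)[:3], [2.0, 2.0, 1.0])

    def test_rotated_corners_match_generator_ground_truth(self):
        # 90 degree rotation about z
        spec = fixtures.ScanSpec(
            scan_number=1,
            instruction_name="T2w",
            matrix=(8, 8, 4),
            extent=(16.0, 16.0, 8.0),
            orientation=(0, 1, 0, -1, 0, 0, 0, 0, 1),
            position=(3.0, -2.0, 1.0),
        )
        visu = make_visu(
            VisuCoreSize=list(spec.matrix),
            VisuCoreExtent=list(spec.extent),
            VisuCoreOrientation=list(spec.orientation),
            VisuCorePosition=list(spec.position),
        )
        affine = build_affine(visu)
        expected = fixtures.corner_world_coordinates(spec)
        corners = [
            (i, j, k)
            for i in (0, spec.matrix[0] - 1)
            for j in (0, spec.matrix[1] - 1)
            for k in (0, spec.matrix[2] - 1)
        ]
        got = np.array([(affine @ [*c, 1])[:3] for c in corners])
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_missing_geometry_falls_back_to_diagonal(self, caplog):
        visu = ParameterDict(
            entries={"VisuCoreSize": [4, 4, 2], "VisuCoreExtent": [8.0, 8.0, 2.0]}
        )
        with caplog.at_level("WARNING"):
            affine = build_affine(visu)
        np.testing.assert_allclose(affine, np.diag([2.0, 2.0, 1.0, 1.0]))

    def test_degenerate_orientation_rejected(self):
        visu = make_visu(VisuCoreOrientation=[0.0] * 9)
        with pytest.raises(UnsupportedFormatError, match="degenerate"):
            build_affine(visu)


class TestWriteNifti:
    def _image(self, frames=2, tr=1.5):
        spec = fixtures.ScanSpec(
            scan_number=1,
            instruction_name="bold",
            frames=frames,
            repetition_time=tr,
            slope=2.0,
            offset=1.0,
        )
        payload = fixtures.encode_2dseq(fixtures.scan_array(spec, 0), spec)
        return decode_2dseq(payload, make_visu(
            VisuCoreSize=[8, 8, 4],
            VisuCoreExtent=[8.0, 8.0, 4.0],
            VisuCoreFrameCount=frames,
            VisuCoreDataSlope=2.0,
            VisuCoreDataOffs=1.0,
            VisuAcqRepetitionTime=tr * 1000.0,
        ))

    def test_4d_header_repetition_time(self, tmp_path):
        path = write_nifti(self._image(), tmp_path / "f.nii.gz")
        img = nib.load(path)
        assert img.header.get_zooms()[3] == pytest.approx(1.5)

    def test_3d_dim_count(self, tmp_path):
        path = write_nifti(self._image(frames=1), tmp_path / "a.nii.gz")
        assert nib.load(path).ndim == 3

    def test_readback_equality(self, tmp_path):
        image = self._image()
        path = write_nifti(image, tmp_path / "f.nii.gz")
        data = np.asanyarray(nib.load(path).dataobj)
        np.testing.assert_allclose(data, image.voxels.astype(np.float32))

    def test_keep_int_preserves_raw_and_scl(self, tmp_path):
        image = self._image()
        path = write_nifti(image, tmp_path / "f.nii.gz", keep_int=True)
        img = nib.load(path)
        assert img.get_data_dtype() == np.int16
        # nibabel folds scl into the data proxy on load, so check the
        # on-disk header fields directly
        with gzip.open(path, "rb") as handle:
            hdr = nib.Nifti1Header.from_fileobj(handle)
        assert float(hdr["scl_slope"]) == 2.0
        assert float(hdr["scl_inter"]) == 1.0
        # nibabel applies scl on load: scaled data equals decoded voxels
        np.testing.assert_allclose(img.get_fdata(), image.voxels)

    def test_byte_identical_rewrites(self, tmp_path):
        image = self._image()
        a = write_nifti(image, tmp_path / "a.nii.gz")
        b = write_nifti(image, tmp_path / "b.nii.gz")
        assert a.read_bytes() == b.read_bytes()

    def test_canonical_flag_reorients(self, tmp_path):
        image = self._image(frames=1)
        image.affine[:3, :3] = np.diag([-1.0, 1.0, 1.0])
        path = write_nifti(image, tmp_path / "c.nii.gz", canonical=True)
        img = nib.load(path)
        assert nib.aff2axcodes(img.affine) == ("R", "A", "S")
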
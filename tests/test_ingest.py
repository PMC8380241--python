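import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mnflow.ingest import (
    GatingConfig,
    compute_gating_features,
    crop_pad,
    gate_single_cells,
    normalize_channel,
    read_dataset,
    write_dataset,
)
from mnflow.ingest.io import DatasetFormatError
from mnflow.ingest.records import CellRecord, GatingFeatures
from mnflow.synthimg import PopulationSpec, sample_population
from tests.conftest import make_record


def _disc_image(radius=10.0, ry=None, size=64):
    """Brightfield-style frame: bright background, darker disc."""
    yy, xx = np.mgrid[0:size, 0:size] - (size - 1) / 2.0
    ry = ry or radius
    inside = (xx / radius) ** 2 + (yy / ry) ** 2 <= 1.0
    bf = np.full((size, size), 50000, dtype=np.uint16)
    bf[inside] = 20000
    img = np.zeros((size, size, 2), dtype=np.uint16)
    img[:, :, 1] = bf
    return img


class TestGatingFeatures:
    def test_disc_area_matches_analytic(self):
        # radius 10 px at 0.33 um/px: pi * 10^2 * 0.33^2 = 34.2 um^2
        feats = compute_gating_features(_disc_image(10.0), pixel_size=0.33)
        analytic = np.pi * 10**2 * 0.33**2
        # +/- 1 px-wide ring of discretisation slack
        slack = 2 * np.pi * 10 * 0.33**2
        assert abs(feats.brightfield_area - analytic) <= slack

    def test_circle_aspect_ratio_one(self):
        feats = compute_gating_features(_disc_image(14.0))
        assert feats.aspect_ratio == pytest.approx(1.0, abs=0.02)

    def test_two_to_one_ellipse_aspect_half(self):
        feats = compute_gating_features(_disc_image(radius=20.0, ry=10.0))
        assert feats.aspect_ratio == pytest.approx(0.5, abs=0.03)

    def test_empty_mask_raises(self):
        img = np.full((64, 64, 2), 30000, dtype=np.uint16)
        with pytest.raises(ValueError, match="no object"):
            compute_gating_features(img)


class TestGates:
    def test_quoted_gate_example_kept(self):
        kept, rejected = gate_single_cells([make_record(300, 0.9, 60)])
        assert len(kept) == 1 and not rejected

    def test_below_area_gate_rejected(self):
        kept, rejected = gate_single_cells([make_record(150, 0.9, 60)])
        assert not kept and len(rejected) == 1

    def test_inclusive_boundaries(self):
        kept, _ = gate_single_cells([make_record(200, 0.75, 55)])
        assert len(kept) == 1
        kept, _ = gate_single_cells([make_record(500, 1.0, 80)])
        assert len(kept) == 1

    def test_partition_contract(self):
        recs = [make_record(a, r, g) for a in (150, 300, 600)
                for r in (0.7, 0.9) for g in (50, 60, 90)]
        kept, rejected = gate_single_cells(recs)
        assert len(kept) + len(rejected) == len(recs)
        ids = {id(r) for r in kept} | {id(r) for r in rejected}
        assert len(ids) == len(recs)

    def test_idempotent_and_order_independent(self):
        recs = [make_record(np.random.uniform(100, 700),
                            np.random.uniform(0.5, 1.0),
                            np.random.uniform(40, 100)) for _ in range(50)]
        kept, _ = gate_single_cells(recs)
        kept2, rej2 = gate_single_cells(kept)
        assert kept2 == kept and not rej2
        kept_rev, _ = gate_single_cells(recs[::-1])
        assert {id(r) for r in kept_rev} == {id(r) for r in kept}

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(5)
        recs = [make_record(rng.uniform(50, 900), rng.uniform(0.4, 1.0),
                            rng.uniform(20, 120)) for _ in range(500)]
        kept, _ = gate_single_cells(recs)
        brute = [
            r for r in recs
            if 200 <= r.features.brightfield_area <= 500
            and 0.75 <= r.features.aspect_ratio <= 1.0
            and 55 <= r.features.gradient_rms <= 80
        ]
        assert [id(r) for r in kept] == [id(r) for r in brute]

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            GatingConfig(area_range=(500.0, 200.0))

    def test_missing_features_raise(self):
        rec = make_record()
        rec.features = None
        with pytest.raises(ValueError, match="features"):
            gate_single_cells([rec])


class TestNormalizeChannel:
    def test_linear_map_endpoints_and_half_range(self):
        out = normalize_channel(np.array([[100, 200, 300]]))
        assert out.tolist() == [[0, 32768, 65535]]

    def test_idempotent_up_to_quantisation(self):
        img = np.array([[0, 1000, 65535]], dtype=np.uint16)
        assert np.array_equal(normalize_channel(img), img)

    def test_constant_image_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_channel(np.full((4, 4), 123))
        assert not out.any()

    @given(st.lists(st.integers(0, 65535), min_size=2, max_size=64).filter(
        lambda v: len(set(v)) > 1))
    @settings(max_examples=50, deadline=None)
    def test_preserves_rank_order(self, values):
        arr = np.array(values)
        out = normalize_channel(arr).astype(np.int64)
        for i in range(len(values)):
            for j in range(len(values)):
                if arr[i] < arr[j]:
                    assert out[i] <= out[j]
                if arr[i] == arr[j]:
                    assert out[i] == out[j]


class TestCropPad:
    def test_pad_50x60_centred(self):
        out = crop_pad(np.ones((50, 60)), 64)
        assert out.shape == (64, 64)
        assert not out[:7].any() and not out[-7:].any()
        assert not out[:, :2].any() and not out[:, -2:].any()
        assert out[7:57, 2:62].all()

    def test_identity_64x64(self):
        img = np.arange(64 * 64).reshape(64, 64)
        assert np.array_equal(crop_pad(img, 64), img)

    def test_crop_80x70_matches_slice_oracle(self):
        img = np.arange(80 * 70).reshape(80, 70)
        out = crop_pad(img, 64)
        oracle = img[(80 - 64) // 2:(80 - 64) // 2 + 64,
                     (70 - 64) // 2:(70 - 64) // 2 + 64]
        assert np.array_equal(out, oracle)

    @given(st.integers(1, 100), st.integers(1, 100))
    @settings(max_examples=40, deadline=None)
    def test_always_64x64(self, h, w):
        out = crop_pad(np.ones((h, w)), 64)
        assert out.shape == (64, 64)


class TestDatasetRoundTrip:
    def test_write_read_bit_identical(self, tmp_path):
        pop = PopulationSpec(n_cells=20, seed=77)
        records = sample_population(pop)
        manifest = write_dataset(records, tmp_path / "ds")
        back = read_dataset(manifest)
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert np.array_equal(a.image, b.image)
            assert a.label == b.label
            assert a.features.brightfield_area == pytest.approx(
                b.features.brightfield_area)

    def test_single_page_tiff_rejected(self, tmp_path):
        import tifffile

        d = tmp_path / "ds"
        d.mkdir()
        tifffile.imwrite(d / "cell_0.tif", np.zeros((64, 64), dtype=np.uint16))
        pd.DataFrame([{
            "file": "cell_0.tif", "label": "binucleate", "lab": "x",
            "compound": "", "concentration": 0.0, "replicate": 0,
            "area_um2": 300.0, "aspect_ratio": 0.9, "gradient_rms": 60.0,
        }]).to_csv(d / "manifest.csv", index=False)
        with pytest.raises(DatasetFormatError, match="2-page"):
            read_dataset(d / "manifest.csv")

    def test_unknown_label_names_offending_row(self, tmp_path):
        import tifffile

        d = tmp_path / "ds"
        d.mkdir()
        tifffile.imwrite(d / "c.tif", np.zeros((2, 64, 64), dtype=np.uint16))
        pd.DataFrame([{
            "file": "c.tif", "label": "pentanucleate", "lab": "x",
            "compound": "", "concentration": 0.0, "replicate": 0,
            "area_um2": 300.0, "aspect_ratio": 0.9, "gradient_rms": 60.0,
        }]).to_csv(d / "manifest.csv", index=False)
        with pytest.raises(DatasetFormatError, match="row 0"):
            read_dataset(d / "manifest.csv")

    def test_missing_file_rejected(self, tmp_path):
        d = tmp_path / "ds"
        d.mkdir()
        pd.DataFrame([{
            "file": "ghost.tif", "label": "binucleate", "lab": "x",
            "compound": "", "concentration": 0.0, "replicate": 0,
            "area_um2": 300.0, "aspect_ratio": 0.9, "gradient_rms": 60.0,
        }]).to_csv(d / "manifest.csv", index=False)
        with pytest.raises(DatasetFormatError, match="not found"):
            read_dataset(d / "manifest.csv")
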
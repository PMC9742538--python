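import numpy as np
import pytest

from biofilmoct import (
    BACKGROUND,
    BIOFILM,
    NOT_FOUND,
    SURFACE,
    LabelVolume,
    SegmentationParams,
    SurfaceModel,
    compute_thresholds,
    detect_surface,
    median_filter_bscan,
    remove_subsurface,
    segment_classes,
)
from conftest import brute_force_median


class TestMedianFilter:
    def test_constant_image_unchanged(self):
        img = np.full((5, 5), 7.0)
        np.testing.assert_array_equal(median_filter_bscan(img, 3), img)

    def test_isolated_bright_pixel_suppressed(self):
        img = np.zeros((3, 3))
        img[1, 1] = 100.0
        out = median_filter_bscan(img, 3)
        assert out[1, 1] == 0.0  # median of {100, 0×8}

    @pytest.mark.parametrize("kernel", [1, 3, 5])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, kernel, seed):
        rng = np.random.default_rng(seed)
        shape = rng.integers(4, 17, size=2)
        img = rng.random(tuple(shape))
        np.testing.assert_allclose(
            median_filter_bscan(img, kernel), brute_force_median(img, kernel)
        )

    def test_kernel_1_is_identity(self):
        img = np.random.default_rng(0).random((9, 9))
        np.testing.assert_array_equal(median_filter_bscan(img, 1), img)

    @pytest.mark.parametrize("kernel", [0, 2, 4, -1])
    def test_even_or_nonpositive_kernel_rejected(self, kernel):
        with pytest.raises(ValueError):
            median_filter_bscan(np.ones((3, 3)), kernel)


class TestSegmentClasses:
    @pytest.mark.parametrize("value,expected", [
        (0.05, BACKGROUND),
        (0.4, BIOFILM),
        (0.9, SURFACE),
        (0.2, BIOFILM),   # boundary: t_low inclusive for biofilm
        (0.7, SURFACE),   # boundary: t_high inclusive for surface
    ])
    def test_fixed_threshold_classes(self, value, expected):
        params = SegmentationParams(auto_threshold=False, t_low=0.2, t_high=0.7)
        labels = segment_classes(np.array([[value]]), params)
        assert labels[0, 0] == expected

    def test_monotone_in_t_low(self):
        """Raising t_low never increases the biofilm+surface count."""
        rng = np.random.default_rng(4)
        img = rng.random((32, 32))
        counts = []
        for t_low in (0.1, 0.3, 0.5, 0.65):
            params = SegmentationParams(auto_threshold=False, t_low=t_low, t_high=0.7)
            labels = segment_classes(img, params)
            counts.append(int(np.sum(labels != BACKGROUND)))
        assert counts == sorted(counts, reverse=True)

    def test_out_of_range_intensities_rejected(self):
        params = SegmentationParams(auto_threshold=False, t_low=0.2, t_high=0.7)
        with pytest.raises(ValueError, match="normalised"):
            segment_classes(np.array([[1.5]]), params)

    def test_auto_threshold_separates_three_well_separated_modes(self):
        rng = np.random.default_rng(5)
        img = np.concatenate([
            rng.normal(0.1, 0.01, 400), rng.normal(0.5, 0.01, 400),
            rng.normal(0.9, 0.01, 400),
        ]).clip(0, 1).reshape(40, 30)
        labels = segment_classes(img, SegmentationParams())
        # each mode lands in its own class (Otsu may clip a tail pixel or two)
        flat = labels.ravel()
        assert np.mean(flat[:400] == BACKGROUND) >= 0.99
        assert np.mean(flat[400:800] == BIOFILM) >= 0.99
        assert np.mean(flat[800:] == SURFACE) >= 0.99

    def test_constant_image_rejected_for_auto(self):
        with pytest.raises(ValueError, match="constant|blank"):
            compute_thresholds(np.full((8, 8), 0.5))

    def test_two_valued_blank_scene_has_empty_biofilm_class(self):
        img = np.full((16, 16), 0.05)
        img[10:13] = 0.9
        with pytest.warns(UserWarning, match="blank"):
            t_low, t_high = compute_thresholds(img)
        labels = segment_classes(img, SegmentationParams(), thresholds=(t_low, t_high))
        assert np.sum(labels == BIOFILM) == 0
        assert np.sum(labels == SURFACE) == 16 * 3


def _labels_from_column(column, n_axial=60):
    """Build a 1-B-scan LabelVolume with a single lateral column."""
    lab = np.full((1, n_axial, 1), BACKGROUND, dtype=np.int8)
    for row, value in column.items():
        lab[0, row, 0] = value
    return LabelVolume(labels=lab)


class TestDetectSurface:
    def test_single_run_top_row(self):
        lab = _labels_from_column({r: SURFACE for r in range(40, 46)})
        surf = detect_surface(lab, SegmentationParams())
        assert surf.surface_row[0, 0] == 40
        assert surf.surface_bottom[0, 0] == 45

    def test_no_surface_gives_not_found(self):
        lab = _labels_from_column({10: BIOFILM, 11: BIOFILM})
        surf = detect_surface(lab, SegmentationParams())
        assert surf.surface_row[0, 0] == NOT_FOUND
        assert not surf.found[0, 0]

    def test_longest_run_wins(self):
        runs = {r: SURFACE for r in list(range(10, 12)) + list(range(40, 47))}
        lab = _labels_from_column(runs)
        surf = detect_surface(lab, SegmentationParams(min_surface_run=2))
        assert surf.surface_row[0, 0] == 40

    def test_tie_goes_to_deeper_run(self):
        runs = {r: SURFACE for r in list(range(10, 13)) + list(range(40, 43))}
        lab = _labels_from_column(runs)
        surf = detect_surface(lab, SegmentationParams(min_surface_run=2))
        assert surf.surface_row[0, 0] == 40

    def test_runs_shorter_than_min_run_ignored(self):
        lab = _labels_from_column({20: SURFACE})
        surf = detect_surface(lab, SegmentationParams(min_surface_run=2))
        assert surf.surface_row[0, 0] == NOT_FOUND


class TestRemoveSubsurface:
    def _scene(self):
        """Surface run rows 40–46, biofilm above (30–39) and a stray blob below (60–62)."""
        column = {r: SURFACE for r in range(40, 47)}
        column.update({r: BIOFILM for r in range(30, 40)})
        column.update({r: BIOFILM for r in range(60, 63)})
        return _labels_from_column(column, n_axial=80)

    def test_biofilm_below_run_bottom_removed(self):
        lab = self._scene()
        surf = detect_surface(lab, SegmentationParams())
        cleaned = remove_subsurface(lab, surf)
        assert np.all(cleaned.labels[0, 60:63, 0] == BACKGROUND)

    def test_biofilm_above_surface_kept(self):
        lab = self._scene()
        surf = detect_surface(lab, SegmentationParams())
        cleaned = remove_subsurface(lab, surf)
        assert np.all(cleaned.labels[0, 30:40, 0] == BIOFILM)

    def test_not_found_column_loses_all_biofilm(self):
        lab = _labels_from_column({r: BIOFILM for r in range(20, 25)})
        surf = detect_surface(lab, SegmentationParams())
        cleaned = remove_subsurface(lab, surf)
        assert np.sum(cleaned.labels == BIOFILM) == 0

    def test_partition_conserved_and_surface_untouched(self):
        rng = np.random.default_rng(6)
        lab = LabelVolume(labels=rng.integers(0, 3, size=(3, 40, 8)).astype(np.int8))
        surf = detect_surface(lab, SegmentationParams(min_surface_run=1))
        before = lab.class_counts()
        cleaned = remove_subsurface(lab, surf)
        after = cleaned.class_counts()
        assert sum(after.values()) == sum(before.values()) == 3 * 40 * 8
        assert after[SURFACE] == before[SURFACE]
        assert after[BIOFILM] <= before[BIOFILM]

    def test_shape_mismatch_rejected(self):
        lab = self._scene()
        surf = SurfaceModel(surface_row=np.full((2, 2), NOT_FOUND),
                            surface_bottom=np.full((2, 2), NOT_FOUND))
        with pytest.raises(ValueError, match="shape"):
            remove_subsurface(lab, surf)


class TestParamsContract:
    @pytest.mark.parametrize("kwargs", [
        {"median_kernel": 2},
        {"median_kernel": -3},
        {"min_surface_run": 0},
        {"auto_threshold": False, "t_low": 0.7, "t_high": 0.2},
        {"auto_threshold": False, "t_low": 0.0, "t_high": 0.5},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SegmentationParams(**kwargs)

    def test_yaml_roundtrip(self, tmp_path):
        import yaml
        cfg = {"median_kernel": 5, "auto_threshold": False,
               "t_low": 0.15, "t_high": 0.6, "min_surface_run": 3}
        path = tmp_path / "params.yaml"
        path.write_text(yaml.safe_dump(cfg))
        params = SegmentationParams.from_yaml(path)
        assert params.to_dict() == cfg
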
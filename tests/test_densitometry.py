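"""Background, bleed-through, segmentation and measurement contracts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import quadfluor as qf
from quadfluor import densitometry
from quadfluor.channels import MARKERS
from quadfluor.errors import ValidationError
from quadfluor.imgio import CellROI
from quadfluor.synth import RenderParams, TrueCellState


def flat_image(value=0, shape=(64, 64), **channel_values):
    pixels = np.full((*shape, 4), value, dtype=np.uint16)
    for marker, v in channel_values.items():
        pixels[:, :, MARKERS.index(marker)] = v
    return qf.SectionImage(pixels=pixels, subject_id="s", group_label="control",
                           run_id=1, section_id=1)


def make_cell(cell_id=1, radius=10.0, **expected):
    values = {"TH": 12000.0, "CI20": 0.0, "CIV1": 0.0, "porin": 0.0}
    values.update(expected)
    return TrueCellState(cell_id=cell_id, radius=radius, expected=values,
                         deficient_ci=False, deficient_civ=False)


QUIET = RenderParams(image_shape=(256, 256)).quiet()


class TestBackground:
    def test_constant_region_zero_variance(self):
        image = flat_image(10)
        bg = qf.estimate_background(image, (0, 0, 32, 32), k=2)
        assert bg.mean == pytest.approx([10] * 4)
        assert bg.sd == pytest.approx([0] * 4)
        assert bg.threshold == pytest.approx([10] * 4)

    def test_hand_computed_sample_sd(self):
        # region {8, 10, 12}: mean 10, sample SD 2, threshold 14 at k=2
        image = flat_image(0)
        px = image.pixels
        px[0, 0] = 8
        px[0, 1] = 10
        px[0, 2] = 12
        mask = np.zeros(image.shape, dtype=bool)
        mask[0, :3] = True
        bg = qf.estimate_background(image, mask, k=2, min_pixels=3)
        assert bg.mean == pytest.approx([10] * 4)
        assert bg.sd == pytest.approx([2] * 4)
        assert bg.threshold == pytest.approx([14] * 4)

    def test_region_overlapping_roi_errors(self):
        image = flat_image(5)
        roi = CellROI(1, np.arange(10), np.arange(10))
        with pytest.raises(ValidationError, match="overlaps"):
            qf.estimate_background(image, (0, 0, 32, 32), rois=[roi])

    def test_empty_and_small_regions_error(self):
        image = flat_image(5)
        with pytest.raises(ValidationError):
            qf.estimate_background(image, np.zeros(image.shape, dtype=bool))
        with pytest.raises(ValidationError):
            qf.estimate_background(image, (0, 0, 5, 5), min_pixels=100)


def render_single_label_controls(alpha=None):
    """One control section per marker, each expressing only that marker."""
    controls, backgrounds = {}, {}
    for marker in MARKERS:
        cells = []
        for i in range(5):
            expected = {m: 0.0 for m in MARKERS}
            expected[marker] = 6000.0
            cells.append(TrueCellState(cell_id=i + 1, radius=10.0, expected=expected,
                                       deficient_ci=False, deficient_civ=False))
        image, gt = qf.render_section(cells, QUIET, crosstalk=alpha, seed=1)
        controls[marker] = image
        backgrounds[marker] = densitometry.BackgroundModel(
            individual_id="ctrl", mean=np.zeros(4), sd=np.zeros(4), k=2
        )
    return controls, backgrounds


class TestCrosstalk:
    def test_clean_controls_give_identity(self):
        controls, backgrounds = render_single_label_controls()
        xt = qf.estimate_crosstalk(controls, backgrounds)
        assert np.array_equal(xt.matrix, np.eye(4))

    def test_known_mixing_recovered_exactly(self):
        A = np.eye(4)
        A[2, 1] = 0.05  # CIV <- CI
        controls, backgrounds = render_single_label_controls(alpha=A)
        xt = qf.estimate_crosstalk(controls, backgrounds)
        assert xt.matrix[2, 1] == pytest.approx(0.05, abs=1e-12)
        off = xt.matrix[~np.eye(4, dtype=bool)]
        assert np.count_nonzero(off) == 1

    def test_control_without_own_signal_errors(self):
        controls, backgrounds = render_single_label_controls()
        controls["CI20"] = flat_image(0, shape=(256, 256))
        with pytest.raises(ValidationError, match="CI20"):
            qf.estimate_crosstalk(controls, backgrounds)

    def test_singular_matrix_rejected(self):
        A = np.eye(4)
        A[0, 1] = A[1, 0] = 0.999999
        A[0, 0] = A[1, 1] = 1.0
        A[1] = A[0]  # two identical rows -> singular
        with pytest.raises(ValidationError):
            densitometry.CrosstalkMatrix(A)

    def test_identity_unmixing_is_noop(self):
        image = flat_image(123)
        bg = densitometry.BackgroundModel("s", np.zeros(4), np.zeros(4))
        out = qf.correct_crosstalk(image, densitometry.CrosstalkMatrix.identity(), bg)
        assert np.array_equal(out.pixels, image.pixels)

    def test_unmixing_recovers_generator_truth(self):
        A = np.eye(4)
        A[2, 1] = 0.08
        A[1, 2] = 0.04
        cells = [make_cell(cell_id=i + 1, CI20=5000.0, CIV1=3000.0) for i in range(6)]
        mixed, gt = qf.render_section(cells, QUIET, crosstalk=A, seed=2)
        bg = densitometry.BackgroundModel("s", np.zeros(4), np.zeros(4))
        unmixed = qf.correct_crosstalk(mixed, densitometry.CrosstalkMatrix(A), bg)
        for cell_id in gt.cells.cell_id:
            mask = gt.label_mask == cell_id
            means = unmixed.pixels[mask].astype(float).mean(axis=0)
            assert means[1] == pytest.approx(5000.0, rel=1e-3)
            assert means[2] == pytest.approx(3000.0, rel=1e-3)


class TestSegmentation:
    def _planted_section(self, n=60, seed=19):
        profile = qf.make_default_profiles()[0]
        pop = qf.generate_cell_population(profile, n, seed=seed)
        return qf.render_section(pop, RenderParams(), seed=seed + 1)

    def test_recall_and_fdr_on_planted_cells(self):
        image, gt = self._planted_section()
        bg = qf.estimate_background(image, gt.background_region, k=2)
        rois = qf.segment_cells(image, bg)
        n_true = int(gt.cells.cell_id.size)
        matched_truth = set()
        n_good_rois = 0
        for roi in rois:
            labels, counts = np.unique(gt.label_mask[roi.rows, roi.cols], return_counts=True)
            best = labels[np.argmax(np.where(labels > 0, counts, 0))]
            if best == 0:
                continue
            inter = gt.label_mask[roi.rows, roi.cols] == best
            union = roi.area + int((gt.label_mask == best).sum()) - int(inter.sum())
            if inter.sum() / union >= 0.7:
                matched_truth.add(int(best))
                n_good_rois += 1
        assert len(matched_truth) / n_true >= 0.95
        assert (len(rois) - n_good_rois) / max(len(rois), 1) <= 0.05

    def test_blank_image_yields_no_rois(self):
        image = flat_image(300, shape=(256, 256))
        bg = densitometry.BackgroundModel("s", np.full(4, 300.0), np.full(4, 30.0))
        assert qf.segment_cells(image, bg) == []

    def test_small_components_filtered(self):
        image, gt = qf.render_section([make_cell(radius=4.0)], QUIET, seed=3)
        bg = densitometry.BackgroundModel("s", np.zeros(4), np.full(4, 1.0))
        assert qf.segment_cells(image, bg, min_area=100) == []
        assert len(qf.segment_cells(image, bg, min_area=10)) == 1

    def test_rois_sorted_by_centroid(self):
        image, _ = self._planted_section(n=25, seed=5)
        bg = densitometry.BackgroundModel("s", np.full(4, 300.0), np.full(4, 35.0))
        rois = qf.segment_cells(image, bg)
        centroids = [r.centroid for r in rois]
        assert centroids == sorted(centroids)


class TestMeasurement:
    def test_uniform_roi_background_subtraction(self):
        image = flat_image(50)
        bg = densitometry.BackgroundModel("s", np.full(4, 10.0), np.zeros(4))
        roi = CellROI(1, np.repeat(np.arange(10, 20), 10), np.tile(np.arange(10, 20), 10))
        meas = qf.measure_cells(image, [roi], bg)
        assert meas.loc[0, "raw_porin"] == 50
        assert meas.loc[0, "corr_porin"] == 40

    def test_half_and_half_roi_mean(self):
        image = flat_image(0)
        image.pixels[5, 0:10, :] = 100
        rows = np.repeat(5, 20)
        cols = np.arange(20)
        bg = densitometry.BackgroundModel("s", np.zeros(4), np.zeros(4))
        meas = qf.measure_cells(image, [CellROI(1, rows, cols)], bg)
        assert meas.loc[0, "raw_th"] == 50

    @given(st.integers(0, 500))
    def test_equals_brute_force_pixel_loop(self, seed):
        rng = np.random.default_rng(seed)
        pixels = rng.integers(0, 2**16, size=(64, 64, 4), dtype=np.uint16)
        image = qf.SectionImage(pixels=pixels, subject_id="s", group_label="control",
                                run_id=1, section_id=1)
        n_px = int(rng.integers(5, 60))
        idx = rng.choice(64 * 64, size=n_px, replace=False)
        roi = CellROI(1, idx // 64, idx % 64)
        mu = rng.uniform(0, 500, 4)
        bg = densitometry.BackgroundModel("s", mu, np.zeros(4))
        meas = qf.measure_cells(image, [roi], bg)
        for i, m in enumerate(MARKERS):
            total = 0.0
            for r, c in zip(roi.rows, roi.cols):
                total += float(pixels[r, c, i])
            raw = total / n_px
            assert meas.loc[0, f"raw_{m.lower()}"] == pytest.approx(raw, rel=1e-12)
            assert meas.loc[0, f"corr_{m.lower()}"] == pytest.approx(
                max(0.0, raw - mu[i]), rel=1e-12, abs=1e-12
            )

    def test_cap_keeps_first_hundred_in_centroid_order(self):
        image = flat_image(10, shape=(140, 140))
        rois = []
        k = 0
        for r in range(12):
            for c in range(10):
                rois.append(CellROI(k + 1, np.arange(r * 11, r * 11 + 3),
                                    np.repeat(c * 11, 3)))
                k += 1
        assert len(rois) == 120
        bg = densitometry.BackgroundModel("s", np.zeros(4), np.zeros(4))
        rng = np.random.default_rng(0)
        shuffled = [rois[i] for i in rng.permutation(len(rois))]
        meas = qf.measure_cells(image, shuffled, bg, cap=100)
        assert len(meas) == 100
        kept = sorted(r.centroid for r in rois)[:100]
        measured = sorted(
            (sorted(r.centroid for r in shuffled if r.cell_id == cid)[0])
            for cid in meas["cell_id"]
        )
        assert measured == kept

    def test_out_of_bounds_roi_errors(self):
        image = flat_image(0)
        bg = densitometry.BackgroundModel("s", np.zeros(4), np.zeros(4))
        roi = CellROI(1, np.array([70]), np.array([1]))
        with pytest.raises(ValidationError, match="out of bounds"):
            qf.measure_cells(image, [roi], bg)

    def test_gain_invariance_of_corrected_means(self):
        # doubling one channel's pixels and its background doubles that
        # channel's corrected means exactly
        rng = np.random.default_rng(12)
        pixels = rng.integers(50, 2**14, size=(64, 64, 4), dtype=np.uint16)
        image = qf.SectionImage(pixels=pixels, subject_id="s", group_label="control",
                                run_id=1, section_id=1)
        scaled_px = pixels.copy()
        scaled_px[:, :, 3] = 2 * pixels[:, :, 3]
        scaled = qf.SectionImage(pixels=scaled_px, subject_id="s", group_label="control",
                                 run_id=1, section_id=1)
        roi = CellROI(1, np.arange(30), np.arange(30))
        mu = np.array([20.0, 20.0, 20.0, 20.0])
        mu2 = mu.copy()
        mu2[3] *= 2
        bg1 = densitometry.BackgroundModel("s", mu, np.zeros(4))
        bg2 = densitometry.BackgroundModel("s", mu2, np.zeros(4))
        m1 = qf.measure_cells(image, [roi], bg1)
        m2 = qf.measure_cells(scaled, [roi], bg2)
        assert m2.loc[0, "corr_porin"] == 2 * m1.loc[0, "corr_porin"]
        assert m2.loc[0, "corr_th"] == m1.loc[0, "corr_th"]
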
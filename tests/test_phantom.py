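"""Phantom generator: geometry, determinism, motion statistics, events."""

import dataclasses

import numpy as np
import pytest

from aimtk.phantom import (
    CellClass,
    Event,
    MotionModel,
    NoiseModel,
    PackingError,
    PhantomSpec,
    make_classification_samples,
    render_frame,
    render_video,
    simulate_tracks,
)


class TestRenderFrame:
    def test_single_nucleus_disc_area(self):
        # nucleus radius 0.4 * 20 = 8 px -> area within 5% of pi r^2
        spec = PhantomSpec(
            image_size=(96, 96), n_cells=1, cell_radius_range=(20.0, 20.0),
            nucleus_radius_fraction=0.4, seed=3,
        )
        _, _, truth = render_frame(spec, 0)
        area = int((truth.masks["nucleus"] > 0).sum())
        assert area == pytest.approx(np.pi * 8**2, rel=0.05)

    def test_no_cells_all_background(self):
        spec = PhantomSpec(n_cells=0, seed=0)
        _, fls, truth = render_frame(spec, 0)
        assert all((m == 0).all() for m in truth.masks.values())
        for f in fls:
            assert np.ptp(f.pixels) == 0.0  # flat background

    def test_seed_determinism_bit_identical(self, noisy):
        spec = PhantomSpec(image_size=(96, 96), n_cells=3, seed=7, noise=noisy)
        tl1, fl1, _ = render_frame(spec, 0)
        tl2, fl2, _ = render_frame(spec, 0)
        assert np.array_equal(tl1.pixels, tl2.pixels)
        for a, b in zip(fl1, fl2):
            assert np.array_equal(a.pixels, b.pixels)

    def test_mask_conservation(self, easy_spec):
        _, _, truth = render_frame(easy_spec, 0)
        h, w = easy_spec.image_size
        for mask in truth.masks.values():
            counts = np.bincount(mask.ravel())
            assert counts.sum() == h * w

    def test_organelle_channels(self):
        for mode in ("puncta", "fibers"):
            spec = PhantomSpec(image_size=(96, 96), n_cells=2, organelle_mode=mode, seed=2)
            _, fls, truth = render_frame(spec, 0)
            assert "organelle" in truth.masks
            assert (truth.masks["organelle"] > 0).any()
            # organelles live inside their cell
            org = truth.masks["organelle"]
            cell = truth.masks["cell"]
            assert np.all(cell[org > 0] == org[org > 0])

    def test_unsatisfiable_packing_fails_loudly(self):
        spec = PhantomSpec(image_size=(64, 64), n_cells=50, cell_radius_range=(14, 15), seed=0)
        with pytest.raises(PackingError, match="overlap"):
            render_frame(spec, 0)

    def test_frame_index_out_of_range(self, easy_spec):
        with pytest.raises(ValueError, match="frame_index"):
            render_frame(easy_spec, 5)

    def test_cells_do_not_overlap(self, two_class_spec):
        _, _, truth = render_frame(two_class_spec, 0)
        # instance labels partition the cell mask: areas sum to foreground
        cell = truth.masks["cell"]
        assert (np.bincount(cell.ravel())[1:] > 0).all()


class TestVideoAndMotion:
    def test_static_motion_zero_displacement(self):
        spec = PhantomSpec(image_size=(96, 96), n_cells=3, n_frames=5, seed=1)
        tracks = simulate_tracks(spec)
        for t in tracks:
            assert np.allclose(np.diff(t.xy, axis=0), 0.0)

    def test_brownian_mean_squared_step(self):
        # E|dr|^2 = 4D per frame for 2-D Brownian motion
        D = 0.5
        spec = PhantomSpec(
            image_size=(512, 512), n_cells=50, n_frames=200,
            motion=MotionModel("brownian", diffusion=D), seed=7,
        )
        steps = np.concatenate([np.diff(t.xy, axis=0) for t in simulate_tracks(spec)])
        msq = (steps**2).sum(axis=1).mean()
        assert msq == pytest.approx(4 * D, rel=0.10)

    def test_event_switches_class_exactly_at_frame(self):
        classes = [CellClass("live"), CellClass("dead", intensity=0.5)]
        ev = Event(track_id=0, frame=3, new_class="dead", new_motion=MotionModel("static"))
        spec = PhantomSpec(
            image_size=(96, 96), n_cells=2, n_frames=6, class_defs=classes,
            initial_classes=("live",), events=[ev], seed=4,
        )
        _, _, truth = render_video(spec)
        labels = [ft.cell_classes[0] for ft in truth.frame_truths]
        assert labels == ["live", "live", "live", "dead", "dead", "dead"]
        other = [ft.cell_classes[1] for ft in truth.frame_truths]
        assert all(c == "live" for c in other)

    def test_video_requires_two_frames(self, easy_spec):
        with pytest.raises(ValueError, match="n_frames"):
            render_video(easy_spec)

    def test_event_frame_validated(self):
        ev = Event(track_id=0, frame=10, new_class=None)
        spec = PhantomSpec(n_cells=1, n_frames=5, events=[ev], seed=0)
        with pytest.raises(ValueError, match="event frame"):
            spec.validate()

    def test_persistent_walk_moves_at_speed(self):
        spec = PhantomSpec(
            image_size=(256, 256), n_cells=5, n_frames=20,
            motion=MotionModel("persistent", speed=2.0, persistence=0.9), seed=2,
        )
        for t in simulate_tracks(spec):
            lens = np.linalg.norm(np.diff(t.xy, axis=0), axis=1)
            # reflection can shorten a step; all steps at most the speed
            assert np.all(lens <= 2.0 + 1e-9)
            assert lens.mean() > 1.0


class TestClassificationSamples:
    def test_bookkeeping_balanced(self, two_class_spec):
        specs = [
            dataclasses.replace(two_class_spec, sample_id=s, seed=50 + i)
            for i, s in enumerate("ABC")
        ]
        patches = make_classification_samples(specs, roi_side=41, rois_per_class=100)
        assert len(patches) == 2 * 3 * 100
        for sid in "ABC":
            for cls in ("round", "elongated"):
                n = sum(1 for p in patches if p.sample_id == sid and p.label == cls)
                assert n == 100

    def test_zero_rois_empty_no_error(self, two_class_spec):
        specs = [
            dataclasses.replace(two_class_spec, sample_id=s, seed=50 + i)
            for i, s in enumerate("AB")
        ]
        assert make_classification_samples(specs, roi_side=41, rois_per_class=0) == []

    def test_eccentricity_oracle_separates_classes(self, two_class_spec):
        from skimage import measure

        specs = [
            dataclasses.replace(two_class_spec, sample_id=s, seed=70 + i)
            for i, s in enumerate("AB")
        ]
        patches = make_classification_samples(
            specs, roi_side=61, rois_per_class=30, include_truth=True
        )
        # reflect-padded border patches merge with their mirror image and
        # distort the shape; the oracle applies to interior patches
        interior = [p for p in patches if not p.padded]
        assert len(interior) >= len(patches) // 2
        correct = 0
        for p in interior:
            props = measure.regionprops(p.images["truth:cell"].astype(int))
            ecc = props[0].eccentricity
            predicted = "elongated" if ecc > 0.5 else "round"
            correct += predicted == p.label
        assert correct == len(interior)

    def test_single_class_rejected(self, easy_spec):
        specs = [dataclasses.replace(easy_spec, sample_id=s) for s in "AB"]
        with pytest.raises(ValueError, match="2 distinct"):
            make_classification_samples(specs, roi_side=41, rois_per_class=5)

    def test_class_in_single_sample_rejected(self, two_class_spec):
        with pytest.raises(ValueError, match="<2 samples"):
            make_classification_samples(
                [two_class_spec], roi_side=41, rois_per_class=5
            )


def test_noise_model_applied_in_order(noisy):
    spec_clean = PhantomSpec(image_size=(96, 96), n_cells=2, seed=8)
    spec_noisy = dataclasses.replace(spec_clean, noise=noisy)
    tl_c, _, _ = render_frame(spec_clean, 0)
    tl_n, _, _ = render_frame(spec_noisy, 0)
    resid = tl_n.pixels - tl_c.pixels
    assert resid.std() > 0.01  # noise present
    assert abs(resid.mean()) < 0.01  # but unbiased
    # truth masks are noise-free and identical
    _, _, t_c = render_frame(spec_clean, 0)
    _, _, t_n = render_frame(spec_noisy, 0)
    assert np.array_equal(t_c.masks["nucleus"], t_n.masks["nucleus"])
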
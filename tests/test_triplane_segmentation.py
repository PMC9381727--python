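"""Frame stacks, threshold fallback, CNN training, and majority fusion."""

import itertools
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitrevol import (
    OCTVolume,
    PhantomSpec,
    PlaneMask,
    RaterErrorModel,
    SparseLabelSet,
    TrainingConfig,
    dice,
    extract_frame_stacks,
    fuse_majority,
    generate_phantom,
    predict_plane,
    simulate_rater,
    threshold_segment_fallback,
    train_plane_segmenter,
)


def make_volume(data, spacing=(0.1, 0.1, 0.1)):
    return OCTVolume(intensities=data, spacing=spacing)


class TestFrameStacks:
    def test_edge_replication(self):
        rng = np.random.default_rng(0)
        data = rng.random((4, 5, 3)).astype(np.float32)
        vol = make_volume(data)
        stacks = extract_frame_stacks(vol, "axial")  # frames along axis 1
        assert stacks.shape == (5, 3, 4, 3)
        lo, hi = data.min(), data.max()
        norm = (data - lo) / (hi - lo)
        np.testing.assert_allclose(stacks[0, 0], norm[:, 0, :], rtol=1e-6)
        np.testing.assert_allclose(stacks[0, 1], norm[:, 0, :], rtol=1e-6)
        np.testing.assert_allclose(stacks[0, 2], norm[:, 1, :], rtol=1e-6)
        np.testing.assert_allclose(stacks[2, 0], norm[:, 1, :], rtol=1e-6)
        np.testing.assert_allclose(stacks[2, 2], norm[:, 3, :], rtol=1e-6)
        np.testing.assert_allclose(stacks[4, 2], norm[:, 4, :], rtol=1e-6)

    def test_single_frame_plane(self):
        data = np.random.default_rng(1).random((6, 6, 1)).astype(np.float32)
        stacks = extract_frame_stacks(make_volume(data), "coronal")
        assert stacks.shape == (1, 3, 6, 6)
        assert np.array_equal(stacks[0, 0], stacks[0, 1])
        assert np.array_equal(stacks[0, 1], stacks[0, 2])

    def test_invalid_plane_rejected(self):
        with pytest.raises(ValueError, match="unknown plane"):
            extract_frame_stacks(make_volume(np.zeros((3, 3, 3))), "oblique")


@pytest.fixture(scope="module")
def training_eye():
    """Noiseless two-intensity phantom, small grid, with sparse labels."""
    spec = PhantomSpec(
        grid_shape=(64, 48, 32), speckle_shape=None, seed=11
    ).with_default_cavities(None)
    vol, truth = generate_phantom(spec)
    labels = simulate_rater(truth, "axial", RaterErrorModel(frame_step=8, seed=2))
    return vol, truth, labels


class TestFallbackSegmenter:
    def test_recovers_threshold_between_modes(self, training_eye):
        vol, truth, labels = training_eye
        pm = threshold_segment_fallback(vol, labels)
        assert pm.provenance == "fallback"
        assert dice(pm.mask, truth.fluid_mask) >= 0.99

    def test_empty_labels_give_empty_mask(self, training_eye):
        vol, _, labels = training_eye
        empty = SparseLabelSet(
            plane="axial",
            labeled_frames={k: np.zeros_like(v) for k, v in labels.labeled_frames.items()},
        )
        assert not threshold_segment_fallback(vol, empty).mask.any()

    def test_deterministic(self, training_eye):
        vol, _, labels = training_eye
        m1 = threshold_segment_fallback(vol, labels)
        m2 = threshold_segment_fallback(vol, labels)
        assert np.array_equal(m1.mask, m2.mask)

    def test_no_labels_rejected(self, training_eye):
        vol, _, _ = training_eye
        with pytest.raises(ValueError, match="labeled frame"):
            threshold_segment_fallback(
                vol, SparseLabelSet(plane="axial", labeled_frames={})
            )


class TestTrainedSegmenter:
    def test_training_reaches_high_dice_on_separable_phantom(self, training_eye):
        vol, truth, labels = training_eye
        cfg = TrainingConfig(
            filter_depth=8, epochs=120, learning_rate=1e-3, batch_size=4, seed=5
        )
        seg = train_plane_segmenter(vol, labels, cfg)
        pm = predict_plane(seg, vol, "axial")
        assert pm.mask.shape == vol.shape
        # held-out labeled frames (every 5th is the validation split)
        idx = sorted(labels.labeled_frames)
        held = idx[::5]
        d = np.mean(
            [dice(np.take(pm.mask, k, axis=1), labels.labeled_frames[k]) for k in held]
        )
        assert d >= 0.95
        assert dice(pm.mask, truth.fluid_mask) >= 0.9
        # fallback and trained segmenter converge on the separable phantom
        fb = threshold_segment_fallback(vol, labels)
        assert dice(pm.mask, fb.mask) >= 0.95

    def test_training_is_reproducible(self, training_eye):
        vol, _, labels = training_eye
        cfg = TrainingConfig(filter_depth=4, epochs=3, batch_size=2, seed=9)
        s1 = train_plane_segmenter(vol, labels, cfg)
        s2 = train_plane_segmenter(vol, labels, cfg)
        assert s1.train_loss == s2.train_loss
        p1 = predict_plane(s1, vol, "axial")
        p2 = predict_plane(s2, vol, "axial")
        assert np.array_equal(p1.mask, p2.mask)

    def test_all_background_labels_predict_empty(self, training_eye):
        vol, _, labels = training_eye
        idx = sorted(labels.labeled_frames)[:4]
        empty = SparseLabelSet(
            plane="axial",
            labeled_frames={
                k: np.zeros_like(labels.labeled_frames[k]) for k in idx
            },
        )
        cfg = TrainingConfig(
            filter_depth=4, epochs=100, learning_rate=5e-3, batch_size=4, seed=1
        )
        seg = train_plane_segmenter(vol, empty, cfg)
        stacks = np.stack(
            [np.take(vol.intensities, k, axis=1) for k in idx]
        )[:, None].repeat(3, axis=1)
        proba = seg.predict_proba(stacks.astype(np.float32))
        assert (proba < 0.5).all()

    def test_longer_training_never_worse(self, training_eye):
        # best-so-far checkpointing: monitored loss is monotone in epochs
        vol, _, labels = training_eye
        idx = sorted(labels.labeled_frames)[:4]  # <5 frames: no val split
        small = SparseLabelSet(
            plane="axial",
            labeled_frames={k: labels.labeled_frames[k] for k in idx},
        )
        short = train_plane_segmenter(
            vol, small, TrainingConfig(filter_depth=4, epochs=4, batch_size=2, seed=3)
        )
        long = train_plane_segmenter(
            vol, small, TrainingConfig(filter_depth=4, epochs=8, batch_size=2, seed=3)
        )
        assert long.train_loss <= short.train_loss

    def test_too_few_labels_rejected(self, training_eye):
        vol, _, labels = training_eye
        k = sorted(labels.labeled_frames)[0]
        one = SparseLabelSet(
            plane="axial", labeled_frames={k: labels.labeled_frames[k]}
        )
        with pytest.raises(ValueError, match="at least 2"):
            train_plane_segmenter(vol, one)

    def test_plane_mismatch_rejected(self, training_eye):
        vol, _, labels = training_eye
        cfg = TrainingConfig(filter_depth=4, epochs=2, seed=0)
        seg = train_plane_segmenter(vol, labels, cfg)
        with pytest.raises(ValueError, match="trained for plane"):
            predict_plane(seg, vol, "coronal")

    def test_save_load_roundtrip(self, training_eye, tmp_path):
        vol, _, labels = training_eye
        cfg = TrainingConfig(filter_depth=4, epochs=2, seed=0)
        seg = train_plane_segmenter(vol, labels, cfg)
        path = tmp_path / "seg_axial.npz"
        seg.save(path)
        from vitrevol import PlaneSegmenter

        loaded = PlaneSegmenter.load(path)
        p1 = predict_plane(seg, vol, "axial")
        p2 = predict_plane(loaded, vol, "axial")
        assert np.array_equal(p1.mask, p2.mask)


class TestFusion:
    def test_vote_table_exhaustive(self):
        # all 2^3 vote combinations against the brute-force majority table
        for votes in itertools.product([0, 1], repeat=3):
            masks = [
                PlaneMask(plane=p, mask=np.full((2, 2, 2), bool(v)))
                for p, v in zip(("axial", "sagittal", "coronal"), votes)
            ]
            fused = fuse_majority(*masks)
            expected = sum(votes) >= 2
            assert fused.mask.all() == expected and fused.mask.any() == expected
            assert (fused.votes == sum(votes)).all()

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_fusion_properties_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        a, s, c = (rng.random((5, 4, 3)) < 0.5 for _ in range(3))
        pm = lambda p, m: PlaneMask(plane=p, mask=m)
        fused = fuse_majority(pm("axial", a), pm("sagittal", s), pm("coronal", c))
        # brute-force majority
        assert np.array_equal(
            fused.mask, (a.astype(int) + s.astype(int) + c.astype(int)) >= 2
        )
        # symmetry in arguments
        perm = fuse_majority(pm("axial", c), pm("sagittal", a), pm("coronal", s))
        assert np.array_equal(fused.mask, perm.mask)
        # bounds: intersection <= fused <= union
        assert ((a & s & c) <= fused.mask).all()
        assert (fused.mask <= (a | s | c)).all()
        # idempotent when all planes agree
        same = fuse_majority(pm("axial", a), pm("sagittal", a), pm("coronal", a))
        assert np.array_equal(same.mask, a)

    def test_shape_mismatch_rejected(self):
        pm = lambda p, shape: PlaneMask(plane=p, mask=np.zeros(shape, bool))
        with pytest.raises(ValueError, match="shape"):
            fuse_majority(
                pm("axial", (3, 3, 3)), pm("sagittal", (3, 3, 3)), pm("coronal", (3, 3, 4))
            )
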
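"""Trait estimation: segmentation, PLA, MAE/ME, biomass regression."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from growsim.traits import (
    BiomassRegressor,
    NotFittedError,
    UnknownMethodError,
    center_instance,
    mae_me,
    pla,
    segment_plants,
    trait_delta,
)


class TestSegmentation:
    def test_bare_soil_gives_empty_masks(self, tiny_dataset):
        bare = [r for r in tiny_dataset.records if r.t == 7][0]
        masks = segment_plants(bare.image)
        # pre-emergence images contain (almost) no vegetation pixels
        assert masks["sw"].sum() + masks["fb"].sum() <= 2

    def test_ground_truth_method_returns_stored_masks(self, tiny_dataset):
        rec = tiny_dataset.records[3]
        masks = segment_plants(rec.image, method="ground_truth", record=rec)
        np.testing.assert_array_equal(masks["sw"], rec.gt_masks["sw"])
        np.testing.assert_array_equal(masks["fb"], rec.gt_masks["fb"])

    def test_unknown_method_rejected(self, tiny_dataset):
        with pytest.raises(UnknownMethodError):
            segment_plants(tiny_dataset.records[0].image, method="telepathy")

    def test_hue_threshold_recovers_truth_at_early_stages(self, small_dataset):
        ious = {"sw": [], "fb": []}
        for rec in small_dataset.records:
            if rec.t not in (28, 42):
                continue
            masks = segment_plants(rec.image)
            for sp in ("sw", "fb"):
                gt = rec.gt_masks[sp]
                if gt.sum() == 0:
                    continue
                ious[sp].append((masks[sp] & gt).sum() / (masks[sp] | gt).sum())
        assert np.mean(ious["sw"]) >= 0.9
        assert np.mean(ious["fb"]) >= 0.9


class TestCenterInstance:
    def test_single_instance_returned(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:5, 2:5] = True
        np.testing.assert_array_equal(center_instance(mask), mask)

    def test_nearest_to_center_wins(self):
        mask = np.zeros((41, 41), dtype=bool)
        mask[18:23, 18:23] = True  # centroid ~5 px from center after offset
        mask[1:4, 1:4] = True  # far corner instance
        picked = center_instance(mask)
        assert picked[20, 20]
        assert not picked[2, 2]

    def test_empty_mask_returns_empty(self):
        out = center_instance(np.zeros((8, 8), dtype=bool))
        assert out.sum() == 0 and out.shape == (8, 8)

    def test_tie_breaks_to_lowest_label(self):
        # two single-pixel instances symmetric about the center
        mask = np.zeros((11, 11), dtype=bool)
        mask[5, 3] = True  # labeled first (row-major)
        mask[5, 7] = True
        picked = center_instance(mask)
        assert picked[5, 3] and not picked[5, 7]


class TestPla:
    def test_full_mask_is_100_percent(self):
        mask = np.ones((256, 256), dtype=bool)
        px, pct, phys = pla(mask)
        assert px == 256 * 256 and pct == 100.0

    def test_forced_percent_arithmetic(self):
        mask = np.zeros((256, 256), dtype=bool)
        mask.flat[:6553] = True
        _, pct, _ = pla(mask)
        assert pct == pytest.approx(100.0 * 6553 / 65536, abs=1e-9)
        assert pct == pytest.approx(10.0, abs=0.01)

    def test_physical_area_via_gsd(self):
        # 1000 px at the 0.23 mm ground sample distance
        mask = np.zeros((256, 256), dtype=bool)
        mask.flat[:1000] = True
        _, _, phys = pla(mask, gsd=0.23)
        assert phys == pytest.approx(52.9, abs=1e-9)

    def test_invalid_gsd_rejected(self):
        with pytest.raises(ValueError):
            pla(np.ones((4, 4), dtype=bool), gsd=0.0)

    def test_percent_invariant_to_nearest_resize(self):
        rng = np.random.default_rng(0)
        mask = rng.random((64, 64)) < 0.3
        _, pct, _ = pla(mask)
        big = np.kron(mask, np.ones((2, 2), dtype=bool))  # nearest 2x upsample
        _, pct_big, _ = pla(big)
        assert pct_big == pytest.approx(pct, abs=1.0)


class TestMaeMe:
    def test_identical_lists_give_zero(self):
        assert mae_me([1.0, 2.0], [1.0, 2.0]) == (0.0, 0.0)

    def test_forced_arithmetic(self):
        mae, me = mae_me([1.0, 3.0], [2.0, 2.0])
        assert mae == 1.0 and me == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mae_me([1.0], [1.0, 2.0])

    @given(
        st.lists(
            st.floats(-100, 100, allow_nan=False), min_size=1, max_size=100
        ).flatmap(
            lambda g: st.tuples(
                st.just(g),
                st.lists(
                    st.floats(-100, 100, allow_nan=False),
                    min_size=len(g),
                    max_size=len(g),
                ),
            )
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_loop_oracle_and_bounds(self, pair):
        gen, ref = pair
        mae, me = mae_me(gen, ref)
        # element-wise loop oracle
        abs_sum = sig_sum = 0.0
        for g, r in zip(gen, ref):
            abs_sum += abs(g - r)
            sig_sum += g - r
        assert mae == pytest.approx(abs_sum / len(gen), rel=1e-12, abs=1e-12)
        assert me == pytest.approx(sig_sum / len(gen), rel=1e-12, abs=1e-9)
        assert mae >= abs(me) - 1e-12

    def test_delta_antisymmetric(self):
        assert trait_delta(3.0, 1.0) == -trait_delta(1.0, 3.0)


class TestBiomassRegressor:
    def test_untrained_predict_rejected(self):
        model = BiomassRegressor(width=4)
        with pytest.raises(NotFittedError):
            model.predict(np.zeros((1, 32, 32, 3), dtype=np.float32))

    def test_outputs_nonnegative_after_fit(self, tiny_dataset):
        imgs = np.stack([r.image for r in tiny_dataset.records[:16]])
        targets = np.stack([r.b for r in tiny_dataset.records[:16]])
        model = BiomassRegressor(width=4).fit(imgs, targets, epochs=2)
        pred = model.predict(imgs)
        assert pred.shape == (16, 2)
        assert np.all(pred >= 0)


@pytest.fixture(scope="module")
def fitted(small_dataset):
    train_idx = small_dataset.indices_by_split("train")
    imgs = np.stack([small_dataset.records[i].image for i in train_idx])
    targets = np.stack([small_dataset.records[i].b for i in train_idx])
    return BiomassRegressor(width=16, seed=0).fit(imgs, targets, epochs=60, seed=0)


class TestBiomassRecovery:
    """Parameter recovery of the regressor on the synthetic testbed."""

    def test_heldout_rank_correlation(self, small_dataset, fitted):
        from scipy.stats import spearmanr

        test_idx = small_dataset.indices_by_split("test")
        imgs = np.stack([small_dataset.records[i].image for i in test_idx])
        truth = np.stack([small_dataset.records[i].b for i in test_idx])
        pred = fitted.predict(imgs)
        # rank correlation over stands that contain the species (exact-
        # zero truths on the other species' monocultures are ties that
        # carry no ordering information)
        for k in (0, 1):
            present = truth[:, k] > 0
            rho = spearmanr(pred[present, k], truth[present, k]).statistic
            assert rho >= 0.9

    def test_species_swap_sanity(self, small_dataset, fitted):
        """SW estimates on FB monocultures stay far below SW estimates
        on SW monocultures (the model separates the species)."""
        kinds = {t.treatment_id: t.kind for t in small_dataset.treatments}
        late = [r for r in small_dataset.records if r.t >= 54]
        sw_mono = np.stack(
            [r.image for r in late if kinds[r.treatment_id] == "sw_mono"]
        )
        fb_mono = np.stack(
            [r.image for r in late if kinds[r.treatment_id] == "fb_mono"]
        )
        sw_on_sw = fitted.predict(sw_mono)[:, 0].mean()
        sw_on_fb = fitted.predict(fb_mono)[:, 0].mean()
        assert sw_on_fb < 0.5 * sw_on_sw
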
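"""Synthetic field testbed: factorial design, growth curves, rendering,
dataset assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from growsim.field import (
    DEFAULT_SEASON,
    DesignSpec,
    GrowthCurveParams,
    InvalidDesignError,
    RenderConfig,
    SplitError,
    biomass_at,
    enumerate_plots,
    enumerate_treatments,
    generate_dataset,
    load_dataset,
    make_layout,
    render_plot_image,
    save_dataset,
)
from growsim.field.dataset import _assign_splits


def brute_force_compositions(f, s):
    """Oracle: explicit enumeration of the composition set."""
    comps = [("mixture", fb, sw) for fb in range(f) for sw in range(s)]
    comps += [("fb_mono", fb, None) for fb in range(f)]
    comps += [("sw_mono", None, sw) for sw in range(s)]
    return comps


class TestDesignEnumeration:
    @pytest.mark.parametrize(
        "f,s,d,expected",
        [
            (2, 12, 2, 76),  # the field experiment's printed factorial
            (1, 1, 1, 3),  # 1 mixture + 2 monocultures
            (3, 4, 2, 38),
        ],
    )
    def test_treatment_counts(self, f, s, d, expected):
        design = DesignSpec(n_fb_cultivars=f, n_sw_entries=s, n_densities=d)
        treatments = enumerate_treatments(design)
        assert len(treatments) == expected
        assert len({t.treatment_id for t in treatments}) == expected

    @given(
        f=st.integers(1, 4), s=st.integers(1, 4), d=st.integers(1, 2)
    )
    @settings(max_examples=32, deadline=None)
    def test_treatment_formula_matches_brute_force(self, f, s, d):
        design = DesignSpec(n_fb_cultivars=f, n_sw_entries=s, n_densities=d)
        treatments = enumerate_treatments(design)
        assert len(treatments) == len(brute_force_compositions(f, s)) * d
        # every composition appears exactly once per density
        seen = {
            (t.kind, t.fb_cultivar, t.sw_entry, t.density) for t in treatments
        }
        assert len(seen) == len(treatments)

    def test_invalid_design_rejected(self):
        with pytest.raises((InvalidDesignError, ValueError)):
            DesignSpec(n_fb_cultivars=0)

    @pytest.mark.parametrize(
        "kwargs,expected_plots",
        [
            (dict(), 320),  # 76 treatments, 4 reps, 8 for FB monocultures
            (
                dict(
                    n_fb_cultivars=1,
                    n_sw_entries=1,
                    n_densities=1,
                    replicates_default=1,
                    replicates_fb_mono=1,
                ),
                3,
            ),
            (
                # oracle count: d * (f*s*R + s*R + f*R_fb) = 1*(2*2*2 + 2*2 + 2*4)
                dict(
                    n_fb_cultivars=2,
                    n_sw_entries=2,
                    n_densities=1,
                    replicates_default=2,
                    replicates_fb_mono=4,
                ),
                20,
            ),
        ],
    )
    def test_plot_counts(self, kwargs, expected_plots):
        design = DesignSpec(**kwargs)
        treatments = enumerate_treatments(design)
        plots = enumerate_plots(treatments, design)
        assert len(plots) == expected_plots
        assert len({p.plot_id for p in plots}) == expected_plots

    def test_fb_mono_replication(self):
        design = DesignSpec()
        treatments = enumerate_treatments(design)
        plots = enumerate_plots(treatments, design)
        counts = pd.Series([p.treatment_id for p in plots]).value_counts()
        for t in treatments:
            expected = 8 if t.kind == "fb_mono" else 4
            assert counts[t.treatment_id] == expected


class TestGrowthCurves:
    def setup_method(self):
        self.params = GrowthCurveParams()
        design = DesignSpec()
        self.trt_mix = enumerate_treatments(design)[0]

    def test_logistic_tail_and_midpoint(self):
        early = biomass_at(self.params, self.trt_mix, -500)
        assert np.all(early < 1e-6)
        mid_sw = biomass_at(self.params, self.trt_mix, self.params.t0_sw)[0]
        dens = self.params.density_factors[self.trt_mix.density]
        assert mid_sw == pytest.approx(self.params.k_sw * dens * 0.5 / 2, rel=1e-6)

    def test_monotone_on_grid(self):
        grid = np.linspace(0, 150, 100)
        b = biomass_at(self.params, self.trt_mix, grid)
        assert np.all(np.diff(b[:, 0]) >= 0)
        assert np.all(np.diff(b[:, 1]) >= 0)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            GrowthCurveParams(r_sw=0.0)


class TestRenderer:
    def setup_method(self):
        design = DesignSpec()
        self.trts = enumerate_treatments(design)
        self.config = RenderConfig(image_size=32)
        self.params = GrowthCurveParams()
        self.layout = make_layout(
            self.trts[0], self.config, np.random.default_rng(5)
        )

    def test_pre_emergence_is_bare_soil(self):
        rec = render_plot_image(
            self.trts[0], self.layout, self.params, -300, 9, self.config
        )
        assert rec.gt_masks["sw"].sum() == 0
        assert rec.gt_masks["fb"].sum() == 0

    def test_determinism(self):
        a = render_plot_image(self.trts[0], self.layout, self.params, 54, 9, self.config)
        b = render_plot_image(self.trts[0], self.layout, self.params, 54, 9, self.config)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.gt_masks["sw"], b.gt_masks["sw"])

    def test_doubling_fb_asymptote_grows_fb_mask(self):
        bigger = GrowthCurveParams(k_fb=2 * self.params.k_fb)
        base = render_plot_image(self.trts[0], self.layout, self.params, 60, 9, self.config)
        grown = render_plot_image(self.trts[0], self.layout, bigger, 60, 9, self.config)
        assert grown.gt_masks["fb"].sum() > base.gt_masks["fb"].sum()

    def test_mask_area_nondecreasing_in_time(self):
        areas = [
            render_plot_image(self.trts[0], self.layout, self.params, t, 9, self.config)
            .gt_masks["fb"]
            .sum()
            for t in (20, 40, 60, 80, 100)
        ]
        assert all(a2 >= a1 for a1, a2 in zip(areas, areas[1:]))

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            RenderConfig(image_size=8)


class TestDatasetAssembly:
    def test_split_sizes_and_disjointness(self, tiny_dataset):
        md = tiny_dataset.metadata
        seq_splits = md.groupby("sequence_id")["split"].agg(["nunique", "first"])
        assert (seq_splits["nunique"] == 1).all()
        counts = seq_splits["first"].value_counts()
        assert counts["train"] == 7 and counts["val"] == 2 and counts["test"] == 1

    def test_exact_14_3_3_split_on_20_sequences(self):
        rng = np.random.default_rng(0)
        assignment = _assign_splits([f"s{i}" for i in range(20)], (0.7, 0.15, 0.15), rng)
        counts = pd.Series(assignment).value_counts()
        assert counts["train"] == 14 and counts["val"] == 3 and counts["test"] == 3

    def test_bad_split_fractions_rejected(self):
        with pytest.raises(SplitError):
            generate_dataset(
                image_size=32, n_sequences=4, split_fractions=(0.5, 0.2, 0.2)
            )

    def test_sequence_length_bounded_by_season(self, tiny_dataset):
        md = tiny_dataset.metadata
        assert md.groupby("sequence_id").size().max() <= len(DEFAULT_SEASON)

    def test_regeneration_is_reproducible(self):
        a = generate_dataset(image_size=32, n_sequences=6, seed=11)
        b = generate_dataset(image_size=32, n_sequences=6, seed=11)
        pd.testing.assert_frame_equal(a.metadata, b.metadata)
        assert all(
            np.array_equal(x.image, y.image) for x, y in zip(a.records, b.records)
        )

    def test_biomass_matches_curve(self, tiny_dataset):
        for rec in tiny_dataset.records[:20]:
            trt = tiny_dataset.treatments[rec.treatment_id]
            expected = biomass_at(tiny_dataset.growth, trt, rec.t)
            np.testing.assert_allclose(rec.b, expected, rtol=1e-5)

    def test_style_shared_within_date(self, tiny_dataset):
        from growsim.field.render import style_params

        b1, t1 = style_params(123, 28, tiny_dataset.render_config)
        b2, t2 = style_params(123, 28, tiny_dataset.render_config)
        assert b1 == b2 and np.array_equal(t1, t2)


class TestDiskRoundTrip:
    def test_save_load_round_trip(self, tmp_path):
        ds = generate_dataset(image_size=32, n_sequences=4, seed=2)
        save_dataset(ds, tmp_path)
        loaded = load_dataset(tmp_path)
        assert len(loaded.records) == len(ds.records)
        pd.testing.assert_frame_equal(
            loaded.metadata, ds.metadata, check_dtype=False
        )
        # 8-bit quantization bounds the image round-trip error
        assert np.max(np.abs(loaded.records[0].image - ds.records[0].image)) < 1 / 254

    def test_missing_image_raises(self, tmp_path):
        ds = generate_dataset(image_size=32, n_sequences=4, seed=2)
        save_dataset(ds, tmp_path)
        victim = tmp_path / ds.metadata["path"].iloc[0]
        victim.unlink()
        with pytest.raises(FileNotFoundError, match="row 0"):
            load_dataset(tmp_path)

    def test_split_leakage_detected(self, tmp_path):
        ds = generate_dataset(image_size=32, n_sequences=4, seed=2)
        save_dataset(ds, tmp_path)
        md = pd.read_csv(tmp_path / "metadata.csv")
        md.loc[0, "split"] = "test" if md.loc[0, "split"] != "test" else "train"
        md.to_csv(tmp_path / "metadata.csv", index=False)
        with pytest.raises(ValueError, match="leakage"):
            load_dataset(tmp_path)
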
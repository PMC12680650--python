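"""Phantom generator: rendering oracles, cryo-effect scaling, cohort layout."""

import dataclasses
import math

import numpy as np
import pytest

from cryoht import (
    GeometryError,
    PhantomSpec,
    StudyDesign,
    ValidationError,
    analytic_volumes,
    apply_cryo_effect,
    render_tomogram,
    simulate_study,
)

ISO01 = (0.1, 0.1, 0.1)


def nucleus_only_spec(**kw):
    """A phantom whose midpiece and tail are optically invisible."""
    defaults = dict(
        nucleus_semiaxes=(2.0, 1.0, 1.0), nucleus_ri=1.415,
        midpiece_ri=1.337, tail_ri=1.337,
        midpiece_length=0.5, midpiece_radius=0.2,
        tail_length=0.5, tail_radius=0.1,
        medium_ri=1.337, noise_sd=0.0,
    )
    defaults.update(kw)
    return PhantomSpec(**defaults)


class TestRenderTomogram:
    def test_noise_free_nucleus_only_is_two_valued(self):
        spec = nucleus_only_spec()
        tomo = render_tomogram(spec, ISO01, (56, 56, 56))
        values = set(np.unique(tomo.grid))
        assert values == {np.float32(1.337), np.float32(1.415)}

    def test_ellipsoid_voxel_count_matches_analytic_volume(self):
        # 4/3*pi*2*1*1 = 8.378 µm³, voxel-count oracle at 0.1 µm pitch
        spec = nucleus_only_spec()
        tomo = render_tomogram(spec, ISO01, (56, 56, 56))
        vol = np.count_nonzero(tomo.grid == np.float32(1.415)) * 0.1**3
        expected = 4.0 / 3.0 * math.pi * 2.0 * 1.0 * 1.0
        assert vol == pytest.approx(expected, rel=0.03)

    def test_same_spec_same_seed_bit_identical(self):
        spec = PhantomSpec(seed=42)
        a = render_tomogram(spec)
        b = render_tomogram(spec)
        assert np.array_equal(a.grid, b.grid)

    def test_different_seed_differs(self):
        a = render_tomogram(PhantomSpec(seed=1))
        b = render_tomogram(PhantomSpec(seed=2))
        assert not np.array_equal(a.grid, b.grid)

    def test_phantom_exceeding_grid_raises(self):
        with pytest.raises(GeometryError):
            render_tomogram(PhantomSpec(), ISO01, (16, 16, 16))

    def test_nonpositive_voxel_size_raises(self):
        with pytest.raises(ValidationError):
            render_tomogram(PhantomSpec(), (0.1, 0.0, 0.1), (64, 64, 64))

    def test_compartment_ri_values_present(self, quiet_spec):
        tomo = render_tomogram(quiet_spec)
        for ri in (quiet_spec.nucleus_ri, quiet_spec.midpiece_ri, quiet_spec.tail_ri):
            assert np.any(tomo.grid == np.float32(ri))


class TestApplyCryoEffect:
    def test_identity_factors_leave_geometry_unchanged(self):
        spec = PhantomSpec()
        out = apply_cryo_effect(spec, {r: 1.0 for r in ("nucleus", "midpiece", "tail")})
        assert out.nucleus_semiaxes == spec.nucleus_semiaxes
        assert out.midpiece_length == spec.midpiece_length
        assert out.tail_radius == spec.tail_radius

    def test_input_spec_is_unchanged(self):
        spec = PhantomSpec()
        before = dataclasses.asdict(spec)
        apply_cryo_effect(spec, {"midpiece": 0.5})
        assert dataclasses.asdict(spec) == before

    def test_volume_scales_exactly_by_factor(self):
        spec = PhantomSpec()
        out = apply_cryo_effect(spec, {"midpiece": 0.5, "nucleus": 0.9})
        v0, v1 = analytic_volumes(spec), analytic_volumes(out)
        assert v1["midpiece"] == pytest.approx(0.5 * v0["midpiece"], rel=1e-12)
        assert v1["nucleus"] == pytest.approx(0.9 * v0["nucleus"], rel=1e-12)
        assert v1["tail"] == pytest.approx(v0["tail"], rel=1e-12)

    @pytest.mark.parametrize("factor", [0.5, 1.2])
    def test_rendered_midpiece_window_volume_tracks_factor(self, factor):
        # voxel-count oracle on paired renders (same seed, same placement)
        spec = PhantomSpec(noise_sd=0.0, seed=3)
        shrunk = apply_cryo_effect(spec, {"midpiece": factor})
        grid = (72, 72, 160)
        base = render_tomogram(spec, ISO01, grid)
        after = render_tomogram(shrunk, ISO01, grid)
        ri = np.float32(spec.midpiece_ri)
        v0 = np.count_nonzero(base.grid == ri)
        v1 = np.count_nonzero(after.grid == ri)
        assert v1 / v0 == pytest.approx(factor, rel=0.05)

    def test_monotonicity_of_rendered_volume_in_factor(self):
        spec = PhantomSpec(noise_sd=0.0, seed=5)
        grid = (72, 72, 160)
        ri = np.float32(spec.midpiece_ri)
        counts = []
        for f in (0.5, 0.8, 1.1):
            t = render_tomogram(apply_cryo_effect(spec, {"midpiece": f}), ISO01, grid)
            counts.append(np.count_nonzero(t.grid == ri))
        assert counts[0] < counts[1] < counts[2]

    @pytest.mark.parametrize("bad", [0.0, -0.3])
    def test_nonpositive_factor_rejected(self, bad):
        with pytest.raises(ValidationError):
            apply_cryo_effect(PhantomSpec(), {"midpiece": bad})

    def test_unknown_region_rejected(self):
        with pytest.raises(ValidationError):
            apply_cryo_effect(PhantomSpec(), {"acrosome": 0.9})


class TestStudyDesign:
    def test_fresh_extender_must_be_listed(self):
        with pytest.raises(ValidationError):
            StudyDesign(extenders=("A", "B"), fresh_extender="C",
                        extender_effects={"A": {}, "B": {}})

    def test_frozen_extender_needs_distribution(self):
        with pytest.raises(ValidationError):
            StudyDesign(extenders=("INRA96", "Mystery"), fresh_extender="INRA96")


class TestSimulateStudy:
    def small_design(self, **kw):
        defaults = dict(
            n_donors=2,
            extenders=("INRA96", "BotuCrio"),
            fresh_extender="INRA96",
            cells_per_sample=3,
            extender_effects={"BotuCrio": {"midpiece": (0.7, 0.0)}},
            good_cooler_donors=(),
            seed=11,
        )
        defaults.update(kw)
        return StudyDesign(**defaults)

    def test_counts_one_tomogram_per_donor_extender_cell(self):
        sim = simulate_study(self.small_design())
        assert len(sim) == 2 * 2 * 3
        truth = sim.ground_truth
        cells = truth[["donor", "extender", "cell_id"]].drop_duplicates()
        assert len(cells) == 12
        assert set(truth["region"]) == {"nucleus", "midpiece", "tail", "whole"}

    def test_degenerate_shrinkage_gives_exact_paired_ratio(self):
        # sd = 0: every frozen cell's true midpiece volume is 0.7x its
        # fresh counterpart, cell by cell
        truth = simulate_study(self.small_design()).ground_truth
        mid = truth[truth.region == "midpiece"].pivot_table(
            index=["donor", "cell_id"], columns="extender", values="true_volume_um3"
        )
        np.testing.assert_allclose(mid["BotuCrio"], 0.7 * mid["INRA96"], rtol=1e-12)

    def test_unspecified_regions_are_unshrunk(self):
        truth = simulate_study(self.small_design()).ground_truth
        nuc = truth[truth.region == "nucleus"].pivot_table(
            index=["donor", "cell_id"], columns="extender", values="true_volume_um3"
        )
        np.testing.assert_allclose(nuc["BotuCrio"], nuc["INRA96"], rtol=1e-12)

    def test_plans_reproducible_from_seed(self):
        a = simulate_study(self.small_design())
        b = simulate_study(self.small_design())
        assert [p.spec for p in a.plans] == [p.spec for p in b.plans]
        ta = a.render(a.plans[0])
        tb = b.render(b.plans[0])
        assert np.array_equal(ta.grid, tb.grid)

    def test_good_cooler_donor_barely_shrinks(self):
        design = self.small_design(
            good_cooler_donors=(1,), good_cooler_effect=(0.98, 0.0)
        )
        truth = simulate_study(design).ground_truth
        mid = truth[truth.region == "midpiece"].pivot_table(
            index=["donor", "cell_id"], columns="extender", values="true_volume_um3"
        )
        ratios = (mid["BotuCrio"] / mid["INRA96"]).groupby(level="donor").mean()
        assert ratios.loc[1] == pytest.approx(0.98, rel=1e-9)
        assert ratios.loc[2] == pytest.approx(0.70, rel=1e-9)

    def test_default_design_matches_study_scale(self):
        design = StudyDesign()
        assert design.n_donors == 11
        assert len(design.extenders) == 5
        assert design.cells_per_sample == 40
        assert design.fresh_extender == "INRA96"
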
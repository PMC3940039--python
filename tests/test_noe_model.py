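import math

import numpy as np
import pytest

from conformeq.data import centroid_tables_from_distances
from conformeq.errors import ConfigurationError
from conformeq.noe_model import (
    InteractionModel,
    buildup_rate_factor,
    centroid_rate,
    cross_structure_scale,
    jump_effective_rate,
    predict_noe_table,
)
from conformeq.structure_io import (
    InteractionGeometry,
    MethylGroup,
    ProbeSite,
    build_methyl_protons,
    methyl_probe_geometry,
)

from conftest import axial_probe
from oracles import jump_rate_spherical_harmonics


class TestBuildupFactor:
    def test_extreme_narrowing_limit_is_two_tau_c(self):
        tau_c = 1e-12
        assert buildup_rate_factor(tau_c, 1.0) == pytest.approx(2 * tau_c, rel=1e-9)

    def test_zero_crossing_at_sqrt5_over_2(self):
        # 6J(2w) = J(0)  <=>  w tau_c = sqrt(5)/2
        tau_c = 4e-9
        omega = math.sqrt(5.0) / 2.0 / tau_c
        assert abs(buildup_rate_factor(tau_c, omega)) < 1e-12

    def test_slow_tumbling_regime_is_negative(self):
        omega = 2 * math.pi * 600e6
        assert buildup_rate_factor(5.8e-9, omega) < 0

    def test_nonpositive_tau_c_rejected(self):
        with pytest.raises(ValueError):
            buildup_rate_factor(0.0, 1.0)


class TestJumpRate:
    def test_far_field_collapses_to_inverse_sixth(self, ideal_methyl):
        # methyl radius shrunk 1000x: all angles -> 0, all r -> d
        tiny = MethylGroup(
            ideal_methyl.residue, ideal_methyl.carbon_name, ideal_methyl.carbon,
            ideal_methyl.antecedent,
            ideal_methyl.carbon + 1e-3 * (ideal_methyl.protons - ideal_methyl.carbon),
        )
        probe = axial_probe(10.0)
        d = np.linalg.norm(probe.pos - tiny.mean_proton)
        rate = jump_effective_rate(methyl_probe_geometry(tiny, probe))
        assert rate * d ** 6 == pytest.approx(1.0, abs=1e-4)

    def test_orthogonal_angles_cancel_exactly(self):
        g = InteractionGeometry(
            distances=np.array([2.0, 2.0, 2.0]),
            angles=np.array([[0.0, 90, 90], [90, 0, 90], [90, 90, 0]]),
        )
        # diagonal contributes 3*2, off-diagonal 6*(-1): exact cancellation
        assert jump_effective_rate(g) == pytest.approx(0.0, abs=1e-15)

    def test_matches_spherical_harmonics_oracle(self):
        """Pairwise P2 contraction equals the addition-theorem contraction."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            protons = rng.uniform(-1.5, 1.5, (3, 3))
            probe_pos = rng.uniform(2.5, 9.0) * _random_unit(rng)
            site = ProbeSite(("A", 9, "TRP"), "HE1", probe_pos,
                             probe_pos + np.array([0, 0, 0.98]))
            m = MethylGroup(("A", 1, "VAL"), "CG1", np.zeros(3),
                            np.array([0, 0, -1.54]), protons)
            ours = jump_effective_rate(methyl_probe_geometry(m, site))
            oracle = jump_rate_spherical_harmonics(protons, probe_pos)
            assert ours == pytest.approx(oracle, rel=1e-8, abs=1e-14)

    def test_far_field_model_convergence(self, ideal_methyl):
        """All three rates converge in the far field.

        Jump and mean-proton share the proton centroid, so they agree at
        second order in (radius/d) - well under 1% at 50 Angstrom.  The
        carbon point is axially offset from the proton centroid by ~0.36
        Angstrom, so its rate differs at first order (~6*0.36/d) and needs a
        larger d to reach the same tolerance.
        """
        probe = axial_probe(50.0)
        jump = jump_effective_rate(methyl_probe_geometry(ideal_methyl, probe))
        meanp = centroid_rate(ideal_methyl, probe, "mean-proton")
        assert abs(jump - meanp) / meanp < 0.01

        far = axial_probe(500.0)
        jump_far = jump_effective_rate(methyl_probe_geometry(ideal_methyl, far))
        carbon_far = centroid_rate(ideal_methyl, far, "carbon")
        meanp_far = centroid_rate(ideal_methyl, far, "mean-proton")
        for a, b in ((jump_far, carbon_far), (jump_far, meanp_far),
                     (carbon_far, meanp_far)):
            assert abs(a - b) / b < 0.01


def _random_unit(rng):
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


class TestCentroidRate:
    @pytest.mark.parametrize("r", [1.0, 4.14])
    def test_inverse_sixth_power(self, ideal_methyl, r):
        probe = axial_probe(r)
        assert centroid_rate(ideal_methyl, probe, "carbon") == pytest.approx(r ** -6)

    def test_unknown_centroid_rejected(self, ideal_methyl):
        with pytest.raises(ConfigurationError):
            centroid_rate(ideal_methyl, axial_probe(3.0), "ring")


class TestPredictTable:
    def test_normalization_and_gating(self, scene):
        model = InteractionModel("jump", cutoff=7.0)
        table = predict_noe_table(scene.conformer_a, scene.probe_a, model)
        vols = table.entries["normalized_volume"]
        assert (vols.max() == 1.0) and (vols == 1.0).sum() == 1
        assert ((vols > 0) & (vols <= 1.0)).all()
        assert (table.entries["gating_distance_A"] <= 7.0).all()

    def test_single_methyl_normalizes_to_one(self, scene):
        model = InteractionModel("jump", cutoff=7.0)
        table = predict_noe_table(
            scene.conformer_a, scene.probe_a, model, methyl_selection="A:2:CD1"
        )
        assert len(table) == 1
        assert table.entries["normalized_volume"].iloc[0] == 1.0

    def test_degenerate_merge_sums_raw_rates(self, scene):
        model = InteractionModel("jump")
        plain = predict_noe_table(scene.conformer_a, scene.probe_a, model)
        raw = {(r.resnum, r.atom): r.raw_rate for r in plain.entries.itertuples()}
        src, dst = None, None
        keys = set(raw)
        for rn in {k[0] for k in keys}:
            if (rn, "CG1") in keys and (rn, "CG2") in keys:
                src, dst = (rn, "CG1"), (rn, "CG2")
                break
        assert src is not None
        merged = predict_noe_table(
            scene.conformer_a, scene.probe_a, model, merge_map=[(src, dst)]
        )
        mraw = {(r.resnum, r.atom): r.raw_rate for r in merged.entries.itertuples()}
        assert src not in mraw
        assert mraw[dst] == pytest.approx(raw[src] + raw[dst], rel=1e-12)

    def test_exclusion_drops_entry(self, scene):
        model = InteractionModel("jump")
        plain = predict_noe_table(scene.conformer_a, scene.probe_a, model)
        key = (int(plain.entries["resnum"].iloc[0]), plain.entries["atom"].iloc[0])
        pruned = predict_noe_table(
            scene.conformer_a, scene.probe_a, model, exclude=[key]
        )
        assert key not in pruned.volumes()

    def test_no_methyl_in_range_warns_not_raises(self, scene):
        model = InteractionModel("jump", cutoff=0.5)
        with pytest.warns(UserWarning, match="no methyl"):
            table = predict_noe_table(scene.conformer_a, scene.probe_a, model)
        assert len(table) == 0


class TestCrossStructureScale:
    def test_identical_structures_give_unity(self, scene):
        model = InteractionModel("jump")
        t = predict_noe_table(scene.conformer_a, scene.probe_a, model)
        assert cross_structure_scale(t, t) == 1.0

    def test_mode_mismatch_rejected(self, scene):
        a = predict_noe_table(scene.conformer_a, scene.probe_a, InteractionModel("jump"))
        b = predict_noe_table(scene.conformer_a, scene.probe_a, InteractionModel("carbon"))
        with pytest.raises(ConfigurationError):
            cross_structure_scale(a, b)

    def test_carbon_scale_from_tabulated_distances(self, fkbp12):
        """The ratio of maximum r^-6 rates follows from the closest carbons."""
        _, _, scale = centroid_tables_from_distances(fkbp12)
        assert scale == pytest.approx((3.32 / 4.14) ** 6, rel=1e-9)
        assert scale == pytest.approx(0.266, abs=5e-3)
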
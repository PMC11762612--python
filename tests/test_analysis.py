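"""Load cases, gap/stress extraction and report plumbing."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

import pelvifem as pf
from pelvifem.analysis import (AnalysisError, STANCE_CASES, VALIDATION_CASES,
                               convergence_study, fracture_gap,
                               make_load_case, regional_stress)
from pelvifem import fem


class TestLoadCases:
    @pytest.mark.parametrize("name", VALIDATION_CASES)
    def test_validation_cases_use_294N_with_fixed_acetabula(self, name):
        case = make_load_case(name)
        assert case.magnitude == pytest.approx(294.0)
        assert set(case.fixed_patches) == {"acetabulum_left", "acetabulum_right"}
        assert case.loads[0][0] == "s1_endplate"

    def test_bipedal_splits_walking_force_evenly(self):
        case = make_load_case("bipedal")
        assert case.magnitude == pytest.approx(2048.0)
        per_side = {p: np.linalg.norm(f) for p, f in case.loads}
        assert per_side == {"acetabulum_left": pytest.approx(1024.0),
                            "acetabulum_right": pytest.approx(1024.0)}

    def test_one_leg_loads_only_the_stance_hip(self):
        case = make_load_case("right_one_leg")
        assert case.magnitude == pytest.approx(2048.0)
        assert [p for p, _ in case.loads] == ["acetabulum_right"]
        assert "acetabulum_left" not in case.fixed_patches

    def test_unknown_case_rejected(self):
        with pytest.raises(AnalysisError):
            make_load_case("hopping")


class TestFractureGap:
    def _stub(self, mesh, u):
        return SimpleNamespace(u=u)

    def test_zero_displacement_zero_gap(self, inputs):
        mesh = inputs.fractured
        sol = self._stub(mesh, np.zeros((mesh.n_nodes, 3)))
        for pair in mesh.fracture_face_pairs:
            assert fracture_gap(sol, mesh, pair).headline == 0.0

    def test_rigid_lateral_translation_reads_plus_one(self, inputs):
        mesh = inputs.fractured
        pair = mesh.fracture_face_pairs["posterior_ring"]
        u = np.zeros((mesh.n_nodes, 3))
        u[pair.lateral, 0] = 1.0   # lateral fragment moves +x (away, right side)
        sol = self._stub(mesh, u)
        assert fracture_gap(sol, mesh, "posterior_ring").headline == pytest.approx(1.0)

    def test_perpendicular_translation_reads_zero(self, inputs):
        mesh = inputs.fractured
        pair = mesh.fracture_face_pairs["posterior_ring"]
        u = np.zeros((mesh.n_nodes, 3))
        u[pair.lateral, 1] = 1.0
        sol = self._stub(mesh, u)
        assert fracture_gap(sol, mesh, "posterior_ring").headline == 0.0

    def test_band_split_reports_both_bands(self, inputs):
        mesh = inputs.fractured
        pair = mesh.fracture_face_pairs["posterior_ring"]
        u = np.zeros((mesh.n_nodes, 3))
        split = inputs.intact.metadata["geometry"]["s1_mid_mm"]
        sup = pair.lateral[mesh.nodes[pair.medial, 2] >= split]
        u[sup, 0] = 2.0
        g = fracture_gap(self._stub(mesh, u), mesh, "posterior_ring",
                         band_split=split)
        assert g.superior_band == pytest.approx(2.0)
        assert g.inferior_band == pytest.approx(0.0)

    def test_unknown_pair_rejected(self, inputs):
        sol = self._stub(inputs.fractured,
                         np.zeros((inputs.fractured.n_nodes, 3)))
        with pytest.raises(AnalysisError):
            fracture_gap(sol, inputs.fractured, "nonexistent")


class TestRegionalStress:
    def _box_system(self, value_by_element):
        mesh = pf.box_mesh((4.0, 4.0, 4.0), h=2.0,
                           region="sacrum_S1_right")
        stress = np.zeros((mesh.n_elements, 6))
        stress[:, 0] = value_by_element(mesh)
        sol = SimpleNamespace(stress=stress)
        system = SimpleNamespace(fixed_nodes=np.array([], dtype=np.int64),
                                 loaded_patches=[])
        return mesh, sol, system

    def test_uniform_field_reports_its_value(self):
        mesh, sol, system = self._box_system(lambda m: 5.0)
        assert regional_stress(sol, mesh, system, "S1_right") == pytest.approx(5.0)

    def test_zero_field_reports_zero(self):
        mesh, sol, system = self._box_system(lambda m: 0.0)
        assert regional_stress(sol, mesh, system, "S1_right") == 0.0

    def test_signed_extremum_keeps_sign(self):
        def field(mesh):
            v = np.full(mesh.n_elements, 2.0)
            v[0] = -3.0
            return v
        mesh, sol, system = self._box_system(field)
        assert regional_stress(sol, mesh, system, "S1_right") == pytest.approx(-3.0)

    def test_empty_region_rejected(self):
        mesh, sol, system = self._box_system(lambda m: 1.0)
        with pytest.raises(AnalysisError):
            regional_stress(sol, mesh, system, "S2_left")


class TestIntactSymmetry:
    def test_bipedal_stress_symmetric_on_intact_phantom(self):
        """On the uninjured, noiseless phantom under bipedal stance the
        left/right regional stresses agree: any asymmetry in instrumented
        runs is attributable to the fracture and construct."""
        params = pf.PhantomParams(hu_noise_sd=0.0)
        mesh, hu = pf.build_phantom(params)
        springs = pf.make_springs(mesh)
        materials = pf.assign_materials(mesh, hu)
        case = make_load_case("bipedal")
        system, sol = pf.solve_case(mesh, materials, springs, case)
        for region in ("S1", "S2"):
            left = regional_stress(sol, mesh, system, f"{region}_left")
            right = regional_stress(sol, mesh, system, f"{region}_right")
            assert left == pytest.approx(right, rel=0.01)


class TestConvergenceProtocol:
    def test_single_size_rejected(self):
        with pytest.raises(AnalysisError):
            convergence_study(edge_lengths=(5.0,))

    def test_non_descending_sizes_rejected(self):
        with pytest.raises(AnalysisError):
            convergence_study(edge_lengths=(3.0, 5.0))

    def test_identical_resolution_twice_changes_nothing(self, monkeypatch):
        """Re-meshing at the same size must report exactly 0% change."""
        import pelvifem.analysis as an
        orig = an.AnalysisError
        sizes_seen = []
        real_build = pf.build_phantom

        def fake_build(p):
            sizes_seen.append(p.target_edge_length)
            import dataclasses
            return real_build(dataclasses.replace(p, target_edge_length=5.0))

        monkeypatch.setattr(an, "build_phantom", fake_build)
        res = convergence_study(edge_lengths=(5.0, 2.5))
        assert sizes_seen == [5.0, 2.5]
        assert res.rows["tension_change"].iloc[-1] == pytest.approx(0.0, abs=1e-12)
        assert res.accepted
        del orig


class TestReportDeterminism:
    def test_identical_run_produces_identical_rows(self, inputs):
        r1 = pf.compare_constructs(inputs, variants=("TSI",),
                                   load_cases=("bipedal",))
        r2 = pf.compare_constructs(inputs, variants=("TSI",),
                                   load_cases=("bipedal",))
        assert r1.gap_csv() == r2.gap_csv()
        assert r1.stress_csv() == r2.stress_csv()
        assert r1.manifest["config_hash"] == r2.manifest["config_hash"]

    def test_reports_mirror_clinical_table_layout(self, comparison):
        gap = comparison.gap_report
        assert list(gap.columns) == ["USI", "BSI", "TSI"]
        assert gap.index.names == ["load_case", "site"]
        assert set(gap.index.get_level_values(0)) == set(STANCE_CASES)
        stress = comparison.stress_report
        assert set(stress.index.get_level_values(1)) == {
            "S1_right", "S1_left", "S2_right", "S2_left"}
        assert not gap.isna().any().any()
        assert not stress.isna().any().any()
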
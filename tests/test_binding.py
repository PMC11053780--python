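"""RMSD_BM statistic, panel utilities and the glycosidic torsion."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bbkit.binding import (
    BindingModePanel,
    BindingModeVector,
    FingerprintHistogram,
    TorsionInput,
    binding_heatmap_data,
    fingerprint_rmsd_bm,
    radar_data,
    residue_ranking,
    rmsd_bm,
    rmsd_bm_matrix,
    torsion_angle,
)
from bbkit.errors import DomainError, GeometryError, SchemaError


def vec(ligand_id, values):
    return BindingModeVector(
        ligand_id=ligand_id,
        entries={f"R{i}": v for i, v in enumerate(values)},
    )


energy_vectors = st.lists(st.floats(-30.0, 0.0), min_size=2, max_size=12)


class TestRMSDBM:
    @pytest.mark.parametrize(
        "ligand,published",
        [
            ("Ara-C", 0.878),
            ("2'-deoxycytidine", 1.378),
            ("cytidine", 1.739),
            ("5-azacytidine", 1.622),
        ],
    )
    def test_published_panel_values(self, dck_panel, ligand, published):
        """Native-reference RMSD_BM over the 18-residue kinase panel with
        divisor n−1 = 17 matches the published digits to within the rounding
        envelope of the mixed 2/3-decimal inputs."""
        ref = dck_panel.vector("Ara-C 15PZ")
        res = rmsd_bm(ref, dck_panel.vector(ligand), "n_minus_1")
        assert res.n_used == 17
        assert res.value == pytest.approx(published, abs=1.5e-3)

    def test_equal_vectors_zero_under_every_divisor(self):
        p = vec("p", [-1.0, -2.0, -3.0])
        for mode in ("n", "n_minus_1", "engaged_only"):
            assert rmsd_bm(p, p, mode).value == 0.0

    def test_uniform_shift_under_divisor_n(self):
        p = vec("p", [-1.0, -2.0, -3.0, -4.0])
        q = vec("q", [-1.5, -2.5, -3.5, -4.5])
        assert rmsd_bm(p, q, "n").value == pytest.approx(0.5)

    def test_engaged_only_divisor(self):
        p = vec("p", [-2.0, 0.0, 0.0, 0.0])
        q = vec("q", [0.0, 0.0, -1.0, 0.0])
        res = rmsd_bm(p, q, "engaged_only")
        assert res.n_used == 2
        assert res.value == pytest.approx(math.sqrt((4.0 + 1.0) / 2.0))

    def test_label_mismatch_rejected(self):
        p = vec("p", [-1.0, -2.0])
        q = BindingModeVector(ligand_id="q", entries={"R1": -1.0, "R0": -2.0})
        with pytest.raises(SchemaError):
            rmsd_bm(p, q)

    def test_all_zero_engaged_degenerate(self):
        p = vec("p", [0.0, 0.0])
        with pytest.raises(DomainError):
            rmsd_bm(p, p, "engaged_only")

    @given(p=energy_vectors, q=energy_vectors, r=energy_vectors, c=st.floats(0.1, 5.0))
    @settings(max_examples=100, derandomize=True)
    def test_pseudometric_and_scaling(self, p, q, r, c):
        n = min(len(p), len(q), len(r))
        p, q, r = p[:n], q[:n], r[:n]
        vp, vq, vr = vec("p", p), vec("q", q), vec("r", r)
        dpq = rmsd_bm(vp, vq, "n").value
        dqp = rmsd_bm(vq, vp, "n").value
        assert dpq == pytest.approx(dqp)
        assert rmsd_bm(vp, vp, "n").value == 0.0
        # triangle inequality
        assert rmsd_bm(vp, vr, "n").value <= dpq + rmsd_bm(vq, vr, "n").value + 1e-9
        # absolute homogeneity in the energies
        sp = vec("p", [c * x for x in p])
        sq = vec("q", [c * x for x in q])
        assert rmsd_bm(sp, sq, "n").value == pytest.approx(c * dpq, rel=1e-9, abs=1e-9)


class TestPanelOperations:
    def test_matrix_symmetric_zero_diagonal(self, dck_panel):
        mat = rmsd_bm_matrix(dck_panel, "n_minus_1")
        assert np.allclose(np.diag(mat.values), 0.0)
        assert np.allclose(mat.values, mat.values.T)
        a, b = "Ara-C 15PZ", "cytidine"
        expected = rmsd_bm(
            dck_panel.vector(a), dck_panel.vector(b), "n_minus_1"
        ).value
        assert mat.loc[a, b] == pytest.approx(expected)

    def test_single_ligand_panel(self):
        panel = BindingModePanel(residues=["R0"], ligands=[vec("only", [-1.0])])
        mat = rmsd_bm_matrix(panel)
        assert mat.shape == (1, 1) and mat.iloc[0, 0] == 0.0

    def test_heatmap_difference_mode(self, dck_panel):
        df = binding_heatmap_data(dck_panel, reference_ligand="Ara-C")
        assert (df["Ara-C"] == 0).all()
        # fluorinated analogue binds Arg128 more weakly than cytarabine
        assert df.loc["Arg128", "Gemcitabine"] == pytest.approx(1.49)

    def test_heatmap_absolute_extreme_cell(self, dck_panel):
        df = binding_heatmap_data(dck_panel)
        strongest = df.min().min()
        assert strongest == pytest.approx(-26.063)
        assert df.loc["Phe137", "Gemcitabine 1P62"] == strongest

    def test_heatmap_unknown_reference(self, dck_panel):
        with pytest.raises(LookupError):
            binding_heatmap_data(dck_panel, reference_ligand="nope")

    def test_residue_ranking_leader(self, dck_panel):
        ranked = residue_ranking(dck_panel)
        assert list(ranked.index)[0] == "Phe137"  # stacking residue dominates

    def test_residue_ranking_brute_force(self):
        panel = BindingModePanel(
            residues=["A", "B"],
            ligands=[
                BindingModeVector(ligand_id="x", entries={"A": -1.0, "B": -5.0}),
                BindingModeVector(ligand_id="y", entries={"A": -2.0, "B": -4.0}),
            ],
        )
        ranked = residue_ranking(panel)
        assert list(ranked.index) == ["B", "A"]
        assert ranked["B"] == pytest.approx(-4.5)

    def test_ranking_tie_breaks_alphabetically(self):
        panel = BindingModePanel(
            residues=["Zz", "Aa"],
            ligands=[BindingModeVector(ligand_id="x", entries={"Zz": -1.0, "Aa": -1.0})],
        )
        assert list(residue_ranking(panel).index) == ["Aa", "Zz"]

    def test_radar_polygons_closed_and_lossless(self, dck_panel):
        polys = radar_data(dck_panel)
        assert set(polys) == set(dck_panel.ligand_ids)
        for series in polys.values():
            assert len(series) == len(dck_panel.residues) + 1
            assert series[0] == series[-1]
        assert dict(polys["Ara-C 15PZ"][:-1])["Phe137"] == pytest.approx(-23.73)

    def test_positive_energy_flagged_on_ingest(self):
        with pytest.warns(UserWarning, match="positive interaction energy"):
            vec("odd", [-1.0, 0.5])


class TestFingerprintRMSD:
    def grid(self, weights, structure_id="g"):
        return FingerprintHistogram(
            di_edges=[0.5, 1.0, 1.5],
            de_edges=[0.5, 1.0, 1.5],
            weights=weights,
            structure_id=structure_id,
        )

    def test_identical_grids_zero(self):
        a = self.grid([[10.0, 20.0], [30.0, 40.0]])
        assert fingerprint_rmsd_bm(a, a).value == 0.0

    def test_single_bin_difference(self):
        a = self.grid([[10.0, 20.0], [30.0, 40.0]], "a")
        b = self.grid([[10.0, 20.0], [30.0, 43.0]], "b")
        res = fingerprint_rmsd_bm(a, b, "n")
        assert res.value == pytest.approx(3.0 / math.sqrt(4))

    def test_grid_mismatch(self):
        a = self.grid([[10.0, 20.0], [30.0, 40.0]])
        b = FingerprintHistogram(
            di_edges=[0.0, 1.0, 2.0], de_edges=[0.5, 1.0, 1.5],
            weights=[[10.0, 20.0], [30.0, 40.0]],
        )
        with pytest.raises(SchemaError):
            fingerprint_rmsd_bm(a, b)


class TestTorsion:
    def torsion(self, coords):
        return torsion_angle(TorsionInput(atoms=["a", "b", "c", "d"], coords=coords))

    def test_planar_cis_is_zero(self):
        assert self.torsion(
            [[1, 1, 0], [1, 0, 0], [2, 0, 0], [2, 1, 0]]
        ) == pytest.approx(0.0, abs=1e-9)

    def test_planar_trans_is_180(self):
        assert self.torsion(
            [[1, 1, 0], [1, 0, 0], [2, 0, 0], [2, -1, 0]]
        ) == pytest.approx(180.0)

    @pytest.mark.parametrize("theta", [10.0, 45.0, 77.0, 120.0, 179.0])
    def test_constructed_angle(self, theta):
        """Four points engineered so the dihedral equals theta exactly."""
        c = [
            [1, 0, 0],
            [0, 0, 0],
            [0, 0, 1],
            [math.cos(math.radians(theta)), math.sin(math.radians(theta)), 1],
        ]
        assert self.torsion(c) == pytest.approx(theta, abs=1e-9)
        mirrored = [[p[0], -p[1], p[2]] for p in c]
        assert self.torsion(mirrored) == pytest.approx(-theta, abs=1e-9)

    def test_degenerate_geometry(self):
        with pytest.raises(GeometryError):
            self.torsion([[0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]])
        with pytest.raises(GeometryError):
            self.torsion([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]])
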
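import numpy as np
import pytest

from crossbeta import (
    build_monomer,
    enumerate_assembly_series,
    make_ligand,
    pair_sheets,
    score_structure,
    stack_strands,
)
from crossbeta.structures import IDEAL_DIHEDRALS, NOMINAL_SPACING, _ladder_count

SEQ = "GSTDYGILQINSRWWS"


class TestBuildMonomer:
    def test_beta_strand_geometry(self, monomer_b):
        ca = monomer_b.ca_xyz
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert d.min() > 3.7 and d.max() < 3.9  # trans-peptide virtual bond
        # extended chain: ~3.3-3.8 A rise per residue over 15 virtual bonds
        assert np.linalg.norm(ca[-1] - ca[0]) > 45.0

    @pytest.mark.parametrize("tag", ["B", "H"])
    def test_dihedrals_match_ideals(self, tag):
        m = build_monomer(SEQ, tag)
        phi0, psi0 = IDEAL_DIHEDRALS[tag]
        for phi, psi in m.backbone_dihedrals()[1:-1]:
            assert phi == pytest.approx(phi0, abs=15.0)
            assert psi == pytest.approx(psi0, abs=15.0)

    def test_two_residue_helix_exact(self):
        m = build_monomer("GG", "H")
        dih = m.backbone_dihedrals()
        assert dih[0][1] == pytest.approx(IDEAL_DIHEDRALS["H"][1], abs=1e-9)
        assert dih[1][0] == pytest.approx(IDEAL_DIHEDRALS["H"][0], abs=1e-9)

    def test_deterministic(self, monomer_b):
        again = build_monomer(SEQ, "B")
        assert np.array_equal(monomer_b.xyz, again.xyz)

    def test_rejected_inputs(self, monomer_b):
        with pytest.raises(ValueError):
            build_monomer("GXTD", "B")
        with pytest.raises(ValueError):
            build_monomer(SEQ, "Q")
        with pytest.raises(ValueError):
            build_monomer(SEQ, "N")  # native requires a template
        # template path: reuses the supplied coordinates
        n = build_monomer(SEQ, "N", template=monomer_b)
        assert n.tag == "N" and np.array_equal(n.xyz, monomer_b.xyz)


class TestStackStrands:
    def test_single_strand_is_the_monomer(self, monomer_b):
        asm = stack_strands(monomer_b, 1, "antiparallel", "BA1")
        assert asm.n_strands == 1
        assert np.allclose(asm.strands[0].xyz, monomer_b.xyz)

    def test_four_strands_have_64_residues(self, ba2_sheet):
        assert ba2_sheet.n_residues == 64

    def test_topology_axis_signs(self, monomer_b):
        par = stack_strands(monomer_b, 2, "parallel", "BP")
        anti = stack_strands(monomer_b, 2, "antiparallel", "BA2")
        assert np.dot(*par.strand_axes()) > 0
        assert np.dot(*anti.strand_axes()) < 0

    def test_spacing_near_nominal(self, ba2_sheet):
        assert ba2_sheet.mean_interstrand_spacing() == pytest.approx(
            NOMINAL_SPACING, abs=1.0
        )

    def test_incompatible_tag_phase_rejected(self, monomer_b, monomer_h):
        with pytest.raises(ValueError):
            stack_strands(monomer_h, 2, "antiparallel", "BA1")
        with pytest.raises(ValueError):
            stack_strands(monomer_b, 2, "parallel", "H")
        with pytest.raises(ValueError):
            stack_strands(monomer_b, 2, "parallel", "BA2")

    def test_phase_vectors(self, monomer_b):
        ba1 = stack_strands(monomer_b, 4, "antiparallel", "BA1")
        ba2 = stack_strands(monomer_b, 4, "antiparallel", "BA2")
        assert ba1.phase_vector == (False, False, False, False)
        assert ba2.phase_vector == (False, True, False, True)

    @pytest.mark.parametrize("phase,topo", [("BA2", "antiparallel"), ("BP", "parallel")])
    def test_hbond_ladder_constant_per_interface(self, monomer_b, phase, topo):
        """Each added strand contributes a constant-width backbone ladder."""
        series = enumerate_assembly_series(monomer_b, 5, topo, phase)
        widths = set()
        for asm in series[1:]:
            for i in range(asm.n_strands - 1):
                widths.add(_ladder_count(asm.strands[i], asm.strands[i + 1]))
        assert len(widths) == 1 and min(widths) > 0


class TestAssemblySeries:
    def test_counts_one_to_n(self, ba2_series):
        assert [a.n_strands for a in ba2_series] == [1, 2, 3, 4, 5]

    def test_prefix_property(self, ba2_series):
        for small, big in zip(ba2_series[:-1], ba2_series[1:]):
            for i in range(small.n_strands):
                assert np.allclose(small.strands[i].xyz, big.strands[i].xyz)

    def test_single_element(self, monomer_b):
        series = enumerate_assembly_series(monomer_b, 1, "antiparallel", "BA2")
        assert len(series) == 1

    def test_baa_is_at_least_as_stable_as_fixed_phases(self, monomer_b):
        baa = stack_strands(monomer_b, 4, "antiparallel", "BAa")
        e_baa = score_structure(baa)
        for phase in ("BA1", "BA2"):
            e = score_structure(stack_strands(monomer_b, 4, "antiparallel", phase))
            assert e_baa <= e + 1e-6


class TestPairSheets:
    def test_zero_poses(self, ba2_sheet):
        assert pair_sheets(ba2_sheet, ba2_sheet, n_poses=0, seed=0) == []

    def test_ranked_reproducible_clash_free(self, ba2_sheet):
        cores = pair_sheets(ba2_sheet, ba2_sheet, n_poses=5, seed=42)
        assert 1 <= len(cores) <= 5
        energies = [score_structure(c) for c in cores]
        assert energies == sorted(energies)
        again = pair_sheets(ba2_sheet, ba2_sheet, n_poses=5, seed=42)
        assert np.allclose(cores[0].translation, again[0].translation)
        for c in cores:
            assert c.min_intersheet_distance() >= 2.0
            assert 8.0 - 2.0 <= c.sheet_separation() <= 12.0 + 2.0

    def test_unequal_strand_counts_rejected(self, monomer_b, ba2_sheet):
        two = stack_strands(monomer_b, 2, "antiparallel", "BA2")
        with pytest.raises(ValueError):
            pair_sheets(ba2_sheet, two, n_poses=1, seed=0)


class TestLigands:
    def test_templates(self):
        rosm = make_ligand("rosmarinic-like")
        tht = make_ligand("tht-like")
        assert "donor" in rosm.roles and "acceptor" in rosm.roles
        # ThT-like carries no H-bonding sites at all
        assert set(tht.roles) == {"apolar"}

    def test_custom_requires_roles(self):
        with pytest.raises(ValueError):
            make_ligand("custom")
        with pytest.raises(ValueError):
            make_ligand("unobtainium-like")
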
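import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crossbeta import (
    EnergyLedger,
    average_ledgers,
    classify_ligand,
    delta_e_per_monomer,
    delta_ep_core,
    score_structure,
)
from crossbeta.contacts import ContactMap
from crossbeta.energetics import load_scorer_params
from crossbeta.geometry import rotation_about_axis
from helpers import toy_sites


class TestScorer:
    def test_single_site_scores_zero(self):
        assert score_structure(toy_sites([[0.0, 0.0, 0.0]])) == 0.0

    def test_lj_minimum_is_minus_epsilon(self):
        p = load_scorer_params()
        rmin, eps = p["lj"]["CB"]["rmin"], p["lj"]["CB"]["eps"]
        pair = toy_sites([[0, 0, 0], [rmin, 0, 0]])
        assert score_structure(pair) == pytest.approx(-eps, rel=1e-12)

    def test_clash_penalty_is_finite_and_large(self):
        pair = toy_sites([[0, 0, 0], [0.1, 0, 0]])
        e = score_structure(pair)
        assert np.isfinite(e) and e > 100.0

    def test_brute_force_oracle_equivalence(self, rng):
        """Vectorized scorer equals an explicit double loop over site pairs."""
        p = load_scorer_params()

        def oracle(sites):
            rmin = np.full(len(sites), p["lj"]["CB"]["rmin"])
            eps = np.full(len(sites), p["lj"]["CB"]["eps"])
            total = 0.0
            for i in range(len(sites)):
                for j in range(i + 1, len(sites)):
                    if sites.mol_id[i] == sites.mol_id[j]:
                        continue
                    d = float(np.linalg.norm(sites.xyz[i] - sites.xyz[j]))
                    r = max(d, p["r_floor"])
                    rm = 0.5 * (rmin[i] + rmin[j])
                    x6 = (rm / r) ** 6
                    total += min(
                        np.sqrt(eps[i] * eps[j]) * (x6 * x6 - 2 * x6), p["pair_cap"]
                    )
                    rc = max(d, p["coulomb"]["r_floor"])
                    total += (
                        p["coulomb"]["k"] * sites.charge[i] * sites.charge[j]
                        / (p["coulomb"]["dielectric_slope"] * rc * rc)
                    )
                    h = p["hbond"]
                    if (
                        (sites.donor[i] and sites.acceptor[j])
                        or (sites.donor[j] and sites.acceptor[i])
                    ) and h["r_on"] <= d <= h["r_off"]:
                        taper = min(
                            max((h["r_off"] - d) / (h["r_off"] - h["r_full"]), 0.0), 1.0
                        )
                        total += -h["sidechain_eps"] * taper
            return total

        for _ in range(5):
            n = 3 + int(rng.integers(0, 8))
            sites = toy_sites(
                rng.uniform(-4, 4, size=(n, 3)),
                charges=rng.choice([-1.0, 0.0, 1.0], size=n).tolist(),
                donors=rng.random(n) < 0.4,
                acceptors=rng.random(n) < 0.4,
            )
            assert score_structure(sites) == pytest.approx(oracle(sites), rel=1e-9)

    def test_rigid_motion_invariance(self, ba2_sheet):
        e0 = score_structure(ba2_sheet)
        moved = ba2_sheet.transformed(
            R=rotation_about_axis([1.0, 2.0, 3.0], 37.0), t=np.array([5.0, -3.0, 11.0])
        )
        assert abs(score_structure(moved) - e0) < 1e-6


class TestBookkeeping:
    @pytest.mark.parametrize(
        "En,E1,n,expected",
        [
            (-8.0, -2.0, 4, 0.0),  # additive assembly: no gain
            (-2166.0, -1.9, 4, -539.6),  # per-monomer gain of the 4-strand sheet
            (-10.0, -1.0, 2, -4.0),
        ],
    )
    def test_delta_e_per_monomer(self, En, E1, n, expected):
        assert delta_e_per_monomer(En, E1, n) == pytest.approx(expected, abs=0.05)

    def test_delta_e_literal_reading(self):
        assert delta_e_per_monomer(-10.0, -1.0, 2, literal=True) == -9.0

    def test_delta_e_rejects_bad_n(self):
        with pytest.raises(ValueError):
            delta_e_per_monomer(-10.0, -1.0, 0)

    @pytest.mark.parametrize(
        "core,sheet,expected",
        [(-4211, -2074, -63), (-4300, -2137, -26), (-4307, -2121, -65)],
    )
    def test_pairing_gain_from_printed_energies(self, core, sheet, expected):
        assert delta_ep_core(core, sheet) == expected

    def test_pairing_gain_rounding_discrepancy_row(self):
        # one published row prints -28 where the formula gives -27
        assert delta_ep_core(-4359, -2166) == pytest.approx(-28, abs=1)

    @given(x=st.floats(-1e5, 1e5, allow_nan=False))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_pairing_gain_vanishes_for_additive_core(self, x):
        assert delta_ep_core(2 * x, x) == pytest.approx(0.0, abs=1e-9)

    def test_average_ledgers_reproduces_ba_average(self):
        rows = [
            EnergyLedger("BAa", E_1=0.0, Ep_sheet=-2137, Ep_core=-4300),
            EnergyLedger("BA1", E_1=0.0, Ep_sheet=-2121, Ep_core=-4307),
            EnergyLedger("BA2", E_1=0.0, Ep_sheet=-2166, Ep_core=-4359),
        ]
        avg = average_ledgers(rows, label="BA (avg)").rounded()
        assert avg["Ep_sheet"] == -2141
        assert avg["Ep_core"] == -4322
        assert avg["delta_Ep_core"] == -40

    def test_average_single_and_empty(self):
        one = EnergyLedger("x", E_1=1.0, Ep_sheet=-10, Ep_core=-25)
        assert average_ledgers([one]) is one
        with pytest.raises(ValueError):
            average_ledgers([])

    def test_ledger_identity_holds(self):
        led = EnergyLedger("x", E_1=-2.0, E_n=(-2.0, -10.0), Ep_sheet=-100.0, Ep_core=-230.0)
        assert led.delta_Ep_core == pytest.approx(-30.0)
        assert led.delta_E_n[0] == 0.0  # no gain for a lone monomer


def _map(cells, strands=("A", "B", "C", "D"), length=16):
    counts = np.zeros((len(strands), length, 2), dtype=int)
    for (s, pos, kind), v in cells.items():
        counts[strands.index(s), pos - 1, ContactMap.type_index(kind)] = v
    return ContactMap(strands=tuple(strands), length=length, counts=counts)


class TestClassifyLigand:
    def setup_method(self):
        # core stabilized by the Arg13 column on every strand
        self.core_map = _map({(s, 13, "hbond"): 100 for s in "ABCD"})

    def test_competitive_overlapping_ligand_is_inhibitory(self):
        lig = _map({("A", 13, "hbond"): 30, ("D", 13, "hbond"): 25})
        v = classify_ligand(-59, -40, lig, self.core_map, ligand_name="rosmarinic")
        assert v.energy_competitive and v.call == "inhibitory"

    def test_weak_nonoverlapping_ligand_is_non_inhibitory(self):
        lig = _map({("A", 14, "hbond"): 30, ("D", 14, "hbond"): 25})
        v = classify_ligand(-26, -40, lig, self.core_map, ligand_name="resveratrol")
        assert v.call == "non-inhibitory"

    def test_boundary_with_identical_map_is_inhibitory(self):
        v = classify_ligand(-40, -40, self.core_map, self.core_map)
        assert v.call == "inhibitory" and v.contact_overlap == pytest.approx(1.0)

    def test_no_hbonds_but_competitive_is_indeterminate(self):
        empty = _map({})
        v = classify_ligand(-33, -40, empty, self.core_map, ligand_name="tht")
        assert v.call == "indeterminate"

    def test_shape_mismatch_rejected(self):
        small = _map({}, strands=("A",), length=4)
        with pytest.raises(ValueError):
            classify_ligand(-59, -40, small, self.core_map)

    @given(de=st.floats(-200, 0, allow_nan=False))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_binding_gain(self, de):
        """A more favourable gain can never turn inhibitory into non-inhibitory."""
        lig = _map({(s, 13, "hbond"): 10 for s in "ABCD"})
        v_weak = classify_ligand(de, -40, lig, self.core_map)
        v_strong = classify_ligand(de - 50, -40, lig, self.core_map)
        if v_weak.call == "inhibitory":
            assert v_strong.call == "inhibitory"


class TestGrowthTrend:
    def test_per_monomer_gain_stabilizes_by_fourth_strand(self, ba2_series):
        E1 = score_structure(ba2_series[0])
        dE = [
            delta_e_per_monomer(score_structure(a), E1, n)
            for n, a in enumerate(ba2_series, start=1)
        ]
        assert all(b < a for a, b in zip(dE, dE[1:]))  # monotone gain
        assert abs(dE[4] - dE[3]) < abs(dE[1] - dE[0])  # increments stabilize
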
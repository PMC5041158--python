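"""Coarse-grained energy scoring, assembly-energy bookkeeping and the
ligand-competition classifier.

The scorer is a stand-in potential over interaction sites: Lennard-Jones
terms with per-role radii and depths, screened Coulomb with a
distance-dependent dielectric, and a directional backbone hydrogen-bond
bonus.  Its absolute energies are on their own scale — what the pipeline
relies on are the bookkeeping identities (per-monomer gain, sheet-pairing
gain) and the orderings and trends they imply.

Bookkeeping definitions::

    dE_n      = (E_n - n * E_1) / n      per-monomer gain of an n-strand sheet
    dEp_core  = Ep_core - 2 * Ep_sheet   gain of pairing two sheets into a core

A ligand competes with core formation when its binding gain is at least
comparable to the sheet-pairing gain, *and* its hydrogen-bond contact map
overlaps the positions that stabilize the core.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .sequence import RESIDUE_DATA
from .structures import SiteArray, as_sites

__all__ = [
    "EnergyLedger",
    "LigandVerdict",
    "load_scorer_params",
    "score_structure",
    "delta_e_per_monomer",
    "delta_ep_core",
    "average_ledgers",
    "ligand_binding_gain",
    "classify_ligand",
    "ENERGY_TOLERANCE",
    "OVERLAP_THRESHOLD",
]

#: "Comparable" window for the energy-competition criterion (kcal/mol).
ENERGY_TOLERANCE = 20.0
#: Minimum contact-map cosine overlap for an inhibitory call.
OVERLAP_THRESHOLD = 0.3

_params_cache: dict = {}


def load_scorer_params(path: str | Path | None = None) -> dict:
    """Load the versioned scorer parameter set (cached per path)."""
    key = str(path) if path else "__default__"
    if key not in _params_cache:
        if path is None:
            text = resources.files("crossbeta").joinpath("scorer_params.yaml").read_text()
        else:
            text = Path(path).read_text()
        _params_cache[key] = yaml.safe_load(text)
    return _params_cache[key]


def _site_lj(sites: SiteArray, params: dict) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (rmin, eps); eps 0 disables LJ for that site (amide H)."""
    lj = params["lj"]
    names = np.asarray(sites.atom_name)
    n = len(sites)
    rmin = np.zeros(n)
    eps = np.zeros(n)
    for a in ("N", "CA", "C", "O", "CB"):
        m = names == a
        rmin[m] = lj[a]["rmin"]
        eps[m] = lj[a]["eps"]
    sc = names == "SC"
    if sc.any():
        rmin[sc] = [RESIDUE_DATA[r]["radius"] for r in sites.res_name[sc]]
        eps[sc] = np.where(sites.aromatic[sc], lj["sc_eps_aromatic"], lj["sc_eps_polar"])
    is_lig = sites.strand == "L"
    if is_lig.any():
        rmin[is_lig] = lj["ligand"]["rmin"]
        eps[is_lig] = np.where(
            sites.aromatic[is_lig], lj["ligand"]["eps_apolar"], lj["ligand"]["eps_polar"]
        )
    return rmin, eps


def _pair_mask(sites: SiteArray) -> np.ndarray:
    """Upper-triangle mask of scorable pairs (bonded/intra-rigid excluded).

    Excluded: same residue of the same strand, adjacent residues of the same
    strand (bonded backbone), and any intra-ligand pair (rigid body).
    """
    n = len(sites)
    iu, ju = np.triu_indices(n, k=1)
    same_mol = sites.mol_id[iu] == sites.mol_id[ju]
    is_lig = np.array([s == "L" for s in sites.strand])
    lig_pair = same_mol & (is_lig[iu] | is_lig[ju])
    near = same_mol & (np.abs(sites.res_index[iu] - sites.res_index[ju]) <= 1)
    keep = ~(lig_pair | near)
    return iu[keep], ju[keep]


def score_structure(structure, params_path: str | Path | None = None) -> float:
    """Total coarse energy (kcal/mol) of a structure or raw :class:`SiteArray`.

    Deterministic, translation/rotation invariant; overlapping sites give a
    large finite positive penalty, never a non-finite value.
    """
    params = load_scorer_params(params_path)
    sites = as_sites(structure)
    n = len(sites)
    if n < 2:
        return 0.0
    iu, ju = _pair_mask(sites)
    if len(iu) == 0:
        return 0.0

    d = np.linalg.norm(sites.xyz[iu] - sites.xyz[ju], axis=1)

    rmin, eps = _site_lj(sites, params)
    lj_pairs = (eps[iu] > 0) & (eps[ju] > 0)
    r = np.maximum(d, params["r_floor"])
    rm = 0.5 * (rmin[iu] + rmin[ju])
    ep = np.sqrt(eps[iu] * eps[ju])
    x6 = (rm / r) ** 6
    e_lj = np.where(lj_pairs, ep * (x6 * x6 - 2.0 * x6), 0.0)
    e_lj = np.minimum(e_lj, params["pair_cap"])

    cpar = params["coulomb"]
    q = sites.charge
    qq = q[iu] * q[ju]
    rc = np.maximum(d, cpar["r_floor"])
    e_coul = cpar["k"] * qq / (cpar["dielectric_slope"] * rc * rc)
    e_coul = np.clip(e_coul, -params["pair_cap"], params["pair_cap"])

    e_hb = _hbond_energy(sites, iu, ju, d, params["hbond"])

    return float(e_lj.sum() + e_coul.sum() + e_hb.sum())


class CrossPotential:
    """Precomputed rigid-body interaction between two site sets.

    Evaluates only the cross terms (LJ + screened Coulomb + H-bond bonus)
    between group A and group B, which is exactly the part of the total
    energy that changes when one rigid body moves relative to the other.
    Used by the pose searches, where the same pair topology is scored many
    times at different relative placements.
    """

    def __init__(self, sitesA: SiteArray, sitesB: SiteArray, params_path=None):
        params = load_scorer_params(params_path)
        self.params = params
        self.A = sitesA
        self.B = sitesB
        ra, ea = _site_lj(sitesA, params)
        rb, eb = _site_lj(sitesB, params)
        self.lj_ok = (ea[:, None] > 0) & (eb[None, :] > 0)
        self.rm = 0.5 * (ra[:, None] + rb[None, :])
        self.ep = np.sqrt(ea[:, None] * eb[None, :])
        self.qq = sitesA.charge[:, None] * sitesB.charge[None, :]
        self.hb_ab = sitesA.donor[:, None] & sitesB.acceptor[None, :]
        self.hb_ba = sitesA.acceptor[:, None] & sitesB.donor[None, :]
        self.bb = sitesA.backbone[:, None] & sitesB.backbone[None, :]

    def energy(self, xyzA: np.ndarray, xyzB: np.ndarray) -> float:
        p = self.params
        diff = xyzA[:, None, :] - xyzB[None, :, :]
        d = np.sqrt((diff * diff).sum(axis=-1))
        r = np.maximum(d, p["r_floor"])
        x6 = (self.rm / r) ** 6
        e_lj = np.where(self.lj_ok, self.ep * (x6 * x6 - 2.0 * x6), 0.0)
        e_lj = np.minimum(e_lj, p["pair_cap"])
        cpar = p["coulomb"]
        rc = np.maximum(d, cpar["r_floor"])
        e_c = cpar["k"] * self.qq / (cpar["dielectric_slope"] * rc * rc)
        hpar = p["hbond"]
        elig = self.hb_ab | self.hb_ba
        inwin = elig & (d >= hpar["r_on"]) & (d <= hpar["r_off"])
        taper = np.clip(
            (hpar["r_off"] - d) / (hpar["r_off"] - hpar["r_full"]), 0.0, 1.0
        )
        strength = np.where(self.bb, hpar["backbone_eps"], hpar["sidechain_eps"])
        e_hb = np.where(inwin, -strength * taper, 0.0)
        return float(e_lj.sum() + e_c.sum() + e_hb.sum())


def _hbond_energy(sites, iu, ju, d, hpar):
    don_i = sites.donor[iu] & sites.acceptor[ju]
    don_j = sites.donor[ju] & sites.acceptor[iu]
    pair = (don_i | don_j) & (d >= hpar["r_on"]) & (d <= hpar["r_off"])
    if not pair.any():
        return np.zeros(0)
    idx = np.where(pair)[0]
    di = np.where(don_i[idx], iu[idx], ju[idx])
    ai = np.where(don_i[idx], ju[idx], iu[idx])
    taper = np.clip((hpar["r_off"] - d[idx]) / (hpar["r_off"] - hpar["r_full"]), 0.0, 1.0)

    strength = np.where(
        sites.backbone[di] & sites.backbone[ai],
        hpar["backbone_eps"],
        hpar["sidechain_eps"],
    )
    # directional factor for backbone donors with an explicit amide H
    ang = np.ones(len(idx))
    hp = sites.h_partner[di]
    has_h = hp >= 0
    if has_h.any():
        dvec = sites.xyz[ai[has_h]] - sites.xyz[hp[has_h]]
        nvec = sites.xyz[hp[has_h]] - sites.xyz[di[has_h]]
        cos = np.einsum("ij,ij->i", dvec, nvec) / (
            np.linalg.norm(dvec, axis=1) * np.linalg.norm(nvec, axis=1) + 1e-12
        )
        ang[has_h] = np.clip(cos, 0.0, 1.0) ** 2
    return -strength * taper * ang


# ---------------------------------------------------------------------------
# bookkeeping


def delta_e_per_monomer(E_n: float, E_1: float, n: int, literal: bool = False) -> float:
    """Per-monomer energy gain of an n-strand assembly.

    The standard reading is ``(E_n - n * E_1) / n``: the assembly energy less
    what n isolated monomers would contribute, normalized per monomer.  The
    ``literal`` flag instead evaluates ``E_n - (E_1 * n) / n``, i.e. simply
    ``E_n - E_1``, kept for comparison.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if literal:
        return float(E_n - (E_1 * n) / n)
    return float((E_n - n * E_1) / n)


def delta_ep_core(Ep_core: float, Ep_sheet: float) -> float:
    """Sheet-pairing gain: Ep_core - 2 * Ep_sheet (kcal/mol)."""
    if not (np.isfinite(Ep_core) and np.isfinite(Ep_sheet)):
        raise ValueError("energies must be finite")
    return float(Ep_core - 2.0 * Ep_sheet)


@dataclass(frozen=True)
class EnergyLedger:
    """Per-assembly energies with derived gains (kcal/mol).

    ``delta_E_n`` is recomputed from ``E_n`` / ``E_1`` and ``delta_Ep_core``
    from ``Ep_core`` / ``Ep_sheet``, so the stored gains always satisfy the
    defining identities (up to the reporting rounding policy).
    """

    label: str
    E_1: float
    E_n: tuple = ()
    Ep_sheet: float = float("nan")
    Ep_core: float = float("nan")
    uncertainty: dict = field(default_factory=dict)

    @property
    def delta_E_n(self) -> tuple:
        return tuple(
            delta_e_per_monomer(e, self.E_1, n)
            for n, e in enumerate(self.E_n, start=1)
        )

    @property
    def delta_Ep_core(self) -> float:
        return delta_ep_core(self.Ep_core, self.Ep_sheet)

    def rounded(self) -> dict:
        """Report-ready dict, nearest-integer kcal/mol.

        The pairing gain is recomputed from the *rounded* Ep fields, so a
        reported row is always internally consistent (gain = core - 2*sheet
        holds exactly on the printed integers).
        """
        ep_sheet = int(round(self.Ep_sheet))
        ep_core = int(round(self.Ep_core))
        return {
            "label": self.label,
            "Ep_sheet": ep_sheet,
            "Ep_core": ep_core,
            "delta_Ep_core": ep_core - 2 * ep_sheet,
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "label": self.label,
            "E_1": self.E_1,
            "E_n": list(self.E_n),
            "delta_E_n": list(self.delta_E_n),
            "Ep_sheet": self.Ep_sheet,
            "Ep_core": self.Ep_core,
            "delta_Ep_core": self.delta_Ep_core,
            "uncertainty": self.uncertainty,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def average_ledgers(ledgers: list[EnergyLedger], label: str = "avg") -> EnergyLedger:
    """Arithmetic mean per field; the pairing gain of the average is
    recomputed from the averaged Ep fields (not averaged itself)."""
    if not ledgers:
        raise ValueError("need at least one ledger")
    if len(ledgers) == 1:
        return ledgers[0]
    n_series = {len(l.E_n) for l in ledgers}
    if len(n_series) != 1:
        raise ValueError("ledgers have incongruent E_n series")
    E_n = tuple(
        float(np.mean([l.E_n[i] for l in ledgers])) for i in range(n_series.pop())
    )
    return EnergyLedger(
        label=label,
        E_1=float(np.mean([l.E_1 for l in ledgers])),
        E_n=E_n,
        Ep_sheet=float(np.mean([l.Ep_sheet for l in ledgers])),
        Ep_core=float(np.mean([l.Ep_core for l in ledgers])),
    )


# ---------------------------------------------------------------------------
# ligand competition


def ligand_binding_gain(assembly, ligand_pose) -> float:
    """Binding gain of a posed ligand: E(complex) - E(assembly) (kcal/mol).

    The ligand is rigid (no internal energy), so the difference is exactly
    the ligand-assembly interaction energy.
    """
    from .structures import _with_ligand

    return score_structure(_with_ligand(assembly, ligand_pose)) - score_structure(
        assembly
    )


@dataclass(frozen=True)
class LigandVerdict:
    """Outcome of the energy-competition test for one ligand."""

    ligand: str
    delta_ep_ligand: float
    reference_delta_ep_core: float
    energy_competitive: bool
    contact_overlap: float
    call: str  # 'inhibitory' | 'non-inhibitory' | 'indeterminate'

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


def classify_ligand(
    ligand_delta_ep: float,
    reference_delta_ep_core: float,
    ligand_map,
    core_map,
    ligand_name: str = "ligand",
    tolerance: float = ENERGY_TOLERANCE,
    overlap_threshold: float = OVERLAP_THRESHOLD,
) -> LigandVerdict:
    """Energy-competition classifier for a candidate aggregation inhibitor.

    A ligand is *energy-competitive* when its binding gain is at least
    comparable to the sheet-pairing gain of the core
    (``delta_ep_ligand <= reference + tolerance``, gains being negative).
    The *contact overlap* is the cosine similarity between the ligand's
    hydrogen-bond map and the core's sheet-sheet hydrogen-bond map
    restricted to the core's stabilizing cells (counts >= half the maximum).

    Calls: ``inhibitory`` needs both energy competitiveness and overlap at
    or above the threshold.  A competitive ligand that formed *no* hydrogen
    bonds at all is ``indeterminate`` (binding energy alone cannot place it
    in the competition mechanism — the ThT case).  Everything else is
    ``non-inhibitory``.
    """
    from .contacts import ContactMap

    if not isinstance(ligand_map, ContactMap) or not isinstance(core_map, ContactMap):
        raise TypeError("maps must be ContactMap instances")
    if ligand_map.counts.shape != core_map.counts.shape:
        raise ValueError("contact maps have mismatched shapes")

    competitive = ligand_delta_ep <= reference_delta_ep_core + tolerance

    lig_hb = ligand_map.counts[:, :, ligand_map.type_index("hbond")].astype(float)
    core_hb = core_map.counts[:, :, core_map.type_index("hbond")].astype(float)
    overlap = _stabilizing_overlap(lig_hb, core_hb)

    if competitive and overlap >= overlap_threshold:
        call = "inhibitory"
    elif competitive and lig_hb.sum() == 0:
        call = "indeterminate"
    else:
        call = "non-inhibitory"
    return LigandVerdict(
        ligand=ligand_name,
        delta_ep_ligand=float(ligand_delta_ep),
        reference_delta_ep_core=float(reference_delta_ep_core),
        energy_competitive=bool(competitive),
        contact_overlap=float(overlap),
        call=call,
    )


def _stabilizing_overlap(lig_hb: np.ndarray, core_hb: np.ndarray) -> float:
    """Cosine similarity on the core's stabilizing cells (>= half its max)."""
    if core_hb.max() <= 0:
        return 0.0
    mask = core_hb >= 0.5 * core_hb.max()
    a = lig_hb[mask].ravel()
    b = core_hb[mask].ravel()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))
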
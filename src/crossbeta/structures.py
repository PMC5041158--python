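"""Idealized peptide conformers, beta-sheet assemblies and cross-beta cores.

The builder follows the classic amyloid "steric zipper" picture: extended
16-mer strands are stacked into a hydrogen-bonded beta-sheet (parallel or
antiparallel, with a chosen up/down side-chain phase per strand), and two
such sheets are paired face to face to form the fibril core.  Side chains
are coarse-grained to Cbeta plus a single centroid pseudo-site per residue;
this is enough to reproduce residue-resolution contact statistics and
energy bookkeeping, which is all the downstream analysis needs.

Sheet variants follow the field's naming:

======  ==========================================================
BP      all strands parallel, side chains in phase
BA1     antiparallel, all strands with the same side-chain phase
BA2     antiparallel, alternating side-chain phase strand to strand
BAa     antiparallel, per-strand phases chosen by exhaustive
        energy minimization over the 2**n up/down combinations
N / H   reference stacks of native-template or alpha-helical monomers
======  ==========================================================
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import dihedral, kabsch_frame, place_atom, rotation_about_axis
from .sequence import RESIDUE_DATA, PeptideSequence

__all__ = [
    "Conformer",
    "SheetAssembly",
    "CoreModel",
    "LigandPose",
    "SiteArray",
    "IDEAL_DIHEDRALS",
    "NOMINAL_SPACING",
    "CLASH_FLOOR",
    "build_monomer",
    "stack_strands",
    "enumerate_assembly_series",
    "pair_sheets",
    "make_ligand",
    "place_ligand",
    "as_sites",
]

#: Ideal backbone dihedrals (phi, psi) in degrees per conformation tag.
IDEAL_DIHEDRALS = {"B": (-139.0, 135.0), "H": (-57.0, -47.0)}

#: Nominal inter-strand Calpha-Calpha spacing of a beta-sheet (A).
NOMINAL_SPACING = 4.8
#: Larger axial spacing used for the reference helix / native stacks (A).
STACK_SPACING = {"H": 10.0, "N": 10.0}
#: Minimum allowed heavy-atom distance between rigid bodies (A).
CLASH_FLOOR = 2.0
#: Allowed window for the mean-plane separation of the two core sheets (A).
SHEET_SEPARATION_WINDOW = (8.0, 12.0)

# backbone bond geometry (A / degrees), trans peptide
_B_NC = 1.329
_B_NCA = 1.458
_B_CAC = 1.525
_B_CO = 1.231
_B_NH = 1.010
_B_CACB = 1.530
_A_CNCA = 121.7
_A_NCAC = 111.2
_A_CACN = 116.2
_A_CACO = 120.5
_A_CNH = 119.0
_OMEGA = 180.0

_LIGAND_ROLES = ("donor", "acceptor", "apolar")


# ---------------------------------------------------------------------------
# flat site table


@dataclass
class SiteArray:
    """Flat per-site topology + coordinates shared by scoring and contacts.

    One row per interaction site (backbone heavy atoms, amide H, Cbeta,
    side-chain centroid, or ligand site).  ``mol_id`` identifies the rigid
    unit a site belongs to (one id per strand; ligands get their own id),
    which drives bonded-pair exclusions in the scorer.
    """

    xyz: np.ndarray
    strand: np.ndarray
    res_index: np.ndarray
    res_name: np.ndarray
    atom_name: np.ndarray
    mol_id: np.ndarray
    heavy: np.ndarray
    charge: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    backbone: np.ndarray
    aromatic: np.ndarray
    h_partner: np.ndarray  # index of the amide H of a backbone N donor, else -1

    def __len__(self) -> int:
        return len(self.xyz)

    def with_coords(self, xyz: np.ndarray) -> "SiteArray":
        if xyz.shape != self.xyz.shape:
            raise ValueError("coordinate shape mismatch")
        return replace(self, xyz=np.asarray(xyz, dtype=float))

    @staticmethod
    def concat(parts: list["SiteArray"]) -> "SiteArray":
        offset = 0
        hs = []
        for p in parts:
            h = p.h_partner.copy()
            h[h >= 0] += offset
            hs.append(h)
            offset += len(p)
        return SiteArray(
            xyz=np.concatenate([p.xyz for p in parts]),
            strand=np.concatenate([p.strand for p in parts]),
            res_index=np.concatenate([p.res_index for p in parts]),
            res_name=np.concatenate([p.res_name for p in parts]),
            atom_name=np.concatenate([p.atom_name for p in parts]),
            mol_id=np.concatenate([p.mol_id for p in parts]),
            heavy=np.concatenate([p.heavy for p in parts]),
            charge=np.concatenate([p.charge for p in parts]),
            donor=np.concatenate([p.donor for p in parts]),
            acceptor=np.concatenate([p.acceptor for p in parts]),
            backbone=np.concatenate([p.backbone for p in parts]),
            aromatic=np.concatenate([p.aromatic for p in parts]),
            h_partner=np.concatenate(hs),
        )


# ---------------------------------------------------------------------------
# conformer


@dataclass(frozen=True)
class Conformer:
    """One peptide monomer in a tagged conformation with explicit sites."""

    sequence: PeptideSequence
    tag: str
    atom_name: tuple
    res_index: np.ndarray
    xyz: np.ndarray

    @property
    def ca_xyz(self) -> np.ndarray:
        mask = np.array([a == "CA" for a in self.atom_name])
        return self.xyz[mask]

    @property
    def axis(self) -> np.ndarray:
        ca = self.ca_xyz
        v = ca[-1] - ca[0]
        return v / np.linalg.norm(v)

    def transformed(self, R: np.ndarray = None, t: np.ndarray = None) -> "Conformer":
        xyz = self.xyz
        if R is not None:
            xyz = xyz @ np.asarray(R).T
        if t is not None:
            xyz = xyz + np.asarray(t)
        return replace(self, xyz=xyz)

    def backbone_dihedrals(self) -> list[tuple[float, float]]:
        """(phi, psi) per residue; terminal phi/psi are NaN."""
        idx = {}
        for i, (name, r) in enumerate(zip(self.atom_name, self.res_index)):
            idx[(int(r), name)] = i
        L = len(self.sequence)
        out = []
        for r in range(1, L + 1):
            phi = psi = float("nan")
            if r > 1:
                phi = dihedral(
                    self.xyz[idx[(r - 1, "C")]],
                    self.xyz[idx[(r, "N")]],
                    self.xyz[idx[(r, "CA")]],
                    self.xyz[idx[(r, "C")]],
                )
            if r < L:
                psi = dihedral(
                    self.xyz[idx[(r, "N")]],
                    self.xyz[idx[(r, "CA")]],
                    self.xyz[idx[(r, "C")]],
                    self.xyz[idx[(r + 1, "N")]],
                )
            out.append((phi, psi))
        return out


def build_monomer(
    seq: PeptideSequence | str,
    tag: str,
    template: "Conformer | None" = None,
) -> Conformer:
    """Build one peptide monomer in conformation *tag*.

    tag ``B`` (beta-strand) and ``H`` (alpha-helix) are constructed from the
    ideal backbone dihedrals in :data:`IDEAL_DIHEDRALS`; tag ``N`` (native)
    is template-derived only — pass the template conformer read from a
    coordinate file.  Deterministic: identical inputs give bit-identical
    coordinates.
    """
    if not isinstance(seq, PeptideSequence):
        seq = PeptideSequence(seq)
    if tag not in ("N", "H", "B"):
        raise ValueError(f"unknown conformation tag {tag!r}")
    if tag == "N":
        if template is None:
            raise ValueError("tag 'N' requires a template conformer")
        if template.sequence.residues != seq.residues:
            raise ValueError("template sequence does not match")
        return replace(template, tag="N")

    phi, psi = IDEAL_DIHEDRALS[tag]
    L = len(seq)

    # backbone trace via NeRF
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_NCA, 0.0, 0.0])]
    ang = np.deg2rad(180.0 - _A_NCAC)
    C = [CA[0] + _B_CAC * np.array([np.cos(ang), np.sin(ang), 0.0])]
    for i in range(1, L):
        N.append(place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_NC, _A_CACN, psi))
        CA.append(place_atom(CA[i - 1], C[i - 1], N[i], _B_NCA, _A_CNCA, _OMEGA))
        C.append(place_atom(C[i - 1], N[i], CA[i], _B_CAC, _A_NCAC, phi))

    atom_name: list[str] = []
    res_index: list[int] = []
    xyz: list[np.ndarray] = []

    def add(r, name, pos):
        res_index.append(r)
        atom_name.append(name)
        xyz.append(np.asarray(pos, dtype=float))

    for i in range(L):
        r = i + 1
        aa = seq[r]
        add(r, "N", N[i])
        if i == 0:
            H = place_atom(C[0], CA[0], N[0], _B_NH, 109.5, 180.0)
        else:
            O_prev = place_atom(N[i], CA[i - 1], C[i - 1], _B_CO, _A_CACO, 180.0)
            H = place_atom(O_prev, C[i - 1], N[i], _B_NH, _A_CNH, 180.0)
        if aa != "P":
            add(r, "H", H)
        add(r, "CA", CA[i])
        add(r, "C", C[i])
        # carbonyl O trans to the next amide N (psi + 180)
        O = place_atom(N[i], CA[i], C[i], _B_CO, _A_CACO, psi + 180.0)
        add(r, "O", O)
        data = RESIDUE_DATA[aa]
        if aa != "G":
            # L-configuration Cbeta off the N-C-CA improper
            CB = place_atom(N[i], C[i], CA[i], _B_CACB, 110.5, 122.6)
            add(r, "CB", CB)
            if data["sc_dist"] > 1.6:
                u = CB - CA[i]
                u = u / np.linalg.norm(u)
                add(r, "SC", CA[i] + data["sc_dist"] * u)

    xyz_arr = np.array(xyz)

    # canonical frame: centroid at origin, N->C axis on +x, H-bond dir on +y
    co = np.array(
        [
            xyz_arr[j] - C[r - 1]
            for j, (r, name) in enumerate(zip(res_index, atom_name))
            if name == "O"
        ]
    )
    origin, R = kabsch_frame(np.array(CA), co)
    xyz_arr = (xyz_arr - origin) @ R.T

    return Conformer(
        sequence=seq,
        tag=tag,
        atom_name=tuple(atom_name),
        res_index=np.array(res_index, dtype=int),
        xyz=xyz_arr,
    )


# ---------------------------------------------------------------------------
# sheet assembly


_PHASES = ("BP", "BA1", "BA2", "BAa", "N", "H")
_STRAND_LABELS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class SheetAssembly:
    """Ordered strands with topology and side-chain phase."""

    strands: tuple
    topology: str  # 'parallel' | 'antiparallel'
    phase: str  # one of _PHASES
    spacing: float
    phase_vector: tuple

    @property
    def labels(self) -> tuple:
        return tuple(_STRAND_LABELS[i] for i in range(len(self.strands)))

    @property
    def n_strands(self) -> int:
        return len(self.strands)

    @property
    def sequence(self) -> PeptideSequence:
        return self.strands[0].sequence

    @property
    def n_residues(self) -> int:
        return sum(len(s.sequence) for s in self.strands)

    def strand_axes(self) -> np.ndarray:
        return np.array([s.axis for s in self.strands])

    def mean_interstrand_spacing(self) -> float:
        """Mean over adjacent strand pairs of the mean nearest-Calpha distance."""
        if self.n_strands < 2:
            return float("nan")
        vals = []
        for a, b in zip(self.strands[:-1], self.strands[1:]):
            d = np.linalg.norm(a.ca_xyz[:, None, :] - b.ca_xyz[None, :, :], axis=-1)
            vals.append(d.min(axis=1).mean())
        return float(np.mean(vals))

    def mean_plane_point_normal(self) -> tuple[np.ndarray, np.ndarray]:
        """Best-fit plane of all Calpha positions (point, unit normal)."""
        ca = np.concatenate([s.ca_xyz for s in self.strands])
        centroid = ca.mean(axis=0)
        _, _, vt = np.linalg.svd(ca - centroid)
        return centroid, vt[2]

    def transformed(self, R=None, t=None) -> "SheetAssembly":
        return replace(
            self, strands=tuple(s.transformed(R, t) for s in self.strands)
        )


def _phase_vector(phase: str, n: int) -> tuple:
    if phase in ("BP", "BA1", "N", "H"):
        return tuple(False for _ in range(n))
    if phase == "BA2":
        return tuple(k % 2 == 1 for k in range(n))
    raise ValueError(f"no fixed phase rule for {phase!r}")


def _posed_strand(monomer, k, antiparallel, flip_phase, dx, dy):
    """Strand ``k``: optional topology/phase flips, then translate to its slot."""
    c = monomer
    if antiparallel and k % 2 == 1:
        c = c.transformed(R=rotation_about_axis([0.0, 0.0, 1.0], 180.0))
    if flip_phase:
        c = c.transformed(R=rotation_about_axis([1.0, 0.0, 0.0], 180.0))
    return c.transformed(t=np.array([dx, dy, 0.0]))


def _backbone_no_pairs(strand_a: Conformer, strand_b: Conformer):
    """Donor-N / acceptor-O cross distances between two strands."""
    def pick(c, name):
        mask = np.array([a == name for a in c.atom_name])
        return c.xyz[mask]

    d1 = np.linalg.norm(
        pick(strand_a, "N")[:, None, :] - pick(strand_b, "O")[None, :, :], axis=-1
    )
    d2 = np.linalg.norm(
        pick(strand_b, "N")[:, None, :] - pick(strand_a, "O")[None, :, :], axis=-1
    )
    return d1, d2


def _ladder_count(strand_a, strand_b, cutoff=3.0) -> int:
    d1, d2 = _backbone_no_pairs(strand_a, strand_b)
    return int((d1 < cutoff).sum() + (d2 < cutoff).sum())


def _pair_energy(strand_a: Conformer, strand_b: Conformer) -> float:
    from .energetics import score_structure

    pair = SiteArray.concat(
        [_conformer_sites(strand_a, 0, 0), _conformer_sites(strand_b, 1, 1)]
    )
    return score_structure(pair)


_registry_cache: dict = {}


def _best_registry(monomer, prev_strand, prev_dx, k, prev_flip, antiparallel, flip_phase, spacing):
    """Scan in-plane offsets for the strand-k slot minimizing the pair energy.

    The scan emulates the registry search a docking step performs: the new
    strand slides along the strand axis (dx) and breathes about the nominal
    spacing (dy) until the backbone donor/acceptor ladder locks in without
    steric clashes.  Ties prefer the offset closest to (0, nominal spacing).
    Deterministic; results are cached per relative pair geometry (which is
    translation invariant), so repeated interfaces cost one scan.
    """
    key = (
        monomer.sequence.residues, monomer.tag, antiparallel,
        (k - 1) % 2, prev_flip, k % 2, flip_phase, round(spacing, 3),
    )
    prev_y = float(np.mean(prev_strand.ca_xyz[:, 1]))
    if key in _registry_cache:
        rel_dx, dy = _registry_cache[key]
        return (
            _posed_strand(
                monomer, k, antiparallel, flip_phase, prev_dx + rel_dx, prev_y + dy
            ),
            prev_dx + rel_dx,
        )
    dxs = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.25), 3)
    dys = np.round(np.arange(spacing - 0.5, spacing + 0.5 + 1e-9, 0.1), 3)
    best = None
    for rel_dx in sorted(dxs, key=lambda v: (abs(v), v)):
        for dy in sorted(dys, key=lambda v: (abs(v - spacing), v)):
            cand = _posed_strand(
                monomer, k, antiparallel, flip_phase, prev_dx + rel_dx, prev_y + dy
            )
            e = _pair_energy(prev_strand, cand)
            if best is None or e < best[0] - 1e-9:
                best = (e, cand, rel_dx, dy)
    _registry_cache[key] = (best[2], best[3])
    return best[1], prev_dx + best[2]


def stack_strands(
    monomer: Conformer,
    n: int,
    topology: str,
    phase: str,
    spacing: float = None,
    phase_vector: tuple | None = None,
    optimize_registry: bool = True,
) -> SheetAssembly:
    """Stack *n* copies of *monomer* into a sheet of the requested variant.

    ``topology`` is ``"parallel"`` or ``"antiparallel"`` (``"BP"``/``"BA"``
    accepted as aliases); ``phase`` selects the side-chain phase rule.  The
    monomer tag must be compatible: B for the beta phases, H/N for the
    reference stacks.  Strands are added one by one; each new strand's
    in-plane registry is optimized against its predecessor, so an n-strand
    assembly literally contains the (n-1)-strand one as a prefix.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    topo_alias = {"BP": "parallel", "BA": "antiparallel"}
    topology = topo_alias.get(topology, topology)
    if topology not in ("parallel", "antiparallel"):
        raise ValueError(f"unknown topology {topology!r}")
    if phase not in _PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    required_tag = {"BP": "B", "BA1": "B", "BA2": "B", "BAa": "B", "N": "N", "H": "H"}
    if monomer.tag != required_tag[phase]:
        raise ValueError(
            f"monomer tag {monomer.tag!r} incompatible with phase {phase!r}"
        )
    if phase == "BP" and topology != "parallel":
        raise ValueError("phase 'BP' requires parallel topology")
    if phase in ("BA1", "BA2", "BAa") and topology != "antiparallel":
        raise ValueError(f"phase {phase!r} requires antiparallel topology")

    if spacing is None:
        spacing = STACK_SPACING.get(phase, NOMINAL_SPACING)
    antiparallel = topology == "antiparallel"

    if phase == "BAa":
        if phase_vector is None:
            return _stack_baa(monomer, n, spacing, optimize_registry)
        pv = tuple(bool(p) for p in phase_vector)
    else:
        pv = _phase_vector(phase, n)
    if len(pv) != n:
        raise ValueError("phase_vector length mismatch")

    strands = [_posed_strand(monomer, 0, antiparallel, pv[0], 0.0, 0.0)]
    dx = 0.0
    for k in range(1, n):
        if phase in ("N", "H") or not optimize_registry:
            prev_y = float(np.mean(strands[-1].ca_xyz[:, 1]))
            strands.append(
                _posed_strand(monomer, k, antiparallel, pv[k], 0.0, prev_y + spacing)
            )
        else:
            cand, dx = _best_registry(
                monomer, strands[-1], dx, k, pv[k - 1], antiparallel, pv[k], spacing
            )
            strands.append(cand)

    return SheetAssembly(
        strands=tuple(strands),
        topology=topology,
        phase=phase,
        spacing=spacing,
        phase_vector=pv,
    )


def _stack_baa(monomer, n, spacing, optimize_registry):
    """Exhaustive up/down phase search for the BAa variant (n <= 6)."""
    if n > 6:
        raise ValueError("BAa exhaustive phase search supports at most 6 strands")
    from .energetics import score_structure  # deferred: avoids import cycle

    best = None
    for pv in itertools.product((False, True), repeat=n):
        asm = stack_strands(
            monomer, n, "antiparallel", "BAa",
            spacing=spacing, phase_vector=pv, optimize_registry=optimize_registry,
        )
        e = score_structure(asm)
        if best is None or e < best[0] - 1e-9:
            best = (e, asm)
    return best[1]


def enumerate_assembly_series(
    monomer: Conformer,
    n_max: int,
    topology: str,
    phase: str,
    **kwargs,
) -> list[SheetAssembly]:
    """Assemblies for n = 1..n_max sharing geometry (for growth-energy curves).

    Elements are prefixes of one another.  For BAa the phase vector is
    optimized once at ``n_max`` and its prefixes are reused, keeping the
    incremental-construction contract.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if phase == "BAa":
        full = stack_strands(monomer, n_max, topology, phase, **kwargs)
        pv = full.phase_vector
        return [
            stack_strands(monomer, n, topology, phase, phase_vector=pv[:n], **kwargs)
            for n in range(1, n_max + 1)
        ]
    return [
        stack_strands(monomer, n, topology, phase, **kwargs)
        for n in range(1, n_max + 1)
    ]


# ---------------------------------------------------------------------------
# ligands


@dataclass(frozen=True)
class LigandPose:
    """Abstracted small molecule: named interaction sites, no real chemistry.

    ``rosmarinic-like`` carries a donor/acceptor-rich site string, the
    ``resveratrol-like`` profile is hydroxyl donors on an apolar scaffold,
    and ``tht-like`` is purely aromatic — it can make no hydrogen bonds at
    all, mirroring the dye's behaviour against the amyloid core.
    """

    name: str
    roles: tuple
    xyz: np.ndarray

    def __post_init__(self):
        if len(self.roles) < 1:
            raise ValueError("a ligand needs at least one site")
        bad = set(self.roles) - set(_LIGAND_ROLES)
        if bad:
            raise ValueError(f"unknown site role(s): {sorted(bad)}")
        object.__setattr__(self, "xyz", np.asarray(self.xyz, dtype=float))
        if self.xyz.shape != (len(self.roles), 3):
            raise ValueError("xyz must be (n_sites, 3)")

    def transformed(self, R=None, t=None) -> "LigandPose":
        xyz = self.xyz
        if R is not None:
            xyz = xyz @ np.asarray(R).T
        if t is not None:
            xyz = xyz + np.asarray(t)
        return replace(self, xyz=xyz)


_LIGAND_TEMPLATES = {
    # site strings laid out on a 2.5 A linear scaffold
    "rosmarinic-like": ("donor", "acceptor", "apolar", "acceptor", "donor"),
    "resveratrol-like": ("donor", "apolar", "apolar", "donor"),
    "tht-like": ("apolar", "apolar", "apolar"),
}


def make_ligand(kind: str, roles: tuple | None = None) -> LigandPose:
    """Template ligand of the given kind (or ``custom`` with explicit roles)."""
    if kind == "custom":
        if not roles:
            raise ValueError("custom ligand needs explicit roles")
    else:
        if kind not in _LIGAND_TEMPLATES:
            raise ValueError(f"unknown ligand kind {kind!r}")
        roles = _LIGAND_TEMPLATES[kind]
    xyz = np.array([[2.5 * i, 0.0, 0.0] for i in range(len(roles))])
    xyz -= xyz.mean(axis=0)
    return LigandPose(name=kind, roles=tuple(roles), xyz=xyz)


# ---------------------------------------------------------------------------
# core model


@dataclass(frozen=True)
class CoreModel:
    """Two paired sheets forming a cross-beta zipper, plus optional ligand."""

    sheet1: SheetAssembly
    sheet2: SheetAssembly
    rotation: np.ndarray
    translation: np.ndarray
    ligand: LigandPose | None = None

    def __post_init__(self):
        if self.sheet1.n_strands != self.sheet2.n_strands:
            raise ValueError("sheets must have equal strand counts")

    def min_intersheet_distance(self) -> float:
        s1 = as_sites(self.sheet1)
        s2 = as_sites(self.sheet2)
        a = s1.xyz[s1.heavy]
        b = s2.xyz[s2.heavy]
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
        return float(d.min())

    def sheet_separation(self) -> float:
        p1, n1 = self.sheet1.mean_plane_point_normal()
        p2, _ = self.sheet2.mean_plane_point_normal()
        return float(abs(np.dot(p2 - p1, n1)))


def pair_sheets(
    sheet1: SheetAssembly,
    sheet2: SheetAssembly,
    n_poses: int,
    seed: int,
    separation_window: tuple = SHEET_SEPARATION_WINDOW,
    clash_floor: float = CLASH_FLOOR,
    refine_steps: int = 40,
) -> list[CoreModel]:
    """Seeded pose search for the face-to-face sheet pairing.

    Each candidate flips the second sheet onto the first sheet's side-chain
    face, applies a random in-plane rotation and translation jitter, scans
    the separation window for the closest clash-free approach, then refines
    by steepest descent on the rigid translation.  Returns up to *n_poses*
    clash-free cores sorted by energy (ascending, ties by generation order);
    empty list with a warning if no clash-free pose exists.
    """
    if sheet1.n_strands != sheet2.n_strands:
        raise ValueError("sheets must have equal strand counts")
    if n_poses == 0:
        return []
    if n_poses < 0:
        raise ValueError("n_poses must be >= 0")
    from .energetics import CrossPotential, score_structure

    rng = np.random.default_rng(seed)
    s1_sites = as_sites(sheet1)
    a_heavy = s1_sites.xyz[s1_sites.heavy]

    flip = rotation_about_axis([1.0, 0.0, 0.0], 180.0)
    lo, hi = separation_window
    cores = []
    for ipose in range(n_poses):
        theta = rng.uniform(0.0, 360.0)
        Rz = rotation_about_axis([0.0, 0.0, 1.0], theta)
        R = Rz @ flip
        dx, dy = rng.integers(-2, 3, size=2).astype(float)
        base = sheet2.transformed(R=R)
        base_sites = as_sites(base)
        pot = CrossPotential(s1_sites, base_sites)
        b_heavy_base = base_sites.xyz[base_sites.heavy]

        def clashfree(t):
            d = np.linalg.norm(
                a_heavy[:, None, :] - (b_heavy_base + t)[None, :, :], axis=-1
            )
            return d.min() >= clash_floor

        placed = None
        for dz in np.arange(lo, hi + 1e-9, 1.0):
            t = np.array([dx, dy, dz])
            if clashfree(t):
                placed = t
                break
        if placed is None:
            continue

        # steepest-descent rigid-translation refinement inside the window
        def energy_at(t):
            return pot.energy(s1_sites.xyz, base_sites.xyz + t)

        t = placed
        e = energy_at(t)
        step = 0.5
        for _ in range(refine_steps):
            improved = False
            for axis in range(3):
                for sgn in (+1.0, -1.0):
                    cand = t.copy()
                    cand[axis] += sgn * step
                    if not lo <= cand[2] <= hi:
                        continue
                    if not clashfree(cand):
                        continue
                    ec = energy_at(cand)
                    if ec < e - 1e-9:
                        t, e = cand, ec
                        improved = True
            if not improved:
                if step <= 0.25:
                    break
                step /= 2.0
        core = CoreModel(sheet1, base.transformed(t=t), rotation=R, translation=t)
        cores.append((score_structure(core), ipose, core))

    if not cores:
        warnings.warn("no clash-free pose found within the search window")
        return []
    cores.sort(key=lambda c: (c[0], c[1]))
    return [c[2] for c in cores]


def place_ligand(
    assembly: SheetAssembly | CoreModel,
    ligand: LigandPose,
    seed: int,
    n_poses: int = 20,
    standoff: float = 5.0,
) -> LigandPose:
    """Dock a template ligand against a sheet face by seeded pose sampling.

    Candidate poses are scattered over the side-chain face of the assembly
    (random in-plane position, random orientation) and slid along the face
    normal; every clash-free approach height is scored by the ligand-sheet
    interaction energy and the global best pose is returned.  A stand-in
    for real docking: only the coarse site chemistry is considered.
    """
    from .energetics import CrossPotential

    rng = np.random.default_rng(seed)
    target = assembly if isinstance(assembly, SheetAssembly) else assembly.sheet1
    sites = as_sites(assembly)
    heavy_xyz = sites.xyz[sites.heavy]
    lig0 = _ligand_sites(ligand, 0)
    pot = CrossPotential(sites, lig0)
    ca = np.concatenate([s.ca_xyz for s in target.strands])
    lo = ca.min(axis=0)
    hi = ca.max(axis=0)
    ztop = heavy_xyz[:, 2].max()

    best = None
    for _ in range(max(1, n_poses)):
        ang = rng.uniform(0, 360, size=3)
        R = (
            rotation_about_axis([0, 0, 1], ang[0])
            @ rotation_about_axis([0, 1, 0], ang[1])
            @ rotation_about_axis([1, 0, 0], ang[2])
        )
        x = rng.uniform(lo[0], hi[0])
        y = rng.uniform(lo[1], hi[1])
        for dz in np.arange(standoff, -standoff, -0.25):
            t = np.array([x, y, ztop + dz])
            xyz = ligand.xyz @ R.T + t
            d = np.linalg.norm(heavy_xyz[:, None, :] - xyz[None, :, :], axis=-1).min()
            if d < CLASH_FLOOR:
                break
            e = pot.energy(sites.xyz, xyz)
            if best is None or e < best[0]:
                best = (e, ligand.transformed(R=R, t=t))
    return best[1]


def _with_ligand(assembly, pose: LigandPose):
    if isinstance(assembly, CoreModel):
        return replace(assembly, ligand=pose)
    # wrap a bare sheet + ligand as a degenerate complex for scoring
    return ("complex", assembly, pose)


# ---------------------------------------------------------------------------
# site flattening


def _conformer_sites(c: Conformer, strand_ord: int, mol_id: int) -> SiteArray:
    n = len(c.atom_name)
    strand = np.full(n, _STRAND_LABELS[strand_ord])
    res_name = np.array([c.sequence[int(r)] for r in c.res_index], dtype=object)
    heavy = np.array([a != "H" for a in c.atom_name])
    charge = np.zeros(n)
    donor = np.zeros(n, dtype=bool)
    acceptor = np.zeros(n, dtype=bool)
    backbone = np.array([a in ("N", "H", "CA", "C", "O") for a in c.atom_name])
    aromatic = np.zeros(n, dtype=bool)
    h_partner = np.full(n, -1, dtype=int)

    last_n_idx = {}
    for i, (a, r) in enumerate(zip(c.atom_name, c.res_index)):
        aa = c.sequence[int(r)]
        data = RESIDUE_DATA[aa]
        if a == "N" and aa != "P":
            donor[i] = True
            last_n_idx[int(r)] = i
        elif a == "H":
            h_partner[last_n_idx[int(r)]] = i
        elif a == "O":
            acceptor[i] = True
        elif a == "SC" or (a == "CB" and data["sc_dist"] <= 1.6):
            if a == "SC":
                donor[i] = data["donor"]
                acceptor[i] = data["acceptor"]
                charge[i] = data["charge"]
                aromatic[i] = data["aromatic"]

    return SiteArray(
        xyz=np.asarray(c.xyz, dtype=float),
        strand=strand,
        res_index=np.asarray(c.res_index, dtype=int),
        res_name=res_name,
        atom_name=np.array(c.atom_name, dtype=object),
        mol_id=np.full(n, mol_id, dtype=int),
        heavy=heavy,
        charge=charge,
        donor=donor,
        acceptor=acceptor,
        backbone=backbone,
        aromatic=aromatic,
        h_partner=h_partner,
    )


def _ligand_sites(pose: LigandPose, mol_id: int) -> SiteArray:
    n = len(pose.roles)
    prefix = {"donor": "D", "acceptor": "A", "apolar": "P"}
    names = []
    counters = {"D": 0, "A": 0, "P": 0}
    for role in pose.roles:
        p = prefix[role]
        counters[p] += 1
        names.append(f"{p}{counters[p]}")
    return SiteArray(
        xyz=np.asarray(pose.xyz, dtype=float),
        strand=np.full(n, "L"),
        res_index=np.arange(1, n + 1, dtype=int),
        res_name=np.full(n, "", dtype=object),
        atom_name=np.array(names, dtype=object),
        mol_id=np.full(n, mol_id, dtype=int),
        heavy=np.ones(n, dtype=bool),
        charge=np.zeros(n),
        donor=np.array([r == "donor" for r in pose.roles]),
        acceptor=np.array([r == "acceptor" for r in pose.roles]),
        backbone=np.zeros(n, dtype=bool),
        aromatic=np.array([r == "apolar" for r in pose.roles]),
        h_partner=np.full(n, -1, dtype=int),
    )


def as_sites(obj) -> SiteArray:
    """Flatten any structure object into one :class:`SiteArray`.

    Strand ordinals restart per sheet (chains A.. for sheet1, continuing
    for sheet2) and the ligand occupies chain L.  mol_ids are unique per
    strand across the whole complex.
    """
    if isinstance(obj, SiteArray):
        return obj
    if isinstance(obj, Conformer):
        return _conformer_sites(obj, 0, 0)
    if isinstance(obj, LigandPose):
        return _ligand_sites(obj, 0)
    if isinstance(obj, SheetAssembly):
        return SiteArray.concat(
            [_conformer_sites(s, i, i) for i, s in enumerate(obj.strands)]
        )
    if isinstance(obj, CoreModel):
        parts = [
            _conformer_sites(s, i, i) for i, s in enumerate(obj.sheet1.strands)
        ]
        off = obj.sheet1.n_strands
        parts += [
            _conformer_sites(s, off + i, off + i)
            for i, s in enumerate(obj.sheet2.strands)
        ]
        if obj.ligand is not None:
            parts.append(_ligand_sites(obj.ligand, 2 * off))
        return SiteArray.concat(parts)
    if isinstance(obj, tuple) and len(obj) == 3 and obj[0] == "complex":
        _, sheet, pose = obj
        parts = [
            _conformer_sites(s, i, i) for i, s in enumerate(sheet.strands)
        ]
        parts.append(_ligand_sites(pose, sheet.n_strands))
        return SiteArray.concat(parts)
    raise TypeError(f"cannot flatten {type(obj).__name__} into sites")
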
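"""Peptide sequences and per-residue coarse-grained chemistry.

The study peptide is the 16-residue fragment 49-64 of hen egg white lysozyme
with the C-terminal cysteine replaced by serine (GSTDYGILQINSRWWS) to prevent
disulfide formation.  Everything downstream (conformer building, contact
chemistry, scoring) keys off the tables defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.SeqUtils import molecular_weight

__all__ = [
    "PeptideSequence",
    "peptide_average_mass",
    "HEWL_PEPTIDE",
    "RESIDUE_DATA",
]

_CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")

#: Per-residue coarse side-chain model.  Each entry:
#:   sc_dist  - Calpha -> side-chain-centroid distance (A); 0.0 means no
#:              explicit side-chain site (glycine)
#:   radius   - Lennard-Jones r_min for the centroid pseudo-site (A)
#:   charge   - formal charge class carried by the centroid (R/K +1, D/E -1)
#:   donor/acceptor - side-chain hydrogen-bonding capability
#:   aromatic - flagged for the hydrophobic/stacking term
RESIDUE_DATA: dict[str, dict] = {
    "G": dict(sc_dist=0.0, radius=0.0, charge=0.0, donor=False, acceptor=False, aromatic=False),
    "A": dict(sc_dist=1.53, radius=3.6, charge=0.0, donor=False, acceptor=False, aromatic=False),
    "S": dict(sc_dist=1.9, radius=3.6, charge=0.0, donor=True, acceptor=True, aromatic=False),
    "C": dict(sc_dist=2.0, radius=3.8, charge=0.0, donor=True, acceptor=False, aromatic=False),
    "T": dict(sc_dist=1.9, radius=3.9, charge=0.0, donor=True, acceptor=True, aromatic=False),
    "V": dict(sc_dist=2.0, radius=4.2, charge=0.0, donor=False, acceptor=False, aromatic=False),
    "L": dict(sc_dist=2.6, radius=4.4, charge=0.0, donor=False, acceptor=False, aromatic=False),
    "I": dict(sc_dist=2.3, radius=4.4, charge=0.0, donor=False, acceptor=False, aromatic=False),
    "M": dict(sc_dist=2.9, radius=4.4, charge=0.0, donor=False, acceptor=False, aromatic=False),
    "P": dict(sc_dist=1.9, radius=4.0, charge=0.0, donor=False, acceptor=False, aromatic=False),
    "F": dict(sc_dist=3.4, radius=4.8, charge=0.0, donor=False, acceptor=False, aromatic=True),
    "W": dict(sc_dist=3.9, radius=5.2, charge=0.0, donor=True, acceptor=False, aromatic=True),
    "Y": dict(sc_dist=3.8, radius=4.8, charge=0.0, donor=True, acceptor=True, aromatic=True),
    "H": dict(sc_dist=3.1, radius=4.4, charge=0.0, donor=True, acceptor=True, aromatic=True),
    "K": dict(sc_dist=3.5, radius=4.2, charge=1.0, donor=True, acceptor=False, aromatic=False),
    "R": dict(sc_dist=4.1, radius=4.4, charge=1.0, donor=True, acceptor=False, aromatic=False),
    "D": dict(sc_dist=2.5, radius=3.8, charge=-1.0, donor=False, acceptor=True, aromatic=False),
    "E": dict(sc_dist=3.1, radius=4.0, charge=-1.0, donor=False, acceptor=True, aromatic=False),
    "N": dict(sc_dist=2.5, radius=3.9, charge=0.0, donor=True, acceptor=True, aromatic=False),
    "Q": dict(sc_dist=3.1, radius=4.1, charge=0.0, donor=True, acceptor=True, aromatic=False),
}

_THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}
_ONE_LETTER = {v: k for k, v in _THREE_LETTER.items()}


@dataclass(frozen=True)
class PeptideSequence:
    """An ordered one-letter amino-acid string with 1-based display positions."""

    residues: str

    def __post_init__(self) -> None:
        seq = self.residues.upper()
        if len(seq) < 2:
            raise ValueError("a peptide needs at least 2 residues")
        bad = sorted(set(seq) - _CANONICAL)
        if bad:
            raise ValueError(f"unknown residue code(s): {', '.join(bad)}")
        object.__setattr__(self, "residues", seq)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def __getitem__(self, position: int) -> str:
        """Residue at 1-based *position*."""
        if not 1 <= position <= len(self):
            raise IndexError(f"position {position} outside 1..{len(self)}")
        return self.residues[position - 1]

    @property
    def positions(self) -> range:
        return range(1, len(self) + 1)

    def three_letter(self, position: int) -> str:
        return _THREE_LETTER[self[position]]


def peptide_average_mass(seq: PeptideSequence | str) -> float:
    """Average molecular mass of the free peptide in Da (residues + one water).

    Matches synthesis QC: the HEWL 49-64 peptide (C64S) weighs 1883.0 Da.
    """
    residues = seq.residues if isinstance(seq, PeptideSequence) else seq.upper()
    if len(residues) < 1:
        raise ValueError("empty sequence")
    bad = sorted(set(residues) - _CANONICAL)
    if bad:
        raise ValueError(f"unknown residue code(s): {', '.join(bad)}")
    return float(molecular_weight(residues, seq_type="protein", monoisotopic=False))


#: The study peptide: HEWL residues 49-64 with C64S.
HEWL_PEPTIDE = PeptideSequence("GSTDYGILQINSRWWS")

def three_to_one(resname: str) -> str:
    try:
        return _ONE_LETTER[resname.upper()]
    except KeyError:
        raise ValueError(f"unknown residue name {resname!r}") from None


def one_to_three(code: str) -> str:
    try:
        return _THREE_LETTER[code.upper()]
    except KeyError:
        raise ValueError(f"unknown residue code {code!r}") from None
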
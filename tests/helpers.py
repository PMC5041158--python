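"""Hand-assembled site-table helpers shared across test modules."""

import numpy as np

from crossbeta.structures import SiteArray


def toy_sites(xyz, names=None, charges=None, donors=None, acceptors=None, mols=None):
    """Hand-assembled SiteArray of neutral Cbeta-like carbons by default."""
    xyz = np.asarray(xyz, dtype=float)
    n = len(xyz)
    if mols is None:
        mols = list(range(n))
    return SiteArray(
        xyz=xyz,
        strand=np.array([chr(65 + m) for m in mols]),
        res_index=np.arange(1, n + 1),
        res_name=np.array(["A"] * n, dtype=object),
        atom_name=np.array(names if names is not None else ["CB"] * n, dtype=object),
        mol_id=np.array(mols),
        heavy=np.ones(n, dtype=bool),
        charge=np.array(charges if charges is not None else np.zeros(n), dtype=float),
        donor=np.array(donors if donors is not None else np.zeros(n, dtype=bool)),
        acceptor=np.array(acceptors if acceptors is not None else np.zeros(n, dtype=bool)),
        backbone=np.zeros(n, dtype=bool),
        aromatic=np.zeros(n, dtype=bool),
        h_partner=np.full(n, -1, dtype=int),
    )
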
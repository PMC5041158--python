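"""Readers/writers for the formats the pipeline touches, plus run configuration.

Structures and trajectories travel as multi-model PDB (one MODEL per frame;
chain IDs encode strand labels, the ligand is chain L with HETATM records
and residue name LIG).  Contact maps travel as CSV with their metadata in a
``#``-comment header block.  Multi-model PDB is deliberately preferred over
a binary trajectory format: every file the pipeline writes can be opened in
a text editor.
"""

from __future__ import annotations

import io
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .contacts import HBOND_CUTOFF, VDW_CUTOFF, ContactMap, Trajectory
from .energetics import ENERGY_TOLERANCE, OVERLAP_THRESHOLD
from .sequence import RESIDUE_DATA, one_to_three, three_to_one
from .structures import SiteArray, as_sites

__all__ = [
    "RunConfig",
    "write_pdb",
    "read_pdb_models",
    "write_map_csv",
    "read_map_csv",
    "log_stage",
]

logger = logging.getLogger("crossbeta")

_ELEMENT = {"N": "N", "O": "O", "H": "H"}


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Every run writes its resolved config next to its outputs so any result
    can be traced to the cutoffs, thresholds and seed that produced it.
    """

    hbond_cutoff: float = HBOND_CUTOFF
    vdw_cutoff: float = VDW_CUTOFF
    scorer_params: str | None = None
    rounding: str = "nearest-int"
    energy_tolerance: float = ENERGY_TOLERANCE
    overlap_threshold: float = OVERLAP_THRESHOLD
    seed: int = 0
    outdir: str = "."

    def __post_init__(self):
        if self.hbond_cutoff <= 0 or self.vdw_cutoff <= 0:
            raise ValueError("cutoffs must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def log_stage(stage: str, **fields) -> None:
    """One structured log line per pipeline stage."""
    parts = " ".join(f"{k}={v}" for k, v in fields.items())
    logger.info("stage=%s %s", stage, parts)


# ---------------------------------------------------------------------------
# PDB


def _to_atom_array(sites: SiteArray) -> struc.AtomArray:
    n = len(sites)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(sites.xyz, dtype=np.float32)
    arr.chain_id = np.asarray(sites.strand, dtype="U4")
    arr.res_id = np.asarray(sites.res_index, dtype=int)
    is_lig = sites.strand == "L"
    arr.res_name = np.array(
        [
            "LIG" if lig else one_to_three(rn)
            for lig, rn in zip(is_lig, sites.res_name)
        ],
        dtype="U5",
    )
    arr.atom_name = np.asarray(sites.atom_name, dtype="U6")
    arr.hetero = is_lig
    arr.element = np.array(
        [_ELEMENT.get(a, "C") for a in sites.atom_name], dtype="U2"
    )
    arr.set_annotation("occupancy", np.ones(n))
    arr.set_annotation("b_factor", np.zeros(n))
    return arr


def write_pdb(obj, path: str | Path) -> None:
    """Write a structure or trajectory as (multi-model) PDB.

    Accepts anything :func:`crossbeta.structures.as_sites` can flatten, or a
    :class:`~crossbeta.contacts.Trajectory` (one MODEL per frame).
    """
    pdb = PDBFile()
    if isinstance(obj, Trajectory):
        arrays = [_to_atom_array(obj.frame(i)) for i in range(obj.n_frames)]
        stack = struc.stack(arrays)
        pdb.set_structure(stack)
    else:
        pdb.set_structure(_to_atom_array(as_sites(obj)))
    pdb.write(str(path))


def _validate_pdb_lines(path: Path) -> None:
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            if len(line) < 54:
                raise ValueError(f"{path.name}: malformed ATOM record at line {lineno}")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
                int(line[22:26])
            except ValueError:
                raise ValueError(
                    f"{path.name}: malformed ATOM record at line {lineno}"
                ) from None


def _sites_from_atom_array(arr: struc.AtomArray) -> SiteArray:
    n = arr.array_length()
    strand = np.asarray(arr.chain_id, dtype="U4")
    res_index = np.asarray(arr.res_id, dtype=int)
    atom_name = np.asarray(arr.atom_name, dtype=object)
    is_lig = np.asarray(arr.res_name) == "LIG"

    res_name = np.empty(n, dtype=object)
    charge = np.zeros(n)
    donor = np.zeros(n, dtype=bool)
    acceptor = np.zeros(n, dtype=bool)
    backbone = np.zeros(n, dtype=bool)
    aromatic = np.zeros(n, dtype=bool)
    heavy = np.ones(n, dtype=bool)
    h_partner = np.full(n, -1, dtype=int)
    mol_id = np.zeros(n, dtype=int)

    chain_ids = {}
    last_n: dict = {}
    for i in range(n):
        a = atom_name[i]
        key = strand[i]
        mol_id[i] = chain_ids.setdefault(key, len(chain_ids))
        if is_lig[i]:
            res_name[i] = ""
            donor[i] = a.startswith("D")
            acceptor[i] = a.startswith("A")
            aromatic[i] = a.startswith("P")
            continue
        one = three_to_one(arr.res_name[i])
        res_name[i] = one
        data = RESIDUE_DATA[one]
        if a in ("N", "H", "CA", "C", "O"):
            backbone[i] = True
        if a == "N" and one != "P":
            donor[i] = True
            last_n[(key, res_index[i])] = i
        elif a == "H":
            heavy[i] = False
            src = last_n.get((key, res_index[i]))
            if src is not None:
                h_partner[src] = i
        elif a == "O":
            acceptor[i] = True
        elif a == "SC":
            donor[i] = data["donor"]
            acceptor[i] = data["acceptor"]
            charge[i] = data["charge"]
            aromatic[i] = data["aromatic"]

    return SiteArray(
        xyz=np.asarray(arr.coord, dtype=float),
        strand=strand,
        res_index=res_index,
        res_name=res_name,
        atom_name=atom_name,
        mol_id=mol_id,
        heavy=heavy,
        charge=charge,
        donor=donor,
        acceptor=acceptor,
        backbone=backbone,
        aromatic=aromatic,
        h_partner=h_partner,
    )


def read_pdb_models(path: str | Path):
    """Read a (multi-model) PDB file.

    One MODEL gives a :class:`SiteArray` structure; two or more give a
    :class:`Trajectory`.  Malformed ATOM records fail with the offending
    line number; models with inconsistent topology fail with a clear error.
    """
    path = Path(path)
    _validate_pdb_lines(path)
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models == 1:
        arr = pdb.get_structure(model=1)
        return _sites_from_atom_array(arr)
    try:
        stack = pdb.get_structure()
    except Exception as exc:
        raise ValueError(f"{path.name}: inconsistent topology across models: {exc}") from exc
    topo = _sites_from_atom_array(stack[0])
    return Trajectory(topology=topo, coords=np.asarray(stack.coord, dtype=float))


# ---------------------------------------------------------------------------
# contact-map CSV


def write_map_csv(cmap: ContactMap, path: str | Path) -> None:
    """Contact map as CSV: metadata in '#' header comments, then the table."""
    header = (
        f"# partner={cmap.partner}\n"
        f"# frames={cmap.frames}\n"
        f"# cutoff_hbond={cmap.cutoffs['hbond']}\n"
        f"# cutoff_vdw={cmap.cutoffs['vdw']}\n"
    )
    buf = io.StringIO()
    cmap.to_frame().to_csv(buf, index=False)
    Path(path).write_text(header + buf.getvalue())


def read_map_csv(path: str | Path) -> ContactMap:
    path = Path(path)
    meta = {}
    for line in path.read_text().splitlines():
        if not line.startswith("#"):
            break
        key, _, val = line.lstrip("# ").partition("=")
        meta[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#")
    if "position" not in df.columns:
        raise ValueError(f"{path.name}: missing 'position' column")
    return ContactMap.from_frame(
        df,
        cutoffs={
            "hbond": float(meta.get("cutoff_hbond", HBOND_CUTOFF)),
            "vdw": float(meta.get("cutoff_vdw", VDW_CUTOFF)),
        },
        frames=int(meta.get("frames", 0)),
        partner=meta.get("partner", ""),
    )
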
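"""Per-strand, per-residue contact maps accumulated over trajectory frames.

Two interaction classes are counted between disjoint atom groups:

* hydrogen bonds — donor/acceptor heavy-atom pairs closer than 3 A
  (distance-only criterion; roles come from a fixed chemistry table:
  backbone N-H donates, backbone O accepts, side-chain roles per residue);
* van der Waals contacts — any heavy-atom pair closer than 2.3 A that is
  not already classified as a hydrogen bond (the classes are disjoint,
  hydrogen bonds take priority).

Counts are attributed to the (strand label, residue position) of the first
group's endpoint, so a map answers "which residues of this sheet face the
partner", the statistic behind per-residue interaction-frequency maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .structures import SiteArray

__all__ = [
    "Contact",
    "Trajectory",
    "ContactMap",
    "HBOND_CUTOFF",
    "VDW_CUTOFF",
    "select_strands",
    "select_ligand",
    "detect_hbonds",
    "detect_vdw",
    "accumulate_map",
    "subsample_frames",
    "map_overlap",
]

HBOND_CUTOFF = 3.0  # A, strict '<'
VDW_CUTOFF = 2.3  # A, strict '<'

_TYPES = ("hbond", "vdw")


class Contact(NamedTuple):
    i: int  # site index in the full topology, groupA endpoint
    j: int  # groupB endpoint
    distance: float
    kind: str


@dataclass(frozen=True)
class Trajectory:
    """Ordered coordinate frames over one fixed topology."""

    topology: SiteArray
    coords: np.ndarray  # (n_frames, n_sites, 3)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_sites, 3)")
        if coords.shape[1] != len(self.topology):
            raise ValueError("coords do not match topology size")
        if coords.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        object.__setattr__(self, "coords", coords)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> SiteArray:
        return self.topology.with_coords(self.coords[i])

    @staticmethod
    def from_frames(frames: list[SiteArray]) -> "Trajectory":
        if not frames:
            raise ValueError("no frames")
        return Trajectory(
            topology=frames[0], coords=np.stack([f.xyz for f in frames])
        )


def select_strands(sites: SiteArray, labels) -> np.ndarray:
    """Site indices belonging to the given strand labels (e.g. 'A'..'D')."""
    labels = set(labels)
    return np.where(np.isin(sites.strand, sorted(labels)))[0]


def select_ligand(sites: SiteArray) -> np.ndarray:
    """Site indices of the bound ligand (chain L)."""
    return np.where(sites.strand == "L")[0]


def _check_groups(frame: SiteArray, groupA, groupB):
    ga = np.asarray(groupA, dtype=int)
    gb = np.asarray(groupB, dtype=int)
    if len(np.intersect1d(ga, gb)):
        raise ValueError("groups must be disjoint atom selections")
    if len(ga) == 0 or len(gb) == 0:
        raise ValueError("empty atom selection")
    return ga, gb


def detect_hbonds(
    frame: SiteArray, groupA, groupB, cutoff: float = HBOND_CUTOFF
) -> list[Contact]:
    """Hydrogen bonds between the groups in one frame (strict ``< cutoff``).

    One contact per donor/acceptor heavy-atom pair with one endpoint in each
    group, counted once per frame.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ga, gb = _check_groups(frame, groupA, groupB)
    ha = ga[frame.heavy[ga]]
    hb = gb[frame.heavy[gb]]
    d = np.linalg.norm(frame.xyz[ha][:, None, :] - frame.xyz[hb][None, :, :], axis=-1)
    eligible = (frame.donor[ha][:, None] & frame.acceptor[hb][None, :]) | (
        frame.acceptor[ha][:, None] & frame.donor[hb][None, :]
    )
    ii, jj = np.where(eligible & (d < cutoff))
    return [
        Contact(int(ha[i]), int(hb[j]), float(d[i, j]), "hbond") for i, j in zip(ii, jj)
    ]


def detect_vdw(
    frame: SiteArray,
    groupA,
    groupB,
    cutoff: float = VDW_CUTOFF,
    hbond_cutoff: float = HBOND_CUTOFF,
) -> list[Contact]:
    """Van der Waals contacts (strict ``< cutoff``), hydrogen bonds excluded.

    A pair that satisfies the hydrogen-bond criterion is counted as hbond
    only, keeping the two interaction classes disjoint.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ga, gb = _check_groups(frame, groupA, groupB)
    ha = ga[frame.heavy[ga]]
    hb = gb[frame.heavy[gb]]
    d = np.linalg.norm(frame.xyz[ha][:, None, :] - frame.xyz[hb][None, :, :], axis=-1)
    eligible_hb = (frame.donor[ha][:, None] & frame.acceptor[hb][None, :]) | (
        frame.acceptor[ha][:, None] & frame.donor[hb][None, :]
    )
    is_hb = eligible_hb & (d < hbond_cutoff)
    ii, jj = np.where((d < cutoff) & ~is_hb)
    return [
        Contact(int(ha[i]), int(hb[j]), float(d[i, j]), "vdw") for i, j in zip(ii, jj)
    ]


@dataclass(frozen=True)
class ContactMap:
    """Counts indexed by (strand label, residue position 1..L, type)."""

    strands: tuple
    length: int
    counts: np.ndarray  # (n_strands, length, 2) non-negative ints
    cutoffs: dict = field(default_factory=lambda: {"hbond": HBOND_CUTOFF, "vdw": VDW_CUTOFF})
    frames: int = 0
    partner: str = ""

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (len(self.strands), self.length, 2):
            raise ValueError("counts shape must be (n_strands, length, 2)")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @staticmethod
    def type_index(kind: str) -> int:
        return _TYPES.index(kind)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def cell(self, strand: str, position: int, kind: str) -> int:
        return int(
            self.counts[self.strands.index(strand), position - 1, self.type_index(kind)]
        )

    def argmax_cell(self, kind: str) -> tuple:
        """(strand, position) of the highest-count cell of the given type."""
        sub = self.counts[:, :, self.type_index(kind)]
        s, p = np.unravel_index(int(np.argmax(sub)), sub.shape)
        return str(self.strands[s]), int(p) + 1

    def to_frame(self):
        """Wide table: rows = positions 1..L, columns = '<strand>_<type>'."""
        import pandas as pd

        data = {"position": np.arange(1, self.length + 1)}
        for si, s in enumerate(self.strands):
            for ti, t in enumerate(_TYPES):
                data[f"{s}_{t}"] = self.counts[si, :, ti]
        return pd.DataFrame(data)

    @staticmethod
    def from_frame(df, cutoffs=None, frames=0, partner="") -> "ContactMap":
        cols = [c for c in df.columns if c != "position"]
        strands = []
        for c in cols:
            s, t = c.rsplit("_", 1)
            if t not in _TYPES:
                raise ValueError(f"bad column {c!r}")
            if s not in strands:
                strands.append(s)
        length = len(df)
        counts = np.zeros((len(strands), length, 2), dtype=int)
        for si, s in enumerate(strands):
            for ti, t in enumerate(_TYPES):
                col = f"{s}_{t}"
                if col not in df.columns:
                    raise ValueError(f"missing column {col!r}")
                counts[si, :, ti] = df[col].to_numpy()
        return ContactMap(
            strands=tuple(strands),
            length=length,
            counts=counts,
            cutoffs=cutoffs or {"hbond": HBOND_CUTOFF, "vdw": VDW_CUTOFF},
            frames=frames,
            partner=partner,
        )

    def plot(self, kind: str = "hbond", ax=None):
        """Per-position count profile, one line per strand."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ti = self.type_index(kind)
        for si, s in enumerate(self.strands):
            ax.plot(
                np.arange(1, self.length + 1),
                self.counts[si, :, ti],
                marker="o",
                label=f"strand {s}",
            )
        ax.set_xlabel("residue position")
        ax.set_ylabel(f"{kind} count")
        ax.legend()
        return ax


def accumulate_map(
    traj: Trajectory,
    groupA,
    groupB,
    kind: str = "both",
    hbond_cutoff: float = HBOND_CUTOFF,
    vdw_cutoff: float = VDW_CUTOFF,
    partner: str = "",
) -> ContactMap:
    """Sum per-frame detections into (strand, position) cells on groupA's side."""
    if kind not in ("hbond", "vdw", "both"):
        raise ValueError(f"unknown interaction type {kind!r}")
    if traj.n_frames < 1:
        raise ValueError("empty trajectory")
    top = traj.topology
    ga, gb = _check_groups(top, groupA, groupB)

    strands = sorted(set(top.strand[ga]))
    length = int(top.res_index[ga].max())
    s_of = {s: i for i, s in enumerate(strands)}
    counts = np.zeros((len(strands), length, 2), dtype=int)

    for fi in range(traj.n_frames):
        frame = traj.frame(fi)
        found = []
        if kind in ("hbond", "both"):
            found += detect_hbonds(frame, ga, gb, cutoff=hbond_cutoff)
        if kind in ("vdw", "both"):
            found += detect_vdw(
                frame, ga, gb, cutoff=vdw_cutoff, hbond_cutoff=hbond_cutoff
            )
        for c in found:
            si = s_of[top.strand[c.i]]
            counts[si, top.res_index[c.i] - 1, _TYPES.index(c.kind)] += 1

    return ContactMap(
        strands=tuple(strands),
        length=length,
        counts=counts,
        cutoffs={"hbond": hbond_cutoff, "vdw": vdw_cutoff},
        frames=traj.n_frames,
        partner=partner,
    )


def subsample_frames(traj: Trajectory, stride: int) -> Trajectory:
    """Frames at indices stride, 2*stride, ... (count = floor(N / stride)).

    Mirrors the snapshot-minimization schedule: every ``stride``-th snapshot
    is kept, so 200 frames at stride 10 give 20.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    idx = np.arange(stride - 1, traj.n_frames, stride)
    return replace(traj, coords=traj.coords[idx])


def map_overlap(mapA: ContactMap, mapB: ContactMap) -> float:
    """Cosine similarity of the flattened count vectors, in [0, 1]."""
    if mapA.counts.shape != mapB.counts.shape:
        raise ValueError("contact maps have mismatched shapes")
    a = mapA.counts.ravel().astype(float)
    b = mapB.counts.ravel().astype(float)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))
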
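"""Synthetic inputs with known ground truth for the whole pipeline.

Generators stand in for the molecular-dynamics and assay data the analysis
stages consume: multi-frame jittered coordinates of sheet/core/complex
systems with *planted* contacts, noisy kinetic traces with known
parameters, and four-component Congo-red spectra with an optional 540 nm
red-shift peak.  They exist to exercise the counting and fitting machinery
against a known answer, not to emulate force-field dynamics.

All generators are pure functions of (spec, seed); seeds are mandatory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .contacts import Trajectory
from .kinetics import KineticTrace, SpectrumSet, _exponential, _sigmoid
from .structures import as_sites

__all__ = [
    "PlantedContact",
    "TrajectorySpec",
    "TraceSpec",
    "make_trajectory",
    "make_trace",
    "make_cr_spectra",
]

#: Target distances used when pulling a planted pair inside its cutoff (A).
_PLANT_DISTANCE = {"hbond": 2.7, "vdw": 2.1}


@dataclass(frozen=True)
class PlantedContact:
    """A contact to enforce: (strand, position) on the sheet side vs partner."""

    strand: str
    position: int
    partner: Literal["sheet2", "ligand"]
    kind: Literal["hbond", "vdw"]


@dataclass(frozen=True)
class TrajectorySpec:
    """Recipe for a jittered multi-frame trajectory with planted structure.

    ``sigma`` is the per-atom Gaussian jitter (default 0.3 A: small enough
    to preserve a hydrogen-bond ladder in most frames, large enough to vary
    counts frame to frame); ``fraction`` is the share of frames in which
    every planted contact is enforced (rounded down to whole frames).
    """

    base: object  # SheetAssembly | CoreModel | ('complex', sheet, ligand)
    n_frames: int
    seed: int
    sigma: float = 0.3
    planted: tuple = ()
    fraction: float = 1.0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        planted = tuple(
            p if isinstance(p, PlantedContact) else PlantedContact(*p)
            for p in self.planted
        )
        object.__setattr__(self, "planted", planted)


def _partner_indices(sites, partner: str, sheet1_strands: set) -> np.ndarray:
    if partner == "ligand":
        idx = np.where(sites.strand == "L")[0]
    elif partner == "sheet2":
        idx = np.where(
            ~np.isin(sites.strand, sorted(sheet1_strands)) & (sites.strand != "L")
        )[0]
    else:
        raise ValueError(f"unknown partner {partner!r}")
    if len(idx) == 0:
        raise ValueError(f"base structure has no {partner!r} sites")
    return idx


def _source_index(sites, strand: str, position: int, kind: str) -> tuple[int, bool, bool]:
    """Pick the site on (strand, position) that will anchor the contact.

    For hydrogen bonds prefer a side-chain donor/acceptor, fall back to the
    backbone N (donor) then O (acceptor).  For van der Waals any heavy site
    works; prefer the side-chain centroid, then Cbeta, then Calpha.
    """
    on_res = np.where((sites.strand == strand) & (sites.res_index == position))[0]
    if len(on_res) == 0:
        raise ValueError(f"no residue {position} on strand {strand!r}")
    by_name = {sites.atom_name[i]: i for i in on_res}
    if kind == "hbond":
        for name in ("SC", "N", "O"):
            i = by_name.get(name)
            if i is not None and (sites.donor[i] or sites.acceptor[i]):
                return i, bool(sites.donor[i]), bool(sites.acceptor[i])
        raise ValueError(
            f"residue {position} on strand {strand!r} has no donor/acceptor site"
        )
    for name in ("SC", "CB", "CA"):
        i = by_name.get(name)
        if i is not None:
            return i, False, False
    raise ValueError(f"no heavy site on strand {strand!r} residue {position}")


def make_trajectory(spec: TrajectorySpec) -> Trajectory:
    """Jittered frames of the base structure with contacts planted post-jitter.

    Planted pairs are pulled inside their detection cutoff *after* the
    Gaussian jitter is applied, so the planted cell is guaranteed at least
    ``floor(fraction * n_frames)`` accumulated counts.  Deterministic per
    seed; the seed is recorded in the trajectory metadata.
    """
    sites = as_sites(spec.base)
    base_xyz = sites.xyz
    rng = np.random.default_rng(spec.seed)

    coords = base_xyz[None, :, :] + rng.normal(
        0.0, spec.sigma, size=(spec.n_frames, *base_xyz.shape)
    )

    if spec.planted:
        plant_frames = rng.choice(
            spec.n_frames,
            size=int(np.floor(spec.fraction * spec.n_frames)),
            replace=False,
        )
        resolved = []
        for p in spec.planted:
            src, is_donor, is_acceptor = _source_index(
                sites, p.strand, p.position, p.kind
            )
            partner_idx = _partner_indices(
                sites, p.partner, sheet1_strands=_own_sheet(sites, p.strand)
            )
            if p.kind == "hbond":
                if is_donor:
                    ok = partner_idx[sites.acceptor[partner_idx]]
                else:
                    ok = partner_idx[sites.donor[partner_idx]]
                if len(ok) == 0 and is_donor and is_acceptor:
                    ok = partner_idx[sites.donor[partner_idx]]
            else:
                # avoid donor/acceptor complementarity so the pair stays vdw
                comp = (sites.donor[src] & sites.acceptor[partner_idx]) | (
                    sites.acceptor[src] & sites.donor[partner_idx]
                )
                ok = partner_idx[sites.heavy[partner_idx] & ~comp]
            if len(ok) == 0:
                raise ValueError(
                    f"no compatible partner site for planted contact {p}"
                )
            d = np.linalg.norm(base_xyz[ok] - base_xyz[src], axis=1)
            order = ok[np.argsort(d, kind="stable")]
            resolved.append((src, order, _PLANT_DISTANCE[p.kind]))

        for f in plant_frames:
            used: set = set()
            for src, order, d_target in resolved:
                tgt = next(int(j) for j in order if int(j) not in used)
                used.add(tgt)
                v = coords[f, tgt] - coords[f, src]
                norm = np.linalg.norm(v)
                u = v / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
                coords[f, tgt] = coords[f, src] + d_target * u

    return Trajectory(
        topology=sites,
        coords=coords,
        meta={"seed": spec.seed, "sigma": spec.sigma, "fraction": spec.fraction},
    )


def _own_sheet(sites, strand: str) -> set:
    """Strand labels belonging to the same sheet as ``strand``.

    Sheets are laid out with contiguous label blocks (A..D then E..H); the
    first block is sheet1.  Planted-contact partner selection must exclude
    the whole sheet the source strand belongs to.
    """
    labels = sorted(set(sites.strand) - {"L"})
    if len(labels) % 2 == 0 and len(labels) > 1:
        half = len(labels) // 2
        first, second = set(labels[:half]), set(labels[half:])
        return first if strand in first else second
    return {strand}


@dataclass(frozen=True)
class TraceSpec:
    """Recipe for a noisy kinetic trace with known true parameters."""

    model: Literal["sigmoid", "exponential"]
    params: dict
    times: np.ndarray
    seed: int
    sigma: float = 0.0

    def __post_init__(self):
        if self.model not in ("sigmoid", "exponential"):
            raise ValueError(f"unknown model {self.model!r}")
        needed = {"sigmoid": {"Ai", "Af", "t_half", "k_agg"}, "exponential": {"A", "k_agg"}}
        missing = needed[self.model] - set(self.params)
        if missing:
            raise ValueError(f"missing parameter(s): {sorted(missing)}")
        if self.params["k_agg"] <= 0:
            raise ValueError("k_agg must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))


def make_trace(spec: TraceSpec) -> KineticTrace:
    """Model curve evaluated at the sampling times plus seeded Gaussian noise."""
    fn = _sigmoid if spec.model == "sigmoid" else _exponential
    values = fn(spec.times, **spec.params)
    rng = np.random.default_rng(spec.seed)
    if spec.sigma > 0:
        values = values + rng.normal(0.0, spec.sigma, size=values.shape)
    return KineticTrace(time=spec.times, values=values, baseline_corrected=True)


def make_cr_spectra(
    amyloid: bool,
    seed: int,
    peak_centre: float = 540.0,
    amplitude: float = 0.1,
    noise_sigma: float = 0.0,
    grid: np.ndarray | None = None,
) -> SpectrumSet:
    """Four-component CR absorbance spectra with an optional red-shift peak.

    B and C are smooth baselines (aggregate scattering tail and the free-dye
    band near 490 nm); D = C + B + a Gaussian peak at ``peak_centre`` (only
    if ``amyloid``) + seeded noise.  With ``amyloid=False`` and zero noise
    the difference spectrum is identically zero.
    """
    wl = np.arange(400.0, 701.0, 1.0) if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)

    B = 0.05 * np.exp(-0.5 * ((wl - 430.0) / 90.0) ** 2)
    C = 0.80 * np.exp(-0.5 * ((wl - 490.0) / 35.0) ** 2)
    D = C + B
    if amyloid:
        D = D + amplitude * np.exp(-0.5 * ((wl - peak_centre) / 12.0) ** 2)
    if noise_sigma > 0:
        D = D + rng.normal(0.0, noise_sigma, size=wl.shape)
    return SpectrumSet(wavelength=wl, B=B, C=C, D=D)
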
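# crossbeta

Cross-β amyloid core modelling and inhibitor-competition analysis for the
hen egg white lysozyme (HEWL) 49–64 peptide.

Amyloid fibrils are built from a cross-β core: two face-to-face β-sheets
whose side chains interdigitate into a steric zipper. A small molecule can
inhibit fibril growth if binding it to a preformed sheet is at least as
favourable as pairing that sheet with a second one — and if it binds at the
very positions that stabilize the core. `crossbeta` implements that whole
line of reasoning as a tested pipeline for the 16-mer `GSTDYGILQINSRWWS`
(HEWL residues 49–64 with C64S):

* **structures** — idealized β-strand/α-helix monomers from sequence;
  β-sheets in the four classic variants (parallel `BP`; antiparallel with
  all side chains in phase `BA1`, alternating `BA2`, or energy-optimized
  `BAa`); seeded face-to-face sheet pairing into core models.
* **energetics** — a coarse-grained site potential (Lennard-Jones +
  screened Coulomb + directional backbone H-bond bonus), the energy
  bookkeeping ΔE_n = (E_n − n·E_1)/n and ΔEp_core = Ep_core − 2·Ep_sheet,
  and the energy-competition classifier for candidate inhibitors.
* **contacts** — per-strand, per-residue hydrogen-bond (< 3 Å) and van der
  Waals (< 2.3 Å) contact maps accumulated over trajectory frames.
* **kinetics** — Thioflavin-T trace normalization and least-squares fits of
  the sigmoidal model F(t) = A_i + (A_f − A_i)/(1 + exp((t_1/2 − t)·k_agg))
  and the lag-free mono-exponential F(t) = A·(1 − exp(−k_agg·t)); plateau
  based % inhibition; Congo-red difference spectra R = D − C − B with the
  540 nm red-shift amyloid call.
* **synthetic** — generators for every input the pipeline needs (jittered
  trajectories with planted contacts, noisy kinetic traces, CR spectra)
  with known ground truth.

## Worked example

```python
import numpy as np
from crossbeta import *

monomer = build_monomer(HEWL_PEPTIDE, "B")
print("peptide mass: %.1f Da" % peptide_average_mass(HEWL_PEPTIDE))

series = enumerate_assembly_series(monomer, 5, "antiparallel", "BA2")
E1 = score_structure(series[0])
dE = [delta_e_per_monomer(score_structure(a), E1, n) for n, a in enumerate(series, 1)]
print("per-monomer gain dE_n:", np.round(dE, 1))

sheet = series[3]
core = pair_sheets(sheet, sheet, n_poses=5, seed=1)[0]
print("coarse dEp_core: %.1f kcal/mol"
      % delta_ep_core(score_structure(core), score_structure(sheet)))

traj = make_trajectory(TrajectorySpec(base=core, n_frames=50, seed=2, sigma=0.3,
    planted=[(s, 13, "sheet2", "hbond") for s in "ABCD"], fraction=1.0))
cmap = accumulate_map(traj, select_strands(traj.topology, "ABCD"),
                      select_strands(traj.topology, "EFGH"), partner="sheet2")
print("argmax hbond cell:", cmap.argmax_cell("hbond"))

times = np.linspace(0, 300, 60)
tr = make_trace(TraceSpec("sigmoid", dict(Ai=0.0, Af=1.0, t_half=100.0, k_agg=0.05),
                          times, seed=3, sigma=0.05))
fit = ThTKineticsModel(tr, "sigmoid").fit()
print(fit.summary())
print("inhibition vs control: %.1f %%" % inhibition_percent(0.165, fit.plateau))
```

prints

```
peptide mass: 1883.0 Da
per-monomer gain dE_n: [  0.  -28.9 -38.4 -43.4 -46.3]
coarse dEp_core: -76.8 kcal/mol
argmax hbond cell: ('A', 13)
ThT kinetics fit (sigmoid)
  converged: True   residual norm: 0.4086
  param       estimate     std err
  Ai         -0.008646      0.0213
  Af           0.99476      0.0108
  t_half        98.283        1.81
  k_agg       0.052498     0.00434
  plateau: 0.99476
inhibition vs control: 83.4 %
```

Reading the output: the free peptide weighs 1883.0 Da; growing an
antiparallel sheet gains energy per added monomer, and the gain levels off
by the fourth strand; pairing two 4-strand sheets is itself favourable
(ΔEp_core < 0); a planted Arg13–Arg13′ hydrogen-bond ladder dominates the
sheet–sheet contact map at position 13 of every strand; and a treated
sample whose fitted ThT plateau is 0.165 of the control plateau is 83.4 %
inhibited.

A `crossbeta` umbrella CLI wraps the same stages
(`build-core`, `score`, `contacts`, `classify`, `fit-kinetics`, `cr-call`,
`simulate`); run `crossbeta --help` for the subcommands.

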
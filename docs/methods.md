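# Methods

This note documents the models, numerical choices and limitations behind
`crossbeta`. It is the package's own account of its science; every number
quoted here is computed by the test suite or `scripts/acceptance.py`.

## Peptide and conformer construction

The study peptide is the HEWL 49–64 fragment with the terminal cysteine
replaced by serine (`GSTDYGILQINSRWWS`, average mass 1883.0 Da), an
amyloid-forming 16-mer whose aggregation lacks a lag phase. Monomers are
built from ideal backbone dihedrals by NeRF chain extension with standard
trans-peptide bond geometry:

* β-strand (`B`): φ = −139°, ψ = +135° (ideal antiparallel-sheet values);
* α-helix (`H`): φ = −57°, ψ = −47°;
* native (`N`): template-derived only — no dihedral ideal exists for an
  irregular native fold, so the caller supplies coordinates.

Side chains are coarse-grained to Cβ plus one centroid pseudo-site per
residue at a residue-specific distance along the Cα→Cβ direction, carrying
a radius, a charge class (R/K +1, D/E −1), hydrogen-bond donor/acceptor
capability and an aromatic flag. This resolution supports residue-level
contact statistics and energy trends; it cannot represent rotamers or real
ligand chemistry, and does not claim to.

## Sheet assembly and the cross-β core

Strands stack at a nominal 4.8 Å inter-strand spacing (the canonical
β-sheet hydrogen-bond register). Antiparallel direction reversal is a 180°
rotation about the sheet normal; the per-strand side-chain *phase* is an
additional 180° rotation about the strand axis. The four sheet variants
are: `BP` (parallel, all in phase), `BA1` (antiparallel, all in phase),
`BA2` (antiparallel, alternating phase) and `BAa` (antiparallel, the phase
vector that minimizes the coarse energy, found exhaustively over the 2^n
combinations for n ≤ 6, ties to the lexicographically first).

Each added strand's in-plane registry (slide along the strand axis in
0.25 Å steps, spacing breathing ±0.5 Å in 0.1 Å steps) is chosen to
minimize the two-strand interaction energy. The scan is deterministic and
cached per relative pair geometry, and because each strand is placed only
against its predecessor, an n-strand assembly contains the (n−1)-strand
assembly as an exact prefix. For `BAa` the phase vector is optimized once
at the largest requested size and its prefixes are reused, preserving that
contract. With this construction `BA2` and `BP` carry a constant-width
backbone hydrogen-bond ladder at every interface; `BA1`'s same-phase
interfaces are geometrically frustrated in a rigid model (alternating
ladder widths), consistent with its lower stability ranking.

Core models pair two equal-sized sheets face to face: the second sheet is
flipped onto the first sheet's side-chain face, rotated randomly about the
sheet normal (seeded), scanned down a 8–12 Å mean-plane separation window
for the closest clash-free approach (heavy-atom floor 2.0 Å), and refined
by steepest descent on the rigid translation. Up to `n_poses` clash-free
cores are returned sorted by energy, ties broken by generation order.

## Coarse energy model

`score_structure` sums, over all site pairs not excluded as bonded
(same-residue and adjacent-residue pairs within a strand; all intra-ligand
pairs — ligands are rigid):

* Lennard-Jones in r_min/ε form, e(r) = ε[(r_min/r)¹² − 2(r_min/r)⁶], with
  per-role radii and depths from a versioned parameter file
  (`scorer_params.yaml`); distances are clamped at 0.8 Å and any pair
  energy capped at 10⁴ kcal/mol, so overlapping sites give a large finite
  penalty, never a non-finite value;
* screened Coulomb with a distance-dependent dielectric ε(r) = 4r;
* a hydrogen-bond bonus for donor/acceptor heavy-atom pairs between 2.4
  and 3.5 Å (full strength to 3.0 Å, linear taper beyond): 2.5 kcal/mol for
  backbone–backbone pairs, weighted by a cos² directional factor on the
  amide N–H when an explicit hydrogen exists, 1.5 kcal/mol for side-chain
  and ligand pairs.

The potential is deterministic and rigid-motion invariant (verified to
< 10⁻⁶ kcal/mol). Its absolute energies live on their own scale and are
**not** comparable to force-field potentials; only bookkeeping identities,
orderings and trends are contractual. On builder-generated antiparallel
sheets the per-monomer gain ΔE_n = (E_n − n·E_1)/n decreases monotonically
and its increments stabilize by the fourth strand
(|ΔE_5 − ΔE_4| ≈ 0.1·|ΔE_2 − ΔE_1|), and sheet pairing is favourable
(ΔEp_core < 0) — the qualitative shape of the published growth curves.

The formula ΔE_n = E_n − (E_1 × n)/n is read as (E_n − n·E_1)/n: the
literal precedence collapses to E_n − E_1, which is inconsistent with a
*per-monomer* gain (e.g. a 4-strand total of −2166 kcal/mol giving
−539.6 kcal/mol per monomer). The literal reading remains available behind
the `literal=True` flag for comparison.

### Reporting and rounding

Energy ledgers report nearest-integer kcal/mol, and a reported row's
pairing gain is recomputed from its *rounded* Ep fields, so printed rows
are always internally consistent (gain = core − 2·sheet holds exactly on
the integers). This convention reproduces the published table, including
the one row whose printed gain differs by 1 kcal/mol from the unrounded
formula (−28 printed vs −27 computed) — asserted only to ±1 and documented
as a presentation artefact.

## Contact maps

Hydrogen bonds are donor/acceptor heavy-atom pairs at distance < 3 Å
(strict), with roles from a fixed chemistry table (backbone N–H donates,
backbone O accepts, side-chain roles per residue). The criterion is
distance-only — no angle term — because only distance thresholds define
the statistic being reproduced. Van der Waals contacts are any heavy-atom
pair < 2.3 Å (strict) not already classified as a hydrogen bond; the two
classes are disjoint, hydrogen bonds taking priority. Counts accumulate per
(strand label, residue position) on the first group's side over all frames;
whether published counts were per-pair-per-frame or deduplicated per
residue is unknowable from the text, and per-pair-per-frame is implemented.
Both boundaries are strict for uniformity; the boundary set has measure
zero against jittered coordinates.

ThT-like ligands carry only aromatic sites — zero donors/acceptors — so
they can contribute van der Waals contacts but never hydrogen bonds,
encoding the dye's observed behaviour against the amyloid core.

## Inhibitor classification

A ligand with binding gain ΔEp_ligand *competes* with core formation when
ΔEp_ligand ≤ ΔEp_core + 20 kcal/mol (the tolerance is the published ±19
uncertainty rounded up; gains are negative). Its *contact overlap* is the
cosine similarity between its hydrogen-bond map and the core's sheet–sheet
hydrogen-bond map restricted to the core's stabilizing cells (counts at or
above half the maximum cell). The call is:

* `inhibitory` — energy-competitive **and** overlap ≥ 0.3;
* `indeterminate` — energy-competitive but with an all-zero hydrogen-bond
  map (binding energy alone cannot place such a ligand in the competition
  mechanism; this is the ThT case);
* `non-inhibitory` — everything else. Note that a weakly bound ligand can
  fall inside the energy tolerance and still be non-inhibitory because its
  contacts avoid the stabilizing positions — the resveratrol case, which
  binds Trp14 rather than the Arg13 column.

The classifier is monotone: making ΔEp_ligand more negative never flips
inhibitory to non-inhibitory. Both thresholds are configurable.

## Kinetics and Congo red

Traces are baseline-corrected (mean dye-only signal subtracted), then
normalized to the value at a late anchor time (nearest sample; ties to the
earlier point). Fits use least squares (lmfit) with data-driven starts:
A_i = min F, A_f = max F, t_1/2 = the half-range crossing time,
k_agg = 4/(t_90 − t_10), bounded k_agg ∈ (0, 10] h⁻¹. Non-convergence is
flagged on the result object, never raised. Noiseless synthetic traces are
recovered to 10⁻⁶ relative; over 200 noisy traces (σ = 0.05 on a unit
plateau, 60 points over 300 h) each parameter's mean is within 5 % of truth
and the median |t_1/2| error is ≈ 1 h.

The Congo-red amyloid call computes R = D − C − B on the common
400–700 nm grid and requires a local maximum of R within 540 ± 10 nm
exceeding 3× the median absolute deviation of R outside the 500–600 nm
band (with a tiny absolute floor so an identically-zero R is negative).

## Synthetic data

Generators are pure functions of (spec, seed); seeds are mandatory and are
recorded in output metadata. Trajectories add per-atom Gaussian jitter
(default σ = 0.3 Å — small enough to preserve a hydrogen-bond ladder in
most frames, large enough to vary counts) to a built structure; planted
contacts are pulled inside their cutoff *after* jitter in exactly
⌊fraction·N⌋ frames, guaranteeing the planted cell at least that many
counts. Kinetic traces are model curves plus Gaussian noise; CR spectra are
smooth dye/aggregate baselines plus an optional Gaussian red-shift peak.

What passing tests show — and what they do not: the generators exercise
the counting and fitting machinery against planted truth; they do not
emulate force-field dynamics, solvent, pH, or real ligand chemistry. In
particular the published absolute contact counts and force-field energies
depend on real MD trajectories and are deliberately out of reach; the
package reproduces the *bookkeeping* on published energies exactly, and
the *behaviour* of the machinery on known ground truth.

## Problem sizes

Default sizes mirror the study design where one exists: 16-residue
peptide, sheets of up to 5 strands, 4-strand sheets paired into cores, 10
pose candidates per pairing, 200-frame trajectories subsampled at stride
10 to 20, 200-trace fitting ensembles, 400–700 nm spectra at 1 nm. The
acceptance script runs the full pipeline at these sizes in well under a
minute on one CPU.

## Known limitations

* No force-field MD, docking of real chemistry, or pH titration; the
  native (N) conformer requires a user template.
* Rigid monomers: no backbone relaxation or twist, so β-sheets are flat
  and the BA1 variant's frustrated interfaces carry no ladder.
* Ligands are role-labelled site strings, not molecules; computed binding
  gains are qualitative (ordering only).
* Uncertainties on fitted kinetic parameters are least-squares standard
  errors; plateau-ratio uncertainties can be taken either from those or
  from replicate spread — both are exposed, neither is privileged.
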
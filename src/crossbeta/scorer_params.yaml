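# Coarse-grained scorer constants, version-pinned so that every energy the
# package reports can be traced to one parameter set.  Units: A, kcal/mol.
# Absolute energies from this potential live on their own scale; only
# bookkeeping identities, orderings and trends are meaningful.
version: 1
lj:
  # Lennard-Jones r_min / epsilon per backbone atom class.  Side-chain
  # centroid r_min comes from the per-residue chemistry table; its epsilon
  # is chosen by polarity class below.
  N: {rmin: 3.3, eps: 0.12}
  CA: {rmin: 3.8, eps: 0.08}
  C: {rmin: 3.8, eps: 0.08}
  CB: {rmin: 3.8, eps: 0.10}
  O: {rmin: 3.1, eps: 0.15}
  sc_eps_polar: 0.15
  sc_eps_aromatic: 0.30
  ligand: {rmin: 4.0, eps_polar: 0.15, eps_apolar: 0.30}
coulomb:
  k: 332.06            # Coulomb constant for kcal/mol with e and A
  dielectric_slope: 4.0  # distance-dependent dielectric eps(r) = slope * r
  r_floor: 1.0
hbond:
  backbone_eps: 2.5    # well depth of the directional backbone N-H...O bonus
  sidechain_eps: 1.5   # distance-only bonus for side-chain / ligand pairs
  r_on: 2.4
  r_full: 3.0          # full strength out to here ...
  r_off: 3.5           # ... tapering linearly to zero here
clash_floor: 2.0       # heavy-atom overlap below this is penalized
pair_cap: 10000.0      # finite ceiling for any single pair energy
r_floor: 0.8           # distances are clamped here before LJ evaluation
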
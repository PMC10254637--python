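# Methods

## The deletion-scan model

The quantity of interest is the contribution of each environment residue
*m* to an enzyme's activation barrier, measured by deleting the residue in
both the reactant (R) and transition-state (TS) structures and recording
the barrier shift ΔΔE_m−wt = ΔE_m − ΔE_wt. A negative ΔΔE means the intact
residue stabilizes R more than TS (anticatalytic); cancelling its charge
is predicted to be rate-enhancing.

`dipolescan` implements this scan with a classical surrogate of the
QM/MM electrostatic-embedding experiment. The reacting core is represented
by a fixed set of point charges with two per-state charge vectors; the
environment is a set of point charges read from PQR records. Deleting
residue *m* removes its point charges, so with rigid geometry the only
term that changes is the residue↔core Coulomb energy and

ΔΔE_m = −(V_TS(m) − V_R(m)),  V_X(m) = (k/ε) Σ_{i∈m, j∈core} q_i q_j / r_ij

with k = 332.0637 kcal Å mol⁻¹ e⁻². This is the surrogate's defining
approximation: a real QM/MM deletion also changes MM-internal terms and
the polarization of the QM wavefunction. The surrogate preserves the
*structure* of the analysis — signs, additivity, thresholding, ranking —
not the absolute magnitudes of any particular enzyme. Consequently no
claim is made that the toy ΔΔE values reproduce published per-residue
values for NCS; only the selection logic and arithmetic are asserted, and
those are tested exactly.

Key numerical identities the implementation guarantees:

- **Additivity.** Per-residue ΔΔE values sum to the negated total
  environment differential, because pairwise Coulomb sums are linear in
  the charge sets.
- **λ-linearity.** With rigid geometry, ΔΔE is linear in the fraction λ of
  charge transferred between the donor and acceptor sites; λ = 0 gives 0.
- **Sign law.** For a donor→acceptor transfer of positive charge, a
  positive probe strictly closer to the acceptor has ΔΔE < 0, and |ΔΔE|
  decreases strictly as the probe retreats along the dipole axis. This is
  the geometric selection rationale the scan operationalizes.
- **Ledger replay.** The scan composes ΔE_m as
  (ΔE_wt − V_TS) − (−V_R) — the same floating-point expression the ledger
  applies to an energy table — so exporting a scan as a wild-type/deletion
  table and recomputing reproduces ΔE_m and ΔΔE bit-for-bit.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `dE_wt` | 10.6 kcal mol⁻¹ | wild-type barrier; an input, never computed (the QM core is out of scope). Default is the modeled NCS rearomatization barrier. |
| `radius` | 10.0 Å | deletion-eligibility cutoff: minimum distance from any residue atom (hydrogens included) to any core atom, measured on the reactant. Gly/Pro are always excluded (no side-chain charge worth cancelling, backbone perturbation only). |
| `threshold` | 1.0 kcal mol⁻¹ | candidate cut, strict: ΔΔE < −1.0 exactly excludes a residue at −1.0. |
| `epsilon` | 1 | uniform dielectric divisor; vacuum Coulomb matches the embedding-field character of electrostatic embedding. No distance cutoff, no periodicity. |
| `neighbor_radius` / `max_heavy_neighbors` | 8 Å / 16 | exposure proxy: foreign heavy atoms around the charged-group centroid. |
| `hbond_cutoff` | 3.5 Å | a foreign polar heavy atom (N/O) this close to the charged group marks the residue as H-bond engaged. |

Energies are reported at 0.1 kcal mol⁻¹ in human-readable reports and at
full precision (`repr`) in TSV/CSV machine output. The ledger accepts
hartree (× 627.509474) or kcal mol⁻¹, or an explicit scale factor; it
never applies zero-point, thermal or entropic corrections.

Design points that were genuinely open and were fixed as follows:

- "Within the cutoff of the active-site region" is operationalized as
  minimum atom distance to the *core atoms themselves* on the reactant
  structure; no larger pocket definition exists in the inputs.
- Residue identity is (chain, author residue number, residue name);
  author numbering is preserved verbatim throughout.
- Deletion removes the residue's charges, not merely its side chain;
  under the rigid-environment model the distinction is invisible in ΔΔE.
- Arg has no canonical charge-cancelling partner of similar size; the
  default map sends Arg→Gln rather than dropping Arg candidates, and the
  mapping is config-overridable.
- His counts as charged only when its recorded side-chain charges sum to
  a nonzero integer; protonation is never inferred from the name.
- Exposure and H-bond freedom are deliberately coarse geometric proxies,
  reported as annotations with raw counts and never used as filters.
- RMSD is plain (non-mass-weighted) least-squares superposition with a
  proper rotation (det = +1; mirror images do not superpose to zero). The
  reference frame is an explicit argument, default the first frame.
  Fitting requires ≥3 non-collinear atoms; fit and measure selections may
  differ.

## The synthetic generator

`synthgen` emulates the situation the scan assumes rather than any force
field: a six-atom core whose donor-site atom (quinonoid oxygen) loses λ
and acceptor-site atom (carboxylate oxygen) gains λ of a unit charge
between states (default λ = 0.5: the transferring proton halfway along
the coordinate; site separation 4 Å), surrounded by residues built from
small side-chain-like templates (charged groups summing to ±1 e, polar
dipoles summing to 0) on a 12–18 Å shell. The default `toy-ncs` preset
plants six charged residues on the anticatalytic side of the dipole with
the author numbering of the motivating system's candidates, a neutral but
strongly dipolar tyrosine-like residue close to the core (large negative
ΔΔE with nothing to mutate), a procatalytic buried control caged by 24
neutral atoms, and a far-out exposed control with zero neighbours by
construction.

The environment is rigid: coordinates and environment charges are
identical in R and TS, so all MM–MM terms cancel exactly in ΔΔE and each
residue's ground-truth effect is a closed-form Coulomb sum. The generator
computes that ground truth with a plain Python double loop over the final
precision-rounded records — a code path independent of the vectorized
engine — and stores it in JSON next to the PQR/core files. Coordinates
are written at 0.001 Å and charges at 0.0001 e so files round-trip
exactly.

What the toy fixtures do **not** emulate: conformational flexibility,
polarization and charge transfer, solvent screening, realistic charge
distributions, or coupling between deletions. Passing tests therefore
demonstrate that the *analysis machinery* is correct and internally
consistent, not that the surrogate predicts real mutational outcomes.

Trajectory fixtures add i.i.d. Gaussian noise (σ per coordinate) to a
reference geometry; frame 0 is emitted unjittered so the file's first
model is the exact reference. Energy-table fixtures plant exact ΔΔE
values per residue and optionally add Gaussian noise to every state
energy; the noiseless ledger recovers the planted values to rounding.

## Problem sizes and numerics

The shipped test and acceptance workloads use: 50 random fixtures of up
to ~200 atoms for oracle equivalence (tolerance 1e-9 kcal mol⁻¹ against
unvectorized loops), 100 seeded geometries × 5 retreat steps for the sign
law, 1000 noisy-table replicates (σ = 0.1 kcal mol⁻¹ per energy, planted
effects −2.5…+2.2 with the weakest true candidate at |ΔΔE| = 1.7),
2000-frame σ = 0.05 Å trajectories for monitor recovery (0.02 Å
tolerance), and the seed-42 toy preset for the report pattern. These
sizes make every check sharp while keeping the whole suite around a
minute on one core.

Degenerate inputs are rejected loudly: overlapping cross-group atoms
(< 1e-6 Å), collinear or undersized superposition fits, empty QM regions,
duplicate atom keys or table rows, mismatched R/TS atom orderings, and
core charge vectors whose totals differ (charge must be conserved by the
transfer). Ties in ΔΔE sort by residue key, so all outputs are
deterministic given inputs and seeds.

## Known limitations

- ΔE_wt is pass-through: the surrogate cannot detect an inconsistent
  barrier input.
- The point-charge deletion ignores residue polarizability and geometric
  relaxation after deletion, both present in real QM/MM deletions.
- The exposure/H-bond proxies use fixed geometric cutoffs and no solvent
  model; on real structures they should be read as flags for inspection,
  not verdicts.
- PQR parsing is whitespace-based (both common dialects); fixed-column
  PDB files with unusual residue names wider than 4 characters are not
  supported.
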
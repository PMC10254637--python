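# dipolescan

Rational enzyme-engineering toolkit built around **transition-state
macrodipole stabilization analysis**: find the charged residues whose
electrostatic field stabilizes an enzyme's reactant more than its
transition state, and propose charge-cancelling mutations predicted to be
rate-enhancing.

The motivating system is (*S*)-norcoclaurine synthase (NCS), the enzyme
that opens benzylisoquinoline-alkaloid biosynthesis and a known bottleneck
for producing these drugs in heterologous hosts. In its rate-limiting
rearomatization step, a proton leaves the quinonoid intermediate's C5
toward a catalytic glutamate carboxylate, so negative charge builds on the
substrate's *para* oxygen while the carboxylate is partially neutralized.
Residues whose charges favour the *reactant* side of that rearrangement are
**anticatalytic**; neutralizing them should lower the barrier. The same
analysis applies to any enzyme with a localized charge shift between R and
TS.

## The method

Given reactant (R) and transition-state (TS) structures and the barrier of
the intact enzyme ΔE_wt, delete each environment residue *m* in both
states, recompute the barrier ΔE_m, and record

```
ΔΔE_m−wt = ΔE_m − ΔE_wt
```

Residues with ΔΔE < 0 raise the wild-type barrier; those beyond
−1 kcal mol⁻¹ are mutation candidates. In a full QM/MM treatment ΔE comes
from single-point energies with the residue removed from the MM embedding.
`dipolescan` replaces the QM core with a classical point-charge
distribution that differs between the two states, so a deletion changes
only the residue↔core Coulomb term:

```
ΔΔE_m = −(V_TS(m) − V_R(m)),   V_X(m) = k Σ q_i q_j / r_ij ,
k = 332.0637 kcal Å mol⁻¹ e⁻²
```

ΔE_wt itself is an input (default 10.6 kcal mol⁻¹, the modeled NCS
barrier). The `ledger` module applies the same ΔΔE arithmetic to energy
tables exported from real QM/MM runs, so the surrogate and the real
experiment share one downstream pipeline: scan → ledger → candidate report
with charge-cancelling substitutions (Glu→Gln, Asp→Asn, Lys→Gln; Arg falls
back to Gln), catalytic-residue exclusions, and geometric
exposure/H-bond-freedom annotations. Geometry-stability tools (Kabsch
superposition RMSD, catalytic-distance monitors with min-over-set
semantics) cover the checks usually made on the underlying model before
trusting the energetics.

## Worked example

The package ships a synthetic-fixture generator whose default preset
mimics the NCS study layout: a donor/acceptor charge-transfer core
(λ = 0.5, the proton halfway), six charged residues planted on the
anticatalytic side of the dipole, one neutral but strongly dipolar
tyrosine-like residue, and buried/exposed control residues — all with
closed-form ground-truth ΔΔE.

```
$ dipolescan run --outdir demo --seed 1
[1/3] simulate (seed=1)
[2/3] scan (radius=25.0 Å, wt barrier 10.6 kcal/mol)
[3/3] advise
  candidate ASP64: ddE -5.4 kcal/mol -> ASP->ASN
  candidate ASP71: ddE -3.9 kcal/mol -> ASP->ASN
  candidate GLU117: ddE -3.6 kcal/mol -> GLU->GLN
  candidate ARG105: ddE -3.0 kcal/mol -> ARG->GLN
  candidate LYS110: ddE -2.3 kcal/mol -> LYS->GLN
  candidate LYS163: ddE -2.1 kcal/mol -> LYS->GLN
report -> demo/report.md
```

Each line is one surviving candidate: deleting ASP64's charges changes the
surrogate barrier by −5.4 kcal mol⁻¹ (it stabilizes the reactant most), so
the report suggests the charge-cancelling ASP→ASN substitution. The
neutral tyrosine-like residue also has ΔΔE < −1 but appears only in the
report's ineligible section — there is no charge to cancel — and the
catalytic residues are excluded regardless of their effect.

Individual stages are available as `dipolescan simulate | scan | ledger |
monitor | advise`; e.g. an external QM/MM energy table in hartree:

```
dipolescan ledger --energies energies.csv --unit hartree -o scan.tsv
```

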
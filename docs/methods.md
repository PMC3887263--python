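# Methods

## Scope and model

The package implements the analysis layer of a host–guest inclusion-complex
characterization: interpretation of ESI mass spectra of a host/guest mixture,
and post-processing of electronic-structure results (total energies and
optimized geometries). It does not perform, and does not emulate, the
upstream quantum chemistry — DFT energies and coordinates are consumed
as inputs.

### Ion model

Every candidate ion is a multiset of neutral components (host, guest, or a
registered fragment species) plus charge carriers:

    a·Host + b·Guest + nH·H + nNa·Na,   z = nH + nNa,  |z| ≥ 1

`nH` may be negative (deprotonation); `nNa ≥ 0`. Sodium salts of the guest
are deliberately *not* modelled as separate molecular species: a guest
carried as its sodium salt is compositionally identical to the free acid
plus one Na and minus one H, so treating "AlnNa" as a component would double
count ions (e.g. a 1:2 complex written with two salt guests and two protons
is the same ion as the one written with two free-acid guests and two
sodiums). One canonical H/Na spelling per ion avoids that; the label
grammar renders it as `[βCD + 2AlnH + 2Na]2+`.

Theoretical m/z uses monoisotopic masses and subtracts `z` electron masses
(0.549 mDa per charge — at the 3-decimal precision of TOF peak lists this
correction is larger than the calibration jitter of good peaks and is not
optional). Glucose-oligomer fragments (C₆H₁₀O₅)ₙ, n = 2–6, arising from
in-source fragmentation of the cyclodextrin, are injected as explicit
species rather than enumerated; n = 7 is excluded because it is isomeric
with the intact macrocycle.

### Isotope machinery

Isotope masses and abundances for C, H, N, O, Na, P ship as a versioned
JSON table (`hostguest/data/isotopes.json`, AME2020/CIAAW values) so every
mass in the package is reproducible bit for bit. Patterns are computed by
per-element convolution with binary exponentiation; peaks closer than a
merge width (default 0.01 Da) are coalesced into abundance-weighted
centroids and entries below a prune threshold (default 10⁻⁴ of the base
peak) dropped. Intermediate convolution steps merge 100× narrower and keep
a 1000× deeper floor than requested, so the final merge/prune reproduces
what a single exhaustive isotopologue enumeration would give; the test
suite checks this identity against a brute-force enumeration for small
formulas.

### Assignment

A peak matches a candidate when |observed − theoretical| ≤ 0.010 Da **or**
≤ 25 ppm, whichever is wider at that m/z. The absolute arm covers the
low-m/z region; the relative arm is sized to span the mass-calibration
drift of the reference mixture spectra, which stays below 8 ppm in positive
mode but grows to ≈23 ppm at high m/z in negative mode — with a narrower
ppm gate the documented high-mass negative-ion assignments (e.g. the 1:4
complex dianion and the 3:4 trianion) would be rejected as unassigned.
Candidates for one peak are ranked by |Δm|; exact ties — notably the
[M + H]⁺ / [2M + 2H]²⁺ doubling degeneracy — are broken by parsimony:
fewer neutral components, then lower |z|, then fewer sodiums, then label.
Ranking depends only on m/z, so it is invariant under intensity rescaling.

The isotope-fit score is the cosine between observed and theoretical
intensities sampled at isotopologue slots k = 1…n−1 spaced 1.00336/|z| from
the observed monoisotopic peak. The k = 0 anchor is excluded by design: it
defined the match and would dominate the cosine (pushing any hypothesis
with a matching monoisotopic m/z above 0.9), whereas the slots beyond it
are what actually distinguish charge states — a z = 2 hypothesis for a
z = 1 species finds nothing at half-integer spacing and scores near zero.
The score is reported alongside the rank, never folded into it.

### MS/MS interpretation

Product spectra of singly charged precursors are interpreted as sequential
single neutral losses, expanded breadth-first to a configurable depth
(default 4) with impossible losses (negative element counts) pruned. Each
product peak takes the chain with the smallest |Δm|; chains that tie
exactly in mass — an unavoidable case here, since H₃PO₃ ≡ H₂O + HPO₂
elementally, so a double H₃PO₃ loss and the H₃PO₃→H₂O→HPO₂ sequence give
the same product — are ranked by how many of their intermediate fragments
are themselves observed in the spectrum, then by chain length. This prefers
ladders supported by the data, which is how fragmentation pathways are
assigned in practice.

### Energetics

ΔE = E_complex − (E_host + E_guest), the supermolecule binding energy.
Inputs in hartree are converted at 627.5095 kcal/mol per hartree; the
conversion commutes with the subtraction to numerical precision. No BSSE
or solvation corrections (the upstream calculations are gas phase without
counterpoise). Orientation comparison sorts ascending by ΔE with a stable
label tie-break and reports all pairwise differences and per-orientation
hydrogen-bond counts.

### Hydrogen-bond detection

Molecules are partitioned by covalent connectivity: atoms are bonded when
their separation is below 1.2 × the sum of Cordero covalent radii. PDB
chain labels are ignored — for a docked complex written by a modeling
package, geometry is the ground truth. A hydrogen bond D–H···A requires H
covalently bound to D (O or N), A (O or N) in a different molecule,
H···A ∈ [0.8, 2.8] Å and D–H···A angle > 120°. The distance criterion is
applied to the H···acceptor separation: the 0.8 Å lower bound only makes
sense there (it excludes covalent contacts), and typical detected lengths
(1.7–2.1 Å) are H···A values. Classification is by acceptor environment;
for phosphonate oxygens, the acceptor is labelled "P=O" when it is that
phosphorus' shortest P–O contact and "P–O" otherwise — a bond-length
heuristic for the formal double bond, flagged as heuristic in the
docstring, since no wavefunction information is available.

## Synthetic data

`simulate_spectrum` places each species' top isotopologues at theoretical
m/z, perturbed multiplicatively by Gaussian jitter of σ ppm (default 3 ppm,
a realistic calibration error for a benchtop TOF), plus uniform decoy peaks
rejected within 3σ (≥0.02 Da) of any true peak so that truth labels stay
unambiguous. `plant_hbond_geometry` constructs each requested bond exactly
— hydroxyl donor with O–H = 0.96 Å, acceptor fragment realizing the
requested distance/angle and chemical class — in its own randomly rotated
cluster on a 12 Å grid, with decoy atoms (C/N/O, never H) kept ≥3.5 Å from
planted atoms so they can neither create a spurious bond nor bridge the
donor and acceptor into one molecule. Both generators are deterministic
under a seed.

What passing synthetic tests shows: the bookkeeping (enumeration, tolerance
gating, ranking, geometry math) is correct. What it does not show: behavior
under resolution-limited envelope overlap, detector saturation, real
intensity response, or conformational strain — none of which the generators
model.

## Numerical choices and edge cases

- Assignment Δm ties compare |Δm| rounded to 10⁻⁹ Da so that floating-point
  noise between mathematically identical m/z values (the doubling
  degeneracy) cannot shadow the parsimony tie-break.
- Spectra reject duplicate m/z values closer than 10⁻⁶ Th; peak lists are
  sorted on load; non-numeric CSV rows are rejected with their line number.
- Deprotonation beyond the available hydrogens of the ionic formula is an
  error at m/z evaluation and silently excluded during enumeration.
- Empty formulas have mass 0 and are valid intermediates but invalid
  species; formula subtraction below zero raises.
- Equal-ΔE orientations keep a stable label order.

## Problem sizes

Default enumeration yields 370 candidates per polarity (a, b ≤ 4, nNa ≤ 4,
|z| ≤ 3, plus five glucose-fragment species with H⁺/Na⁺ adducts); the
reference peak lists are 18 (positive) and 10 (negative) peaks. Recovery
statistics in the test suite use 20 seeds for planted-geometry runs and
20 seeds × 4 jitter levels for the monotonicity check; structures carry up
to ~150 decoy atoms, well within the exhaustive-oracle regime used for
cross-validation.

## Known limitations

- Only H⁺/Na⁺ charge carriers (no K⁺, NH₄⁺, Cl⁻) and centroid peak lists
  (no profile data, no mzML).
- The unidentified reference ion at m/z 1179.340 stays unidentified here
  too: no candidate within the default space falls inside tolerance (the
  nearest miss is ≈2 Da away), which is itself a useful negative control.
- Published H-bond tables can be reproduced in format and criterion but not
  recomputed from deposited coordinates (none exist); geometry validation
  is therefore synthetic-only.
- The P=O vs P–O distinction is a distance heuristic, not an electronic-
  structure assignment.
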
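# Methods

## Mass arithmetic

Monoisotopic atomic masses are frozen 7-dp constants (C 12 exactly,
H 1.0078250319, N 14.0030740052, O 15.9949146221, Na 22.98976928,
K 38.9637069, S 31.97207069).  Cation m/z subtracts one electron mass
(0.00054858 Da) per charge: for sodiated sirolimus this yields 936.5444
at 4 dp, where the uncorrected sum would print 936.5449 — the correction
is observable at the precision this field reports.  All arithmetic is
carried at full floating precision; display rounding is decimal half-up
(4 dp for m/z, 1 dp for ppm).  The ppm error uses the theoretical mass in
the denominator, the standard convention.

Metabolic shifts are derived from formula changes, not typed constants:
O-demethylation is −CH2 (−14.015650), hydroxylation +O (+15.994915),
water loss −H2O (−18.010565), methanol loss −CH4O (−32.026215).  Shifts
compose additively and commutatively; all five metabolite-class molecular
ions are reachable from the parent [M+Na]+ by composition.

## The fragment library

The library (`src/metid/data/srl_fragments.tsv`) holds the sodiated
α-cleavage fragments A–R with theoretical m/z, a coverage set of retained
carbon positions (IUPAC numbering, 1–52 plus the token `pip` for the
piperidine ring C3–C6, which MS evidence never resolves), a parent link
forming an MSⁿ tree rooted at the molecular ion, and site-specific
hydroxylation diagnostic ions.  Validation enforces unique labels, a
single precursor whose mass matches the formula arithmetic to 0.0001 Da,
child coverage nested inside parent coverage, and agreement of every
stored mass with the published 4-dp exact-mass table.

Two aspects of the library are reconstructions, because the appendix
carrying per-fragment structures is not deposited in machine-readable
form:

* **Coverage sets** honor every constraint the main analysis states —
  K (607.3969) covers C17–C49/C51/C52 and excludes C16, C11, C12, C14 and
  the piperidine; C (642.3249) and D (345.2036) cover C39 and exclude
  C27; G (614.3300) and O (441.2611) cover C23/C24; Q (320.1105) covers
  the piperidine; D covers C49 — and are otherwise synthetic but
  chemically coherent (contiguous backbone regions plus attached
  methyls).  The solver is agnostic to the specific sets; every published
  exclusion/support argument is reproduced by construction and asserted
  in tests.
* **Sub-4-dp digits.**  Stored masses carry 6 dp chosen inside the
  ±0.00005 window of the printed 4-dp values so that the printed
  *shifted* ions also reproduce at 4 dp (e.g. K = 607.396920 makes
  K − CH2 print 593.3813; G = 614.330020 makes G + O print 630.3249 and
  G + O − H2O print 612.3144).  Naive 4-dp-on-4-dp arithmetic lands on
  rounding boundaries and misses three printed values by one final digit.

Known inconsistencies in the printed sources are documented in the data
files rather than silently corrected: the 27-O-desmethyl molecular ion
once printed as 922.5887 (arithmetic gives 922.5287); the C23/24-shifted
ion printed both 457.2561 and 457.2556 (the library computes 457.2560);
the piperidine diagnostic printed 336.1050 and 336.1053 while Q + O
computes 336.1054 (all within the 5-ppm rule); the ppm table's row O
prints 0.5 where its own mass pair computes 0.2.

## Forward model

`expected_peaks(lib, mods)` shifts every fragment by the summed deltas of
the modification entries whose site intersects its coverage (a candidate
pair like {23,24} shifts a fragment iff the pair intersects coverage).
Hypotheses carry at most two modifications — the study conditions produce
first- and second-generation metabolites only.  Two rules add satellites:

* **R1 (methanol loss).**  Hydroxylating a methyl carbon (C45/C46) turns
  it into −CH2OH, and fragments carrying it readily lose CH3OH; each
  fragment shifted by that entry emits a −32.0262 satellite.
* **R2 (dominant water loss).**  C23/C24 hydroxylation produces a
  secondary alcohol whose water loss is unusually facile; each shifted
  fragment emits a −18.0106 satellite expected to *exceed* its parent's
  intensity (threshold ratio 1.0, configurable).

Diagnostic ions (11→723.4806; 12→711.4442/389.2293/357.2031; 14→612.3133;
25→447.2718/327.1922; 49→361.1978; pip→336.1050) are appended when their
site is hypothesized, shifted by any co-modification intersecting their
own coverage — reproducing, e.g., the 12-hydroxy diagnostic at 697.43 in
the 12-hydroxy/39-desmethyl metabolite and at 727.44 in the
12,23/24-dihydroxy metabolite.

## Inverse solver

`localize` enumerates the 67 legal modification sets, keeps those with
the net type multiset implied by the precursor offset (the six possible
net deltas are ≥ 12 Da apart, so the multiset is unambiguous at 5 ppm),
and rejects a hypothesis when a fragment is observed at a shift the
hypothesis cannot produce — in particular, observed *unshifted* while the
hypothesis places a site inside its coverage — unless the peak is equally
explained by one of the hypothesis' own expected ions.  That escape
clause is how isobaric coincidences are resolved in favor of the
interpretation consistent with the precursor delta; they are real in this
chemistry: A = B − CH3OH, H = N − CH3OH, O = J − CH3OH and I = O + H2O
hold to within 0.2 mDa, so a shifted A sits exactly where shifted B's
methanol satellite would.  For the same reason the R1/R2 signature
detectors ignore satellite candidates that coincide with any legitimate
fragment-shift variant.

Positive signatures then prune: R1 restricts a hydroxylation to {45,46},
R2 to {23,24}, and a matched diagnostic pins its site.  A filter that
would empty the survivor set is recorded as conflicting evidence and not
applied, so a stray coincidence (e.g. the 1.8-ppm proximity of the 14-OH
diagnostic 612.3133 to the C23/24 water-loss ion 612.3144) degrades
gracefully instead of producing a wrong exclusion.  Finally, survivors
are ranked by how many of their predicted satellites and diagnostics are
actually observed, and the best-explaining set is reported; several
equally good survivors set the ambiguity flag, as does any unsplit
candidate pair.  If every hypothesis is contradicted the solver raises a
structured `InconsistentEvidenceError` listing the conflicting evidence —
never a silent best guess.

Enumeration-plus-filtering is equivalent to constraint propagation over
per-modification candidate sets for single modifications, and remains
well-defined when both modifications have the same type (where "intersect
this modification's candidates with the shifted fragment's coverage" is
not, since the shift does not say which of the two entries produced it).

What the noise benchmark shows: with 2 ppm Gaussian mass error and 20
uniform decoys per spectrum, the true sites stay inside the reported
candidates in ≈98–99% of 200 seeded runs; failures are almost entirely
peaks drifting past the 5-ppm gate.  What it does not show: performance
against real chromatographic co-elution, isotope interference, or
intensity physics — the simulator's intensities are flat apart from the
R2 signature, and the solver deliberately uses intensity nowhere else.

## Formation kinetics

`fit_mm` minimizes Σ(v − Vmax·S/(Km+S))² with positivity bounds
(scipy least-squares, analytic Jacobian), initialized at Vmax⁰ = max v
and Km⁰ = the substrate concentration nearest half-maximal velocity; at
least four distinct concentrations are required.  Unweighted by default
with an optional 1/v weighting, since no weighting scheme is reported for
the original fits.  CL_int = Vmax/Km exactly; the seven published
Vmax/Km pairs reproduce every printed CL_int at its printed precision,
and their full-precision sum is 2.3347 (prints 2.33; the source prints a
total of 2.35, which matches neither the unrounded sum nor the sum of its
own rounded entries, 2.36 — the package reports full precision and leaves
the discrepancy documented).

Confidence intervals are percentile bootstrap (default n = 1000, seeded),
case-resampling replicates within each substrate concentration, falling
back to residual resampling with a warning when replicates are missing.
With quadruplicates at seven concentrations and 10% log-normal noise the
empirical coverage of the 95% Vmax interval is ≈88.5% (400-simulation
estimate) — the mild undercoverage expected of the percentile method at
n = 4 per group; the method is kept for its distribution-freeness and
reproducibility, and the test suite asserts the empirically measured
rate, not the nominal one.

The synthetic velocity generator uses the experimental design (3.25, 7.5,
15, 30, 60, 90, 120 µM; quadruplicates) with multiplicative log-normal
noise, default CV 10% — multiplicative because velocities span an order
of magnitude across the grid.  Parameter recovery under those conditions
has median relative errors of ≈2–3% (Vmax) and ≈7% (Km).

## Site energetics

The demethylation thermodynamic cycle sums the methyl-abstraction and
hydrogenation free energies per site; C16 (−24.05) < C39 (−21.89) < C27
(−12.70 computed; printed −12.71) reproduces the preference order
C16 > C39 > C27.  The quantum-chemistry and MD engines are not run here;
the module consumes published or synthetic numbers, because the
combination and ranking logic — not the electronic-structure calculation
— is what this package contributes.

Heme-proximity evidence is reduced to occupancy within a distance
threshold (default 5 Å, the outer edge of the reactive window) plus the
median distance, used ordinally: full radial-distribution-function
estimation is deliberately out of scope since only the ordering of
candidate atoms carries meaning downstream.  The proximity label (C46
over C45, C23 over C24) is soft evidence: the solver reports the unsplit
pair from MS data and leaves the simulation-based preference as an
annotation, keeping the two evidence channels separate.

## Problem sizes and determinism

Every stochastic component takes an explicit seed and is bit-reproducible
given (config, seed).  The analysis drivers and acceptance script use
200 simulations for the solver noise benchmark and per-metabolite
kinetics recovery, 1000 bootstrap resamples for a representative CI, and
5000 frames for the proximity example — sizes at which the reported rates
have sampling errors comfortably inside the margins being asserted while
the full pipeline runs in seconds.

## Limitations

The 21-metabolite fixture set is rendered from a manifest by the
simulator, not measured spectra; passing it demonstrates that the
solver's logic reproduces the documented reasoning chains, not that it
would survive raw instrument data.  Fragment coverage beyond the
documented anchors is reconstructed, so per-fragment conclusions that
depend on undocumented coverage should not be read off the fixture.
Stereochemistry, rotamers (the 39-O-desmethyl rotamer peak is a
chromatographic phenomenon), ring-opened seco degradation artifacts, and
quantitative abundance from intensities are out of scope.
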
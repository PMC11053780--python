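# Methods

`bbkit` implements the comparative-analysis machinery used to screen
cytarabine (Ara-C)-class nucleoside analogues against deoxycytidine kinase
(dCK): zero-field ¹⁴N NQR algebra, Hirshfeld-surface contact statistics,
a binding-mode distance statistic (RMSD_BM), conceptual-DFT reactivity
descriptors with reference-relative forms, and a combined screening rule.
This note records the models, the conventions chosen where the design was
genuinely open, and what the tests do and do not establish.

## ¹⁴N NQR triplet algebra (`bbkit.nqr`)

A spin-1 nucleus in zero field resonates at up to three frequencies
ν₊ ≥ ν₋ ≥ ν₀ with ν₀ = ν₊ − ν₋. The pair (ν₊, ν₋) determines the
quadrupole coupling constant and the electric-field-gradient asymmetry:

    e²qQ/h = (2/3)(ν₊ + ν₋)  [MHz]      η = 3(ν₊ − ν₋)/(ν₊ + ν₋)  ∈ [0, 1]

and conversely ν± = (e²qQ/h)/4·(3 ± η). A pair with ν₋ < ν₊/2 would imply
η > 1 and is rejected as an invalid triplet. Experiment yields only
|e²qQ/h|; `QuadrupoleParams` stores the magnitude and carries an optional
signed field for calculated values.

Published triplet tables are occasionally internally inconsistent (rounded
literature values, at least one outright typo). The validator therefore
*reports* — ν₀ consistency at a tolerance (default 0.005 MHz, the printed
resolution), implied-η range, and optional agreement with printed
parameters at 3 decimals — and never corrects the data.

**Experiment-vs-calculation agreement** is an ordinary least-squares fit of
experimental frequencies on calculated ones (scipy `linregress`), reporting
slope, intercept, r² and the residual sd on n − 2 degrees of freedom. Which
quantities enter the published fit is not stated; this package regresses
the paired frequencies. Empirically, regressing the derived (e²qQ/h, η)
pairs instead reproduces the published r² = 0.997 for the
hydrogen-optimized cytarabine block; a unit test records that observation.

## Hirshfeld contact statistics (`bbkit.contacts`)

A contact table gives the percentage of a crystal's Hirshfeld surface
assigned to each species-pair category; for the {C, H, N, O} compounds
treated here the ten categories in fixed order are
CC HH NN OO CH CN CO NH OH NO (hydrogen is written second in heteronuclear
labels). Derived quantities:

* surface proportion  S_X = C_XX + ½·Σ_{Y≠X} C_XY  (an exact partition:
  the proportions sum to the table total);
* random-mixing expectation  R_XY = 2·S_X·S_Y/100 (X ≠ Y), S_X²/100;
* enrichment  E_XY = C_XY / R_XY, privileged above 1, disfavored below.

Entries with R_XY < ε are reported as null; ε defaults to 0.1%, which
suppresses exactly the near-zero-over-near-zero ratios (e.g. C···C in
carbon-poor surfaces) that blow up numerically. Distances between tables
use the fixed 10-component order: Euclidean, or RMSD = Euclidean/√k with
k the number of compared components (k = 10 for contact tables; for
enrichment inputs only components non-null in *both* operands count).
Group averages against a reference default to the mean of per-structure
distances; the distance to the group-mean table is available as an option
(`mode="distance_of_mean"`) since the published convention is unstated.

Printed tables round: totals within 100 ± 1 are accepted silently, larger
deviations load as printed with a `UserWarning` (the shipped fixtures
contain three such rows, all documented in the warning text).

## Binding-mode distance (`bbkit.binding`)

A ligand's binding mode is its vector of per-residue interaction energies
(kcal/mol, ≤ 0 by convention, 0 = no contact) over a fixed residue order.
The comparison statistic is

    RMSD_BM(P, Q) = sqrt( Σᵢ (pᵢ − qᵢ)² / m )

with the divisor m configurable: `n` (the straight formula, default),
`n_minus_1`, or `engaged_only` (residues nonzero in at least one vector).
The published values for the 18-residue dCK panel are reproduced with
m = 17, i.e. `n_minus_1`; both conventions are first-class and every result
records the divisor used. RMSD_BM is a pseudometric for fixed `n`:
symmetric, zero on identical vectors, triangle inequality, and absolutely
homogeneous in the energy scale. The same statistic applies to aligned 2D
fingerprint histograms (flattened (d_i, d_e) bin weights); since no
reference grids are published, that path is validated purely against the
synthetic generator.

Panel utilities: symmetric all-pairs matrices (zero diagonal), absolute and
reference-differenced heatmap matrices, residue ranking by mean energy
(most negative first, alphabetical tie-break — the statistic behind the
published ordering is unstated beyond its leading residues), and lossless
radar-polygon serialization. One published panel cell is positive
(+2.626 kcal/mol); ingest flags it with a warning and keeps it.

The glycosidic torsion ϕ (C(2)–N(1)–C–O) is the standard signed dihedral,
IUPAC sign convention, range (−180°, 180°], computed from four labelled
coordinates; coincident or collinear points raise a geometry error.

## Conceptual-DFT descriptors (`bbkit.reactivity`)

With the Koopmans mapping I = −E_HOMO, A = −E_LUMO applied uniformly:
χ = (I+A)/2, hardness = (I−A)/2, ω = χ²/2·hardness, softness = 1/hardness,
electro-donating power (3I+A)²/16(I−A), electro-accepting power
(I+3A)²/16(I−A), net electrophilicity their sum, ΔN_max = χ/hardness (the
standard form; no published value depends on it). Relative descriptors
divide a ligand's donating/accepting power by a reference ligand's
(R⁺ donating ratio, R⁻ accepting ratio; self-reference is exactly (1, 1)).

Superscript conventions for ω± vary in the literature; fields here are
named by what they compute, and the fixture loader maps the published
table's "ω⁺" column to `omega_donating` and "ω⁻" to `omega_accepting`,
which reproduces every printed number. The reference for R± is the native
(co-crystallized) cytarabine ligand, the row where the published table
prints exactly 1.000.

## Screening rule (`bbkit.screen`)

A candidate is screened on (R⁺, R⁻, RMSD_BM) against the reference ligand:
inside the low-R region (R⁺ ≤ 1.1 and R⁻ ≤ 1.1 by default) it is
anti-cancer-like when RMSD_BM < 1.4 and anti-viral-like otherwise; outside
the region it is unclassified. The 1.4 cut is published; the R caps are
not — 1.1 is chosen because it separates exactly the ligands named inside
the region (Ara-C, Gemcitabine, Decitabine, Zalcitabine) from those named
outside (cytidine, 5-azacytidine, 3′-deoxycytidine) on the reference
panel. All three thresholds are configuration, not constants. No curve is
fitted to the descriptor relations; only Pearson/Spearman coefficients are
offered, with Spearman recommended for the monotone-but-nonlinear shapes
these descriptors show.

## Synthetic data (`bbkit.synthetic`)

All generators are driven by one integer seed (numpy `default_rng`) and are
bit-reproducible. Defaults state a fixed world and are not tuned:

* **Binding panels** — a base profile of negative energies spanning
  −25…−0.3 kcal/mol (the dynamic range of the published dCK panel), plus
  iid Gaussian noise of sd 1.0 kcal/mol per ligand (the order of the
  ligand-to-ligand spread in that panel). Under divisor `n`,
  RMSD_BM(base, ligand) is σ·chi(n)/√n-distributed, which the recovery
  tests check against the 99% interval at n = 50 and 400. Optional
  clipping at zero breaks the exact chi law; it is off by default.
* **Contact tables** — built from target enrichment ratios by a damped
  fixed-point iteration on the surface proportions until the table is
  exactly self-consistent. A total-100 table constrains the
  random-weighted mean of E to 1, so arbitrary requests are feasible only
  up to one uniform scale; ground truth records both the request and the
  achieved map, and the achieved map is recovered to float tolerance.
  Default proportions (C 7.0, H 67.5, N 7.0, O 18.5)% are the cytarabine
  surface rounded to sum exactly to 100.
* **NQR sites** — (e²qQ/h, η) uniform over 2–4 MHz × 0–0.95, the envelope
  of the measured and calculated tables, emitted through the exact forward
  map so recovery is an identity.
* **Frontier pairs** — HOMO ∈ [−8.5, −7.0] eV, LUMO ∈ [−0.8, 0.3] eV
  (the published panel's envelope); disjoint ranges guarantee physical
  ordering.

What a green synthetic test establishes: the algebraic contracts (inverse
pairs, chi statistics, ranking consistency). What it does not: realism of
docking energies, crystal-packing correlations between contact categories,
or correlated noise across residues — real panels are not iid.

## Numerical choices and limitations

* Comparisons against printed tables use the printed precision; where a
  published digit cannot be reproduced from its own printed inputs (three
  RMSD_BM digits off by ≤ 0.002 from mixed 2/3-decimal inputs, one
  R⁺ rounding, two internally inconsistent source rows), the package
  computes honestly and the tests assert within the input-rounding
  envelope instead of to the last digit.
* Species sets beyond {C, H, N, O} are supported by the contact machinery
  (e.g. fluorinated analogues); the shipped fixtures are four-species.
* CSV ingest is strict: dot-decimal only (locale commas rejected with row
  context), mandatory headers, duplicate keys rejected; Unicode minus
  signs are normalized to ASCII.
* The package does not compute electronic structure, Hirshfeld surfaces,
  docking poses or binding affinities — those enter only as data.
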
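# Methods

## The descriptor

The semi-empirical electrotopological index treats a molecule as its
hydrogen-suppressed heavy-atom graph. Each atom *i* carries a positive
scalar SET_i derived from its net atomic charge Q_i = Z − q_i (isolated-atom
electron count minus bound-atom Mulliken population, in e), via a linear
map per carbon category (primary/secondary/tertiary/quaternary,
heteroatom). The index is

    I_SET = Σ_i [ S_i + Σ_{j∈N(i)} log10 S_j ]

with S_i the effective SET. For polar molecules the effective SET of every
heteroatom and of every carbon bonded to a heteroatom is A_μ·SET_i, where

    A_μ = 1 + log10(1 + μ/μ_F),   μ_F = d·|Q_C − Q_X|

μ is the molecular dipole moment (Debye), d the C–heteroatom bond length
(Å), and Q_C, Q_X the net charges of the polar group. All logarithms are
base 10 — this is fixed by the worked 3-hexanone example, whose C2
contribution (0.9998 + log 0.9892 + log 0.3899 = 0.5860) only reproduces
with decadic logs. Molecules with μ = 0 or without heteroatoms skip the
dipolar step entirely (A_μ = 1).

Assumptions and conventions:

- **Bond order does not enter the aggregation.** A C=O double bond is one
  adjacency; order is retained only as an annotation. Atom indices are
  1-based. Mixtures (disconnected graphs) are rejected — the index is
  defined for single molecules.
- **One dipolar context per molecule.** A single (C, X) pair defines μ_F.
  For molecules with several candidate pairs (esters), the pair is chosen
  by a pluggable `mu_f_strategy`; the default trusts the sidecar's declared
  polar group (the carbonyl pair for the studied classes). Class-specific
  alternative μ_F definitions exist in the retention-index literature for
  esters and alcohols but are not fully specified here, so they are left
  as configuration.
- **Charges are inputs.** The AM1/Mulliken step is out of scope; electronic
  states arrive via a YAML sidecar (`dipole_debye`, `polar_group`,
  per-atom `net_charge_e` and optional `set_value`). The charge→SET linear
  coefficients are likewise configuration (`SetMap`): the packaged
  worked-example fixture uses an explicit per-atom override table because
  only the resulting SET values, not the coefficients, are published. The
  raw SET values of the scaled atoms in that fixture (0.22678 for the
  carbonyl carbon, 1.13459 for the oxygen) are back-derived from their
  published A_μ-scaled values by dividing out A_μ; forward computation
  then reproduces every published 4-decimal figure.
- **Display rounding.** Contributions are carried at full precision;
  tables display 4 decimals. The published total for 3-hexanone (6.1931)
  is the sum of the 4-dp-rounded contributions; full precision gives
  6.19322. `ISetBreakdown.total` is the full-precision sum,
  `rounded_total` the hand-tabulation convention.

## Calibration and validation statistics

Per compound class, experimental log P (Y) is regressed on a single
predictor X by ordinary least squares. Reported diagnostics: Pearson r
(signed by the slope), r², residual standard deviation
s = sqrt(SS_res/(n−2)), F = (n−2)·r²/(1−r²) from unrounded r², and
leave-one-out cross-validation PRESS = Σ (y_i − ŷ_(−i))² with
q²_cv = 1 − PRESS/SS_tot about the full-sample mean. PRESS uses the exact
hat-matrix identity e_(−i) = e_i/(1−h_ii); an explicit n-refit loop is kept
as a cross-check and agrees to 1e−10. Records without experimental values
are excluded from every fit and every PRESS loop, never imputed.

External validation regresses observed against predicted values in both
directions, with and without intercept (through-origin slope Σxy/Σx²;
its r² is computed about the mean of the response, comparable with the
free fit). Deviations are experimental − predicted — the sign convention
fixed by the published external table (1-undecanol: 4.42 − 4.64 = −0.22)
— and are displayed at 2 decimals. Two deviation summaries are reported,
mean |Δ| and RMS, because the published "average standard deviation" has
no stated formula (the two bracket it: 0.133 and 0.157 vs 0.15 for the
descriptor model).

### Predictor conventions in the published statistics table

The published per-class table is internally inconsistent about X: refitting
shows the ketone, ester and alcohol descriptor rows are regressions on the
raw index (their intercepts/slopes, r², s, F and q² reproduce exactly:
e.g. alcohols a = −3.2482, b = 0.6394, q²_cv = 0.9870), while the
hydrocarbon and aldehyde rows match regressions on the calculated-log P
column (b ≈ 1). Both conventions are supported (`x_kind`); r, r², s and q²
are affine-invariant in X, so the choice only matters where a calculated
column is not an exact affine image of the index (the ester column —
hence its s of 0.1071 under the column convention vs the published
0.1186 under the raw convention). Comparisons are made under each class's
published convention. The published intercept for alcohols is printed
unsigned; consistency with the calculated column and the external
deviations fixes it as negative.

### A known irreproducibility

The published external observed-vs-predicted line for the seven held-out
alcohols (Y = 1.0273X − 0.1223, r² = 0.9858) cannot be recovered from the
published external table: every computation route (printed calibration,
unrounded refit, deviation-implied predictions) yields Y = 1.0052X −
0.0362 with r² = 0.9828. The per-compound deviations themselves reproduce
within ±0.01, so the discrepancy lies in the published regression
constants, not the data. This package reports the recomputed values; the
corresponding assertion in the acceptance tests is intentionally left
failing as documentation of the inconsistency.

## Packaged tables

141 training compounds (25 hydrocarbons, 9 aldehydes, 23 ketones,
24 esters, 60 alcohols; 125 with experimental values — subsets of 23, 9,
19, 14, 60 enter the calibrations) and 7 external alcohols, stored as TSV
with sha256 integrity checks and flags instead of edits:

- decimal commas and an unsigned intercept normalised, each flagged;
- the Isobutyl Acetate descriptor value (4.2872) is inconsistent with the
  ester calibration (would predict ≈ −0.33 against a printed calculated
  value of 1.69); it is kept verbatim, flagged `suspect_typo`, and has no
  experimental value, so no statistic depends on it;
- missing experimental cells load as absent values, never zero;
- loaders keep the original row strings, so load→write round-trips are
  byte-stable.

## Synthetic generator

`synthetic` produces seeded fixtures for every pipeline stage: connected
heavy-atom trees (chains or random branched trees with degree ≤ 4),
per-atom SET values drawn N(0.95, 0.05) truncated positive — matching the
near-unity SETs of saturated carbons, with the study's observed range
roughly 0.23–1.14 — and, when a heteroatom is requested, an oxygen with
Q_O ~ −|N(0.28, 0.03)|, a carbon partner with Q_C ~ |N(0.22, 0.03)|,
μ ~ U(1.5, 3.5) D and d ~ U(1.2, 1.45) Å, bracketing the worked example's
carbonyl values. `synth_calibration_dataset` draws x uniformly over the
descriptor range of the study compounds (2–18) and adds Gaussian noise to
a known line. All randomness flows through one `numpy.random.Generator`
per spec; identical specs (including seed) reproduce identical output.

What the generator does **not** emulate: chemically consistent charges
(no charge balance, no conformational effects), rings, multiple
heteroatoms, or correlated noise in calibration data. Tests passing on
synthetic draws therefore certify graph/arithmetic behaviour and
statistical machinery, not chemical realism; the packaged study tables
provide the real-data anchor.

## Numerical choices and problem sizes

- Totals use compensated summation (`math.fsum`); invariance tests assert
  1e−10 agreement against an edge-based re-evaluation of the double sum.
- Degenerate inputs fail loudly: constant predictors, holdouts that leave
  a constant predictor, nonpositive SET values (the log is undefined),
  μ_F = 0 for a polar molecule, structure/sidecar mismatches.
- r² = 1 yields an explicitly infinite F rather than an exception.
- Parameter-recovery checks use 200 replicates at n = 60 with σ = 0.15
  (the alcohol-class residual scale); graph property tests use random
  trees of ≤ 8 atoms. The full suite runs in a few seconds on one CPU.

## Limitations

Behaviour outside the studied aliphatic classes (aromatics, multiple
heteroatoms, charged species) is unvalidated; the per-category charge→SET
coefficients are not published here, so descriptor computation for new
molecules requires either those coefficients from the retention-index
literature or precomputed SET values; and the published comparison-method
columns (Ghose/Crippen, AlogP, ClogP, MlogP) are data, not
reimplementations.
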
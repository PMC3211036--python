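# iset — semi-empirical electrotopological index for log P estimation

A one-descriptor QSPR toolkit for aliphatic organic compounds (alkanes,
alkenes, aldehydes, ketones, esters, alcohols). It computes the
semi-empirical electrotopological index *I*<sub>SET</sub> — a molecular-graph
descriptor built from semi-empirical (AM1) net atomic charges with a
molecular-dipole correction — and calibrates it linearly against
experimental octanol/water partition coefficients (log *P*), with the
standard diagnostic and validation suite used in QSPR work. It is aimed at
cheminformatics practitioners who want a transparent, desk-scale
lipophilicity model and at anyone reproducing the published per-class
statistics for this descriptor family.

## The model

Every heavy atom *i* carries a scalar SET<sub>*i*</sub> obtained from a
linear function of its net atomic charge *Q*<sub>*i*</sub> = *Z* −
*q*<sub>*i*</sub>. The descriptor aggregates over the hydrogen-suppressed
molecular graph:

```
I_SET = Σ_i [ S_i + Σ_{j ∈ N(i)} log10 S_j ]
```

where *S*<sub>*i*</sub> is the *effective* SET of atom *i*. For polar
molecules, the SET values of each heteroatom and of each carbon bonded to
one are multiplied by the dipolar function

```
A_μ = 1 + log10(1 + μ/μ_F),     μ_F = d · |Q_C − Q_X|
```

with μ the molecular dipole moment (Debye), *d* the C–heteroatom bond
length (Å) and *Q*<sub>C</sub>, *Q*<sub>X</sub> the net charges (e) of the
polar group; apolar molecules use *A*<sub>μ</sub> = 1. Per compound class,
log *P* is then estimated by ordinary least squares, log *P* = *a* +
*b*·*I*<sub>SET</sub>, and judged by *r*, *r*², *s* (residual standard
deviation, *n*−2 df), *F*, and leave-one-out cross-validation (PRESS,
*q*²<sub>cv</sub>), plus external-test-set regressions.

Quantum chemistry is **not** performed here: net charges, dipole moments
and bond lengths enter through a per-molecule "electronic state" sidecar
(YAML), alongside structures in SMILES or MOL/SDF.

## Worked example

```
$ python examples/compute_descriptor.py
local dipole moment mu_F = 0.6319
dipolar function   A_mu  = 1.7193
  C1: 0.9891
  C2: 0.5860
  C3: 0.6799
  O4: 1.5416
  C5: 0.5444
  C6: 0.8986
  C7: 0.9535
I_SET = 6.1931
```

For 3-hexanone, the carbonyl group's local dipole μ_F = 1.2342·|0.224 −
(−0.288)| = 0.6319 gives A_μ = 1.7193, which scales the SET values of the
oxygen and the carbonyl carbon. Each line is one atom's contribution (its
effective SET plus the base-10 logs of its neighbours'); their sum,
6.1931, is the molecule's descriptor value. The ketone calibration maps
it to a predicted log *P* of 1.37 (experimental: 1.45).

The same pipeline is exposed on the command line:

```
iset compute --structure mol.smi --state mol.state.yaml [--format json]
iset calibrate --class alcohol --x raw_iset --out-model alcohol.json
iset validate --model alcohol.json
iset reproduce --method all
iset synth --n-atoms 6 --heteroatom-position 3 --seed 7 --out fix/
```

Other narrative examples: `examples/calibrate_alcohols.py` (60-alcohol
fit, *q*²<sub>cv</sub> = 0.9870), `examples/validate_external.py` (seven
held-out alcohols, mean |Δ| = 0.13), `examples/synthetic_fixture.py`
(seeded generator).

## Packaged data

`src/iset/data/` ships the 141-compound training table (descriptor, five
methods' calculated log *P*, experimental values where determined), the
published per-class statistics for comparison, the seven external
alcohols, and the 3-hexanone electronic-state fixture. Cells are stored
verbatim apart from flagged mechanical normalisation (decimal commas,
an unsigned intercept); known anomalies are flagged, never edited. See
`docs/methods.md` for conventions and caveats.

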
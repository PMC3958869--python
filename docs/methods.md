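# Methods

## Scope and model

The package estimates the PDMS–water partition coefficient K_fw of neutral
organic compounds from molecular structure, via ordinary least squares on
three computed descriptors (Φ, ¹χ, I) with optional experimental inputs
(water solubility WS in mg/L, log K_ow, molecular weight). The response is
always log10 K_fw; tables of raw K_fw are converted at load time. All
logarithms are base 10.

The model's domain is that of its training data: C/H/N/O/halogen
compounds — alkanes, cycloalkanes, benzenoid aromatics and monofunctional
benzenes with K_fw spanning ~0.4 to ~9×10^4. Predictions for strong
hydrogen-bond donors (phenols, alcohols) are systematically high; the
external validation below quantifies this.

## Molecular graphs

SMILES input is parsed into a hydrogen-suppressed graph. Only the subset
needed for the model's chemical space is accepted — atoms C/N/O/F/Cl/Br/I,
aromatic c/n/o, branches, ring closures, bond symbols `-`/`=`/`#` — and
everything else is rejected with a positioned parse error rather than
risking a silent mis-parse. Implicit hydrogens are assigned from standard
valences (C:4, N:3, O:2, halogen:1); a negative count raises a valence
error.

Lowercase-aromatic input is Kekulized immediately by a deterministic
depth-first perfect matching (always extended from the lowest unmatched
atom index), so downstream code sees explicit alternating bond orders.
For benzenoid systems every valid matching yields identical descriptors;
this is property-tested across atom reorderings. Fused 6-ring systems
(naphthalene) and ring assemblies (biphenyl) are supported; more exotic
aromaticity is out of scope. Explicit uppercase single/double input such
as `C1=CC=CC=C1` is deliberately taken literally as a non-aromatic cyclic
polyene (the cycle term applies, the aromatic indicator rule does not):
aromaticity is an input declaration, not a perception pass. Ring counts
use the cyclomatic number |E| − |V| + 1; ring membership of bonds comes
from a bridge decomposition; the ring inventory from a minimum cycle
basis (networkx).

## Descriptors

**¹χ (first-order valence connectivity).** δ = Zv − h for C, N, O, F;
δ = (Zv − h)/(Z − Zv − 1) for Cl (7/9), Br (7/27), I (7/45). The index is
the sum over bonds of (δi·δj)^−1/2, each bond once regardless of order;
multiple bonds act only through the reduced hydrogen counts. The
higher-row ratio is required: the plain difference (δCl = 6) would give
chlorobenzene ¹χ = 2.115 against the printed 2.477. A molecule with no
bonds (methane) has ¹χ = 0.

**Φ (additive polarizability).** Feature counts dotted with the published
contribution factors (carbon 0.577, hydrogen −0.120, oxygen −0.825,
hydroxyl −3.701, Cl −0.187, Br −0.222, I 0.407, F −0.570, cycle −0.952,
double bond −0.859, triple bond −0.109). Three counting conventions are
not stated in the source and were fixed by back-calculating the 87 printed
table values; each is exposed as a `PolarizabilityScheme` flag:

1. *Aromatic rings contribute three double-bond terms each and no cycle
   term.* Forced by benzene (0.165), toluene (0.502) vs cyclopentane
   (0.733); for fused systems the count is per ring — naphthalene
   (−0.344) and 1-methylnaphthalene (−0.007) require six double-bond
   terms, one more than a Kekulé structure has. Non-aromatic rings take
   the cycle term.
2. *All hydrogens count, including O–H and N–H.* The factor table's
   footnote says carbon-attached only, but the printed Φ of 4-fluorophenol,
   m-cresol, 3-chlorophenol, 4-chloroaniline and the benzylic alcohols
   back-calculate only when every hydrogen counts. (Phenol itself is the
   lone exception and is catalogued as an anomaly.)
3. *Hydroxyl oxygens take the plain oxygen factor.* The printed values of
   the phenols AND of the aliphatic benzylic alcohols (benzyl alcohol
   −0.323, phenethyl alcohol 0.014) all back-calculate with −0.825, so the
   −3.701 hydroxyl factor is never exercised by the packaged data; it is
   available via `hydroxyl_uses_own_factor=True` for the literal
   factor-table behaviour.
4. Nitrogen has no published factor; benzonitrile (0.753) and
   4-chloroaniline (−0.022) show it contributes 0, encoded explicitly.

**I (indicator).** 1 if any N/O/halogen is bonded to a carbon carrying
hydrogen, any C≡C bond exists, or any aromatic carbon carries hydrogen;
else 0.

## Regression and validation conventions

- Fits are OLS (statsmodels under the `KfwRegressor` estimator); the
  quoted fit statistic is the multiple correlation coefficient
  r = sqrt(1 − SSE/SST). Single-descriptor r values are signed Pearson
  correlations with exact-t p-values (df = n − 2); the source prints them
  unsigned for the negative slopes, so tests compare |r|. No
  multiple-testing correction is applied, matching the source analysis.
- Rank-deficient designs raise a collinearity error naming the dependent
  columns.
- Stepwise model building is reproduced as forward selection on the pool
  {Φ, ¹χ, I, WS} with entry p ≤ 0.05 — an approximation of the SPSS
  stepwise defaults used originally.
- The published equations are also available verbatim (no refitting) in a
  registry; refitting the three-descriptor form on the packaged training
  table reproduces the printed coefficients to better than ±0.01 and
  r = 0.989.
- **External validation scale.** Plain Pearson correlation between
  observed and predicted gives 0.544 (log scale) / 0.530 (linear) for the
  three-descriptor equation on the 26-compound test set — far from the
  published 0.819. The published test-set statistics are reproduced by a
  proportional (through-origin) fit of observed on predicted log10 K_fw,
  R = sqrt(1 − SSE/Σy²): 0.813 for the four-descriptor equation with its
  WS term omitted, 0.816 for the three-descriptor equation, 0.808 for the
  two-descriptor one. `validate()` therefore reports all three statistics
  (`r_obs_pred` on the requested scale, plus `proportional_r`), and the
  acceptance script reports the proportional log-scale R. Note the
  four-descriptor equation applied *verbatim* (+0.001·WS with test-set WS
  up to 8.28×10^4 mg/L) produces meaningless predictions (Pearson
  r = −0.65); its printed WS coefficient also disagrees in sign with the
  refit value (−1×10^−4). It is kept verbatim for fidelity and flagged
  here.

## Packaged data and its anomalies

The training (n = 61) and test (n = 26) tables ship as CSV with the
printed K_fw, descriptors and, for training, MW/WS/log K_ow — verbatim,
misprints included; printed values are never silently corrected. SMILES
were curated by hand from the compound names ("2-methylbutylbenzene" is
curated as (2-methylbutyl)benzene, whose printed ¹χ 4.365 back-calculates
exactly). `check_consistency()` recomputes ¹χ/Φ/I/MW from the SMILES and
must flag exactly the eleven catalogued anomalies (see
`KNOWN_ANOMALIES` for magnitudes and notes):

- Φ: 1,2,4-trimethylbenzene (1.76, pattern says 1.176), phenol (−0.540,
  omits the O–H hydrogen), biphenyl (−0.007, equals the C11H10
  computation — apparently copied from 1-methylnaphthalene; C12H10 gives
  0.570).
- ¹χ: 2,2,3-trimethylbutane (3.944 vs 2.944), 3-methylhexane (2.9 vs
  3.308), trans-1,2-dimethylcyclopentane (3.207 vs 3.305), iodobenzene
  (3.161 vs 3.179), and three chlorine entries (4-chlorotoluene,
  3-chlorophenol, 4-chloroanisole) that imply a C–Cl bond term of ≈0.602
  (δCl ≈ 0.69) although chlorobenzene, 4-chloroaniline and
  4-chloroacetophenone in the same tables match δCl = 7/9.
- MW: 1-ethyl-1-methylcyclopentane printed 122; C8H16 weighs 112.

Regression-reproduction numbers are computed on the printed columns,
anomalies included, since that is what the original fits used. One
residual irreproducibility remains: the printed single-parameter MW row
(intercept 1.859, r 0.474) computes as (1.911, 0.458) from the printed
table; all five other rows reproduce to printed precision.

## Synthetic generators

Property tests draw on two generators. `generate_alkane` samples labelled
trees uniformly via Prüfer sequences, rejecting vertex degrees above 4,
and emits SMILES — exercising the parser and the closed forms
Φ = 0.337k − 0.240 and, for n-alkanes, ¹χ = 0.5(k − 3) + √2. It emulates
saturated acyclic hydrocarbons only: no rings, heteroatoms or unsaturation,
so passing these tests says nothing about aromatic perception (covered by
the fixture compounds instead). `generate_linear_dataset` produces
y = b0 + Xβ + N(0, σ) with standard-normal columns for parameter-recovery
tests (exact at σ = 0; within 3 standard errors at σ > 0, n = 200, fixed
seed).

## Numerical notes and limitations

- Descriptor golden-value comparisons use ±0.005 (printed precision is 3
  decimals); MW comparisons use ±1 g/mol (tables print integers).
- The SPME calculator is the closed-form two-phase equilibrium; mass
  balance Cf·Vf + Cs·Vs = Co·Vs holds to 1e−12 relative (property-tested
  over 10^3 random systems). Units must be self-consistent; kinetics and
  three-phase headspace systems are out of scope.
- Kekulization is exponential in the worst case but the matching search on
  ≤ 12-atom aromatic systems is instantaneous; the supported chemical
  space never approaches the pathological cases.
- The predictive equations carry no uncertainty intervals (none were
  published); residual spread on the training set is ~0.1 log units, and
  test-set predictions for polar compounds err high by 1–2 log units.
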
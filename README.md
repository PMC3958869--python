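# spmekfw

QSPR prediction of partition coefficients of organic compounds between
polydimethylsiloxane (PDMS) SPME fibre coatings and water.

Solid phase microextraction (SPME) pre-concentrates aqueous analytes onto a
polymer-coated fibre; the sensitivity of the technique for a given compound
is governed by its coating–water partition coefficient, K<sub>fw</sub> =
C<sub>f</sub>/C<sub>s</sub>. Measured K<sub>fw</sub> values exist only for a
few hundred compounds, so analytical chemists planning SPME work need a way
to *estimate* K<sub>fw</sub> from structure alone. This package implements
a quantitative structure–property relationship (QSPR) that does exactly
that, for neutral organic molecules (alkanes, aromatics, simple
monofunctional benzenes), plus the equilibrium extraction calculator that
turns a K<sub>fw</sub> into an extracted mass.

## The model

Three descriptors are computed directly from the hydrogen-suppressed
molecular graph:

- **Φ — additive polarizability.** A group-contribution sum
  Φ = Σ F<sub>i</sub> · n<sub>i</sub> over atom/bond features (carbon
  0.577, hydrogen −0.120, oxygen −0.825, halogens, cycle −0.952, double
  bond −0.859, triple bond −0.109, …). Aromatic rings contribute three
  double-bond terms each and no cycle term.
- **¹χ — first-order valence molecular connectivity index.**
  ¹χ = Σ<sub>bonds</sub> (δ<sub>i</sub>δ<sub>j</sub>)<sup>−1/2</sup>, where
  δ = Z<sub>v</sub> − h (valence electrons minus attached hydrogens), with
  the Kier–Hall higher-row form δ = (Z<sub>v</sub> − h)/(Z − Z<sub>v</sub> − 1)
  for Cl, Br and I. Branching lowers ¹χ.
- **I — hydrogen-bonding indicator.** 1 for compounds with an
  electronegative atom on an H-bearing carbon, acetylenic compounds, or
  aromatics with ring hydrogens; else 0.

The central regression, fitted to a 61-compound training set of measured
PDMS–water partition coefficients, is

```
log10 Kfw = 1.447 + 0.728 Φ + 0.316 ¹χ − 0.224 I      (r = 0.989, n = 61)
```

with published single-descriptor and four-descriptor variants available in
the model registry (`published_model("eq4" | "eq5" | "eq6" | "table1_*")`).
At equilibrium, the mass extracted by a coating of volume V<sub>f</sub>
from a sample of volume V<sub>s</sub> is
M<sub>f</sub> = K<sub>fs</sub>C<sub>o</sub>V<sub>s</sub>V<sub>f</sub> / (K<sub>fs</sub>V<sub>f</sub> + V<sub>s</sub>).

## Worked example

```bash
$ printf 'c1ccccc1 benzene\nCCc1ccccc1 ethylbenzene\nOc1ccccc1 phenol\n' > demo.smi
$ spmekfw descriptors demo.smi
name,smiles,chi1,phi,indicator,mw,error
benzene,c1ccccc1,2.0,0.165,1,78.114,
ethylbenzene,CCc1ccccc1,2.9713,0.839,1,106.168,
phenol,Oc1ccccc1,2.1343,-0.66,1,94.113,

$ spmekfw predict demo.smi --model eq5
name,smiles,log_kfw,kfw,error
benzene,c1ccccc1,1.9751,94.4322,
ethylbenzene,CCc1ccccc1,2.7727,592.5659,
phenol,Oc1ccccc1,1.417,26.119,
```

Benzene's predicted K<sub>fw</sub> ≈ 94 and ethylbenzene's ≈ 593 sit near
their measured values (58 and 566); phenol, a hydrogen-bond donor at the
polar edge of the model's domain, is predicted ≈ 26 against a measured
0.66 — external validation shows the model systematically over-predicts
the most water-soluble compounds, so treat sub-unity K<sub>fw</sub>
predictions as order-of-magnitude guidance.

Feeding a partition coefficient into the extraction calculator (a 0.66 µL
PDMS coating in a 1 mL sample at 0.05 µg/µL, ethylbenzene's
K<sub>fs</sub> = 566):

```bash
$ spmekfw uptake --kfs 566 --vf 6.6e-4 --vs 1 --c0 0.05
{
  "kfs": 566.0,
  "mf": 0.01359824...,
  "fraction_extracted": 0.27196...
}
```

i.e. the fibre extracts 27.2% of the analyte mass (0.0136 µg) at
equilibrium.

The same workflow is available as a library, scikit-learn style:

```python
from sklearn.pipeline import Pipeline
from spmekfw import KfwRegressor, MolecularDescriptors, load_training
import numpy as np

train = load_training()
pipe = Pipeline([("desc", MolecularDescriptors()), ("ols", KfwRegressor())])
pipe.fit(train["smiles"].tolist(), np.log10(train["kfw"]))
pipe.predict(["CCc1ccccc1"])   # array([2.77...]) — log10 Kfw
```

## Data

The packaged 61-compound training table and 26-compound test table carry
the measured K<sub>fw</sub> and printed descriptor values verbatim,
including eleven catalogued misprints/inconsistencies
(`spmekfw.datasets.KNOWN_ANOMALIES`); `spmekfw check-data` diffs
recomputed descriptors against the printed columns and must flag exactly
that list.

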
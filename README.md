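# tightknot

Characterization toolkit for cysteine-rich tight-binding protease
inhibitors — the kind of small disulfide-stabilized proteins found in
spider venoms and digestive secretions that titrate serine proteases
almost stoichiometrically.

When such an inhibitor is isolated, the same battery of desk analyses
recurs: estimate the dissociation constant from a residual-activity
titration, deconvolve an ESI charge-state envelope to a neutral mass,
compute theoretical mass/pI and PEST degradation motifs from the
sequence, classify the disulfide scaffold (ICK, Kunitz, Kazal, HAND,
DDH, MIT1/colipase-like), and inspect docking poses for the
reactive-site loop and its hydrogen bonds to the catalytic machinery.
`tightknot` packages those analyses as tested, reusable components, with
a synthetic-data module so every estimator can be validated against a
known ground truth without downloading anything.

## The core model

A tight-binding inhibitor depletes free inhibitor, so fractional
residual activity follows the Morrison (tight-binding quadratic)
equilibrium rather than classical inhibition kinetics:

    a([I]t) = 1 − ( [E]t + [I]t + K_D − √(([E]t + [I]t + K_D)² − 4[E]t[I]t) ) / (2[E]t)

Two estimators of K_D operate on a titration `a` versus `[I]t`:

* **stoichiometric titration** — the rectilinear descending limb
  extrapolates to the equivalence point ([I]t = [E]t); the residual
  activity there gives the free-enzyme fraction a_eq, and
  K_D = [E][I]/[EI] with [E] = [I] = a_eq·[E]t and [EI] = [E]t − [E];
* **Morrison fit** — least squares on the quadratic, fitting K_D (and
  [E]t when unknown).

For mass spectra, each envelope ion obeys M = z·(m/z) − z·m_adduct; the
deconvolver exhaustively searches consecutive-descending charge
placements over z ∈ [1, 30] and keeps the one minimizing the variance of
the implied neutral masses.

## Worked example

```python
import numpy as np
from tightknot import synthetic, kinetics, massspec
from tightknot.seqprops import pest_score

# simulate a triplicate titration at realistic assay conditions:
# 515 nM trypsin (12 ng/uL at 23.3 kDa), 0-4 uM inhibitor, 2% noise
spec = synthetic.TitrationSimSpec(true_kd=30.25, enzyme_total=515.0,
                                  noise_cv=0.02, n_replicates=3, seed=7)
series = synthetic.gen_titration(spec)
res = kinetics.TightBindingTitration(series).fit(method="stoichiometric", seed=7)
print(res.summary())

env = massspec.IonEnvelope(np.array([1102.4051, 1239.9110, 1417.0741]))
print(massspec.deconvolve(env).summary())
print("PEST:", round(pest_score("KCQQDSGEEPSEE"), 2))
```

prints

```
Tight-binding K_D estimate (stoichiometric)
--------------------------------------------
K_D                     31.213 nM  (SE 0.468)
equivalence point      515.000 nM
[E] free               112.136 nM
[I] free               112.136 nM
[EI] complex           402.864 nM
activity_at_equivalence 0.217739
extrapolated_intercept_nM 759.033
rectilinear         False
region_r_squared    0.94693

Envelope deconvolution: M = 9912.0927 Da (spread 0.7494 Da across 3 peaks, charges 9, 8, 7)
PEST: 13.33
```

The estimator recovers the simulated K_D of 30.25 nM to within the run's
noise (31.2 ± 0.5 nM bootstrap SE). `[E] free` is the enzyme left
uncomplexed at the equivalence point; `rectilinear False` warns that on
this coarse 0.25 µM grid no 4-point prefix of the curve is linear at
R² ≥ 0.99, so the extrapolated intercept (759 nM) is reported only as a
diagnostic while the known enzyme concentration anchors the estimate.
The envelope ions are assigned charges 9/8/7 and average to a neutral
mass of 9912.09 Da with a 0.75 Da spread; the 13-residue window scores
13.33 on the PEST scale (scores above +5 flag rapid-turnover signals).

A `tightknot` command-line tool mirrors the library (`simulate`,
`titrate`, `deconvolve`, `characterize-seq`, `classify-cys`, `contacts`,
`coverage`, and `run --config run.yaml` for a consolidated JSON report).

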
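# expressivity

Quantifying how strongly clinically relevant attributes are encoded in the
internal feature representations of image classifiers, by neural estimation
of mutual information.

## The problem

A classifier trained to detect severe left ventricular hypertrophy (SLVH)
from chest radiographs never sees the patient's age, sex, or the
echocardiographic wall measurements that define the condition — yet an
effective model should internalize them. This package measures that
implicit encoding. For a feature matrix `F` harvested from any layer of a
trained network and a scalar attribute `A` (age in years, sex as 0/1,
IVSDd/LVPWDd/LVIDd in cm), it estimates the mutual information

    I(F; A) = D_KL( P_FA || P_F ⊗ P_A )

via the Donsker–Varadhan lower bound

    I(F; A) ≥ E_joint[ T(f, a) ] − log E_marginal[ exp T(f, a) ],

maximized over a small neural critic `T` (MINE). The joint expectation is
estimated on matched mini-batch pairs `(f_i, a_i)`, the marginal one on
derangement-mismatched pairs `(f_i, a_j), i ≠ j`; the gradient of the
log-marginal term is stabilized with an exponential moving average of
`E[exp T]`. The resulting *expressivity* score — averaged over M
independently seeded fits, reported in nats — can be profiled across
early/mid/final layers and across attributes to reveal what a network has
learned beyond its labels.

Everything needed to exercise the estimator end-to-end ships with the
package: a synthetic echocardiographic cohort generator with an exact
label rule, a toy radiograph renderer whose pixel content carries the
attributes at controllable strengths, linear-Gaussian feature channels
with closed-form true MI (the estimator's oracle), desk-scale
convolutional and frozen-transformer backbones with layer taps, balanced
subset construction, and AUROC/AUPRC with bootstrap confidence intervals.

## Worked example

Estimate MI for correlated Gaussians against the closed form
`−½·ln(1−ρ²)`, which is 0.2231 nats at ρ = 0.6:

```python
import numpy as np
from expressivity import FeatureMatrix, AttributeVector, expressivity

rng = np.random.default_rng(0)
z = rng.multivariate_normal([0, 0], [[1, .6], [.6, 1]], size=5000)
F = FeatureMatrix(z[:, :1])
A = AttributeVector(z[:, 1], kind="continuous", name="a")

res = expressivity(F, A)   # 10 seeded MINE fits, averaged
print(f"{res.mean_estimate:.4f} ± {res.std_estimate:.4f} nats")
```

```
0.2275 ± 0.0133 nats
```

The estimate sits within a few centinats of the 0.2231-nat truth; per-seed
values are in `res.per_seed_estimates` and slightly negative estimates
(possible when the true MI is zero) are reported raw, never clipped.

The full pipeline — simulate a cohort, render images, balance classes,
train the classifier, profile expressivity over a 3 × 5 layer/attribute
grid, and report metrics with 95% bootstrap CIs — runs from the CLI:

```bash
expressivity run-all --seed 0 --out runs/demo
```

which ends by printing the run report (grid estimated on the balanced
test split of 2000 synthetic images; small-sample noise expected):

```
== classification metrics (test split) ==
AUROC 0.928 [95% CI: 0.875-0.964]
AUPRC 0.919 [95% CI: 0.861-0.969]

== expressivity (nats), mean +/- sd over seeds ==
stage           age       sex     IVSDd    LVPWDd     LVIDd
early         0.016     0.045     0.152     0.186     0.091
mid           0.077     0.075     0.193     0.209     0.358
final         0.126     0.091     0.219     0.302     0.210
```

The anatomical wall measurements (IVSDd, LVPWDd) that drive the label
are encoded far more strongly at the final tap than at the early one —
the classifier has internalized them from pixels alone.

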
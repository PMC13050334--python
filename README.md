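# ect1d — Euler characteristic transforms of one-dimensional shapes

`ect1d` computes Euler characteristic transforms (ECT), Euler
characteristic curves (ECC) and smooth Euler characteristic transforms
(SECT) of one-dimensional shapes embedded in Euclidean space: curve
networks and closed outlines of the kind extracted from segmented
biological images (cell outlines, leaf contours, vessel skeletons).
Alongside the exact transform of sampled shapes it provides the
curvature-aware stability bounds that make ECT comparisons meaningful on
such data, and a Gaussian-process estimator that consistently recovers
the transform of a shape from independently noise-perturbed point
samples.

## The descriptor

For a compact shape $X \subseteq \mathbb{R}^d$, a direction
$v \in S^{d-1}$ and a level $t$, the ECT records the Euler characteristic
of a sublevel set of the directional height function:

$$\mathrm{ECT}_X(v, t) = \chi\{x \in X : \langle x, v\rangle \le t\}.$$

For fixed $v$ this is an integer step function of $t$ (the ECC).  With
all projections inside $[-a, a]$, the SECT integrates the mean-centred
ECC, giving a continuous signature that vanishes at both ends.  Fields
are compared by the sup over directions of the exact $L^1$ distance in
$t$.

For a shape given as a finite CW complex (vertices, edges, one sampled
curve per edge) the transform of the chord interpolation on a vertex set
$A$ with sub-edge multiset $E$ is computed exactly by counting:

$$\mathrm{ECT}^A(v,t) = \#\{i : \langle a_i, v\rangle \le t\}
  - \#\{(i,j) \in E : \max(\langle a_i,v\rangle, \langle a_j,v\rangle) \le t\},$$

with breakpoints at the projection values and no quadrature anywhere.

Three families of results make this usable on real, noisy data:

* **Stability.** The ECT is *not* stable under small Hausdorff
  perturbations — a wave of amplitude $\varepsilon$ hugging a straight
  line keeps an ECT distance $\ge 1$ once it oscillates fast enough.  It
  *is* stable once curvature is controlled: for two embeddings of the
  same complex within $\varepsilon$ of each other (sup norm and arc
  lengths, constant-velocity parametrisations), the ECT distance is at
  most $|Z_0|\varepsilon + \sum_\lambda G_\lambda(\varepsilon)$ with an
  explicit $G_\lambda$ built from the curvature bound $M$ and the edge
  lengths (`ect1d.stability_bounds`).
* **PL approximation.** Replacing a $C^2$ shape by its chord
  interpolation on an $\varepsilon$-dense vertex set changes the ECT by
  at most $M L \varepsilon / \sqrt{12}$.
* **Estimation.** Sampling the shape at $n$ equally spaced points,
  perturbing each coordinate with independent $N(0, \sigma^2)$ noise,
  and smoothing each coordinate with a GP posterior mean (the periodic
  sine-squared exponential kernel
  $k(s,t) = \exp(-2\sin^2\frac{s-t}{2})$ for closed curves) yields an
  estimator whose ECT/SECT converges to the truth as $n$ grows
  (`ect1d.estimator`).

## Worked example

```python
import numpy as np
from ect1d import *
from ect1d.ect_core import polyline_ecc
from ect1d.complex_model import hausdorff_distance

# the curvature instability: a line and a tight wave
wave, line = make_wave_and_line(0.05)          # amplitude 0.05, 20 oscillations
h = hausdorff_distance(wave.curves["e0"].points, line.curves["e0"].points)
ecc_w = polyline_ecc(wave.curves["e0"].points, [0.0, 1.0])
ecc_l = polyline_ecc(line.curves["e0"].points, [0.0, 1.0])
d = ecc_w.l1_distance(ecc_l, -1.0, 2.0)
print(f"Hausdorff distance:       {h:.4f}")
print(f"vertical ECC L1 distance: {d:.4f}")

# the matching stability bound for a curvature-controlled comparison
p = BoundParams(M=1.0, lengths=[2*np.pi], eps=0.01, n_vertices=1)
print(f"stability bound at eps=0.01: {curvature_stability_bound(p):.4f}")
```

prints

```
Hausdorff distance:       0.0502
vertical ECC L1 distance: 1.9979
stability bound at eps=0.01: 6.7708
```

The two curves are everywhere within $0.05$ of each other, yet their
bottom-up ECCs differ by $\approx 2$ in $L^1$ — the instability the
curvature-aware metric repairs.  The last line is the guaranteed ECT
distance bound for two unit-circle-like embeddings within
$\varepsilon = 0.01$ of each other.

Running the estimator study on the package's seeded closed test curve
(noise sd $\sigma = 0.002$, 20 repetitions):

```python
from ect1d.estimator import consistency_experiment, summarise_consistency
from ect1d.synth_shapes import default_fourier_spec

X = make_fourier_curve(default_fourier_spec())
table = consistency_experiment(X, (20, 50, 100), reps=20, sigma=0.002, seed=7)
print(summarise_consistency(table)[["n", "reps", "mean", "sd", "median"]].to_string(index=False))
```

```
  n  reps     mean       sd   median
 20    20 0.005493 0.001460 0.005182
 50    20 0.003815 0.001368 0.003391
100    20 0.002423 0.000516 0.002318
```

The SECT distance between the smoothed estimate and the true curve
shrinks as the sample count grows — the consistency of the estimator in
action.

A command-line interface mirrors the library:

```bash
ect1d simulate --shape circle --out circle.json
ect1d ect --input circle.json --eps 0.05 --dirs 64 --out circle_ect.csv
ect1d bounds --m 1.0 --lengths 6.2832 --eps 0.01 --n0 1
ect1d consistency --n 20,50,100 --reps 20 --sigma 0.002 --seed 7 --out table.csv
```

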
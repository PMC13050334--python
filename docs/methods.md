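# Methods

## Shape model

A shape is a finite one-dimensional CW complex — a topological graph with
0-cells (vertices) and 1-cells (edges; loops and parallel edges allowed) —
together with an embedding into $\mathbb{R}^d$: one coordinate per vertex
and one parametrised curve per edge.  Curves are stored as finite sample
chains on a strictly increasing parameter grid in $[0,1]$; every smooth
("$C^2$") object in the theory is represented by a dense polyline.  This
is not a loss of substance: the PL-approximation bound
$\|{\rm ECT}_f - {\rm ECT}^A_f\| \le M L \varepsilon/\sqrt{12}$ quantifies
exactly what chord interpolation on an $\varepsilon$-dense vertex set
costs, so refining the sampling provably converges.

The homeomorphism type is always *given*.  The package never infers
topology from a point cloud; comparisons (`cw_distance_upper`) fix a
caller-supplied edge correspondence and optimise only over per-edge
orientation, returning an **upper estimate** of the embedding metric (the
true metric is an infimum over all homeomorphism pairs, which is not
computable from samples).

## Exact transform computation

Sublevel sets use the closed convention $\langle x, v\rangle \le t$;
ECCs are right-continuous integer step functions whose jumps sit exactly
at projection values.  For a chord shape, a chord is submerged exactly
when both endpoints are (projections are affine on chords), so
$\chi = \#\text{vertices}_{\le t} - \#\text{chords}_{\le t}$ is exact.
Ties — several samples with equal projection, as happens for symmetric
shapes at axis directions — are handled by merging equal breakpoints and
summing jumps; no symbolic perturbation is applied.  Tie instants have
measure zero, so the exact $L^1$ integrals used for all distances are
unaffected.  Almost-everywhere identities (such as the Mayer–Vietoris
gluing identity $\chi_Z = \chi_V + \chi_W - \chi_S$) are verified by
requiring the difference step function to have support of length below
$10^{-9}$; this absorbs last-bit discrepancies between BLAS matrix-row
and vector dot products that can split a cancelling jump across two
adjacent floats.

Distances: the supremum over the sphere is replaced by a maximum over a
finite direction grid — for $d = 2$ the regular $m$-gon of directions,
default $m = 64$, configurable.  The finite grid *under-estimates* the
true supremum; the bounds are of $\le$ type, so the certification tests
remain valid.  The bounding radius $a$ defaults to $1.05\times$ the
maximal point norm; when two fields are compared the larger $a$ wins and
the other field is zero-extended, which does not change any integral.

The SECT integrates the mean-centred ECC exactly (piecewise-linear
output with knots at the step breakpoints); its value at $+a$ is zero up
to accumulated rounding and is asserted below $10^{-9}$ in tests rather
than snapped.

## Subdivision

`build_compatible_subset` splits each edge of arc length $L$ into
$k = \max(\lceil L/\varepsilon\rceil, 2)$ equal-arc-length pieces,
incrementing $k$ until $L/k < \varepsilon$ strictly.  The floor of 2
guarantees at least one interior point per edge, so loops are always
represented by at least two chords and the subset is compatible in the
CW sense.

## Stability bounds

All closed forms are evaluated literally, with branch predicates as
printed (first branch iff $L/n > 2\varepsilon$ strictly; the short-piece
branch applies at equality).  The per-edge piece count
$n = \max(\lceil (M^2L^3/24\varepsilon)^{1/3}\rceil, \lceil LM/\pi\rceil)$
is floored at 1 so that straight edges ($M = 0$) do not crash the bound;
the theory implicitly assumes $M > 0$ there.

The directional envelope $f(\theta)$ underlying the near-straight bound
is implemented with a **minus** sign on its fourth term,
$-\max(0, \varepsilon - L|\sin\theta|)$: the published display carries a
plus sign, but the accompanying evaluation at $\theta = 0$
($f(0) = \sqrt{8L\varepsilon} + \sqrt{2L\varepsilon + \varepsilon^2}
- \varepsilon$) requires the minus, and the minus version is what the
package asserts against the branch bounds.  Only the even symmetry
$f(-\theta) = f(\theta)$ holds for the literal formula; a quarter-period
symmetry sometimes attributed to it fails numerically and is not
asserted.

Empirical certification harnesses measure a perturbation
$\varepsilon$ as the computed upper metric estimate inflated by
$10^{-9}$ (the bound's hypothesis is a strict inequality) and inflate
measured curvature maxima by 5% before evaluating bounds, since the
theory requires a true upper bound $M$ while finite differences estimate
it from below on discrete data.

## Curvature estimation

Curvature is the central second difference of the constant-velocity
resampling, $\kappa_i = \|p_{i-1} - 2p_i + p_{i+1}\|/h^2$.  The
finite-difference spacing is kept at least four input samples wide
(resample count $\max(\min(200, n), \lfloor n/4\rfloor)$): the
constant-velocity resampling linearly interpolates the input chain and
carries an $O(\Delta_{\rm in}^2)$ scallop which the second difference
amplifies by $1/h^2$, so matching $h$ to the input spacing would leave a
non-vanishing $\sim 12\%$ bias.  With the 4-sample cap the bias is below
1% on analytic test shapes (circle, 2:1 ellipse).

Similarly, the constant-velocity resampling is exact in arc-length
spacing, but the Euclidean *chord* speeds of the output chain vary at
second order, $(\kappa h)^2/24$; tests assert chord-speed constancy at
$10^{-3}$ for smooth curves rather than machine precision.

## Gaussian-process smoothing

Observations are modelled as $y_{ij} = f^j(a_i) + \zeta_{ij}$ with
$\zeta_{ij} \sim N(0, \sigma^2)$ i.i.d. per coordinate $j$.  All
interfaces take the noise **variance** $\sigma^2$; the literature
sometimes writes $N(0, \sigma)$ for the same object, so the convention
is fixed here once.  Posterior conditioning uses a Cholesky
factorisation of $K(a,a) + \sigma^2 I$ with a jitter ladder
$0 \to 10^{-10} \to 10^{-8} \to 10^{-6}$ (relative to the mean diagonal)
on failure; randomness enters only through explicit seeds.

The closed-curve kernel is the sine-squared exponential
$k(s,t) = \exp(-2\sin^2\frac{s-t}{2})$ on $[0, 2\pi)$, with analytic
derivatives up to the second mixed partial
($k_{xy}(t,t) = 1$); kernels lacking analytic partials fall back to
central differences with step $10^{-5}$ and emit a `RuntimeWarning`.
The derivative-process variance
$v'_n(t) = k_{xy}(t,t) - K_x(t,a) B_n^{-1} K_y(a,t)$ is clipped at zero
for negative values above $-10^{-8}$ and is verified to decrease
monotonically as observations are appended.

Covering numbers for the entropy integral
$J(Z, d) = \int_0^\infty \sqrt{\log N(Z,\varepsilon,d)}\,d\varepsilon$
are computed by a greedy frontier cover on a finite dense sampling
(default 2000 domain points, 400-point log-spaced $\varepsilon$-grid):
an upper bound on the minimal cover, within a factor two on intervals,
which suffices for every $\le$-type use.  For the circle under the
angular metric the exact count $N(\varepsilon) = \lceil
\pi/\varepsilon\rceil$ is integrated directly.

## Estimator

Sample locations are equally spaced in arc length (deterministic;
density is all the consistency theory needs, and determinism buys exact
reproducibility).  Loops take fractions $i/n$, $i = 0..n-1$; open edges
include both endpoints.  One GP per edge smooths all coordinates through
a shared Gram factorisation; the posterior mean is evaluated on a dense
uniform grid ($m$ defaults to $\max(4n, 256)$ points per edge — a
heuristic refinement, not a theorem), reparametrised to constant
velocity, and fed to the exact PL transform.  Posterior curve draws use
an eigenvalue square root of the posterior covariance and a shared seed
stream, with coordinates drawn independently per the model.  The
reference transform of a known truth is computed from a 10× finer
interpolation of the true chain.

## Synthetic shapes

Generators cover the shapes the theory speaks about: circles (analytic
reference ECT known in closed form: $0, 1, 0$ with breakpoints at
$\mp r$), straight segments, the line/wave instability pair (amplitude
$\varepsilon$, $\lceil 1/\varepsilon\rceil$ *full* oscillations — enough
for the ECC separation $\ge 1$), and closed curves from complex Fourier
coefficients $t \mapsto \sum_k c_k e^{ikt}$.  The default test curve is
a seeded random spectrum with $c_1 = 1$ and $|c_k| = |k|^{-3}$ for
$2 \le |k| \le 5$: a smooth, simple perturbed circle of diameter about
2, emulating a closed outline at the scale the estimator study uses.

What the generators do *not* emulate: segmentation artefacts
(quantisation, spurious spurs), correlated or heteroscedastic noise,
outliers, partial occlusion, and unknown topology.  Passing tests
therefore certify the transform machinery, the bounds and the
estimator's statistical behaviour under the stated model — independent
Gaussian perturbations of a known homeomorphism type — not robustness to
arbitrary real-image pathologies.

## Problem sizes

Test and reproduction runs use desk-scale sizes chosen to keep every
quantity well inside its asymptotic regime: polylines of 2000–20000
samples for geometric oracles, 64 directions for field distances, 30
perturbed pairs for the stability certification, sample counts
$n \in \{20, 50, 100\}$ with 20 repetitions and noise sd
$\sigma = 0.002$ for the estimator study.  The estimator's error level
depends on the particular test curve; only its monotone decrease in $n$
and the inequality certificates are claims, not the absolute error
values.

## Known limitations

* Direction grids under-estimate the sup over $S^{d-1}$; for $d > 2$
  only a seeded random direction fallback is provided.
* `cw_distance_upper` is an upper estimate; no optimisation over
  reparametrisations beyond orientation is attempted.
* No hyperparameter estimation: the kernel and $\sigma^2$ are fixed
  inputs.  No low-rank Gram approximations; fits are $O(n^3)$.
* Shapes of dimension $\ge 2$ (meshes), persistent-homology transforms,
  and reconstruction of shapes from their transforms are out of scope.
* Whether a given data-generating curve lies in the kernel's RKHS (a
  hypothesis of the consistency theory) is not testable here; no
  membership check is attempted.
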
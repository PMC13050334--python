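"""Gaussian-process machinery for smoothing noisy curve samples.

A centred GP prior with kernel k, conditioned on n noisy observations
y_i = f(a_i) + zeta_i with zeta_i ~ N(0, sigma^2) i.i.d., has posterior

    mean(X') = K(X', a) (K(a, a) + sigma^2 I)^{-1} y
    cov(X')  = K(X', X') - K(X', a) (K(a, a) + sigma^2 I)^{-1} K(a, X'),

and, for a twice-differentiable kernel, the derivative process is again
a GP with kernel k_xy whose posterior variance

    v'_n(t) = k_xy(t, t) - K_x(t, a) (K(a, a) + sigma^2 I)^{-1} K_y(a, t)

is nonincreasing as observations are appended.  Throughout, sigma^2
denotes the noise VARIANCE.  The module also provides the canonical
kernel metric d_k and the covering-number entropy integral
J(Z, d) = int_0^inf sqrt(log N(Z, eps, d)) d eps, whose finiteness is the
hypothesis under which the posterior mean converges uniformly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .complex_model import InvalidInputError

__all__ = [
    "KernelModel",
    "GPFit",
    "KernelValidityError",
    "ConditioningError",
    "kernel_sine_squared",
    "pullback_kernel",
    "dk_metric",
    "covering_number",
    "covering_integral",
    "covering_integral_from_counts",
    "circle_entropy_integral",
    "gp_posterior",
    "derivative_variance",
]

JITTER_LADDER = (0.0, 1e-10, 1e-8, 1e-6)


class KernelValidityError(InvalidInputError):
    """A kernel evaluation violates positive semidefiniteness."""


class ConditioningError(RuntimeError):
    """The regularised Gram matrix could not be factorised."""


@dataclass(frozen=True)
class KernelModel:
    """A symmetric PSD kernel with (optional) analytic partial derivatives.

    ``k`` is vectorised over broadcastable arrays.  ``kx`` and ``ky`` are
    the partials in the first and second slot, ``kxy`` the second mixed
    partial; missing derivatives trigger a central-difference fallback
    (step 1e-5) with a warning.
    """

    k: Callable[[np.ndarray, np.ndarray], np.ndarray]
    kx: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    ky: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    kxy: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    periodic: bool = False
    period: float | None = None
    name: str = "kernel"
    params: dict = field(default_factory=dict)

    _FD_STEP = 1e-5

    def _fd(self, which: str, s: np.ndarray, t: np.ndarray) -> np.ndarray:
        warnings.warn(
            f"{self.name}: analytic {which} unavailable; falling back to "
            "central differences (reduced precision)",
            RuntimeWarning,
            stacklevel=3,
        )
        h = self._FD_STEP
        if which == "kx":
            return (self.k(s + h, t) - self.k(s - h, t)) / (2 * h)
        if which == "ky":
            return (self.k(s, t + h) - self.k(s, t - h)) / (2 * h)
        return (
            self.k(s + h, t + h)
            - self.k(s + h, t - h)
            - self.k(s - h, t + h)
            + self.k(s - h, t - h)
        ) / (4 * h * h)

    def eval_kx(self, s, t):
        s, t = np.asarray(s, float), np.asarray(t, float)
        return self.kx(s, t) if self.kx is not None else self._fd("kx", s, t)

    def eval_ky(self, s, t):
        s, t = np.asarray(s, float), np.asarray(t, float)
        return self.ky(s, t) if self.ky is not None else self._fd("ky", s, t)

    def eval_kxy(self, s, t):
        s, t = np.asarray(s, float), np.asarray(t, float)
        return self.kxy(s, t) if self.kxy is not None else self._fd("kxy", s, t)

    def gram(self, s: np.ndarray, t: np.ndarray | None = None) -> np.ndarray:
        s = np.asarray(s, float)
        t = s if t is None else np.asarray(t, float)
        return np.asarray(self.k(s[:, None], t[None, :]), float)


def kernel_sine_squared() -> KernelModel:
    """The sine-squared exponential kernel on the circle.

    k(s, t) = exp(-2 sin^2((s - t)/2)), 2*pi-periodic, with analytic
    derivatives: writing u = s - t and k = k(u),
    k_x = -sin(u) k, k_y = sin(u) k, k_xy = (cos u - sin^2 u) k.
    Its diagonal is 1 and the prior derivative variance k_xy(t, t) is 1.
    """

    def k(s, t):
        return np.exp(-2.0 * np.sin(0.5 * (s - t)) ** 2)

    def kx(s, t):
        u = s - t
        return -np.sin(u) * np.exp(-2.0 * np.sin(0.5 * u) ** 2)

    def ky(s, t):
        u = s - t
        return np.sin(u) * np.exp(-2.0 * np.sin(0.5 * u) ** 2)

    def kxy(s, t):
        u = s - t
        return (np.cos(u) - np.sin(u) ** 2) * np.exp(-2.0 * np.sin(0.5 * u) ** 2)

    return KernelModel(
        k=k, kx=kx, ky=ky, kxy=kxy, periodic=True, period=2.0 * np.pi,
        name="sine-squared-exponential",
    )


def pullback_kernel(base: KernelModel, f: Callable[[np.ndarray], np.ndarray],
                    name: str | None = None) -> KernelModel:
    """Kernel k'(s, t) = k(f(s), f(t)) induced by precomposition with f.

    Derivatives of the composite are left to the finite-difference
    fallback unless the base kernel metric is needed only through values.
    """
    def k(s, t):
        return base.k(f(np.asarray(s, float)), f(np.asarray(t, float)))

    return KernelModel(k=k, name=name or f"pullback({base.name})")


def dk_metric(kernel: KernelModel, s, t) -> np.ndarray | float:
    """Canonical kernel metric d_k(s,t) = sqrt(k(s,s)+k(t,t)-2k(s,t))."""
    s = np.asarray(s, float)
    t = np.asarray(t, float)
    sq = kernel.k(s, s) + kernel.k(t, t) - 2.0 * kernel.k(s, t)
    sq = np.asarray(sq, float)
    if np.any(sq < -1e-10):
        raise KernelValidityError("negative squared kernel distance")
    out = np.sqrt(np.clip(sq, 0.0, None))
    return out if out.ndim else float(out)


def covering_number(dist_matrix: np.ndarray, eps: float) -> int:
    """Greedy cover size of a finite metric space with eps-balls.

    An upper bound on the minimal covering number of the sampled space.
    """
    n = dist_matrix.shape[0]
    uncovered = np.ones(n, dtype=bool)
    count = 0
    while uncovered.any():
        i = int(np.argmax(uncovered))
        uncovered &= dist_matrix[i] > eps
        count += 1
    return count


def covering_integral(
    dist_matrix: np.ndarray,
    eps_grid: np.ndarray | None = None,
    n_eps: int = 400,
) -> float:
    """Entropy integral J = int sqrt(log N(eps)) d eps on a finite sampling.

    Covering numbers come from the greedy cover; the integrand vanishes
    once a single ball covers everything, so the integral is effectively
    over (0, diameter].  Trapezoid quadrature on a log-spaced grid.
    """
    D = np.asarray(dist_matrix, float)
    if D.size == 0:
        raise InvalidInputError("empty domain")
    diam = float(D.max())
    if diam == 0.0:
        return 0.0
    if eps_grid is None:
        eps_grid = np.concatenate(
            [[0.0], np.geomspace(diam * 1e-6, diam * 1.0001, n_eps)]
        )
    eps_grid = np.asarray(eps_grid, float)
    integrand = np.empty(len(eps_grid))
    for i, e in enumerate(eps_grid):
        if e <= 0:
            # the finite sampling cannot resolve below its resolution;
            # extend the smallest positive value to 0 (conservative cap)
            integrand[i] = np.nan
            continue
        N = covering_number(D, e)
        integrand[i] = np.sqrt(np.log(N)) if N > 1 else 0.0
    if np.isnan(integrand[0]):
        integrand[0] = integrand[1]
    return float(np.trapezoid(integrand, eps_grid))


def covering_integral_from_counts(
    count_fn: Callable[[float], float],
    eps_max: float,
    eps_min: float = 1e-8,
    n_eps: int = 2000,
) -> float:
    """Entropy integral from an explicit covering-number function."""
    eps = np.geomspace(eps_min, eps_max, n_eps)
    N = np.array([count_fn(float(e)) for e in eps], float)
    integrand = np.where(N > 1.0, np.sqrt(np.log(np.maximum(N, 1.0))), 0.0)
    head = integrand[0] * eps[0]  # constant extension over (0, eps_min]
    return float(np.trapezoid(integrand, eps) + head)


def circle_entropy_integral(n_eps: int = 2000) -> float:
    """J of the unit circle under the angular metric, N(eps) = ceil(pi/eps)."""
    return covering_integral_from_counts(
        lambda e: np.ceil(np.pi / e), eps_max=np.pi, n_eps=n_eps
    )


class GPFit:
    """Posterior state of a GP regression with fixed kernel and noise.

    Observations ``y`` may have several columns (independent outputs
    sharing inputs and the Gram factorisation).  ``sigma2`` is the noise
    variance added to the Gram diagonal.
    """

    def __init__(
        self,
        kernel: KernelModel,
        train_inputs: Sequence[float],
        y: np.ndarray,
        sigma2: float,
    ) -> None:
        if sigma2 <= 0:
            raise InvalidInputError("noise variance must be positive")
        self.kernel = kernel
        self.a = np.asarray(train_inputs, float).ravel()
        y = np.asarray(y, float)
        self.y = y[:, None] if y.ndim == 1 else y
        if len(self.a) != len(self.y):
            raise InvalidInputError("inputs and observations length mismatch")
        self.sigma2 = float(sigma2)
        self._factor = None
        if len(self.a):
            B = self.kernel.gram(self.a) + self.sigma2 * np.eye(len(self.a))
            self._factor = _factor_with_jitter(B)
            self.alpha = cho_solve(self._factor, self.y)
        else:
            self.alpha = np.zeros((0, self.y.shape[1]))

    @property
    def n(self) -> int:
        return len(self.a)

    def _solve(self, rhs: np.ndarray) -> np.ndarray:
        if self._factor is None:
            return np.zeros_like(rhs)
        return cho_solve(self._factor, rhs)

    def posterior(self, query: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean (m, p) and covariance (m, m) at the query points."""
        q = np.asarray(query, float).ravel()
        K_qq = self.kernel.gram(q)
        if self.n == 0:
            return np.zeros((len(q), self.y.shape[1])), K_qq
        K_qa = self.kernel.gram(q, self.a)
        mean = K_qa @ self.alpha
        cov = K_qq - K_qa @ self._solve(K_qa.T)
        return mean, cov

    def posterior_mean(self, query: Sequence[float]) -> np.ndarray:
        q = np.asarray(query, float).ravel()
        if self.n == 0:
            return np.zeros((len(q), self.y.shape[1]))
        return self.kernel.gram(q, self.a) @ self.alpha

    def variance(self, query: Sequence[float]) -> np.ndarray:
        _, cov = self.posterior(query)
        return np.diag(cov).copy()

    def derivative_variance(self, t: Sequence[float]) -> np.ndarray:
        """Posterior variance of the derivative process at t."""
        t = np.asarray(t, float).ravel()
        prior = np.asarray(self.kernel.eval_kxy(t, t), float)
        if self.n == 0:
            return prior * np.ones(len(t))
        Kx = np.asarray(self.kernel.eval_kx(t[:, None], self.a[None, :]), float)
        Ky = np.asarray(self.kernel.eval_ky(self.a[:, None], t[None, :]), float)
        reduction = np.einsum("ij,ji->i", Kx, self._solve(Ky))
        v = prior - reduction
        if np.any(v < -1e-8):
            raise KernelValidityError("derivative variance is significantly negative")
        return np.clip(v, 0.0, None)

    def derivative_mean(self, t: Sequence[float]) -> np.ndarray:
        """Posterior mean of the derivative process (same weights alpha)."""
        t = np.asarray(t, float).ravel()
        if self.n == 0:
            return np.zeros((len(t), self.y.shape[1]))
        Kx = np.asarray(self.kernel.eval_kx(t[:, None], self.a[None, :]), float)
        return Kx @ self.alpha

    def sample_posterior(
        self, query: Sequence[float], n_draws: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Draw posterior sample paths, shape (n_draws, m, p).

        Coordinates are drawn independently, matching the model's
        independent-output assumption.
        """
        mean, cov = self.posterior(query)
        m, p = mean.shape
        factor = _factor_psd(cov)
        z = rng.standard_normal((n_draws, p, factor.shape[1]))
        paths = mean.T[None, :, :] + z @ factor.T[None, :, :]
        return np.swapaxes(paths, 1, 2)


def _factor_with_jitter(B: np.ndarray):
    last_err: Exception | None = None
    scale = np.trace(B) / len(B)
    for jit in JITTER_LADDER:
        try:
            return cho_factor(B + jit * scale * np.eye(len(B)), lower=True)
        except np.linalg.LinAlgError as err:  # pragma: no cover - rare path
            last_err = err
    raise ConditioningError(f"Gram matrix not PSD within jitter ladder: {last_err}")


def _factor_psd(cov: np.ndarray) -> np.ndarray:
    """Symmetric square root of a PSD matrix via eigen-decomposition."""
    w, V = np.linalg.eigh((cov + cov.T) / 2.0)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)[None, :]


def gp_posterior(fit: GPFit, query: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and covariance at the query points (see GPFit)."""
    return fit.posterior(query)


def derivative_variance(fit: GPFit, t: Sequence[float]) -> np.ndarray:
    """Posterior derivative variance v'_n(t) (see GPFit)."""
    return fit.derivative_variance(t)
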
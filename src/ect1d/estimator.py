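"""Consistent ECT/SECT estimation from noisy point samples.

Pipeline: sample a known 1-D shape at equal arc-length spacing, perturb
every coordinate independently with Gaussian noise, smooth each
coordinate with a GP posterior mean (a periodic kernel on [0, 2*pi) for
closed curves), reparametrise the smoothed curve to constant velocity,
and take the exact PL ECT/SECT of its dense interpolation.  As the
number of samples grows the posterior mean converges uniformly to the
true curve (given a kernel with finite entropy integral whose RKHS
contains the curve), so the estimated transform converges to the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .complex_model import (
    EmbeddedComplex,
    InvalidInputError,
    SampledCurve,
    arc_length,
    curve_param_at_arclength,
    curve_points_at_params,
    cumulative_arc_length,
    reparam_constant_velocity,
    single_curve_complex,
)
from .ect_core import (
    DirectionSet,
    ECTField,
    SECTField,
    ect_distance,
    ect_field_of_polylines,
    sect_distance,
    sect_from_ect,
    uniform_directions,
)
from .gp_smoothing import GPFit, KernelModel, kernel_sine_squared

__all__ = [
    "NoisyObservationSet",
    "EstimateResult",
    "sample_noisy",
    "smooth_embedding",
    "estimate_ect",
    "consistency_experiment",
]


@dataclass(frozen=True)
class NoisyObservationSet:
    """Noisy coordinate observations at known sample locations.

    ``locations`` pairs each row of ``y`` with an (edge_id, param)
    position on the complex; noise is independent N(0, sigma_j^2) per
    coordinate j.
    """

    locations: Tuple[Tuple[str, float], ...]
    y: np.ndarray
    sigma: np.ndarray
    seed: int | None
    closed: bool

    def __post_init__(self) -> None:
        y = np.asarray(self.y, float)
        sigma = np.atleast_1d(np.asarray(self.sigma, float))
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "sigma", sigma)
        if len(self.locations) != len(y):
            raise InvalidInputError("one observation row per location required")
        if np.any(sigma <= 0):
            raise InvalidInputError("noise standard deviations must be positive")

    def params_for_edge(self, edge_id: str) -> np.ndarray:
        return np.array([p for e, p in self.locations if e == edge_id])

    def y_for_edge(self, edge_id: str) -> np.ndarray:
        mask = np.array([e == edge_id for e, _ in self.locations])
        return self.y[mask]


@dataclass(frozen=True)
class EstimateResult:
    """Smoothed complex, its PL transform, and distances to a reference."""

    smoothed: EmbeddedComplex
    ect: ECTField
    sect: SECTField
    edge_lengths: Dict[str, float]
    distances: Dict[str, float] = field(default_factory=dict)


def sample_noisy(
    X: EmbeddedComplex,
    n: int,
    sigma: float | Sequence[float],
    seed: int | np.random.Generator | None = None,
) -> NoisyObservationSet:
    """n equal-arc-length samples per edge, Gaussian-perturbed per coordinate.

    Closed single-loop complexes are sampled at arc fractions i/n
    (i = 0..n-1, the vertex included once); open edges include both
    endpoints at fractions i/(n-1).
    """
    if n < 4:
        raise InvalidInputError("need at least 4 samples")
    sig = np.atleast_1d(np.asarray(sigma, float))
    if sig.size == 1:
        sig = np.repeat(sig, X.dimension)
    if np.any(sig <= 0):
        raise InvalidInputError("sigma must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, int) else None

    locations: List[Tuple[str, float]] = []
    rows: List[np.ndarray] = []
    closed = _is_single_loop(X)
    for eid, u, v in X.structure.edges:
        curve = X.curves[eid]
        L = arc_length(curve)
        if closed:
            fracs = np.arange(n) / n
        else:
            fracs = np.linspace(0.0, 1.0, n)
        t_par = curve_param_at_arclength(curve, fracs * L)
        pts = curve_points_at_params(curve, t_par)
        noise = rng.normal(0.0, 1.0, size=pts.shape) * sig[None, :]
        for tp, row in zip(t_par, pts + noise):
            locations.append((eid, float(tp)))
            rows.append(row)
    return NoisyObservationSet(
        locations=tuple(locations),
        y=np.vstack(rows),
        sigma=sig,
        seed=seed_val,
        closed=closed,
    )


def _is_single_loop(X: EmbeddedComplex) -> bool:
    edges = X.structure.edges
    return len(edges) == 1 and edges[0][1] == edges[0][2]


def fit_edge_gp(
    obs: NoisyObservationSet,
    edge_id: str,
    kernel: KernelModel,
) -> GPFit:
    """One multi-output GP per edge; parameters are mapped to the kernel's
    native domain (angles on [0, 2*pi) for periodic kernels)."""
    t_par = obs.params_for_edge(edge_id)
    y = obs.y_for_edge(edge_id)
    scale = kernel.period if (kernel.periodic and kernel.period) else 1.0
    sigma2 = float(np.mean(obs.sigma**2))
    return GPFit(kernel, t_par * scale, y, sigma2)


def smooth_embedding(
    obs: NoisyObservationSet,
    X: EmbeddedComplex,
    kernel: KernelModel | None = None,
    m_eval: int = 256,
) -> EmbeddedComplex:
    """Posterior-mean curve per edge, evaluated on a dense uniform grid.

    For closed curves with a periodic kernel the two endpoint evaluations
    coincide by periodicity, so the smoothed loop closes exactly.
    """
    if kernel is None:
        kernel = kernel_sine_squared()
    scale = kernel.period if (kernel.periodic and kernel.period) else 1.0
    curves: Dict[str, SampledCurve] = {}
    vertex_coords: Dict[str, np.ndarray] = dict(X.vertex_coords)
    for eid, u, v in X.structure.edges:
        fitted = fit_edge_gp(obs, eid, kernel)
        t_grid = np.linspace(0.0, 1.0, m_eval + 1)
        mean = fitted.posterior_mean(t_grid * scale)
        if u == v and kernel.periodic:
            mean[-1] = mean[0]
        curves[eid] = SampledCurve(t_grid, mean)
        vertex_coords[u] = mean[0]
        vertex_coords[v] = mean[-1]
    return EmbeddedComplex(X.structure, vertex_coords, curves)


def estimate_ect(
    obs: NoisyObservationSet,
    X: EmbeddedComplex,
    kernel: KernelModel | None = None,
    m: int | None = None,
    directions: DirectionSet | None = None,
    a: float | None = None,
    reference_ect: ECTField | None = None,
    reference_sect: SECTField | None = None,
) -> EstimateResult:
    """GP smoothing, constant-velocity resampling, then the exact PL ECT.

    m defaults to max(4n, 256) interpolation points per edge, a heuristic
    refinement of the observation count.
    """
    if kernel is None:
        kernel = kernel_sine_squared()
    n_per_edge = max(
        sum(1 for e, _ in obs.locations if e == eid)
        for eid, _, _ in X.structure.edges
    )
    if m is None:
        m = max(4 * n_per_edge, 256)
    if directions is None:
        directions = uniform_directions(64, X.dimension)
    smoothed = smooth_embedding(obs, X, kernel, m_eval=m)
    uniform = EmbeddedComplex(
        smoothed.structure,
        smoothed.vertex_coords,
        {
            eid: reparam_constant_velocity(c, m + 1)
            for eid, c in smoothed.curves.items()
        },
    )
    ect = ect_field_of_polylines(uniform, directions, a)
    sect = sect_from_ect(ect)
    lengths = {eid: arc_length(c) for eid, c in uniform.curves.items()}
    distances: Dict[str, float] = {}
    if reference_ect is not None:
        ref = reference_ect.rebounded(max(reference_ect.a, ect.a))
        distances["ect"] = ect_distance(ect.rebounded(ref.a), ref)
    if reference_sect is not None:
        distances["sect"] = sect_distance(sect, reference_sect)
    return EstimateResult(uniform, ect, sect, lengths, distances)


def reference_transforms(
    X: EmbeddedComplex,
    directions: DirectionSet,
    a: float,
    refine: int = 10,
) -> Tuple[ECTField, SECTField]:
    """ECT/SECT of the true shape from a refine-times finer interpolation."""
    fine = EmbeddedComplex(
        X.structure,
        X.vertex_coords,
        {
            eid: reparam_constant_velocity(c, refine * c.n_samples)
            for eid, c in X.curves.items()
        },
    )
    ect = ect_field_of_polylines(fine, directions, a)
    return ect, sect_from_ect(ect)


def consistency_experiment(
    X: EmbeddedComplex,
    n_list: Sequence[int] = (20, 50, 100),
    reps: int = 20,
    n_posterior: int = 0,
    sigma: float = 0.002,
    seed: int = 0,
    n_directions: int = 64,
    kernel: KernelModel | None = None,
) -> pd.DataFrame:
    """SECT error of the estimator across sample sizes.

    For each n and repetition: draw noisy samples, fit the GP, measure
    the SECT distance of the posterior-mean curve to the truth
    (point_estimate_distance); optionally draw n_posterior posterior
    curves and record the mean and sd of their SECT distances.  Returns
    one row per (n, rep).
    """
    if kernel is None:
        kernel = kernel_sine_squared()
    directions = uniform_directions(n_directions, X.dimension)
    a = 1.5 * X.max_norm()
    _, ref_sect = reference_transforms(X, directions, a)
    ss = np.random.SeedSequence(seed)
    rows = []
    for n in n_list:
        for rep in range(reps):
            child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(n, rep))
            rng = np.random.default_rng(child)
            obs = sample_noisy(X, n, sigma, rng)
            result = estimate_ect(
                obs, X, kernel, directions=directions, a=a,
                reference_sect=ref_sect,
            )
            row = {
                "n": n,
                "rep": rep,
                "point_estimate_distance": result.distances["sect"],
                "posterior_mean_distance": np.nan,
                "posterior_sd_distance": np.nan,
            }
            if n_posterior > 0:
                draws = _posterior_sect_distances(
                    obs, X, kernel, directions, a, ref_sect, n_posterior, rng
                )
                row["posterior_mean_distance"] = float(np.mean(draws))
                row["posterior_sd_distance"] = float(np.std(draws, ddof=1))
            rows.append(row)
    return pd.DataFrame(rows)


def _posterior_sect_distances(
    obs: NoisyObservationSet,
    X: EmbeddedComplex,
    kernel: KernelModel,
    directions: DirectionSet,
    a: float,
    ref_sect: SECTField,
    n_draws: int,
    rng: np.random.Generator,
    m_eval: int = 128,
) -> np.ndarray:
    eid = X.structure.edges[0][0]
    fitted = fit_edge_gp(obs, eid, kernel)
    scale = kernel.period if (kernel.periodic and kernel.period) else 1.0
    t_grid = np.linspace(0.0, 1.0, m_eval + 1)
    paths = fitted.sample_posterior(t_grid * scale, n_draws, rng)
    out = np.empty(n_draws)
    for i in range(n_draws):
        pts = paths[i]
        pts[-1] = pts[0]
        curve = SampledCurve(t_grid, pts)
        complex_i = single_curve_complex(curve, closed=True)
        ect = ect_field_of_polylines(complex_i, directions, a)
        out[i] = sect_distance(sect_from_ect(ect), ref_sect)
    return out


def summarise_consistency(table: pd.DataFrame) -> pd.DataFrame:
    """Per-n mean/sd/median of the recorded distances."""
    return table.groupby("n").agg(
        reps=("rep", "count"),
        mean=("point_estimate_distance", "mean"),
        sd=("point_estimate_distance", "std"),
        median=("point_estimate_distance", "median"),
        posterior_mean=("posterior_mean_distance", "mean"),
        posterior_sd=("posterior_sd_distance", "mean"),
    ).reset_index()
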
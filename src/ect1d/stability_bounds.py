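"""Closed-form stability bounds for the ECT of curvature-constrained shapes.

The ECT of a one-dimensional shape is not stable under arbitrary small
Hausdorff perturbations, but it is stable once the comparison respects a
curvature bound M: if two embeddings of the same complex stay within eps
of each other (in sup norm, with arc lengths differing by at most eps,
both at constant velocity per edge), the ECT distance is controlled by an
explicit function of (M, edge lengths, eps).  The bound splits each edge
into n nearly straight pieces, bounds each piece by the near-straight
estimate, and sums.  A companion bound controls the error of replacing a
smooth shape by its chord interpolation on an eps-dense vertex set, and a
further factor converts any ECT distance into a SECT distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np

from .complex_model import InvalidInputError

__all__ = [
    "BoundParams",
    "BoundReport",
    "OutOfDomainError",
    "segment_count",
    "edge_term",
    "curvature_stability_bound",
    "near_straight_bound",
    "stability_envelope",
    "chord_lower_bound",
    "pl_approximation_bound",
    "sect_factor",
    "bound_report",
]


class OutOfDomainError(InvalidInputError):
    """A bound is evaluated outside its stated hypothesis."""


@dataclass(frozen=True)
class BoundParams:
    """Inputs to the stability bounds.

    M: curvature bound; lengths: arc length per edge; eps: perturbation
    size; n_vertices: number of 0-cells; a: bounding radius (only needed
    for the SECT conversion factor).
    """

    M: float
    lengths: Sequence[float]
    eps: float
    n_vertices: int
    a: float | None = None

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise InvalidInputError("eps must be positive")
        if self.M < 0:
            raise InvalidInputError("curvature bound must be nonnegative")
        if any(L <= 0 for L in self.lengths):
            raise InvalidInputError("edge lengths must be positive")
        if self.n_vertices < 0:
            raise InvalidInputError("vertex count must be nonnegative")


def segment_count(M: float, L: float, eps: float) -> int:
    """Pieces needed to make each sub-arc of an edge nearly straight.

    n = max(ceil((M^2 L^3 / 24 eps)^(1/3)), ceil(L M / pi)), floored at 1
    so straight edges (M = 0) still yield a well-defined split.
    """
    if eps <= 0 or L <= 0:
        raise InvalidInputError("eps and L must be positive")
    if M < 0:
        raise InvalidInputError("M must be nonnegative")
    n1 = math.ceil((M * M * L**3 / (24.0 * eps)) ** (1.0 / 3.0))
    n2 = math.ceil(L * M / math.pi)
    return max(n1, n2, 1)


def edge_term(eps: float, L: float, n: int) -> float:
    """Per-edge contribution G(eps) = 8 sqrt(L n eps) + n eps, or 11 n eps.

    The first branch applies when the pieces are long relative to the
    perturbation (L/n > 2 eps); otherwise each piece falls into the
    short-segment regime.
    """
    if n < 1:
        raise InvalidInputError("n must be at least 1")
    if eps <= 0 or L <= 0:
        raise InvalidInputError("eps and L must be positive")
    if L / n > 2.0 * eps:
        return 8.0 * math.sqrt(L * n * eps) + n * eps
    return 11.0 * n * eps


def curvature_stability_bound(p: BoundParams) -> float:
    """Total ECT stability bound |Z_0| eps + sum of per-edge terms."""
    total = p.n_vertices * p.eps
    for L in p.lengths:
        n = segment_count(p.M, L, p.eps)
        total += edge_term(p.eps, L, n)
    return float(total)


def near_straight_bound(L: float, eps: float) -> float:
    """ECT distance bound for two nearly straight curves.

    alpha has endpoints a distance L apart with arc length <= L + eps;
    beta has arc length <= L + 2 eps and endpoints within eps of alpha's.
    Then the ECT distance is at most 8 sqrt(L eps) for L > 2 eps and
    10 eps otherwise.
    """
    if L <= 0 or eps <= 0:
        raise InvalidInputError("L and eps must be positive")
    if L > 2.0 * eps:
        return 8.0 * math.sqrt(L * eps)
    return 10.0 * eps


def stability_envelope(theta: float | np.ndarray, L: float, eps: float) -> np.ndarray | float:
    """Directional envelope underlying the near-straight bound.

    f(theta) = sqrt((L+2e)^2 - max(0, L|cos t| - 2e)^2)
             + sqrt((L+e)^2 - L^2 cos^2 t)
             - 2 max(0, L|sin t| - 2e) - max(0, e - L|sin t|).

    The maximum of f over theta dominates the per-direction ECC distance
    and stays below the near-straight bound.
    """
    theta = np.asarray(theta, dtype=float)
    ac = L * np.abs(np.cos(theta))
    as_ = L * np.abs(np.sin(theta))
    term1 = np.sqrt((L + 2 * eps) ** 2 - np.maximum(0.0, ac - 2 * eps) ** 2)
    term2 = np.sqrt(np.maximum((L + eps) ** 2 - ac**2, 0.0))
    term3 = -2.0 * np.maximum(0.0, as_ - 2 * eps)
    term4 = -np.maximum(0.0, eps - as_)
    out = term1 + term2 + term3 + term4
    return out if out.ndim else float(out)


def chord_lower_bound(M: float, eps: float) -> Dict[str, float]:
    """Lower bound on the chord of an arc of length eps under curvature M.

    For an arc-length window eps < pi/M the chord between the ends is at
    least (2/M) sin(M eps / 2), itself at least eps - M^2 eps^3 / 24.
    """
    if M <= 0:
        raise InvalidInputError("M must be positive; straight arcs have chord = eps")
    if not 0 < eps < math.pi / M:
        raise OutOfDomainError("requires 0 < eps < pi/M")
    exact = (2.0 / M) * math.sin(0.5 * M * eps)
    cubic = eps - M * M * eps**3 / 24.0
    return {"bound": exact, "cubic": cubic}


def pl_approximation_bound(M: float, L: float, eps: float) -> float:
    """Error bound M L eps / sqrt(12) of the chord interpolation.

    Valid for an eps-dense vertex set with eps < pi/M; M = 0 returns 0
    (chords reproduce straight shapes exactly).
    """
    if L <= 0 or eps <= 0:
        raise InvalidInputError("L and eps must be positive")
    if M < 0:
        raise InvalidInputError("M must be nonnegative")
    if M > 0 and eps >= math.pi / M:
        raise OutOfDomainError("requires eps < pi/M")
    return M * L * eps / math.sqrt(12.0)


def sect_factor(a: float) -> float:
    """SECT distances are at most (2a + 1) times ECT distances on [-a, a]."""
    if a <= 0:
        raise InvalidInputError("a must be positive")
    return 2.0 * a + 1.0


@dataclass(frozen=True)
class BoundReport:
    """Evaluated stability quantities for one parameter set."""

    params: BoundParams
    segment_counts: Dict[int, int]
    edge_terms: Dict[int, float]
    total_bound: float
    pl_bound: float | None
    near_straight: Dict[int, float]
    sect_multiplier: float | None

    def as_dict(self) -> Dict[str, object]:
        return {
            "M": self.params.M,
            "lengths": list(self.params.lengths),
            "eps": self.params.eps,
            "n_vertices": self.params.n_vertices,
            "segment_counts": {str(k): v for k, v in self.segment_counts.items()},
            "edge_terms": {str(k): v for k, v in self.edge_terms.items()},
            "total_bound": self.total_bound,
            "pl_bound": self.pl_bound,
            "near_straight_bounds": {str(k): v for k, v in self.near_straight.items()},
            "sect_multiplier": self.sect_multiplier,
        }


def bound_report(p: BoundParams) -> BoundReport:
    """Evaluate every closed-form bound for the given parameters."""
    counts = {i: segment_count(p.M, L, p.eps) for i, L in enumerate(p.lengths)}
    terms = {i: edge_term(p.eps, L, counts[i]) for i, L in enumerate(p.lengths)}
    total = p.n_vertices * p.eps + sum(terms.values())
    L_total = float(sum(p.lengths))
    try:
        pl = pl_approximation_bound(p.M, L_total, p.eps) if p.M >= 0 else None
    except OutOfDomainError:
        pl = None
    near = {i: near_straight_bound(L, p.eps) for i, L in enumerate(p.lengths)}
    mult = sect_factor(p.a) if p.a is not None else None
    return BoundReport(p, counts, terms, float(total), pl, near, mult)
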
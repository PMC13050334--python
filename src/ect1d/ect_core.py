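"""Exact Euler characteristic transform machinery for 1-D shapes.

The directional Euler characteristic curve (ECC) of a piecewise-linear
shape is an integer-valued step function of the filtration level t: the
Euler characteristic of the part of the shape with projection <x, v> <= t.
For a chord interpolation on a compatible vertex set A with sub-edge
multiset E this is computed exactly by counting:

    ECC(t) = #{i : <a_i, v> <= t} - #{(i,j) in E : max projection <= t},

with breakpoints exactly at the projection values (no quadrature).  The
ECT is the collection of ECCs over a finite direction grid; the SECT
integrates each mean-centred ECC, giving a piecewise-linear function
vanishing at both ends of [-a, a].  Distances between fields are exact L1
integrals computed by breakpoint merging, maximised over directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np

from .complex_model import (
    EmbeddedComplex,
    InvalidInputError,
    SampledCurve,
    cumulative_arc_length,
    curve_param_at_arclength,
    curve_points_at_params,
)

__all__ = [
    "DirectionSet",
    "StepFunction",
    "PiecewiseLinear",
    "ECTField",
    "SECTField",
    "CompatibleSubset",
    "BoundViolationError",
    "FieldMismatchError",
    "uniform_directions",
    "build_compatible_subset",
    "pl_ect",
    "polyline_ecc",
    "ect_field",
    "ect_field_of_polylines",
    "ect_distance",
    "sect_from_ect",
    "sect_distance",
    "glue_check",
]


class BoundViolationError(InvalidInputError):
    """A bounding radius does not contain the shape."""


class FieldMismatchError(InvalidInputError):
    """Two fields do not share a direction set."""


@dataclass(frozen=True)
class DirectionSet:
    """A finite set of unit directions standing in for the sphere."""

    vectors: np.ndarray

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        object.__setattr__(self, "vectors", v)
        norms = np.linalg.norm(v, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-12):
            raise InvalidInputError("directions must be unit vectors")

    def __len__(self) -> int:
        return len(self.vectors)

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]

    def rotated(self, rotation: np.ndarray) -> "DirectionSet":
        return DirectionSet(self.vectors @ np.asarray(rotation, dtype=float).T)


def uniform_directions(m: int, d: int = 2, seed: int | None = None) -> DirectionSet:
    """m unit directions: the regular angular grid for d=2, random otherwise."""
    if m < 1:
        raise InvalidInputError("need at least one direction")
    if d == 2:
        theta = 2.0 * np.pi * np.arange(m) / m
        return DirectionSet(np.column_stack([np.cos(theta), np.sin(theta)]))
    rng = np.random.default_rng(0 if seed is None else seed)
    v = rng.standard_normal((m, d))
    return DirectionSet(v / np.linalg.norm(v, axis=1, keepdims=True))


class StepFunction:
    """Right-continuous integer step function, 0 before its first breakpoint.

    ``values[i]`` holds on [breakpoints[i], breakpoints[i+1]); the last
    value holds on [breakpoints[-1], inf).
    """

    __slots__ = ("breakpoints", "values")

    def __init__(self, breakpoints: Sequence[float], values: Sequence[float]):
        bp = np.asarray(breakpoints, dtype=float)
        va = np.asarray(values, dtype=float)
        if bp.ndim != 1 or len(bp) != len(va):
            raise InvalidInputError("breakpoints/values length mismatch")
        if len(bp) and not np.all(np.diff(bp) > 0):
            raise InvalidInputError("breakpoints must be strictly increasing")
        self.breakpoints = bp
        self.values = va

    @classmethod
    def from_jumps(cls, positions: np.ndarray, jumps: np.ndarray) -> "StepFunction":
        """Build from jump locations; equal positions are merged exactly."""
        positions = np.asarray(positions, dtype=float)
        jumps = np.asarray(jumps, dtype=float)
        order = np.argsort(positions, kind="stable")
        pos, jmp = positions[order], jumps[order]
        uniq, inverse = np.unique(pos, return_inverse=True)
        agg = np.zeros(len(uniq))
        np.add.at(agg, inverse, jmp)
        keep = agg != 0
        # zero net jumps are dropped; cumulative values are exact integers
        uniq, agg = uniq[keep], agg[keep]
        vals = np.cumsum(agg)
        nz = vals != np.concatenate([[0.0], vals[:-1]])
        return cls(uniq[nz], vals[nz])

    def __call__(self, t: float | np.ndarray) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        if len(self.breakpoints) == 0:
            out = np.zeros(t.shape)
            return out if out.ndim else 0.0
        idx = np.searchsorted(self.breakpoints, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 0.0)
        return out if out.ndim else float(out)

    def _merged(self, other: "StepFunction") -> np.ndarray:
        return np.unique(np.concatenate([self.breakpoints, other.breakpoints]))

    def _combine(self, other: "StepFunction", sign: float) -> "StepFunction":
        grid = self._merged(other)
        vals = np.asarray(self(grid)) + sign * np.asarray(other(grid))
        # keep a grid point only where the value actually changes
        prev = np.concatenate([[0.0], vals[:-1]])
        mask = vals != prev
        return StepFunction(grid[mask], vals[mask])

    def __add__(self, other: "StepFunction") -> "StepFunction":
        return self._combine(other, +1.0)

    def __sub__(self, other: "StepFunction") -> "StepFunction":
        return self._combine(other, -1.0)

    def l1_distance(self, other: "StepFunction", lo: float, hi: float) -> float:
        """Exact integral of |self - other| over [lo, hi] by breakpoint merge."""
        grid = np.unique(np.concatenate([[lo, hi], np.clip(self._merged(other), lo, hi)]))
        left = grid[:-1]
        diff = np.asarray(self(left)) - np.asarray(other(left))
        return float(np.abs(diff) @ np.diff(grid))

    def integral(self, lo: float, hi: float) -> float:
        grid = np.unique(np.concatenate([[lo, hi], np.clip(self.breakpoints, lo, hi)]))
        left = grid[:-1]
        return float(np.asarray(self(left)) @ np.diff(grid))

    def terminal_value(self) -> float:
        return float(self.values[-1]) if len(self.values) else 0.0


class PiecewiseLinear:
    """Continuous piecewise-linear function given by knots and values."""

    __slots__ = ("knots", "values")

    def __init__(self, knots: Sequence[float], values: Sequence[float]):
        k = np.asarray(knots, dtype=float)
        v = np.asarray(values, dtype=float)
        if len(k) < 2 or len(k) != len(v) or not np.all(np.diff(k) > 0):
            raise InvalidInputError("invalid piecewise-linear data")
        self.knots = k
        self.values = v

    def __call__(self, t: float | np.ndarray) -> np.ndarray | float:
        out = np.interp(np.asarray(t, dtype=float), self.knots, self.values)
        return out if out.ndim else float(out)

    def l1_distance(self, other: "PiecewiseLinear") -> float:
        """Exact integral of the absolute difference over the common span."""
        lo = max(self.knots[0], other.knots[0])
        hi = min(self.knots[-1], other.knots[-1])
        grid = np.unique(np.clip(np.concatenate([self.knots, other.knots]), lo, hi))
        d = np.asarray(self(grid)) - np.asarray(other(grid))
        total = 0.0
        for i in range(len(grid) - 1):
            w = grid[i + 1] - grid[i]
            y0, y1 = d[i], d[i + 1]
            if y0 * y1 >= 0:
                total += 0.5 * abs(y0 + y1) * w
            else:
                total += 0.5 * w * (y0 * y0 + y1 * y1) / (abs(y0) + abs(y1))
        return float(total)

    def l1_norm(self) -> float:
        zero = PiecewiseLinear(self.knots[[0, -1]], [0.0, 0.0])
        return self.l1_distance(zero)


@dataclass(frozen=True)
class CompatibleSubset:
    """A finite vertex set on a complex with its induced sub-edge multiset.

    Contains every 0-cell plus at least one interior point per 1-cell, so
    that removing it leaves disjoint open arcs; ``edges`` lists the index
    pairs of consecutive points along each original edge, with
    multiplicity, and ``sub_lengths`` the image arc length of each open
    arc.  The subset is epsilon-dense when every sub-length is < epsilon.
    """

    points: np.ndarray                       # coordinates, one row per sample
    edges: Tuple[Tuple[int, int], ...]       # unordered index pairs, multiset
    sub_lengths: np.ndarray                  # arc length per sub-edge
    vertex_index: Dict[str, int]             # 0-cell id -> row index
    locations: Tuple[Tuple[str, float], ...]  # (edge_id, param) per interior point

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def epsilon_dense(self) -> float:
        """The smallest epsilon for which this subset is epsilon-dense."""
        return float(self.sub_lengths.max()) if len(self.sub_lengths) else 0.0

    def degrees(self) -> np.ndarray:
        c = np.zeros(self.n_points, dtype=int)
        for i, j in self.edges:
            c[i] += 1
            c[j] += 1
        return c

    def euler_characteristic(self) -> int:
        return self.n_points - len(self.edges)


def build_compatible_subset(X: EmbeddedComplex, eps: float) -> CompatibleSubset:
    """Equal-arc-length subdivision of every edge into sub-arcs of length < eps.

    Each edge is split into k = max(ceil(L/eps), 2) pieces (k increased
    until L/k < eps), guaranteeing at least one interior point per edge.
    """
    if eps <= 0:
        raise InvalidInputError("eps must be positive")
    vertex_index: Dict[str, int] = {}
    points: List[np.ndarray] = []
    for vid in X.structure.vertex_ids:
        vertex_index[vid] = len(points)
        points.append(X.vertex_coords[vid])
    edges: List[Tuple[int, int]] = []
    sub_lengths: List[float] = []
    locations: List[Tuple[str, float]] = []
    for eid, u, v in X.structure.edges:
        curve = X.curves[eid]
        s = cumulative_arc_length(curve.points)
        L = s[-1]
        k = max(int(np.ceil(L / eps)), 2)
        while L / k >= eps:
            k += 1
        s_targets = L * np.arange(1, k) / k
        t_interior = curve_param_at_arclength(curve, s_targets)
        interior = curve_points_at_params(curve, t_interior)
        idx_chain = [vertex_index[u]]
        for t_par, pt in zip(t_interior, interior):
            idx_chain.append(len(points))
            points.append(pt)
            locations.append((eid, float(t_par)))
        idx_chain.append(vertex_index[v])
        for a, b in zip(idx_chain[:-1], idx_chain[1:]):
            edges.append((a, b))
        sub_lengths.extend([L / k] * k)
    return CompatibleSubset(
        points=np.vstack(points),
        edges=tuple(edges),
        sub_lengths=np.asarray(sub_lengths),
        vertex_index=dict(vertex_index),
        locations=tuple(locations),
    )


def _ecc_from_projections(proj: np.ndarray, edge_max: np.ndarray) -> StepFunction:
    positions = np.concatenate([proj, edge_max])
    jumps = np.concatenate([np.ones(len(proj)), -np.ones(len(edge_max))])
    return StepFunction.from_jumps(positions, jumps)


def pl_ect(A: CompatibleSubset, v: Sequence[float], coords: np.ndarray | None = None) -> StepFunction:
    """Exact ECC of the chord interpolation on A in direction v.

    Counts vertices below the level minus fully submerged chords; the
    projection of a chord is affine, so a chord is below level t exactly
    when both endpoints are, making the count exact for the PL shape.
    """
    pts = A.points if coords is None else np.asarray(coords, dtype=float)
    if len(pts) != A.n_points:
        raise InvalidInputError("coords inconsistent with the subset")
    v = np.asarray(v, dtype=float)
    proj = pts @ v
    if A.edges:
        e = np.asarray(A.edges)
        edge_max = np.maximum(proj[e[:, 0]], proj[e[:, 1]])
    else:
        edge_max = np.empty(0)
    return _ecc_from_projections(proj, edge_max)


def polyline_ecc(points: np.ndarray, v: Sequence[float], closed: bool = False) -> StepFunction:
    """ECC of a polyline (its own samples as the compatible subset)."""
    points = np.asarray(points, dtype=float)
    v = np.asarray(v, dtype=float)
    if closed:
        # a closed chain stored with a duplicated endpoint sheds the copy
        if np.allclose(points[0], points[-1]):
            points = points[:-1]
        proj = points @ v
        edge_max = np.maximum(proj, np.roll(proj, -1))
    else:
        proj = points @ v
        edge_max = np.maximum(proj[:-1], proj[1:])
    return _ecc_from_projections(proj, edge_max)


@dataclass(frozen=True)
class ECTField:
    """ECCs for a shared direction set, supported inside [-a, a]."""

    directions: DirectionSet
    curves: Tuple[StepFunction, ...]
    a: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise BoundViolationError("bounding radius must be positive")
        if len(self.curves) != len(self.directions):
            raise InvalidInputError("one step function per direction required")

    def rebounded(self, a_new: float) -> "ECTField":
        if a_new < self.a:
            raise BoundViolationError("cannot shrink the bounding radius")
        return ECTField(self.directions, self.curves, a_new)


@dataclass(frozen=True)
class SECTField:
    """Integrated mean-centred ECCs; piecewise linear, vanishing at +-a."""

    directions: DirectionSet
    curves: Tuple[PiecewiseLinear, ...]
    a: float


def ect_field(
    X: EmbeddedComplex,
    eps: float,
    directions: DirectionSet,
    a: float | None = None,
) -> ECTField:
    """PL ECT of X on its eps-dense compatible subset, for every direction."""
    subset = build_compatible_subset(X, eps)
    return ect_field_of_subset(subset, directions, a)


def ect_field_of_subset(
    subset: CompatibleSubset,
    directions: DirectionSet,
    a: float | None = None,
) -> ECTField:
    max_norm = float(np.linalg.norm(subset.points, axis=1).max())
    if a is None:
        a = 1.05 * max_norm if max_norm > 0 else 1.0
    elif a < max_norm:
        raise BoundViolationError(f"a={a} is smaller than the shape radius {max_norm}")
    proj_all = subset.points @ directions.vectors.T  # (n_points, n_dirs)
    e = np.asarray(subset.edges) if subset.edges else None
    curves = []
    for j in range(len(directions)):
        proj = proj_all[:, j]
        if e is not None:
            edge_max = np.maximum(proj[e[:, 0]], proj[e[:, 1]])
        else:
            edge_max = np.empty(0)
        curves.append(_ecc_from_projections(proj, edge_max))
    return ECTField(directions, tuple(curves), float(a))


def ect_field_of_polylines(
    X: EmbeddedComplex,
    directions: DirectionSet,
    a: float | None = None,
) -> ECTField:
    """PL ECT using every stored sample point of X as the compatible subset."""
    vertex_index: Dict[str, int] = {}
    points: List[np.ndarray] = []
    for vid in X.structure.vertex_ids:
        vertex_index[vid] = len(points)
        points.append(X.vertex_coords[vid])
    edges: List[Tuple[int, int]] = []
    sub_lengths: List[float] = []
    locations: List[Tuple[str, float]] = []
    for eid, u, v in X.structure.edges:
        c = X.curves[eid]
        idx_chain = [vertex_index[u]]
        for t_par, pt in zip(c.params[1:-1], c.points[1:-1]):
            idx_chain.append(len(points))
            points.append(pt)
            locations.append((eid, float(t_par)))
        idx_chain.append(vertex_index[v])
        seg = np.linalg.norm(np.diff(c.points, axis=0), axis=1)
        for (i1, i2), s in zip(zip(idx_chain[:-1], idx_chain[1:]), seg):
            edges.append((i1, i2))
            sub_lengths.append(float(s))
    subset = CompatibleSubset(
        points=np.vstack(points),
        edges=tuple(edges),
        sub_lengths=np.asarray(sub_lengths),
        vertex_index=vertex_index,
        locations=tuple(locations),
    )
    return ect_field_of_subset(subset, directions, a)


def _common_bound(E1: ECTField, E2: ECTField) -> float:
    return max(E1.a, E2.a)


def _check_directions(d1: DirectionSet, d2: DirectionSet) -> None:
    if d1.vectors.shape != d2.vectors.shape or not np.allclose(
        d1.vectors, d2.vectors, atol=1e-12
    ):
        raise FieldMismatchError("direction sets differ")


def ect_distance(E1: ECTField, E2: ECTField) -> float:
    """Max over the direction grid of the exact L1 distance of ECC pairs.

    A finite grid under-estimates the supremum over the whole sphere.
    """
    _check_directions(E1.directions, E2.directions)
    a = _common_bound(E1, E2)
    return max(
        c1.l1_distance(c2, -a, a) for c1, c2 in zip(E1.curves, E2.curves)
    )


def sect_from_ect(E: ECTField) -> SECTField:
    """Exact integration of each mean-centred ECC over [-a, a]."""
    a = E.a
    curves = []
    for ecc in E.curves:
        knots = np.unique(np.concatenate([[-a, a], np.clip(ecc.breakpoints, -a, a)]))
        left_vals = np.asarray(ecc(knots[:-1]))
        widths = np.diff(knots)
        mean = float(left_vals @ widths) / (2.0 * a)
        increments = (left_vals - mean) * widths
        vals = np.concatenate([[0.0], np.cumsum(increments)])
        curves.append(PiecewiseLinear(knots, vals))
    return SECTField(E.directions, tuple(curves), a)


def sect_distance(S1: SECTField, S2: SECTField) -> float:
    """Max over directions of the exact L1 distance of the PL functions."""
    _check_directions(S1.directions, S2.directions)
    return max(c1.l1_distance(c2) for c1, c2 in zip(S1.curves, S2.curves))


def sect_norm(S: SECTField) -> float:
    return max(c.l1_norm() for c in S.curves)


def glue_check(
    E_V: StepFunction,
    E_W: StepFunction,
    E_S: StepFunction,
    E_Z: StepFunction,
    tol: float = 1e-9,
) -> bool:
    """Whether ECC_Z = ECC_V + ECC_W - ECC_S away from a negligible set.

    Almost-everywhere equality of step functions means equality off a set
    of measure zero; numerically, the combined step function
    V + W - S - Z may carry cancelling jumps at float-adjacent
    breakpoints, so the support of the difference is required to have
    total length below ``tol`` (and the difference must vanish
    eventually).
    """
    diff = (E_V + E_W) - (E_S + E_Z)
    if len(diff.breakpoints) == 0:
        return True
    if diff.terminal_value() != 0:
        return False
    widths = np.diff(diff.breakpoints)
    support = float(widths[diff.values[:-1] != 0].sum())
    return support < tol
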
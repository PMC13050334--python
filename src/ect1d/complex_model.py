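"""Embedded one-dimensional CW complexes and their differential geometry.

A shape here is a topological graph (vertices = 0-cells, edges = 1-cells,
loops and parallel edges allowed) together with an embedding into
Euclidean space: one coordinate per vertex and one densely sampled
parametrised curve per edge.  All smooth curves are represented by finite
sample chains; quantities such as arc length, curvature and variation are
the corresponding polygonal estimates, which converge as the sampling is
refined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "CWStructure",
    "SampledCurve",
    "EmbeddedComplex",
    "InvalidInputError",
    "DegenerateCurveError",
    "StructureMismatchError",
    "arc_length",
    "cumulative_arc_length",
    "reparam_constant_velocity",
    "curvature_max",
    "directional_variation",
    "hausdorff_distance",
    "cw_distance_upper",
]


class InvalidInputError(ValueError):
    """An argument violates a documented precondition."""


class DegenerateCurveError(InvalidInputError):
    """The curve has zero length where positive length is required."""


class StructureMismatchError(InvalidInputError):
    """Two complexes do not share a compatible CW structure."""


@dataclass(frozen=True)
class CWStructure:
    """Combinatorial part of a finite 1-D CW complex.

    ``edges`` is a multiset of ``(edge_id, u, v)`` triples; ``u == v``
    encodes a loop.  Edge ids and vertex ids must each be unique.
    """

    vertex_ids: Tuple[str, ...]
    edges: Tuple[Tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        if len(set(self.vertex_ids)) != len(self.vertex_ids):
            raise InvalidInputError("duplicate vertex ids")
        edge_ids = [e[0] for e in self.edges]
        if len(set(edge_ids)) != len(edge_ids):
            raise InvalidInputError("duplicate edge ids")
        vs = set(self.vertex_ids)
        for eid, u, v in self.edges:
            if u not in vs or v not in vs:
                raise InvalidInputError(
                    f"edge {eid!r} references unknown vertex {u!r} or {v!r}"
                )

    @property
    def euler_characteristic(self) -> int:
        return len(self.vertex_ids) - len(self.edges)


@dataclass(frozen=True)
class SampledCurve:
    """A parametrised curve stored as samples on a grid in [0, 1].

    ``params`` is strictly increasing with endpoints 0 and 1; ``points``
    holds one d-dimensional coordinate per parameter.
    """

    params: np.ndarray
    points: np.ndarray

    def __post_init__(self) -> None:
        params = np.asarray(self.params, dtype=float)
        points = np.asarray(self.points, dtype=float)
        if points.ndim == 1:
            points = points[:, None]
        object.__setattr__(self, "params", params)
        object.__setattr__(self, "points", points)
        if params.ndim != 1 or len(params) < 3:
            raise InvalidInputError("need at least 3 samples")
        if len(params) != len(points):
            raise InvalidInputError("params and points length mismatch")
        if not np.all(np.diff(params) > 0):
            raise InvalidInputError("params must be strictly increasing")
        if abs(params[0]) > 0 or abs(params[-1] - 1) > 0:
            raise InvalidInputError("params must start at 0 and end at 1")
        if not np.all(np.isfinite(points)):
            raise InvalidInputError("non-finite coordinates")

    @property
    def dimension(self) -> int:
        return self.points.shape[1]

    @property
    def n_samples(self) -> int:
        return len(self.params)

    def reversed(self) -> "SampledCurve":
        return SampledCurve(1.0 - self.params[::-1], self.points[::-1].copy())


@dataclass(frozen=True)
class EmbeddedComplex:
    """A CW structure plus an embedding of every cell."""

    structure: CWStructure
    vertex_coords: Dict[str, np.ndarray]
    curves: Dict[str, SampledCurve]
    endpoint_tol: float = 1e-9

    def __post_init__(self) -> None:
        coords = {k: np.asarray(v, dtype=float) for k, v in self.vertex_coords.items()}
        object.__setattr__(self, "vertex_coords", coords)
        dims = {c.dimension for c in self.curves.values()}
        dims |= {v.shape[0] for v in coords.values()}
        if len(dims) > 1:
            raise InvalidInputError(f"mixed ambient dimensions {sorted(dims)}")
        for eid, u, v in self.structure.edges:
            if eid not in self.curves:
                raise InvalidInputError(f"missing curve for edge {eid!r}")
            c = self.curves[eid]
            du = np.linalg.norm(c.points[0] - coords[u])
            dv = np.linalg.norm(c.points[-1] - coords[v])
            if du > self.endpoint_tol or dv > self.endpoint_tol:
                raise InvalidInputError(
                    f"curve of edge {eid!r} does not match its endpoints "
                    f"(|start-u|={du:.3g}, |end-v|={dv:.3g})"
                )

    @property
    def dimension(self) -> int:
        if self.curves:
            return next(iter(self.curves.values())).dimension
        return next(iter(self.vertex_coords.values())).shape[0]

    def all_points(self) -> np.ndarray:
        """Stack every stored sample point and vertex coordinate."""
        blocks = [c.points for c in self.curves.values()]
        blocks += [v[None, :] for v in self.vertex_coords.values()]
        return np.vstack(blocks)

    def max_norm(self) -> float:
        return float(np.linalg.norm(self.all_points(), axis=1).max())

    def total_length(self) -> float:
        return float(sum(arc_length(c) for c in self.curves.values()))

    def translated(self, shift: Sequence[float]) -> "EmbeddedComplex":
        s = np.asarray(shift, dtype=float)
        return EmbeddedComplex(
            self.structure,
            {k: v + s for k, v in self.vertex_coords.items()},
            {k: SampledCurve(c.params, c.points + s) for k, c in self.curves.items()},
            self.endpoint_tol,
        )

    def rotated(self, rotation: np.ndarray) -> "EmbeddedComplex":
        R = np.asarray(rotation, dtype=float)
        return EmbeddedComplex(
            self.structure,
            {k: R @ v for k, v in self.vertex_coords.items()},
            {k: SampledCurve(c.params, c.points @ R.T) for k, c in self.curves.items()},
            self.endpoint_tol,
        )


def arc_length(curve: SampledCurve) -> float:
    """Polygonal length of the sample chain, sum of ||p_{i+1} - p_i||."""
    if curve.n_samples < 2:
        raise InvalidInputError("need at least 2 points for a length")
    return float(np.linalg.norm(np.diff(curve.points, axis=0), axis=1).sum())


def cumulative_arc_length(points: np.ndarray) -> np.ndarray:
    """Cumulative chord length along a point chain, starting at 0."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _interp_at_arclength(points: np.ndarray, s_targets: np.ndarray) -> np.ndarray:
    """Points on the polyline at prescribed cumulative arc lengths."""
    s = cumulative_arc_length(points)
    out = np.empty((len(s_targets), points.shape[1]))
    for j in range(points.shape[1]):
        out[:, j] = np.interp(s_targets, s, points[:, j])
    return out


def reparam_constant_velocity(curve: SampledCurve, n_out: int) -> SampledCurve:
    """Resample a curve at equal arc-length spacing on a uniform grid.

    The image polyline is unchanged up to resampling; output parameters
    are uniform in [0, 1] so the discrete speed is constant.
    """
    if n_out < 3:
        raise InvalidInputError("n_out must be at least 3")
    L = arc_length(curve)
    if L <= 0:
        raise DegenerateCurveError("cannot reparametrise a zero-length curve")
    s_targets = np.linspace(0.0, L, n_out)
    pts = _interp_at_arclength(curve.points, s_targets)
    pts[0] = curve.points[0]
    pts[-1] = curve.points[-1]
    return SampledCurve(np.linspace(0.0, 1.0, n_out), pts)


def curve_param_at_arclength(curve: SampledCurve, s_targets: np.ndarray) -> np.ndarray:
    """Invert the chord-length function: parameters at given arc lengths."""
    s = cumulative_arc_length(curve.points)
    return np.interp(np.asarray(s_targets, dtype=float), s, curve.params)


def curve_points_at_params(curve: SampledCurve, t: np.ndarray) -> np.ndarray:
    """Linear interpolation of the sample chain at arbitrary parameters."""
    t = np.asarray(t, dtype=float)
    out = np.empty((len(t), curve.dimension))
    for j in range(curve.dimension):
        out[:, j] = np.interp(t, curve.params, curve.points[:, j])
    return out


def curvature_max(curve: SampledCurve, n_min: int = 200) -> float:
    """Maximum curvature estimate of the arc-length parametrisation.

    The curve is resampled at constant speed and kappa = ||alpha''|| is
    estimated by second-order central differences of the resampled chain;
    an estimate of the curvature bound M.  The finite-difference spacing
    is kept at least four input samples wide so that the O(spacing^2)
    interpolation wiggle of the resampling does not dominate the second
    difference.
    """
    if curve.n_samples < 5:
        raise InvalidInputError("need at least 5 samples for curvature")
    n = max(min(n_min, curve.n_samples), curve.n_samples // 4, 5)
    uni = reparam_constant_velocity(curve, n)
    L = arc_length(curve)
    h = L / (n - 1)
    p = uni.points
    second = (p[:-2] - 2.0 * p[1:-1] + p[2:]) / h**2
    return float(np.linalg.norm(second, axis=1).max())


def directional_variation(curve: SampledCurve, v: Sequence[float]) -> float:
    """Discrete total variation of the projection <v, curve> along the chain."""
    v = np.asarray(v, dtype=float)
    if abs(np.linalg.norm(v) - 1.0) > 1e-9:
        raise InvalidInputError("direction must be a unit vector")
    proj = curve.points @ v
    return float(np.abs(np.diff(proj)).sum())


def hausdorff_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two finite point sets."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if len(A) == 0 or len(B) == 0:
        raise InvalidInputError("point sets must be nonempty")
    d_ab = cKDTree(B).query(A)[0].max()
    d_ba = cKDTree(A).query(B)[0].max()
    return float(max(d_ab, d_ba))


def cw_distance_upper(
    X: EmbeddedComplex,
    Y: EmbeddedComplex,
    correspondence: Dict[str, str] | None = None,
    n_grid: int = 512,
) -> float:
    """Upper estimate of the embedding metric between two complexes.

    Every paired edge is reparametrised to constant velocity on a common
    grid; the result is max(sup-norm of pointwise differences, max
    arc-length difference), minimised over the two orientations of each
    pairing.  The true metric is an infimum over all homeomorphism pairs
    and is not computed; this fixes the caller-supplied correspondence
    (identity by default) and therefore over-estimates.
    """
    if X.dimension != Y.dimension:
        raise StructureMismatchError("ambient dimensions differ")
    if correspondence is None:
        ids_x = {e[0] for e in X.structure.edges}
        ids_y = {e[0] for e in Y.structure.edges}
        if ids_x != ids_y:
            raise StructureMismatchError("edge id sets differ; supply a correspondence")
        correspondence = {eid: eid for eid in ids_x}
    if len(X.structure.edges) != len(Y.structure.edges):
        raise StructureMismatchError("edge counts differ")

    worst = 0.0
    for ex, ey in correspondence.items():
        cx = reparam_constant_velocity(X.curves[ex], n_grid)
        cy = Y.curves[ey]
        len_diff = abs(arc_length(X.curves[ex]) - arc_length(cy))
        best_sup = np.inf
        for cand in (cy, cy.reversed()):
            cu = reparam_constant_velocity(cand, n_grid)
            sup = np.linalg.norm(cx.points - cu.points, axis=1).max()
            best_sup = min(best_sup, float(sup))
        worst = max(worst, best_sup, len_diff)
    # vertices with no incident edge still contribute through their coordinates
    for vid, coord in X.vertex_coords.items():
        if vid in Y.vertex_coords and not any(
            vid in (u, v) for _, u, v in X.structure.edges
        ):
            worst = max(worst, float(np.linalg.norm(coord - Y.vertex_coords[vid])))
    return worst


def single_curve_complex(curve: SampledCurve, closed: bool | None = None) -> EmbeddedComplex:
    """Wrap one sampled curve as a complex: a loop if closed, else one edge."""
    if closed is None:
        closed = bool(np.linalg.norm(curve.points[0] - curve.points[-1]) <= 1e-9)
    if closed:
        structure = CWStructure(("v0",), (("e0", "v0", "v0"),))
        coords = {"v0": curve.points[0]}
    else:
        structure = CWStructure(("v0", "v1"), (("e0", "v0", "v1"),))
        coords = {"v0": curve.points[0], "v1": curve.points[-1]}
    return EmbeddedComplex(structure, coords, {"e0": curve})
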
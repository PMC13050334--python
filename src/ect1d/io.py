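"""Interchange formats: complex JSON, point-list CSV, ECT/SECT CSV.

Complex JSON schema::

    {"dimension": d,
     "vertices": {"id": [coords], ...},
     "edges": [{"id": ..., "u": ..., "v": ...,
                "params": [...], "points": [[...], ...]}, ...]}

Point-list CSV: one row per point, columns x1..xd, optional "param".
ECT CSV: direction_index, angle (d = 2) or components, breakpoint, value.
SECT CSV: direction_index, knot, value.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from .complex_model import CWStructure, EmbeddedComplex, SampledCurve
from .ect_core import (
    DirectionSet,
    ECTField,
    PiecewiseLinear,
    SECTField,
    StepFunction,
)

__all__ = [
    "ComplexParseError",
    "read_complex",
    "write_complex",
    "read_point_csv",
    "write_point_csv",
    "write_ect_csv",
    "read_ect_csv",
    "write_sect_csv",
    "read_sect_csv",
]


class ComplexParseError(ValueError):
    """A document violates the complex interchange schema.

    The message carries a JSON-pointer-style location of the offence.
    """


def _require(doc: dict, key: str, where: str):
    if key not in doc:
        raise ComplexParseError(f"{where}/{key}: missing required field")
    return doc[key]


def read_complex(path: str | Path) -> EmbeddedComplex:
    with open(path) as fh:
        doc = json.load(fh)
    return complex_from_dict(doc)


def complex_from_dict(doc: dict) -> EmbeddedComplex:
    dim = int(_require(doc, "dimension", ""))
    vertices = _require(doc, "vertices", "")
    edges_doc = _require(doc, "edges", "")
    vertex_coords: Dict[str, np.ndarray] = {}
    for vid, coords in vertices.items():
        arr = np.asarray(coords, float)
        if arr.shape != (dim,):
            raise ComplexParseError(f"/vertices/{vid}: expected {dim} coordinates")
        vertex_coords[vid] = arr
    edge_triples = []
    curves: Dict[str, SampledCurve] = {}
    for i, e in enumerate(edges_doc):
        where = f"/edges/{i}"
        eid = str(_require(e, "id", where))
        u = str(_require(e, "u", where))
        v = str(_require(e, "v", where))
        for vid in (u, v):
            if vid not in vertex_coords:
                raise ComplexParseError(
                    f"{where}: edge {eid!r} references unknown vertex {vid!r}"
                )
        params = np.asarray(_require(e, "params", where), float)
        points = np.asarray(_require(e, "points", where), float)
        if points.ndim != 2 or points.shape[1] != dim:
            raise ComplexParseError(f"{where}/points: expected shape (n, {dim})")
        edge_triples.append((eid, u, v))
        try:
            curves[eid] = SampledCurve(params, points)
        except ValueError as err:
            raise ComplexParseError(f"{where}: {err}") from err
    structure = CWStructure(tuple(vertex_coords.keys()), tuple(edge_triples))
    try:
        return EmbeddedComplex(structure, vertex_coords, curves)
    except ValueError as err:
        raise ComplexParseError(f"/: {err}") from err


def complex_to_dict(X: EmbeddedComplex) -> dict:
    return {
        "dimension": X.dimension,
        "vertices": {vid: coords.tolist() for vid, coords in X.vertex_coords.items()},
        "edges": [
            {
                "id": eid,
                "u": u,
                "v": v,
                "params": X.curves[eid].params.tolist(),
                "points": X.curves[eid].points.tolist(),
            }
            for eid, u, v in X.structure.edges
        ],
    }


def write_complex(X: EmbeddedComplex, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(complex_to_dict(X), fh)
        fh.write("\n")


def read_point_csv(path: str | Path) -> SampledCurve:
    df = pd.read_csv(path)
    coord_cols = [c for c in df.columns if c.startswith("x")]
    if not coord_cols:
        raise ComplexParseError("/: no coordinate columns x1..xd found")
    points = df[coord_cols].to_numpy(float)
    if "param" in df.columns:
        params = df["param"].to_numpy(float)
    else:
        params = np.linspace(0.0, 1.0, len(df))
    return SampledCurve(params, points)


def write_point_csv(curve: SampledCurve, path: str | Path) -> None:
    cols = {f"x{j + 1}": curve.points[:, j] for j in range(curve.dimension)}
    cols["param"] = curve.params
    pd.DataFrame(cols).to_csv(path, index=False)


def _direction_frame(directions: DirectionSet) -> pd.DataFrame:
    if directions.dimension == 2:
        angles = np.arctan2(directions.vectors[:, 1], directions.vectors[:, 0])
        return pd.DataFrame(
            {"direction_index": np.arange(len(directions)), "angle": angles}
        )
    cols = {
        f"v{j + 1}": directions.vectors[:, j] for j in range(directions.dimension)
    }
    return pd.DataFrame({"direction_index": np.arange(len(directions)), **cols})


def write_ect_csv(field: ECTField, path: str | Path) -> None:
    dirs = _direction_frame(field.directions)
    rows: List[dict] = []
    for idx, step in enumerate(field.curves):
        meta = dirs.iloc[idx].to_dict()
        for bp, val in zip(step.breakpoints, step.values):
            rows.append({**meta, "breakpoint": bp, "value": val})
    out = pd.DataFrame(rows)
    out.attrs["a"] = field.a
    out.insert(0, "a", field.a)
    out.to_csv(path, index=False)


def read_ect_csv(path: str | Path) -> ECTField:
    df = pd.read_csv(path)
    a = float(df["a"].iloc[0])
    if "angle" in df.columns:
        meta = df.drop_duplicates("direction_index").sort_values("direction_index")
        vecs = np.column_stack([np.cos(meta["angle"]), np.sin(meta["angle"])])
    else:
        vcols = sorted(c for c in df.columns if c.startswith("v"))
        meta = df.drop_duplicates("direction_index").sort_values("direction_index")
        vecs = meta[vcols].to_numpy(float)
    directions = DirectionSet(vecs)
    curves = []
    for idx in range(len(directions)):
        sub = df[df["direction_index"] == idx].sort_values("breakpoint")
        curves.append(StepFunction(sub["breakpoint"].to_numpy(), sub["value"].to_numpy()))
    return ECTField(directions, tuple(curves), a)


def write_sect_csv(field: SECTField, path: str | Path) -> None:
    dirs = _direction_frame(field.directions)
    rows: List[dict] = []
    for idx, pl in enumerate(field.curves):
        meta = dirs.iloc[idx].to_dict()
        for knot, val in zip(pl.knots, pl.values):
            rows.append({**meta, "knot": knot, "value": val})
    out = pd.DataFrame(rows)
    out.insert(0, "a", field.a)
    out.to_csv(path, index=False)


def read_sect_csv(path: str | Path) -> SECTField:
    df = pd.read_csv(path)
    a = float(df["a"].iloc[0])
    if "angle" in df.columns:
        meta = df.drop_duplicates("direction_index").sort_values("direction_index")
        vecs = np.column_stack([np.cos(meta["angle"]), np.sin(meta["angle"])])
    else:
        vcols = sorted(c for c in df.columns if c.startswith("v"))
        meta = df.drop_duplicates("direction_index").sort_values("direction_index")
        vecs = meta[vcols].to_numpy(float)
    directions = DirectionSet(vecs)
    curves = []
    for idx in range(len(directions)):
        sub = df[df["direction_index"] == idx].sort_values("knot")
        curves.append(PiecewiseLinear(sub["knot"].to_numpy(), sub["value"].to_numpy()))
    return SECTField(directions, tuple(curves), a)
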
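"""Deterministic generators for the test shapes.

Circles, segments, closed curves built from complex Fourier coefficients,
and the line/high-frequency-wave pair that exhibits the curvature
instability of the ECT (two curves at Hausdorff distance eps whose ECTs
stay at distance >= 1 once the wave completes ceil(1/eps) oscillations).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .complex_model import (
    CWStructure,
    EmbeddedComplex,
    InvalidInputError,
    SampledCurve,
    single_curve_complex,
)
from .ect_core import BoundViolationError, DirectionSet, ECTField, StepFunction

__all__ = [
    "FourierSpec",
    "make_circle",
    "make_segment",
    "make_wave_and_line",
    "make_fourier_curve",
    "random_fourier_spec",
    "default_fourier_spec",
    "analytic_circle_ect",
]


@dataclass(frozen=True)
class FourierSpec:
    """Complex Fourier coefficients c_k for a closed planar curve.

    The curve is t -> sum_k c_k e^{ikt} on [0, 2*pi], read as x + iy; it
    is closed by construction.
    """

    coefficients: dict  # k -> complex
    n_samples: int = 512
    seed: int | None = None

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        z = np.zeros(len(t), dtype=complex)
        for k, c in self.coefficients.items():
            z += complex(c) * np.exp(1j * k * np.asarray(t, float))
        return np.column_stack([z.real, z.imag])


def make_circle(r: float, n: int) -> EmbeddedComplex:
    """Unit-vertex loop sampled at n uniform angles on a circle of radius r."""
    if r <= 0 or n < 8:
        raise InvalidInputError("need r > 0 and n >= 8")
    t = np.linspace(0.0, 1.0, n)
    theta = 2.0 * np.pi * t
    pts = r * np.column_stack([np.cos(theta), np.sin(theta)])
    pts[-1] = pts[0]
    return single_curve_complex(SampledCurve(t, pts), closed=True)


def make_segment(p0: Sequence[float], p1: Sequence[float], n: int = 2) -> EmbeddedComplex:
    """Straight segment between two points with n samples."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    n = max(n, 3)
    t = np.linspace(0.0, 1.0, n)
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    return single_curve_complex(SampledCurve(t, pts), closed=False)


def make_wave_and_line(
    eps: float, oscillations: int | None = None, n: int | None = None
) -> Tuple[EmbeddedComplex, EmbeddedComplex]:
    """The instability pair: a unit segment and a nearby high-frequency wave.

    The line runs from (0,0) to (1,0); the wave is x -> (x, eps * sin(2
    pi osc x)) with osc = ceil(1/eps) full oscillations by default, so the
    Hausdorff distance is eps while the vertical ECC distance is >= 1.
    """
    if not 0.0 < eps < 0.5:
        raise InvalidInputError("eps must lie in (0, 0.5)")
    osc = int(np.ceil(1.0 / eps)) if oscillations is None else int(oscillations)
    if osc < 1:
        raise InvalidInputError("need at least one oscillation")
    if n is None:
        n = max(40 * osc, 400)
    if n < 40 * osc:
        raise InvalidInputError("need at least 40 samples per oscillation")
    line = make_segment((0.0, 0.0), (1.0, 0.0), n=max(2, n // 10))
    t = np.linspace(0.0, 1.0, n)
    pts = np.column_stack([t, eps * np.sin(2.0 * np.pi * osc * t)])
    wave = single_curve_complex(SampledCurve(t, pts), closed=False)
    return wave, line


def make_fourier_curve(spec: FourierSpec) -> EmbeddedComplex:
    """Closed planar curve from a Fourier coefficient spec: one loop edge."""
    t_par = np.linspace(0.0, 1.0, spec.n_samples)
    pts = spec.evaluate(2.0 * np.pi * t_par)
    if np.linalg.norm(pts[0] - pts[-1]) > 1e-9:
        raise InvalidInputError("generator bug: curve failed to close")
    pts[-1] = pts[0]
    return single_curve_complex(SampledCurve(t_par, pts), closed=True)


def random_fourier_spec(
    seed: int,
    n_harmonics: int = 5,
    decay: float = 3.0,
    n_samples: int = 512,
) -> FourierSpec:
    """Seeded random closed curve: |c_k| ~ |k|^-decay around a unit circle.

    c_1 = 1 anchors the curve to a perturbed circle so the result stays a
    simple closed loop for the default decay.
    """
    rng = np.random.default_rng(seed)
    coeffs = {1: 1.0 + 0.0j}
    for k in range(2, n_harmonics + 1):
        for kk in (k, -k):
            mag = abs(kk) ** (-decay)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            coeffs[kk] = mag * np.exp(1j * phase)
    return FourierSpec(coefficients=coeffs, n_samples=n_samples, seed=seed)


def default_fourier_spec(n_samples: int = 512) -> FourierSpec:
    """The documented default closed test curve (seeded, 5 harmonics)."""
    return random_fourier_spec(seed=20260926, n_harmonics=5, n_samples=n_samples)


def analytic_circle_ect(r: float, directions: DirectionSet, a: float) -> ECTField:
    """Closed-form ECT of a circle of radius r centred at the origin.

    Every directional sublevel set is empty below -r, a contractible arc
    on [-r, r) and the full circle from r on, so each ECC is the step
    function 0, 1, 0 with breakpoints at -r and r.
    """
    if a <= r:
        raise BoundViolationError("bounding radius must exceed r")
    step = StepFunction([-r, r], [1.0, 0.0])
    return ECTField(directions, tuple(step for _ in range(len(directions))), a)
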
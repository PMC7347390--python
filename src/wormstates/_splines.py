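"""Quadratic B-spline bases used to compress body-angle and width profiles.

The posture pipeline represents the 1000 inter-point tangent angles of the
centerline with 14 quadratic B-spline coefficients, and each side's 1001
half-width samples with 30 coefficients.  Both use an open uniform knot
vector on [0, 1] and an ordinary least-squares fit (no smoothing penalty:
the low component count is the smoother).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.interpolate import BSpline

DEGREE = 2
N_ANGLE_COEFFS = 14
N_WIDTH_COEFFS = 30


def open_uniform_knots(n_coeffs: int, degree: int = DEGREE) -> np.ndarray:
    """Open uniform knot vector on [0, 1] yielding ``n_coeffs`` basis functions."""
    n_interior = n_coeffs - degree - 1
    if n_interior < 0:
        raise ValueError(f"need at least {degree + 1} coefficients, got {n_coeffs}")
    interior = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
    return np.concatenate(
        [np.zeros(degree + 1), interior, np.ones(degree + 1)]
    )


@lru_cache(maxsize=32)
def _design_matrix_cached(n_coeffs: int, n_samples: int, degree: int) -> np.ndarray:
    knots = open_uniform_knots(n_coeffs, degree)
    s = np.linspace(0.0, 1.0, n_samples)
    return BSpline.design_matrix(s, knots, degree, extrapolate=False).toarray()


def design_matrix(n_coeffs: int, n_samples: int, degree: int = DEGREE) -> np.ndarray:
    """Dense (n_samples, n_coeffs) B-spline design matrix on a uniform grid.

    Rows are evaluations of the basis at ``n_samples`` evenly spaced
    parameter values in [0, 1].  The basis is a partition of unity, so a
    constant shift of the coefficients shifts the reconstruction by the
    same constant; that is what makes mean-centering of coefficients
    well-defined.
    """
    return _design_matrix_cached(n_coeffs, n_samples, degree)


def fit_coeffs(samples: np.ndarray, n_coeffs: int, degree: int = DEGREE) -> np.ndarray:
    """Least-squares B-spline coefficients for one or more sampled profiles.

    ``samples`` is (n_samples,) or (n_profiles, n_samples); the fit is on a
    uniform parameter grid covering the full profile.
    """
    samples = np.asarray(samples, dtype=float)
    squeeze = samples.ndim == 1
    if squeeze:
        samples = samples[None, :]
    B = design_matrix(n_coeffs, samples.shape[1], degree)
    coeffs, *_ = np.linalg.lstsq(B, samples.T, rcond=None)
    out = coeffs.T
    return out[0] if squeeze else out


def evaluate(coeffs: np.ndarray, n_samples: int, degree: int = DEGREE) -> np.ndarray:
    """Reconstruct a profile of ``n_samples`` points from B-spline coefficients."""
    coeffs = np.asarray(coeffs, dtype=float)
    B = design_matrix(coeffs.shape[-1], n_samples, degree)
    return coeffs @ B.T
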
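"""The path-curve family: closed, symmetric 2D silhouette curves.

A path curve is governed by one shape factor ``lam`` (λ): λ = 1 gives a
circle, λ < 1 a vase shape (widest section above mid-height), λ > 1 a conical
shape (widest section below mid-height). Its width ``w`` and height ``h`` are
free scale parameters. With the normalizations used here the curve spans
heights (0, h) and reaches half-width w/2 at the parameter value t_max.

Parametrically, for t in [-20, 20]:

    a(t)   = 1 / (exp(-λ t) + (h/2) exp(t))
    x(t)   = ∓ w' a(t)                    (two mirror branches)
    y(t)   = a(t) exp(t) h² / 2
    t_max  = ln(2λ/h) / (λ + 1)
    w'     = w (exp(-λ t_max) + (h/2) exp(t_max)) / 2

so that a(t) peaks at t_max and x(t_max) = ∓ w/2. y(t) increases
monotonically from 0 to h and is an image-style coordinate: y = 0 is the TOP
tip of the silhouette and y = h the bottom tip (rows grow downward in mask
images). This orientation is what makes λ > 1 conical (widest section in the
lower canopy) and λ < 1 vase-shaped (widest section in the upper canopy);
physical height above the canopy base is h − y.
"""
from __future__ import annotations

import numpy as np

T_DOMAIN = (-20.0, 20.0)


def t_max(lam: float, h: float) -> float:
    """Parameter value where the curve reaches its maximum half-width."""
    if h <= 0:
        raise ValueError("path-curve height must be positive")
    if lam <= 0:
        raise ValueError("path-curve shape factor must be positive")
    return np.log(2.0 * lam / h) / (lam + 1.0)


def curve_xy(w: float, h: float, lam: float,
             n_samples: int = 1500) -> tuple[np.ndarray, np.ndarray]:
    """Sample one branch of the path curve.

    Returns ``(x_half, y)`` where ``x_half >= 0`` is the half-width at each
    sample and ``y`` runs from ~0 (top tip, image convention) to ~h (bottom
    tip). The full closed curve is the union of (+x_half, y) and (-x_half, y).
    """
    t = np.linspace(T_DOMAIN[0], T_DOMAIN[1], n_samples)
    return _branch(t, w, h, lam)


def _branch(t: np.ndarray, w: float, h: float, lam: float):
    tm = t_max(lam, h)
    denom_tm = np.exp(-lam * tm) + 0.5 * h * np.exp(tm)
    w_base = 0.5 * w * denom_tm
    a = 1.0 / (np.exp(-lam * t) + 0.5 * h * np.exp(t))
    x_half = w_base * a
    y = a * np.exp(t) * h * h / 2.0
    return x_half, y


def radius_at_height(y_query: np.ndarray, w: float, h: float, lam: float,
                     n_samples: int = 4000) -> np.ndarray:
    """Half-width of the curve at depths ``y_query`` below the top tip.

    ``y_query`` follows the curve's image convention (0 = top tip, h =
    bottom tip); physical height above the canopy base is h − y. y(t) is
    strictly monotone in t, so the radius profile is obtained by
    interpolating the sampled branch. Depths outside (0, h) return 0.
    """
    x_half, y = curve_xy(w, h, lam, n_samples)
    yq = np.asarray(y_query, dtype=float)
    r = np.interp(yq, y, x_half, left=0.0, right=0.0)
    r[(yq <= 0) | (yq >= h)] = 0.0
    return r


def revolution_volume(w: float, h: float, lam: float,
                      n_samples: int = 20000) -> float:
    """Volume of the solid of revolution of the curve about its axis.

    V = ∫ π r(y)² dy, evaluated by trapezoidal quadrature along the branch.
    """
    x_half, y = curve_xy(w, h, lam, n_samples)
    return float(np.trapezoid(np.pi * x_half**2, y))
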
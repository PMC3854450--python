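"""Moment-invariant shape descriptors: Hu (2D and 3D) and Zernike.

All moments are intensity-weighted (computed on the raw grey values, not a
binarised mask), so they summarise the intensity distribution of the object
neighbourhood relative to its centre of mass.
"""

from __future__ import annotations

from math import factorial
from typing import List, Tuple

import numpy as np

from .errors import ArgumentError, DegenerateInputError
from .volume import ImageVolume


# ---------------------------------------------------------------- 2D Hu ----

def _central_moments_2d(plane: np.ndarray, order: int = 3) -> np.ndarray:
    """mu[p, q] = sum (x - xbar)^p (y - ybar)^q I(x, y), p+q <= order."""
    plane = np.asarray(plane, dtype=float)
    total = plane.sum()
    if total <= 0:
        raise DegenerateInputError("zero total intensity")
    ys, xs = np.mgrid[0:plane.shape[0], 0:plane.shape[1]]
    xbar = (xs * plane).sum() / total
    ybar = (ys * plane).sum() / total
    dx = xs - xbar
    dy = ys - ybar
    mu = np.zeros((order + 1, order + 1))
    for p in range(order + 1):
        for q in range(order + 1 - p):
            mu[p, q] = (dx ** p * dy ** q * plane).sum()
    return mu


def hu_moments_2d(plane: np.ndarray) -> np.ndarray:
    """The 7 classical Hu invariants plus the extra skew invariant (8 values).

    Built from scale-normalised central moments
    eta_pq = mu_pq / mu_00^(1 + (p+q)/2); invariant to translation, scale
    and rotation.  The 8th value is the known additional third-order
    invariant

        I8 = eta11 [(eta30 + eta12)^2 - (eta03 + eta21)^2]
             - (eta20 - eta02)(eta30 + eta12)(eta03 + eta21)
    """
    mu = _central_moments_2d(plane)
    m00 = mu[0, 0]
    eta = np.zeros_like(mu)
    for p in range(4):
        for q in range(4 - p):
            if p + q >= 2:
                eta[p, q] = mu[p, q] / m00 ** (1 + (p + q) / 2.0)
    e20, e02, e11 = eta[2, 0], eta[0, 2], eta[1, 1]
    e30, e03, e21, e12 = eta[3, 0], eta[0, 3], eta[2, 1], eta[1, 2]
    a = e30 + e12   # third-order x-projection
    b = e21 + e03   # third-order y-projection
    phi = np.empty(8)
    phi[0] = e20 + e02
    phi[1] = (e20 - e02) ** 2 + 4 * e11 ** 2
    phi[2] = (e30 - 3 * e12) ** 2 + (3 * e21 - e03) ** 2
    phi[3] = a ** 2 + b ** 2
    phi[4] = (e30 - 3 * e12) * a * (a ** 2 - 3 * b ** 2) + \
             (3 * e21 - e03) * b * (3 * a ** 2 - b ** 2)
    phi[5] = (e20 - e02) * (a ** 2 - b ** 2) + 4 * e11 * a * b
    phi[6] = (3 * e21 - e03) * a * (a ** 2 - 3 * b ** 2) - \
             (e30 - 3 * e12) * b * (3 * a ** 2 - b ** 2)
    phi[7] = e11 * (a ** 2 - b ** 2) - (e20 - e02) * a * b
    return phi


# ---------------------------------------------------------------- 3D Hu ----

def _central_moments_3d(volume: np.ndarray, order: int = 3) -> dict:
    vol = np.asarray(volume, dtype=float)
    total = vol.sum()
    if total <= 0:
        raise DegenerateInputError("zero total intensity")
    zs, ys, xs = np.mgrid[0:vol.shape[0], 0:vol.shape[1], 0:vol.shape[2]]
    xbar = (xs * vol).sum() / total
    ybar = (ys * vol).sum() / total
    zbar = (zs * vol).sum() / total
    dx, dy, dz = xs - xbar, ys - ybar, zs - zbar
    mu = {}
    for p in range(order + 1):
        for q in range(order + 1 - p):
            for r in range(order + 1 - p - q):
                mu[(p, q, r)] = (dx ** p * dy ** q * dz ** r * vol).sum()
    return mu


def hu_moments_3d(volume: ImageVolume | np.ndarray) -> np.ndarray:
    """8 translation- and scale-normalised 3D moment summaries.

    Values, from the scale-normalised central moments
    eta_pqr = mu_pqr / mu_000^(1 + (p+q+r)/3):

    1. J1 = eta200 + eta020 + eta002 (trace of the second-moment tensor)
    2. J2 = sum of its 2x2 principal minors
    3. J3 = its determinant
    J1-J3 are invariant to rotation (hence to axis permutation).
    4. sum of squared pure third-order moments (eta300, eta030, eta003)
    5. sum of squared mixed third-order moments with one repeated axis
    6. eta111 squared
    7. squared norm of the contracted third-order vector
       (eta300+eta120+eta102, eta210+eta030+eta012, eta201+eta021+eta003)
    8. squared norm of the complementary contraction with minus signs
       (eta300-eta120-eta102, ...)
    Values 4-8 are translation and scale invariant summaries of the
    third-order intensity distribution about the centre of mass.
    """
    arr = volume.data if isinstance(volume, ImageVolume) else np.asarray(volume)
    mu = _central_moments_3d(arr)
    m0 = mu[(0, 0, 0)]

    def eta(p: int, q: int, r: int) -> float:
        # index order mirrors (x, y, z) exponents
        return mu[(p, q, r)] / m0 ** (1 + (p + q + r) / 3.0)

    e200, e020, e002 = eta(2, 0, 0), eta(0, 2, 0), eta(0, 0, 2)
    e110, e101, e011 = eta(1, 1, 0), eta(1, 0, 1), eta(0, 1, 1)
    j1 = e200 + e020 + e002
    j2 = (e200 * e020 + e200 * e002 + e020 * e002
          - e110 ** 2 - e101 ** 2 - e011 ** 2)
    m2 = np.array([[e200, e110, e101],
                   [e110, e020, e011],
                   [e101, e011, e002]])
    j3 = float(np.linalg.det(m2))
    e300, e030, e003 = eta(3, 0, 0), eta(0, 3, 0), eta(0, 0, 3)
    e210, e201 = eta(2, 1, 0), eta(2, 0, 1)
    e120, e021 = eta(1, 2, 0), eta(0, 2, 1)
    e102, e012 = eta(1, 0, 2), eta(0, 1, 2)
    e111 = eta(1, 1, 1)
    b1 = e300 ** 2 + e030 ** 2 + e003 ** 2
    b2 = e210 ** 2 + e201 ** 2 + e120 ** 2 + e021 ** 2 + e102 ** 2 + e012 ** 2
    b3 = e111 ** 2
    v_plus = (e300 + e120 + e102, e210 + e030 + e012, e201 + e021 + e003)
    v_minus = (e300 - e120 - e102, e030 - e210 - e012, e003 - e201 - e021)
    b4 = sum(v ** 2 for v in v_plus)
    b5 = sum(v ** 2 for v in v_minus)
    return np.array([j1, j2, j3, b1, b2, b3, b4, b5])


# -------------------------------------------------------------- Zernike ----

def zernike_orders(count: int) -> List[Tuple[int, int]]:
    """First ``count`` (n, m) index pairs: n ascending, m >= 0, n-m even."""
    orders: List[Tuple[int, int]] = []
    n = 0
    while len(orders) < count:
        for m in range(n % 2, n + 1, 2):
            orders.append((n, m))
            if len(orders) == count:
                break
        n += 1
    return orders


def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for s in range((n - m) // 2 + 1):
        c = ((-1) ** s * factorial(n - s)
             / (factorial(s) * factorial((n + m) // 2 - s)
                * factorial((n - m) // 2 - s)))
        out += c * rho ** (n - 2 * s)
    return out


def zernike_moments(plane: np.ndarray, count: int = 20) -> np.ndarray:
    """Magnitudes |A_nm| of the first ``count`` Zernike moments.

    The image is mapped onto the unit disk centred on its intensity
    centroid, with radius the largest centroid-to-corner distance, so every
    pixel contributes.  Magnitudes are rotation invariant.
    """
    if count < 1:
        raise ArgumentError("count must be >= 1")
    plane = np.asarray(plane, dtype=float)
    total = plane.sum()
    if total <= 0:
        raise DegenerateInputError("zero total intensity")
    ys, xs = np.mgrid[0:plane.shape[0], 0:plane.shape[1]]
    xbar = (xs * plane).sum() / total
    ybar = (ys * plane).sum() / total
    corners = [(0, 0), (0, plane.shape[1] - 1),
               (plane.shape[0] - 1, 0),
               (plane.shape[0] - 1, plane.shape[1] - 1)]
    radius = max(np.hypot(cx - xbar, cy - ybar) for cy, cx in corners)
    radius = max(radius, 1.0)
    u = (xs - xbar) / radius
    v = (ys - ybar) / radius
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    inside = rho <= 1.0
    f = plane * inside / total  # mass-normalised so magnitudes are unitless
    out = np.empty(count)
    for i, (n, m) in enumerate(zernike_orders(count)):
        rad = _radial_poly(n, m, rho)
        basis = rad * np.exp(-1j * m * theta) * inside
        a = (n + 1) / np.pi * np.sum(f * basis)
        out[i] = abs(a)
    return out
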
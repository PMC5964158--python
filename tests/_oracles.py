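"""Independent oracles used by the test suite.

Everything here is deliberately implemented from first principles, separately
from the package code paths it checks: a Legendre-series solution for layered
spherical conductors, a naive point-to-triangle projection, and small
Monte-Carlo reference simulations.
"""

from __future__ import annotations

import numpy as np
from scipy.special import eval_legendre


# ---------------------------------------------------------------------------
# Concentric-shell conductor: analytic series solution
# ---------------------------------------------------------------------------

def cap_coefficients(n_max: int, theta0: float, current: float, R_m: float):
    """Legendre coefficients of the inward current density of a uniform
    spherical-cap electrode of half-angle ``theta0`` carrying ``current``."""
    x0 = np.cos(theta0)
    J0 = current / (2 * np.pi * R_m**2 * (1 - x0))
    ns = np.arange(n_max + 1)
    Pm1 = np.array([eval_legendre(n - 1, x0) if n >= 1 else 1.0 for n in ns])
    Pp1 = np.array([eval_legendre(n + 1, x0) for n in ns])
    return J0 * (Pm1 - Pp1) / 2.0


def shell_potential(
    points_m: np.ndarray,
    radii_m: np.ndarray,
    sigmas: np.ndarray,
    elec_dirs: list,
    currents_a: list,
    theta0: float,
    n_max: int = 250,
) -> np.ndarray:
    """Potential (V) at points inside a concentric layered sphere driven by
    cap electrodes on the outer surface.

    Per harmonic n the radial solution in layer j is A_j x^n + B_j x^-(n+1)
    (x = r/R for conditioning, B innermost = 0) with continuity of V and of
    sigma dV/dr at interfaces and the cap current density at the surface.
    """
    radii_m = np.asarray(radii_m, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    nl = len(radii_m)
    R = radii_m[-1]
    x_b = radii_m / R
    pts = np.asarray(points_m, dtype=float)
    r = np.linalg.norm(pts, axis=1)
    x = r / R
    layer = np.clip(np.searchsorted(radii_m, r - 1e-12), 0, nl - 1)
    coeffs = cap_coefficients(n_max, theta0, 1.0, R)

    AB = np.zeros((n_max + 1, nl, 2))
    for n in range(1, n_max + 1):
        m = np.zeros((2 * nl - 1, 2 * nl - 1))
        rhs = np.zeros(2 * nl - 1)

        def col(j, which):
            return j if which == 0 else nl + j - 1

        row = 0
        for j in range(nl - 1):
            xb = x_b[j]
            m[row, col(j, 0)] += xb**n
            if j > 0:
                m[row, col(j, 1)] += xb ** -(n + 1)
            m[row, col(j + 1, 0)] -= xb**n
            m[row, col(j + 1, 1)] -= xb ** -(n + 1)
            row += 1
            m[row, col(j, 0)] += sigmas[j] * n * xb ** (n - 1)
            if j > 0:
                m[row, col(j, 1)] += -sigmas[j] * (n + 1) * xb ** -(n + 2)
            m[row, col(j + 1, 0)] -= sigmas[j + 1] * n * xb ** (n - 1)
            m[row, col(j + 1, 1)] -= -sigmas[j + 1] * (n + 1) * xb ** -(n + 2)
            row += 1
        m[row, col(nl - 1, 0)] = sigmas[-1] * n / R
        m[row, col(nl - 1, 1)] = -sigmas[-1] * (n + 1) / R
        rhs[row] = coeffs[n]
        sol = np.linalg.solve(m, rhs)
        for j in range(nl):
            AB[n, j, 0] = sol[col(j, 0)]
            AB[n, j, 1] = 0.0 if j == 0 else sol[col(j, 1)]

    V = np.zeros(len(pts))
    safe_x = np.where(x == 0, 1.0, x)
    safe_r = np.where(r == 0, 1.0, r)
    for d, current in zip(elec_dirs, currents_a):
        cosg = np.clip(pts @ np.asarray(d, dtype=float) / safe_r, -1.0, 1.0)
        for n in range(1, n_max + 1):
            A = AB[n, layer, 0]
            B = AB[n, layer, 1]
            V += current * (A * x**n + B * safe_x ** -(n + 1)) * eval_legendre(n, cosg)
    return V


# ---------------------------------------------------------------------------
# Naive nearest-point-on-triangle projection
# ---------------------------------------------------------------------------

def _closest_on_segment(p, a, b):
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
    return a + t * ab


def naive_closest_on_triangle(p, a, b, c):
    """Candidate-enumeration closest point: plane foot if its barycentric
    coordinates are all nonnegative, else the best of the three edges."""
    n = np.cross(b - a, c - a)
    nn = np.dot(n, n)
    candidates = []
    if nn > 0:
        foot = p - np.dot(p - a, n) / nn * n
        # barycentric test
        v0, v1, v2 = b - a, c - a, foot - a
        d00, d01, d11 = np.dot(v0, v0), np.dot(v0, v1), np.dot(v1, v1)
        d20, d21 = np.dot(v2, v0), np.dot(v2, v1)
        denom = d00 * d11 - d01 * d01
        if denom != 0:
            v = (d11 * d20 - d01 * d21) / denom
            w = (d00 * d21 - d01 * d20) / denom
            if v >= 0 and w >= 0 and v + w <= 1:
                candidates.append(foot)
    candidates.append(_closest_on_segment(p, a, b))
    candidates.append(_closest_on_segment(p, a, c))
    candidates.append(_closest_on_segment(p, b, c))
    d2 = [np.dot(p - q, p - q) for q in candidates]
    return candidates[int(np.argmin(d2))]


def naive_closest_on_surface(vertices, triangles, p):
    """Exhaustive search over every triangle; returns (point, distance).

    Vectorised candidate enumeration: for each triangle take the orthogonal
    plane foot (if it lands inside, by barycentric test) and the clamped
    projections onto all three edges, then take the global minimum.  Same
    answer as a per-triangle loop of :func:`naive_closest_on_triangle`.
    """
    a = vertices[triangles[:, 0]]
    b = vertices[triangles[:, 1]]
    c = vertices[triangles[:, 2]]

    def seg(p, u, v):
        uv = v - u
        t = np.einsum("ij,ij->i", p - u, uv) / np.einsum("ij,ij->i", uv, uv)
        return u + np.clip(t, 0.0, 1.0)[:, None] * uv

    P = np.broadcast_to(p, a.shape)
    n = np.cross(b - a, c - a)
    nn = np.einsum("ij,ij->i", n, n)
    nn_safe = np.where(nn == 0, 1.0, nn)
    foot = P - (np.einsum("ij,ij->i", P - a, n) / nn_safe)[:, None] * n
    v0, v1, v2 = b - a, c - a, foot - a
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d20 = np.einsum("ij,ij->i", v2, v0)
    d21 = np.einsum("ij,ij->i", v2, v1)
    denom = d00 * d11 - d01 * d01
    denom_safe = np.where(denom == 0, 1.0, denom)
    vv = (d11 * d20 - d01 * d21) / denom_safe
    ww = (d00 * d21 - d01 * d20) / denom_safe
    inside = (vv >= 0) & (ww >= 0) & (vv + ww <= 1) & (denom != 0) & (nn != 0)

    candidates = [seg(P, a, b), seg(P, a, c), seg(P, b, c)]
    best = candidates[0]
    best_d2 = np.einsum("ij,ij->i", best - P, best - P)
    for cand in candidates[1:]:
        d2 = np.einsum("ij,ij->i", cand - P, cand - P)
        better = d2 < best_d2
        best = np.where(better[:, None], cand, best)
        best_d2 = np.where(better, d2, best_d2)
    foot_d2 = np.einsum("ij,ij->i", foot - P, foot - P)
    use_foot = inside & (foot_d2 < best_d2)
    best = np.where(use_foot[:, None], foot, best)
    best_d2 = np.where(use_foot, foot_d2, best_d2)

    k = int(np.argmin(best_d2))
    return best[k], float(np.sqrt(best_d2[k]))


# ---------------------------------------------------------------------------
# Monte-Carlo positioning-error oracle
# ---------------------------------------------------------------------------

def mc_nearest_distance_to_line(
    sigma: float, spacing_mm: float, n_draws: int = 100_000, seed: int = 12345
) -> float:
    """Mean nearest-point distance from N(0, sigma^2 I3)-perturbed points to a
    straight reference polyline sampled every ``spacing_mm``."""
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=(n_draws, 3))
    # true point uniform within a sampling cell along the line (x axis)
    x0 = rng.uniform(0.0, spacing_mm, size=n_draws)
    x = x0 + noise[:, 0]
    k = np.round(x / spacing_mm)
    dx = x - k * spacing_mm
    return float(np.mean(np.sqrt(dx**2 + noise[:, 1] ** 2 + noise[:, 2] ** 2)))
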
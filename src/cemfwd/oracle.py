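"""Closed-form surface potential of a current dipole in a homogeneous,
electrically insulated conducting sphere.

Independent of the finite-element code path; used to validate the forward
solvers.  Derivation: expand the infinite-medium dipole potential in Legendre
harmonics about the sphere center and add the interior harmonic series that
cancels the normal current on the surface.  For a dipole with moment m (A*m)
at distance b from the center of a sphere of radius R and conductivity sigma,
the surface potential at a point with unit direction rhat is

    u = 1/(4 pi sigma R^2) * sum_{n>=1} (2n+1)/n * (b/R)^(n-1)
        * [ n m_r P_n(c) + (m_t . rhat) P_n'(c) ],

where c = rhat . zhat (zhat the dipole-position direction), m_r = m . zhat
and m_t = m - m_r zhat.  The n = 1 term alone reproduces the classical
center-dipole result u = 3 m.rhat / (4 pi sigma R^2).
"""

from __future__ import annotations

import numpy as np

from .exceptions import ValidationError


def dipole_potential_insulated_sphere(
    obs_points: np.ndarray,
    dipole_pos: np.ndarray,
    dipole_moment: np.ndarray,
    sigma: float,
    radius: float,
    tol: float = 1e-12,
    max_terms: int = 4000,
) -> np.ndarray:
    """Surface potential (volts) at ``obs_points`` on the sphere of
    ``radius`` for a dipole of ``dipole_moment`` (A*m) at ``dipole_pos``.

    Observation points are radially projected onto the sphere surface.  The
    Legendre series is summed until the term bound (2n+1)/n t^(n-1) (n + 1)
    falls below ``tol`` relative to the accumulated scale.
    """
    obs = np.asarray(obs_points, dtype=float)
    r0 = np.asarray(dipole_pos, dtype=float)
    m = np.asarray(dipole_moment, dtype=float)
    if sigma <= 0 or radius <= 0:
        raise ValidationError("sigma and radius must be positive")
    b = np.linalg.norm(r0)
    if b >= radius:
        raise ValidationError("dipole must lie strictly inside the sphere")
    t = b / radius

    if b > 0:
        zhat = r0 / b
    else:
        zhat = np.array([0.0, 0.0, 1.0])
    m_r = float(m @ zhat)
    m_t = m - m_r * zhat

    rhat = obs / np.linalg.norm(obs, axis=-1, keepdims=True)
    c = np.clip(rhat @ zhat, -1.0, 1.0)
    mt_dot = rhat @ m_t

    # Legendre recurrences: P_n and P_n' via d/dx P_n = x P'_{n-1} + n P_{n-1}
    p_prev = np.ones_like(c)  # P_0
    p_cur = c.copy()  # P_1
    dp_prev = np.zeros_like(c)  # P_0'
    dp_cur = np.ones_like(c)  # P_1'

    u = np.zeros_like(c)
    tn = 1.0  # t^(n-1)
    n = 1
    while n <= max_terms:
        coef = (2 * n + 1) / n * tn
        u += coef * (n * m_r * p_cur + mt_dot * dp_cur)
        # term bound: |P_n| <= 1, |P_n'| <= n(n+1)/2
        if n > 10 and coef * (n + n * (n + 1) / 2) < tol:
            break
        n += 1
        tn *= t
        if tn == 0.0:
            break
        p_next = ((2 * n - 1) * c * p_cur - (n - 1) * p_prev) / n
        dp_next = c * dp_cur + n * p_cur
        p_prev, p_cur = p_cur, p_next
        dp_prev, dp_cur = dp_cur, dp_next

    return u / (4.0 * np.pi * sigma * radius**2)
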
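"""Forward-difference and localization-difference measures.

RDM (relative difference measure, %) compares the topographies of two
voltage patterns after normalization and ranges over [0, 200]; MAG
(magnitude measure, %) is the relative norm ratio minus 100.  For dipole
estimates, PD is the Euclidean position difference (mm), AD the angle
between moments (degrees) and ND the depth difference true-minus-estimate
(mm), so positive ND means the estimate lies deeper than the truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import UndefinedMeasureError, ValidationError


def _check_nonzero(u, name):
    u = np.asarray(u, dtype=float)
    if not np.any(u):
        raise UndefinedMeasureError(f"{name} is the zero vector")
    return u


def rdm(u1, u2) -> float:
    """100 * || u1/||u1|| - u2/||u2|| ||_2; symmetric, scale-invariant."""
    u1 = _check_nonzero(u1, "u1")
    u2 = _check_nonzero(u2, "u2")
    return 100.0 * float(
        np.linalg.norm(u1 / np.linalg.norm(u1) - u2 / np.linalg.norm(u2))
    )


def mag(u1, u2) -> float:
    """100 * ||u2|| / ||u1|| - 100; zero when magnitudes agree."""
    u1 = _check_nonzero(u1, "u1")
    u2 = np.asarray(u2, dtype=float)
    return 100.0 * float(np.linalg.norm(u2) / np.linalg.norm(u1)) - 100.0


def pd(r_true, r_est) -> float:
    """Position difference ||r_true - r_est|| in mm (inputs in meters)."""
    return 1e3 * float(np.linalg.norm(np.asarray(r_true) - np.asarray(r_est)))


def ad(q_true, q_est) -> float:
    """Angular difference between moments in degrees; scale-invariant."""
    q1 = np.asarray(q_true, dtype=float)
    q2 = np.asarray(q_est, dtype=float)
    n1, n2 = np.linalg.norm(q1), np.linalg.norm(q2)
    if n1 == 0 or n2 == 0:
        raise UndefinedMeasureError("zero moment has no direction")
    c = np.clip(q1 @ q2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def nd(r_true, r_est) -> float:
    """Norm (depth) difference ||r_true|| - ||r_est|| in mm.

    Positive when the estimate sits deeper (closer to the head center) than
    the true source; the complementary depth bias is -nd."""
    return 1e3 * float(
        np.linalg.norm(np.asarray(r_true)) - np.linalg.norm(np.asarray(r_est))
    )


@dataclass(frozen=True)
class BoxplotSummary:
    """Median, interquartile range and extremes of a sample."""

    median: float
    iqr_low: float
    iqr_high: float
    minimum: float
    maximum: float


def boxplot_summary(values) -> BoxplotSummary:
    """Five-number summary; quartiles use linear interpolation between order
    statistics."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValidationError("empty sample")
    q1, med, q3 = np.percentile(v, [25.0, 50.0, 75.0], method="linear")
    return BoxplotSummary(float(med), float(q1), float(q3), float(v.min()), float(v.max()))
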